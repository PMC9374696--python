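"""Over-representation analysis of DEGs within annotation terms.

One-sided Fisher's exact test (hypergeometric upper tail) per term,
followed by the two-branch selection rule: a term is reported when its
p-value is <= 0.1, or when 0.1 < p < 0.5 and more than half of the term's
genes are DEGs.  Raw p-values are used throughout; no multiple-testing
correction enters the selection.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Iterable, Mapping, Set

import pandas as pd
from scipy.stats import hypergeom


@dataclasses.dataclass
class AnnotationMap:
    """term_id -> gene set, with optional human-readable term names."""

    terms: dict[str, frozenset]
    names: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [t for t, genes in self.terms.items() if not genes]
        if empty:
            warnings.warn(f"dropping {len(empty)} empty terms: {empty[:5]}")
            self.terms = {t: g for t, g in self.terms.items() if g}

    @property
    def annotated_genes(self) -> frozenset:
        out: set = set()
        for genes in self.terms.values():
            out |= genes
        return frozenset(out)


def read_annotations(path) -> AnnotationMap:
    """Read a GAF-lite TSV: term_id <TAB> gene_id [<TAB> term name]."""
    terms: dict[str, set] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed annotation line: {line!r}")
            term, gene = parts[0], parts[1]
            terms.setdefault(term, set()).add(gene)
            if len(parts) > 2 and parts[2]:
                names[term] = parts[2]
    return AnnotationMap(
        terms={t: frozenset(g) for t, g in terms.items()}, names=names
    )


def fisher_enrichment(term_genes: Set, deg_genes: Set, background: Set) -> float:
    """One-sided over-representation p-value for one term.

    Probability, under the hypergeometric null with the observed margins,
    of drawing at least the observed number of DEGs into the term.
    """
    if not background:
        raise ValueError("background gene universe is empty")
    for label, genes in (("term", term_genes), ("DEG", deg_genes)):
        outside = set(genes) - set(background)
        if outside:
            raise ValueError(
                f"{label} gene {sorted(outside)[0]!r} is outside the background"
            )
    n_bg = len(background)
    n_deg = len(deg_genes)
    n_term = len(term_genes)
    k = len(set(term_genes) & set(deg_genes))
    p = float(hypergeom.sf(k - 1, n_bg, n_deg, n_term))
    return min(p, 1.0)


def enrich_table(
    deg_genes: Set,
    annotations: AnnotationMap,
    background: Set,
) -> pd.DataFrame:
    """Per-term enrichment records for DEGs against a background universe.

    Terms are restricted to the background; genes annotated outside it
    raise.  Use :func:`select_terms` to apply the reporting rule.
    """
    deg_genes = set(deg_genes) & set(background)
    rows = []
    for term, genes in sorted(annotations.terms.items()):
        p = fisher_enrichment(genes, deg_genes, background)
        n_in = len(genes & deg_genes)
        rows.append(
            {
                "term_id": term,
                "term_name": annotations.names.get(term, ""),
                "n_term": len(genes),
                "n_deg_in_term": n_in,
                "n_deg_total": len(deg_genes),
                "n_background": len(background),
                "fisher_p": p,
                "deg_fraction": n_in / len(genes),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "term_id",
            "term_name",
            "n_term",
            "n_deg_in_term",
            "n_deg_total",
            "n_background",
            "fisher_p",
            "deg_fraction",
        ],
    )


def select_terms(records: pd.DataFrame) -> pd.DataFrame:
    """Apply the two-branch term-selection rule and sort for reporting.

    Branch 1: fisher_p <= 0.1.  Branch 2 (borderline-majority): 0.1 <
    fisher_p < 0.5 and more than 50% of the term's genes are DEGs.
    Output sorted by (selected desc, fisher_p asc, term_id).  Idempotent.
    """
    out = records.copy()
    p = out["fisher_p"]
    frac = out["deg_fraction"]
    primary = p <= 0.1
    borderline = (p > 0.1) & (p < 0.5) & (frac > 0.5)
    out["selected"] = primary | borderline
    out["selection_branch"] = "none"
    out.loc[borderline, "selection_branch"] = "borderline_majority"
    out.loc[primary, "selection_branch"] = "p_le_0.1"
    return out.sort_values(
        ["selected", "fisher_p", "term_id"], ascending=[False, True, True]
    ).reset_index(drop=True)
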