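"""Summary artifacts: index scatters, phase-sorted heatmaps, gene panels.

Every artifact is emitted as a TSV data table; image files are optional
companions rendered from the same table, so tests and downstream use rest
on the deterministic data, never on pixels.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, TimeCourse, write_table
from .rhythm import _replicate_values, _zscore_rows


@dataclasses.dataclass
class HeatmapMatrix:
    """Z-normalized replicate-mean courses, rows sorted by ascending peak time."""

    gene_ids: list[str]
    times_h: np.ndarray
    values: np.ndarray  # (n_genes, n_times), each row mean 0 / SD 1
    peak_times_h: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, columns=[f"LL{t:g}" for t in self.times_h]
        )
        df.insert(0, "gene_id", self.gene_ids)
        df.insert(1, "peak_time_h", self.peak_times_h)
        return df


def replicate_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Conservative per-gene pair: min amplitude, max p over replicates.

    Thresholding this pair (amplitude > 0.1 and p < 0.1) is exactly the
    per-replicate AND rule, so the cycling region of an amplitude/p
    scatter built from it is the set of called genes.
    """
    amp_cols = [c for c in records.columns if c.startswith("amplitude_rep")]
    p_cols = [c for c in records.columns if c.startswith("pvalue_rep")]
    if not amp_cols or not p_cols:
        raise ValueError("records carry no per-replicate amplitude/pvalue columns")
    return pd.DataFrame(
        {
            "gene_id": records["gene_id"],
            "summary_amplitude": records[amp_cols].min(axis=1),
            "summary_pvalue": records[p_cols].max(axis=1),
        }
    )


def zscore_row(tc_mean) -> np.ndarray:
    """(v - mean)/SD with the population SD; raises on a constant row."""
    values = np.asarray(getattr(tc_mean, "values", tc_mean), dtype=float)
    sd = values.std()
    if sd == 0:
        raise ValueError("constant time course cannot be z-normalized")
    return (values - values.mean()) / sd


def replicate_mean_course(
    matrix: ExpressionMatrix, condition: str
) -> tuple[np.ndarray, pd.DataFrame]:
    """(times, genes x times DataFrame) of the replicate-mean course."""
    reps = matrix.replicates_for(condition)
    times0 = None
    stacks = []
    for rep in reps:
        times, vals = _replicate_values(matrix, condition, rep)
        if times0 is None:
            times0 = times
        elif not np.allclose(times, times0):
            raise ValueError("replicates have differing time grids")
        stacks.append(vals)
    mean = np.mean(stacks, axis=0)
    return times0, pd.DataFrame(mean, index=matrix.gene_ids)


def heatmap_order(
    records: pd.DataFrame,
    matrix: ExpressionMatrix,
    condition: str,
    gene_subset,
) -> HeatmapMatrix:
    """Phase-sorted heatmap rows for a gene subset (usually the cycling set).

    Rows are z-normalized replicate means sorted by ascending peak time,
    ties broken by gene id; constant rows are excluded with a warning.
    """
    subset = list(gene_subset)
    unknown = [g for g in subset if g not in matrix.values.index]
    if unknown:
        raise ValueError(f"gene {unknown[0]!r} not in matrix")
    if not subset:
        warnings.warn("empty gene subset: empty heatmap")
        return HeatmapMatrix([], np.array([]), np.empty((0, 0)), np.array([]))

    times, mean = replicate_mean_course(matrix, condition)
    peaks = records.set_index("gene_id")["peak_time_h"]
    rows = []
    for g in subset:
        vals = mean.loc[g].to_numpy()
        if vals.std() == 0:
            warnings.warn(f"gene {g!r}: constant course excluded from heatmap")
            continue
        rows.append((float(peaks[g]), g, zscore_row(vals)))
    rows.sort(key=lambda r: (r[0], r[1]))
    if not rows:
        return HeatmapMatrix([], times, np.empty((0, times.size)), np.array([]))
    return HeatmapMatrix(
        gene_ids=[g for _, g, _ in rows],
        times_h=times,
        values=np.vstack([z for _, _, z in rows]),
        peak_times_h=np.array([p for p, _, _ in rows]),
    )


def cycling_overlap_counts(
    records_low: pd.DataFrame, records_high: pd.DataFrame
) -> dict[str, int]:
    """Counts of cycling genes in low only / high only / both conditions."""
    low = set(records_low.loc[records_low["is_cycling"], "gene_id"])
    high = set(records_high.loc[records_high["is_cycling"], "gene_id"])
    return {
        "cycling_low_only": len(low - high),
        "cycling_high_only": len(high - low),
        "cycling_both": len(low & high),
    }


def gene_panel_table(matrix: ExpressionMatrix, gene_id: str) -> pd.DataFrame:
    """Long-format TPM trace of one gene across conditions and replicates."""
    rows = []
    for s in matrix.samples:
        rows.append(
            {
                "gene_id": gene_id,
                "condition": s.condition,
                "replicate": s.replicate,
                "time_ll_h": s.time_ll_h,
                "tpm": float(matrix.values.loc[gene_id, s.sample_id]),
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["condition", "replicate", "time_ll_h"])
        .reset_index(drop=True)
    )


def write_report(
    records: pd.DataFrame,
    matrix: ExpressionMatrix,
    condition: str,
    out_dir,
    gene_list=None,
    make_plots: bool = True,
) -> dict[str, Path]:
    """Emit scatter, heatmap and per-gene panel tables (plus PNG companions).

    Returns the paths written, keyed by artifact name.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    scatter = replicate_summary(records).merge(
        records[["gene_id", "peak_time_h", "is_cycling"]], on="gene_id"
    )
    paths["scatter"] = out_dir / f"scatter_{condition}.tsv"
    write_table(scatter, paths["scatter"])

    cycling_genes = records.loc[records["is_cycling"], "gene_id"].tolist()
    hm = heatmap_order(records, matrix, condition, cycling_genes)
    paths["heatmap"] = out_dir / f"heatmap_{condition}.tsv"
    write_table(hm.to_frame(), paths["heatmap"])

    for g in gene_list or []:
        p = out_dir / f"panel_{g}.tsv"
        write_table(gene_panel_table(matrix, g), p)
        paths[f"panel_{g}"] = p

    if make_plots:
        paths.update(_render_plots(scatter, hm, condition, out_dir))
    return paths


def _render_plots(scatter: pd.DataFrame, hm: HeatmapMatrix, condition, out_dir) -> dict:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = {}
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(
        scatter["summary_pvalue"],
        scatter["summary_amplitude"],
        s=6,
        c=np.where(scatter["is_cycling"], "tab:orange", "tab:gray"),
    )
    ax.axhline(0.1, ls="--", lw=0.8, c="k")
    ax.axvline(0.1, ls="--", lw=0.8, c="k")
    ax.set_xlabel("correlation p-value (max over replicates)")
    ax.set_ylabel("amplitude (min over replicates)")
    ax.set_title(condition)
    paths["scatter_png"] = Path(out_dir) / f"scatter_{condition}.png"
    fig.savefig(paths["scatter_png"], dpi=120, bbox_inches="tight")
    plt.close(fig)

    if hm.values.size:
        fig, ax = plt.subplots(figsize=(4, max(2, 0.08 * len(hm.gene_ids))))
        ax.imshow(hm.values, aspect="auto", cmap="RdBu_r", vmin=-2, vmax=2)
        ax.set_xticks(range(hm.times_h.size))
        ax.set_xticklabels([f"{t:g}" for t in hm.times_h])
        ax.set_xlabel("hours in LL")
        ax.set_yticks([])
        ax.set_title(f"{condition}: rows by ascending peak time")
        paths["heatmap_png"] = Path(out_dir) / f"heatmap_{condition}.png"
        fig.savefig(paths["heatmap_png"], dpi=120, bbox_inches="tight")
        plt.close(fig)
    return paths
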