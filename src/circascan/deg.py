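"""Fold-change differential expression between salt conditions.

DEGs are called from condition means taken over a circadian-controlled
window (LL 16, 22, 28 and 34 by default) across all replicates — eight
values per condition in the two-replicate study design — so transcript
changes driven by the endogenous clock average out.  The criterion is
purely fold-change based: |log2 FC| >= 1 marks a DEG, |log2 FC| >= 2 the
"highly" changed tier.  No dispersion model or p-value is involved.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

CATEGORIES = ("up_high", "up", "unchanged", "down", "down_high", "undefined_zero")


@dataclasses.dataclass(frozen=True)
class DEGParams:
    """Window, thresholds and pseudocount for fold-change DEG calling."""

    window_times_h: tuple = (16.0, 22.0, 28.0, 34.0)
    up_threshold_fc: float = 2.0
    down_threshold_fc: float = 0.5
    high_tier_log2: float = 2.0
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        if not self.window_times_h:
            raise ValueError("window_times_h must be non-empty")
        if self.up_threshold_fc <= 0 or self.down_threshold_fc <= 0:
            raise ValueError("fold-change thresholds must be positive")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")

    @property
    def up_log2(self) -> float:
        return math.log2(self.up_threshold_fc)

    @property
    def down_log2(self) -> float:
        return math.log2(self.down_threshold_fc)


def condition_means(
    matrix: ExpressionMatrix, params: DEGParams | None = None
) -> pd.DataFrame:
    """Per-gene mean TPM over the window samples of each condition.

    The mean is flat over all (replicate x window-time) samples of the
    condition: the divisor is 8 in the 2-replicate / 4-time design.
    Raises if any replicate of either condition lacks a window time.
    """
    params = params or DEGParams()
    window = set(float(t) for t in params.window_times_h)
    out = pd.DataFrame({"gene_id": matrix.gene_ids})
    for condition, col in (("low_salt", "mean_low"), ("high_salt", "mean_high")):
        missing = []
        for rep in matrix.replicates_for(condition):
            have = {s.time_ll_h for s in matrix.samples_for(condition, rep)}
            missing += [
                f"{condition} replicate {rep} time {t}" for t in sorted(window - have)
            ]
        if missing:
            raise ValueError("missing window samples: " + "; ".join(missing))
        sids = [
            s.sample_id
            for s in matrix.samples_for(condition)
            if s.time_ll_h in window
        ]
        if not sids:
            raise ValueError(f"no samples for condition {condition!r}")
        out[col] = matrix.values[sids].mean(axis=1).to_numpy()
    return out


def log2_fold_change(mean_high: float, mean_low: float, pseudocount: float = 0.0) -> float:
    """log2((high + pc) / (low + pc)); +/-inf when one side is zero at pc = 0.

    Returns NaN when both means are zero (the ``undefined_zero`` flag).
    """
    if mean_high < 0 or mean_low < 0:
        raise ValueError("condition means must be non-negative")
    h, lo = mean_high + pseudocount, mean_low + pseudocount
    if h == 0 and lo == 0:
        return math.nan
    if lo == 0:
        return math.inf
    if h == 0:
        return -math.inf
    return math.log2(h / lo)


def categorize(log2fc: float, params: DEGParams | None = None) -> str:
    """Tier a log2 fold change; boundaries are inclusive (>= 1, >= 2)."""
    params = params or DEGParams()
    if math.isnan(log2fc):
        return "undefined_zero"
    if log2fc >= params.high_tier_log2:
        return "up_high"
    if log2fc >= params.up_log2:
        return "up"
    if log2fc <= -params.high_tier_log2:
        return "down_high"
    if log2fc <= params.down_log2:
        return "down"
    return "unchanged"


def deg_table(matrix: ExpressionMatrix, params: DEGParams | None = None) -> pd.DataFrame:
    """One DEG record per gene: condition means, log2 FC and tier."""
    params = params or DEGParams()
    out = condition_means(matrix, params)
    out["log2fc"] = [
        log2_fold_change(h, lo, params.pseudocount)
        for h, lo in zip(out["mean_high"], out["mean_low"])
    ]
    out["category"] = [categorize(x, params) for x in out["log2fc"]]
    return out


def category_counts(table: pd.DataFrame) -> dict[str, int]:
    """Gene counts per tier, all categories present (zero-filled)."""
    counts = table["category"].value_counts().to_dict()
    return {c: int(counts.get(c, 0)) for c in CATEGORIES}
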