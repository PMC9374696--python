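"""Synthetic expression matrices with the structure the analysis assumes.

The generator emulates the study design: ~3843 genes sampled at LL 4, 10,
16, 22, 28 and 34 h in two conditions x two replicates, a minority of
genes carrying a planted 24-h cosine with condition-dependent prevalence
and phase mode, condition-dependent fold changes, and multiplicative
log-normal noise.  Gene g, condition c, replicate r, time t:

    value = B_g * F_gc * (1 + A_gc * cos(2*pi*(t - phi_gc)/24)) * eps

with log-normal baseline B, condition factor F from the planted log2 FC,
planted relative amplitude A (0 for arrhythmic genes), and eps log-normal
with mean 1 and CV = ``noise_cv``, independent across samples.  A truth
table accompanies every matrix so detection and DEG calls can be scored
against planted ground truth.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from . import deg as _deg
from .io import ExpressionMatrix, SampleMeta

PHASE_MODES = ("uniform_0_24", "fixed_peak_16")


@dataclasses.dataclass(frozen=True)
class SimParams:
    """Study-design parameters of the synthetic generator.

    Defaults mirror the emulated design: 3843 genes, six LL times, two
    replicates, cycling prevalence ~1.3% under low salt and ~5.7% under
    high salt with one shared cycling gene, widely distributed phases
    under low salt versus a common LL16 peak under high salt, and planted
    up/down fold changes at log2 FC = 2 for ~36% / ~12% of genes.
    """

    n_genes: int = 3843
    times_h: tuple = (4.0, 10.0, 16.0, 22.0, 28.0, 34.0)
    n_replicates: int = 2
    conditions: tuple = ("low_salt", "high_salt")
    frac_cycling_low: float = 51 / 3843
    frac_cycling_high: float = 218 / 3843
    n_cycling_shared: int = 1
    amplitude_range: tuple = (0.15, 0.6)
    phase_distribution_low: str = "uniform_0_24"
    phase_distribution_high: str = "fixed_peak_16"
    baseline_log10_tpm_mean: float = 1.5
    baseline_log10_tpm_sd: float = 0.6
    noise_cv: float = 0.1
    frac_up: float = 1368 / 3843
    frac_down: float = 446 / 3843
    effect_log2fc: float = 2.0
    period_h: float = 24.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_cycling_low", "frac_cycling_high", "frac_up", "frac_down"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_up + self.frac_down > 1:
            raise ValueError("frac_up + frac_down exceeds 1")
        lo, hi = self.amplitude_range
        if not (0 < lo <= hi < 1):
            raise ValueError("amplitude_range must lie inside (0, 1)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        for mode in (self.phase_distribution_low, self.phase_distribution_high):
            if mode not in PHASE_MODES:
                raise ValueError(f"unknown phase mode {mode!r}")
        n_low = round(self.frac_cycling_low * self.n_genes)
        n_high = round(self.frac_cycling_high * self.n_genes)
        shared = min(self.n_cycling_shared, n_low, n_high)
        if n_low + n_high - shared > self.n_genes:
            raise ValueError("cycling fractions are jointly infeasible")


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative noise: log-normal with mean exactly 1 and CV = cv."""
    if cv == 0:
        return np.ones(shape)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=shape)


def _planted_phases(
    rng: np.random.Generator, mode: str, n: int, period_h: float
) -> np.ndarray:
    if mode == "uniform_0_24":
        return rng.uniform(0.0, period_h, size=n)
    return np.full(n, 16.0)


def simulate(params: SimParams | None = None) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate one expression matrix plus its planted-truth table.

    The truth table has one row per gene: per-condition cycling flag,
    planted relative amplitude and peak hour, plus the planted log2 fold
    change (high vs low) and its fold-change tier.
    """
    params = params or SimParams()
    rng = np.random.default_rng(params.seed)
    n = params.n_genes
    width = max(4, len(str(n)))
    gene_ids = [f"G{i:0{width}d}" for i in range(1, n + 1)]
    times = np.asarray(params.times_h, dtype=float)

    baseline = 10.0 ** rng.normal(
        params.baseline_log10_tpm_mean, params.baseline_log10_tpm_sd, size=n
    )

    # planted cycling sets with controlled overlap between conditions
    n_low = round(params.frac_cycling_low * n)
    n_high = round(params.frac_cycling_high * n)
    shared = min(params.n_cycling_shared, n_low, n_high)
    perm = rng.permutation(n)
    shared_idx = perm[:shared]
    low_idx = np.concatenate([shared_idx, perm[shared : shared + n_low - shared]])
    high_idx = np.concatenate(
        [shared_idx, perm[shared + n_low - shared : n_low + n_high - shared]]
    )

    cycling = {c: np.zeros(n, dtype=bool) for c in ("low_salt", "high_salt")}
    cycling["low_salt"][low_idx] = True
    cycling["high_salt"][high_idx] = True
    amp = {c: np.zeros(n) for c in ("low_salt", "high_salt")}
    phase = {c: np.full(n, np.nan) for c in ("low_salt", "high_salt")}
    lo_a, hi_a = params.amplitude_range
    for cond, idx, mode in (
        ("low_salt", low_idx, params.phase_distribution_low),
        ("high_salt", high_idx, params.phase_distribution_high),
    ):
        amp[cond][idx] = rng.uniform(lo_a, hi_a, size=idx.size)
        phase[cond][idx] = _planted_phases(rng, mode, idx.size, params.period_h)

    # planted condition effects, disjoint up/down sets
    n_up = round(params.frac_up * n)
    n_down = round(params.frac_down * n)
    perm2 = rng.permutation(n)
    log2fc = np.zeros(n)
    log2fc[perm2[:n_up]] = params.effect_log2fc
    log2fc[perm2[n_up : n_up + n_down]] = -params.effect_log2fc
    factor = {"low_salt": np.ones(n), "high_salt": 2.0**log2fc}

    columns: dict[str, np.ndarray] = {}
    samples: list[SampleMeta] = []
    for cond in params.conditions:
        wave = np.ones((n, times.size))
        planted = cycling[cond]
        if planted.any():
            wave[planted] = 1.0 + amp[cond][planted, None] * np.cos(
                2
                * np.pi
                * (times[None, :] - phase[cond][planted, None])
                / params.period_h
            )
        clean = baseline[:, None] * factor[cond][:, None] * wave
        for rep in range(1, params.n_replicates + 1):
            eps = _lognormal_noise(rng, params.noise_cv, (n, times.size))
            vals = clean * eps
            for j, t in enumerate(times):
                sid = f"{cond}_r{rep}_t{t:04.1f}"
                samples.append(
                    SampleMeta(
                        sample_id=sid, condition=cond, replicate=rep, time_ll_h=float(t)
                    )
                )
                columns[sid] = vals[:, j]

    values = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
    matrix = ExpressionMatrix(values=values, samples=samples)

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "is_cycling_low": cycling["low_salt"],
            "true_amplitude_low": amp["low_salt"],
            "true_peak_low_h": phase["low_salt"],
            "is_cycling_high": cycling["high_salt"],
            "true_amplitude_high": amp["high_salt"],
            "true_peak_high_h": phase["high_salt"],
            "true_log2fc": log2fc,
            "true_category": [_deg.categorize(x) for x in log2fc],
        }
    )
    return matrix, truth


def simulate_null(params: SimParams | None = None) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """As :func:`simulate` with no planted rhythm or condition effect.

    Useful as a calibration input: every gene is arrhythmic noise around
    its baseline, identical in distribution across conditions.
    """
    params = params or SimParams()
    return simulate(
        dataclasses.replace(
            params,
            frac_cycling_low=0.0,
            frac_cycling_high=0.0,
            n_cycling_shared=0,
            frac_up=0.0,
            frac_down=0.0,
        )
    )


def truth_cycling(truth: pd.DataFrame, condition: str) -> pd.Series:
    """Planted cycling flags of one condition, indexed by gene id."""
    col = "is_cycling_low" if condition == "low_salt" else "is_cycling_high"
    return truth.set_index("gene_id")[col]
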