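# Methods

## The rhythmicity model

The detector asks one narrow question per gene and replicate: how close is
the six-point TPM profile to a 24-h cosine, and is its relative fluctuation
large enough to matter? It does not estimate period (fixed at 24 h), does
not model damping or non-sinusoidal waveforms, and applies no
multiple-testing correction — the call is a fixed dual-threshold rule
applied per replicate and combined by AND.

**Amplitude.** The time course is divided by its mean and the population
standard deviation (divide by *n*, not *n* − 1) of the result is taken.
This equals the coefficient of variation of the raw series. Raw-TPM SD
would make a fixed threshold meaningless across expression levels, and
z-scoring would force every amplitude to 1; the CV is the only scale-free
reading compatible with a single 0.1 cut. Population SD is the natural
descriptive convention for a fixed six-point series and is stated here so
the threshold is reproducible.

**Correlation statistic.** The regressor bank is
cos(2π(t − φ_k)/24), φ_k = k·24/60 for k = 0…59 (0.4-h spacing). Cosine
parameterization makes the best phase directly the peak time. Ties take
the smallest k. Pearson correlation is invariant to positive-affine
transforms of the data, so the statistic depends only on profile shape.

**Null and p-value.** The null draws i.i.d. standard-normal series on the
observed time grid and scores each with the same max-correlation statistic.
Because Pearson r is location/scale-free, only the i.i.d. shape of the
noise matters, and the Gaussian is the neutral choice; the calibration
check below confirms the resulting p-values are uniform enough in practice
for log-normal TPM noise at realistic CVs. One null is built per time grid
and shared by all genes and conditions — it does not depend on the data —
which makes the 10⁶-draw default affordable (a few seconds, vectorized in
10⁵-row chunks). The p-value uses the add-one estimator
(1 + exceedances)/(n_null + 1): strictly positive, valid, and equal to the
plain fraction in the large-n_null limit.

**Combination rule.** Cycling ⇔ amplitude > 0.1 AND p < 0.1 in every
replicate. The reported per-gene summary is the conservative pair
(min amplitude, max p), whose thresholding is provably identical to the
AND rule — a property the test suite asserts as set equality. The peak
time is the best phase of the replicate-mean course, reported modulo 24
into [0, 24); per-replicate phases are also emitted.

**Degenerate genes.** All-zero or constant courses have undefined Pearson
correlation; they receive amplitude 0, p-value 1, a `degenerate_rep*` flag,
and are never cycling.

**Aliasing.** With samples at 4–34 h and a 24-h period, the 28-h and 34-h
columns repeat the circadian phases of 4 h and 10 h, so the six samples
cover only four distinct phases (4, 10, 16, 22, with double weight on the
first two). This limits phase resolution; the ±2-h peak-recovery tolerance
used in the planted-recovery checks is a design constant reflecting that
grid, not a fitted number.

## Differential expression

Condition means are flat averages over all (replicate × window-time)
samples — eight values per condition for the default LL {16, 22, 28, 34}
window, which deliberately excludes LL 4/10 so clock-driven transients do
not masquerade as salinity responses. Averaging flat over the eight values
versus averaging replicates first is identical when no value is missing;
missing window samples are a hard error, so the order never matters here.
Tiers on log2 FC = log2(mean_high/mean_low): up at ≥ 1, highly up at ≥ 2,
mirrored for down; boundaries inclusive. The default pseudocount is 0 with
explicit ±∞ flags and an `undefined_zero` category for doubly-zero genes,
keeping zero-expression genes visible rather than silently shifted.

## Term enrichment

One-sided (over-representation) Fisher exact test, computed as the
hypergeometric upper tail via scipy; the test suite cross-checks it
against exhaustive enumeration of all tables with the observed margins on
backgrounds ≤ 50. The background universe defaults to annotated genes
present in the matrix and can be widened to all genes — the denominator
choice is genuinely ambiguous in this kind of analysis, so both readings
are reproducible. Selection is the raw-p two-branch rule (p ≤ 0.1, or
0.1 < p < 0.5 with DEG share > 50 %); no hierarchy propagation of
annotations is performed.

## Synthetic data

Gene g, condition c, replicate r, time t:

    TPM = B_g · F_gc · (1 + A_gc · cos(2π(t − φ_gc)/24)) · ε

- **Baseline** B ~ 10^N(1.5, 0.6): median ≈ 32 TPM with a long right tail,
  a realistic bulk-RNA-seq abundance spread.
- **Condition factor** F = 2^(planted log2 FC): +2/−2 for the planted up /
  down fractions (≈ 36 % / 12 % of genes by default), 1 otherwise.
- **Rhythm** A drawn uniformly from [0.15, 0.6] for planted cycling genes
  (≈ 1.3 % of genes in low salt, ≈ 5.7 % in high salt, one shared gene by
  default), 0 otherwise. Low-salt phases are uniform over [0, 24); high-salt
  phases share a fixed LL16 peak — the two phase modes the emulated design
  exhibits.
- **Noise** ε log-normal with mean exactly 1 and CV = 0.1 by default,
  independent across samples. Multiplicative log-normal noise keeps TPM
  positive, lets variance grow with the mean, and makes planted relative
  amplitudes directly comparable to the CV-based amplitude statistic.

The noise CV and baseline parameters are the generator's own realism
choices — no replicate noise model is published for this design — and were
fixed once. The truth table records per-condition cycling flags, planted
amplitude and peak, and the planted log2 FC/tier.

What the generator does *not* emulate: library-size/TPM renormalization
coupling between genes, batch effects, waveform shapes other than a clean
cosine, and count-level (shot) noise. Passing tests therefore demonstrate
that the statistics do what they claim under the model's own assumptions,
not that real data meet those assumptions.

## Numerical choices

- Pearson r computed via population z-scores and a matrix product; the
  naive per-phase loop is kept in the tests as an independent oracle and
  must agree to 1e-12.
- `argmax` tie-breaking takes the first (smallest-phase) maximum.
- The six-point/60-phase bank contains near-antiphase pairs, so the null
  r_max is empirically confined to [0, 1]; the test asserts this on 10⁴
  draws.
- Null reproducibility is exact for a given (grid, period, n_phases,
  n_null, seed) digest; the TSV cache stores that digest and is refused on
  mismatch.

## Problem sizes in the checks

The automated checks run the null calibration at 10 000 genes with a
10⁵-draw null, planted recovery at 2 000 genes with a 10⁴-draw null, and
one full study-scale pass (3843 genes, both conditions) against a shared
10⁵-draw null — sizes chosen so the whole battery completes in seconds
while keeping Monte Carlo error well inside the asserted tolerances
(binomial SE ≈ 0.003 on the 0.10 calibration fraction at n = 10 000).

## Known limitations

- Six time points spanning 1.25 cycles cannot distinguish a genuine
  circadian oscillation from a single salt-induced transient peaking once
  in the window; the detector reports fit to a cosine, nothing more.
- The fixed 24-h period means mis-specified periods lower r_max rather
  than being estimated.
- The amplitude index inherits the CV's sensitivity to low means: a gene
  near zero expression can show a large CV from trivial absolute changes.
- Empirical p-values are lower-bounded at 1/(n_null + 1); ranking genes
  below that resolution requires a larger null.
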