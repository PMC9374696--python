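import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import pearsonr

from circascan.io import TimeCourse
from circascan.rhythm import (
    DegenerateTimeCourseError,
    NullDistribution,
    RhythmParams,
    amplitude,
    build_null,
    correlation_pvalue,
    detect_cycling,
    max_correlation,
    mean_normalize,
    sinusoid_grid,
)
from conftest import STUDY_TIMES, build_matrix

TIMES = np.array(STUDY_TIMES)


def tc(values, times=TIMES):
    return TimeCourse("g", "low_salt", 1, np.asarray(times, float), values)


def brute_force_max_correlation(values, times=TIMES, period=24.0, n_phases=60):
    """Naive double-loop oracle: scipy pearsonr against each phase separately."""
    best_r, best_phi = -np.inf, None
    for k in range(n_phases):
        phi = k * period / n_phases
        reg = np.cos(2 * np.pi * (times - phi) / period)
        r = pearsonr(values, reg).statistic
        if r > best_r:
            best_r, best_phi = r, phi
    return best_r, best_phi


class TestMeanNormalizeAndAmplitude:
    @pytest.mark.parametrize(
        "raw, rel, amp",
        [
            ([10] * 6, [1.0] * 6, 0.0),
            ([5, 15, 5, 15, 5, 15], [0.5, 1.5, 0.5, 1.5, 0.5, 1.5], 0.5),
        ],
    )
    def test_hand_examples(self, raw, rel, amp):
        out = mean_normalize(tc(raw))
        np.testing.assert_allclose(out.values, rel)
        assert out.values.mean() == pytest.approx(1.0)
        assert amplitude(out) == pytest.approx(amp)

    def test_composition_clears_threshold(self):
        assert amplitude(mean_normalize(tc([5, 15, 5, 15, 5, 15]))) > 0.1

    def test_all_zero_is_degenerate(self):
        with pytest.raises(DegenerateTimeCourseError):
            mean_normalize(tc([0, 0, 0, 0, 0, 0]))

    def test_amplitude_uses_population_sd(self):
        # n divisor, not n-1: CV of [0.5,1.5]x3 is exactly 0.5
        assert amplitude(tc([0.5, 1.5, 0.5, 1.5, 0.5, 1.5])) == pytest.approx(0.5)


class TestSinusoidGrid:
    def test_phase16_regressor_by_hand(self):
        bank = sinusoid_grid(TIMES, 24.0, 60)
        k16 = int(np.argmin(np.abs(bank.phases_h - 16.0)))
        assert bank.phases_h[k16] == pytest.approx(16.0)
        np.testing.assert_allclose(
            bank.values[k16], [-1, 0, 1, 0, -1, 0], atol=1e-12
        )

    def test_default_grid_spacing(self):
        bank = sinusoid_grid(TIMES, 24.0, 60)
        assert np.diff(bank.phases_h) == pytest.approx(0.4)
        assert bank.n_phases == 60

    def test_two_phases_are_antiphase(self):
        bank = sinusoid_grid(TIMES, 24.0, 2)
        np.testing.assert_allclose(bank.values[0], -bank.values[1], atol=1e-12)

    def test_aliasing_of_28_and_34(self):
        """At period 24, samples at 28 h and 34 h repeat the phases of 4 h and 10 h."""
        bank = sinusoid_grid(TIMES, 24.0, 60)
        np.testing.assert_allclose(bank.values[:, 4], bank.values[:, 0], atol=1e-12)
        np.testing.assert_allclose(bank.values[:, 5], bank.values[:, 1], atol=1e-12)


class TestMaxCorrelation:
    def test_self_correlation(self):
        bank = sinusoid_grid(TIMES)
        r, phi = max_correlation(np.array([-1.0, 0, 1, 0, -1, 0]), bank)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert phi == 16.0

    def test_matches_brute_force_on_seeded_series(self):
        bank = sinusoid_grid(TIMES)
        rng = np.random.default_rng(123)
        for _ in range(100):
            v = rng.normal(size=6)
            r, phi = max_correlation(v, bank)
            r0, phi0 = brute_force_max_correlation(v)
            assert r == pytest.approx(r0, abs=1e-12)
            assert phi == phi0

    def test_positive_affine_invariance_example(self):
        bank = sinusoid_grid(TIMES)
        v = np.array([0.2, 0.8, 1.9, 1.4, 0.5, 1.2])
        assert max_correlation(v, bank) == pytest.approx(
            max_correlation(v * 7 + 3, bank)
        )

    @given(
        st.lists(st.floats(-100, 100), min_size=6, max_size=6),
        st.floats(0.1, 50),
        st.floats(-100, 100),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_affine_invariance_property(self, values, a, b):
        v = np.asarray(values)
        if v.std() == 0 or (a * v).std() == 0:
            return
        bank = sinusoid_grid(TIMES)
        r1, p1 = max_correlation(v, bank)
        r2, p2 = max_correlation(a * v + b, bank)
        assert r1 == pytest.approx(r2, abs=1e-9)
        assert p1 == p2

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateTimeCourseError):
            max_correlation(np.ones(6), sinusoid_grid(TIMES))


class TestNullDistribution:
    def test_same_seed_identical(self):
        p = RhythmParams(n_null=2000, seed=5)
        a, b = build_null(TIMES, p), build_null(TIMES, p)
        np.testing.assert_array_equal(a.rmax_sorted, b.rmax_sorted)

    def test_six_point_default_null_lies_in_unit_interval(self):
        # with 60 phases the bank holds near-antiphase pairs, so rmax >= 0
        null = build_null(TIMES, RhythmParams(n_null=10_000, seed=3))
        assert null.rmax_sorted[0] >= 0.0
        assert null.rmax_sorted[-1] <= 1.0

    def test_quantile_stability_across_seeds(self):
        p1 = RhythmParams(n_null=100_000, seed=1)
        p2 = RhythmParams(n_null=100_000, seed=2)
        q1 = build_null(TIMES, p1).quantile(0.9)
        q2 = build_null(TIMES, p2).quantile(0.9)
        assert abs(q1 - q2) < 0.01

    def test_save_load_round_trip(self, tmp_path):
        null = build_null(TIMES, RhythmParams(n_null=500, seed=4))
        path = tmp_path / "null.tsv"
        null.save(path)
        back = NullDistribution.load(path)
        assert back.matches(TIMES, RhythmParams(n_null=500, seed=4))
        np.testing.assert_allclose(back.rmax_sorted, null.rmax_sorted, rtol=1e-8)


@pytest.fixture(scope="module")
def null():
    return build_null(TIMES, RhythmParams(n_null=1000, seed=8))


class TestCorrelationPvalue:

    def test_rmax_one_gives_minimal_p(self, null):
        assert correlation_pvalue(1.0, null) == pytest.approx(1 / 1001)

    def test_rmax_minus_one_gives_p_one(self, null):
        assert correlation_pvalue(-1.0, null) == 1.0

    def test_median_gives_about_half(self, null):
        med = float(np.median(null.rmax_sorted))
        assert correlation_pvalue(med, null) == pytest.approx(0.5, abs=2 / 1000)

    def test_monotone_non_increasing(self, null):
        grid = np.linspace(-1, 1, 201)
        p = correlation_pvalue(grid, null)
        assert np.all(np.diff(p) <= 0)


def _sine(amp, phase, base=100.0, times=TIMES):
    return base * (1 + amp * np.cos(2 * np.pi * (times - phase) / 24.0))


class TestDetectCycling:
    def test_both_replicates_must_pass(self):
        """A clean rhythm in one replicate but a flat second replicate is not cycling."""
        m = build_matrix(
            {
                "both": {("low_salt", 1): _sine(0.4, 16),
                         ("low_salt", 2): _sine(0.4, 16)},
                "one_rep": {("low_salt", 1): _sine(0.4, 16),
                            ("low_salt", 2): [100.0, 101, 100, 99, 100, 101]},
            },
            n_replicates=2,
        )
        rec = detect_cycling(m, "low_salt", RhythmParams(n_null=2000, seed=1))
        rec = rec.set_index("gene_id")
        assert bool(rec.loc["both", "is_cycling"])
        assert not bool(rec.loc["one_rep", "is_cycling"])
        assert rec.loc["both", "peak_time_h"] == pytest.approx(16.0)

    def test_degenerate_gene_flagged_never_cycling(self):
        m = build_matrix(
            {"flat": [0, 0, 0, 0, 0, 0], "ok": _sine(0.4, 10)}, n_replicates=1
        )
        rec = detect_cycling(m, "low_salt", RhythmParams(n_null=500, seed=1))
        row = rec.set_index("gene_id").loc["flat"]
        assert row["amplitude_rep1"] == 0.0
        assert row["pvalue_rep1"] == 1.0
        assert bool(row["degenerate_rep1"])
        assert not bool(row["is_cycling"])

    def test_differing_time_grids_error(self):
        m1 = build_matrix({"g": [1, 2, 3, 4, 5, 6]}, n_replicates=1)
        m2 = build_matrix({"g": [1, 2, 3]}, n_replicates=1, times=(4.0, 10.0, 16.0))
        samples = m1.samples + [
            dataclasses.replace(s, replicate=2, sample_id=s.sample_id + "b")
            for s in m2.samples
        ]
        values = m1.values.join(
            m2.values.rename(columns=lambda c: c + "b")
        )
        from circascan.io import ExpressionMatrix

        m = ExpressionMatrix(values=values, samples=samples)
        with pytest.raises(ValueError, match="differing time grids"):
            detect_cycling(m, "low_salt", RhythmParams(n_null=500, seed=1))

    def test_planted_genes_recovered(self, small_sim):
        params, matrix, truth = small_sim
        rec = detect_cycling(matrix, "low_salt", RhythmParams(n_null=5000, seed=2))
        merged = rec.merge(truth, on="gene_id")
        planted = merged["is_cycling_low"]
        assert merged.loc[planted, "is_cycling"].all()
        err = np.abs(
            merged.loc[planted, "peak_time_h"] - merged.loc[planted, "true_peak_low_h"]
        )
        err = np.minimum(err, 24 - err)
        assert (err <= 2.0).all()

    def test_deterministic_output(self, small_sim):
        _, matrix, _ = small_sim
        p = RhythmParams(n_null=1000, seed=6)
        a = detect_cycling(matrix, "low_salt", p).to_csv()
        b = detect_cycling(matrix, "low_salt", p).to_csv()
        assert a == b

    def test_amplitude_and_pvalue_under_affine_transform(self, small_sim):
        """p is invariant under y -> a*y + b; amplitude moves exactly as the CV."""
        _, matrix, _ = small_sim
        p = RhythmParams(n_null=2000, seed=3)
        base = detect_cycling(matrix, "low_salt", p)
        shifted = matrix.values * 3.0 + 7.0
        from circascan.io import ExpressionMatrix

        m2 = ExpressionMatrix(values=shifted, samples=list(matrix.samples))
        out = detect_cycling(m2, "low_salt", p)
        np.testing.assert_allclose(out["pvalue_rep1"], base["pvalue_rep1"])
        # expected CV of a*y+b recomputed from the raw block
        sids = [s.sample_id for s in matrix.samples_for("low_salt", 1)]
        raw = matrix.values[sids].to_numpy()
        expected_cv = (3.0 * raw.std(axis=1)) / (3.0 * raw.mean(axis=1) + 7.0)
        np.testing.assert_allclose(out["amplitude_rep1"], expected_cv, rtol=1e-9)
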