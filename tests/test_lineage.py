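"""t-tests, permutation tests, and the Bonferroni-corrected lineage battery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from paleosize import (
    LineagePair,
    TTestVariant,
    bonferroni_alpha,
    extract_lineage_pairs,
    permutation_t,
    run_lineage_battery,
    two_sample_t,
)

finite_sample = st.lists(
    st.floats(min_value=-50, max_value=50), min_size=3, max_size=10
)


class TestTwoSampleT:
    def test_identical_samples_give_t_zero_p_one(self):
        x = [1.0, 2.0, 3.0]
        t, p, _ = two_sample_t(x, x, TTestVariant.POOLED)
        assert t == 0.0 and p == 1.0

    def test_pooled_hand_computed_example(self):
        """Pooled t for {1,2,3} vs {2,3,4}: means 2 vs 3, pooled variance 1,
        SE = sqrt(2/3), so t = -1.2247 with df = 4."""
        t, p, df = two_sample_t([1, 2, 3], [2, 3, 4], TTestVariant.POOLED)
        assert t == pytest.approx(-1.2247, abs=5e-5)
        assert df == 4
        assert p == pytest.approx(2 * stats.t.sf(1.2247, 4), abs=1e-4)

    def test_positive_t_when_first_mean_larger(self):
        t, _, _ = two_sample_t([10, 11, 12], [1, 2, 3])
        assert t > 0

    def test_pooled_equals_welch_for_balanced_equal_variance(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [11.0, 12.0, 13.0, 14.0]  # same spread, shifted
        tp, pp, dfp = two_sample_t(x, y, TTestVariant.POOLED)
        tw, pw, dfw = two_sample_t(x, y, TTestVariant.WELCH)
        assert tp == tw and pp == pw and dfp == dfw

    def test_undersized_sample_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [1.0, 2.0])

    def test_zero_total_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            two_sample_t([2.0, 2.0], [2.0, 2.0])

    @given(finite_sample, finite_sample)
    @settings(max_examples=50, deadline=None)
    def test_antisymmetric_in_arguments(self, x, y):
        if np.var(x, ddof=1) + np.var(y, ddof=1) == 0:
            return
        t_xy, p_xy, _ = two_sample_t(x, y)
        t_yx, p_yx, _ = two_sample_t(y, x)
        assert t_xy == pytest.approx(-t_yx, rel=1e-12, abs=1e-12)
        assert p_xy == pytest.approx(p_yx, rel=1e-12, abs=1e-12)


class TestPermutationT:
    def test_identical_constant_vectors_give_p_one(self):
        t, p = permutation_t([2.0, 2.0], [2.0, 2.0])
        assert p == 1.0 and t == 0.0

    def test_exhaustive_enumeration_small_example(self):
        """{1,2} vs {3,4}: of the C(4,2)=6 assignments, only the observed
        split and its mirror are as extreme, so p = 2/6."""
        _, p = permutation_t([1.0, 2.0], [3.0, 4.0], exhaustive=True)
        assert p == pytest.approx(1 / 3, abs=1e-12)

    def test_exhaustive_matches_scipy_oracle(self):
        x = [2.1, 3.3, 4.0, 1.2]
        y = [5.0, 6.1, 4.9]
        _, p = permutation_t(x, y, exhaustive=True)
        ref = stats.permutation_test(
            (x, y),
            lambda a, b, axis=-1: stats.ttest_ind(a, b, axis=axis).statistic,
            permutation_type="independent",
            n_resamples=np.inf,
            alternative="two-sided",
        )
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_monte_carlo_agrees_with_exhaustive(self):
        x = [1.0, 4.0, 2.5, 3.1]
        y = [5.5, 6.0, 4.8, 7.2]
        _, p_ex = permutation_t(x, y, exhaustive=True)
        n_perm = 100_000
        _, p_mc = permutation_t(
            x, y, n_perm=n_perm, rng=np.random.default_rng(3), exhaustive=False
        )
        se = np.sqrt(p_ex * (1 - p_ex) / n_perm)
        assert abs(p_mc - p_ex) < 3 * se + 2 / n_perm

    def test_p_in_unit_interval_and_never_zero(self, rng):
        x = rng.normal(0, 1, 10)
        y = rng.normal(8, 1, 10)  # hugely separated
        _, p = permutation_t(x, y, n_perm=999, rng=rng, exhaustive=False)
        assert 0 < p <= 1

    def test_singleton_groups_use_mean_difference(self):
        # df = 0, t undefined: the statistic falls back to |mean difference|
        _, p = permutation_t([1.0], [3.0], exhaustive=True)
        assert p == 1.0  # both assignments have |diff| = 2

    def test_pooled_p_close_to_permutation_p_for_normal_data(self):
        """At n = 50/50 with equal variances the pooled t-test and the
        permutation test are interchangeable to ~0.02 on average."""
        rng = np.random.default_rng(12)
        gaps = []
        for _ in range(100):
            x = rng.normal(0, 1, 50)
            y = rng.normal(0.3, 1, 50)
            _, p_t, _ = two_sample_t(x, y)
            _, p_perm = permutation_t(x, y, n_perm=999, rng=rng, exhaustive=False)
            gaps.append(abs(p_t - p_perm))
        assert np.mean(gaps) < 0.02


class TestBonferroni:
    def test_arithmetic(self):
        assert bonferroni_alpha(0.05, 1) == 0.05
        assert bonferroni_alpha(0.05, 10) == 0.005
        assert bonferroni_alpha(0.05, 7) == pytest.approx(0.00714, abs=5e-6)

    def test_invalid_m_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)


class TestLineageBattery:
    @staticmethod
    def pair(name, fx, mx):
        return LineagePair(name, name, name, np.asarray(fx), np.asarray(mx))

    def test_identical_populations_never_significant(self):
        x = [3.0, 4.0, 5.0, 6.0]
        out = run_lineage_battery([self.pair("same", x, x)])
        row = out.iloc[0]
        assert not row["significant_raw"] and not row["significant_bonferroni"]
        assert row["p_pooled"] == 1.0

    def test_m_defaults_to_number_of_pairs(self, rng):
        pairs = [
            self.pair(f"L{i}", rng.normal(10, 1, 8), rng.normal(10, 1, 8))
            for i in range(4)
        ]
        out = run_lineage_battery(pairs, alpha=0.05)
        assert (out["m"] == 4).all()
        assert (out["alpha_corrected"] == 0.05 / 4).all()

    def test_bonferroni_implies_raw(self, rng):
        pairs = [
            self.pair(f"L{i}", rng.normal(10, 1, 10), rng.normal(10 + i, 1, 10))
            for i in range(5)
        ]
        out = run_lineage_battery(pairs)
        assert (~out["significant_bonferroni"] | out["significant_raw"]).all()

    def test_stable_input_ordering(self, rng):
        pairs = [
            self.pair(name, rng.normal(5, 1, 6), rng.normal(5, 1, 6))
            for name in ("zeta", "alpha", "mid")
        ]
        out = run_lineage_battery(pairs)
        assert list(out["lineage_name"]) == ["zeta", "alpha", "mid"]

    def test_error_annotated_with_lineage_name(self):
        bad = self.pair("shorty", [1.0], [2.0, 3.0])
        with pytest.raises(ValueError, match="shorty"):
            run_lineage_battery([bad])

    def test_three_sd_shift_detected_after_correction(self):
        """Power check: a 3-within-SD mean shift at n = 30/30 is essentially
        always Bonferroni-significant (m = 7)."""
        rng = np.random.default_rng(2026)
        hits = 0
        n_reps = 200
        for _ in range(n_reps):
            x = rng.normal(20.0, 2.0, 30)
            y = rng.normal(26.0, 2.0, 30)  # 3 within-population SDs
            out = run_lineage_battery(
                [self.pair("shifted", x, y)], m=7, n_perm=199, seed=1
            )
            hits += bool(out.iloc[0]["significant_bonferroni"])
        assert hits / n_reps >= 0.99


class TestExtractPairs:
    def test_anagenetic_pair_uses_both_species(self, ppwa_records):
        pairs = extract_lineage_pairs(
            ppwa_records,
            [
                {
                    "name": "torcula",
                    "fossil_species": "Torcula perattenuata",
                    "modern_species": "Torcula exoleta",
                }
            ],
        )
        assert pairs[0].fossil_lengths.mean() == pytest.approx(97.0)
        assert pairs[0].modern_lengths.mean() == pytest.approx(48.3)

    def test_missing_population_reported(self, ppwa_records):
        with pytest.raises(ValueError, match="ghost"):
            extract_lineage_pairs(
                ppwa_records,
                [
                    {
                        "name": "ghost",
                        "fossil_species": "Nonexistent sp.",
                        "modern_species": "Torcula exoleta",
                    }
                ],
            )
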