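"""Two-normal mixture bimodality criterion, variance pretesting and the
pooled/Welch comparison of laterality strength."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from equilat import (
    GroupMoments,
    assess_bimodality,
    bonett_variance_test,
    equal_variance_pretest,
    group_moments,
    separation_factor,
    split_by_sign,
    two_sample_t,
)


class TestSplitAndMoments:
    def test_fixture_split_sizes(self, focal_results):
        right, left = split_by_sign(focal_results)
        assert (len(right), len(left)) == (22, 21)
        assert all(r.li > 0 for r in right) and all(r.li < 0 for r in left)

    def test_fixture_group_moments(self, focal_results):
        right, left = split_by_sign(focal_results)
        mr = group_moments([r.li for r in right])
        ml = group_moments([r.li for r in left])
        # published mixture components of the full cohort
        assert mr.mean == pytest.approx(35.05, abs=0.005)
        assert mr.sd == pytest.approx(18.83, abs=0.005)
        assert ml.mean == pytest.approx(-52.11, abs=0.005)
        assert ml.sd == pytest.approx(28.93, abs=0.005)

    def test_moments_oracle(self):
        values = [1.0, 2.0, 4.0, 8.0]
        m = group_moments(values)
        assert m.n == 4
        assert m.mean == pytest.approx(np.mean(values))
        assert m.sd == pytest.approx(np.std(values, ddof=1))

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            group_moments([1.0])


def _mixture_mode_count(mu, ratio):
    """Number of modes of 0.5 N(0,1) + 0.5 N(mu, ratio) on a fine grid."""
    grid = np.linspace(-5, mu + 5 * ratio, 20001)
    dens = 0.5 * stats.norm.pdf(grid) + 0.5 * stats.norm.pdf(grid, mu, ratio)
    signs = np.sign(np.diff(dens))
    signs = signs[signs != 0]
    return int(np.sum((signs[:-1] > 0) & (signs[1:] < 0)))


class TestSeparationFactor:
    def test_equal_variances_give_classical_threshold(self):
        assert separation_factor(1.0) == pytest.approx(1.0, abs=1e-9)

    def test_published_study_ratio(self):
        # the study's sigma ratio 18.83/28.93 ~ 0.65 implies a factor
        # near 1.16; the digitized table must land within 0.02 of it
        assert separation_factor(18.83 / 28.93) == pytest.approx(1.16, abs=0.02)

    def test_scale_symmetry(self):
        for r in (0.1, 0.3, 0.65, 0.9):
            assert separation_factor(r) == pytest.approx(separation_factor(1 / r))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            separation_factor(0.01)
        with pytest.raises(ValueError):
            separation_factor(-1.0)

    @pytest.mark.parametrize("ratio", [0.25, 0.5, 0.65, 0.8, 1.0])
    def test_factor_is_the_bimodality_threshold(self, ratio):
        """Independent oracle: a two-normal equal-weight mixture with
        sigma1 = 1, sigma2 = ratio must be unimodal just below
        S * (1 + ratio) mean separation and bimodal just above it."""
        s = separation_factor(ratio)
        scale = 1.0 + ratio
        assert _mixture_mode_count((s - 0.02) * scale, ratio) == 1
        assert _mixture_mode_count((s + 0.02) * scale, ratio) == 2


class TestAssessBimodality:
    def test_fixture_cohort_is_bimodal(self, focal_results):
        right, left = split_by_sign(focal_results)
        verdict = assess_bimodality(
            group_moments([r.li for r in right]),
            group_moments([r.li for r in left]),
        )
        # published: S(sigma1+sigma2) = 55.38 < mu1 - mu2 = 87.16
        assert verdict.is_bimodal
        assert verdict.rhs == pytest.approx(87.16, abs=0.005)
        assert verdict.group_r.sd + verdict.group_l.sd == pytest.approx(47.76, abs=0.005)
        assert verdict.lhs == pytest.approx(55.38, abs=0.7)

    def test_overlapping_groups_are_unimodal(self):
        verdict = assess_bimodality(
            GroupMoments(10, 5.0, 20.0), GroupMoments(10, -5.0, 20.0)
        )
        assert not verdict.is_bimodal

    @settings(max_examples=60, derandomize=True)
    @given(
        st.floats(-50, 50), st.floats(0.5, 5),
        st.floats(5, 40), st.floats(5, 40), st.floats(-80, -1), st.floats(1, 80),
    )
    def test_translation_and_scale_invariance(self, shift, scale, s1, s2, mu2, mu1):
        base = assess_bimodality(
            GroupMoments(10, mu1, s1), GroupMoments(10, mu2, s2)
        )
        moved = assess_bimodality(
            GroupMoments(10, scale * mu1 + shift, scale * s1),
            GroupMoments(10, scale * mu2 + shift, scale * s2),
        )
        assert moved.is_bimodal == base.is_bimodal
        assert moved.sigma_ratio == pytest.approx(base.sigma_ratio)


class TestVariancePretest:
    def test_bonett_equal_samples_give_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        assert bonett_variance_test(x, x) == pytest.approx(1.0)

    def test_bonett_symmetry(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(0, 1, 25), rng.normal(0, 3, 30)
        assert bonett_variance_test(x, y) == pytest.approx(
            bonett_variance_test(y, x)
        )

    def test_bonett_detects_gross_variance_ratio(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 40), rng.normal(0, 4, 40)
        assert bonett_variance_test(x, y) < 0.001

    def test_small_sample_uses_minimum_rule(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 12), rng.normal(0, 1, 15)
        p = equal_variance_pretest(x, y)
        levene = stats.levene(x, y, center="median").pvalue
        assert p == pytest.approx(min(bonett_variance_test(x, y), levene))

    def test_large_sample_uses_bonett_alone(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(0, 1, 25), rng.normal(0, 1.5, 30)
        assert equal_variance_pretest(x, y) == pytest.approx(
            bonett_variance_test(x, y)
        )

    def test_fixture_strength_groups_fail_pretest(self, focal_results):
        """|LI| of the two full-cohort sign groups: the pretest rejects
        equal variances, which is why the published comparison is Welch."""
        right, left = split_by_sign(focal_results)
        p = equal_variance_pretest(
            [abs(r.li) for r in right], [abs(r.li) for r in left]
        )
        assert p < 0.05


class TestTwoSampleT:
    def test_published_welch_row_all_horses(self, focal_results):
        right, left = split_by_sign(focal_results)
        cmp = two_sample_t(
            [abs(r.li) for r in left], [abs(r.li) for r in right]
        )
        assert cmp.method == "welch"
        assert cmp.t == pytest.approx(2.28, abs=0.005)
        assert cmp.df == 34
        assert cmp.p_value == pytest.approx(0.029, abs=0.0005)

    def test_published_pooled_row_females(self, focal_records, focal_results):
        from equilat import Sex

        sex = {r.horse_id: r.sex for r in focal_records}
        mares = [r for r in focal_results if sex[r.horse_id] is Sex.MARE]
        right, left = split_by_sign(mares)
        cmp = two_sample_t(
            [abs(r.li) for r in left], [abs(r.li) for r in right]
        )
        assert cmp.method == "pooled"
        assert cmp.t == pytest.approx(2.40, abs=0.005)
        assert cmp.df == 19
        assert cmp.p_value == pytest.approx(0.027, abs=0.0005)

    def test_pooled_matches_scipy(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(0, 2, 14), rng.normal(1, 2, 11)
        cmp = two_sample_t(x, y, method="pooled")
        t, p = stats.ttest_ind(x, y, equal_var=True)
        assert cmp.t == pytest.approx(t, rel=1e-12)
        assert cmp.p_value == pytest.approx(p, rel=1e-12)

    def test_welch_df_truncated_never_exceeds_pooled(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            x = rng.normal(0, rng.uniform(0.5, 4), rng.integers(5, 30))
            y = rng.normal(0, rng.uniform(0.5, 4), rng.integers(5, 30))
            cmp = two_sample_t(x, y, method="welch")
            df_ws = (x.var(ddof=1) / len(x) + y.var(ddof=1) / len(y)) ** 2 / (
                (x.var(ddof=1) / len(x)) ** 2 / (len(x) - 1)
                + (y.var(ddof=1) / len(y)) ** 2 / (len(y) - 1)
            )
            assert cmp.df == int(df_ws)
            assert cmp.df <= len(x) + len(y) - 2

    def test_degenerate_constant_samples(self):
        cmp = two_sample_t([3.0, 3.0, 3.0], [3.0, 3.0, 3.0], method="welch")
        assert cmp.t == 0.0 and cmp.p_value == 1.0

    def test_invalid_method_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1, 2, 3], [1, 2, 3], method="median")
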