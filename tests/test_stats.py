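"""CV ratio, per-parameter aggregation, equal-split chi-squared test and
consistency flags."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import chisquare

from cvratio.model import ParameterSummary
from cvratio.stats import (
    chi_squared_equal_split,
    compute_consistency_flags,
    cv_ratio,
    flag_cross_threshold,
    flag_mean_vs_proportion,
    significant_in_both,
    summarize_parameter,
)

positive_cv = st.floats(min_value=1e-6, max_value=10.0, allow_nan=False)


class TestCvRatio:
    def test_equal_cvs_give_half(self):
        assert cv_ratio(0.2, 0.2) == pytest.approx(0.5)

    def test_37_percent_difference_benchmark(self):
        """One CV equal to 63% of the other lands at 0.61 / 0.39 after
        rounding, the analytic reference for a biologically meaningful
        sex difference in variability."""
        assert round(cv_ratio(1.0, 0.63), 2) == 0.61
        assert round(cv_ratio(0.63, 1.0), 2) == 0.39

    def test_rejects_negative_and_double_zero(self):
        with pytest.raises(ValueError):
            cv_ratio(-0.1, 0.2)
        with pytest.raises(ValueError):
            cv_ratio(0.0, 0.0)

    @given(a=positive_cv, b=positive_cv)
    def test_antisymmetry(self, a, b):
        assert cv_ratio(a, b) + cv_ratio(b, a) == pytest.approx(1.0, abs=1e-12)

    @given(a=positive_cv)
    def test_identical_cvs_sit_at_half(self, a):
        assert cv_ratio(a, a) == pytest.approx(0.5)

    @given(a=positive_cv, b=positive_cv, eps=st.floats(min_value=1e-3, max_value=1.0))
    def test_strictly_increasing_in_female_cv(self, a, b, eps):
        assert cv_ratio(a + eps, b) > cv_ratio(a, b)

    def test_exceeds_half_iff_female_more_variable(self):
        assert cv_ratio(0.31, 0.30) > 0.5
        assert cv_ratio(0.29, 0.30) < 0.5


class TestSummarizeParameter:
    def test_ferritin_like_counts_and_percentages(self, make_dataset):
        """Four data sets, three above 0.5 and one below, reproduce the
        75% / 25% split and the 0.43-0.58 range."""
        ratios = [0.43, 0.52, 0.55, 0.58]
        pool = [make_dataset(ratio=r, project_id=f"P{i}") for i, r in enumerate(ratios)]
        s = summarize_parameter(pool, "glucose", threshold=5)
        assert (s.n_gt, s.n_lt, s.n_tie) == (3, 1, 0)
        assert (s.pct_gt, s.pct_lt) == (75, 25)
        assert s.ratio_min == pytest.approx(0.43)
        assert s.ratio_max == pytest.approx(0.58)
        assert s.mean_cv_ratio == pytest.approx(np.mean(ratios))
        assert s.sd_cv_ratio == pytest.approx(np.std(ratios, ddof=1))
        assert s.n_projects == 4
        assert s.n_mice_total == 80  # 4 data sets x (10 f + 10 m)

    def test_no_surviving_datasets_yield_empty_summary(self):
        s = summarize_parameter([], "ck", threshold=5)
        assert s.empty and s.n_datasets == 0

    def test_exact_ties_excluded_from_percentage_denominator(self, make_dataset):
        pool = [
            make_dataset(ratio=0.5, project_id="P0"),
            make_dataset(ratio=0.6, project_id="P1"),
            make_dataset(ratio=0.6, project_id="P2"),
            make_dataset(ratio=0.4, project_id="P3"),
        ]
        s = summarize_parameter(pool, "glucose", threshold=5)
        assert (s.n_gt, s.n_lt, s.n_tie) == (2, 1, 1)
        assert s.pct_gt == 67  # 2 of 3 non-tied, half-up
        assert s.n_datasets == 4
        # ties still contribute to mean and range
        assert s.ratio_min == pytest.approx(0.4)

    def test_mean_sd_match_direct_two_pass_computation(self, make_dataset):
        rng = np.random.default_rng(31)
        ratios = rng.uniform(0.05, 0.95, size=500)
        pool = [make_dataset(ratio=r, project_id=f"P{i%7}") for i, r in enumerate(ratios)]
        s = summarize_parameter(pool, "glucose", threshold=5)
        assert s.mean_cv_ratio == pytest.approx(ratios.mean(), abs=1e-12)
        assert s.sd_cv_ratio == pytest.approx(ratios.std(ddof=1), abs=1e-12)
        assert s.n_projects == 7

    @given(
        ratios=st.lists(
            st.floats(min_value=0.01, max_value=0.99, allow_nan=False),
            min_size=1, max_size=40,
        )
    )
    def test_bucket_conservation(self, ratios):
        """n_gt + n_lt + n_tie always equals n_datasets, and the mean sits
        inside the min-max range."""
        from cvratio.model import Sex, SexGroupSummary, StrainDataSet

        pool = []
        for i, r in enumerate(ratios):
            f = SexGroupSummary("P%d" % i, "glucose", "A/J", Sex.FEMALE, 10, 100.0, r * 100, r)
            m = SexGroupSummary("P%d" % i, "glucose", "A/J", Sex.MALE, 10, 100.0, (1 - r) * 100, 1 - r)
            pool.append(
                StrainDataSet("P%d" % i, "glucose", "A/J", f, m, cv_ratio(f.cv, m.cv))
            )
        s = summarize_parameter(pool, "glucose", threshold=5)
        assert s.n_gt + s.n_lt + s.n_tie == s.n_datasets == len(ratios)
        assert s.ratio_min - 1e-12 <= s.mean_cv_ratio <= s.ratio_max + 1e-12
        assert s.n_mice_total == 20 * len(ratios)


class TestChiSquaredEqualSplit:
    def test_even_counts_give_zero_statistic(self):
        r = chi_squared_equal_split(10, 10)
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(1.0)
        assert not r.significant

    @pytest.mark.parametrize(
        "n_gt,n_lt,stat,p,significant",
        [
            (5, 16, 121 / 21, 0.016377, True),   # frozen via erfc(sqrt(stat/2))
            (1, 9, 6.4, 0.011412, True),
            (62, 44, 324 / 106, 0.080410, False),
        ],
    )
    def test_frozen_reference_values(self, n_gt, n_lt, stat, p, significant):
        r = chi_squared_equal_split(n_gt, n_lt)
        assert r.statistic == pytest.approx(stat)
        assert r.p_value == pytest.approx(p, abs=1e-5)
        assert r.significant is significant
        # independent closed form for the df=1 upper tail
        assert r.p_value == pytest.approx(math.erfc(math.sqrt(r.statistic / 2)), abs=1e-12)

    @given(a=st.integers(0, 200), b=st.integers(0, 200))
    def test_matches_generic_pearson(self, a, b):
        if a + b == 0:
            assert not chi_squared_equal_split(a, b).evaluable
            return
        r = chi_squared_equal_split(a, b)
        expected = chisquare([a, b])
        assert r.statistic == pytest.approx(expected.statistic, abs=1e-9)
        assert r.p_value == pytest.approx(expected.pvalue, abs=1e-9)
        assert r.df == 1

    def test_zero_total_not_evaluable(self):
        r = chi_squared_equal_split(0, 0)
        assert not r.evaluable and not r.significant and math.isnan(r.statistic)


def _summary(key, mean, n_gt, n_lt, threshold=5, n_tie=0):
    n = n_gt + n_lt + n_tie
    return ParameterSummary(
        parameter_key=key, threshold=threshold, n_datasets=n,
        mean_cv_ratio=mean, sd_cv_ratio=0.1, n_gt=n_gt, n_lt=n_lt, n_tie=n_tie,
        pct_gt=None, pct_lt=None, ratio_min=min(mean, 0.09), ratio_max=max(mean, 0.9),
        n_mice_total=10 * n, n_projects=1,
    )


class TestConsistencyFlags:
    def test_mean_below_half_but_majority_above_is_inconsistent(self):
        # the MCV-like constellation: mean 0.49 yet 183 of 332 sets above 0.5
        assert flag_mean_vs_proportion(_summary("mcv", 0.49, 183, 149))

    def test_agreeing_mean_and_majority_is_consistent(self):
        assert not flag_mean_vs_proportion(_summary("cholesterol", 0.52, 220, 111))

    def test_neutral_mean_never_flags(self):
        assert not flag_mean_vs_proportion(_summary("x", 0.5, 30, 10))

    def test_even_split_never_flags(self):
        assert not flag_mean_vs_proportion(_summary("x", 0.43, 10, 10))

    def test_cross_threshold_flip_detected(self):
        s5 = _summary("chloride", 0.51, 66, 50)
        s10 = _summary("chloride", 0.46, 6, 9, threshold=10)
        assert flag_cross_threshold(s5, s10)

    def test_cross_threshold_same_side_not_flagged(self):
        s5 = _summary("cholesterol", 0.52, 220, 111)
        s10 = _summary("cholesterol", 0.51, 62, 44, threshold=10)
        assert not flag_cross_threshold(s5, s10)

    def test_cross_threshold_requires_strict_sign_flip(self):
        s5 = _summary("x", 0.5, 10, 10)
        s10 = _summary("x", 0.55, 12, 8, threshold=10)
        assert not flag_cross_threshold(s5, s10)

    def test_cross_threshold_rejects_mismatched_parameters(self):
        with pytest.raises(ValueError):
            flag_cross_threshold(_summary("a", 0.6, 5, 1), _summary("b", 0.6, 5, 1))

    def test_alt_like_counts_significant_in_both(self):
        s5 = _summary("alt", 0.44, 5, 16)
        s10 = _summary("alt", 0.39, 1, 9, threshold=10)
        assert significant_in_both(s5, s10)

    def test_even_counts_not_significant_in_both(self):
        s5 = _summary("x", 0.5, 10, 10)
        s10 = _summary("x", 0.5, 10, 10, threshold=10)
        assert not significant_in_both(s5, s10)

    def test_flags_not_evaluable_with_empty_summary(self):
        s5 = _summary("ck", 0.52, 5, 1)
        empty = ParameterSummary(parameter_key="ck", threshold=10, n_datasets=0, empty=True)
        flags = compute_consistency_flags(s5, empty)
        assert flags.cross_threshold_inconsistent is None
        assert flags.significant_in_both is None
        assert flags.mean_vs_proportion_inconsistent is not None
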