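"""Statistic core: the CV ratio, per-parameter aggregation, the equal-split
chi-squared test, and the consistency flags.

The CV ratio r = CV_f / (CV_f + CV_m) maps the relative dispersion of the
two sexes onto [0, 1]: r = 0.5 means equal variability, r > 0.5 means the
female group is more variable. It is antisymmetric (r(a, b) + r(b, a) = 1),
scale-free, and bounded, which makes it convenient for pooling across
parameters measured in different units. Under the null hypothesis of no
sex-specific variability, data-set counts above and below 0.5 should split
evenly; the Pearson chi-squared test of that split reduces to
(n_gt - n_lt)^2 / (n_gt + n_lt) on one degree of freedom.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .model import ChiSquaredResult, ConsistencyFlags, ParameterSummary, StrainDataSet

DEFAULT_ALPHA = 0.05


def cv_ratio(cv_female: float, cv_male: float) -> float:
    """Female share of the summed coefficients of variation.

    Both CVs must be non-negative and not both zero (the ratio would be
    0/0). Strictly increasing in ``cv_female``, so the ratio exceeds 0.5
    exactly when the female CV exceeds the male CV.
    """
    if cv_female < 0 or cv_male < 0:
        raise ValueError(f"CVs must be non-negative, got ({cv_female}, {cv_male})")
    if cv_female == 0 and cv_male == 0:
        raise ValueError("CV ratio is undefined when both CVs are zero")
    return cv_female / (cv_female + cv_male)


def _round_half_up(x: float, ndigits: int = 0) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def summarize_parameter(
    datasets: Iterable[StrainDataSet],
    parameter_key: str,
    threshold: int,
) -> ParameterSummary:
    """Aggregate the retained strain data sets of one parameter.

    Produces the per-parameter row of the main analysis: unweighted mean
    and sample SD (n-1) of the CV ratios, strict counts above/below 0.5
    with half-up integer percentages (ties sit in neither bucket and leave
    the percentage denominator), the ratio range, the total number of mice
    (females + males over all data sets) and the number of distinct
    contributing projects. No surviving data sets yield an ``empty``
    summary rather than an error.
    """
    pool = [d for d in datasets if d.parameter_key == parameter_key]
    if not pool:
        return ParameterSummary(
            parameter_key=parameter_key, threshold=threshold, n_datasets=0, empty=True
        )
    ratios = np.asarray([d.cv_ratio for d in pool], dtype=float)
    n = ratios.size
    n_gt = int((ratios > 0.5).sum())
    n_lt = int((ratios < 0.5).sum())
    n_tie = n - n_gt - n_lt
    denom = n_gt + n_lt
    pct_gt = int(_round_half_up(100.0 * n_gt / denom)) if denom else None
    pct_lt = int(_round_half_up(100.0 * n_lt / denom)) if denom else None
    return ParameterSummary(
        parameter_key=parameter_key,
        threshold=threshold,
        n_datasets=n,
        mean_cv_ratio=float(ratios.mean()),
        sd_cv_ratio=float(ratios.std(ddof=1)) if n > 1 else None,
        n_gt=n_gt,
        n_lt=n_lt,
        n_tie=n_tie,
        pct_gt=pct_gt,
        pct_lt=pct_lt,
        ratio_min=float(ratios.min()),
        ratio_max=float(ratios.max()),
        n_mice_total=sum(d.n_mice for d in pool),
        n_projects=len({d.project_id for d in pool}),
        empty=False,
    )


def chi_squared_equal_split(
    n_gt: int, n_lt: int, alpha: float = DEFAULT_ALPHA
) -> ChiSquaredResult:
    """Pearson chi-squared test of an even split between the two buckets.

    With expected counts (n_gt + n_lt)/2 in both cells the statistic
    collapses to (n_gt - n_lt)^2 / (n_gt + n_lt), df = 1, upper-tail p.
    No continuity correction is applied (classical Pearson). Zero total
    count yields a non-evaluable result instead of a division by zero.
    """
    if n_gt < 0 or n_lt < 0:
        raise ValueError("counts must be non-negative")
    total = n_gt + n_lt
    if total == 0:
        return ChiSquaredResult(
            statistic=math.nan, df=1, p_value=math.nan, significant=False, evaluable=False
        )
    statistic = (n_gt - n_lt) ** 2 / total
    p_value = float(sps.chi2.sf(statistic, df=1))
    return ChiSquaredResult(
        statistic=float(statistic),
        df=1,
        p_value=p_value,
        significant=bool(p_value < alpha),
    )


def flag_mean_vs_proportion(summary: ParameterSummary) -> bool:
    """Mean on one side of 0.5, majority of data sets on the other.

    True iff sign(mean - 0.5) differs from sign(n_gt - n_lt) with both
    non-zero; either quantity exactly at its neutral point (mean = 0.5, or
    an even gt/lt split) agrees with nothing and never raises the flag.
    """
    if summary.empty:
        raise ValueError("mean-vs-proportion flag needs a non-empty summary")
    mean_side = _sign(summary.mean_cv_ratio - 0.5)
    count_side = _sign(summary.n_gt - summary.n_lt)
    return mean_side != 0 and count_side != 0 and mean_side != count_side


def flag_cross_threshold(
    summary5: ParameterSummary, summary10: ParameterSummary
) -> bool:
    """Mean CV ratio on strictly opposite sides of 0.5 at the two
    group-size thresholds (> 0.5 at n >= 5 but < 0.5 at n >= 10, or vice
    versa). A mean exactly at 0.5 never counts as a flip."""
    if summary5.empty or summary10.empty:
        raise ValueError("cross-threshold flag needs two non-empty summaries")
    if summary5.parameter_key != summary10.parameter_key:
        raise ValueError("summaries describe different parameters")
    s5 = _sign(summary5.mean_cv_ratio - 0.5)
    s10 = _sign(summary10.mean_cv_ratio - 0.5)
    return s5 != 0 and s10 != 0 and s5 != s10


def significant_in_both(
    summary5: ParameterSummary,
    summary10: ParameterSummary,
    alpha: float = DEFAULT_ALPHA,
) -> bool:
    """Equal-split test rejects at both thresholds for this parameter.

    The criterion behind "a consistent significant deviation from the even
    split in both analyses": each threshold's (n_gt, n_lt) counts must be
    individually significant at ``alpha``.
    """
    if summary5.empty or summary10.empty:
        return False
    return (
        chi_squared_equal_split(summary5.n_gt, summary5.n_lt, alpha).significant
        and chi_squared_equal_split(summary10.n_gt, summary10.n_lt, alpha).significant
    )


def compute_consistency_flags(
    summary5: Optional[ParameterSummary],
    summary10: Optional[ParameterSummary],
    alpha: float = DEFAULT_ALPHA,
) -> ConsistencyFlags:
    """All three robustness flags for one parameter; None marks a flag that
    is not evaluable because a required summary is empty or missing.

    The mean-vs-proportion flag is raised if the inconsistency appears in
    either threshold analysis.
    """
    key = (summary5 or summary10).parameter_key
    s5_ok = summary5 is not None and not summary5.empty
    s10_ok = summary10 is not None and not summary10.empty
    mvp: Optional[bool]
    if s5_ok or s10_ok:
        mvp = False
        if s5_ok:
            mvp = mvp or flag_mean_vs_proportion(summary5)
        if s10_ok:
            mvp = mvp or flag_mean_vs_proportion(summary10)
    else:
        mvp = None
    cross = (
        flag_cross_threshold(summary5, summary10) if (s5_ok and s10_ok) else None
    )
    sig = (
        significant_in_both(summary5, summary10, alpha) if (s5_ok and s10_ok) else None
    )
    return ConsistencyFlags(
        parameter_key=key,
        mean_vs_proportion_inconsistent=mvp,
        cross_threshold_inconsistent=cross,
        significant_in_both=sig,
    )


def _sign(x: float) -> int:
    if x > 0:
        return 1
    if x < 0:
        return -1
    return 0
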