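"""Domain types for the CV-ratio pipeline.

The atomic unit of every analysis is the *strain data set*: the female and
male groups of one strain, for one blood parameter, within one project.
Everything upstream (per-animal records, per-sex group summaries) exists to
build strain data sets; everything downstream (per-parameter and per-family
summaries) counts them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class Sex(str, Enum):
    FEMALE = "f"
    MALE = "m"


class StrainClass(str, Enum):
    """Genetic background class of a mouse line.

    Strain-survey analyses keep genetically uniform lines (classical inbred,
    Collaborative Cross-derived inbred, F1 hybrid, recombinant inbred) and
    drop everything else (outbred stocks, lines with newly generated
    alleles), which callers mark as OTHER.
    """

    INBRED = "inbred"
    CC_INBRED = "cc_inbred"
    F1_HYBRID = "f1_hybrid"
    RECOMBINANT_INBRED = "recombinant_inbred"
    OTHER = "other"


class ExclusionReason(str, Enum):
    NONE = "none"
    FEMALE_CV = "female_cv"
    MALE_CV = "male_cv"
    BOTH_CV = "both_cv"


@dataclass(frozen=True)
class ParameterDef:
    """One blood parameter, identified by a short key and, where available,
    a vertebrate trait (VT) ontology term."""

    key: str
    display_name: str
    vt_term: Optional[str] = None


@dataclass(slots=True)
class AnimalMeasurement:
    """One animal's value for one parameter in one project."""

    project_id: str
    parameter_key: str
    strain: str
    strain_class: StrainClass
    sex: Sex
    age_weeks: float
    treated: bool
    value: float

    def __post_init__(self) -> None:
        if not isinstance(self.sex, Sex):
            self.sex = Sex(self.sex)
        if not isinstance(self.strain_class, StrainClass):
            self.strain_class = StrainClass(self.strain_class)
        if self.age_weeks < 0:
            raise ValueError(f"age_weeks must be >= 0, got {self.age_weeks}")


@dataclass(slots=True)
class SexGroupSummary:
    """n / mean / SD / CV for one strain x sex x parameter x project group.

    ``cv`` is standard deviation divided by mean (sample SD, n-1
    denominator), computed on the raw measurement scale. ``degenerate``
    marks groups whose SD is undefined (n = 1) or whose mean is
    non-positive; such groups never survive the default selection.
    """

    project_id: str
    parameter_key: str
    strain: str
    sex: Sex
    n: int
    mean: float
    sd: float
    cv: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.sex, Sex):
            self.sex = Sex(self.sex)
        if self.n < 1:
            raise ValueError(f"group size must be >= 1, got {self.n}")


@dataclass(slots=True)
class StrainDataSet:
    """Paired female + male group summaries with the CV ratio.

    cv_ratio = female CV / (female CV + male CV): 0.5 means equal
    variability in both sexes, > 0.5 means females more variable.
    """

    project_id: str
    parameter_key: str
    strain: str
    female: SexGroupSummary
    male: SexGroupSummary
    cv_ratio: float
    excluded: bool = False
    exclusion_reason: ExclusionReason = ExclusionReason.NONE

    def __post_init__(self) -> None:
        if self.female.sex is not Sex.FEMALE or self.male.sex is not Sex.MALE:
            raise ValueError("female/male summaries carry the wrong sex code")
        for attr in ("project_id", "parameter_key", "strain"):
            if getattr(self.female, attr) != getattr(self, attr) or getattr(
                self.male, attr
            ) != getattr(self, attr):
                raise ValueError(f"{attr} differs between the paired summaries")
        if self.excluded != (self.exclusion_reason is not ExclusionReason.NONE):
            raise ValueError("excluded flag inconsistent with exclusion_reason")

    @property
    def n_mice(self) -> int:
        return self.female.n + self.male.n


@dataclass(frozen=True)
class ParameterSummary:
    """One per-parameter row of the main analysis at one group-size threshold.

    Counts of strain data sets above / below a CV ratio of 0.5 are strict;
    exact ties are tracked separately, excluded from the percentage
    denominator but included in mean / SD / range. An ``empty`` summary
    records that the selection left no data sets for the parameter.
    """

    parameter_key: str
    threshold: int
    n_datasets: int
    mean_cv_ratio: Optional[float] = None
    sd_cv_ratio: Optional[float] = None
    n_gt: int = 0
    n_lt: int = 0
    n_tie: int = 0
    pct_gt: Optional[int] = None
    pct_lt: Optional[int] = None
    ratio_min: Optional[float] = None
    ratio_max: Optional[float] = None
    n_mice_total: int = 0
    n_projects: int = 0
    empty: bool = False

    def __post_init__(self) -> None:
        if self.n_gt + self.n_lt + self.n_tie != self.n_datasets:
            raise ValueError("n_gt + n_lt + n_tie must equal n_datasets")
        if self.empty != (self.n_datasets == 0):
            raise ValueError("empty flag inconsistent with n_datasets")
        if self.n_datasets >= 1 and not (
            self.ratio_min - 1e-12 <= self.mean_cv_ratio <= self.ratio_max + 1e-12
        ):
            raise ValueError("mean CV ratio outside its min-max range")


@dataclass(frozen=True)
class StrainParameterSummary:
    """Mean CV ratio of one parameter within one inbred-strain family.

    ``gt_half`` compares the unrounded mean against 0.5, so a mean that
    prints as "0.50" can still be flagged as female-more-variable.
    ``sd_cv_ratio`` is None for a single data set (SD undefined).
    """

    strain_family: str
    parameter_key: str
    n_datasets: int
    mean_cv_ratio: float
    sd_cv_ratio: Optional[float]
    gt_half: bool

    def __post_init__(self) -> None:
        if self.n_datasets < 1:
            raise ValueError("a strain-parameter summary needs >= 1 data set")
        expected = self.mean_cv_ratio > 0.5
        if self.gt_half != expected and not math.isnan(self.mean_cv_ratio):
            raise ValueError("gt_half must reflect the unrounded mean")


@dataclass(frozen=True)
class ChiSquaredResult:
    """Equal-split goodness-of-fit test on the (n_gt, n_lt) counts.

    The Pearson statistic against a 50/50 split of two cells reduces to
    (n_gt - n_lt)^2 / (n_gt + n_lt) on 1 degree of freedom.
    """

    statistic: float
    df: int
    p_value: float
    significant: bool
    evaluable: bool = True


@dataclass(frozen=True)
class ConsistencyFlags:
    """Robustness flags for one parameter across the two threshold analyses.

    mean_vs_proportion_inconsistent: the pooled mean CV ratio falls on the
    opposite side of 0.5 from the majority of individual data sets, in
    either threshold analysis.
    cross_threshold_inconsistent: the mean CV ratio crosses 0.5 between the
    two thresholds.
    significant_in_both: the equal-split test rejects at both thresholds.
    None means not evaluable (a required summary was empty).
    """

    parameter_key: str
    mean_vs_proportion_inconsistent: Optional[bool]
    cross_threshold_inconsistent: Optional[bool]
    significant_in_both: Optional[bool]
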