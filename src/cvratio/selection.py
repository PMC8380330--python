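"""Data-set selection: eligibility filtering, group summarization, sex
pairing and the high-CV outlier exclusion.

The selection reproduces the strain-survey inclusion rules: genetically
uniform lines only, untreated animals, ages 7-26 weeks inclusive, and at
least ``min_n_per_sex`` animals in both the female and the male group.
Data sets in which either sex shows a CV above 0.5 are treated as
outliers (technical artefacts or unrecognized sources of variability) and
excluded from the main analysis; the exclusion is optional so that the
per-strain-family analysis can run on the unfiltered pool.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import ConfigurationError
from .model import (
    AnimalMeasurement,
    ExclusionReason,
    Sex,
    SexGroupSummary,
    StrainClass,
    StrainDataSet,
)
from .stats import cv_ratio

logger = logging.getLogger(__name__)

DEFAULT_STRAIN_CLASSES = frozenset(
    {
        StrainClass.INBRED,
        StrainClass.CC_INBRED,
        StrainClass.F1_HYBRID,
        StrainClass.RECOMBINANT_INBRED,
    }
)


@dataclass(frozen=True)
class SelectionCriteria:
    """Eligibility rules for animals and strain data sets.

    Defaults reproduce the published selection: inbred-type lines, no
    treatment, 7-26 weeks of age (inclusive bounds), n >= 5 per sex, and
    exclusion of data sets with a female and/or male CV > 0.5 (strict
    inequality; a CV of exactly 0.5 is kept).
    """

    allowed_strain_classes: frozenset = DEFAULT_STRAIN_CLASSES
    require_untreated: bool = True
    age_min_weeks: float = 7.0
    age_max_weeks: float = 26.0
    min_n_per_sex: int = 5
    outlier_cv_threshold: Optional[float] = 0.5
    apply_outlier_exclusion: bool = True

    def __post_init__(self) -> None:
        if self.age_min_weeks > self.age_max_weeks:
            raise ConfigurationError("age_min_weeks must be <= age_max_weeks")
        if self.min_n_per_sex < 1:
            raise ConfigurationError("min_n_per_sex must be >= 1")
        if self.outlier_cv_threshold is not None and self.outlier_cv_threshold <= 0:
            raise ConfigurationError("outlier_cv_threshold must be positive")


@dataclass(frozen=True)
class RejectedAnimal:
    """One animal that failed eligibility, with the first failing rule
    (checked in the fixed order strain_class -> treatment -> age)."""

    measurement: AnimalMeasurement
    reason: str  # "strain_class" | "treatment" | "age"


@dataclass(frozen=True)
class DroppedGroupKey:
    """A (project, parameter, strain) combination that could not be paired."""

    project_id: str
    parameter_key: str
    strain: str
    reason: str  # "missing_sex" | "undersized" | "degenerate"


def filter_animals(
    measurements: Iterable[AnimalMeasurement], criteria: SelectionCriteria
) -> tuple[list[AnimalMeasurement], list[RejectedAnimal]]:
    """Partition animals into eligible and rejected-with-reason.

    The age window is inclusive on both bounds ("7-26 weeks"). Each
    rejection carries exactly one reason: the first failing rule in the
    order strain_class -> treatment -> age, so logs are deterministic.
    """
    kept: list[AnimalMeasurement] = []
    rejected: list[RejectedAnimal] = []
    for m in measurements:
        if m.strain_class not in criteria.allowed_strain_classes:
            rejected.append(RejectedAnimal(m, "strain_class"))
        elif criteria.require_untreated and m.treated:
            rejected.append(RejectedAnimal(m, "treatment"))
        elif not (criteria.age_min_weeks <= m.age_weeks <= criteria.age_max_weeks):
            rejected.append(RejectedAnimal(m, "age"))
        else:
            kept.append(m)
    return kept, rejected


def summarize_groups(
    measurements: Iterable[AnimalMeasurement],
) -> list[SexGroupSummary]:
    """Collapse animals into per-(project, parameter, strain, sex) groups.

    Mean and sample SD (n-1 denominator) are computed on the raw
    measurement scale; CV = SD/mean. A single-animal group has no defined
    SD and is emitted with sd = 0 and ``degenerate`` set (it cannot survive
    any min_n_per_sex >= 2 anyway); a non-positive mean likewise flags the
    group degenerate because every parameter in scope is strictly positive.
    """
    buckets: dict[tuple[str, str, str, Sex], list[float]] = {}
    for m in measurements:
        buckets.setdefault(
            (m.project_id, m.parameter_key, m.strain, m.sex), []
        ).append(m.value)
    summaries: list[SexGroupSummary] = []
    for (project_id, parameter_key, strain, sex), values in buckets.items():
        arr = np.asarray(values, dtype=float)
        n = arr.size
        mean = float(arr.mean())
        sd = float(arr.std(ddof=1)) if n > 1 else 0.0
        degenerate = n == 1 or mean <= 0
        cv = sd / mean if mean > 0 else math.nan
        summaries.append(
            SexGroupSummary(
                project_id=project_id,
                parameter_key=parameter_key,
                strain=strain,
                sex=sex,
                n=n,
                mean=mean,
                sd=sd,
                cv=cv,
                degenerate=degenerate,
            )
        )
    return summaries


def pair_datasets(
    group_summaries: Iterable[SexGroupSummary],
    criteria: SelectionCriteria,
) -> tuple[list[StrainDataSet], list[DroppedGroupKey]]:
    """Pair female and male groups into strain data sets.

    A data set exists only where BOTH sexes reach ``min_n_per_sex``.
    Combinations lacking one sex, under the size threshold, or with both
    CVs exactly zero (the CV ratio would be 0/0) are dropped with a logged
    reason; the division is never attempted.
    """
    by_key: dict[tuple[str, str, str], dict[Sex, SexGroupSummary]] = {}
    for g in group_summaries:
        by_key.setdefault((g.project_id, g.parameter_key, g.strain), {})[g.sex] = g
    datasets: list[StrainDataSet] = []
    dropped: list[DroppedGroupKey] = []
    for (project_id, parameter_key, strain), sexes in by_key.items():
        female = sexes.get(Sex.FEMALE)
        male = sexes.get(Sex.MALE)
        if female is None or male is None:
            dropped.append(
                DroppedGroupKey(project_id, parameter_key, strain, "missing_sex")
            )
            continue
        if female.n < criteria.min_n_per_sex or male.n < criteria.min_n_per_sex:
            dropped.append(
                DroppedGroupKey(project_id, parameter_key, strain, "undersized")
            )
            continue
        if (
            (female.cv == 0 and male.cv == 0)
            or math.isnan(female.cv)
            or math.isnan(male.cv)
        ):
            dropped.append(
                DroppedGroupKey(project_id, parameter_key, strain, "degenerate")
            )
            continue
        datasets.append(
            StrainDataSet(
                project_id=project_id,
                parameter_key=parameter_key,
                strain=strain,
                female=female,
                male=male,
                cv_ratio=cv_ratio(female.cv, male.cv),
            )
        )
    if dropped:
        logger.info("pairing dropped %d group combinations", len(dropped))
    return datasets, dropped


def apply_outlier_exclusion(
    datasets: Iterable[StrainDataSet], threshold: float = 0.5
) -> tuple[list[StrainDataSet], list[StrainDataSet]]:
    """Split data sets into (kept, excluded) by the high-CV outlier rule.

    A data set is excluded iff the female and/or the male group has a CV
    strictly above ``threshold``; the exclusion reason records which sex
    triggered it (female_cv / male_cv / both_cv), supporting the
    female/male/both outlier breakdown of the main analysis.
    """
    kept: list[StrainDataSet] = []
    excluded: list[StrainDataSet] = []
    for d in datasets:
        f_out = d.female.cv > threshold
        m_out = d.male.cv > threshold
        if not f_out and not m_out:
            kept.append(d)
            continue
        if f_out and m_out:
            reason = ExclusionReason.BOTH_CV
        elif f_out:
            reason = ExclusionReason.FEMALE_CV
        else:
            reason = ExclusionReason.MALE_CV
        excluded.append(replace(d, excluded=True, exclusion_reason=reason))
    return kept, excluded


@dataclass
class SelectionResult:
    """Full bookkeeping of one selection run."""

    datasets: list[StrainDataSet]
    excluded: list[StrainDataSet] = field(default_factory=list)
    rejected_animals: list[RejectedAnimal] = field(default_factory=list)
    dropped_groups: list[DroppedGroupKey] = field(default_factory=list)

    @property
    def exclusion_counts(self) -> dict[str, int]:
        counts = {r.value: 0 for r in ExclusionReason if r is not ExclusionReason.NONE}
        for d in self.excluded:
            counts[d.exclusion_reason.value] += 1
        return counts


def select_datasets(
    measurements: Iterable[AnimalMeasurement], criteria: SelectionCriteria
) -> SelectionResult:
    """Run the whole selection: filter animals, summarize groups, pair
    sexes, and (optionally) exclude high-CV outlier data sets."""
    kept_animals, rejected = filter_animals(measurements, criteria)
    groups = summarize_groups(kept_animals)
    datasets, dropped = pair_datasets(groups, criteria)
    if criteria.apply_outlier_exclusion and criteria.outlier_cv_threshold is not None:
        datasets, excluded = apply_outlier_exclusion(
            datasets, criteria.outlier_cv_threshold
        )
    else:
        excluded = []
    return SelectionResult(
        datasets=datasets,
        excluded=excluded,
        rejected_animals=rejected,
        dropped_groups=dropped,
    )


def select_from_summaries(
    group_summaries: Iterable[SexGroupSummary], criteria: SelectionCriteria
) -> SelectionResult:
    """Selection entry point for per-group summary input (no animal-level
    filtering is possible; the caller vouches for age/treatment/class)."""
    datasets, dropped = pair_datasets(group_summaries, criteria)
    if criteria.apply_outlier_exclusion and criteria.outlier_cv_threshold is not None:
        datasets, excluded = apply_outlier_exclusion(
            datasets, criteria.outlier_cv_threshold
        )
    else:
        excluded = []
    return SelectionResult(datasets=datasets, excluded=excluded, dropped_groups=dropped)
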