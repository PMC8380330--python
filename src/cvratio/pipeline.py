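"""End-to-end orchestration of the two published analyses.

``analyze_parameters`` runs the per-parameter analysis twice, at per-sex
group-size thresholds of 5 and 10 animals (the threshold-10 pool is by
construction a subset of the threshold-5 pool), applies the high-CV
outlier exclusion, and derives the per-parameter consistency flags.
``analyze_strains`` runs the per-strain-family analysis: threshold 5, no
outlier exclusion, data sets pooled by designation prefix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .model import (
    AnimalMeasurement,
    ConsistencyFlags,
    ParameterSummary,
    StrainDataSet,
    StrainParameterSummary,
)
from .registry import ParameterRegistry, default_registry
from .selection import SelectionCriteria, SelectionResult, select_datasets
from .stats import DEFAULT_ALPHA, compute_consistency_flags, summarize_parameter
from .strains import StrainFamilyConfig, strain_overview, summarize_families

PARAMETER_THRESHOLDS = (5, 10)


@dataclass
class ParameterAnalysis:
    """Everything the per-parameter analysis produces."""

    summaries5: list[ParameterSummary]
    summaries10: list[ParameterSummary]
    flags: list[ConsistencyFlags]
    selection5: SelectionResult
    selection10: SelectionResult

    def summary(self, parameter_key: str, threshold: int) -> ParameterSummary:
        pool = self.summaries5 if threshold == 5 else self.summaries10
        for s in pool:
            if s.parameter_key == parameter_key:
                return s
        raise KeyError(parameter_key)


@dataclass
class FamilyOverview:
    """The two overview counts for one strain family."""

    strain_family: str
    n5_gt_half: int
    n5_total: int
    n1_gt_half: int
    n1_total: int


@dataclass
class StrainAnalysis:
    """Everything the per-strain-family analysis produces."""

    summaries: list[StrainParameterSummary]
    overviews: list[FamilyOverview]
    selection: SelectionResult


def analyze_parameters(
    measurements: Iterable[AnimalMeasurement],
    registry: Optional[ParameterRegistry] = None,
    criteria: SelectionCriteria = SelectionCriteria(),
    alpha: float = DEFAULT_ALPHA,
) -> ParameterAnalysis:
    """Run the per-parameter analysis at both group-size thresholds.

    Every parameter of the registry gets a row at each threshold, empty
    where the selection retained nothing. Flags are evaluable only where
    the needed summaries are non-empty.
    """
    registry = registry or default_registry()
    measurements = list(measurements)
    criteria5 = replace(criteria, min_n_per_sex=PARAMETER_THRESHOLDS[0])
    criteria10 = replace(criteria, min_n_per_sex=PARAMETER_THRESHOLDS[1])
    sel5 = select_datasets(measurements, criteria5)
    sel10 = select_datasets(measurements, criteria10)
    summaries5 = [
        summarize_parameter(sel5.datasets, key, PARAMETER_THRESHOLDS[0])
        for key in registry.keys
    ]
    summaries10 = [
        summarize_parameter(sel10.datasets, key, PARAMETER_THRESHOLDS[1])
        for key in registry.keys
    ]
    flags = [
        compute_consistency_flags(s5, s10, alpha)
        for s5, s10 in zip(summaries5, summaries10)
    ]
    return ParameterAnalysis(
        summaries5=summaries5,
        summaries10=summaries10,
        flags=flags,
        selection5=sel5,
        selection10=sel10,
    )


def analyze_strains(
    measurements: Iterable[AnimalMeasurement],
    registry: Optional[ParameterRegistry] = None,
    family_config: StrainFamilyConfig = StrainFamilyConfig(),
    criteria: SelectionCriteria = SelectionCriteria(),
) -> StrainAnalysis:
    """Run the per-strain-family analysis.

    Group-size threshold 5 per sex, outlier exclusion disabled (the family
    pools stay complete), data sets pooled by family designation prefix.
    Overviews count, per family, the parameters whose mean CV ratio
    exceeds 0.5 among those with >= 5 and >= 1 data sets.
    """
    registry = registry or default_registry()
    crit = replace(
        criteria, min_n_per_sex=PARAMETER_THRESHOLDS[0], apply_outlier_exclusion=False
    )
    sel = select_datasets(list(measurements), crit)
    summaries = summarize_families(sel.datasets, registry.keys, family_config)
    overviews = []
    for family in family_config.family_names:
        fam = [s for s in summaries if s.strain_family == family]
        n5_gt, n5_total = strain_overview(fam, min_datasets=5)
        n1_gt, n1_total = strain_overview(fam, min_datasets=1)
        overviews.append(
            FamilyOverview(
                strain_family=family,
                n5_gt_half=n5_gt,
                n5_total=n5_total,
                n1_gt_half=n1_gt,
                n1_total=n1_total,
            )
        )
    return StrainAnalysis(summaries=summaries, overviews=overviews, selection=sel)


def pooled_mean_cv_ratio(datasets: Sequence[StrainDataSet]) -> float:
    """Unweighted mean CV ratio over a pool of strain data sets."""
    if not datasets:
        raise ValueError("empty data-set pool")
    return float(np.mean([d.cv_ratio for d in datasets]))
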