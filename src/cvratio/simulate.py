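"""Seeded generator of strain-survey-style animal tables with known truth.

The generator emulates the structure of a multi-project strain survey:
several projects, each measuring a panel of strains in both sexes, with
group sizes of 5-30 animals and configurable per-sex coefficients of
variation. The female CV is ``cv_female_factor`` times the male CV, so
``k = 1`` is the no-sex-difference null and ``k = 1.37`` mirrors a 37%
variability inflation in one sex (the published group-housing effect size,
used here as the closest thing to a positive control). A configurable
fraction of data sets is contaminated with a high-variability sex group
(target CV drawn uniformly from (0.5, 0.9]) to exercise the outlier
exclusion; the contaminated side follows the female : male : both mix
observed in the survey data (1.1 : 0.6 : 0.6).

Values are lognormal by default (blood analytes are positive and
right-skewed), with the log-scale parameters chosen so that the arithmetic
mean and CV match the configured targets exactly; a truncated normal is
available for sensitivity checks. Ground truth (configured n/mean/CV and
outlier flags per group; expected keep/reject per animal under the default
selection) is emitted alongside, so tests never re-derive truth from data.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .errors import ConfigurationError
from .model import AnimalMeasurement, Sex, StrainClass
from .selection import SelectionCriteria

#: plausible central values per blood parameter (conventional mouse units);
#: CV-based analyses are scale-free, so these only anchor the simulated scale.
DEFAULT_BASE_MEANS: dict[str, float] = {
    "cholesterol": 95.0,
    "creatinine": 0.35,
    "glucose": 180.0,
    "total_protein": 5.2,
    "triglycerides": 110.0,
    "urea": 45.0,
    "uric_acid": 2.5,
    "ferritin": 3500.0,
    "transferrin": 1.9,
    "calcium": 9.5,
    "chloride": 112.0,
    "phosphorus": 7.5,
    "potassium": 5.5,
    "sodium": 150.0,
    "alt": 35.0,
    "ast": 75.0,
    "alpha_amylase": 2200.0,
    "ap": 90.0,
    "ck": 400.0,
    "lipase": 60.0,
    "hemoglobin": 14.5,
    "mcv": 48.0,
    "rbc": 9.5,
    "wbc": 7.0,
    "platelets": 1100.0,
}

_STRAIN_POOL: tuple[str, ...] = (
    "C57BL/6J",
    "C57BL/6NJ",
    "BALB/cJ",
    "BALB/cByJ",
    "A/J",
    "C3H/HeJ",
    "C3H/HeOuJ",
    "CBA/J",
    "CBA/CaJ",
    "DBA/2J",
    "DBA/1J",
    "129S1/SvImJ",
    "FVB/NJ",
    "NOD/ShiLtJ",
    "NZO/HlLtJ",
    "AKR/J",
    "SJL/J",
    "LP/J",
    "NZB/BlNJ",
    "PL/J",
    "SWR/J",
    "KK/HlJ",
    "SM/J",
    "CAST/EiJ",
    "PWK/PhJ",
    "WSB/EiJ",
    "MRL/MpJ",
    "BUB/BnJ",
    "CE/J",
    "I/LnJ",
)

#: female : male : both mix for which side of an outlier data set is inflated
_OUTLIER_SIDE_P = (1.1 / 2.3, 0.6 / 2.3, 0.6 / 2.3)


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one simulated survey.

    ``n_per_sex`` is either a fixed group size or an inclusive (lo, hi)
    range sampled per group. ``outlier_fraction`` is the probability that
    a strain data set is contaminated with at least one high-CV sex group.
    ``base_mean`` may be a single value, a per-parameter mapping, or None
    for the built-in per-parameter defaults.
    """

    n_projects: int = 5
    strains_per_project: int = 10
    parameters: tuple[str, ...] = ("glucose",)
    n_per_sex: Union[int, tuple[int, int]] = (5, 30)
    base_mean: Union[float, Mapping[str, float], None] = None
    cv_male: float = 0.2
    cv_female_factor: float = 1.0
    outlier_fraction: float = 0.0
    age_range: tuple[float, float] = (7.0, 26.0)
    treated_fraction: float = 0.0
    distribution: str = "lognormal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_projects < 1 or self.strains_per_project < 1:
            raise ConfigurationError("need at least one project and one strain")
        if not self.parameters:
            raise ConfigurationError("need at least one parameter")
        lo, hi = self.n_range
        if lo < 1 or hi < lo:
            raise ConfigurationError(f"invalid n_per_sex range ({lo}, {hi})")
        if self.cv_male <= 0 or self.cv_female_factor <= 0:
            raise ConfigurationError("cv_male and cv_female_factor must be positive")
        if not 0 <= self.outlier_fraction < 1:
            raise ConfigurationError("outlier_fraction must be in [0, 1)")
        if not 0 <= self.treated_fraction < 1:
            raise ConfigurationError("treated_fraction must be in [0, 1)")
        if self.age_range[0] < 0 or self.age_range[1] < self.age_range[0]:
            raise ConfigurationError(f"invalid age_range {self.age_range}")
        if self.distribution not in ("lognormal", "truncated_normal"):
            raise ConfigurationError(
                f"unknown distribution {self.distribution!r}; "
                "choose lognormal or truncated_normal"
            )

    @property
    def n_range(self) -> tuple[int, int]:
        if isinstance(self.n_per_sex, int):
            return (self.n_per_sex, self.n_per_sex)
        return (int(self.n_per_sex[0]), int(self.n_per_sex[1]))

    @property
    def cv_female(self) -> float:
        return self.cv_female_factor * self.cv_male

    def mean_for(self, parameter_key: str) -> float:
        if self.base_mean is None:
            return DEFAULT_BASE_MEANS.get(parameter_key, 100.0)
        if isinstance(self.base_mean, (int, float)):
            return float(self.base_mean)
        return float(self.base_mean[parameter_key])


@dataclass(frozen=True)
class GroupTruth:
    """Configured (not realized) properties of one emitted sex group."""

    project_id: str
    parameter_key: str
    strain: str
    sex: Sex
    n: int
    mean: float
    cv: float
    is_outlier: bool


@dataclass
class GeneratorTruth:
    """Ground truth emitted next to the data: one record per group, plus
    the expected keep/reject outcome per animal under the given criteria."""

    groups: list[GroupTruth]
    animal_expected_kept: list[bool]
    criteria: SelectionCriteria = field(default_factory=SelectionCriteria)

    @property
    def n_outlier_datasets(self) -> int:
        flagged = {
            (g.project_id, g.parameter_key, g.strain)
            for g in self.groups
            if g.is_outlier
        }
        return len(flagged)

    @property
    def n_datasets(self) -> int:
        return len({(g.project_id, g.parameter_key, g.strain) for g in self.groups})


def _strain_names(k: int) -> list[str]:
    names = list(_STRAIN_POOL[:k])
    names += [f"SIM{i:04d}/J" for i in range(len(names), k)]
    return names


def _sample_group(
    rng: np.random.Generator, n: int, mean: float, cv: float, distribution: str
) -> np.ndarray:
    if distribution == "lognormal":
        sigma = math.sqrt(math.log1p(cv * cv))
        mu = math.log(mean) - 0.5 * sigma * sigma
        return rng.lognormal(mean=mu, sigma=sigma, size=n)
    # truncated normal: resample the (rare) negative draws
    values = rng.normal(loc=mean, scale=cv * mean, size=n)
    while True:
        bad = values <= 0
        if not bad.any():
            return values
        values[bad] = rng.normal(loc=mean, scale=cv * mean, size=int(bad.sum()))


def generate(
    config: SimulationConfig,
    criteria: SelectionCriteria = SelectionCriteria(),
) -> tuple[list[AnimalMeasurement], GeneratorTruth]:
    """Generate a per-animal table and its ground truth.

    Output order is fully determined by the seed: projects, then strains,
    then parameters, then females before males. ``criteria`` only defines
    what the truth's expected keep/reject flags refer to; it does not
    change the generated data.
    """
    rng = np.random.default_rng(config.seed)
    strains = _strain_names(config.strains_per_project)
    lo, hi = config.n_range
    records: list[AnimalMeasurement] = []
    groups: list[GroupTruth] = []
    expected_kept: list[bool] = []
    for p in range(config.n_projects):
        project_id = f"SIMPROJ{p + 1:04d}"
        for strain in strains:
            for parameter_key in config.parameters:
                base_mean = config.mean_for(parameter_key)
                is_outlier_ds = (
                    config.outlier_fraction > 0
                    and rng.random() < config.outlier_fraction
                )
                if is_outlier_ds:
                    side = rng.choice(3, p=_OUTLIER_SIDE_P)  # 0=f, 1=m, 2=both
                    inflate = {
                        Sex.FEMALE: side in (0, 2),
                        Sex.MALE: side in (1, 2),
                    }
                else:
                    inflate = {Sex.FEMALE: False, Sex.MALE: False}
                for sex, base_cv in (
                    (Sex.FEMALE, config.cv_female),
                    (Sex.MALE, config.cv_male),
                ):
                    n = int(rng.integers(lo, hi + 1)) if hi > lo else lo
                    cv = base_cv
                    if inflate[sex]:
                        cv = float(rng.uniform(0.5, 0.9))
                    values = _sample_group(rng, n, base_mean, cv, config.distribution)
                    ages = rng.uniform(config.age_range[0], config.age_range[1], size=n)
                    treated = (
                        rng.random(n) < config.treated_fraction
                        if config.treated_fraction > 0
                        else np.zeros(n, dtype=bool)
                    )
                    groups.append(
                        GroupTruth(
                            project_id=project_id,
                            parameter_key=parameter_key,
                            strain=strain,
                            sex=sex,
                            n=n,
                            mean=base_mean,
                            cv=cv,
                            is_outlier=bool(inflate[sex]),
                        )
                    )
                    for j in range(n):
                        m = AnimalMeasurement(
                            project_id=project_id,
                            parameter_key=parameter_key,
                            strain=strain,
                            strain_class=StrainClass.INBRED,
                            sex=sex,
                            age_weeks=float(ages[j]),
                            treated=bool(treated[j]),
                            value=float(values[j]),
                        )
                        records.append(m)
                        expected_kept.append(_expected_kept(m, criteria))
    truth = GeneratorTruth(
        groups=groups, animal_expected_kept=expected_kept, criteria=criteria
    )
    return records, truth


def _expected_kept(m: AnimalMeasurement, criteria: SelectionCriteria) -> bool:
    if m.strain_class not in criteria.allowed_strain_classes:
        return False
    if criteria.require_untreated and m.treated:
        return False
    return criteria.age_min_weeks <= m.age_weeks <= criteria.age_max_weeks


# ---------------------------------------------------------------------------
# scenario presets

_LARGE = dict(n_projects=25, strains_per_project=20, n_per_sex=200)

_SCENARIOS: dict[str, dict] = {
    # 500 data sets of n = 200/sex: large enough that sample CVs sit on
    # their targets and the pooled mean CV ratio is a sharp estimate.
    "null_equal_cv": dict(cv_female_factor=1.0, **_LARGE),
    "female_inflated_37": dict(cv_female_factor=1.37, **_LARGE),
    "male_inflated_37": dict(cv_female_factor=1.0 / 1.37, **_LARGE),
    # outlier contamination at the rate observed in the survey data (2.3%
    # of strain data sets), with survey-like group sizes
    "with_outliers": dict(
        n_projects=25,
        strains_per_project=20,
        n_per_sex=20,
        outlier_fraction=0.023,
    ),
}


def scenario(name: str, seed: int = 0) -> SimulationConfig:
    """A named preset configuration; unknown names raise with the list of
    available choices."""
    try:
        kwargs = _SCENARIOS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown scenario {name!r}; choose one of {sorted(_SCENARIOS)}"
        ) from None
    return SimulationConfig(seed=seed, **kwargs)


def scenario_names() -> list[str]:
    return sorted(_SCENARIOS)


# ---------------------------------------------------------------------------
# truth serialization (plain text, one row per group / per animal)


def write_truth(truth: GeneratorTruth, directory: Union[str, Path]) -> None:
    """Write truth_groups.csv and truth_animals.csv under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "truth_groups.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(
            ["project_id", "parameter_key", "strain", "sex", "n", "mean", "cv", "is_outlier"]
        )
        for g in truth.groups:
            writer.writerow(
                [
                    g.project_id,
                    g.parameter_key,
                    g.strain,
                    g.sex.value,
                    g.n,
                    repr(g.mean),
                    repr(g.cv),
                    str(g.is_outlier).lower(),
                ]
            )
    with open(directory / "truth_animals.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["animal_index", "expected_kept"])
        for i, kept in enumerate(truth.animal_expected_kept):
            writer.writerow([i, str(kept).lower()])
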