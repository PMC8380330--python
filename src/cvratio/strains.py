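"""Per-strain-family analysis: pool strain data sets by designation prefix
and summarize CV ratios per family x parameter.

Laboratory strain designations encode a family as a prefix: "C57BL/6J" and
"C57BL/6NJ" are both C57BL/6 substrains. The family analysis pools all
data sets whose strain designation starts with a configured prefix and
asks, per blood parameter, whether the mean CV ratio exceeds 0.5. Unlike
the per-parameter analysis this one runs WITHOUT the high-CV outlier
exclusion, so that sparse family pools are not thinned further.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import yaml

from .errors import ConfigurationError
from .model import StrainDataSet, StrainParameterSummary

#: the six classical inbred families most often examined in strain surveys;
#: CBA uses the prefix "CBA/" so that e.g. "CBAXYZ" novelty names do not
#: match, and DBA/2 pools every DBA/2 substrain (DBA/2J, DBA/2NCrl, ...).
DEFAULT_FAMILIES: tuple[tuple[str, str], ...] = (
    ("A/J", "A/J"),
    ("BALB/c", "BALB/c"),
    ("C3H", "C3H"),
    ("C57BL/6", "C57BL/6"),
    ("CBA", "CBA/"),
    ("DBA/2J", "DBA/2"),
)


@dataclass(frozen=True)
class StrainFamilyConfig:
    """Ordered (family_name, designation_prefix) pairs.

    Prefix matching is case-sensitive on the canonical designation; when a
    strain matches several prefixes the longest prefix wins, so configs may
    list both "C57BL/6" and "C57BL/6N" as distinct families.
    """

    families: tuple[tuple[str, str], ...] = DEFAULT_FAMILIES

    def __post_init__(self) -> None:
        names = [f for f, _ in self.families]
        if len(set(names)) != len(names):
            raise ConfigurationError("family names must be unique")
        if any(not p for _, p in self.families):
            raise ConfigurationError("family prefixes must be non-empty")

    @property
    def family_names(self) -> list[str]:
        return [name for name, _ in self.families]


def load_family_config(path: Union[str, Path]) -> StrainFamilyConfig:
    """Load a family config from YAML: a ``families`` list of
    ``{name, prefix}`` mappings."""
    doc = yaml.safe_load(Path(path).read_text("utf-8"))
    try:
        entries = doc["families"]
        families = tuple((e["name"], e["prefix"]) for e in entries)
    except (TypeError, KeyError) as exc:
        raise ConfigurationError(
            "family config must contain a 'families' list of {name, prefix}"
        ) from exc
    return StrainFamilyConfig(families=families)


def assign_family(
    strain_name: str, config: StrainFamilyConfig = StrainFamilyConfig()
) -> Optional[str]:
    """Family of a strain designation, or None if no prefix matches."""
    best: Optional[tuple[str, str]] = None
    for name, prefix in config.families:
        if strain_name.startswith(prefix):
            if best is None or len(prefix) > len(best[1]):
                best = (name, prefix)
    return best[0] if best else None


def summarize_strain_parameter(
    datasets: Iterable[StrainDataSet],
    family: str,
    parameter_key: str,
    config: StrainFamilyConfig = StrainFamilyConfig(),
) -> Optional[StrainParameterSummary]:
    """Mean +/- SD of the CV ratio over one family's data sets for one
    parameter.

    Returns None when the family contributed no data sets for the
    parameter (an absent cell). The SD is None for a single data set.
    ``gt_half`` compares the unrounded mean against 0.5.
    """
    ratios = [
        d.cv_ratio
        for d in datasets
        if d.parameter_key == parameter_key and assign_family(d.strain, config) == family
    ]
    if not ratios:
        return None
    arr = np.asarray(ratios, dtype=float)
    mean = float(arr.mean())
    return StrainParameterSummary(
        strain_family=family,
        parameter_key=parameter_key,
        n_datasets=arr.size,
        mean_cv_ratio=mean,
        sd_cv_ratio=float(arr.std(ddof=1)) if arr.size > 1 else None,
        gt_half=mean > 0.5,
    )


def summarize_families(
    datasets: Sequence[StrainDataSet],
    parameter_keys: Sequence[str],
    config: StrainFamilyConfig = StrainFamilyConfig(),
) -> list[StrainParameterSummary]:
    """All non-empty family x parameter summaries, in config x parameter
    order."""
    out: list[StrainParameterSummary] = []
    for family in config.family_names:
        for key in parameter_keys:
            s = summarize_strain_parameter(datasets, family, key, config)
            if s is not None:
                out.append(s)
    return out


def strain_overview(
    family_summaries: Iterable[StrainParameterSummary], min_datasets: int
) -> tuple[int, int]:
    """(parameters with mean CV ratio > 0.5, parameters counted) for one
    family.

    A parameter is counted when it has at least ``min_datasets`` data sets;
    among the counted ones, those flagged ``gt_half`` form the numerator.
    With ``min_datasets=1`` this is the all-data overview; with 5 it keeps
    only parameters with reasonably supported means.
    """
    summaries = list(family_summaries)
    families = {s.strain_family for s in summaries}
    if len(families) > 1:
        raise ValueError(f"overview expects one family, got {sorted(families)}")
    counted = [s for s in summaries if s.n_datasets >= min_datasets]
    gt = sum(1 for s in counted if s.gt_half)
    return gt, len(counted)
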