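"""Reading and writing the delimiter-separated tables the pipeline uses.

Two ingestion paths mirror how strain-survey repositories distribute data:
per-animal records (one row per mouse) and per-group summaries (one row per
strain x sex group with n / mean / SD). Both are plain UTF-8 text with one
header row; the delimiter (comma or tab) is sniffed unless fixed in the
dialect.

Column headers are mapped onto canonical field names through a
:class:`TableDialect`; the default dialect understands both the canonical
names and MPD-style headers (``projsym``, ``varname``, ...).
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .errors import ConfigurationError, DataError
from .model import (
    AnimalMeasurement,
    ConsistencyFlags,
    ParameterSummary,
    Sex,
    SexGroupSummary,
    StrainClass,
    StrainParameterSummary,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

#: canonical field -> accepted header spellings (matched case-insensitively)
DEFAULT_ALIASES: dict[str, tuple[str, ...]] = {
    "project_id": ("project_id", "projsym", "project"),
    "parameter_key": ("parameter_key", "parameter", "varname"),
    "strain": ("strain",),
    "strain_class": ("strain_class",),
    "sex": ("sex",),
    "age_weeks": ("age_weeks", "age_wks", "age"),
    "treated": ("treated",),
    "value": ("value",),
    "n": ("n", "nmice", "count"),
    "mean": ("mean",),
    "sd": ("sd", "stddev", "std"),
}

_SEX_CODES = {"f": Sex.FEMALE, "female": Sex.FEMALE, "m": Sex.MALE, "male": Sex.MALE}
_TRUE = {"true", "t", "1", "yes", "y"}
_FALSE = {"false", "f", "0", "no", "n", ""}


@dataclass(frozen=True)
class TableDialect:
    """How to read a delimited table: delimiter plus header mapping.

    ``delimiter`` of None means sniff between comma and tab. ``columns``
    maps canonical field names to the exact header used in the file and
    takes precedence over the built-in aliases.
    """

    delimiter: Optional[str] = None
    columns: Mapping[str, str] = field(default_factory=dict)


DEFAULT_DIALECT = TableDialect()


@dataclass(frozen=True)
class RowIssue:
    """One skipped or invalid input row (1-based data row index)."""

    row: int
    reason: str


@dataclass
class ReadResult:
    """Parsed records plus the rows that could not be used."""

    records: list
    skipped: list[RowIssue] = field(default_factory=list)

    @property
    def n_skipped(self) -> int:
        return len(self.skipped)


def _read_frame(path: PathLike, dialect: TableDialect) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    sep = dialect.delimiter
    try:
        if sep is None:
            frame = pd.read_csv(
                path, sep=None, engine="python", dtype=str, keep_default_na=False
            )
        else:
            frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise DataError(f"empty input file: {path}") from exc
    frame.columns = [str(c).strip() for c in frame.columns]
    return frame


def _resolve_columns(
    frame: pd.DataFrame,
    dialect: TableDialect,
    required: Sequence[str],
    optional: Sequence[str] = (),
) -> dict[str, str]:
    lower = {c.lower(): c for c in frame.columns}
    mapping: dict[str, str] = {}
    for canonical in (*required, *optional):
        override = dialect.columns.get(canonical)
        if override is not None:
            if override not in frame.columns:
                raise ConfigurationError(
                    f"dialect maps {canonical!r} to header {override!r}, "
                    f"which is not in the file (headers: {list(frame.columns)})"
                )
            mapping[canonical] = override
            continue
        for alias in DEFAULT_ALIASES[canonical]:
            if alias in lower:
                mapping[canonical] = lower[alias]
                break
    missing = [c for c in required if c not in mapping]
    if missing:
        raise ConfigurationError(
            f"cannot map required column(s) {missing} onto headers "
            f"{list(frame.columns)}; supply a TableDialect with explicit columns"
        )
    return mapping


def _parse_sex(raw: str) -> Optional[Sex]:
    return _SEX_CODES.get(raw.strip().lower())


def _parse_bool(raw: str) -> Optional[bool]:
    token = raw.strip().lower()
    if token in _TRUE:
        return True
    if token in _FALSE:
        return False
    return None


def read_animal_table(
    path: PathLike, dialect: TableDialect = DEFAULT_DIALECT
) -> ReadResult:
    """Read per-animal measurements.

    Rows with a missing or unparseable value, sex or age are collected in
    ``skipped`` and logged, never fatal. A file without a ``strain_class``
    or ``treated`` column is usable: such animals default to classical
    inbred / untreated with a single logged warning.
    """
    frame = _read_frame(path, dialect)
    cols = _resolve_columns(
        frame,
        dialect,
        required=("project_id", "parameter_key", "strain", "sex", "age_weeks", "value"),
        optional=("strain_class", "treated"),
    )
    if "strain_class" not in cols:
        logger.warning(
            "%s: no strain_class column; defaulting every animal to 'inbred'", path
        )
    if "treated" not in cols:
        logger.warning("%s: no treated column; assuming all animals untreated", path)

    records: list[AnimalMeasurement] = []
    skipped: list[RowIssue] = []
    class_values = set(StrainClass._value2member_map_)
    data = {canon: frame[col].tolist() for canon, col in cols.items()}
    for i in range(1, len(frame) + 1):
        get = lambda canon: str(data[canon][i - 1]).strip() if canon in data else ""
        raw_value = get("value")
        if raw_value == "":
            skipped.append(RowIssue(i, "missing value"))
            continue
        sex = _parse_sex(get("sex"))
        if sex is None:
            skipped.append(RowIssue(i, f"missing or unknown sex code {get('sex')!r}"))
            continue
        try:
            value = float(raw_value)
        except ValueError:
            skipped.append(RowIssue(i, f"non-numeric value {raw_value!r}"))
            continue
        try:
            age = float(get("age_weeks"))
        except ValueError:
            skipped.append(RowIssue(i, f"non-numeric age {get('age_weeks')!r}"))
            continue
        if age < 0:
            skipped.append(RowIssue(i, f"negative age {age}"))
            continue
        raw_class = get("strain_class") or StrainClass.INBRED.value
        if raw_class.lower() not in class_values:
            skipped.append(RowIssue(i, f"unknown strain_class {raw_class!r}"))
            continue
        treated = _parse_bool(get("treated"))
        if treated is None:
            skipped.append(RowIssue(i, f"unparseable treated flag {get('treated')!r}"))
            continue
        records.append(
            AnimalMeasurement(
                project_id=get("project_id"),
                parameter_key=get("parameter_key"),
                strain=get("strain"),
                strain_class=StrainClass(raw_class.lower()),
                sex=sex,
                age_weeks=age,
                treated=treated,
                value=value,
            )
        )
    if skipped:
        logger.info("%s: skipped %d of %d rows", path, len(skipped), len(frame))
    return ReadResult(records=records, skipped=skipped)


def read_group_summary_table(
    path: PathLike, dialect: TableDialect = DEFAULT_DIALECT
) -> ReadResult:
    """Read per-group summaries (one row per strain x sex group).

    The CV is always recomputed as sd/mean, overriding any CV column in the
    file. Blood parameters are strictly positive, so a group with mean <= 0
    is flagged invalid and excluded; n < 1 rejects the row.
    """
    frame = _read_frame(path, dialect)
    cols = _resolve_columns(
        frame,
        dialect,
        required=("project_id", "parameter_key", "strain", "sex", "n", "mean", "sd"),
    )
    records: list[SexGroupSummary] = []
    skipped: list[RowIssue] = []
    data = {canon: frame[col].tolist() for canon, col in cols.items()}
    for i in range(1, len(frame) + 1):
        get = lambda canon: str(data[canon][i - 1]).strip()
        sex = _parse_sex(get("sex"))
        if sex is None:
            skipped.append(RowIssue(i, f"missing or unknown sex code {get('sex')!r}"))
            continue
        try:
            n = int(float(get("n")))
            mean = float(get("mean"))
            sd = float(get("sd"))
        except ValueError:
            skipped.append(RowIssue(i, "non-numeric n/mean/sd"))
            continue
        if n < 1:
            skipped.append(RowIssue(i, f"group size {n} < 1"))
            continue
        if mean <= 0:
            skipped.append(RowIssue(i, f"non-positive mean {mean} (invalid group)"))
            continue
        if sd < 0:
            skipped.append(RowIssue(i, f"negative sd {sd}"))
            continue
        records.append(
            SexGroupSummary(
                project_id=get("project_id"),
                parameter_key=get("parameter_key"),
                strain=get("strain"),
                sex=sex,
                n=n,
                mean=mean,
                sd=sd,
                cv=sd / mean,
            )
        )
    if skipped:
        logger.info("%s: skipped %d of %d rows", path, len(skipped), len(frame))
    return ReadResult(records=records, skipped=skipped)


# ---------------------------------------------------------------------------
# writers


def format_ratio(x: Optional[float]) -> str:
    """Render a CV ratio: two decimals, three when two would print "0.50".

    A mean that sits so close to the equal-variability point that it rounds
    to 0.50 is ambiguous at two decimals, so one more digit is shown
    (0.496, 0.501, ...). None renders as the empty-cell marker.
    """
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "-"
    two = Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    if two == Decimal("0.50"):
        three = Decimal(repr(x)).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP)
        return f"{three:.3f}"
    return f"{two:.2f}"


def _fmt(x) -> str:
    if x is None:
        return "-"
    if isinstance(x, float) and math.isnan(x):
        return "-"
    if isinstance(x, bool):
        return str(x).lower()
    return repr(x) if isinstance(x, float) else str(x)


def write_group_summary_table(
    summaries: Sequence[SexGroupSummary], path: PathLike, delimiter: str = ","
) -> None:
    """Write group summaries; floats use shortest-exact repr so a write/read
    round trip reproduces n/mean/sd bit-exactly."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(
            ["project_id", "parameter_key", "strain", "sex", "n", "mean", "sd", "cv"]
        )
        for s in summaries:
            writer.writerow(
                [
                    s.project_id,
                    s.parameter_key,
                    s.strain,
                    s.sex.value,
                    s.n,
                    repr(s.mean),
                    repr(s.sd),
                    repr(s.cv),
                ]
            )


def write_animal_table(
    records: Sequence[AnimalMeasurement], path: PathLike, delimiter: str = ","
) -> None:
    """Write per-animal measurements in the canonical column layout."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(
            [
                "project_id",
                "parameter_key",
                "strain",
                "strain_class",
                "sex",
                "age_weeks",
                "treated",
                "value",
            ]
        )
        for r in records:
            writer.writerow(
                [
                    r.project_id,
                    r.parameter_key,
                    r.strain,
                    r.strain_class.value,
                    r.sex.value,
                    repr(float(r.age_weeks)),
                    str(r.treated).lower(),
                    repr(float(r.value)),
                ]
            )


PARAMETER_TABLE_COLUMNS = [
    "parameter_key",
    "threshold",
    "n_datasets",
    "mean_cv_ratio",
    "sd_cv_ratio",
    "pct_gt",
    "n_gt",
    "pct_lt",
    "n_lt",
    "n_tie",
    "ratio_min",
    "ratio_max",
    "n_mice_total",
    "n_projects",
    "empty",
]


def write_parameter_summary_table(
    summaries: Sequence[ParameterSummary], path: PathLike, delimiter: str = ","
) -> None:
    """Write one row per parameter in the main-table column order.

    Ratio columns use :func:`format_ratio`; a parameter for which the
    selection retained nothing is rendered as a marker row of "-" cells
    with ``empty=true``.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(PARAMETER_TABLE_COLUMNS)
        for s in summaries:
            if s.empty:
                row = [s.parameter_key, s.threshold] + ["-"] * 12 + ["true"]
                writer.writerow(row)
                continue
            writer.writerow(
                [
                    s.parameter_key,
                    s.threshold,
                    s.n_datasets,
                    format_ratio(s.mean_cv_ratio),
                    format_ratio(s.sd_cv_ratio) if s.sd_cv_ratio is not None else "-",
                    _fmt(s.pct_gt),
                    s.n_gt,
                    _fmt(s.pct_lt),
                    s.n_lt,
                    s.n_tie,
                    format_ratio(s.ratio_min),
                    format_ratio(s.ratio_max),
                    s.n_mice_total,
                    s.n_projects,
                    "false",
                ]
            )


def write_strain_summary_table(
    summaries: Sequence[StrainParameterSummary], path: PathLike, delimiter: str = ","
) -> None:
    """Write family x parameter summaries in long form.

    ``gt_half`` is an explicit boolean column (the analogue of the bold
    typography in printed tables); SD is "-" for single-data-set cells.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(
            [
                "strain_family",
                "parameter_key",
                "n_datasets",
                "mean_cv_ratio",
                "sd_cv_ratio",
                "gt_half",
            ]
        )
        for s in summaries:
            writer.writerow(
                [
                    s.strain_family,
                    s.parameter_key,
                    s.n_datasets,
                    format_ratio(s.mean_cv_ratio),
                    format_ratio(s.sd_cv_ratio) if s.sd_cv_ratio is not None else "-",
                    str(s.gt_half).lower(),
                ]
            )


def write_consistency_flags_table(
    flags: Sequence[ConsistencyFlags], path: PathLike, delimiter: str = ","
) -> None:
    """Write per-parameter robustness flags; None renders as "-" (not
    evaluable)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(
            [
                "parameter_key",
                "mean_vs_proportion_inconsistent",
                "cross_threshold_inconsistent",
                "significant_in_both",
            ]
        )
        for f in flags:
            writer.writerow(
                [
                    f.parameter_key,
                    _fmt(f.mean_vs_proportion_inconsistent),
                    _fmt(f.cross_threshold_inconsistent),
                    _fmt(f.significant_in_both),
                ]
            )
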