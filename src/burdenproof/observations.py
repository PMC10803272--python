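"""Observation-level data model and I/O for relative-risk extraction tables.

One :class:`ObservationRecord` holds a single reported effect size — a
relative risk (odds and hazard ratios are ingested as RR without
conversion, since all three are pooled as one relative measure) — together
with its uncertainty, the exposure-definition fields used by the
prioritization cascade, and binary bias-covariate flags.

All modelling downstream happens on the natural-log scale; see
:func:`to_log_scale`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields

import pandas as pd

__all__ = [
    "Design",
    "SmokingStatus",
    "ExposureLocation",
    "ExposureSource",
    "ExposureTiming",
    "SexScope",
    "SubgroupLevel",
    "EndpointType",
    "ObservationRecord",
    "ValidationError",
    "SchemaError",
    "RowError",
    "to_log_scale",
    "read_extraction_table",
    "write_extraction_table",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class ValidationError(ValueError):
    """An ObservationRecord violates a type invariant."""


class SchemaError(ValueError):
    """An extraction table is missing required columns."""


class Design(str, enum.Enum):
    PROSPECTIVE_COHORT = "prospective_cohort"
    CASE_CONTROL = "case_control"
    NESTED_CASE_CONTROL = "nested_case_control"
    RETROSPECTIVE_COHORT = "retrospective_cohort"
    CASE_COHORT = "case_cohort"
    CASE_CROSSOVER = "case_crossover"


class SmokingStatus(str, enum.Enum):
    NEVER = "never"
    FORMER = "former"
    NONSMOKER = "nonsmoker"
    ANY_UNSPECIFIED = "any_unspecified"
    ADJUSTED_NEVER = "adjusted_never"


class ExposureLocation(str, enum.Enum):
    HOME_OR_WORK = "home_or_work"
    HOME = "home"
    WORK = "work"
    ANY_UNSPECIFIED = "any_unspecified"


class ExposureSource(str, enum.Enum):
    FAMILY = "family"
    PARENTAL = "parental"
    MATERNAL = "maternal"
    PATERNAL = "paternal"
    SPOUSE = "spouse"
    ANY_UNSPECIFIED = "any_unspecified"


class ExposureTiming(str, enum.Enum):
    CURRENT = "current"
    EVER = "ever"


class SexScope(str, enum.Enum):
    BOTH = "both"
    FEMALE = "female"
    MALE = "male"


class SubgroupLevel(str, enum.Enum):
    WHOLE_POPULATION = "whole_population"
    SEX_SPECIFIC = "sex_specific"
    AGE_SPECIFIC = "age_specific"
    OTHER_SUBGROUP = "other_subgroup"


class EndpointType(str, enum.Enum):
    INCIDENCE = "incidence"
    MORTALITY = "mortality"
    COMBINED = "combined"


@dataclass
class ObservationRecord:
    """One reported effect size with its uncertainty and descriptors.

    Exactly one of the CI pair ``(ci_lower, ci_upper)`` or ``se_log_rr``
    must resolve to a positive standard error on the log-RR scale.
    ``bias_flags`` maps bias-covariate names to 0/1 indicators relative to
    the gold-standard (all-zero) study.
    """

    obs_id: str
    study_id: str
    outcome_id: str
    rr: float
    ci_lower: float | None = None
    ci_upper: float | None = None
    se_log_rr: float | None = None
    design: Design = Design.PROSPECTIVE_COHORT
    smoking_status: SmokingStatus = SmokingStatus.NONSMOKER
    exposure_location: ExposureLocation = ExposureLocation.HOME_OR_WORK
    exposure_source: ExposureSource = ExposureSource.ANY_UNSPECIFIED
    exposure_timing: ExposureTiming = ExposureTiming.CURRENT
    sex_scope: SexScope = SexScope.BOTH
    children_only: bool = False
    subgroup_level: SubgroupLevel = SubgroupLevel.WHOLE_POPULATION
    endpoint_type: EndpointType = EndpointType.COMBINED
    adjustment_rank: int = 0
    group_key: str = ""
    mutually_exclusive: bool = True
    bias_flags: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # coerce plain strings so records can be built from parsed text
        for f, cls in _ENUM_FIELDS.items():
            v = getattr(self, f)
            if not isinstance(v, cls):
                setattr(self, f, cls(v))
        self.validate()

    def validate(self) -> None:
        if not (self.rr > 0):
            raise ValidationError(f"{self.obs_id}: rr must be positive, got {self.rr}")
        has_ci = self.ci_lower is not None and self.ci_upper is not None
        if has_ci:
            if not (0 < self.ci_lower <= self.rr <= self.ci_upper):
                raise ValidationError(
                    f"{self.obs_id}: CI ({self.ci_lower}, {self.ci_upper}) "
                    f"inconsistent with rr={self.rr}"
                )
        if self.se_log_rr is not None and not (self.se_log_rr > 0):
            raise ValidationError(f"{self.obs_id}: se_log_rr must be positive")
        if not has_ci and self.se_log_rr is None:
            raise ValidationError(f"{self.obs_id}: need a CI pair or se_log_rr")
        if (
            self.smoking_status is SmokingStatus.ADJUSTED_NEVER
            and not self.children_only
        ):
            raise ValidationError(
                f"{self.obs_id}: adjusted_never smoking status is only defined "
                "for children-only samples"
            )
        for name, v in self.bias_flags.items():
            if v not in (0, 1):
                raise ValidationError(f"{self.obs_id}: bias flag {name!r} not in {{0,1}}")


_ENUM_FIELDS = {
    "design": Design,
    "smoking_status": SmokingStatus,
    "exposure_location": ExposureLocation,
    "exposure_source": ExposureSource,
    "exposure_timing": ExposureTiming,
    "sex_scope": SexScope,
    "subgroup_level": SubgroupLevel,
    "endpoint_type": EndpointType,
}


def to_log_scale(record: ObservationRecord) -> tuple[float, float]:
    """Return ``(log_rr, se_log_rr)`` for a record.

    ``log_rr = ln(rr)``.  When no standard error is reported the 95% CI is
    assumed symmetric on the log scale, giving
    ``se = (ln(ci_upper) - ln(ci_lower)) / (2 * 1.96)``.
    """
    log_rr = math.log(record.rr)
    if record.se_log_rr is not None:
        return log_rr, record.se_log_rr
    if record.ci_lower == record.ci_upper:
        raise ValidationError(
            f"{record.obs_id}: zero-width CI gives zero variance"
        )
    se = (math.log(record.ci_upper) - math.log(record.ci_lower)) / (2.0 * Z_95)
    return log_rr, se


# --- CSV extraction dialect -------------------------------------------------
#
# Fixed header, comma-separated UTF-8.  Bias covariates are stored as one
# column per flag, prefixed "bias_".  The column dictionary shipped in
# docs/column_dictionary.md documents every field.

_SCALAR_COLUMNS = [
    "obs_id", "study_id", "outcome_id", "rr", "ci_lower", "ci_upper",
    "se_log_rr", "design", "smoking_status", "exposure_location",
    "exposure_source", "exposure_timing", "sex_scope", "children_only",
    "subgroup_level", "endpoint_type", "adjustment_rank", "group_key",
    "mutually_exclusive",
]
_REQUIRED_COLUMNS = ["obs_id", "study_id", "outcome_id", "rr"]
BIAS_PREFIX = "bias_"


@dataclass
class RowError:
    """A rejected input row: 1-based data row number plus the reason."""

    row: int
    message: str


def _parse_optional_float(v) -> float | None:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    if isinstance(v, str):
        v = v.replace("−", "-")  # normalize Unicode minus
    return float(v)


def _parse_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    return str(v).strip().lower() in ("true", "1", "yes")


def read_extraction_table(
    path, schema: dict[str, str] | None = None
) -> tuple[list[ObservationRecord], list[RowError]]:
    """Read a CSV extraction table.

    Parameters
    ----------
    path
        Delimited UTF-8 text file with a header row.
    schema
        Optional mapping of canonical column name -> column name in the
        file, for tables using a different layout.

    Returns
    -------
    records, errors
        Valid rows as records, and per-row validation failures with their
        1-based data row numbers.  A missing required column raises
        :class:`SchemaError` instead.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    bias_cols = [c for c in df.columns if c.startswith(BIAS_PREFIX)]
    records: list[ObservationRecord] = []
    errors: list[RowError] = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        try:
            kwargs = {
                "obs_id": row["obs_id"],
                "study_id": row["study_id"],
                "outcome_id": row["outcome_id"],
                "rr": _parse_optional_float(row["rr"]),
                "ci_lower": _parse_optional_float(row.get("ci_lower")),
                "ci_upper": _parse_optional_float(row.get("ci_upper")),
                "se_log_rr": _parse_optional_float(row.get("se_log_rr")),
                "children_only": _parse_bool(row.get("children_only", False)),
                "adjustment_rank": int(row.get("adjustment_rank", 0) or 0),
                "group_key": row.get("group_key", ""),
                "mutually_exclusive": _parse_bool(row.get("mutually_exclusive", True)),
                "bias_flags": {
                    c[len(BIAS_PREFIX):]: int(row[c]) for c in bias_cols if row[c] != ""
                },
            }
            for f in _ENUM_FIELDS:
                if f in row and row[f] != "":
                    kwargs[f] = row[f]
            if kwargs["rr"] is None:
                raise ValidationError("rr is empty")
            records.append(ObservationRecord(**kwargs))
        except (ValidationError, ValueError) as exc:
            errors.append(RowError(row=i, message=str(exc)))
    return records, errors


def write_extraction_table(records, path) -> None:
    """Write records to the CSV extraction dialect (lossless round trip)."""
    records = list(records)
    bias_names = sorted({n for r in records for n in r.bias_flags})
    rows = []
    for r in records:
        row = {}
        for f in fields(r):
            if f.name == "bias_flags":
                continue
            v = getattr(r, f.name)
            row[f.name] = v.value if isinstance(v, enum.Enum) else v
        for n in bias_names:
            row[BIAS_PREFIX + n] = r.bias_flags.get(n, 0)
        rows.append(row)
    cols = _SCALAR_COLUMNS + [BIAS_PREFIX + n for n in bias_names]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
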