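"""Prioritization cascade and repeat-measurement standard-error inflation.

Each included study may report several effect sizes for the same outcome
(different exposure definitions, subgroups, adjustment sets).  The cascade
reduces them to the analysis set:

1. exposure definition — best-available smoking status, then exposure
   location, then source, then timing, each judged against an ordered list
   of priority *tiers* (values inside one tier are equivalent, e.g. home
   and work exposure both being components of the home-or-work reference
   definition);
2. granularity — whole-population rows over sex-/age-specific subgroups,
   combined incidence+mortality endpoints over either alone, aggregate
   outcomes over subtypes (configurable label list);
3. adjustment — the most-adjusted remaining rows.

Rows that survive every stage with identical cascade attributes and group
key are true duplicates and are reduced to one deterministically (smallest
standard error, then obs_id).

After selection, observations reported for multiple non-mutually-exclusive
exposure groups within one age–sex–smoking-status group are down-weighted:
each of the k repeats has its standard error inflated by sqrt(k), so the
group jointly carries one observation's inverse-variance weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from .observations import (
    EndpointType,
    ExposureLocation,
    ExposureSource,
    ExposureTiming,
    ObservationRecord,
    SmokingStatus,
    SubgroupLevel,
    to_log_scale,
)

__all__ = ["SelectionConfig", "AuditEntry", "select_observations",
           "drop_subtype_outcomes", "adjust_se_for_repeats"]

Tiers = list[list[str]]


def _default_smoking_priority() -> Tiers:
    # nonsmoker matches the reference definition exactly; never/former (and
    # adjusted-never, treated as never) are its components; any/unspecified last
    return [
        [SmokingStatus.NONSMOKER.value],
        [SmokingStatus.NEVER.value, SmokingStatus.ADJUSTED_NEVER.value,
         SmokingStatus.FORMER.value],
        [SmokingStatus.ANY_UNSPECIFIED.value],
    ]


def _default_location_priority() -> Tiers:
    return [
        [ExposureLocation.HOME_OR_WORK.value],
        [ExposureLocation.HOME.value, ExposureLocation.WORK.value],
        [ExposureLocation.ANY_UNSPECIFIED.value],
    ]


def _default_source_priority() -> Tiers:
    # all specific sources are equivalent components; unspecified last
    return [
        [ExposureSource.FAMILY.value, ExposureSource.PARENTAL.value,
         ExposureSource.MATERNAL.value, ExposureSource.PATERNAL.value,
         ExposureSource.SPOUSE.value],
        [ExposureSource.ANY_UNSPECIFIED.value],
    ]


def _default_timing_priority() -> Tiers:
    return [[ExposureTiming.CURRENT.value], [ExposureTiming.EVER.value]]


@dataclass
class SelectionConfig:
    """Priority tiers and granularity preferences for the cascade.

    Each priority attribute is an ordered list of tiers (lists of enum
    values); flattened, it must be a permutation of the admissible values.
    A bare string entry is promoted to a singleton tier.
    """

    smoking_priority: Tiers = field(default_factory=_default_smoking_priority)
    location_priority: Tiers = field(default_factory=_default_location_priority)
    source_priority: Tiers = field(default_factory=_default_source_priority)
    timing_priority: Tiers = field(default_factory=_default_timing_priority)
    prefer_combined_endpoint: bool = True
    prefer_whole_population: bool = True
    subtype_outcomes: dict[str, list[str]] = field(default_factory=dict)
    """Aggregate outcome label -> subtype labels dropped when it is present."""

    def __post_init__(self) -> None:
        for name, enum_cls in [
            ("smoking_priority", SmokingStatus),
            ("location_priority", ExposureLocation),
            ("source_priority", ExposureSource),
            ("timing_priority", ExposureTiming),
        ]:
            tiers = [[t] if isinstance(t, str) else list(t)
                     for t in getattr(self, name)]
            setattr(self, name, tiers)
            flat = sorted(v for tier in tiers for v in tier)
            expected = sorted(e.value for e in enum_cls)
            if flat != expected:
                raise ValueError(
                    f"{name} must flatten to a permutation of "
                    f"{expected}, got {flat}"
                )


@dataclass
class AuditEntry:
    obs_id: str
    eliminated_by_rule: str


def _rank(value: str, tiers: Tiers) -> int:
    for i, tier in enumerate(tiers):
        if value in tier:
            return i
    raise ValueError(f"value {value!r} not in priority tiers {tiers}")


def drop_subtype_outcomes(
    records: list[ObservationRecord], config: SelectionConfig
) -> tuple[list[ObservationRecord], list[AuditEntry]]:
    """Within each study, drop subtype-outcome rows when the aggregate
    outcome is also reported (e.g. ischemic/hemorrhagic stroke vs stroke)."""
    audit: list[AuditEntry] = []
    kept: list[ObservationRecord] = []
    by_study: dict[str, set[str]] = {}
    for r in records:
        by_study.setdefault(r.study_id, set()).add(r.outcome_id)
    drop_of = {
        sub: agg for agg, subs in config.subtype_outcomes.items() for sub in subs
    }
    for r in records:
        agg = drop_of.get(r.outcome_id)
        if agg is not None and agg in by_study[r.study_id]:
            audit.append(AuditEntry(r.obs_id, f"subtype_of:{agg}"))
        else:
            kept.append(r)
    return kept, audit


def select_observations(
    records: list[ObservationRecord],
    config: SelectionConfig | None = None,
) -> tuple[list[ObservationRecord], list[AuditEntry]]:
    """Apply the prioritization cascade within each study × outcome.

    Returns the retained records (input order preserved) and an audit log
    naming the rule that eliminated each dropped observation.
    """
    if config is None:
        config = SelectionConfig()
    records = list(records)
    if not records:
        warnings.warn("select_observations: empty input", stacklevel=2)
        return [], []

    outcomes = {r.outcome_id for r in records}
    if len(outcomes) > 1:
        raise ValueError(
            f"records span multiple outcomes {sorted(outcomes)}; "
            "apply drop_subtype_outcomes and split by outcome first"
        )

    audit: list[AuditEntry] = []
    kept: list[ObservationRecord] = []
    by_study: dict[str, list[ObservationRecord]] = {}
    for r in records:
        by_study.setdefault(r.study_id, []).append(r)

    for group in by_study.values():
        kept.extend(_select_within_study(group, config, audit))
    kept_ids = {r.obs_id for r in kept}
    return [r for r in records if r.obs_id in kept_ids], audit


def _filter_best(group, keyfunc, rule, audit):
    best = min(keyfunc(r) for r in group)
    out = []
    for r in group:
        if keyfunc(r) == best:
            out.append(r)
        else:
            audit.append(AuditEntry(r.obs_id, rule))
    return out


def _select_within_study(group, config: SelectionConfig, audit):
    # stage 1: exposure definition, one attribute at a time
    stages = [
        ("smoking_status", lambda r: _rank(r.smoking_status.value,
                                           config.smoking_priority)),
        ("exposure_location", lambda r: _rank(r.exposure_location.value,
                                              config.location_priority)),
        ("exposure_source", lambda r: _rank(r.exposure_source.value,
                                            config.source_priority)),
        ("exposure_timing", lambda r: _rank(r.exposure_timing.value,
                                            config.timing_priority)),
    ]
    for rule, key in stages:
        group = _filter_best(group, key, rule, audit)

    # stage 2: least granular
    if config.prefer_whole_population:
        group = _filter_best(
            group,
            lambda r: 0 if r.subgroup_level is SubgroupLevel.WHOLE_POPULATION else 1,
            "subgroup_level", audit,
        )
    if config.prefer_combined_endpoint:
        group = _filter_best(
            group,
            lambda r: 0 if r.endpoint_type is EndpointType.COMBINED else 1,
            "endpoint_type", audit,
        )

    # stage 3: most adjusted
    group = _filter_best(group, lambda r: -r.adjustment_rank,
                         "adjustment_rank", audit)

    # exact duplicates (same cascade attributes and group key): keep one,
    # smallest se then obs_id, for reproducibility
    def dup_key(r):
        return (r.smoking_status, r.exposure_location, r.exposure_source,
                r.exposure_timing, r.subgroup_level, r.endpoint_type,
                r.adjustment_rank, r.sex_scope, r.group_key)

    by_dup: dict[tuple, list[ObservationRecord]] = {}
    for r in group:
        by_dup.setdefault(dup_key(r), []).append(r)
    out = []
    for dups in by_dup.values():
        dups.sort(key=lambda r: (to_log_scale(r)[1], r.obs_id))
        out.append(dups[0])
        for r in dups[1:]:
            audit.append(AuditEntry(r.obs_id, "duplicate_tie_break"))
    return out


def adjust_se_for_repeats(
    records: list[ObservationRecord], factor: str = "sqrt_k"
) -> list[ObservationRecord]:
    """Inflate standard errors of non-mutually-exclusive repeats.

    Within each study, every group_key holding k >= 2 retained
    non-mutually-exclusive observations has each member's se multiplied by
    sqrt(k) (``factor="sqrt_k"``, default: the k repeats jointly carry one
    observation's inverse-variance weight) or by k (``factor="k"``, the
    literal reading of a factor matching the number of repeats).

    Records whose se came from a CI have it materialized into
    ``se_log_rr`` so the inflation is explicit.
    """
    if factor not in ("sqrt_k", "k"):
        raise ValueError("factor must be 'sqrt_k' or 'k'")
    counts: dict[tuple[str, str], int] = {}
    for r in records:
        if not r.mutually_exclusive:
            key = (r.study_id, r.group_key)
            counts[key] = counts.get(key, 0) + 1
    out = []
    for r in records:
        k = counts.get((r.study_id, r.group_key), 1) if not r.mutually_exclusive else 1
        if k >= 2:
            _, se = to_log_scale(r)
            mult = k ** 0.5 if factor == "sqrt_k" else float(k)
            out.append(replace(r, se_log_rr=se * mult,
                               ci_lower=None, ci_upper=None))
        else:
            out.append(r)
    return out
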