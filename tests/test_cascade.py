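import itertools
import math

import numpy as np
import pytest

from burdenproof.cascade import (
    SelectionConfig, adjust_se_for_repeats, drop_subtype_outcomes,
    select_observations,
)
from burdenproof.observations import to_log_scale

from conftest import make_record

# independent brute-force reimplementation of the cascade rules, used as
# the oracle for randomized inputs
SMOKING_TIERS = [["nonsmoker"], ["never", "adjusted_never", "former"],
                 ["any_unspecified"]]
LOCATION_TIERS = [["home_or_work"], ["home", "work"], ["any_unspecified"]]
SOURCE_TIERS = [["family", "parental", "maternal", "paternal", "spouse"],
                ["any_unspecified"]]
TIMING_TIERS = [["current"], ["ever"]]


def brute_force_select(records):
    def tier(value, tiers):
        return next(i for i, t in enumerate(tiers) if value in t)

    kept = []
    for study in sorted({r.study_id for r in records}):
        group = [r for r in records if r.study_id == study]
        for attr, tiers in [("smoking_status", SMOKING_TIERS),
                            ("exposure_location", LOCATION_TIERS),
                            ("exposure_source", SOURCE_TIERS),
                            ("exposure_timing", TIMING_TIERS)]:
            best = min(tier(getattr(r, attr).value, tiers) for r in group)
            group = [r for r in group
                     if tier(getattr(r, attr).value, tiers) == best]
        if any(r.subgroup_level.value == "whole_population" for r in group):
            group = [r for r in group
                     if r.subgroup_level.value == "whole_population"]
        if any(r.endpoint_type.value == "combined" for r in group):
            group = [r for r in group if r.endpoint_type.value == "combined"]
        best_adj = max(r.adjustment_rank for r in group)
        group = [r for r in group if r.adjustment_rank == best_adj]
        # exact duplicates collapse to smallest se then obs_id
        seen = {}
        for r in group:
            key = (r.smoking_status, r.exposure_location, r.exposure_source,
                   r.exposure_timing, r.subgroup_level, r.endpoint_type,
                   r.adjustment_rank, r.sex_scope, r.group_key)
            seen.setdefault(key, []).append(r)
        for dups in seen.values():
            kept.append(min(dups, key=lambda r: (to_log_scale(r)[1], r.obs_id)))
    return sorted(r.obs_id for r in kept)


class TestSelectObservations:
    def test_single_observation_is_identity(self):
        recs = [make_record()]
        kept, audit = select_observations(recs)
        assert kept == recs and audit == []

    def test_whole_population_preferred_over_sex_specific(self):
        """A study reporting both sex-specific and aggregated estimates
        with identical exposure definitions keeps only the aggregate."""
        recs = [
            make_record(obs_id="agg", subgroup_level="whole_population"),
            make_record(obs_id="m", subgroup_level="sex_specific", sex_scope="male"),
            make_record(obs_id="f", subgroup_level="sex_specific", sex_scope="female"),
        ]
        kept, audit = select_observations(recs)
        assert [r.obs_id for r in kept] == ["agg"]
        assert {e.obs_id: e.eliminated_by_rule for e in audit} == {
            "m": "subgroup_level", "f": "subgroup_level"}

    def test_equal_tier_repeats_both_retained(self):
        """home and work rows are components of the same priority tier and
        both survive when the combined definition is absent."""
        recs = [
            make_record(obs_id="h", exposure_location="home", group_key="g",
                        mutually_exclusive=False),
            make_record(obs_id="w", exposure_location="work", group_key="g",
                        mutually_exclusive=False),
        ]
        kept, _ = select_observations(recs)
        assert sorted(r.obs_id for r in kept) == ["h", "w"]

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning):
            kept, audit = select_observations([])
        assert kept == [] and audit == []

    def test_matches_brute_force_oracle_on_randomized_attributes(self):
        rng = np.random.default_rng(2024)
        smoking = ["never", "former", "nonsmoker", "any_unspecified"]
        location = ["home_or_work", "home", "work", "any_unspecified"]
        source = ["family", "parental", "maternal", "paternal", "spouse",
                  "any_unspecified"]
        for trial in range(200):
            recs = []
            for i in range(6):
                recs.append(make_record(
                    obs_id=f"o{i}",
                    study_id=f"s{rng.integers(2)}",
                    se_log_rr=float(rng.uniform(0.05, 0.4)),
                    smoking_status=smoking[rng.integers(4)],
                    exposure_location=location[rng.integers(4)],
                    exposure_source=source[rng.integers(6)],
                    exposure_timing=["current", "ever"][rng.integers(2)],
                    subgroup_level=["whole_population", "sex_specific",
                                    "age_specific"][rng.integers(3)],
                    endpoint_type=["incidence", "mortality",
                                   "combined"][rng.integers(3)],
                    adjustment_rank=int(rng.integers(3)),
                    group_key=f"g{rng.integers(2)}",
                ))
            kept, audit = select_observations(recs)
            assert sorted(r.obs_id for r in kept) == brute_force_select(recs)
            # every input row is either kept or audited exactly once
            assert sorted([r.obs_id for r in kept]
                          + [e.obs_id for e in audit]) == sorted(
                              r.obs_id for r in recs)

    def test_selection_deterministic_under_input_order(self):
        recs = [make_record(obs_id=f"o{i}", adjustment_rank=i % 2,
                            se_log_rr=0.1 + 0.01 * i) for i in range(5)]
        ids1 = [r.obs_id for r in select_observations(recs)[0]]
        for perm in itertools.permutations(recs):
            ids2 = [r.obs_id for r in select_observations(list(perm))[0]]
            assert sorted(ids1) == sorted(ids2)

    def test_priority_list_must_be_permutation(self):
        with pytest.raises(ValueError, match="permutation"):
            SelectionConfig(timing_priority=[["current"]])

    def test_subtype_dropped_only_when_aggregate_present(self):
        cfg = SelectionConfig(subtype_outcomes={
            "stroke": ["ischemic_stroke", "hemorrhagic_stroke"]})
        recs = [
            make_record(obs_id="a", study_id="s1", outcome_id="stroke"),
            make_record(obs_id="b", study_id="s1", outcome_id="ischemic_stroke"),
            make_record(obs_id="c", study_id="s2", outcome_id="ischemic_stroke"),
        ]
        kept, audit = drop_subtype_outcomes(recs, cfg)
        assert [r.obs_id for r in kept] == ["a", "c"]
        assert audit[0].obs_id == "b"


class TestSeInflation:
    def test_no_repeats_is_identity(self):
        recs = [make_record(obs_id=f"o{i}", group_key=f"g{i}",
                            mutually_exclusive=False) for i in range(3)]
        assert adjust_se_for_repeats(recs) == recs

    def test_sqrt_k_rule_and_information_preservation(self):
        """k=4 repeats at se=0.1 each become se=0.2; the group's summed
        inverse variance equals one original observation's."""
        recs = [make_record(obs_id=f"o{i}", group_key="g", se_log_rr=0.1,
                            mutually_exclusive=False) for i in range(4)]
        out = adjust_se_for_repeats(recs)
        assert all(r.se_log_rr == pytest.approx(0.2) for r in out)
        total_weight = sum(1 / to_log_scale(r)[1] ** 2 for r in out)
        assert total_weight == pytest.approx(1 / 0.1**2)

    def test_literal_k_factor_switch(self):
        recs = [make_record(obs_id=f"o{i}", group_key="g", se_log_rr=0.1,
                            mutually_exclusive=False) for i in range(2)]
        out = adjust_se_for_repeats(recs, factor="k")
        assert all(r.se_log_rr == pytest.approx(0.2) for r in out)

    def test_inflation_is_local_to_the_repeating_study(self):
        pair = [make_record(obs_id=f"p{i}", study_id="s1", group_key="g",
                            se_log_rr=0.1, mutually_exclusive=False)
                for i in range(2)]
        lone = make_record(obs_id="q", study_id="s2", group_key="g",
                           se_log_rr=0.1, mutually_exclusive=False)
        out = adjust_se_for_repeats(pair + [lone])
        assert out[0].se_log_rr == pytest.approx(0.1 * math.sqrt(2))
        assert out[2].se_log_rr == 0.1

    def test_mutually_exclusive_groups_untouched(self):
        recs = [make_record(obs_id=f"o{i}", group_key="g", se_log_rr=0.1,
                            mutually_exclusive=True) for i in range(3)]
        assert adjust_se_for_repeats(recs) == recs

    def test_never_decreases_se(self):
        rng = np.random.default_rng(5)
        recs = [make_record(obs_id=f"o{i}", study_id=f"s{rng.integers(3)}",
                            group_key=f"g{rng.integers(2)}",
                            se_log_rr=float(rng.uniform(0.05, 0.5)),
                            mutually_exclusive=bool(rng.integers(2)))
                for i in range(30)]
        out = adjust_se_for_repeats(recs)
        for before, after in zip(recs, out):
            assert to_log_scale(after)[1] >= to_log_scale(before)[1] - 1e-15
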