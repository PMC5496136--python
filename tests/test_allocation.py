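"""Winner-takes-all allocation by salary rank, level splits and shares."""

import itertools
import math

import pytest

from cadreplan import (
    CadreCategory,
    CompetencyMatrix,
    CountryYearProfile,
    InterventionSpec,
    Level,
    WorkforceAssumptions,
    allocate,
    cadre_shares,
    compute_need,
    level_split_sensitivity,
    split_by_level,
)


def brute_force_allocate(need, matrix, cadres):
    """Independent oracle: enumerate interventions, pick min-rank competent cadre."""
    rank = {c.cadre_id: c.salary_rank for c in cadres}
    by_cadre = {c.cadre_id: 0.0 for c in cadres}
    assignments, unallocatable = {}, []
    for spec in need.catalogue:
        competent = sorted(
            (c for c in rank if matrix.is_competent(c, spec.intervention_id)),
            key=rank.__getitem__,
        )
        if not competent:
            unallocatable.append(spec.intervention_id)
            continue
        assignments[spec.intervention_id] = competent[0]
        by_cadre[competent[0]] += need.need_of(spec.intervention_id).fte
    return by_cadre, assignments, unallocatable


class TestAllocate:
    def test_lowest_paid_competent_cadre_wins(self, worked_example, cadres):
        """FTEs competent for ranks {2, 5} all go to rank 2."""
        catalogue, profile, assumptions = worked_example
        need = compute_need(catalogue, profile, assumptions)
        matrix = CompetencyMatrix.from_lists(
            {"ecv": ("midwife", "obstetrician_gynaecologist")}
        )
        result = allocate(need, matrix, cadres)
        assert result.assignments == {"ecv": "midwife"}
        assert math.isclose(result.fte_by_cadre["midwife"], need.total_fte)
        assert round(result.fte_by_cadre["midwife"], 2) == 5.83

    def test_single_competent_cadre_forced(self, toy_catalogue, toy_profile, cadres):
        need = compute_need(toy_catalogue, toy_profile)
        matrix = CompetencyMatrix.from_lists(
            {i.intervention_id: ("generalist_doctor",) for i in toy_catalogue}
        )
        result = allocate(need, matrix, cadres)
        assert set(result.assignments.values()) == {"generalist_doctor"}

    def test_matches_brute_force_on_mixed_matrix(self, toy_catalogue, toy_profile,
                                                 toy_matrix, cadres):
        need = compute_need(toy_catalogue, toy_profile)
        result = allocate(need, toy_matrix, cadres)
        by_cadre, assignments, unallocatable = brute_force_allocate(need, toy_matrix, cadres)
        assert result.assignments == assignments
        assert list(result.unallocatable) == unallocatable
        for cadre, fte in by_cadre.items():
            assert math.isclose(result.fte_by_cadre[cadre], fte, abs_tol=1e-12)

    def test_unallocatable_reported_not_fatal(self, toy_catalogue, toy_profile, cadres):
        need = compute_need(toy_catalogue, toy_profile)
        matrix = CompetencyMatrix.from_lists({"i1": ("midwife",)})  # i2, i3 uncovered
        result = allocate(need, matrix, cadres)
        assert set(result.unallocatable) == {"i2", "i3"}
        assert math.isclose(
            result.total_allocated_fte, need.need_of("i1").fte, rel_tol=1e-9
        )

    def test_empty_cadre_list_raises(self, toy_catalogue, toy_profile, toy_matrix):
        need = compute_need(toy_catalogue, toy_profile)
        with pytest.raises(ValueError):
            allocate(need, toy_matrix, [])

    def test_aggregates_conserve_total(self, toy_catalogue, toy_profile, toy_matrix, cadres):
        need = compute_need(toy_catalogue, toy_profile)
        result = allocate(need, toy_matrix, cadres)
        total = need.total_fte
        assert math.isclose(sum(result.fte_by_cadre.values()), total, rel_tol=1e-9)
        assert math.isclose(sum(result.fte_by_stage.values()), total, rel_tol=1e-9)
        assert math.isclose(sum(result.fte_by_level.values()), total, rel_tol=1e-9)
        assert math.isclose(
            sum(result.fte_by_cadre_and_stage.values()), total, rel_tol=1e-9
        )

    def test_rank_dominance(self, toy_catalogue, toy_profile, cadres):
        """Adding a lower-ranked competent cadre captures the intervention's FTEs."""
        need = compute_need(toy_catalogue, toy_profile)
        before = allocate(
            need, CompetencyMatrix.from_lists({"i1": ("midwife",)}), cadres
        )
        after = allocate(
            need, CompetencyMatrix.from_lists({"i1": ("auxiliary", "midwife")}), cadres
        )
        assert before.assignments["i1"] == "midwife"
        assert after.assignments["i1"] == "auxiliary"
        assert math.isclose(
            after.fte_by_cadre["auxiliary"], before.fte_by_cadre["midwife"]
        )


class TestSplitByLevel:
    def test_all_levels_uses_default_weights(self, cadres):
        """10 FTEs of all-level work split 6/3/1 at the default 60/30/10."""
        profile = CountryYearProfile("x", 2012, 1, 1, 1, 1, 1, rates={})
        # 10 FTEs = 10 x 1316 h = 789 600 min for one case: engineer via minutes
        cat = [InterventionSpec("a", "a", "pregnancy", 10 * 1316 * 60, 1,
                                "all_levels", "pregnancies", "ALL")]
        need = compute_need(cat, profile)
        assert math.isclose(need.total_fte, 10.0)
        by_level = split_by_level(need)
        assert math.isclose(by_level[Level.PRIMARY], 6.0)
        assert math.isclose(by_level[Level.SECONDARY], 3.0)
        assert math.isclose(by_level[Level.TERTIARY], 1.0)

    def test_single_level_intervention_keeps_its_level(self):
        profile = CountryYearProfile("x", 2012, 1, 1, 1, 1, 1, rates={})
        cat = [InterventionSpec("a", "a", "pregnancy", 10 * 1316 * 60, 1,
                                "primary", "pregnancies", "ALL")]
        need = compute_need(cat, profile)
        by_level = split_by_level(need)
        assert math.isclose(by_level[Level.PRIMARY], 10.0)
        assert by_level[Level.SECONDARY] == 0.0
        assert by_level[Level.TERTIARY] == 0.0

    def test_mixed_catalogue_matches_hand_weighted_sum(self, toy_catalogue, toy_profile):
        need = compute_need(toy_catalogue, toy_profile)
        f1 = need.need_of("i1").fte  # primary-only
        f2 = need.need_of("i2").fte  # all levels
        f3 = need.need_of("i3").fte  # tertiary-only
        by_level = split_by_level(need)
        assert math.isclose(by_level[Level.PRIMARY], f1 + 0.6 * f2, rel_tol=1e-12)
        assert math.isclose(by_level[Level.SECONDARY], 0.3 * f2, rel_tol=1e-12)
        assert math.isclose(by_level[Level.TERTIARY], f3 + 0.1 * f2, rel_tol=1e-12)
        assert math.isclose(sum(by_level.values()), need.total_fte, rel_tol=1e-9)


class TestCadreShares:
    def test_shares_normalise_to_100(self, toy_catalogue, toy_profile, toy_matrix, cadres):
        need = compute_need(toy_catalogue, toy_profile)
        shares = cadre_shares(allocate(need, toy_matrix, cadres))
        assert math.isclose(sum(shares.values()), 100.0, abs_tol=1e-9)

    def test_hand_ratio(self, cadres):
        from cadreplan.allocation import AllocationResult

        result = AllocationResult(
            fte_by_cadre={"midwife": 75.0, "auxiliary": 25.0},
            fte_by_stage={}, fte_by_level={}, fte_by_cadre_and_stage={},
            assignments={}, unallocatable=(),
        )
        assert cadre_shares(result) == {"midwife": 75.0, "auxiliary": 25.0}

    def test_zero_total_raises(self):
        from cadreplan.allocation import AllocationResult

        empty = AllocationResult({}, {}, {}, {}, {}, ())
        with pytest.raises(ValueError, match="no allocated need"):
            cadre_shares(empty)


class TestLevelSplitSensitivity:
    def test_all_multi_level_catalogue_shares_equal_weights(self):
        profile = CountryYearProfile("x", 2012, 1000, 500, 100, 80, 80, rates={})
        cat = [InterventionSpec("a", "a", "pregnancy", 30, 1, "all_levels",
                                "pregnancies", "ALL")]
        rows = level_split_sensitivity(compute_need(cat, profile))
        assert [round(r["primary_share_pct"], 9) for r in rows] == [50.0, 60.0, 70.0]

    def test_primary_only_catalogue_always_100(self):
        profile = CountryYearProfile("x", 2012, 1000, 500, 100, 80, 80, rates={})
        cat = [InterventionSpec("a", "a", "pregnancy", 30, 1, "primary",
                                "pregnancies", "ALL")]
        rows = level_split_sensitivity(compute_need(cat, profile))
        assert all(math.isclose(r["primary_share_pct"], 100.0) for r in rows)

    def test_primary_share_monotone_in_primary_weight(self, toy_catalogue, toy_profile):
        rows = level_split_sensitivity(compute_need(toy_catalogue, toy_profile))
        shares = [r["primary_share_pct"] for r in rows]
        assert shares[0] < shares[1] < shares[2]
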