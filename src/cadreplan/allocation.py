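"""Competency-based task allocation and aggregation.

Each intervention's entire FTE requirement goes to the lowest-paid cadre
competent to deliver it (winner-takes-all by minimum salary rank) — the
economically efficient assignment when any competent cadre provides adequate
quality. Results are then aggregated by cadre, by continuum-of-care stage
and by health-system level. Interventions with no competent cadre are
reported as unallocatable rather than raising, so partial competency
matrices can be explored.

Level-of-care aggregation: an intervention tied to a single level
contributes all its FTEs there; an intervention delivered at all levels is
split by the assumed time shares (60/30/10 primary/secondary/tertiary by
default, with 50/30/20 and 70/20/10 as standard sensitivity scenarios).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .datamodel import (
    ALL_LEVELS,
    CadreCategory,
    CompetencyMatrix,
    InterventionSpec,
    Level,
    Stage,
    WorkforceAssumptions,
    check_cadres,
)
from .need import NeedResult

__all__ = [
    "AllocationResult",
    "DEFAULT_SENSITIVITY_SPLITS",
    "allocate",
    "split_by_level",
    "cadre_shares",
    "level_split_sensitivity",
]

#: The standard level-split scenarios (primary, secondary, tertiary).
DEFAULT_SENSITIVITY_SPLITS: tuple[tuple[float, float, float], ...] = (
    (0.5, 0.3, 0.2),
    (0.6, 0.3, 0.1),
    (0.7, 0.2, 0.1),
)


@dataclass(frozen=True)
class AllocationResult:
    """FTEs by cadre, stage and level, plus the per-intervention assignment."""

    fte_by_cadre: dict[str, float]
    fte_by_stage: dict[Stage, float]
    fte_by_level: dict[Level, float]
    fte_by_cadre_and_stage: dict[tuple[str, Stage], float]
    assignments: dict[str, str]
    unallocatable: tuple[str, ...]

    @property
    def total_allocated_fte(self) -> float:
        return sum(self.fte_by_cadre.values())


def _level_contributions(
    spec: InterventionSpec, fte: float, assumptions: WorkforceAssumptions
) -> dict[Level, float]:
    if spec.levels == ALL_LEVELS:
        return {level: fte * w for level, w in assumptions.level_weights.items()}
    return {spec.levels: fte}


def allocate(
    need: NeedResult,
    matrix: CompetencyMatrix,
    cadres: Sequence[CadreCategory],
) -> AllocationResult:
    """Assign every intervention's FTEs to its lowest-paid competent cadre.

    The matrix is expected to be remapped for absent cadres already (see
    :func:`cadreplan.datamodel.remap_absent_cadres`); salary ranks must be
    strictly ordered. Unallocatable interventions (no competent cadre) are
    listed and excluded from all aggregates.
    """
    check_cadres(cadres)
    rank_of = {c.cadre_id: c.salary_rank for c in cadres}

    fte_by_cadre = {c.cadre_id: 0.0 for c in cadres}
    fte_by_stage = {s: 0.0 for s in Stage}
    fte_by_level = {lv: 0.0 for lv in Level}
    fte_by_cadre_and_stage: dict[tuple[str, Stage], float] = {}
    assignments: dict[str, str] = {}
    unallocatable: list[str] = []

    for spec in need.catalogue:
        competent = [c for c in matrix.competent_cadres(spec.intervention_id) if c in rank_of]
        if not competent:
            unallocatable.append(spec.intervention_id)
            continue
        winner = min(competent, key=rank_of.__getitem__)
        fte = need.need_of(spec.intervention_id).fte
        assignments[spec.intervention_id] = winner
        fte_by_cadre[winner] += fte
        fte_by_stage[spec.stage] += fte
        key = (winner, spec.stage)
        fte_by_cadre_and_stage[key] = fte_by_cadre_and_stage.get(key, 0.0) + fte
        for level, contribution in _level_contributions(spec, fte, need.assumptions).items():
            fte_by_level[level] += contribution

    return AllocationResult(
        fte_by_cadre=fte_by_cadre,
        fte_by_stage=fte_by_stage,
        fte_by_level=fte_by_level,
        fte_by_cadre_and_stage=fte_by_cadre_and_stage,
        assignments=assignments,
        unallocatable=tuple(unallocatable),
    )


def split_by_level(
    need: NeedResult,
    catalogue: Sequence[InterventionSpec] | None = None,
    assumptions: WorkforceAssumptions | None = None,
) -> dict[Level, float]:
    """Distribute the total FTE requirement over health-system levels.

    Single-level interventions contribute everything to their level;
    all-level interventions are split by the assumed time shares. The level
    totals sum to the need total.
    """
    catalogue = catalogue if catalogue is not None else need.catalogue
    assumptions = assumptions or need.assumptions
    totals = {lv: 0.0 for lv in Level}
    for spec in catalogue:
        fte = need.need_of(spec.intervention_id).fte
        for level, contribution in _level_contributions(spec, fte, assumptions).items():
            totals[level] += contribution
    return totals


def cadre_shares(result: AllocationResult) -> dict[str, float]:
    """Percentage of allocated FTEs carried by each cadre (sums to 100)."""
    total = result.total_allocated_fte
    if total <= 0:
        raise ValueError("no allocated need: total allocated FTEs is zero")
    return {cadre: fte / total * 100.0 for cadre, fte in result.fte_by_cadre.items()}


def level_split_sensitivity(
    need: NeedResult,
    catalogue: Sequence[InterventionSpec] | None = None,
    splits: Sequence[Sequence[float]] = DEFAULT_SENSITIVITY_SPLITS,
) -> list[dict]:
    """Primary-level share of FTEs under alternative level splits.

    Returns one row per scenario with the split weights and the percentage
    of total FTEs falling at primary level.
    """
    catalogue = catalogue if catalogue is not None else need.catalogue
    rows = []
    for split in splits:
        assumptions = need.assumptions.with_level_split(split)
        by_level = split_by_level(need, catalogue, assumptions)
        total = sum(by_level.values())
        primary_share = by_level[Level.PRIMARY] / total * 100.0 if total > 0 else 0.0
        rows.append(
            {
                "primary_w": assumptions.level_split[0],
                "secondary_w": assumptions.level_split[1],
                "tertiary_w": assumptions.level_split[2],
                "primary_share_pct": primary_share,
            }
        )
    return rows
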