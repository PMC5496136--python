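"""Workforce-density benchmarks.

Model outputs are expressed on three reference scales used in global
workforce policy:

* FTEs per 10 000 women of reproductive age (15–49), the natural density
  for a workforce whose main user group is women of reproductive age;
* midwives (or nurse-midwives) per 175 births, against the classic
  one-midwife-per-175-births staffing threshold — restricted to the
  pregnancy, labour/birth and postnatal stages so that the comparison
  excludes services to women who are not pregnant, like the original
  benchmark does;
* the WHO density floor of 44.5 skilled health professionals per 10 000
  population, against which the SRMNAH requirement is expressed as a share.

All returned values are full precision; integer-percent and 1-dp roundings
are confined to report rendering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .datamodel import CadreCategory, CountryYearProfile, Level, Stage
from .allocation import AllocationResult

__all__ = [
    "WHO_PROFESSIONALS_PER_10K",
    "MIDWIFE_BENCHMARK_BIRTHS",
    "BenchmarkReport",
    "fte_per_10k_wra",
    "midwives_per_175_births",
    "who_threshold_comparison",
    "build_benchmark_report",
]

#: WHO threshold: skilled health professionals needed per 10 000 population.
WHO_PROFESSIONALS_PER_10K = 44.5

#: Births covered by one midwife under the 2005 World Health Report threshold.
MIDWIFE_BENCHMARK_BIRTHS = 175.0

#: Stages counted in the midwife benchmark (pregnancy onwards).
PREGNANCY_LINKED_STAGES = (Stage.PREGNANCY, Stage.LABOUR_BIRTH, Stage.POSTNATAL)


@dataclass(frozen=True)
class BenchmarkReport:
    fte_per_10k_wra: float
    midwives_per_175_births: float
    who_total_professionals_needed: float
    srmnah_share_of_needed_workforce_pct: float
    primary_level_share_pct: float


def fte_per_10k_wra(total_fte: float, profile: CountryYearProfile) -> float:
    """FTEs needed per 10 000 women of reproductive age."""
    if profile.women_reproductive_age <= 0:
        raise ValueError("women_reproductive_age must be positive for this benchmark")
    return total_fte / profile.women_reproductive_age * 10_000.0


def _cadres_by_rank(cadres: Sequence[CadreCategory], rank: int) -> set[str]:
    return {c.cadre_id for c in cadres if c.salary_rank == rank}


def midwives_per_175_births(
    allocation: AllocationResult,
    profile: CountryYearProfile,
    cadres: Sequence[CadreCategory],
    include_auxiliaries: bool = False,
) -> float:
    """Midwife FTEs needed per 175 births, restricted to pregnancy-linked stages.

    The numerator is the FTEs allocated to the midwife/nurse-midwife cadre
    (salary rank 2; rank 1 auxiliaries added when ``include_auxiliaries``)
    within the pregnancy, labour/birth and postnatal stages. Pre-pregnancy
    services (family planning, STI care, ...) are deliberately excluded so
    the number is comparable with the one-per-175-births benchmark.
    """
    if profile.live_births <= 0:
        raise ValueError("live_births must be positive for this benchmark")
    numerator_cadres = _cadres_by_rank(cadres, 2)
    if include_auxiliaries:
        numerator_cadres |= _cadres_by_rank(cadres, 1)
    numerator = sum(
        fte
        for (cadre, stage), fte in allocation.fte_by_cadre_and_stage.items()
        if cadre in numerator_cadres and stage in PREGNANCY_LINKED_STAGES
    )
    return numerator / (profile.live_births / MIDWIFE_BENCHMARK_BIRTHS)


def who_threshold_comparison(
    total_fte: float,
    profile: CountryYearProfile | None = None,
    threshold: float = WHO_PROFESSIONALS_PER_10K,
    needed_professionals: float | None = None,
) -> tuple[float, float]:
    """(total professionals needed, SRMNAH share in percent) under the WHO floor.

    The needed-workforce figure is ``population × threshold / 10 000``;
    alternatively a pre-computed count can be passed directly via
    ``needed_professionals`` (useful when the count was published from
    unrounded population figures). The share is returned at full precision;
    reports round it to integer percent.
    """
    if needed_professionals is None:
        if profile is None or profile.total_population <= 0:
            raise ValueError("total_population must be positive for this benchmark")
        needed_professionals = profile.total_population * threshold / 10_000.0
    if needed_professionals <= 0:
        raise ValueError("needed professionals must be positive")
    share_pct = total_fte / needed_professionals * 100.0
    return needed_professionals, share_pct


def build_benchmark_report(
    total_fte: float,
    allocation: AllocationResult,
    profile: CountryYearProfile,
    cadres: Sequence[CadreCategory],
    include_auxiliaries: bool = False,
) -> BenchmarkReport:
    needed, share = who_threshold_comparison(total_fte, profile)
    level_total = sum(allocation.fte_by_level.values())
    primary_share = (
        allocation.fte_by_level[Level.PRIMARY] / level_total * 100.0
        if level_total > 0
        else 0.0
    )
    return BenchmarkReport(
        fte_per_10k_wra=fte_per_10k_wra(total_fte, profile),
        midwives_per_175_births=midwives_per_175_births(
            allocation, profile, cadres, include_auxiliaries=include_auxiliaries
        ),
        who_total_professionals_needed=needed,
        srmnah_share_of_needed_workforce_pct=share,
        primary_level_share_pct=primary_share,
    )
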