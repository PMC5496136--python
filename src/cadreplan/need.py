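"""FTE need estimation.

The pipeline for each intervention is: annual cases (demographic denominator
times epidemiological rate) → annual contact minutes (cases × contacts per
case × minutes per contact) → annual hours → FTEs (hours divided by the
clinical hours one full-time worker supplies per year, 1316 at the default
assumptions). Universal coverage is assumed throughout: every case that
needs an intervention receives it.

No intermediate rounding anywhere — fractional cases and hours are carried
forward, and totals are exact sums of the unrounded per-intervention values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .datamodel import (
    CountryYearProfile,
    InterventionSpec,
    WorkforceAssumptions,
    validate_catalogue,
)

__all__ = [
    "InterventionNeed",
    "NeedResult",
    "annual_cases",
    "intervention_time",
    "fte_requirement",
    "compute_need",
]


@dataclass(frozen=True)
class InterventionNeed:
    """Annual workload for one intervention: cases, minutes, hours and FTEs."""

    intervention_id: str
    annual_cases: float
    total_minutes: float
    total_hours: float
    fte: float


@dataclass(frozen=True)
class NeedResult:
    """Per-intervention and total annual FTE requirement for one country-year."""

    profile: CountryYearProfile
    assumptions: WorkforceAssumptions
    catalogue: tuple[InterventionSpec, ...]
    per_intervention: tuple[InterventionNeed, ...]
    total_fte: float

    def need_of(self, intervention_id: str) -> InterventionNeed:
        for n in self.per_intervention:
            if n.intervention_id == intervention_id:
                return n
        raise KeyError(intervention_id)

    def spec_of(self, intervention_id: str) -> InterventionSpec:
        for s in self.catalogue:
            if s.intervention_id == intervention_id:
                return s
        raise KeyError(intervention_id)


def annual_cases(spec: InterventionSpec, profile: CountryYearProfile) -> float:
    """Number of individuals needing the intervention in the year (fractional).

    The demographic denominator named by ``spec.population_base`` is
    multiplied by the epidemiological rate named by ``spec.rate_key`` (1.0
    for the universal key). Not rounded.
    """
    try:
        rate = profile.rate(spec.rate_key)
    except KeyError as exc:
        raise KeyError(
            f"intervention {spec.intervention_id!r}: {exc.args[0]}"
        ) from None
    return profile.denominator(spec.population_base) * rate


def intervention_time(spec: InterventionSpec, cases: float) -> tuple[float, float]:
    """Total annual contact time as (minutes, hours), unrounded."""
    if cases < 0:
        raise ValueError(f"cases must be >= 0, got {cases}")
    minutes = cases * spec.contacts_per_case * spec.minutes_per_contact
    return minutes, minutes / 60.0


def fte_requirement(hours: float, assumptions: WorkforceAssumptions) -> float:
    """Convert annual clinical hours into FTEs.

    One FTE supplies ``assumptions.clinical_hours`` clinical hours per year,
    so the requirement is simply hours divided by that constant. Returned at
    full precision; display rounding (2 decimals) is a report concern.
    """
    if hours < 0:
        raise ValueError(f"hours must be >= 0, got {hours}")
    clinical = assumptions.clinical_hours
    if clinical <= 0:
        raise ValueError(f"clinical hours per FTE must be positive, got {clinical}")
    return hours / clinical


def compute_need(
    catalogue: Sequence[InterventionSpec],
    profile: CountryYearProfile,
    assumptions: WorkforceAssumptions | None = None,
) -> NeedResult:
    """Run the full need pipeline over a catalogue.

    Raises if the catalogue fails validation against the profile (unresolved
    rate keys, duplicate ids); errors name the offending intervention.
    """
    assumptions = assumptions or WorkforceAssumptions()
    issues = validate_catalogue(catalogue, profile)
    if issues:
        raise ValueError(
            "catalogue failed validation:\n" + "\n".join(str(i) for i in issues)
        )
    per = []
    for spec in catalogue:
        cases = annual_cases(spec, profile)
        minutes, hours = intervention_time(spec, cases)
        per.append(
            InterventionNeed(
                intervention_id=spec.intervention_id,
                annual_cases=cases,
                total_minutes=minutes,
                total_hours=hours,
                fte=fte_requirement(hours, assumptions),
            )
        )
    return NeedResult(
        profile=profile,
        assumptions=assumptions,
        catalogue=tuple(catalogue),
        per_intervention=tuple(per),
        total_fte=sum(n.fte for n in per),
    )
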