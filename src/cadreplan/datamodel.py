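"""Domain types and input/output dialects for needs-based SRMNAH workforce planning.

The model works with four input families:

* an intervention catalogue (what care is delivered, to whom, for how long,
  at which level of the health system);
* a country-year profile (demographic denominators and epidemiological rates);
* a cadre catalogue with a competency matrix (who may deliver what, ordered
  by salary);
* workforce assumptions (working hours, clinical time fraction, level split).

All quantities are carried at full precision; rounding happens only when
reports are rendered.
"""

from __future__ import annotations

import enum
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "Stage",
    "Level",
    "ALL_LEVELS",
    "PopulationBase",
    "UNIVERSAL_RATE_KEY",
    "InterventionSpec",
    "CountryYearProfile",
    "CadreCategory",
    "CompetencyMatrix",
    "WorkforceAssumptions",
    "ValidationIssue",
    "validate_catalogue",
    "remap_absent_cadres",
    "read_interventions_csv",
    "write_interventions_csv",
    "read_cadres_csv",
    "write_cadres_csv",
    "read_competencies_csv",
    "write_competencies_csv",
    "read_profile_json",
    "write_profile_json",
    "read_assumptions_yaml",
    "write_assumptions_yaml",
]


class Stage(str, enum.Enum):
    """Stage on the continuum of care."""

    PRE_PREGNANCY = "pre_pregnancy"
    PREGNANCY = "pregnancy"
    LABOUR_BIRTH = "labour_birth"
    POSTNATAL = "postnatal"


class Level(str, enum.Enum):
    """Institutional level of the health system."""

    PRIMARY = "primary"
    SECONDARY = "secondary"
    TERTIARY = "tertiary"


#: Sentinel for interventions delivered at every level of care; their
#: workload is distributed with :attr:`WorkforceAssumptions.level_split`.
ALL_LEVELS = "all_levels"


class PopulationBase(str, enum.Enum):
    """Demographic denominator an intervention applies to."""

    WOMEN_REPRODUCTIVE_AGE = "women_reproductive_age"
    PREGNANCIES = "pregnancies"
    LIVE_BIRTHS = "live_births"
    NEWBORNS = "newborns"
    TOTAL_POPULATION = "total_population"


#: Rate key meaning "every member of the base population needs this
#: intervention" (rate 1.0), e.g. routine antenatal contacts.
UNIVERSAL_RATE_KEY = "ALL"

_SPACE_NUMBER = re.compile(r"[\s  ]+")


def parse_number(value) -> float:
    """Parse a number, accepting spaces as thousands separators ("100 000")."""
    if isinstance(value, (int, float)):
        return float(value)
    text = _SPACE_NUMBER.sub("", str(value).strip())
    if text == "":
        raise ValueError("empty numeric field")
    return float(text)


@dataclass(frozen=True)
class InterventionSpec:
    """One essential SRMNAH intervention.

    Parameters
    ----------
    intervention_id
        Short unique key within a catalogue.
    stage
        Continuum-of-care stage.
    minutes_per_contact
        Contact time in minutes to deliver the intervention once.
    contacts_per_case
        Number of contacts each case requires per year (e.g. an antenatal
        visit schedule); default one contact.
    levels
        A single :class:`Level`, or :data:`ALL_LEVELS` when delivery spans
        the whole system (severe cases referred upwards).
    population_base
        Demographic denominator the need rate applies to.
    rate_key
        Name of the epidemiological rate in the country profile, or
        :data:`UNIVERSAL_RATE_KEY` for a rate of 1.
    """

    intervention_id: str
    name: str
    stage: Stage
    minutes_per_contact: float
    contacts_per_case: int = 1
    levels: Level | str = ALL_LEVELS
    population_base: PopulationBase = PopulationBase.WOMEN_REPRODUCTIVE_AGE
    rate_key: str = UNIVERSAL_RATE_KEY

    def __post_init__(self):
        object.__setattr__(self, "stage", Stage(self.stage))
        object.__setattr__(self, "population_base", PopulationBase(self.population_base))
        if self.levels != ALL_LEVELS:
            object.__setattr__(self, "levels", Level(self.levels))
        if not self.intervention_id:
            raise ValueError("intervention_id must be non-empty")
        if not (self.minutes_per_contact > 0):
            raise ValueError(
                f"{self.intervention_id}: minutes_per_contact must be > 0, "
                f"got {self.minutes_per_contact}"
            )
        if int(self.contacts_per_case) != self.contacts_per_case or self.contacts_per_case < 1:
            raise ValueError(
                f"{self.intervention_id}: contacts_per_case must be an integer >= 1, "
                f"got {self.contacts_per_case}"
            )
        object.__setattr__(self, "contacts_per_case", int(self.contacts_per_case))


@dataclass(frozen=True)
class CountryYearProfile:
    """Demographic denominators and epidemiological rates for one country-year."""

    country_code: str
    year: int
    total_population: float
    women_reproductive_age: float
    pregnancies: float
    live_births: float
    newborns: float
    rates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for name in (
            "total_population",
            "women_reproductive_age",
            "pregnancies",
            "live_births",
            "newborns",
        ):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        for key, rate in self.rates.items():
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"rate {key!r} must lie in [0, 1], got {rate}")
        object.__setattr__(self, "rates", dict(self.rates))

    def denominator(self, base: PopulationBase) -> float:
        return getattr(self, base.value)

    def rate(self, rate_key: str) -> float:
        """Resolve a rate key; the universal key resolves to 1.0."""
        if rate_key == UNIVERSAL_RATE_KEY:
            return 1.0
        try:
            return self.rates[rate_key]
        except KeyError:
            raise KeyError(
                f"rate_key {rate_key!r} not found in profile for "
                f"{self.country_code}/{self.year}"
            ) from None

    def with_denominators(self, **denominators) -> "CountryYearProfile":
        """Copy of this profile with some denominators (or the year) replaced.

        Rates are carried over unchanged, which is what projection under
        frozen epidemiology requires.
        """
        fields = dict(
            country_code=self.country_code,
            year=self.year,
            total_population=self.total_population,
            women_reproductive_age=self.women_reproductive_age,
            pregnancies=self.pregnancies,
            live_births=self.live_births,
            newborns=self.newborns,
        )
        fields.update(denominators)
        return CountryYearProfile(rates=dict(self.rates), **fields)


@dataclass(frozen=True)
class CadreCategory:
    """A category of health worker, ranked by salary (1 = lowest paid)."""

    cadre_id: str
    name: str
    salary_rank: int
    present_in_country: bool = True

    def __post_init__(self):
        if not (1 <= self.salary_rank <= 5):
            raise ValueError(
                f"{self.cadre_id}: salary_rank must be in 1..5, got {self.salary_rank}"
            )


def check_cadres(cadres: Sequence[CadreCategory]) -> None:
    """Reject duplicate ids and tied salary ranks.

    The allocation rule needs a unique lowest-paid competent cadre, so ties
    in salary rank are an input error rather than something to break
    arbitrarily.
    """
    if not cadres:
        raise ValueError("cadre catalogue is empty")
    ids = [c.cadre_id for c in cadres]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate cadre_id(s): {', '.join(dupes)}")
    ranks = [c.salary_rank for c in cadres]
    if len(set(ranks)) != len(ranks):
        tied = sorted({r for r in ranks if ranks.count(r) > 1})
        raise ValueError(f"salary_rank values must be unique; tied rank(s): {tied}")


class CompetencyMatrix:
    """Boolean cadre-by-intervention competency grid.

    Missing entries are false: the matrix is total over the grid. The usual
    query is :meth:`competent_cadres` for one intervention.
    """

    def __init__(self, entries: Mapping[tuple[str, str], bool]):
        self._entries = {k: bool(v) for k, v in entries.items() if v}

    @classmethod
    def from_lists(cls, competencies: Mapping[str, Iterable[str]]) -> "CompetencyMatrix":
        """Build from a map intervention_id -> iterable of competent cadre_ids."""
        entries = {}
        for intervention_id, cadre_ids in competencies.items():
            for cadre_id in cadre_ids:
                entries[(cadre_id, intervention_id)] = True
        return cls(entries)

    def is_competent(self, cadre_id: str, intervention_id: str) -> bool:
        return (cadre_id, intervention_id) in self._entries

    def competent_cadres(self, intervention_id: str) -> frozenset[str]:
        return frozenset(
            c for (c, i) in self._entries if i == intervention_id
        )

    @property
    def entries(self) -> dict[tuple[str, str], bool]:
        return dict.fromkeys(self._entries, True)

    def cadre_ids(self) -> frozenset[str]:
        return frozenset(c for (c, _) in self._entries)

    def intervention_ids(self) -> frozenset[str]:
        return frozenset(i for (_, i) in self._entries)

    def __eq__(self, other):
        return isinstance(other, CompetencyMatrix) and self._entries == other._entries

    def __repr__(self):
        return f"CompetencyMatrix({len(self._entries)} true entries)"


@dataclass(frozen=True)
class WorkforceAssumptions:
    """Working-time assumptions that convert clinical hours into FTEs.

    At the defaults (40 h/week, 52 weeks, 5 sick days + 20 leave days at
    8 h/day, 70% clinical time) a full-time worker supplies 1880 working
    hours per year of which 1316 are clinical.
    """

    weekly_hours: float = 40.0
    sick_days: float = 5.0
    annual_leave_days: float = 20.0
    hours_per_day: float = 8.0
    weeks_per_year: float = 52.0
    clinical_fraction: float = 0.70
    level_split: tuple[float, float, float] = (0.60, 0.30, 0.10)

    def __post_init__(self):
        if not (0 < self.clinical_fraction <= 1):
            raise ValueError(
                f"clinical_fraction must lie in (0, 1], got {self.clinical_fraction}"
            )
        split = tuple(float(w) for w in self.level_split)
        if len(split) != 3:
            raise ValueError("level_split must have exactly three components")
        if any(w < 0 for w in split):
            raise ValueError(f"level_split components must be >= 0, got {split}")
        if not math.isclose(sum(split), 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"level_split must sum to 1, got {split} (sum {sum(split)})")
        object.__setattr__(self, "level_split", split)
        if self.annual_working_hours <= 0:
            raise ValueError("derived annual working hours must be positive")

    @property
    def annual_working_hours(self) -> float:
        """Hours worked per FTE-year: weekly hours over the year minus leave and sickness."""
        return (
            self.weekly_hours * self.weeks_per_year
            - (self.sick_days + self.annual_leave_days) * self.hours_per_day
        )

    @property
    def clinical_hours(self) -> float:
        """Hours per FTE-year spent delivering clinical interventions."""
        return self.clinical_fraction * self.annual_working_hours

    @property
    def level_weights(self) -> dict[Level, float]:
        return dict(zip((Level.PRIMARY, Level.SECONDARY, Level.TERTIARY), self.level_split))

    def with_level_split(self, split: Sequence[float]) -> "WorkforceAssumptions":
        return WorkforceAssumptions(
            weekly_hours=self.weekly_hours,
            sick_days=self.sick_days,
            annual_leave_days=self.annual_leave_days,
            hours_per_day=self.hours_per_day,
            weeks_per_year=self.weeks_per_year,
            clinical_fraction=self.clinical_fraction,
            level_split=tuple(split),
        )


@dataclass(frozen=True)
class ValidationIssue:
    """One catalogue problem: which intervention, which rule, and a message."""

    intervention_id: str
    rule: str
    message: str

    def __str__(self):
        return f"[{self.intervention_id}] {self.rule}: {self.message}"


def validate_catalogue(
    catalogue: Sequence[InterventionSpec], profile: CountryYearProfile
) -> list[ValidationIssue]:
    """Check a catalogue against a profile; all problems are reported, none raised.

    Returns an empty list iff every intervention's rate key resolves in the
    profile (or is the universal key) and the catalogue's uniqueness
    invariant holds. Type-level invariants (positive minutes, enum
    membership) are enforced at construction, so they cannot reach here.
    """
    if not catalogue:
        raise ValueError("catalogue is empty")
    issues: list[ValidationIssue] = []
    seen: set[str] = set()
    for spec in catalogue:
        if spec.intervention_id in seen:
            issues.append(
                ValidationIssue(
                    spec.intervention_id,
                    "duplicate_intervention_id",
                    "intervention_id appears more than once in the catalogue",
                )
            )
        seen.add(spec.intervention_id)
        if spec.rate_key != UNIVERSAL_RATE_KEY and spec.rate_key not in profile.rates:
            issues.append(
                ValidationIssue(
                    spec.intervention_id,
                    "unresolved rate_key",
                    f"rate_key {spec.rate_key!r} not present in the profile rates "
                    f"for {profile.country_code}/{profile.year}",
                )
            )
    return issues


def remap_absent_cadres(
    matrix: CompetencyMatrix, cadres: Sequence[CadreCategory]
) -> CompetencyMatrix:
    """Drop competencies of cadres not present in the country.

    Where a cadre (e.g. medical officers) does not exist, its tasks fall
    through to the next-lowest-paid present cadre that is competent — which
    is exactly what allocation over the restricted matrix does. An
    intervention whose only competent cadres are absent keeps no competent
    cadre and is later reported as unallocatable.
    """
    present = {c.cadre_id for c in cadres if c.present_in_country}
    if not present:
        raise ValueError("no cadre is present in the country; nothing can be allocated")
    return CompetencyMatrix(
        {(c, i): True for (c, i) in matrix.entries if c in present}
    )


# ---------------------------------------------------------------------------
# File dialects
# ---------------------------------------------------------------------------

INTERVENTIONS_HEADER = [
    "intervention_id",
    "name",
    "stage",
    "minutes_per_contact",
    "contacts_per_case",
    "levels",
    "population_base",
    "rate_key",
]

CADRES_HEADER = ["cadre_id", "name", "salary_rank", "present_in_country"]

_BOOL = {"1": True, "0": False, "true": True, "false": False, "yes": True, "no": False}


def _read_csv(path) -> list[dict[str, str]]:
    import csv

    with open(path, newline="", encoding="utf-8") as fh:
        return list(csv.DictReader(fh))


def read_interventions_csv(path) -> list[InterventionSpec]:
    rows = _read_csv(path)
    out = []
    for lineno, row in enumerate(rows, start=2):
        try:
            out.append(
                InterventionSpec(
                    intervention_id=row["intervention_id"].strip(),
                    name=row["name"].strip(),
                    stage=row["stage"].strip(),
                    minutes_per_contact=parse_number(row["minutes_per_contact"]),
                    contacts_per_case=int(parse_number(row.get("contacts_per_case") or 1)),
                    levels=row["levels"].strip(),
                    population_base=row["population_base"].strip(),
                    rate_key=row["rate_key"].strip(),
                )
            )
        except (KeyError, ValueError) as exc:
            raise ValueError(f"{path}, line {lineno}: {exc}") from exc
    return out


def write_interventions_csv(path, catalogue: Sequence[InterventionSpec]) -> None:
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(INTERVENTIONS_HEADER)
        for s in catalogue:
            levels = s.levels if isinstance(s.levels, str) else s.levels.value
            writer.writerow(
                [
                    s.intervention_id,
                    s.name,
                    s.stage.value,
                    f"{s.minutes_per_contact:g}",
                    s.contacts_per_case,
                    levels,
                    s.population_base.value,
                    s.rate_key,
                ]
            )


def read_cadres_csv(path) -> list[CadreCategory]:
    rows = _read_csv(path)
    out = []
    for lineno, row in enumerate(rows, start=2):
        try:
            present = row.get("present_in_country", "1").strip().lower() or "1"
            out.append(
                CadreCategory(
                    cadre_id=row["cadre_id"].strip(),
                    name=row["name"].strip(),
                    salary_rank=int(parse_number(row["salary_rank"])),
                    present_in_country=_BOOL[present],
                )
            )
        except (KeyError, ValueError) as exc:
            raise ValueError(f"{path}, line {lineno}: {exc}") from exc
    check_cadres(out)
    return out


def write_cadres_csv(path, cadres: Sequence[CadreCategory]) -> None:
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CADRES_HEADER)
        for c in cadres:
            writer.writerow(
                [c.cadre_id, c.name, c.salary_rank, int(c.present_in_country)]
            )


def read_competencies_csv(path) -> CompetencyMatrix:
    """Read the wide boolean matrix: first column intervention_id, one column per cadre."""
    rows = _read_csv(path)
    entries = {}
    for lineno, row in enumerate(rows, start=2):
        try:
            intervention_id = row["intervention_id"].strip()
            for cadre_id, cell in row.items():
                if cadre_id == "intervention_id":
                    continue
                entries[(cadre_id.strip(), intervention_id)] = _BOOL[cell.strip().lower()]
        except (KeyError, ValueError) as exc:
            raise ValueError(f"{path}, line {lineno}: {exc}") from exc
    return CompetencyMatrix(entries)


def write_competencies_csv(
    path, matrix: CompetencyMatrix, cadres: Sequence[CadreCategory],
    catalogue: Sequence[InterventionSpec],
) -> None:
    import csv

    cadre_ids = [c.cadre_id for c in sorted(cadres, key=lambda c: c.salary_rank)]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["intervention_id"] + cadre_ids)
        for s in catalogue:
            writer.writerow(
                [s.intervention_id]
                + [int(matrix.is_competent(c, s.intervention_id)) for c in cadre_ids]
            )


def read_profile_json(path) -> CountryYearProfile:
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    try:
        return CountryYearProfile(
            country_code=str(raw["country_code"]),
            year=int(raw["year"]),
            total_population=parse_number(raw["total_population"]),
            women_reproductive_age=parse_number(raw["women_reproductive_age"]),
            pregnancies=parse_number(raw["pregnancies"]),
            live_births=parse_number(raw["live_births"]),
            newborns=parse_number(raw["newborns"]),
            rates={k: parse_number(v) for k, v in raw.get("rates", {}).items()},
        )
    except (KeyError, ValueError) as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_profile_json(path, profile: CountryYearProfile) -> None:
    payload = {
        "country_code": profile.country_code,
        "year": profile.year,
        "total_population": profile.total_population,
        "women_reproductive_age": profile.women_reproductive_age,
        "pregnancies": profile.pregnancies,
        "live_births": profile.live_births,
        "newborns": profile.newborns,
        "rates": dict(sorted(profile.rates.items())),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=False)
        fh.write("\n")


_ASSUMPTION_FIELDS = (
    "weekly_hours",
    "sick_days",
    "annual_leave_days",
    "hours_per_day",
    "weeks_per_year",
    "clinical_fraction",
    "level_split",
)


def read_assumptions_yaml(path) -> WorkforceAssumptions:
    """Read workforce assumptions; omitted fields take the documented defaults."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - set(_ASSUMPTION_FIELDS)
    if unknown:
        raise ValueError(f"{path}: unknown assumption field(s): {sorted(unknown)}")
    kwargs = {}
    for name in _ASSUMPTION_FIELDS:
        if name in raw:
            kwargs[name] = (
                tuple(float(w) for w in raw[name]) if name == "level_split"
                else float(raw[name])
            )
    try:
        return WorkforceAssumptions(**kwargs)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_assumptions_yaml(path, assumptions: WorkforceAssumptions) -> None:
    payload = {
        name: (list(getattr(assumptions, name)) if name == "level_split"
               else getattr(assumptions, name))
        for name in _ASSUMPTION_FIELDS
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
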