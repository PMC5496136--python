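"""Multi-year projections of workforce need.

For each year of a horizon the model is re-run on that year's demographic
denominators while the base year's epidemiological rates are held fixed
(frozen epidemiology): prevalences are assumed to persist unless the user
supplies per-year rates, which this module deliberately does not model.
Each year is recomputed in full — need, allocation, benchmarks — not
interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .datamodel import (
    CadreCategory,
    CompetencyMatrix,
    CountryYearProfile,
    InterventionSpec,
    WorkforceAssumptions,
)
from .need import NeedResult, compute_need
from .allocation import AllocationResult, allocate
from .benchmarks import BenchmarkReport, build_benchmark_report

__all__ = [
    "DemographicYear",
    "YearOutcome",
    "ProjectionSeries",
    "project",
    "read_demographic_series_csv",
    "write_demographic_series_csv",
]


@dataclass(frozen=True)
class DemographicYear:
    """Demographic denominators for one projected year."""

    year: int
    total_population: float
    women_reproductive_age: float
    pregnancies: float
    live_births: float
    newborns: float | None = None  # tracks live_births when not supplied

    def __post_init__(self):
        for name in ("total_population", "women_reproductive_age", "pregnancies", "live_births"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.year}: {name} must be >= 0")
        if self.newborns is None:
            object.__setattr__(self, "newborns", self.live_births)


@dataclass(frozen=True)
class YearOutcome:
    profile: CountryYearProfile
    need: NeedResult
    allocation: AllocationResult
    benchmarks: BenchmarkReport


@dataclass(frozen=True)
class ProjectionSeries:
    country_code: str
    years: tuple[int, ...]
    per_year: Mapping[int, YearOutcome]

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.years, self.years[1:])):
            raise ValueError("projection years must be strictly increasing")


def project(
    base_profile: CountryYearProfile,
    demographic_series: Mapping[int, DemographicYear] | Sequence[DemographicYear],
    catalogue: Sequence[InterventionSpec],
    matrix: CompetencyMatrix,
    cadres: Sequence[CadreCategory],
    assumptions: WorkforceAssumptions | None = None,
    years: Sequence[int] | None = None,
) -> ProjectionSeries:
    """Re-run need → allocation → benchmarks for every year in the horizon.

    ``demographic_series`` supplies the denominators per year; the base
    profile contributes the (frozen) epidemiological rates. ``years``
    defaults to every year in the series, ascending. A requested year
    missing from the series raises, naming the year.
    """
    assumptions = assumptions or WorkforceAssumptions()
    if not isinstance(demographic_series, Mapping):
        demographic_series = {d.year: d for d in demographic_series}
    if years is None:
        years = sorted(demographic_series)
    if not years:
        raise ValueError("projection horizon is empty")
    per_year: dict[int, YearOutcome] = {}
    for year in years:
        try:
            demo = demographic_series[year]
        except KeyError:
            raise KeyError(f"demographic series has no entry for year {year}") from None
        profile = base_profile.with_denominators(
            year=year,
            total_population=demo.total_population,
            women_reproductive_age=demo.women_reproductive_age,
            pregnancies=demo.pregnancies,
            live_births=demo.live_births,
            newborns=demo.newborns,
        )
        need = compute_need(catalogue, profile, assumptions)
        allocation = allocate(need, matrix, cadres)
        report = build_benchmark_report(need.total_fte, allocation, profile, cadres)
        per_year[year] = YearOutcome(
            profile=profile, need=need, allocation=allocation, benchmarks=report
        )
    return ProjectionSeries(
        country_code=base_profile.country_code,
        years=tuple(years),
        per_year=per_year,
    )


SERIES_HEADER = [
    "year",
    "total_population",
    "women_reproductive_age",
    "pregnancies",
    "live_births",
    "newborns",
]


def read_demographic_series_csv(path) -> dict[int, DemographicYear]:
    """Read `year,total_population,women_reproductive_age,pregnancies,live_births,newborns`."""
    import csv

    from .datamodel import parse_number

    out: dict[int, DemographicYear] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.DictReader(fh), start=2):
            try:
                year = int(parse_number(row["year"]))
                newborns = row.get("newborns")
                out[year] = DemographicYear(
                    year=year,
                    total_population=parse_number(row["total_population"]),
                    women_reproductive_age=parse_number(row["women_reproductive_age"]),
                    pregnancies=parse_number(row["pregnancies"]),
                    live_births=parse_number(row["live_births"]),
                    newborns=parse_number(newborns) if newborns not in (None, "") else None,
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from exc
    if not out:
        raise ValueError(f"{path}: demographic series is empty")
    return out


def write_demographic_series_csv(path, series: Mapping[int, DemographicYear]) -> None:
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SERIES_HEADER)
        for year in sorted(series):
            d = series[year]
            writer.writerow(
                [d.year, f"{d.total_population:.6f}", f"{d.women_reproductive_age:.6f}",
                 f"{d.pregnancies:.6f}", f"{d.live_births:.6f}", f"{d.newborns:.6f}"]
            )
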