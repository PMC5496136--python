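"""Synthetic input generation.

Everything the model consumes can be generated here, deterministically from
a seed, so the full pipeline is exercisable without any external dataset:

* :func:`table1_fixture` — the single-intervention worked example (external
  cephalic version for breech presentation) used to illustrate the need
  pipeline: 100 000 births, 4.3% breech prevalence, 107 minutes per
  procedure;
* :func:`synthetic_archetype` — a full input set (catalogue, profile,
  competency matrix, cadres) for a parameterised country archetype; six
  presets echo the demographic/epidemiological contrasts of real low- and
  middle-income countries (high-fertility/high-HIV vs low-fertility/low-HIV);
* :func:`demographic_series_fixture` — closed-form multi-year demographic
  series for projections.

The archetype catalogues and competency matrices are illustrative, not a
reconstruction of any published national catalogue: they support qualitative
property checks (ratios, shares, monotonicities), not country point
estimates. Each synthetic intervention carries a provenance tag
(``pmnch_like`` / ``qmnc_like``) in its name purely for reporting symmetry
with the two intervention frameworks the field distinguishes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .datamodel import (
    ALL_LEVELS,
    CadreCategory,
    CompetencyMatrix,
    CountryYearProfile,
    InterventionSpec,
    Level,
    PopulationBase,
    Stage,
    UNIVERSAL_RATE_KEY,
    WorkforceAssumptions,
    write_assumptions_yaml,
    write_cadres_csv,
    write_competencies_csv,
    write_interventions_csv,
    write_profile_json,
)
from .projections import DemographicYear

__all__ = [
    "ArchetypeSpec",
    "ARCHETYPE_PRESETS",
    "default_cadres",
    "table1_fixture",
    "synthetic_archetype",
    "demographic_series_fixture",
    "write_fixture_dir",
]

#: Fraction of the total population that is women aged 15–49.
WRA_SHARE_OF_POPULATION = 0.25
#: Reproductive lifespan (years) used to convert total fertility into an
#: annual birth rate per woman of reproductive age: births/WRA-year = TFR/35.
REPRODUCTIVE_YEARS = 35.0
#: Pregnancies per live birth (losses and terminations included).
PREGNANCIES_PER_BIRTH = 1.25
#: Annual sterilisation procedures per WRA, per unit of sterilisation share
#: in the contraceptive mix: contraceptive prevalence ~0.5, one procedure
#: per ~25 years of use.
STERILISATION_INCIDENCE_FACTOR = 0.02


@dataclass(frozen=True)
class ArchetypeSpec:
    """Parameters of a synthetic country archetype."""

    name: str
    total_fertility_rate: float
    hiv_prevalence: float
    sterilisation_share: float
    population_scale: float = 10_000_000.0
    seed: int = 0

    def __post_init__(self):
        if not (self.total_fertility_rate > 0):
            raise ValueError(f"total_fertility_rate must be > 0, got {self.total_fertility_rate}")
        for name in ("hiv_prevalence", "sterilisation_share"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.population_scale <= 0:
            raise ValueError("population_scale must be positive")


#: Six presets whose fertility, HIV prevalence and sterilisation share echo
#: the published indicators of six real countries; outputs are synthetic.
ARCHETYPE_PRESETS: dict[str, ArchetypeSpec] = {
    "azerbaijan_like": ArchetypeSpec("azerbaijan_like", 2.30, 0.001, 0.008, seed=101),
    "malawi_like": ArchetypeSpec("malawi_like", 5.25, 0.109, 0.210, seed=102),
    "myanmar_like": ArchetypeSpec("myanmar_like", 2.25, 0.007, 0.022, seed=103),
    "peru_like": ArchetypeSpec("peru_like", 2.50, 0.004, 0.107, seed=104),
    "uzbekistan_like": ArchetypeSpec("uzbekistan_like", 2.48, 0.002, 0.032, seed=105),
    "zambia_like": ArchetypeSpec("zambia_like", 5.45, 0.128, 0.039, seed=106),
}


def default_cadres(medical_officer_present: bool = True) -> list[CadreCategory]:
    """The five-category cadre scheme, ordered from lowest to highest paid."""
    return [
        CadreCategory("auxiliary", "Auxiliary midwives and nurse-midwives", 1),
        CadreCategory("midwife", "Midwives and nurse-midwives", 2),
        CadreCategory("medical_officer", "Medical officers", 3,
                      present_in_country=medical_officer_present),
        CadreCategory("generalist_doctor", "Doctors (generalists)", 4),
        CadreCategory("obstetrician_gynaecologist",
                      "Doctors (obstetricians/gynaecologists)", 5),
    ]


def table1_fixture() -> tuple[list[InterventionSpec], CountryYearProfile, WorkforceAssumptions]:
    """The external-cephalic-version worked example.

    One intervention (ECV, 107 min, one contact per case, live-birth base,
    breech-presentation rate) and a profile with 100 000 annual births and a
    4.3% breech rate. With default assumptions the pipeline yields 4 300
    cases, 460 100 minutes, 7 668 hours and 5.83 FTEs (at 2 dp).
    """
    catalogue = [
        InterventionSpec(
            intervention_id="ecv",
            name="External cephalic version",
            stage=Stage.PREGNANCY,
            minutes_per_contact=107.0,
            contacts_per_case=1,
            levels=Level.SECONDARY,
            population_base=PopulationBase.LIVE_BIRTHS,
            rate_key="breech_rate",
        )
    ]
    profile = CountryYearProfile(
        country_code="worked_example",
        year=2012,
        total_population=5_000_000,
        women_reproductive_age=1_250_000,
        pregnancies=125_000,
        live_births=100_000,
        newborns=100_000,
        rates={"breech_rate": 0.043},
    )
    return catalogue, profile, WorkforceAssumptions()


# ---------------------------------------------------------------------------
# Archetype catalogue template
# ---------------------------------------------------------------------------
# Columns: id, name, stage, base minutes, contacts/case, level, population
# base, rate key, competent cadres (allocation picks the lowest-paid),
# provenance tag. Minutes are nominal values; the generator applies a small
# seeded jitter so distinct archetypes are not byte-identical catalogues.

_PB = PopulationBase
_T = [
    # --- pre-pregnancy: services to women of reproductive age -------------
    ("fp_counselling", "Family planning counselling", Stage.PRE_PREGNANCY, 15, 2,
     Level.PRIMARY, _PB.WOMEN_REPRODUCTIVE_AGE, "fp_need_rate",
     ("auxiliary", "midwife", "medical_officer"), "pmnch_like"),
    ("fp_short_acting", "Short-acting contraceptive provision", Stage.PRE_PREGNANCY, 10, 4,
     Level.PRIMARY, _PB.WOMEN_REPRODUCTIVE_AGE, "short_acting_rate",
     ("auxiliary", "midwife"), "pmnch_like"),
    ("fp_larc", "Long-acting reversible contraceptive insertion", Stage.PRE_PREGNANCY, 30, 1,
     Level.PRIMARY, _PB.WOMEN_REPRODUCTIVE_AGE, "larc_rate",
     ("midwife", "medical_officer", "generalist_doctor"), "pmnch_like"),
    ("fp_sterilisation", "Female sterilisation", Stage.PRE_PREGNANCY, 120, 1,
     Level.SECONDARY, _PB.WOMEN_REPRODUCTIVE_AGE, "sterilisation_rate",
     ("medical_officer", "generalist_doctor", "obstetrician_gynaecologist"), "pmnch_like"),
    ("sti_management", "STI case management", Stage.PRE_PREGNANCY, 20, 1,
     Level.PRIMARY, _PB.WOMEN_REPRODUCTIVE_AGE, "sti_rate",
     ("midwife", "medical_officer", "generalist_doctor"), "pmnch_like"),
    ("hiv_testing", "HIV testing and counselling", Stage.PRE_PREGNANCY, 15, 1,
     Level.PRIMARY, _PB.WOMEN_REPRODUCTIVE_AGE, "hiv_testing_rate",
     ("auxiliary", "midwife"), "pmnch_like"),
    ("hiv_art_management", "HIV antiretroviral therapy management", Stage.PRE_PREGNANCY, 20, 4,
     ALL_LEVELS, _PB.WOMEN_REPRODUCTIVE_AGE, "hiv_prevalence",
     ("generalist_doctor",), "pmnch_like"),
    ("cervical_screening", "Cervical cancer screening", Stage.PRE_PREGNANCY, 15, 1,
     Level.PRIMARY, _PB.WOMEN_REPRODUCTIVE_AGE, "cervical_screening_rate",
     ("midwife", "medical_officer"), "pmnch_like"),
    ("adolescent_srh", "Adolescent SRH counselling", Stage.PRE_PREGNANCY, 20, 1,
     Level.PRIMARY, _PB.WOMEN_REPRODUCTIVE_AGE, "adolescent_srh_rate",
     ("auxiliary", "midwife"), "qmnc_like"),
    ("well_woman_checkup", "Well-woman preventive check-up", Stage.PRE_PREGNANCY, 20, 1,
     Level.PRIMARY, _PB.WOMEN_REPRODUCTIVE_AGE, "well_woman_rate",
     ("auxiliary", "midwife"), "qmnc_like"),
    ("gbv_support", "Gender-based violence first-line support", Stage.PRE_PREGNANCY, 30, 1,
     ALL_LEVELS, _PB.WOMEN_REPRODUCTIVE_AGE, "gbv_rate",
     ("midwife", "generalist_doctor"), "qmnc_like"),
    ("infertility_counselling", "Infertility assessment and counselling", Stage.PRE_PREGNANCY, 30, 1,
     Level.SECONDARY, _PB.WOMEN_REPRODUCTIVE_AGE, "infertility_rate",
     ("medical_officer", "generalist_doctor", "obstetrician_gynaecologist"), "pmnch_like"),
    # --- pregnancy ---------------------------------------------------------
    ("anc_routine", "Routine antenatal contacts", Stage.PREGNANCY, 30, 8,
     ALL_LEVELS, _PB.PREGNANCIES, UNIVERSAL_RATE_KEY,
     ("midwife", "medical_officer", "generalist_doctor"), "pmnch_like"),
    ("anc_ultrasound", "Antenatal ultrasound assessment", Stage.PREGNANCY, 20, 1,
     Level.SECONDARY, _PB.PREGNANCIES, UNIVERSAL_RATE_KEY,
     ("midwife", "medical_officer", "obstetrician_gynaecologist"), "qmnc_like"),
    ("anc_syphilis_screening", "Antenatal syphilis screening", Stage.PREGNANCY, 10, 1,
     Level.PRIMARY, _PB.PREGNANCIES, UNIVERSAL_RATE_KEY,
     ("auxiliary", "midwife"), "pmnch_like"),
    ("pmtct", "Prevention of mother-to-child HIV transmission", Stage.PREGNANCY, 60, 1,
     ALL_LEVELS, _PB.PREGNANCIES, "hiv_prevalence",
     ("generalist_doctor",), "pmnch_like"),
    ("ecv", "External cephalic version", Stage.PREGNANCY, 107, 1,
     Level.SECONDARY, _PB.LIVE_BIRTHS, "breech_rate",
     ("obstetrician_gynaecologist",), "qmnc_like"),
    ("eclampsia_management", "Hypertensive disorder / eclampsia management", Stage.PREGNANCY, 120, 1,
     Level.TERTIARY, _PB.PREGNANCIES, "hdp_rate",
     ("obstetrician_gynaecologist",), "pmnch_like"),
    ("post_abortion_care", "Post-abortion care", Stage.PREGNANCY, 60, 1,
     Level.SECONDARY, _PB.PREGNANCIES, "abortion_rate",
     ("midwife", "medical_officer", "generalist_doctor"), "pmnch_like"),
    # --- labour and birth ---------------------------------------------------
    ("skilled_birth_attendance", "Skilled attendance at birth", Stage.LABOUR_BIRTH, 420, 1,
     ALL_LEVELS, _PB.LIVE_BIRTHS, UNIVERSAL_RATE_KEY,
     ("midwife", "medical_officer", "generalist_doctor"), "pmnch_like"),
    ("labour_companionship", "Supportive labour companionship", Stage.LABOUR_BIRTH, 60, 1,
     ALL_LEVELS, _PB.LIVE_BIRTHS, UNIVERSAL_RATE_KEY,
     ("auxiliary", "midwife"), "qmnc_like"),
    ("caesarean_section", "Caesarean section", Stage.LABOUR_BIRTH, 120, 1,
     Level.TERTIARY, _PB.LIVE_BIRTHS, "caesarean_rate",
     ("obstetrician_gynaecologist",), "pmnch_like"),
    ("assisted_delivery", "Assisted vaginal delivery", Stage.LABOUR_BIRTH, 60, 1,
     Level.SECONDARY, _PB.LIVE_BIRTHS, "assisted_delivery_rate",
     ("generalist_doctor", "obstetrician_gynaecologist"), "pmnch_like"),
    ("pph_management", "Postpartum haemorrhage management", Stage.LABOUR_BIRTH, 60, 1,
     ALL_LEVELS, _PB.LIVE_BIRTHS, "pph_rate",
     ("midwife", "medical_officer", "generalist_doctor"), "pmnch_like"),
    ("newborn_resuscitation", "Newborn resuscitation", Stage.LABOUR_BIRTH, 30, 1,
     ALL_LEVELS, _PB.NEWBORNS, "resuscitation_rate",
     ("midwife", "medical_officer", "generalist_doctor"), "pmnch_like"),
    # --- postnatal ----------------------------------------------------------
    ("pnc_mother", "Postnatal contacts for the mother", Stage.POSTNATAL, 20, 3,
     Level.PRIMARY, _PB.LIVE_BIRTHS, UNIVERSAL_RATE_KEY,
     ("auxiliary", "midwife"), "pmnch_like"),
    ("newborn_routine_care", "Routine newborn care", Stage.POSTNATAL, 15, 2,
     Level.PRIMARY, _PB.NEWBORNS, UNIVERSAL_RATE_KEY,
     ("auxiliary", "midwife"), "pmnch_like"),
    ("breastfeeding_support", "Breastfeeding support", Stage.POSTNATAL, 20, 1,
     Level.PRIMARY, _PB.NEWBORNS, UNIVERSAL_RATE_KEY,
     ("auxiliary", "midwife"), "qmnc_like"),
    ("hiv_exposed_infant", "Care of the HIV-exposed infant", Stage.POSTNATAL, 45, 1,
     Level.SECONDARY, _PB.NEWBORNS, "hiv_prevalence",
     ("generalist_doctor",), "pmnch_like"),
    ("postpartum_fp", "Postpartum family planning counselling", Stage.POSTNATAL, 15, 1,
     Level.PRIMARY, _PB.LIVE_BIRTHS, UNIVERSAL_RATE_KEY,
     ("midwife",), "qmnc_like"),
]

#: Epidemiological rates that do not vary across archetypes (regional
#: averages in spirit): need rates for preventive services and the fairly
#: uniform obstetric complication rates.
FIXED_RATES: dict[str, float] = {
    "fp_need_rate": 0.35,
    "short_acting_rate": 0.25,
    "larc_rate": 0.05,
    "sti_rate": 0.15,
    "hiv_testing_rate": 0.30,
    "cervical_screening_rate": 0.10,
    "adolescent_srh_rate": 0.20,
    "well_woman_rate": 0.25,
    "gbv_rate": 0.05,
    "infertility_rate": 0.03,
    "breech_rate": 0.043,
    "hdp_rate": 0.025,
    "abortion_rate": 0.10,
    "caesarean_rate": 0.05,
    "assisted_delivery_rate": 0.03,
    "pph_rate": 0.06,
    "resuscitation_rate": 0.07,
}


def synthetic_archetype(
    spec: ArchetypeSpec,
) -> tuple[list[InterventionSpec], CountryYearProfile, CompetencyMatrix, list[CadreCategory]]:
    """Generate a complete synthetic input set for one archetype.

    Deterministic given ``spec.seed``. Pregnancy-linked denominators derive
    from the fertility rate and population scale; HIV-management workload is
    proportional to HIV prevalence and lands on generalist doctors;
    sterilisation workload is proportional to the sterilisation share of the
    contraceptive mix and lands on medical officers; specialist obstetric
    interventions land on obstetricians/gynaecologists; everything else on
    the midwife or auxiliary cadres.
    """
    rng = np.random.default_rng(spec.seed)

    wra = spec.population_scale * WRA_SHARE_OF_POPULATION
    live_births = wra * spec.total_fertility_rate / REPRODUCTIVE_YEARS
    pregnancies = live_births * PREGNANCIES_PER_BIRTH

    rates = dict(FIXED_RATES)
    rates["hiv_prevalence"] = spec.hiv_prevalence
    rates["sterilisation_rate"] = min(
        1.0, STERILISATION_INCIDENCE_FACTOR * spec.sterilisation_share
    )

    profile = CountryYearProfile(
        country_code=spec.name,
        year=2012,
        total_population=spec.population_scale,
        women_reproductive_age=wra,
        pregnancies=pregnancies,
        live_births=live_births,
        newborns=live_births,
        rates=rates,
    )

    catalogue: list[InterventionSpec] = []
    competencies: dict[str, tuple[str, ...]] = {}
    for (iid, name, stage, minutes, contacts, level, base, rate_key, cadre_ids, tag) in _T:
        jittered = max(1, int(round(minutes * rng.uniform(0.9, 1.1))))
        catalogue.append(
            InterventionSpec(
                intervention_id=iid,
                name=f"{name} [{tag}]",
                stage=stage,
                minutes_per_contact=float(jittered),
                contacts_per_case=contacts,
                levels=level,
                population_base=base,
                rate_key=rate_key,
            )
        )
        competencies[iid] = cadre_ids

    matrix = CompetencyMatrix.from_lists(competencies)
    return catalogue, profile, matrix, default_cadres()


def demographic_series_fixture(
    base_profile: CountryYearProfile,
    years: Sequence[int],
    fertility_change_per_year: float = 0.0,
    wra_growth_per_year: float = 0.0,
    seed: int = 0,
) -> dict[int, DemographicYear]:
    """Closed-form demographic series for projections.

    Women of reproductive age (and the total population) compound at
    ``wra_growth_per_year``; births and pregnancies compound at the combined
    fertility-change and WRA-growth rate, so a −2%/year fertility change
    over 15 years with constant WRA leaves births at 0.98**15 of the base.
    Newborns track live births. The series is closed-form and fully
    deterministic; ``seed`` is accepted for interface symmetry with the
    other generators and is unused.
    """
    if not years:
        raise ValueError("projection horizon is empty")
    base_year = min(int(y) for y in years)
    out: dict[int, DemographicYear] = {}
    for year in years:
        t = int(year) - base_year
        growth = (1.0 + wra_growth_per_year) ** t
        fertility = (1.0 + fertility_change_per_year) ** t
        births = base_profile.live_births * fertility * growth
        out[int(year)] = DemographicYear(
            year=int(year),
            total_population=base_profile.total_population * growth,
            women_reproductive_age=base_profile.women_reproductive_age * growth,
            pregnancies=base_profile.pregnancies * fertility * growth,
            live_births=births,
            newborns=births,
        )
    return out


def write_fixture_dir(out_dir, preset: str | ArchetypeSpec) -> dict[str, Path]:
    """Write one archetype's four input files (plus assumptions) to a directory.

    Returns the paths written, keyed by input family.
    """
    spec = ARCHETYPE_PRESETS[preset] if isinstance(preset, str) else preset
    catalogue, profile, matrix, cadres = synthetic_archetype(spec)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "interventions": out_dir / "interventions.csv",
        "cadres": out_dir / "cadres.csv",
        "competencies": out_dir / "competencies.csv",
        "profile": out_dir / "profile.json",
        "assumptions": out_dir / "assumptions.yaml",
    }
    write_interventions_csv(paths["interventions"], catalogue)
    write_cadres_csv(paths["cadres"], cadres)
    write_competencies_csv(paths["competencies"], matrix, cadres, catalogue)
    write_profile_json(paths["profile"], profile)
    write_assumptions_yaml(paths["assumptions"], WorkforceAssumptions())
    return paths
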