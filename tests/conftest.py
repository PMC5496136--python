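import pytest

from cadreplan import (
    CadreCategory,
    CompetencyMatrix,
    CountryYearProfile,
    InterventionSpec,
    WorkforceAssumptions,
    default_cadres,
    table1_fixture,
)


@pytest.fixture
def worked_example():
    """Single-intervention ECV example: 100 000 births, 4.3% breech, 107 min."""
    return table1_fixture()


@pytest.fixture
def cadres():
    return default_cadres()


@pytest.fixture
def toy_profile():
    return CountryYearProfile(
        country_code="toy",
        year=2012,
        total_population=40_000,
        women_reproductive_age=10_000,
        pregnancies=2_000,
        live_births=1_600,
        newborns=1_600,
        rates={"r1": 0.5, "r2": 0.25},
    )


@pytest.fixture
def toy_catalogue():
    """Three interventions with hand-checkable workloads."""
    return [
        InterventionSpec("i1", "Preventive counselling", "pre_pregnancy", 30, 2,
                         "primary", "women_reproductive_age", "r1"),
        InterventionSpec("i2", "Routine pregnancy care", "pregnancy", 60, 1,
                         "all_levels", "pregnancies", "ALL"),
        InterventionSpec("i3", "Complication management", "labour_birth", 90, 1,
                         "tertiary", "live_births", "r2"),
    ]


@pytest.fixture
def toy_matrix():
    return CompetencyMatrix.from_lists(
        {
            "i1": ("auxiliary", "midwife"),
            "i2": ("midwife", "generalist_doctor"),
            "i3": ("obstetrician_gynaecologist",),
        }
    )
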