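# Methods

## Model

`cadreplan` is a deterministic demand model for the SRMNAH workforce. It
answers "how many full-time-equivalent workers does this population need,
and from which cadres?", not "how many are available?". Need is defined as
universal coverage: every case that requires an essential intervention
receives it. There is no coverage multiplier, no queueing or utilisation
modelling, and no supply-side constraint — contact time is the only
workload measure, and the model's outputs are targets, not rosters.

The chain per intervention is

```
cases  = denominator(population_base) × rate(rate_key)
minutes = cases × contacts_per_case × minutes_per_contact
FTEs    = (minutes / 60) / clinical_hours
```

with full precision carried throughout. This matters for reproducibility:
the worked example's printed "7 668 h" is a display rounding of
460 100/60 = 7 668.33 h, and the printed 5.83 FTEs is obtained by dividing
the *unrounded* hours by 1 316 and rounding only at the end (the division
of the rounded figure happens to give 5.83 as well, but the engine never
relies on that). All report roundings (2-dp FTEs, integer percents) happen
in the CLI's rendering layer; JSON outputs carry full precision.

## Assumptions and parameters

| Parameter | Default | Meaning |
|---|---|---|
| `weekly_hours` | 40 h | contracted working week |
| `weeks_per_year` | 52 | working weeks per year |
| `sick_days` + `annual_leave_days` | 5 + 20 days | absence, at `hours_per_day` = 8 h |
| `clinical_fraction` | 0.70 | share of working time spent on clinical care |
| `level_split` | (0.60, 0.30, 0.10) | time shares at primary/secondary/tertiary for all-level interventions |

The derived constants are 40·52 − 25·8 = **1880** working hours and
0.70·1880 = **1316** clinical hours per FTE-year; one FTE of need is
defined as 1316 clinical hours. The level split is an assumption rather
than an evidence-based quantity, which is why 50/30/20 and 70/20/10 ship as
standard sensitivity scenarios and the split is overridable everywhere.

Allocation uses a winner-takes-all rule: all of an intervention's FTEs go
to the competent cadre with the lowest salary rank. This is the economically
efficient reading of competency-based task allocation when any competent
cadre delivers adequate quality; no capacity ceilings are imposed because
the model describes need, not supply. Salary ranks must be strictly unique —
a tie would make "the lowest-paid competent cadre" ill-defined, so ties are
rejected at load time instead of broken arbitrarily. Interventions with no
competent cadre (possible with partial matrices, or after an absent cadre's
competencies are dropped) are reported as unallocatable and excluded from
aggregates; the CLI's `--require-full-allocation` turns them into errors.

Cadre absence is handled by restriction: competencies of cadres flagged not
present are removed, and allocation over the restricted matrix naturally
falls through to the next-lowest-paid present competent cadre (e.g. medical
officers' tasks passing to generalist doctors). The operation is idempotent
and the identity when all cadres are present.

The five-category cadre scheme merges midwives and nurse-midwives into one
cadre. Countries with a sharp distinction between the two can split them in
a user-supplied cadre catalogue; nothing in the engine assumes five rows,
only unique ranks.

## Benchmarks

* **FTEs per 10,000 women of reproductive age** — the main density measure,
  because women 15–49 are the main user group and much SRMNAH need (family
  planning, STI/HIV care) occurs outside pregnancy.
* **Midwives per 175 births** — numerator restricted to the
  midwife/nurse-midwife cadre (rank 2) and to the pregnancy, labour/birth
  and postnatal stages, so the figure is comparable with the historical
  one-midwife-per-175-births threshold, which also ignored services to
  women who are not pregnant. Whether auxiliaries belong in the numerator is
  genuinely ambiguous, so it is an explicit option (`include_auxiliaries`,
  default false) rather than a silent choice.
* **Share of the WHO 44.5-per-10,000 floor** — the needed-workforce count is
  either computed from the profile's population or supplied directly,
  because published counts are often derived from unrounded populations that
  a profile cannot reproduce.

## Projections

Projections re-run the full model per year on user-supplied demographic
denominators, with the base year's epidemiological rates frozen. Freezing
epidemiology is unrealistic over long horizons (HIV prevalence will not
stay constant to 2030) and is a stated contract, not a forecast: real
national estimates need modelled future prevalence. Newborns track live
births 1:1 unless a separate series is supplied. Years are recomputed
annually, never interpolated.

## Synthetic data

The fixtures module generates every input family so the pipeline is
testable without any external dataset; no network access is ever needed
and all generation is deterministic given a seed.

* The **worked example** is the single-intervention ECV case (100,000
  births, 4.3% breech, 107 min) with default assumptions.
* **Archetypes** are parameterised by total fertility rate, HIV prevalence,
  sterilisation share of the contraceptive mix, population scale and seed.
  Six presets use the published indicator values of six real low- and
  middle-income countries as generator parameters, but their catalogues
  (30 interventions spanning all four stages and all level kinds) and
  competency matrices are illustrative constructions, so preset outputs are
  synthetic and support only qualitative properties — density ratios, cadre
  -share orderings, monotonicities — never country point estimates, whose
  originals depend on national datasets and full intervention/competency
  annexes that are not publicly distributable.
* Generator demography, chosen once as field-plausible round numbers: women
  of reproductive age are 25% of the population; live births per WRA-year
  are TFR/35 (a 35-year reproductive span); pregnancies are 1.25 per live
  birth; newborns equal live births. Sterilisation incidence per WRA is
  0.02 × (sterilisation share of the mix): contraceptive prevalence ≈ 0.5
  and one procedure per ≈ 25 years of use. Nominal per-intervention contact
  times get a seeded ±10% jitter so distinct seeds give distinct catalogues.
* The **demographic series** generator is closed-form compounding: births
  and pregnancies scale with (1+fertility change)^t × (1+WRA growth)^t, the
  population and WRA with (1+WRA growth)^t.

What passing tests on these fixtures shows: the arithmetic chain, the
allocation rule, conservation, benchmark definitions and projection
mechanics are correct, and the model responds to fertility/HIV contrasts in
the expected direction and rough magnitude. What they do not show: accuracy
of any real country's need estimate, which stands or falls with the quality
of the user-supplied catalogue, competency matrix and epidemiological data.

## Numerical choices

* Tolerances: conservation and share identities are asserted to 1e-9
  relative; derived hour constants to 1e-9 absolute.
* Fractional cases and FTEs are never rounded internally.
* Degenerate inputs: zero denominators or rates simply produce zero need;
  zero allocated total makes cadre shares undefined (error, and the CLI
  reports zeros); zero women of reproductive age, births or population make
  the corresponding benchmark an error rather than an infinity.
* CSV/JSON readers accept spaces as thousands separators ("100 000"), as
  published tables often print them.
* Determinism: identical inputs give byte-identical reports; timestamps are
  confined to logs.

## Problem sizes

The test suite and the acceptance script run entirely on generated inputs:
catalogues of 1–30 interventions, five cadres, populations of 10 million,
projection horizons up to 19 years, 250 randomised allocation problems and
the exhaustive 512-matrix allocation oracle. These sizes exercise every
code path while keeping a full run in seconds; the engine itself is linear
in catalogue size × years and comfortably handles much larger inputs.
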