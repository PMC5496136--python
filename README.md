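# cadreplan

Needs-based planning of the sexual, reproductive, maternal, newborn and
adolescent health (SRMNAH) workforce.

Classic workforce benchmarks ("x doctors, nurses and midwives per 10,000
population") assume every population needs the same workforce. They do not:
a country with a total fertility rate above 5 and double-digit HIV
prevalence needs far more — and a differently composed — SRMNAH workforce
than one with low fertility and little HIV. `cadreplan` implements an
adjusted service target model that estimates, from a country's demography
and epidemiology, how many full-time-equivalent (FTE) workers are needed to
deliver universal coverage of essential SRMNAH interventions, and which
cadres should ideally deliver them. It is written for health-workforce
planners, health economists and demographers.

## The model

For each essential intervention *i* in a catalogue, in a given country-year:

1. **Cases**: `cases_i = N(base_i) × rate_i`, where `N(base_i)` is the
   demographic denominator the intervention applies to (women aged 15–49,
   pregnancies, live births, newborns or the total population) and `rate_i`
   is the epidemiological need rate (1 for universally needed services).
2. **Time**: `minutes_i = cases_i × contacts_i × minutes_per_contact_i`;
   `hours_i = minutes_i / 60`.
3. **FTEs**: `FTE_i = hours_i / H_clin`, where `H_clin` is the clinical
   hours one full-time worker supplies per year. At the defaults — 40 h/week
   × 52 weeks − (5 sick + 20 leave days) × 8 h/day = **1880** working hours,
   70% of them clinical — `H_clin` = **1316** h.
4. **Allocation**: the whole of `FTE_i` is assigned to the *lowest-paid*
   cadre competent to deliver intervention *i* (five salary-ranked cadres:
   auxiliary midwives/nurse-midwives < midwives/nurse-midwives < medical
   officers < generalist doctors < obstetricians/gynaecologists). Where a
   cadre does not exist in a country, its tasks fall through to the
   next-lowest-paid competent cadre.
5. **Aggregation**: FTEs are summed by cadre, by continuum-of-care stage
   (pre-pregnancy, pregnancy, labour/birth, postnatal) and by health-system
   level; interventions delivered at all levels are split 60/30/10 across
   primary/secondary/tertiary by default (50/30/20 and 70/20/10 are standard
   sensitivity scenarios).

Outputs are also expressed against three density benchmarks: FTEs per
10,000 women of reproductive age; midwives per 175 births (restricted to
pregnancy-linked stages, for comparability with the one-per-175-births
threshold); and the share of the WHO floor of 44.5 skilled health
professionals per 10,000 population. Multi-year projections re-run the
model on projected denominators with epidemiological rates frozen at the
base year.

No intermediate rounding occurs anywhere; reports round only for display.

## Worked example

The standard illustration of steps 1–3 is external cephalic version (ECV),
turning a breech-presenting foetus head-down before labour: with 100,000
annual births and a 4.3% breech rate, 4,300 women need the 107-minute
procedure each year — 460,100 minutes ≈ 7,668 hours, i.e. 7,668/1,316 =
**5.83 FTEs**.

```python
from cadreplan import table1_fixture, compute_need

catalogue, profile, assumptions = table1_fixture()
need = compute_need(catalogue, profile, assumptions)
n = need.per_intervention[0]
print(n.annual_cases, n.total_minutes, round(n.total_hours), round(n.fte, 2))
# 4300.0 460100.0 7668 5.83
```

The same run from the shell, on a bundled synthetic high-fertility/high-HIV
country archetype (all archetype inputs are generated, labelled synthetic,
and support qualitative comparisons only):

```text
$ cadreplan fixtures --preset malawi_like -o demo/in
$ cadreplan compute -i demo/in -o demo/out
INFO workforce assumptions: 40 h/week x 52 weeks - (5 sick + 20 leave) days x 8 h/day
     = 1880 working h/year; clinical fraction 70% -> 1316 clinical h/FTE-year;
     level split (0.6, 0.3, 0.1)
total need: 6523.69 FTEs (26.1 per 10,000 WRA); reports in demo/out

$ cat demo/out/by_cadre.csv
cadre_id,fte,share_pct
auxiliary,1936.50,30
midwife,4099.05,63
medical_officer,42.84,1
generalist_doctor,378.39,6
obstetrician_gynaecologist,66.91,1

$ cadreplan sensitivity -i demo/in -o demo/out
split 0.5/0.3/0.2: 62.3% of FTEs at primary level
split 0.6/0.3/0.1: 68.9% of FTEs at primary level
split 0.7/0.2/0.1: 75.5% of FTEs at primary level
```

Reading: this synthetic population needs about 6,500 SRMNAH FTEs (26 per
10,000 women of reproductive age); midwives and auxiliaries could cover
~93% of that need if tasks go to the lowest-paid competent cadre, with
generalist doctors carrying the HIV-management workload; and most of the
need sits at the primary level of care under every level-split scenario.
Other subcommands: `validate` (input checking), `project` (multi-year
projection from a `demographic_series.csv`).

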