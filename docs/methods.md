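# Model description and design notes

## The model

`vapesim` is a deterministic, cohort-based compartment model of cigarette
smoking and nicotine-vaping-product (NVP) use. Each birth cohort (one gender,
one birth year) is projected one year at a time; age and calendar year
advance together. All transition inputs are annual probabilities, not
hazards, and there is no within-year subdivision. Within a step, mortality
acts first and the annual transitions act on survivors, so total cohort mass
can only shrink, and only through mortality.

Two scenarios are projected and differenced:

**No-NVP scenario** (counterfactual without vaping) with states never (N),
current (S) and former (F) smoker:

    N_a = N (1 - m^N)(1 - i)
    S_a = N (1 - m^N) i + S (1 - m^S)(1 - c)
    F_a = F (1 - m^F) + S (1 - m^S) c

where `i` and `c` are cohort-, gender- and age-specific initiation and
cessation probabilities (initiation is zero above age 40; cessation here
means quitting for at least two years, with no relapse modelled — the
two-year definition is embedded in the input rates), and `m^·` are
status-specific mortality probabilities. All right-hand terms are at age
`a-1`, year `t-1`.

**NVP scenario** adds exclusive NVP users (V), former NVP users (FV), former
smokers who vape (FSV) and, optionally, pre-35 non-vaping quitters (Q35).
Its initiation and cessation rates are the No-NVP rates scaled by four
constant multipliers (smoking initiation, NVP initiation, smoking cessation,
NVP cessation), and current smokers additionally switch to exclusive NVP use
at an age-banded, gender-specific annual rate. Vaping-state mortality
interpolates between the bracketing smoking statuses by the NVP relative
risk `r`: `m^V = m^N + r (m^S - m^N)`, `m^FV = m^N + r (m^F - m^N)`,
`m^FSV = m^F + r (m^S - m^F)`.

Competing exits from a state (smoking + NVP initiation; cessation +
switching) are additive probabilities. If their sum exceeds 1 at any cell,
the engine raises a hard error naming the cell instead of silently
renormalising; baseline magnitudes are far from that boundary.

### The age-35 rule

Smokers who switch to exclusive vaping before reaching age 35 are classed
with never-smokers who vape (state V, mortality `m^V`), reflecting the
epidemiological finding that excess smoking mortality is minimal for those
who quit young; switchers landing at age 35 or above become former smokers
who vape (FSV). The rule keys on the landing age, evaluated at the end of
the step.

Whether *complete cessation* before 35 should also escape former-smoker
mortality is genuinely ambiguous in the source descriptions of this model
family: the transition diagram attaches the age split only to the switching
arrows, while the prose can be read as extending it to cessation. We route
complete cessation to F at every age by default. This choice is the only one
under which the NVP scenario with neutral parameters (smoking multipliers at
100%, NVP initiation at 0, switch rates 0) collapses *exactly* onto the
No-NVP scenario — a structural identity the test suite asserts to machine
precision and a useful guarantee for users building policy counterfactuals.
The alternative reading is preserved as an explicit engine option
(`pre35_quit_state="pre35_quitter"`: a dedicated Q35 class at never-smoker
mortality, excluded from smoker prevalence and from attributable deaths);
under that option neutral-parameter equivalence holds only approximately.

### Outcomes

Prevalences are converted to head counts with exogenous population
projections (which already embed births, mortality and migration — the model
does not simulate demography). Smoking- and vaping-attributable deaths at a
cell apply each state's excess mortality over never smokers: `m^S - m^N`
(S), `m^F - m^N` (F), `r (m^S - m^N)` (V), `r (m^F - m^N)` (FV), and
`(m^F - m^N) + r (m^S - m^F)` (FSV); N and Q35 contribute nothing.
Life-years lost weight those deaths by never-smoker remaining life
expectancy at the same (gender, age, year). Outcomes sum over ages 18–99 by
default (configurable), per year and cumulatively over the run window. The
public-health impact of vaping is the No-NVP minus NVP difference; percent
averted is computed from unrounded cumulative sums and rounded only for
display.

## Parameters

| parameter | meaning | default |
|---|---|---|
| `risk_nvp` | vaping excess mortality as a fraction of smoking's excess | 0.05 (0.40 as the high-risk alternative) |
| `smoking_init_mult` | NVP-scenario smoking initiation / No-NVP initiation | 0.75 |
| `nvp_init_mult` | NVP initiation / No-NVP smoking initiation | 0.50 |
| `smoking_cess_mult` | NVP-scenario smoking cessation / No-NVP cessation | 1.00 |
| `nvp_cess_mult` | NVP cessation / No-NVP smoking cessation | 1.00 |
| `switch_base` | annual smoker-to-vaper switch probability by gender and age band (10–17, 18–24, 25–34, 35–44, 45–54, 55–64, 65+) | preset `methods_text`: male 8.0/4.0/2.5/2.5/1.3/1.2/0.6%, female 5.0/2.5/2.0/1.6/1.4/1.4/1.0% |
| `switch_decay` | exponential annual decline of switch rates from the start year | 0.0 |
| `switch_growth` | bounded early growth `(1+rate)^k`, `k` = growth years elapsed, held after the last year | none (sensitivity uses 5%/yr over 2018–2022) |

Two switch-rate presets are shipped because the two places the source
material states them disagree for ages under 18 (`methods_text`, the
default, uses 8%/5% for ages 10–17; `table_footnote` applies the 18–24 rate,
4%/2.5%, to all ages 24 and below). The discrepancy is surfaced, not
resolved. The decay schedule compounds from the model start year; the growth
factor compounds only within its `[first_year, last_year]` window and is
then held constant.

Multipliers are age- and time-invariant; dual users are not a separate state
(dual use is inside S); there is no relapse. These are deliberate
simplifications of the model family this package implements.

## Synthetic inputs

`make_bundle(SyntheticSpec(seed), RunSpec())` generates a complete input
bundle with the *shape* of the US national inputs the model family consumes,
so everything is testable offline:

- never-smoker mortality is Gompertz (`5e-5 · e^{0.095 a}`, male +15%,
  female −10%, 0.3%/yr secular decline), with current/former relative risks
  by age band (defaults 2.5/2.8/2.2/1.5 current, 1.3/1.5/1.4/1.2 former)
  chosen to sit in the range cohort smoking studies report;
- never-smoker life expectancy is derived from that mortality by a standard
  period life table: `LE(a) = Σ P(a→k)(1 − 0.5 m(k))` with a half-year
  decedent correction and an open-interval closure `(1 − 0.5 m)/m` at the
  top age (constant-mortality tail) — so the LE table is exactly consistent
  with the mortality table;
- initiation is a Gaussian bump in age (peak 16, sd 3, zero below 10 and
  above 40, peak 4%/yr male-shifted +10%) declining log-linearly at 1% per
  birth cohort, mimicking the secular decline embodied in national inputs;
- cessation rises additively with age from 3%/yr at 25 (+1%/decade);
- population is a census-like pyramid (200k per single year of age, tapering
  after 55) with 0.3%/yr growth; the seed adds a few percent of
  multiplicative noise to population only, so rate tables are reproducible
  analytic shapes;
- start-year smoking prevalence is produced by burning in the No-NVP
  recursion for every cohort alive at the start year (pre-start mortality
  held at the start-year column), so the initial state is dynamically
  consistent with the rate schedule and the projection starts without a
  spurious transient.

What the synthetic world does **not** emulate: period effects and policy
shocks, cohort structure in cessation, migration-driven age-profile kinks,
estimation noise in the rate tables, and the absolute level calibration of
any real country. Tests passing on these bundles therefore demonstrate the
*mechanics* (recursions, accounting identities, monotonicities, scenario
differencing), not predictive validity for real populations — reproducing a
published national projection requires the corresponding national input
tables, which this package reads but does not ship.

## Verification strategy

- Every closed-form step has a frozen hand-computed oracle (single-step
  recursions, the age-35 boundary, the switch-rate schedule, excess-death
  arithmetic, the published one-decimal summary arithmetic).
- The life table is checked against a brute-force product-sum series to
  1e-9 on small instances (property-based, derandomised).
- Mass conservation (mass lost each step equals the mortality outflow) is
  asserted to 1e-12 across arbitrary rate combinations and across sampled
  cohorts of the full run.
- An independent 100,000-agent Bernoulli microsimulation of the same
  transition rules reproduces the deterministic compartment prevalences
  within 3 Monte-Carlo standard errors at every checked (age, state) cell.
- Directional sensitivity: halving/doubling switch rates moves cumulative
  averted deaths strictly down/up; raising `risk_nvp` from 5% to 40%
  strictly lowers the gains.

Problem sizes used in the default test run: the full 2013–2060, ages 0–99,
two-gender window for acceptance properties (a scenario pair runs in well
under a second), and an 18-year, 60-age window for most unit tests.

## Numerical notes and limitations

- All state arithmetic is double precision; no renormalisation is applied
  inside the recursion, so the `Σ prevalence = 1` identity holds to ~1e-15
  by construction and is asserted at 1e-12.
- The life-table closure requires nonzero top-age mortality; zero raises.
- Grid gaps are hard errors (no extrapolation); mortality ordering
  violations (never ≤ former ≤ current) are warnings, since estimated
  former-smoker rates can legitimately cross never-smoker rates.
- Genders are fully independent; there is no interaction between cohorts.
- The percent-averted and relative-change operations are undefined at zero
  baselines and raise rather than returning infinities.
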