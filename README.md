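# vapesim

A deterministic, cohort-based simulator of cigarette smoking and
nicotine-vaping-product (NVP) use, for quantifying the population-health
impact of vaping as a harm-reduction (or harm-increasing) technology.

It is aimed at tobacco-control modellers and policy analysts who want a
transparent, scriptable compartment model: given demographic rate tables
(population, mortality by smoking status, never-smoker life expectancy,
cohort initiation/cessation schedules, initial smoking prevalence), it
projects smoking and vaping prevalence by gender, single year of age and
calendar year under two scenarios and differences their death tolls.

## The model

Each birth cohort evolves annually through compartments. The **No-NVP
scenario** (counterfactual without vaping) uses never/current/former smoker
states with survival applied before transitions:

    N_a = N (1 − m^N)(1 − i)
    S_a = N (1 − m^N) i + S (1 − m^S)(1 − c)
    F_a = F (1 − m^F) + S (1 − m^S) c

The **NVP scenario** adds exclusive vapers, former vapers and former smokers
who vape. Its rates are the counterfactual rates scaled by six parameters:
the NVP relative risk `Risk_NVP` (vaping excess mortality as a fraction of
smoking's, baseline 5%), smoking and NVP initiation multipliers (75%, 50%),
smoking and NVP cessation multipliers (100%, 100%), and an age-banded annual
switching rate from smoking to exclusive vaping (0.6–8% by age and gender,
with optional exponential decay or bounded early growth). Smokers who switch
before age 35 are classed with never-smoking vapers (minimal residual risk);
from 35 on they become former smokers who vape, at former-smoker risk plus a
`Risk_NVP` share of the current–former gap.

Attributable deaths apply each state's excess mortality over never smokers
to exogenous population counts; life-years lost weight deaths by
never-smoker remaining life expectancy. The public-health impact is the
cumulative No-NVP minus NVP difference. One-at-a-time sensitivity sweeps and
survey-validation helpers (relative reductions, base-year scaling, CI
coverage) round out the toolkit. See `docs/methods.md` for the full
formulation, parameter table and design rationale.

## Worked example

No national input tables ship with the package; the `synth` command
generates a seeded synthetic world with the right structure (Gompertz
mortality ordered never ≤ former ≤ current, life table-consistent life
expectancy, adolescent-peaked initiation declining across cohorts,
age-rising cessation, burn-in-consistent initial prevalence):

```
$ vapesim synth --seed 1 --out bundle/
wrote synthetic bundle to bundle

$ vapesim run --bundle bundle/ --scenario both --out out/
cumulative averted deaths: 92,149 (7.0%); averted life-years: 2,425,155 (15.4%)
wrote outputs to out
```

Read: over 2013–2060, ages 18–99, both genders, baseline vaping parameters
avert 92,149 of the 1.31 million smoking-attributable deaths the synthetic
counterfactual accumulates (a 7.0% reduction) and 2.43 million of 15.7
million life-years lost (15.4%). `out/` contains per-state prevalence
surfaces (`prevalence_no_nvp.csv`, `prevalence_nvp.csv`), yearly outcome
tables (`outcomes.csv`) and the cumulative summary (`summary.csv`).

The sensitivity sweep reruns the scenario pair for twelve standard parameter
variants at one or more risk levels:

```
$ vapesim sweep --bundle bundle/ --risk 0.05 --risk 0.40 --out sweep.csv
wrote 26 sweep rows to sweep.csv
```

On the seed-1 world, halving all switch rates cuts averted deaths by 34.1%,
doubling them adds 49.1%, and raising the vaping relative risk from 5% to
40% shrinks the gains by 47.9% — the directional pattern expected of a
harm-reduction parameterisation.

The same workflow runs on real data: place the six CSV tables plus
`config.yaml` in a directory (formats in `src/vapesim/input_model.py`) and
point `--bundle` at it.

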