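"""Shared fixtures: synthetic bundles, a hand-built toy world, and an
independent agent-based microsimulation used to cross-check the
deterministic compartment recursions."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from vapesim import InputBundle, RunSpec, SyntheticSpec, make_bundle
from vapesim.input_model import STATUSES, NVPParams, switch_band_index


@pytest.fixture(scope="session")
def small_run() -> RunSpec:
    return RunSpec(start_year=2013, end_year=2030, max_age=60,
                   outcome_age_min=18, outcome_age_max=60)


@pytest.fixture(scope="session")
def small_bundle(small_run) -> InputBundle:
    return make_bundle(SyntheticSpec(seed=7), small_run)


@pytest.fixture(scope="session")
def full_bundle() -> InputBundle:
    """Default-window synthetic world (2013-2060, ages 0-99)."""
    return make_bundle(SyntheticSpec(seed=1))


def build_toy_bundle(run: RunSpec | None = None, *, m_never=0.01, m_current=0.03,
                     m_former=0.02, initiation=0.10, cessation=0.05,
                     initial_current=0.2, initial_former=0.0) -> InputBundle:
    """Constant-rate world small enough for hand recursion."""
    run = run or RunSpec(start_year=2013, end_year=2016, max_age=45,
                         outcome_age_min=18, outcome_age_max=45)
    idx_py = pd.MultiIndex.from_product(
        [run.genders, run.ages, run.years], names=["gender", "age", "year"])
    pop = pd.Series(1000.0, index=idx_py, name="count")
    idx_m = pd.MultiIndex.from_product(
        [run.genders, run.ages, run.years, list(STATUSES)],
        names=["gender", "age", "year", "status"])
    rates = {"never": m_never, "current": m_current, "former": m_former}
    mort = pd.Series([rates[s] for s in idx_m.get_level_values("status")],
                     index=idx_m, name="rate")
    le = pd.Series(10.0, index=idx_py, name="le")
    # flat LE violates no invariant only if non-increasing: constant is fine
    idx_r = pd.MultiIndex.from_product(
        [run.genders, run.cohorts, run.ages], names=["gender", "cohort", "age"])
    init_vals = np.where(idx_r.get_level_values("age") <= run.initiation_max_age,
                         initiation, 0.0)
    init = pd.Series(init_vals, index=idx_r, name="rate")
    cess = pd.Series(cessation, index=idx_r, name="rate")
    idx_ga = pd.MultiIndex.from_product([run.genders, run.ages],
                                        names=["gender", "age"])
    cur = pd.Series(initial_current, index=idx_ga)
    fmr = pd.Series(initial_former, index=idx_ga)
    return InputBundle(run=run, population=pop, mortality=mort, life_expectancy=le,
                       initiation=init, cessation=cess,
                       initial_current=cur, initial_former=fmr)


@pytest.fixture()
def toy_bundle() -> InputBundle:
    return build_toy_bundle()


# ---------------------------------------------------------------------------
# Independent microsimulation oracle (Bernoulli agents, same transition rules)

_STATE_IDS = {s: k for k, s in enumerate(
    ("never", "smoker", "former_smoker", "nvp_user", "former_nvp_user",
     "fs_nvp_user", "pre35_quitter"))}


def _switch_rate(params: NVPParams, gender: str, age: int, year: int,
                 start_year: int) -> float:
    band = switch_band_index(age)
    if band is None:
        return 0.0
    rate = params.switch_base[gender][band] * (1 - params.switch_decay) ** (year - start_year)
    g = params.switch_growth
    if g is not None and year >= g.first_year:
        rate *= (1 + g.rate) ** (min(year, g.last_year) - g.first_year + 1)
    return min(max(rate, 0.0), 1.0)


def microsim_cohort(bundle: InputBundle, params: NVPParams, gender: str,
                    cohort: int, n_agents: int = 100_000, seed: int = 0):
    """Agent-level Bernoulli simulation of the vaping-scenario rules.

    Returns (ages, prevalence matrix over the seven states among survivors,
    alive counts). Mortality is drawn first each year; transitions apply to
    survivors; the age-35 rule keys on the landing age.
    """
    run = bundle.run
    rng = np.random.default_rng(seed)
    a0 = max(0, run.start_year - cohort)
    a1 = min(run.max_age, run.end_year - cohort)

    mort = {s: bundle.mortality.xs((gender, s), level=("gender", "status"))
            for s in STATUSES}
    init = bundle.initiation.xs((gender, cohort), level=("gender", "cohort"))
    cess = bundle.cessation.xs((gender, cohort), level=("gender", "cohort"))

    if cohort >= run.start_year:
        p0 = np.zeros(7)
        p0[_STATE_IDS["never"]] = 1.0
    else:
        cur = bundle.initial_current[(gender, a0)]
        fmr = bundle.initial_former[(gender, a0)]
        p0 = np.zeros(7)
        p0[_STATE_IDS["never"]] = 1.0 - cur - fmr
        p0[_STATE_IDS["smoker"]] = cur
        p0[_STATE_IDS["former_smoker"]] = fmr
    state = rng.choice(7, size=n_agents, p=p0)
    alive = np.ones(n_agents, dtype=bool)

    ages = np.arange(a0, a1 + 1)
    prev = np.zeros((len(ages), 7))
    counts = np.zeros(len(ages), dtype=int)
    r = params.risk_nvp

    def record(j):
        n = alive.sum()
        counts[j] = n
        for s, k in _STATE_IDS.items():
            prev[j, k] = np.mean(state[alive] == k) if n else np.nan

    record(0)
    for j, a in enumerate(range(a0 + 1, a1 + 1), start=1):
        am, ym = a - 1, cohort + a - 1
        mN = mort["never"][(am, ym)]
        mS = mort["current"][(am, ym)]
        mF = mort["former"][(am, ym)]
        m_by_state = np.array([
            mN, mS, mF,
            mN + r * (mS - mN),          # vaper
            mN + r * (mF - mN),          # former vaper
            mF + r * (mS - mF),          # former smoker who vapes
            mN,                          # pre-35 quitter
        ])
        i = init[am] if am <= run.initiation_max_age else 0.0
        c = cess[am]
        ip, vp = params.smoking_init_mult * i, params.nvp_init_mult * i
        cp, qp = params.smoking_cess_mult * c, params.nvp_cess_mult * c
        sigma = _switch_rate(params, gender, am, ym, run.start_year)

        u = rng.random(n_agents)
        alive = alive & (u >= m_by_state[state])
        draw = rng.random(n_agents)
        new = state.copy()
        young = a < run.switch_reclass_age

        sel = alive & (state == _STATE_IDS["never"])
        new[sel & (draw < ip)] = _STATE_IDS["smoker"]
        new[sel & (draw >= ip) & (draw < ip + vp)] = _STATE_IDS["nvp_user"]

        sel = alive & (state == _STATE_IDS["smoker"])
        quit_to = _STATE_IDS["former_smoker"]  # cessation is age-symmetric
        switch_to = _STATE_IDS["nvp_user"] if young else _STATE_IDS["fs_nvp_user"]
        new[sel & (draw < cp)] = quit_to
        new[sel & (draw >= cp) & (draw < cp + sigma)] = switch_to

        sel = alive & (state == _STATE_IDS["nvp_user"])
        new[sel & (draw < qp)] = _STATE_IDS["former_nvp_user"]

        sel = alive & (state == _STATE_IDS["fs_nvp_user"])
        new[sel & (draw < qp)] = _STATE_IDS["former_smoker"]

        state = new
        record(j)
    return ages, prev, counts
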