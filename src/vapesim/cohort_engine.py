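"""Cohort recursions for the no-vaping and vaping scenarios.

Each birth cohort (gender x birth year) is projected one year at a time.
Within a step, mortality is applied first and the annual transition
probabilities act on survivors; total cohort mass can only shrink, and only
through mortality. State masses are normalised to prevalences when scenario
surfaces are assembled.

No-vaping states: never (N), current smoker (S), former smoker (F).
Vaping-scenario states add: exclusive vaper (V), former vaper (FV), former
smoker who vapes (FSV), and pre-35 non-vaping quitter (Q35). The age-35
rule keys on the age at which a transition lands: smokers who switch to
exclusive vaping before reaching age 35 are classed with never-smoking
vapers (state V, near-never mortality), reflecting the minimal residual risk
of quitting young; switchers landing at 35 or above become former smokers
who vape (FSV, former-smoker risk plus a vaping share). Complete smoking
cessation lands in F at every age by default, exactly as in the no-vaping
scenario, which makes the two scenarios collapse onto each other under
neutral parameters. The alternative reading — pre-35 quitters keep
never-smoker mortality in a dedicated Q35 state — is available via
``pre35_quit_state="pre35_quitter"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .input_model import (
    STATUSES,
    InputBundle,
    NVPParams,
    RunSpec,
    switch_band_index,
)

NO_NVP_STATES = ("never", "smoker", "former_smoker")
NVP_STATES = (
    "never",
    "smoker",
    "former_smoker",
    "nvp_user",
    "former_nvp_user",
    "fs_nvp_user",
    "pre35_quitter",
)

NO_NVP = "no_nvp"
NVP = "nvp"


class RateLookupError(Exception):
    """A required rate cell is absent from the input tables."""


class CompetingRiskError(Exception):
    """Additive exit probabilities from a state exceed 1 at some cell."""


@dataclass
class CohortTrajectory:
    """State-occupancy masses for one cohort, ages ``ages[0]..ages[-1]``."""

    gender: str
    cohort: int
    states: tuple[str, ...]
    ages: np.ndarray
    masses: np.ndarray  # shape (n_ages, n_states)

    def prevalence(self) -> np.ndarray:
        totals = self.masses.sum(axis=1, keepdims=True)
        return self.masses / totals


@dataclass
class ScenarioResult:
    """Per-state prevalence surfaces for one scenario.

    ``prevalence`` is indexed by (gender, age, year) with one column per
    state; at every cell the columns sum to 1.
    """

    scenario: str
    prevalence: pd.DataFrame
    params: NVPParams | None = None

    @property
    def states(self) -> tuple[str, ...]:
        return tuple(self.prevalence.columns)


def effective_switch_rate(params: NVPParams, gender: str, age: int, year: int,
                          run: RunSpec) -> float:
    """Annual smoker-to-exclusive-vaper switch probability at an (age, year).

    The banded base rate decays as ``(1 - switch_decay) ** (year - start)``;
    an optional growth schedule multiplies by ``(1 + rate) ** k`` where ``k``
    counts growth years elapsed, held constant after the last growth year.
    """
    band = switch_band_index(age)
    if band is None:
        return 0.0
    try:
        base = params.switch_base[gender][band]
    except KeyError:
        raise RateLookupError(f"no switch schedule for gender {gender!r}")
    rate = base * (1.0 - params.switch_decay) ** (year - run.start_year)
    growth = params.switch_growth
    if growth is not None and year >= growth.first_year:
        k = min(year, growth.last_year) - growth.first_year + 1
        rate *= (1.0 + growth.rate) ** k
    return min(max(rate, 0.0), 1.0)


class _DenseBundle:
    """Dense ndarray views of one gender's tables for fast per-step lookup."""

    def __init__(self, bundle: InputBundle, gender: str):
        run = bundle.run
        self.run = run
        self.gender = gender
        ages = run.ages
        years = run.years
        cohorts = run.cohorts
        self.cohort0 = int(cohorts[0])

        mort = bundle.mortality.xs(gender, level="gender")
        self.m = {}
        for status in STATUSES:
            wide = (mort.xs(status, level="status")
                    .unstack("year").reindex(index=ages, columns=years))
            self.m[status] = wide.to_numpy(dtype=float)
        self.init = (bundle.initiation.xs(gender, level="gender")
                     .unstack("age").reindex(index=cohorts, columns=ages)
                     .to_numpy(dtype=float))
        self.cess = (bundle.cessation.xs(gender, level="gender")
                     .unstack("age").reindex(index=cohorts, columns=ages)
                     .to_numpy(dtype=float))
        self.init_cur = (bundle.initial_current.xs(gender, level="gender")
                         .reindex(ages).to_numpy(dtype=float))
        self.init_fmr = (bundle.initial_former.xs(gender, level="gender")
                         .reindex(ages).to_numpy(dtype=float))

    def mortality(self, status: str, age: int, year: int) -> float:
        v = self.m[status][age, year - self.run.start_year]
        if math.isnan(v):
            raise RateLookupError(
                f"mortality missing at ({self.gender}, age {age}, year {year}, {status})"
            )
        return v

    def initiation(self, cohort: int, age: int) -> float:
        if age > self.run.initiation_max_age:
            return 0.0
        v = self.init[cohort - self.cohort0, age]
        if math.isnan(v):
            raise RateLookupError(
                f"initiation missing at ({self.gender}, cohort {cohort}, age {age})"
            )
        return v

    def cessation(self, cohort: int, age: int) -> float:
        v = self.cess[cohort - self.cohort0, age]
        if math.isnan(v):
            raise RateLookupError(
                f"cessation missing at ({self.gender}, cohort {cohort}, age {age})"
            )
        return v

    def entry_state(self, cohort: int) -> tuple[int, float, float, float]:
        """Entry age and (N, S, F) masses for a cohort.

        Cohorts alive at the start year enter at their start-year age with
        the observed initial prevalence; later cohorts enter at age 0 as
        100% never users.
        """
        run = self.run
        if cohort >= run.start_year:
            return 0, 1.0, 0.0, 0.0
        a0 = run.start_year - cohort
        cur = self.init_cur[a0]
        fmr = self.init_fmr[a0]
        if math.isnan(cur) or math.isnan(fmr):
            raise RateLookupError(
                f"initial prevalence missing at ({self.gender}, age {a0})"
            )
        return a0, 1.0 - cur - fmr, cur, fmr


def _dense(bundle: InputBundle, gender: str) -> _DenseBundle:
    cache = bundle.__dict__.setdefault("_dense_cache", {})
    if gender not in cache:
        cache[gender] = _DenseBundle(bundle, gender)
    return cache[gender]


def project_cohort_no_nvp(bundle: InputBundle, gender: str, cohort: int) -> CohortTrajectory:
    """Project one cohort through the three smoking states.

    Per step (all right-hand terms at age ``a-1``, year ``cohort + a - 1``)::

        N_a = N (1 - mN) (1 - i)
        S_a = N (1 - mN) i + S (1 - mS) (1 - c)
        F_a = F (1 - mF) + S (1 - mS) c
    """
    d = _dense(bundle, gender)
    run = bundle.run
    a0, N, S, F = d.entry_state(cohort)
    a1 = min(run.max_age, run.end_year - cohort)
    ages = np.arange(a0, a1 + 1)
    out = np.empty((len(ages), 3))
    out[0] = (N, S, F)
    for j, a in enumerate(range(a0 + 1, a1 + 1), start=1):
        am, ym = a - 1, cohort + a - 1
        mN = d.mortality("never", am, ym)
        mS = d.mortality("current", am, ym)
        mF = d.mortality("former", am, ym)
        i = d.initiation(cohort, am)
        c = d.cessation(cohort, am)
        N, S, F = (
            N * (1 - mN) * (1 - i),
            N * (1 - mN) * i + S * (1 - mS) * (1 - c),
            F * (1 - mF) + S * (1 - mS) * c,
        )
        out[j] = (N, S, F)
    return CohortTrajectory(gender, cohort, NO_NVP_STATES, ages, out)


def project_cohort_nvp(bundle: InputBundle, params: NVPParams, gender: str,
                       cohort: int,
                       pre35_quit_state: str = "former_smoker") -> CohortTrajectory:
    """Project one cohort through the seven vaping-scenario states.

    Initiation and cessation in this scenario are the no-vaping rates scaled
    by the four multipliers; sigma is the effective switch rate. Vaper
    mortality interpolates between never- and current-smoker rates by
    ``risk_nvp`` (and analogously for former vapers and former smokers who
    vape). Competing exits (i' + v', c' + sigma) above 1 raise
    :class:`CompetingRiskError` rather than being renormalised.

    ``pre35_quit_state`` chooses where complete cessation before age 35
    lands: ``"former_smoker"`` (default; symmetric with the no-vaping
    scenario) or ``"pre35_quitter"`` (a separate class at never-smoker
    mortality, excluded from attributable deaths).
    """
    if pre35_quit_state not in ("former_smoker", "pre35_quitter"):
        raise ValueError(f"unknown pre35_quit_state {pre35_quit_state!r}")
    separate_q35 = pre35_quit_state == "pre35_quitter"
    d = _dense(bundle, gender)
    run = bundle.run
    r = params.risk_nvp
    a0, N, S, F = d.entry_state(cohort)
    V = FV = FSV = Q35 = 0.0  # no vaping at model start
    a1 = min(run.max_age, run.end_year - cohort)
    ages = np.arange(a0, a1 + 1)
    out = np.empty((len(ages), 7))
    out[0] = (N, S, F, V, FV, FSV, Q35)
    reclass = run.switch_reclass_age
    for j, a in enumerate(range(a0 + 1, a1 + 1), start=1):
        am, ym = a - 1, cohort + a - 1
        mN = d.mortality("never", am, ym)
        mS = d.mortality("current", am, ym)
        mF = d.mortality("former", am, ym)
        mV = mN + r * (mS - mN)
        mFV = mN + r * (mF - mN)
        mFSV = mF + r * (mS - mF)
        i = d.initiation(cohort, am)
        c = d.cessation(cohort, am)
        ip = params.smoking_init_mult * i
        vp = params.nvp_init_mult * i
        cp = params.smoking_cess_mult * c
        qp = params.nvp_cess_mult * c
        sigma = effective_switch_rate(params, gender, am, ym, run)
        if ip + vp > 1.0:
            raise CompetingRiskError(
                f"smoking+vaping initiation {ip + vp:.4f} > 1 at "
                f"({gender}, cohort {cohort}, age {am}, year {ym})"
            )
        if cp + sigma > 1.0:
            raise CompetingRiskError(
                f"cessation+switching {cp + sigma:.4f} > 1 at "
                f"({gender}, cohort {cohort}, age {am}, year {ym})"
            )
        young = a < reclass  # landing-age test for the age-35 rule
        sN = N * (1 - mN)
        sS = S * (1 - mS)
        sF = F * (1 - mF)
        sV = V * (1 - mV)
        sFV = FV * (1 - mFV)
        sFSV = FSV * (1 - mFSV)
        sQ = Q35 * (1 - mN)
        quit_to_q35 = separate_q35 and young
        N = sN * (1 - ip - vp)
        S = sN * ip + sS * (1 - cp - sigma)
        V = sN * vp + sV * (1 - qp) + (sS * sigma if young else 0.0)
        FV = sFV + sV * qp
        FSV = sFSV * (1 - qp) + (0.0 if young else sS * sigma)
        F = sF + (0.0 if quit_to_q35 else sS * cp) + sFSV * qp
        Q35 = sQ + (sS * cp if quit_to_q35 else 0.0)
        out[j] = (N, S, F, V, FV, FSV, Q35)
    return CohortTrajectory(gender, cohort, NVP_STATES, ages, out)


def run_scenario(bundle: InputBundle, params: NVPParams | None = None,
                 scenario: str = NO_NVP,
                 pre35_quit_state: str = "former_smoker") -> ScenarioResult:
    """Project every contributing cohort and assemble prevalence surfaces.

    Every (gender, age, year) cell of the run window belongs to exactly one
    cohort (``cohort = year - age``); the cell's prevalences are that
    cohort's normalised state masses at that age.
    """
    run = bundle.run
    if scenario == NO_NVP:
        if params is not None:
            raise ValueError("no_nvp scenario takes no vaping parameters")
        states = NO_NVP_STATES
    elif scenario == NVP:
        if params is None:
            raise ValueError("nvp scenario requires NVPParams")
        states = NVP_STATES
    else:
        raise ValueError(f"unknown scenario {scenario!r}")

    n_ages, n_years = len(run.ages), len(run.years)
    frames = []
    for gender in run.genders:
        surface = np.full((n_ages, n_years, len(states)), np.nan)
        for cohort in run.cohorts:
            cohort = int(cohort)
            if scenario == NO_NVP:
                traj = project_cohort_no_nvp(bundle, gender, cohort)
            else:
                traj = project_cohort_nvp(bundle, params, gender, cohort,
                                          pre35_quit_state=pre35_quit_state)
            prev = traj.prevalence()
            for j, a in enumerate(traj.ages):
                y = cohort + int(a)
                if run.start_year <= y <= run.end_year:
                    surface[int(a), y - run.start_year] = prev[j]
        idx = pd.MultiIndex.from_product(
            [[gender], run.ages, run.years], names=["gender", "age", "year"]
        )
        frames.append(pd.DataFrame(
            surface.reshape(n_ages * n_years, len(states)), index=idx, columns=states
        ))
    prevalence = pd.concat(frames).sort_index()
    if prevalence.isna().any().any():
        raise RateLookupError("scenario surface has uncovered cells")
    return ScenarioResult(scenario=scenario, prevalence=prevalence, params=params)


def neutral_params(base: NVPParams | None = None) -> NVPParams:
    """Parameters that make the vaping scenario collapse onto the no-vaping one."""
    base = base or NVPParams()
    return base.replace(
        smoking_init_mult=1.0,
        nvp_init_mult=0.0,
        smoking_cess_mult=1.0,
        nvp_cess_mult=1.0,
        switch_base={g: tuple(0.0 for _ in v) for g, v in base.switch_base.items()},
        switch_decay=0.0,
        switch_growth=None,
    )
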