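"""Seeded synthetic input bundles shaped like US demographic rate tables.

The generator emulates the structure of the national inputs the projection
consumes: Gompertz never-smoker mortality with current/former relative risks
by age band, a period life table for never-smoker life expectancy, smoking
initiation concentrated in adolescence and zero after the initiation cap,
cessation rising with age, log-linear cohort decline in initiation, and a
start-year smoking prevalence obtained by burning in the no-vaping recursion
so the initial state is dynamically consistent with the rate schedule.
These bundles are test fixtures, not US data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .input_model import (
    BundleValidationError,
    InputBundle,
    RunSpec,
)

#: (age_lo, age_hi, ratio) bands; default relative risks vs never smokers.
DEFAULT_RR_CURRENT: tuple[tuple[int, int, float], ...] = (
    (0, 44, 2.5), (45, 64, 2.8), (65, 79, 2.2), (80, 200, 1.5),
)
DEFAULT_RR_FORMER: tuple[tuple[int, int, float], ...] = (
    (0, 44, 1.3), (45, 64, 1.5), (65, 79, 1.4), (80, 200, 1.2),
)

_GENDER_MORT_MULT = {"male": 1.15, "female": 0.90}
_GENDER_INIT_MULT = {"male": 1.10, "female": 0.90}


@dataclass(frozen=True)
class SyntheticSpec:
    """Knobs of the synthetic world.

    Mortality is Gompertz, ``m(a) = gompertz_a * exp(gompertz_b * a)``, with
    a mild secular decline per calendar year; smoking initiation is a
    Gaussian bump in age peaking at ``init_peak_age`` (zero below age 10 and
    above the run's initiation cap) whose level declines log-linearly across
    birth cohorts; cessation grows additively with age from ``cess_base`` at
    age 25.
    """

    seed: int = 1
    gompertz_a: float = 5e-5
    gompertz_b: float = 0.095
    mortality_trend: float = 0.003  # fractional decline per calendar year
    rr_current: tuple[tuple[int, int, float], ...] = DEFAULT_RR_CURRENT
    rr_former: tuple[tuple[int, int, float], ...] = DEFAULT_RR_FORMER
    init_peak_age: int = 16
    init_peak_rate: float = 0.04
    init_age_sd: float = 3.0
    init_cohort_decline: float = 0.01
    cess_base: float = 0.03
    cess_age_slope: float = 0.01  # additive per decade of age
    population_shape: str = "pyramid"  # or "flat"
    population_base: float = 200_000.0

    def __post_init__(self) -> None:
        if self.population_shape not in ("pyramid", "flat"):
            raise BundleValidationError(
                f"population_shape must be 'pyramid' or 'flat', got {self.population_shape!r}"
            )
        for lo, hi, rc in self.rr_current:
            if rc < 1.0:
                raise BundleValidationError(f"rr_current band {lo}-{hi} ratio {rc} < 1")
        for lo, hi, rf in self.rr_former:
            rc = _band_ratio(self.rr_current, lo)
            if not (1.0 <= rf <= rc):
                raise BundleValidationError(
                    f"rr_former band {lo}-{hi} ratio {rf} outside [1, rr_current={rc}]"
                )


def _band_ratio(bands: tuple[tuple[int, int, float], ...], age: int) -> float:
    for lo, hi, ratio in bands:
        if lo <= age <= hi:
            return ratio
    raise BundleValidationError(f"no relative-risk band covers age {age}")


def _never_mortality(spec: SyntheticSpec, gender: str, ages: np.ndarray,
                     years: np.ndarray, start_year: int) -> np.ndarray:
    base = spec.gompertz_a * np.exp(spec.gompertz_b * ages) * _GENDER_MORT_MULT[gender]
    trend = (1.0 - spec.mortality_trend) ** (years - start_year)
    return np.minimum(np.outer(base, trend), 0.98)


def _initiation_age_profile(spec: SyntheticSpec, run: RunSpec) -> np.ndarray:
    ages = run.ages.astype(float)
    shape = np.exp(-0.5 * ((ages - spec.init_peak_age) / spec.init_age_sd) ** 2)
    shape[ages < 10] = 0.0
    shape[ages > run.initiation_max_age] = 0.0
    return shape


def _cessation_profile(spec: SyntheticSpec, run: RunSpec) -> np.ndarray:
    ages = run.ages.astype(float)
    return np.clip(spec.cess_base + spec.cess_age_slope * (ages - 25.0) / 10.0,
                   0.002, 0.9)


def derive_life_expectancy(mortality: pd.Series, run: RunSpec) -> pd.Series:
    """Never-smoker remaining life expectancy via a period life table.

    For each (gender, year), with annual death probability ``m(k)``::

        LE(a) = sum_{k=a}^{A-1} P(a -> k) * (1 - 0.5 m(k))
                + P(a -> A) * (1 - 0.5 m(A)) / m(A)

    where ``A = max_age`` and ``P(a -> k)`` is survival from exact age a to
    k. Decedents contribute half a year; the open interval beyond the top
    age assumes constant mortality ``m(A)``.
    """
    ages = run.ages
    out = {}
    for gender in run.genders:
        never = mortality.xs(gender, level="gender").xs("never", level="status")
        wide = never.unstack("year").reindex(index=ages, columns=run.years)
        if wide.isna().any().any():
            raise BundleValidationError(
                f"never-smoker mortality incomplete for gender {gender!r}"
            )
        m = wide.to_numpy(dtype=float)
        if np.any(m[-1] <= 0):
            raise BundleValidationError(
                "zero never-smoker mortality at max_age: life-table closure undefined"
            )
        n = len(ages)
        le = np.empty_like(m)
        le[-1] = (1.0 - 0.5 * m[-1]) / m[-1]
        for a in range(n - 2, -1, -1):
            # person-years this age plus discounted remainder
            le[a] = (1.0 - 0.5 * m[a]) + (1.0 - m[a]) * le[a + 1]
        for j, y in enumerate(run.years):
            for a in ages:
                out[(gender, int(a), int(y))] = le[a, j]
    idx = pd.MultiIndex.from_tuples(out.keys(), names=["gender", "age", "year"])
    return pd.Series(list(out.values()), index=idx, name="le")


def _burn_in_prevalence(run: RunSpec, init_by_cohort_age: np.ndarray,
                        cess: np.ndarray, m_never: np.ndarray,
                        m_current: np.ndarray, m_former: np.ndarray) -> np.ndarray:
    """Start-year (current, former) prevalence per age from a no-vaping burn-in.

    Each cohort alive at the start year is rolled forward from age 0 as 100%
    never smokers using its own initiation/cessation column; mortality for
    pre-start years is held at the start-year column.
    """
    cohorts0 = run.start_year - run.max_age
    prev = np.zeros((run.max_age + 1, 2))
    for a0 in range(0, run.max_age + 1):
        cohort = run.start_year - a0
        ci = cohort - cohorts0
        N, S, F = 1.0, 0.0, 0.0
        for a in range(0, a0):
            mN, mS, mF = m_never[a, 0], m_current[a, 0], m_former[a, 0]
            i = init_by_cohort_age[ci, a] if a <= run.initiation_max_age else 0.0
            c = cess[a]
            N, S, F = (
                N * (1 - mN) * (1 - i),
                N * (1 - mN) * i + S * (1 - mS) * (1 - c),
                F * (1 - mF) + S * (1 - mS) * c,
            )
        total = N + S + F
        prev[a0] = (S / total, F / total)
    return prev


def make_bundle(spec: SyntheticSpec, run: RunSpec | None = None) -> InputBundle:
    """Build a complete, internally consistent synthetic input bundle.

    Deterministic given ``spec.seed``; the seed only perturbs population
    counts (a few percent of multiplicative noise), so rate tables are
    reproducible analytic shapes.
    """
    run = run or RunSpec()
    rng = np.random.default_rng(spec.seed)
    ages = run.ages
    years = run.years
    cohorts = run.cohorts

    pop_parts = {}
    mort_parts = {}
    init_parts = {}
    cess_parts = {}
    prev_parts = {}

    age_profile = _initiation_age_profile(spec, run)
    cess_profile = _cessation_profile(spec, run)
    rr_cur = np.array([_band_ratio(spec.rr_current, int(a)) for a in ages])
    rr_fmr = np.array([_band_ratio(spec.rr_former, int(a)) for a in ages])

    for gender in run.genders:
        mN = _never_mortality(spec, gender, ages, years, run.start_year)
        mS = np.minimum(mN * rr_cur[:, None], 0.995)
        mF = np.minimum(mN * rr_fmr[:, None], 0.99)
        # caps can only bind from above; re-impose ordering at the extreme tail
        mF = np.minimum(mF, mS)
        mN = np.minimum(mN, mF)
        mort_parts[gender] = {"never": mN, "current": mS, "former": mF}

        # initiation by (cohort, age): log-linear decline across birth cohorts
        decline = np.exp(-spec.init_cohort_decline * (cohorts - cohorts[0]))
        level = spec.init_peak_rate * _GENDER_INIT_MULT[gender]
        init_parts[gender] = level * np.outer(decline, age_profile)
        cess_parts[gender] = cess_profile

        # population: census-like pyramid or flat, mild growth, seeded noise
        if spec.population_shape == "pyramid":
            shape = np.where(ages < 55, 1.0, np.exp(-0.035 * (ages - 55.0)))
        else:
            shape = np.ones_like(ages, dtype=float)
        noise = rng.normal(1.0, 0.02, size=len(ages)).clip(0.9, 1.1)
        growth = 1.003 ** (years - run.start_year)
        pop_parts[gender] = np.outer(spec.population_base * shape * noise, growth)

        prev_parts[gender] = _burn_in_prevalence(
            run, init_parts[gender], cess_profile, mN, mS, mF
        )

    records = []
    for gender in run.genders:
        for a in ages:
            for j, y in enumerate(years):
                records.append((gender, int(a), int(y), pop_parts[gender][a, j]))
    pop = pd.DataFrame(records, columns=["gender", "age", "year", "count"]) \
        .set_index(["gender", "age", "year"])["count"]

    records = []
    for gender in run.genders:
        for status, arr in mort_parts[gender].items():
            for a in ages:
                for j, y in enumerate(years):
                    records.append((gender, int(a), int(y), status, arr[a, j]))
    mort = pd.DataFrame(records, columns=["gender", "age", "year", "status", "rate"]) \
        .set_index(["gender", "age", "year", "status"])["rate"]

    records = []
    for gender in run.genders:
        for ci, b in enumerate(cohorts):
            for a in ages:
                records.append((gender, int(b), int(a), init_parts[gender][ci, a]))
    init = pd.DataFrame(records, columns=["gender", "cohort", "age", "rate"]) \
        .set_index(["gender", "cohort", "age"])["rate"]

    records = []
    for gender in run.genders:
        for b in cohorts:
            for a in ages:
                records.append((gender, int(b), int(a), cess_parts[gender][a]))
    cess = pd.DataFrame(records, columns=["gender", "cohort", "age", "rate"]) \
        .set_index(["gender", "cohort", "age"])["rate"]

    records = []
    for gender in run.genders:
        for a in ages:
            records.append((gender, int(a), prev_parts[gender][a, 0], prev_parts[gender][a, 1]))
    prev = pd.DataFrame(records, columns=["gender", "age", "current", "former"]) \
        .set_index(["gender", "age"])

    le = derive_life_expectancy(mort, run)

    return InputBundle(
        run=run,
        population=pop,
        mortality=mort,
        life_expectancy=le,
        initiation=init,
        cessation=cess,
        initial_current=prev["current"],
        initial_former=prev["former"],
    )
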