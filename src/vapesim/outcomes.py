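"""Attributable deaths, life-years lost, and scenario differencing.

Prevalences from the engine are converted to head counts with the exogenous
population projections (which already embed births, deaths and migration);
attributable deaths apply per-state excess mortality relative to never
smokers, and life-years lost weight those deaths by never-smoker remaining
life expectancy. The public-health impact of vaping is the difference in
these outcomes between the no-vaping and vaping scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cohort_engine import NO_NVP, ScenarioResult
from .input_model import InputBundle


class GridMismatchError(Exception):
    """Two outcome grids or windows do not line up."""


@dataclass
class OutcomeSeries:
    """Attributable deaths (and optionally life-years lost) for one scenario.

    ``deaths_detail`` is per (gender, age, year) over the outcome age window;
    ``deaths_yearly`` sums over ages; ``deaths_cumulative`` sums over the run
    window per gender. The ``lyl_*`` fields are populated by
    :func:`life_years_lost`.
    """

    scenario: str
    deaths_detail: pd.Series
    deaths_yearly: pd.Series
    deaths_cumulative: pd.Series
    lyl_detail: pd.Series | None = None
    lyl_yearly: pd.Series | None = None
    lyl_cumulative: pd.Series | None = None


@dataclass
class ComparisonResult:
    """Averted deaths and life-years between two scenarios.

    Averted = baseline minus alternative, per year and cumulatively, by
    gender plus a both-gender total. Percentages are computed from the
    unrounded cumulative sums and only rounded for display.
    """

    averted_deaths_yearly: pd.Series
    averted_deaths_cumulative: pd.Series
    averted_lyl_yearly: pd.Series | None
    averted_lyl_cumulative: pd.Series | None
    baseline_deaths_cumulative: pd.Series
    baseline_lyl_cumulative: pd.Series | None

    @property
    def percent_averted_deaths(self) -> float:
        return percent_averted(self.averted_deaths_cumulative["both"],
                               self.baseline_deaths_cumulative["both"])

    @property
    def percent_averted_lyl(self) -> float:
        if self.averted_lyl_cumulative is None:
            raise ValueError("life-years lost not computed")
        return percent_averted(self.averted_lyl_cumulative["both"],
                               self.baseline_lyl_cumulative["both"])

    def summary(self) -> pd.DataFrame:
        rows = {
            "averted_deaths": self.averted_deaths_cumulative,
            "baseline_deaths": self.baseline_deaths_cumulative,
        }
        if self.averted_lyl_cumulative is not None:
            rows["averted_lyl"] = self.averted_lyl_cumulative
            rows["baseline_lyl"] = self.baseline_lyl_cumulative
        return pd.DataFrame(rows)


def percent_averted(averted: float, baseline_total: float) -> float:
    """Averted amount as a percentage of the baseline total (unrounded)."""
    if baseline_total == 0:
        raise ZeroDivisionError("baseline total is zero")
    return averted / baseline_total * 100.0


def _excess_frame(result: ScenarioResult, bundle: InputBundle) -> pd.DataFrame:
    """Per-state excess mortality columns aligned to the prevalence index."""
    wide = bundle.mortality.unstack("status")
    wide = wide.reindex(result.prevalence.index)
    mN, mS, mF = (wide[s].to_numpy() for s in ("never", "current", "former"))
    excess = {"never": np.zeros_like(mN), "smoker": mS - mN, "former_smoker": mF - mN}
    if result.scenario != NO_NVP:
        r = result.params.risk_nvp
        excess["nvp_user"] = r * (mS - mN)
        excess["former_nvp_user"] = r * (mF - mN)
        excess["fs_nvp_user"] = (mF - mN) + r * (mS - mF)
        excess["pre35_quitter"] = np.zeros_like(mN)
    return pd.DataFrame(excess, index=result.prevalence.index)[list(result.states)]


def attributable_deaths(result: ScenarioResult, bundle: InputBundle) -> OutcomeSeries:
    """Smoking- (and vaping-) attributable deaths over the outcome age window.

    deaths(g, a, t) = sum over states of
    prevalence x population(g, a, t) x excess(state, a, t), where excess is
    the state's mortality minus the never-smoker rate (scaled by ``risk_nvp``
    for vaping states).
    """
    run = bundle.run
    prev = result.prevalence
    pop = bundle.population.reindex(prev.index)
    if pop.isna().any():
        raise GridMismatchError("population table does not cover the scenario grid")
    excess = _excess_frame(result, bundle)
    if excess.isna().any().any():
        raise GridMismatchError("mortality table does not cover the scenario grid")
    cell = prev.mul(excess).sum(axis=1) * pop
    ages = cell.index.get_level_values("age")
    cell = cell[(ages >= run.outcome_age_min) & (ages <= run.outcome_age_max)]
    yearly = cell.groupby(level=["gender", "year"]).sum()
    cumulative = yearly.groupby(level="gender").sum()
    return OutcomeSeries(
        scenario=result.scenario,
        deaths_detail=cell.rename("deaths"),
        deaths_yearly=yearly.rename("deaths"),
        deaths_cumulative=cumulative.rename("deaths"),
    )


def life_years_lost(series: OutcomeSeries, le: pd.Series) -> OutcomeSeries:
    """Weight attributable deaths by never-smoker remaining life expectancy."""
    le_cells = le.reindex(series.deaths_detail.index)
    if le_cells.isna().any():
        missing = le_cells[le_cells.isna()].index[0]
        raise GridMismatchError(f"life expectancy missing at {missing}")
    detail = (series.deaths_detail * le_cells).rename("lyl")
    yearly = detail.groupby(level=["gender", "year"]).sum()
    return replace(
        series,
        lyl_detail=detail,
        lyl_yearly=yearly.rename("lyl"),
        lyl_cumulative=yearly.groupby(level="gender").sum().rename("lyl"),
    )


def _with_both(series: pd.Series, level: str = "gender") -> pd.Series:
    """Append a both-gender total along the gender level."""
    if series.index.nlevels == 1:
        out = series.copy()
        out.loc["both"] = series.sum()
        return out
    total = series.groupby(level="year").sum()
    total.index = pd.MultiIndex.from_product([["both"], total.index],
                                             names=series.index.names)
    return pd.concat([series, total]).sort_index()


def compare(no_nvp: OutcomeSeries, nvp: OutcomeSeries) -> ComparisonResult:
    """Difference two scenario outcome series (baseline minus alternative)."""
    if not no_nvp.deaths_yearly.index.equals(nvp.deaths_yearly.index):
        raise GridMismatchError("outcome series cover different (gender, year) grids")
    averted_yearly = _with_both(no_nvp.deaths_yearly - nvp.deaths_yearly)
    averted_cum = _with_both(no_nvp.deaths_cumulative - nvp.deaths_cumulative)
    base_cum = _with_both(no_nvp.deaths_cumulative)
    lyl_yearly = lyl_cum = base_lyl = None
    if no_nvp.lyl_yearly is not None and nvp.lyl_yearly is not None:
        lyl_yearly = _with_both(no_nvp.lyl_yearly - nvp.lyl_yearly)
        lyl_cum = _with_both(no_nvp.lyl_cumulative - nvp.lyl_cumulative)
        base_lyl = _with_both(no_nvp.lyl_cumulative)
    return ComparisonResult(
        averted_deaths_yearly=averted_yearly,
        averted_deaths_cumulative=averted_cum,
        averted_lyl_yearly=lyl_yearly,
        averted_lyl_cumulative=lyl_cum,
        baseline_deaths_cumulative=base_cum,
        baseline_lyl_cumulative=base_lyl,
    )


def scenario_outcomes(result: ScenarioResult, bundle: InputBundle) -> OutcomeSeries:
    """Attributable deaths plus life-years lost in one call."""
    deaths = attributable_deaths(result, bundle)
    return life_years_lost(deaths, bundle.life_expectancy)


def period_prevalence(result: ScenarioResult, bundle: InputBundle,
                      states: tuple[str, ...] | list[str], age_band: tuple[int, int],
                      year: int, gender: str | None = None) -> float:
    """Population-weighted prevalence (%) of a state set over an age band.

    ``gender=None`` pools genders with population weights.
    """
    lo, hi = age_band
    prev = result.prevalence
    ages = prev.index.get_level_values("age")
    years = prev.index.get_level_values("year")
    mask = (ages >= lo) & (ages <= hi) & (years == year)
    if gender is not None:
        mask &= prev.index.get_level_values("gender") == gender
    sub = prev.loc[mask, list(states)].sum(axis=1)
    if sub.empty:
        raise ValueError(f"no modeled ages in band {age_band} for year {year}")
    weights = bundle.population.reindex(sub.index)
    if weights.isna().any():
        raise GridMismatchError("population table does not cover the requested band")
    total = weights.sum()
    if total <= 0:
        raise ValueError("zero population in the requested band")
    return float((sub * weights).sum() / total * 100.0)


def project_impact(bundle: InputBundle, params) -> ComparisonResult:
    """End-to-end baseline comparison: run both scenarios and difference them."""
    from .cohort_engine import NVP, run_scenario

    base = scenario_outcomes(run_scenario(bundle, scenario=NO_NVP), bundle)
    alt = scenario_outcomes(run_scenario(bundle, params, scenario=NVP), bundle)
    return compare(base, alt)
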