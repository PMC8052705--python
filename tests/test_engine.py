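"""Cohort recursions: hand oracles, switch-rate schedule, and invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vapesim import (
    NO_NVP,
    NVP,
    NVPParams,
    RunSpec,
    baseline_params,
    effective_switch_rate,
    neutral_params,
    project_cohort_no_nvp,
    project_cohort_nvp,
    run_scenario,
)
from vapesim.cohort_engine import CompetingRiskError, RateLookupError
from vapesim.input_model import SwitchGrowth
from conftest import build_toy_bundle


class TestSwitchRateSchedule:
    run = RunSpec()

    def test_baseline_young_adult_rate(self):
        p = baseline_params()
        assert effective_switch_rate(p, "male", 20, 2013, self.run) == pytest.approx(0.040)
        assert effective_switch_rate(p, "female", 20, 2013, self.run) == pytest.approx(0.025)

    def test_one_decay_step(self):
        p = baseline_params(switch_decay=0.10)
        assert effective_switch_rate(p, "male", 20, 2014, self.run) == pytest.approx(0.036)

    def test_growth_compounds_within_window_then_holds(self):
        p = baseline_params(switch_growth=SwitchGrowth(0.05, 2018, 2022))
        assert effective_switch_rate(p, "male", 20, 2020, self.run) == pytest.approx(0.046305)
        held = effective_switch_rate(p, "male", 20, 2030, self.run)
        assert held == pytest.approx(0.040 * 1.05 ** 5)

    def test_children_below_first_band_never_switch(self):
        p = baseline_params()
        assert effective_switch_rate(p, "male", 9, 2013, self.run) == 0.0

    def test_band_boundaries(self):
        p = baseline_params()  # youth band differs from 18-24 band
        assert effective_switch_rate(p, "male", 17, 2013, self.run) == pytest.approx(0.080)
        assert effective_switch_rate(p, "male", 18, 2013, self.run) == pytest.approx(0.040)
        assert effective_switch_rate(p, "male", 80, 2013, self.run) == pytest.approx(0.006)


class TestNoNvpRecursion:
    def test_hand_recursion_single_step(self, toy_bundle):
        # entry (N,S,F) = (0.8, 0.2, 0); m = (.01,.03,.02), i=.10, c=.05
        traj = project_cohort_no_nvp(toy_bundle, "male", 1983)  # age 30 at entry
        N, S, F = traj.masses[1]
        assert N == pytest.approx(0.8 * 0.99 * 0.9, abs=1e-12)          # 0.71280
        assert S == pytest.approx(0.8 * 0.99 * 0.1 + 0.2 * 0.97 * 0.95, abs=1e-12)
        assert F == pytest.approx(0.2 * 0.97 * 0.05, abs=1e-12)         # 0.00970

    def test_never_state_absorbing_without_rates(self):
        b = build_toy_bundle(initiation=0.0, cessation=0.0,
                             initial_current=0.0, initial_former=0.0)
        traj = project_cohort_no_nvp(b, "female", 1990)
        prev = traj.prevalence()
        assert prev[:, 0] == pytest.approx(1.0)

    def test_uniform_mortality_conserves_mass_geometrically(self):
        b = build_toy_bundle(m_never=0.02, m_current=0.02, m_former=0.02)
        traj = project_cohort_no_nvp(b, "male", 1983)
        steps = len(traj.ages) - 1
        assert traj.masses[-1].sum() == pytest.approx(0.98 ** steps, rel=1e-12)

    def test_initiation_stops_after_age_cap(self, toy_bundle):
        # cohort entering at age 39: only one initiation step (39 -> 40) applies
        traj = project_cohort_no_nvp(toy_bundle, "male", 1974)
        prev = traj.prevalence()
        # never-prevalence falls while initiation is active, then only drifts
        # by differential mortality (slowly rising share is impossible: never
        # mortality is lowest, so the share can rise only w/o initiation)
        drop_active = prev[0, 0] - prev[1, 0]
        assert drop_active > 0.05
        assert abs(prev[2, 0] - prev[3, 0]) < 0.01


class TestNvpRecursion:
    def test_neutral_parameters_reduce_to_no_nvp(self, toy_bundle):
        p = neutral_params()
        for cohort in (1983, 2014):
            a = project_cohort_no_nvp(toy_bundle, "male", cohort)
            b = project_cohort_nvp(toy_bundle, p, "male", cohort)
            np.testing.assert_allclose(b.masses[:, :3], a.masses, rtol=0, atol=0)
            assert np.all(b.masses[:, 3:] == 0.0)

    def test_full_risk_limit_matches_smoker_mortality(self, toy_bundle):
        """risk = 1 makes vapers die exactly like smokers: with all mass
        forced through V via certain switching, totals shrink at smoker rates."""
        p = NVPParams(risk_nvp=1.0,
                      switch_base={"male": (1.0,) * 7, "female": (1.0,) * 7},
                      smoking_cess_mult=0.0, nvp_cess_mult=0.0,
                      smoking_init_mult=0.0, nvp_init_mult=0.0)
        b = build_toy_bundle(initiation=0.0, initial_current=1.0)
        traj = project_cohort_nvp(b, p, "male", 1983)
        # after first step all smokers switched into V (age 31 < 35)
        assert traj.masses[1, 3] == pytest.approx(0.97)
        # thereafter V carries m^V = m^S = 0.03 exactly
        assert traj.masses[2, 3] == pytest.approx(0.97 ** 2, rel=1e-12)

    def test_age_35_rule_keys_on_landing_age(self):
        """Switchers landing at 34 become exclusive vapers; at 35 they are
        former smokers who vape."""
        p = NVPParams(switch_base={"male": (0.0, 0.0, 0.1, 0.1, 0.0, 0.0, 0.0),
                                   "female": (0.0,) * 7})
        b = build_toy_bundle(initiation=0.0, cessation=0.0, initial_current=0.5)
        traj = project_cohort_nvp(b, p, "male", 1980)  # ages 33, 34, 35, ...
        S0 = 0.5
        sS1 = S0 * 0.97  # smokers surviving the first step
        V1, FSV1 = traj.masses[1, 3], traj.masses[1, 5]
        assert V1 == pytest.approx(sS1 * 0.1, rel=1e-12)   # landed at 34 -> vaper
        assert FSV1 == pytest.approx(0.0, abs=0.0)
        S1 = sS1 * 0.9
        V2, FSV2 = traj.masses[2, 3], traj.masses[2, 5]
        assert FSV2 == pytest.approx(S1 * 0.97 * 0.1, rel=1e-12)  # landed at 35
        # V only decays by vaper mortality after the boundary
        assert V2 < V1

    def test_default_routing_sends_young_quitters_to_former(self):
        p = NVPParams(switch_base={g: (0.0,) * 7 for g in ("male", "female")})
        b = build_toy_bundle(initiation=0.0, cessation=1.0, initial_current=1.0,
                             m_never=0.01, m_current=0.03, m_former=0.02)
        traj = project_cohort_nvp(b, p, "male", 1990)  # ages 23+; quits land < 35
        # all smokers quit in step one into F; F then decays at former rates
        f1, f2 = traj.masses[1, 2], traj.masses[2, 2]
        assert f1 == pytest.approx(0.97, rel=1e-12)
        assert f2 == pytest.approx(0.97 * 0.98, rel=1e-12)
        assert np.all(traj.masses[:, 6] == 0.0)

    def test_optional_pre35_quitter_state_keeps_never_mortality(self):
        p = NVPParams(switch_base={g: (0.0,) * 7 for g in ("male", "female")})
        b = build_toy_bundle(initiation=0.0, cessation=1.0, initial_current=1.0,
                             m_never=0.01, m_current=0.03, m_former=0.02)
        traj = project_cohort_nvp(b, p, "male", 1990,
                                  pre35_quit_state="pre35_quitter")
        # quits landing before 35 enter Q35 and decay at never-smoker rates
        q1, q2 = traj.masses[1, 6], traj.masses[2, 6]
        assert q1 == pytest.approx(0.97, rel=1e-12)
        assert q2 == pytest.approx(0.97 * 0.99, rel=1e-12)

    def test_competing_risk_overflow_raises(self):
        p = NVPParams(switch_base={g: (1.0,) * 7 for g in ("male", "female")},
                      smoking_cess_mult=1.0)
        b = build_toy_bundle(cessation=0.5, initial_current=0.5)
        with pytest.raises(CompetingRiskError, match="cessation\\+switching"):
            project_cohort_nvp(b, p, "male", 1983)

    def test_missing_rate_cell_raises_lookup_error(self, toy_bundle):
        trimmed = toy_bundle.initiation.drop(("male", 1983, 31))
        object.__setattr__(toy_bundle, "initiation", trimmed)
        toy_bundle.__dict__.pop("_dense_cache", None)
        with pytest.raises(RateLookupError, match="cohort 1983, age 31"):
            project_cohort_no_nvp(toy_bundle, "male", 1983)


class TestScenarioAssembly:
    def test_prevalences_sum_to_one_everywhere(self, small_bundle):
        for scenario, params in ((NO_NVP, None), (NVP, baseline_params())):
            res = run_scenario(small_bundle, params, scenario=scenario)
            sums = res.prevalence.sum(axis=1)
            np.testing.assert_allclose(sums.to_numpy(), 1.0, atol=1e-12)

    def test_neutral_scenario_equals_no_nvp_surface(self, small_bundle):
        base = run_scenario(small_bundle, scenario=NO_NVP)
        neut = run_scenario(small_bundle, neutral_params(), scenario=NVP)
        diff = (neut.prevalence[list(base.prevalence.columns)]
                - base.prevalence).abs().to_numpy()
        assert diff.max() == 0.0

    def test_vaping_scenario_lowers_adult_smoking(self, small_bundle):
        base = run_scenario(small_bundle, scenario=NO_NVP)
        alt = run_scenario(small_bundle, baseline_params(), scenario=NVP)
        year = small_bundle.run.end_year
        idx = pd.IndexSlice
        for gender in ("male", "female"):
            b = base.prevalence.loc[idx[gender, 20:60, year], "smoker"]
            a = alt.prevalence.loc[idx[gender, 20:60, year], "smoker"]
            assert (a.to_numpy() < b.to_numpy()).all()

    def test_params_only_accepted_for_nvp(self, toy_bundle):
        with pytest.raises(ValueError):
            run_scenario(toy_bundle, baseline_params(), scenario=NO_NVP)
        with pytest.raises(ValueError):
            run_scenario(toy_bundle, scenario=NVP)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    m=st.tuples(st.floats(0.0, 0.3), st.floats(0.0, 0.3), st.floats(0.0, 0.3)),
    i=st.floats(0.0, 0.5),
    c=st.floats(0.0, 0.5),
)
def test_mass_conservation_under_arbitrary_rates(m, i, c):
    """Per step, total mass lost equals exactly the mortality outflow."""
    mN, mS, mF = sorted(m)
    b = build_toy_bundle(m_never=mN, m_current=mS, m_former=mF,
                         initiation=i, cessation=c)
    p = baseline_params()
    traj = project_cohort_nvp(b, p, "male", 1983)
    states = traj.masses
    mort = np.array([mN, mS, mF,
                     mN + p.risk_nvp * (mS - mN),
                     mN + p.risk_nvp * (mF - mN),
                     mF + p.risk_nvp * (mS - mF),
                     mN])
    for j in range(1, len(states)):
        survivors = (states[j - 1] * (1 - mort)).sum()
        assert states[j].sum() == pytest.approx(survivors, abs=1e-12)
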