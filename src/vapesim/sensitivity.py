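"""One-at-a-time parameter sweeps over the vaping-scenario knobs.

Each variant edits the baseline parameter set (set a field, or scale it),
reruns both scenarios, and reports cumulative averted deaths and life-years
with the relative change against the baseline variant at the same vaping
relative-risk level.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import pandas as pd

from .cohort_engine import NO_NVP, NVP, run_scenario
from .input_model import InputBundle, NVPParams, SwitchGrowth
from .outcomes import compare, scenario_outcomes

BASELINE_LABEL = "baseline"


@dataclass(frozen=True)
class Edit:
    """One parameter edit: set ``field`` to ``value`` or scale it by ``scale``."""

    field: str
    value: object = None
    scale: float | None = None

    def __post_init__(self) -> None:
        if (self.value is None) == (self.scale is None):
            raise ValueError("exactly one of value/scale must be given")


@dataclass(frozen=True)
class SweepVariant:
    label: str
    edits: tuple[Edit, ...] = ()


def apply_edits(params: NVPParams, variant: SweepVariant) -> NVPParams:
    valid = {f.name for f in dataclasses.fields(NVPParams)}
    for edit in variant.edits:
        if edit.field not in valid:
            raise KeyError(f"variant {variant.label!r} edits unknown field {edit.field!r}")
        if edit.scale is not None:
            if edit.field == "switch_base":
                new = {g: tuple(v * edit.scale for v in vs)
                       for g, vs in params.switch_base.items()}
            else:
                new = getattr(params, edit.field) * edit.scale
        else:
            new = edit.value
        params = params.replace(**{edit.field: new})
    return params


def relative_change(variant_value: float, baseline_value: float) -> float:
    """Percent change of a variant quantity against the baseline quantity."""
    if baseline_value == 0:
        raise ZeroDivisionError("relative change undefined for zero baseline")
    return (variant_value - baseline_value) / baseline_value * 100.0


def standard_variants() -> list[SweepVariant]:
    """The canonical 12-variant one-at-a-time sweep.

    Switch rates at 50% and 200% of baseline, a 10% annual switch-rate decay,
    a 5% annual switch-rate increase over 2018-2022, smoking initiation
    multiplier at 25%/125%, vaping initiation at 25%/75%, smoking cessation
    at 50%/150%, and vaping cessation at 50%/150%.
    """
    return [
        SweepVariant("50% of switch rate, no decay", (Edit("switch_base", scale=0.5),)),
        SweepVariant("200% of switch rate, no decay", (Edit("switch_base", scale=2.0),)),
        SweepVariant("100% of switch rate, 10% annual decay",
                     (Edit("switch_decay", value=0.10),)),
        SweepVariant("100% of switch rate, 5% annual increase first 5 years",
                     (Edit("switch_growth",
                           value=SwitchGrowth(rate=0.05, first_year=2018, last_year=2022)),)),
        SweepVariant("25% of smoking initiation", (Edit("smoking_init_mult", value=0.25),)),
        SweepVariant("125% of smoking initiation", (Edit("smoking_init_mult", value=1.25),)),
        SweepVariant("25% of NVP initiation", (Edit("nvp_init_mult", value=0.25),)),
        SweepVariant("75% of NVP initiation", (Edit("nvp_init_mult", value=0.75),)),
        SweepVariant("50% of smoking cessation", (Edit("smoking_cess_mult", value=0.50),)),
        SweepVariant("150% of smoking cessation", (Edit("smoking_cess_mult", value=1.50),)),
        SweepVariant("50% of NVP cessation", (Edit("nvp_cess_mult", value=0.50),)),
        SweepVariant("150% of NVP cessation", (Edit("nvp_cess_mult", value=1.50),)),
    ]


def run_sweep(bundle: InputBundle, baseline: NVPParams,
              variants: list[SweepVariant] | None = None,
              risk_levels: tuple[float, ...] = (0.05,)) -> pd.DataFrame:
    """Run every (risk level x variant) and tabulate averted outcomes.

    Returns one row per combination (baseline first at each risk level) with
    cumulative both-gender averted deaths/life-years and relative changes
    versus the same-risk baseline. A variant whose run fails is reported in
    its ``error`` column; the sweep continues.
    """
    variants = list(variants or [])
    base_outcomes = scenario_outcomes(run_scenario(bundle, scenario=NO_NVP), bundle)

    rows = []
    for risk in risk_levels:
        base_params = baseline.replace(risk_nvp=risk)
        base_cmp = compare(
            base_outcomes,
            scenario_outcomes(run_scenario(bundle, base_params, scenario=NVP), bundle),
        )
        base_svads = base_cmp.averted_deaths_cumulative["both"]
        base_lyls = base_cmp.averted_lyl_cumulative["both"]
        rows.append({
            "risk_nvp": risk, "variant": BASELINE_LABEL,
            "averted_svads": base_svads, "averted_svads_rel_change": 0.0,
            "averted_lyls": base_lyls, "averted_lyls_rel_change": 0.0,
            "error": "",
        })
        for variant in variants:
            row = {"risk_nvp": risk, "variant": variant.label, "error": ""}
            try:
                params = apply_edits(base_params, variant)
                cmp_ = compare(
                    base_outcomes,
                    scenario_outcomes(run_scenario(bundle, params, scenario=NVP), bundle),
                )
                svads = cmp_.averted_deaths_cumulative["both"]
                lyls = cmp_.averted_lyl_cumulative["both"]
                row.update(
                    averted_svads=svads,
                    averted_svads_rel_change=relative_change(svads, base_svads),
                    averted_lyls=lyls,
                    averted_lyls_rel_change=relative_change(lyls, base_lyls),
                )
            except Exception as exc:  # keep sweeping, report per row
                row.update(averted_svads=float("nan"),
                           averted_svads_rel_change=float("nan"),
                           averted_lyls=float("nan"),
                           averted_lyls_rel_change=float("nan"),
                           error=f"{type(exc).__name__}: {exc}")
            rows.append(row)
    return pd.DataFrame(rows)
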