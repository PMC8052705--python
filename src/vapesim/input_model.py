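"""Exogenous data model: demographic tables, rate schedules and scenario parameters.

All tables are pandas Series with named MultiIndex levels. Ages and calendar
years are integers; a birth cohort is ``year - age``; one model step is one
year, so age and year advance together within a cohort. Rates are annual
probabilities, not hazards.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

GENDERS = ("male", "female")
STATUSES = ("never", "current", "former")

#: Age bands over which cigarette-to-vaping switch rates are specified.
SWITCH_AGE_BANDS: tuple[tuple[int, int], ...] = (
    (10, 17),
    (18, 24),
    (25, 34),
    (35, 44),
    (45, 54),
    (55, 64),
    (65, 200),
)

CONFIG_NAME = "config.yaml"

CSV_FILES = {
    "population": "population.csv",
    "mortality": "mortality.csv",
    "life_expectancy": "life_expectancy.csv",
    "initiation": "initiation.csv",
    "cessation": "cessation.csv",
    "initial_prevalence": "initial_prevalence.csv",
}


class BundleLoadError(Exception):
    """A required input file is missing or unreadable."""


class BundleValidationError(Exception):
    """An input bundle violates a hard invariant."""


@dataclass(frozen=True)
class RunSpec:
    """Run window and structural age thresholds of the projection.

    ``switch_reclass_age`` is the age-35 rule: smokers who quit or switch at
    that age or above keep former-smoker mortality risk; younger quitters do
    not. ``initiation_max_age`` caps smoking initiation (through age 40).
    """

    start_year: int = 2013
    end_year: int = 2060
    max_age: int = 99
    outcome_age_min: int = 18
    outcome_age_max: int = 99
    initiation_max_age: int = 40
    switch_reclass_age: int = 35
    genders: tuple[str, ...] = GENDERS

    def __post_init__(self) -> None:
        if self.start_year >= self.end_year:
            raise BundleValidationError(
                f"start_year {self.start_year} must precede end_year {self.end_year}"
            )
        if not (0 < self.outcome_age_min <= self.outcome_age_max <= self.max_age):
            raise BundleValidationError(
                "require 0 < outcome_age_min <= outcome_age_max <= max_age, got "
                f"{self.outcome_age_min}..{self.outcome_age_max} vs max_age {self.max_age}"
            )
        if self.initiation_max_age > self.max_age:
            raise BundleValidationError("initiation_max_age exceeds max_age")
        if not self.genders:
            raise BundleValidationError("genders must be non-empty")
        object.__setattr__(self, "genders", tuple(self.genders))

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)

    @property
    def ages(self) -> np.ndarray:
        return np.arange(0, self.max_age + 1)

    @property
    def cohorts(self) -> np.ndarray:
        """Birth years of every cohort contributing a cell in the run window."""
        return np.arange(self.start_year - self.max_age, self.end_year + 1)

    def cohort_ages(self, cohort: int) -> range:
        """Ages the engine visits for a cohort (entry age to last in-window age)."""
        a0 = max(0, self.start_year - cohort)
        a1 = min(self.max_age, self.end_year - cohort)
        return range(a0, a1 + 1)


@dataclass(frozen=True)
class SwitchGrowth:
    """Bounded early-period exponential growth of switch rates."""

    rate: float
    first_year: int
    last_year: int

    def __post_init__(self) -> None:
        if self.last_year < self.first_year:
            raise BundleValidationError("switch_growth last_year precedes first_year")
        if self.rate < 0:
            raise BundleValidationError("switch_growth rate must be >= 0")


def _default_switch_base() -> dict[str, tuple[float, ...]]:
    return {g: tuple(0.0 for _ in SWITCH_AGE_BANDS) for g in GENDERS}


@dataclass(frozen=True)
class NVPParams:
    """The six nicotine-vaping scenario parameters.

    * ``risk_nvp`` — vaping excess mortality as a fraction of smoking's
      excess mortality (baseline 0.05; 0.40 in sensitivity analysis).
    * ``smoking_init_mult`` / ``nvp_init_mult`` — linear multipliers applied
      to the no-vaping smoking initiation rate to obtain smoking and vaping
      initiation in the vaping scenario (baseline 0.75 / 0.50).
    * ``smoking_cess_mult`` / ``nvp_cess_mult`` — multipliers on the
      no-vaping smoking cessation rate (baseline 1.00 / 1.00).
    * ``switch_base`` — annual probability a current smoker switches to
      exclusive vaping, per gender and age band (:data:`SWITCH_AGE_BANDS`).
    * ``switch_decay`` — exponential annual decline of switch rates from the
      start year; ``switch_growth`` — optional bounded early growth.
    """

    risk_nvp: float = 0.05
    smoking_init_mult: float = 0.75
    nvp_init_mult: float = 0.50
    smoking_cess_mult: float = 1.00
    nvp_cess_mult: float = 1.00
    switch_base: Mapping[str, tuple[float, ...]] = field(default_factory=_default_switch_base)
    switch_decay: float = 0.0
    switch_growth: SwitchGrowth | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.risk_nvp <= 1.0):
            raise BundleValidationError(f"risk_nvp {self.risk_nvp} outside [0, 1]")
        for name in ("smoking_init_mult", "nvp_init_mult", "smoking_cess_mult", "nvp_cess_mult"):
            if getattr(self, name) < 0:
                raise BundleValidationError(f"{name} must be >= 0")
        if not (0.0 <= self.switch_decay <= 1.0):
            raise BundleValidationError("switch_decay outside [0, 1]")
        base = {g: tuple(float(v) for v in vs) for g, vs in dict(self.switch_base).items()}
        for g, vs in base.items():
            if len(vs) != len(SWITCH_AGE_BANDS):
                raise BundleValidationError(
                    f"switch_base[{g!r}] needs {len(SWITCH_AGE_BANDS)} band values, got {len(vs)}"
                )
            for (lo, hi), v in zip(SWITCH_AGE_BANDS, vs):
                if not (0.0 <= v <= 1.0):
                    raise BundleValidationError(
                        f"switch_base[{g!r}] band {lo}-{hi} value {v} outside [0, 1]"
                    )
        object.__setattr__(self, "switch_base", base)

    def replace(self, **kw) -> "NVPParams":
        return dataclasses.replace(self, **kw)


#: Switch-rate presets (male, female), one value per band in SWITCH_AGE_BANDS.
#: ``methods_text`` uses the 8%/5% youth rate; ``table_footnote`` applies the
#: 18-24 rate to all ages 24 and below. The two shipped sources disagree for
#: ages 10-17; ``methods_text`` is the default.
SWITCH_PRESETS: dict[str, dict[str, tuple[float, ...]]] = {
    "methods_text": {
        "male": (0.080, 0.040, 0.025, 0.025, 0.013, 0.012, 0.006),
        "female": (0.050, 0.025, 0.020, 0.016, 0.014, 0.014, 0.010),
    },
    "table_footnote": {
        "male": (0.040, 0.040, 0.025, 0.025, 0.013, 0.012, 0.006),
        "female": (0.025, 0.025, 0.020, 0.016, 0.014, 0.014, 0.010),
    },
}


def baseline_params(preset: str = "methods_text", **overrides) -> NVPParams:
    """Baseline vaping-scenario parameters with a named switch-rate preset."""
    if preset not in SWITCH_PRESETS:
        raise KeyError(f"unknown switch preset {preset!r}; have {sorted(SWITCH_PRESETS)}")
    kw = dict(switch_base=SWITCH_PRESETS[preset])
    kw.update(overrides)
    return NVPParams(**kw)


def switch_band_index(age: int) -> int | None:
    """Index into SWITCH_AGE_BANDS for an age, or None below the first band."""
    for k, (lo, hi) in enumerate(SWITCH_AGE_BANDS):
        if lo <= age <= hi:
            return k
    return None


@dataclass
class InputBundle:
    """All exogenous inputs: the model's world.

    population : persons by (gender, age, year)
    mortality : annual death probability by (gender, age, year, status)
    life_expectancy : never-smoker remaining life-years by (gender, age, year)
    initiation, cessation : annual probabilities by (gender, cohort, age)
    initial_current, initial_former : smoking prevalence by (gender, age) at start_year
    """

    run: RunSpec
    population: pd.Series
    mortality: pd.Series
    life_expectancy: pd.Series
    initiation: pd.Series
    cessation: pd.Series
    initial_current: pd.Series
    initial_former: pd.Series

    def __post_init__(self) -> None:
        names = {
            "population": ("gender", "age", "year"),
            "mortality": ("gender", "age", "year", "status"),
            "life_expectancy": ("gender", "age", "year"),
            "initiation": ("gender", "cohort", "age"),
            "cessation": ("gender", "cohort", "age"),
            "initial_current": ("gender", "age"),
            "initial_former": ("gender", "age"),
        }
        for attr, levels in names.items():
            s = getattr(self, attr)
            if tuple(s.index.names) != levels:
                raise BundleValidationError(
                    f"{attr} index levels {tuple(s.index.names)} != required {levels}"
                )


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def raise_if_errors(self) -> None:
        if self.errors:
            raise BundleValidationError("; ".join(self.errors[:10]))


def _check_range(report: ValidationReport, s: pd.Series, name: str,
                 lo: float = 0.0, hi: float = 1.0) -> None:
    bad = s[(s < lo) | (s > hi) | ~np.isfinite(s)]
    for idx, v in bad.head(20).items():
        report.errors.append(f"{name}{idx} = {v} outside [{lo}, {hi}]")


def _missing_cells(index: pd.MultiIndex, required: Iterable[tuple]) -> list[tuple]:
    have = set(index)
    return [cell for cell in required if cell not in have]


def validate_bundle(bundle: InputBundle) -> ValidationReport:
    """Check every hard invariant (errors) and plausibility rule (warnings).

    Mortality ordering never <= former <= current is a warning, not an error:
    estimated former-smoker rates can cross never-smoker rates through noise.
    """
    rep = ValidationReport()
    run = bundle.run

    # grid completeness over the run window
    required_py = [(g, int(a), int(y)) for g in run.genders for a in run.ages for y in run.years]
    for name, s in (("population", bundle.population),
                    ("life_expectancy", bundle.life_expectancy)):
        miss = _missing_cells(s.index, required_py)
        if miss:
            rep.errors.append(f"{name} missing {len(miss)} cells, first {miss[:3]}")
    req_mort = [(g, a, y, st) for (g, a, y) in required_py for st in STATUSES]
    miss = _missing_cells(bundle.mortality.index, req_mort)
    if miss:
        rep.errors.append(f"mortality missing {len(miss)} cells, first {miss[:3]}")
    # rate coverage for every cohort over the ages the engine visits
    req_rates = [(g, int(b), int(a)) for g in run.genders for b in run.cohorts
                 for a in run.cohort_ages(int(b))]
    for name, s in (("initiation", bundle.initiation), ("cessation", bundle.cessation)):
        miss = _missing_cells(s.index, req_rates)
        if miss:
            rep.errors.append(f"{name} missing {len(miss)} cells, first {miss[:3]}")
    req_init = [(g, int(a)) for g in run.genders for a in run.ages]
    for name, s in (("initial_current", bundle.initial_current),
                    ("initial_former", bundle.initial_former)):
        miss = _missing_cells(s.index, req_init)
        if miss:
            rep.errors.append(f"{name} missing {len(miss)} cells, first {miss[:3]}")

    # value ranges
    pop = bundle.population
    if (pop < 0).any():
        rep.errors.append("population contains negative counts")
    _check_range(rep, bundle.mortality, "mortality")
    _check_range(rep, bundle.initiation, "initiation")
    _check_range(rep, bundle.cessation, "cessation")
    if (bundle.life_expectancy < 0).any():
        rep.errors.append("life_expectancy contains negative values")

    # initiation stops after initiation_max_age
    ages = bundle.initiation.index.get_level_values("age")
    late = bundle.initiation[(ages > run.initiation_max_age) & (bundle.initiation > 0)]
    for idx in late.head(10).index:
        rep.errors.append(
            f"initiation{idx} > 0 but initiation ends at age {run.initiation_max_age}"
        )

    # initial prevalence consistency
    both = bundle.initial_current.add(bundle.initial_former, fill_value=0.0)
    over = both[both > 1.0 + 1e-12]
    for idx, v in over.head(10).items():
        rep.errors.append(f"initial current+former{idx} = {v:.6f} > 1")
    high = both[(both > 0.9) & (both <= 1.0 + 1e-12)]
    for idx, v in high.head(10).items():
        rep.warnings.append(f"initial current+former{idx} = {v:.6f} > 0.9")

    # mortality ordering: never <= former <= current (warn only)
    try:
        wide = bundle.mortality.unstack("status")
        disordered = wide[(wide["never"] > wide["former"] + 1e-15)
                          | (wide["former"] > wide["current"] + 1e-15)]
        for idx in disordered.head(10).index:
            rep.warnings.append(f"mortality ordering never<=former<=current violated at {idx}")
    except KeyError:
        rep.errors.append(f"mortality must cover statuses {STATUSES}")

    # life expectancy non-increasing in age within (gender, year)
    le = bundle.life_expectancy.sort_index()
    for (g, y), grp in le.groupby(level=["gender", "year"], sort=False):
        vals = grp.droplevel(["gender", "year"]).sort_index().to_numpy()
        if np.any(np.diff(vals) > 1e-9):
            rep.errors.append(f"life_expectancy increases with age for ({g}, {y})")
    return rep


# ---------------------------------------------------------------------------
# CSV + config round trip

def _read_csv(directory: Path, key: str) -> pd.DataFrame:
    path = directory / CSV_FILES[key]
    if not path.exists():
        raise BundleLoadError(f"missing input file: {path.name} (in {directory})")
    return pd.read_csv(path)


def read_bundle(directory_path: str | Path) -> InputBundle:
    """Load an input bundle from a directory of CSV files plus ``config.yaml``."""
    directory = Path(directory_path)
    cfg_path = directory / CONFIG_NAME
    if not cfg_path.exists():
        raise BundleLoadError(f"missing input file: {CONFIG_NAME} (in {directory})")
    run, _ = load_config(cfg_path)

    pop = _read_csv(directory, "population").set_index(["gender", "age", "year"])["count"]
    mort = _read_csv(directory, "mortality").set_index(["gender", "age", "year", "status"])["rate"]
    le = _read_csv(directory, "life_expectancy").set_index(["gender", "age", "year"])["le"]
    init = _read_csv(directory, "initiation").set_index(["gender", "cohort", "age"])["rate"]
    cess = _read_csv(directory, "cessation").set_index(["gender", "cohort", "age"])["rate"]
    prev = _read_csv(directory, "initial_prevalence").set_index(["gender", "age"])
    bundle = InputBundle(
        run=run,
        population=pop.rename("count"),
        mortality=mort.rename("rate"),
        life_expectancy=le.rename("le"),
        initiation=init.rename("rate"),
        cessation=cess.rename("rate"),
        initial_current=prev["current"],
        initial_former=prev["former"],
    )
    validate_bundle(bundle).raise_if_errors()
    return bundle


def write_bundle(bundle: InputBundle, directory_path: str | Path,
                 params: NVPParams | None = None) -> list[Path]:
    """Write a bundle (and optionally scenario parameters) to CSV + config.

    ``read_bundle(write_bundle(b))`` reproduces ``b`` to full float precision.
    """
    validate_bundle(bundle).raise_if_errors()
    directory = Path(directory_path)
    directory.mkdir(parents=True, exist_ok=True)
    written = []

    def _dump(key: str, s: pd.Series, value_col: str) -> None:
        path = directory / CSV_FILES[key]
        s.rename(value_col).reset_index().to_csv(path, index=False)
        written.append(path)

    _dump("population", bundle.population, "count")
    _dump("mortality", bundle.mortality, "rate")
    _dump("life_expectancy", bundle.life_expectancy, "le")
    _dump("initiation", bundle.initiation, "rate")
    _dump("cessation", bundle.cessation, "rate")
    prev = pd.DataFrame({"current": bundle.initial_current, "former": bundle.initial_former})
    path = directory / CSV_FILES["initial_prevalence"]
    prev.reset_index().to_csv(path, index=False)
    written.append(path)

    cfg_path = directory / CONFIG_NAME
    save_config(cfg_path, bundle.run, params or NVPParams())
    written.append(cfg_path)
    return written


# ---------------------------------------------------------------------------
# Configuration document (sections: run, nvp_params, switch_schedule)

def _band_label(lo: int, hi: int) -> str:
    return f"{lo}-{hi}" if hi < 200 else f"{lo}+"


def params_to_config(params: NVPParams) -> dict:
    nvp = {
        "risk_nvp": params.risk_nvp,
        "smoking_init_mult": params.smoking_init_mult,
        "nvp_init_mult": params.nvp_init_mult,
        "smoking_cess_mult": params.smoking_cess_mult,
        "nvp_cess_mult": params.nvp_cess_mult,
        "switch_decay": params.switch_decay,
    }
    if params.switch_growth is not None:
        nvp["switch_growth"] = dataclasses.asdict(params.switch_growth)
    schedule = {
        g: {_band_label(lo, hi): float(v) for (lo, hi), v in zip(SWITCH_AGE_BANDS, vs)}
        for g, vs in params.switch_base.items()
    }
    return {"nvp_params": nvp, "switch_schedule": schedule}


def save_config(path: str | Path, run: RunSpec, params: NVPParams) -> None:
    doc = {"run": {
        "start_year": run.start_year, "end_year": run.end_year, "max_age": run.max_age,
        "outcome_age_min": run.outcome_age_min, "outcome_age_max": run.outcome_age_max,
        "initiation_max_age": run.initiation_max_age,
        "switch_reclass_age": run.switch_reclass_age,
        "genders": list(run.genders),
    }}
    doc.update(params_to_config(params))
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_config(path: str | Path) -> tuple[RunSpec, NVPParams]:
    doc = yaml.safe_load(Path(path).read_text())
    run_kw = dict(doc.get("run", {}))
    if "genders" in run_kw:
        run_kw["genders"] = tuple(run_kw["genders"])
    run = RunSpec(**run_kw)
    nvp_kw = dict(doc.get("nvp_params", {}))
    growth = nvp_kw.pop("switch_growth", None)
    if growth is not None:
        growth = SwitchGrowth(**growth)
    schedule = doc.get("switch_schedule", {})
    labels = [_band_label(lo, hi) for lo, hi in SWITCH_AGE_BANDS]
    switch_base = {}
    for g, bands in schedule.items():
        missing = [lab for lab in labels if lab not in bands]
        if missing:
            raise BundleValidationError(
                f"switch_schedule[{g!r}] missing bands {missing}"
            )
        switch_base[g] = tuple(float(bands[lab]) for lab in labels)
    if not switch_base:
        switch_base = _default_switch_base()
    params = NVPParams(switch_base=switch_base, switch_growth=growth, **nvp_kw)
    return run, params
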