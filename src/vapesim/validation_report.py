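"""Model-vs-survey comparison utilities.

Model prevalence levels in the base year generally differ from survey
levels, so validation compares relative reductions over a period, and scales
the model series by the base-year survey/model ratio before checking
coverage of survey confidence intervals. Relative reductions are invariant
to that scaling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd


@dataclass
class SurveySeries:
    """Survey prevalence (%) by (gender, age_band, year), optional 95% CI."""

    label: str
    data: pd.DataFrame  # index (gender, age_band, year); columns value[, lo, hi]

    def __post_init__(self) -> None:
        need = ("gender", "age_band", "year")
        if tuple(self.data.index.names) != need:
            raise ValueError(f"survey index levels must be {need}")
        if "value" not in self.data.columns:
            raise ValueError("survey data needs a 'value' column")
        if {"lo", "hi"} <= set(self.data.columns):
            present = self.data.dropna(subset=["lo", "hi"])
            bad = present[(present["lo"] > present["value"])
                          | (present["value"] > present["hi"])
                          | (present["lo"] < 0) | (present["hi"] > 100)]
            if len(bad):
                raise ValueError(f"malformed CI at {list(bad.index[:3])}")


def read_survey(path: str | Path) -> SurveySeries:
    """Read a generic survey CSV: survey,gender,age_band,year,value[,lo,hi]."""
    df = pd.read_csv(path)
    labels = df["survey"].unique()
    if len(labels) != 1:
        raise ValueError(f"survey file must hold one survey, found {list(labels)}")
    df = df.set_index(["gender", "age_band", "year"]).drop(columns=["survey"])
    return SurveySeries(label=str(labels[0]), data=df)


def _as_series(series: Mapping[int, float] | pd.Series) -> pd.Series:
    return series if isinstance(series, pd.Series) else pd.Series(dict(series))


def relative_reduction(series: Mapping[int, float] | pd.Series,
                       y0: int, y1: int) -> float:
    """Percent change of a prevalence series between two years (negative = drop)."""
    s = _as_series(series)
    for y in (y0, y1):
        if y not in s.index:
            raise KeyError(f"year {y} absent from series")
    if s[y0] == 0:
        raise ZeroDivisionError(f"series value at base year {y0} is zero")
    return (s[y1] - s[y0]) / s[y0] * 100.0


def scale_to_survey(model: Mapping[int, float] | pd.Series,
                    survey: Mapping[int, float] | pd.Series,
                    base_year: int) -> tuple[pd.Series, float]:
    """Scale a model series onto the survey's base-year level.

    Returns (scaled series, factor) with ``factor = survey(base)/model(base)``,
    so ``scaled(base_year)`` equals the survey value exactly.
    """
    m = _as_series(model)
    s = _as_series(survey)
    if base_year not in m.index or base_year not in s.index:
        raise KeyError(f"base year {base_year} missing from model or survey series")
    if m[base_year] == 0:
        raise ZeroDivisionError("model base-year value is zero")
    factor = s[base_year] / m[base_year]
    return m * factor, float(factor)


def ci_coverage(scaled_model: pd.DataFrame | pd.Series, survey: SurveySeries,
                cells: Iterable[tuple]) -> pd.DataFrame:
    """Flag whether scaled model values fall inside survey CIs (closed bounds).

    ``scaled_model`` is indexed like the survey data. Cells lacking a CI are
    reported with ``inside`` left empty and a notice.
    """
    values = scaled_model["value"] if isinstance(scaled_model, pd.DataFrame) else scaled_model
    rows = []
    for cell in cells:
        row = {"cell": cell, "inside": pd.NA, "notice": ""}
        try:
            v = float(values.loc[cell])
            lo = float(survey.data.loc[cell, "lo"])
            hi = float(survey.data.loc[cell, "hi"])
        except KeyError:
            row["notice"] = "missing CI or model value; skipped"
            rows.append(row)
            continue
        if pd.isna(lo) or pd.isna(hi):
            row["notice"] = "missing CI; skipped"
        else:
            row["inside"] = bool(lo <= v <= hi)
            row["value"], row["lo"], row["hi"] = v, lo, hi
        rows.append(row)
    report = pd.DataFrame(rows, columns=["cell", "inside", "notice", "value", "lo", "hi"])
    report.attrs["n_inside"] = int((report["inside"] == True).sum())  # noqa: E712
    report.attrs["n_checked"] = int(report["inside"].notna().sum())
    return report
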