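"""Evaluation of injury criteria against AIS/MAIS records.

Two evaluation routes:

* :func:`evaluate_criteria` — sample Pearson correlation between each
  criterion column and the head-injury MAIS score (treated as numeric 0-6),
  ranked by |r|.
* :func:`risk_report` — map criterion values through literature injury-risk
  curves (logistic or Weibull, supplied as configuration) and tabulate the
  predicted probability beside the recorded AIS, per injury type.

Tables are plain pandas DataFrames: a criteria table has a ``case_id`` column
plus one numeric column per criterion; an injury table has ``case_id``,
``dai_ais``, ``contusion_ais`` (nullable) and ``mais``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, JoinError, UndefinedCorrelationError, ValidationError


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient.

    r = sum((x_i - xbar)(y_i - ybar)) / sqrt(sum((x_i - xbar)^2) * sum((y_i - ybar)^2))

    Raises :class:`UndefinedCorrelationError` for a constant vector rather
    than returning a silent 0 or NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise ValidationError("pearson_r expects 1-D vectors")
    if len(x) != len(y):
        raise ValidationError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise ValidationError("pearson_r needs at least 3 observations")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValidationError("pearson_r input contains missing values")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0.0 or syy == 0.0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    r = float(dx @ dy) / np.sqrt(sxx * syy)
    return float(np.clip(r, -1.0, 1.0))


@dataclass(frozen=True)
class EvaluationReport:
    """Per-criterion Pearson r against MAIS plus the |r| ranking."""

    r: dict[str, float]
    ranking: tuple[str, ...]
    n_cases: int

    def __post_init__(self) -> None:
        for name, val in self.r.items():
            if not -1.0 <= val <= 1.0:
                raise ValidationError(f"r({name}) = {val} outside [-1, 1]")
        by_abs = tuple(sorted(self.r, key=lambda k: abs(self.r[k]), reverse=True))
        if tuple(self.ranking) != by_abs:
            raise ValidationError("ranking inconsistent with |r| values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"criterion": list(self.ranking),
             "r": [self.r[k] for k in self.ranking],
             "rank": np.arange(1, len(self.ranking) + 1)})


def evaluate_criteria(criteria: pd.DataFrame, injuries: pd.DataFrame,
                      method: str = "pearson") -> EvaluationReport:
    """Correlate every criterion column against MAIS over the joined cases.

    ``method`` is "pearson" (the reproduction default; MAIS treated as
    numeric) or "spearman" (rank correlation, offered for sensitivity checks
    only).
    """
    if method not in ("pearson", "spearman"):
        raise ConfigurationError(f"unknown method {method!r}")
    for frame, label in ((criteria, "criteria"), (injuries, "injuries")):
        if "case_id" not in frame.columns:
            raise ValidationError(f"{label} table lacks a case_id column")
        if frame["case_id"].duplicated().any():
            raise ValidationError(f"{label} table has duplicate case ids")
    left = set(criteria["case_id"])
    right = set(injuries["case_id"])
    if left != right:
        raise JoinError(
            f"case-id mismatch: only in criteria {sorted(left - right)}, "
            f"only in injuries {sorted(right - left)}")
    if injuries["mais"].isna().any():
        raise ValidationError("MAIS must be present for every case")
    merged = criteria.merge(injuries[["case_id", "mais"]], on="case_id")
    crit_cols = [c for c in criteria.columns if c != "case_id"]
    mais = merged["mais"].to_numpy(dtype=float)
    r: dict[str, float] = {}
    for col in crit_cols:
        vals = merged[col]
        if vals.isna().any():
            raise ValidationError(f"criterion column {col!r} has missing values")
        x = vals.to_numpy(dtype=float)
        y = mais
        if method == "spearman":
            x = pd.Series(x).rank().to_numpy()
            y = pd.Series(y).rank().to_numpy()
        r[col] = pearson_r(x, y)
    ranking = tuple(sorted(r, key=lambda k: abs(r[k]), reverse=True))
    return EvaluationReport(r=r, ranking=ranking, n_cases=len(merged))


@dataclass(frozen=True)
class RiskCurve:
    """A literature injury-risk curve mapping a criterion value to P(injury).

    form "logistic": p = 1 / (1 + exp(-(intercept + slope * v))), slope >= 0.
    form "weibull":  p = 1 - exp(-((v / scale) ** shape)) for v > 0, else 0;
    scale > 0, shape > 0. Both are monotone non-decreasing with range [0, 1].
    """

    criterion: str
    injury_type: str          # "DAI" or "contusion"
    form: str                 # "logistic" or "weibull"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.injury_type not in ("DAI", "contusion"):
            raise ConfigurationError(f"unknown injury type {self.injury_type!r}")
        if self.form == "logistic":
            missing = {"intercept", "slope"} - set(self.params)
            if missing:
                raise ConfigurationError(f"logistic curve missing {sorted(missing)}")
            if self.params["slope"] < 0:
                raise ConfigurationError("logistic slope must be non-negative")
        elif self.form == "weibull":
            missing = {"scale", "shape"} - set(self.params)
            if missing:
                raise ConfigurationError(f"weibull curve missing {sorted(missing)}")
            if self.params["scale"] <= 0 or self.params["shape"] <= 0:
                raise ConfigurationError("weibull scale and shape must be positive")
        else:
            raise ConfigurationError(f"unknown curve form {self.form!r}")


def risk_probability(curve: RiskCurve, value: float) -> float:
    """Evaluate an injury-risk curve at a criterion value; result in [0, 1]."""
    v = float(value)
    if curve.form == "logistic":
        z = curve.params["intercept"] + curve.params["slope"] * v
        # guard exp overflow for extreme arguments
        if z >= 0:
            p = 1.0 / (1.0 + np.exp(-z))
        else:
            e = np.exp(z)
            p = e / (1.0 + e)
    else:  # weibull
        if v <= 0:
            return 0.0
        p = 1.0 - np.exp(-((v / curve.params["scale"]) ** curve.params["shape"]))
    return float(min(max(p, 0.0), 1.0))


def load_risk_curves(path: str | Path) -> list[RiskCurve]:
    """Load risk-curve definitions from a YAML list of
    {criterion, injury_type, form, params} entries."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ConfigurationError(f"{path}: expected a list of curve entries")
    return [RiskCurve(criterion=e["criterion"], injury_type=e["injury_type"],
                      form=e["form"], params=dict(e.get("params", {})))
            for e in raw]


_AIS_COLUMN = {"DAI": "dai_ais", "contusion": "contusion_ais"}


def risk_report(criteria: pd.DataFrame, injuries: pd.DataFrame,
                curves: Sequence[RiskCurve]) -> pd.DataFrame:
    """Per-case predicted injury probability beside the recorded AIS.

    For each configured curve, cases are restricted to those whose AIS for
    the curve's injury type is recorded (non-missing). Output columns:
    injury_type, criterion, case_id, value, ais, probability.
    """
    if not curves:
        raise ConfigurationError("no risk curves supplied")
    rows = []
    for curve in curves:
        if curve.criterion not in criteria.columns:
            raise ConfigurationError(
                f"no column {curve.criterion!r} in criteria table for "
                f"{curve.injury_type} curve")
        ais_col = _AIS_COLUMN[curve.injury_type]
        # a criteria table may itself carry AIS columns (the packaged
        # sub-study tables do); the injury table is authoritative
        crit_clean = criteria.drop(
            columns=[c for c in _AIS_COLUMN.values() if c in criteria.columns])
        sub = crit_clean.merge(injuries[["case_id", ais_col]], on="case_id")
        sub = sub[sub[ais_col].notna()]
        for _, row in sub.iterrows():
            rows.append({
                "injury_type": curve.injury_type,
                "criterion": curve.criterion,
                "case_id": row["case_id"],
                "value": float(row[curve.criterion]),
                "ais": int(row[ais_col]),
                "probability": risk_probability(curve, row[curve.criterion]),
            })
    return pd.DataFrame(rows)
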