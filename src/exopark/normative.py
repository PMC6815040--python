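"""Normative Z-scoring, laterality indices, and the cumulative score.

Each task parameter is referenced to a healthy-control cohort through an
ordinary-least-squares model ``parameter ~ age + sex + handedness``; the
standardized residual is the parameter's Z-score.  Z-scores are signed raw
residuals - no flipping toward an "abnormality" direction - so direction
interpretation stays with the reporting layer.

The laterality index of a nonnegative bilateral parameter is
``|R - L| / (R + L)`` (0 symmetric, 1 fully unilateral).  The cumulative
score is the root-sum-square of a chosen set of parameter Z-scores, a
global distance from normative performance that can be compared against
summed clinical subscores.  The component set is either selected
data-driven (parameters whose Z-scores shift significantly under
dopamine replacement in responders) or frozen by the caller.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io_clinical import SubjectRecord
from .stats import gated_compare

__all__ = [
    "NormativeModel",
    "LateralityResult",
    "CumulativeScore",
    "fit_normative_model",
    "fit_normative_models",
    "z_score",
    "z_table",
    "laterality_index",
    "select_drt_sensitive",
    "cumulative_score",
    "save_models",
    "load_models",
]

_TERMS = ("intercept", "age", "sex_F", "hand_left")


@dataclass(frozen=True)
class NormativeModel:
    """Control-cohort regression for one parameter plus its residual SD."""

    parameter: str
    coefficients: dict[str, float]  # subset of _TERMS
    residual_sd: float
    n_controls: int
    transform: str = "identity"  # or "log"
    dropped_terms: tuple[str, ...] = ()

    def __post_init__(self):
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")
        if self.transform not in ("identity", "log"):
            raise ValueError(f"unknown transform {self.transform!r}")

    def predict(self, age: float, sex: str, handedness: str) -> float:
        c = self.coefficients
        return (
            c.get("intercept", 0.0)
            + c.get("age", 0.0) * age
            + c.get("sex_F", 0.0) * (sex == "F")
            + c.get("hand_left", 0.0) * (handedness == "left")
        )


@dataclass(frozen=True)
class LateralityResult:
    parameter: str
    li: float  # |R-L|/(R+L); NaN flags an undefined (R+L == 0) index
    arms: tuple[float, float]  # (right, left)


@dataclass(frozen=True)
class CumulativeScore:
    value: float
    parameters: tuple[str, ...]
    z: tuple[float, ...]


def _design(subjects: Sequence[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "intercept": 1.0,
            "age": [s.age for s in subjects],
            "sex_F": [1.0 * (s.sex == "F") for s in subjects],
            "hand_left": [1.0 * (s.handedness == "left") for s in subjects],
        },
        index=[s.subject_id for s in subjects],
    )


def fit_normative_model(
    parameter: str,
    values: Sequence[float],
    subjects: Sequence[SubjectRecord],
    transform: str = "identity",
    min_controls: int = 20,
) -> NormativeModel:
    """OLS fit of one parameter on age, sex and handedness over controls.

    Degenerate covariate columns (e.g. a single-sex cohort) are dropped
    with a warning; a zero-variance response is an error since no Z-score
    is defined.  The residual SD uses an ``n - p`` denominator with ``p``
    the number of retained terms (4 when nothing is dropped).
    """
    y = np.asarray(values, dtype=float)
    if len(subjects) != y.size:
        raise ValueError("values and subjects length mismatch")
    if len(subjects) < min_controls:
        raise ValueError(
            f"{parameter}: need >= {min_controls} controls, got {len(subjects)}"
        )
    if np.ptp(y) == 0:
        raise ValueError(f"{parameter}: zero-variance response, residual SD undefined")
    if transform == "log":
        if np.any(y <= 0):
            raise ValueError(f"{parameter}: log transform requires positive values")
        y = np.log(y)
    X = _design(subjects)
    dropped = [c for c in X.columns if c != "intercept" and X[c].nunique() <= 1]
    if dropped:
        warnings.warn(f"{parameter}: dropping degenerate term(s) {dropped}")
        X = X.drop(columns=dropped)
    fit = sm.OLS(y, X).fit()
    dof = y.size - X.shape[1]
    resid_sd = float(np.sqrt(np.sum(fit.resid**2) / dof)) if dof > 0 else 0.0
    if resid_sd <= 0 or not np.isfinite(resid_sd):
        raise ValueError(f"{parameter}: zero residual variance, Z-scores undefined")
    return NormativeModel(
        parameter=parameter,
        coefficients={c: float(v) for c, v in fit.params.items()},
        residual_sd=resid_sd,
        n_controls=y.size,
        transform=transform,
        dropped_terms=tuple(dropped),
    )


def fit_normative_models(
    wide: pd.DataFrame,
    subjects: Sequence[SubjectRecord],
    control_session: str = "baseline",
    transforms: Mapping[str, str] | None = None,
    min_controls: int = 20,
) -> dict[str, NormativeModel]:
    """Fit a model per column of the wide parameter table, controls only."""
    transforms = transforms or {}
    by_id = {s.subject_id: s for s in subjects}
    ctrl = wide.xs(control_session, level="session")
    ctrl_subjects = [by_id[sid] for sid in ctrl.index]
    models = {}
    for col in ctrl.columns:
        y = ctrl[col]
        ok = y.notna()
        models[col] = fit_normative_model(
            col,
            y[ok].to_numpy(),
            [s for s, keep in zip(ctrl_subjects, ok) if keep],
            transform=transforms.get(col, "identity"),
            min_controls=min_controls,
        )
    return models


def z_score(
    model: NormativeModel, value: float, age: float, sex: str, handedness: str
) -> float:
    """Standardized residual of ``value`` under the normative model."""
    v = math.log(value) if model.transform == "log" else value
    return (v - model.predict(age, sex, handedness)) / model.residual_sd


def z_table(
    wide: pd.DataFrame,
    models: Mapping[str, NormativeModel],
    subjects: Sequence[SubjectRecord],
) -> pd.DataFrame:
    """Z-score every (subject, session) row of the wide parameter table."""
    by_id = {s.subject_id: s for s in subjects}
    out = pd.DataFrame(index=wide.index, columns=list(models), dtype=float)
    for (sid, _session), row in wide.iterrows():
        s = by_id[sid]
        for col, model in models.items():
            v = row.get(col, math.nan)
            out.loc[(sid, _session), col] = (
                z_score(model, v, s.age, s.sex, s.handedness)
                if np.isfinite(v)
                else math.nan
            )
    return out


def laterality_index(right: float, left: float, parameter: str = "") -> LateralityResult:
    """``|R - L| / (R + L)`` for a nonnegative bilateral parameter."""
    if right < 0 or left < 0:
        raise ValueError("laterality index requires nonnegative parameters")
    total = right + left
    li = math.nan if total == 0 else abs(right - left) / total
    if total == 0:
        warnings.warn(f"laterality index undefined for {parameter or 'parameter'}: R+L=0")
    return LateralityResult(parameter=parameter, li=li, arms=(right, left))


def select_drt_sensitive(
    z_off: pd.DataFrame,
    z_on: pd.DataFrame,
    alpha: float = 0.05,
    gate_alpha: float = 0.05,
) -> list[str]:
    """Parameters whose responder Z-scores change significantly under DRT.

    ``z_off``/``z_on`` are aligned (same responder subjects, same columns)
    Z-score tables.  Each parameter is tested with a normality-gated paired
    comparison; parameters with p < ``alpha`` are returned in column order.
    """
    if not z_off.index.equals(z_on.index) or list(z_off.columns) != list(z_on.columns):
        raise ValueError("OFF and ON tables must be aligned")
    if len(z_off) < 5:
        raise ValueError("refusing selection with fewer than 5 responder pairs")
    selected = []
    for col in z_off.columns:
        x = z_off[col].to_numpy(dtype=float)
        y = z_on[col].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 5:
            continue
        res = gated_compare(x[ok], y[ok], paired=True, gate_alpha=gate_alpha)
        if res.p < alpha:
            selected.append(col)
    return selected


def cumulative_score(z: Mapping[str, float] | Sequence[float]) -> CumulativeScore:
    """Root-sum-square of component Z-scores.

    Missing (NaN) components are an error naming the offending parameters:
    a cumulative distance over a silently shrunken component set would not
    be comparable across subjects.
    """
    if isinstance(z, Mapping):
        names = tuple(z.keys())
        vec = np.asarray(list(z.values()), dtype=float)
    else:
        vec = np.asarray(list(z), dtype=float)
        names = tuple(f"z{i}" for i in range(vec.size))
    bad = [n for n, v in zip(names, vec) if not np.isfinite(v)]
    if bad:
        raise ValueError(f"missing z-score component(s): {bad}")
    return CumulativeScore(
        value=float(np.sqrt(np.sum(vec**2))), parameters=names, z=tuple(map(float, vec))
    )


def save_models(models: Mapping[str, NormativeModel], path: str | Path) -> None:
    payload = {
        name: {
            "parameter": m.parameter,
            "coefficients": m.coefficients,
            "residual_sd": m.residual_sd,
            "n_controls": m.n_controls,
            "transform": m.transform,
            "dropped_terms": list(m.dropped_terms),
        }
        for name, m in models.items()
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1), encoding="utf-8")


def load_models(path: str | Path) -> dict[str, NormativeModel]:
    raw = json.loads(Path(path).read_text(encoding="utf-8"))
    return {
        name: NormativeModel(
            parameter=d["parameter"],
            coefficients=d["coefficients"],
            residual_sd=d["residual_sd"],
            n_controls=d["n_controls"],
            transform=d.get("transform", "identity"),
            dropped_terms=tuple(d.get("dropped_terms", ())),
        )
        for name, d in raw.items()
    }
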