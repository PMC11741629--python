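"""Individual survival curves and the Kaplan-Meier population baseline.

A CASE survival curve is simply the vector of calibrated per-period
probabilities ``S_i(tau) = p_hat_{i,tau}``, ``tau = 1..P``.  Curves are NOT
forced monotone: allowing local increases is deliberate, since real cohorts
can show non-monotone risk (e.g. a late survival bump), which population
product-limit curves cannot express.  Between integer periods the curve is
evaluated by linear interpolation with the convention ``S(0) = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .augment import (PERIOD_COL, SOURCE_COL, SurvivalDataset,
                      expand_dataset_for_prediction, expand_for_prediction)

__all__ = ["SurvivalCurve", "interpolate", "predict_curve", "predict_curves",
           "KaplanMeierEstimate", "km_baseline", "curves_to_frame", "curves_from_frame"]


@dataclass(frozen=True)
class SurvivalCurve:
    """Per-subject calibrated survival probabilities over periods 1..P."""

    subject_id: str
    probabilities: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 1 or len(p) == 0:
            raise ValueError("probabilities must be a non-empty 1-D vector")
        if ((p < 0) | (p > 1)).any():
            raise ValueError("survival probabilities must lie in [0, 1]")
        object.__setattr__(self, "probabilities", p)

    @property
    def horizon(self) -> int:
        return len(self.probabilities)

    def __call__(self, t):
        return interpolate(self, t)


def interpolate(curve: SurvivalCurve, t):
    """Survival probability at real time ``t`` in [0, P].

    Piecewise-linear between the knots (0, 1), (1, p_1), ..., (P, p_P);
    exact at integer times.  Times outside [0, P] are a range error —
    extrapolation beyond the study horizon is undefined.
    """
    t_arr = np.asarray(t, dtype=float)
    P = curve.horizon
    if ((t_arr < 0) | (t_arr > P)).any():
        raise ValueError(f"time must lie in [0, {P}]")
    knots_t = np.arange(P + 1)
    knots_p = np.concatenate(([1.0], curve.probabilities))
    out = np.interp(t_arr, knots_t, knots_p)
    return float(out) if t_arr.ndim == 0 else out


def predict_curve(model, cal, record, P: int, feature_names=None,
                  subject_id: str = "test") -> SurvivalCurve:
    """Score one record at every period and calibrate into a survival curve.

    ``model`` follows the classifier-adapter contract (``score(X)`` returning
    raw survive-class probabilities); ``cal`` is a fitted
    :class:`~casesurv.calibrate.CalibrationMap`, or None for raw scores.
    """
    from .calibrate import apply_abbq

    expanded = expand_for_prediction(record, P, source_id=subject_id)
    cols = (list(feature_names) if feature_names is not None
            else [c for c in expanded.columns if c not in (SOURCE_COL, PERIOD_COL)])
    raw = model.score(expanded[cols + [PERIOD_COL]])
    probs = apply_abbq(cal, raw) if cal is not None else np.asarray(raw, dtype=float)
    return SurvivalCurve(subject_id, probs)


def predict_curves(model, cal, dataset: SurvivalDataset, P: int) -> dict[str, SurvivalCurve]:
    """Vectorised curve prediction for every subject in a dataset."""
    from .calibrate import apply_abbq

    expanded = expand_dataset_for_prediction(dataset, P)
    raw = np.asarray(model.score(expanded[dataset.feature_names + [PERIOD_COL]]))
    probs = apply_abbq(cal, raw) if cal is not None else raw
    probs = probs.reshape(dataset.n, P)
    return {sid: SurvivalCurve(sid, probs[i]) for i, sid in enumerate(dataset.ids)}


# ---------------------------------------------------------------------------
# Kaplan-Meier population baseline


@dataclass(frozen=True)
class KaplanMeierEstimate:
    """Product-limit estimate: a right-continuous step function.

    ``event_times`` are the distinct observed event times in ascending
    order and ``survival`` the estimate just after each of them.
    """

    event_times: np.ndarray
    survival: np.ndarray

    def at(self, t):
        """S_hat(t): 1 before the first event time, stepping down at events."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.event_times, t_arr, side="right")
        vals = np.concatenate(([1.0], self.survival))[idx]
        return float(vals[0]) if np.ndim(t) == 0 else vals

    def as_curve(self, P: int, subject_id: str = "population") -> SurvivalCurve:
        return SurvivalCurve(subject_id, self.at(np.arange(1, P + 1)))


def km_baseline(dataset: SurvivalDataset) -> KaplanMeierEstimate:
    """Kaplan-Meier estimator over the whole cohort.

    S_hat(t) = prod_{t_j <= t} (1 - d_j / n_j) over distinct event times
    t_j, with d_j events at t_j and n_j subjects still at risk (censored
    subjects leave the risk set after their censoring time).
    """
    if dataset.n == 0:
        raise ValueError("empty dataset")
    times, events = dataset.time, dataset.event
    ev_times = np.unique(times[events == 1])
    surv = np.empty(len(ev_times))
    s = 1.0
    for j, tj in enumerate(ev_times):
        n_at_risk = int((times >= tj).sum())
        d = int(((times == tj) & (events == 1)).sum())
        s *= 1.0 - d / n_at_risk
        surv[j] = s
    return KaplanMeierEstimate(ev_times, surv)


# ---------------------------------------------------------------------------
# long-format CSV round trip


def curves_to_frame(curves: Mapping[str, SurvivalCurve] | Iterable[SurvivalCurve]) -> pd.DataFrame:
    if isinstance(curves, Mapping):
        curves = curves.values()
    rows = [(c.subject_id, tau, p)
            for c in curves
            for tau, p in enumerate(c.probabilities, start=1)]
    return pd.DataFrame(rows, columns=["subject_id", "period", "probability"])


def curves_from_frame(frame: pd.DataFrame) -> dict[str, SurvivalCurve]:
    out = {}
    for sid, grp in frame.groupby("subject_id", sort=False):
        grp = grp.sort_values("period")
        if not np.array_equal(grp["period"].to_numpy(), np.arange(1, len(grp) + 1)):
            raise ValueError(f"subject {sid!r}: periods must be contiguous from 1")
        out[str(sid)] = SurvivalCurve(str(sid), grp["probability"].to_numpy())
    return out
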