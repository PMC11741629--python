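"""Survival-curve evaluation metrics: iAUSC, mAUSC, ECE and wrappers.

The individual area-under-the-survival-curve metric compares a predicted
curve against the ideal step function of an observed event — survival
probability 1 up to the event time ``T_i`` and 0 after — using an absolute
deviation weighted to emphasise times near the event:

    E_i = int_0^P |S_hat(t) - step_i(t)| w(t) dt / int_0^P w(t) dt,
    w(t) = exp(-|t - min(T_i, P)| / P).

``E_i`` is a weighted error in [0, 1]; the reported iAUSC score is
``1 - E_i`` so that higher is better, matching the orientation in which
model comparisons are read (the raw error is exposed alongside).  mAUSC is
the mean score over event subjects only; censored subjects have no
observed event time to compare against.

The continuous idealisation of the step function is a decreasing sigmoid
through 0.5 at ``T_i`` whose steepness controls how sharply survival and
non-survival separate.

Comparator metrics (C-index, integrated Brier score, time-dependent AUC)
are thin wrappers over scikit-survival and are used only by the evaluation
harness.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .augment import SurvivalDataset
from .curves import SurvivalCurve

__all__ = ["ideal_curve", "weight", "iausc", "iausc_error", "mausc", "ece",
           "concordance_index", "integrated_brier", "time_dependent_auc"]


def ideal_curve(event_time: float, steepness: float):
    """Ideal continuous survival curve: a decreasing sigmoid.

    Returns a callable ``S(t) = 1 / (1 + exp(steepness * (t - event_time)))``
    that passes through 0.5 exactly at the event time and approaches the
    survival step function as steepness grows.
    """
    if steepness <= 0:
        raise ValueError("steepness must be positive")

    def S(t):
        return expit(-steepness * (np.asarray(t, dtype=float) - event_time))

    return S


def weight(t, event_time: float, P: int):
    """Exponential time weight exp(-|t - T_i| / P), with T_i capped at P."""
    if P < 1:
        raise ValueError("P must be >= 1")
    T = min(float(event_time), float(P))
    return np.exp(-np.abs(np.asarray(t, dtype=float) - T) / P)


def _curve_values(curve, grid: np.ndarray, P: int) -> np.ndarray:
    if isinstance(curve, SurvivalCurve):
        knots_t = np.arange(curve.horizon + 1)
        knots_p = np.concatenate(([1.0], curve.probabilities))
        return np.interp(grid, knots_t, knots_p)
    return np.asarray(curve(grid), dtype=float)


def iausc_error(curve, event_time: float, P: int, grid_step: float = 0.01) -> float:
    """Raw weighted mean absolute deviation E_i in [0, 1].

    ``curve`` is a :class:`SurvivalCurve` (linearly interpolated) or any
    callable S(t).  Trapezoidal quadrature on a uniform grid of spacing
    ``grid_step`` periods; the step function is closed at the event time
    (survived through t = T_i), consistent with the augmentation labels.
    """
    if event_time is None or not np.isfinite(event_time):
        raise ValueError("iAUSC requires an observed event time")
    P = int(P)
    n_steps = max(int(round(P / grid_step)), 1)
    grid = np.linspace(0.0, P, n_steps + 1)
    s_hat = _curve_values(curve, grid, P)
    step = (grid <= event_time).astype(float)
    w = weight(grid, event_time, P)
    num = np.trapezoid(np.abs(s_hat - step) * w, grid)
    den = np.trapezoid(w, grid)
    return float(num / den)


def iausc(curve, event_time: float, P: int, grid_step: float = 0.01) -> float:
    """iAUSC score = 1 - weighted error; 1 is a perfect curve, 0.5 is an
    uninformative constant-half predictor."""
    return 1.0 - iausc_error(curve, event_time, P, grid_step)


def mausc(curves, dataset: SurvivalDataset, P: int, grid_step: float = 0.01) -> float:
    """Mean iAUSC over event subjects.

    ``curves`` maps subject id to a curve; censored subjects are skipped.
    """
    ev = dataset.event == 1
    if not ev.any():
        raise ValueError("mAUSC undefined: no event records")
    scores = [iausc(curves[sid], t, P, grid_step)
              for sid, t in zip(dataset.ids[ev], dataset.time[ev])]
    return float(np.mean(scores))


def ece(probabilities, outcomes, bins: int = 10) -> float:
    """Expected calibration error over equal-width probability bins.

    sum_b (n_b / n) |mean predicted_b - observed rate_b|.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if p.size == 0:
        raise ValueError("empty input")
    edges = np.linspace(0.0, 1.0, bins + 1)
    idx = np.clip(np.digitize(p, edges[1:-1]), 0, bins - 1)
    total = 0.0
    for b in range(bins):
        mask = idx == b
        if mask.any():
            total += mask.mean() * abs(p[mask].mean() - y[mask].mean())
    return float(total)


# ---------------------------------------------------------------------------
# Comparator metrics, delegated to scikit-survival.


def _structured(event: np.ndarray, time: np.ndarray):
    from sksurv.util import Surv
    return Surv.from_arrays(event=event.astype(bool), time=time)


def concordance_index(dataset: SurvivalDataset, risk_scores) -> float:
    """Harrell's C-index of risk scores (higher risk = shorter survival)."""
    from sksurv.metrics import concordance_index_censored
    return float(concordance_index_censored(
        dataset.event.astype(bool), dataset.time, np.asarray(risk_scores))[0])


def integrated_brier(train: SurvivalDataset, test: SurvivalDataset,
                     surv_probs: np.ndarray, times: np.ndarray) -> float:
    """Integrated Brier score of per-subject survival probabilities
    evaluated on a time grid (rows: test subjects, columns: times)."""
    from sksurv.metrics import integrated_brier_score
    return float(integrated_brier_score(
        _structured(train.event, train.time), _structured(test.event, test.time),
        np.asarray(surv_probs), np.asarray(times)))


def time_dependent_auc(train: SurvivalDataset, test: SurvivalDataset,
                       risk_over_time: np.ndarray, times: np.ndarray) -> float:
    """Mean cumulative/dynamic AUC over the time grid."""
    from sksurv.metrics import cumulative_dynamic_auc
    _, mean_auc = cumulative_dynamic_auc(
        _structured(train.event, train.time), _structured(test.event, test.time),
        np.asarray(risk_over_time), np.asarray(times))
    return float(mean_auc)
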