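"""Adjusted Bayesian binning-in-quantiles (ABBQ) score calibration.

Raw classifier scores are sorted and split into ``M`` quantile bins of
(nearly) equal occupancy.  Each bin stores its empirical survival rate
``p_emp = n_survive / n`` and its observed score range.  A raw score ``s``
falling in bin ``m`` maps to

    p_hat = p_emp_m + (1/M) * (s - min_m) / (max_m - min_m)

i.e. the bin's empirical rate plus an intra-bin variability term that
preserves score ordering within the bin.  The additive term can push the
result above 1, so outputs are clipped to [0, 1]; an optional centered mode
subtracts 0.5/M so the intra-bin term has zero mean (off by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["CalibrationMap", "fit_abbq", "apply_abbq", "tune_bin_count"]


@dataclass(frozen=True)
class CalibrationMap:
    """Fitted ABBQ bins.

    Arrays are ordered by ascending score.  ``score_min``/``score_max`` are
    the observed extremes inside each bin (they double as assignment edges
    at prediction time); out-of-range scores clamp to the first/last bin.
    """

    n_bins: int
    score_min: np.ndarray
    score_max: np.ndarray
    p_emp: np.ndarray
    bin_n: np.ndarray
    bin_n_survive: np.ndarray
    centered: bool = False

    def __post_init__(self):
        for name in ("score_min", "score_max", "p_emp", "bin_n", "bin_n_survive"):
            arr = np.asarray(getattr(self, name))
            if len(arr) != self.n_bins:
                raise ValueError(f"{name} must have one entry per bin")
            object.__setattr__(self, name, arr)

    def assign(self, scores: np.ndarray) -> np.ndarray:
        """Bin index for each score (first bin whose max covers it)."""
        return np.clip(
            np.searchsorted(self.score_max, scores, side="left"), 0, self.n_bins - 1
        )

    # -- serialization ---------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "n_bins": int(self.n_bins),
            "score_min": self.score_min.tolist(),
            "score_max": self.score_max.tolist(),
            "p_emp": self.p_emp.tolist(),
            "bin_n": self.bin_n.tolist(),
            "bin_n_survive": self.bin_n_survive.tolist(),
            "centered": bool(self.centered),
        })

    @classmethod
    def from_json(cls, text: str) -> "CalibrationMap":
        d = json.loads(text)
        return cls(d["n_bins"], d["score_min"], d["score_max"], d["p_emp"],
                   d["bin_n"], d["bin_n_survive"], d.get("centered", False))


def fit_abbq(scores, labels, n_bins: int, centered: bool = False) -> CalibrationMap:
    """Fit ABBQ quantile bins on (score, survived-label) pairs.

    Scores are stably sorted and dealt into ``n_bins`` contiguous bins whose
    sizes differ by at most one.  Ties in score are kept in sort order, so
    bins at a tie boundary may share a score value; this only widens the
    degenerate-range handling in :func:`apply_abbq`.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.ndim != 1 or scores.shape != labels.shape:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    n_bins = int(n_bins)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if len(scores) < n_bins:
        raise ValueError(
            f"{len(scores)} observations cannot fill {n_bins} bins; use a smaller M"
        )
    order = np.argsort(scores, kind="stable")
    chunks = np.array_split(order, n_bins)
    smin = np.array([scores[c].min() for c in chunks])
    smax = np.array([scores[c].max() for c in chunks])
    n = np.array([len(c) for c in chunks])
    n_surv = np.array([int(labels[c].sum()) for c in chunks])
    return CalibrationMap(n_bins, smin, smax, n_surv / n, n, n_surv, centered)


def apply_abbq(cal: CalibrationMap, scores) -> np.ndarray | float:
    """Map raw scores to calibrated survival probabilities in [0, 1].

    A degenerate bin (zero score range) uses 0.5 as the normalized intra-bin
    position.  Scores outside the fitted range fall into the first/last bin
    with the position clipped to [0, 1].
    """
    arr = np.asarray(scores, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    m = cal.assign(arr)
    lo, hi = cal.score_min[m], cal.score_max[m]
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        pos = np.where(span > 0, (arr - lo) / np.where(span > 0, span, 1.0), 0.5)
    pos = np.clip(pos, 0.0, 1.0)
    out = cal.p_emp[m] + pos / cal.n_bins
    if cal.centered:
        out = out - 0.5 / cal.n_bins
    out = np.clip(out, 0.0, 1.0)
    return float(out[0]) if scalar else out


def tune_bin_count(scores_train, labels_train, scores_val, labels_val,
                   candidates, centered: bool = False) -> int:
    """Pick the bin count minimizing expected calibration error on a
    held-out validation split; ties go to the smaller M.

    Exhaustive search over the candidate grid (typically a handful of values
    between 5 and 100) — deterministic, and equivalent in result space to a
    black-box optimizer over the same grid.
    """
    from .metrics import ece

    candidates = sorted(int(m) for m in candidates)
    if not candidates:
        raise ValueError("empty candidate set")
    best_m, best_err = None, np.inf
    for m in candidates:
        cal = fit_abbq(scores_train, labels_train, m, centered=centered)
        err = ece(apply_abbq(cal, scores_val), labels_val)
        if err < best_err:
            best_m, best_err = m, err
    return best_m
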