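"""Person-period augmentation: the transformation at the heart of CASE.

A right-censored survival dataset ``D = {(x_i, t_i, delta_i)}`` is rewritten
as a binary classification problem by replicating each subject once per
discrete period ``tau = 1..P``.  A subject observed (event or censoring) at
time ``t`` has verifiably survived ``floor(t)`` whole periods, so rows with
``tau <= floor(t)`` are labelled survived (``y = 1``).  An event record is
additionally replicated with ``y = 0`` for every later period up to the
horizon ``P``; a censored record contributes no rows beyond its censoring
time, because nothing is observed there.

This construction converts the heavy class imbalance of long-horizon
survival classification (few long survivors) into a much better balanced
person-period problem, and lets any probabilistic classifier stand in for a
survival model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalDataset",
    "AugmentedDataset",
    "ValidationError",
    "floor_periods",
    "augment",
    "class_ratio",
    "expand_for_prediction",
    "attach_survival_features",
    "ID_COL",
    "TIME_COL",
    "EVENT_COL",
    "SOURCE_COL",
    "PERIOD_COL",
    "LABEL_COL",
]

# Canonical column names for tabular I/O.
ID_COL = "id"
TIME_COL = "time"
EVENT_COL = "event"
SOURCE_COL = "source_id"
PERIOD_COL = "period"
LABEL_COL = "label"


class ValidationError(ValueError):
    """Raised when input data violate the survival-dataset contract."""


def floor_periods(t: np.ndarray | float) -> np.ndarray | int:
    """Number of whole periods verifiably survived by time ``t``.

    A subject censored at 6.4 years has completed 6 periods; fractional
    observation time never counts as a survived period.
    """
    out = np.floor(np.asarray(t)).astype(int)
    return out if out.ndim else int(out)


@dataclass(frozen=True)
class SurvivalDataset:
    """One row per subject: identifier, observed time, event flag, covariates.

    ``time`` is in period units (e.g. years) and may be fractional; ``event``
    is 1 when the event was observed at ``time`` and 0 when the record is
    censored there.  Feature values are held as a DataFrame aligned with
    ``ids``; all feature handling downstream goes through the column names.
    """

    ids: np.ndarray
    time: np.ndarray
    event: np.ndarray
    features: pd.DataFrame

    def __post_init__(self) -> None:
        ids = np.asarray(self.ids, dtype=str)
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event)
        if not (len(ids) == len(time) == len(event) == len(self.features)):
            raise ValidationError("ids, time, event and features must have equal length")
        bad_t = np.flatnonzero(~(time >= 0))
        if bad_t.size:
            raise ValidationError(
                f"negative or non-finite time for subject {ids[bad_t[0]]!r}"
            )
        if not np.isin(event, (0, 1)).all():
            bad = np.flatnonzero(~np.isin(event, (0, 1)))[0]
            raise ValidationError(
                f"event indicator must be 0 or 1; subject {ids[bad]!r} has {event[bad]!r}"
            )
        if len(np.unique(ids)) != len(ids):
            raise ValidationError("subject ids must be unique")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event.astype(int))
        feats = self.features.reset_index(drop=True)
        object.__setattr__(self, "features", feats)

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    @property
    def floor_time(self) -> np.ndarray:
        return floor_periods(self.time)

    def subset(self, mask: np.ndarray) -> "SurvivalDataset":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return SurvivalDataset(
            self.ids[idx], self.time[idx], self.event[idx],
            self.features.iloc[idx].reset_index(drop=True),
        )

    # -- tabular I/O -----------------------------------------------------
    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SurvivalDataset":
        for col in (ID_COL, TIME_COL, EVENT_COL):
            if col not in frame.columns:
                raise ValidationError(f"missing mandatory column {col!r}")
        feats = frame.drop(columns=[ID_COL, TIME_COL, EVENT_COL])
        return cls(frame[ID_COL].to_numpy(dtype=str),
                   frame[TIME_COL].to_numpy(dtype=float),
                   frame[EVENT_COL].to_numpy(),
                   feats)

    @classmethod
    def from_csv(cls, path) -> "SurvivalDataset":
        return cls.from_frame(pd.read_csv(path))

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({ID_COL: self.ids, TIME_COL: self.time, EVENT_COL: self.event})
        return pd.concat([out, self.features], axis=1)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class AugmentedDataset:
    """The person-period dataset: ``source_id, period, label, <features>``.

    Row order is stable: source-record order, then period ascending, so any
    derived artifact (fold assignments, scores) is reproducible.
    """

    frame: pd.DataFrame
    horizon: int
    feature_names: Sequence[str] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    @property
    def source_ids(self) -> np.ndarray:
        return self.frame[SOURCE_COL].to_numpy()

    @property
    def periods(self) -> np.ndarray:
        return self.frame[PERIOD_COL].to_numpy()

    @property
    def labels(self) -> np.ndarray:
        return self.frame[LABEL_COL].to_numpy()

    @property
    def X(self) -> pd.DataFrame:
        """Model matrix: covariates followed by the period column."""
        return self.frame[list(self.feature_names) + [PERIOD_COL]]

    @property
    def y(self) -> np.ndarray:
        return self.labels

    def to_csv(self, path) -> None:
        cols = [SOURCE_COL, PERIOD_COL, LABEL_COL] + list(self.feature_names)
        self.frame[cols].to_csv(path, index=False)


def _check_horizon(P: int) -> int:
    P = int(P)
    if P < 1:
        raise ValidationError(f"horizon P must be >= 1, got {P}")
    return P


def augment(dataset: SurvivalDataset, P: int) -> AugmentedDataset:
    """Replicate each record into person-period rows up to horizon ``P``.

    Event records (``delta = 1``) contribute exactly ``P`` rows with
    ``y = 1`` for ``tau <= floor(t)`` and ``y = 0`` after.  Censored records
    contribute ``min(P, floor(t))`` rows, all ``y = 1``; a record censored
    before completing one period contributes nothing.
    """
    P = _check_horizon(P)
    t_floor = dataset.floor_time
    reps = np.where(dataset.event == 1, P, np.minimum(P, t_floor))
    total = int(reps.sum())
    src = np.repeat(np.arange(dataset.n), reps)
    # period index within each block: 1..reps[i]
    starts = np.cumsum(reps) - reps
    periods = np.arange(total) - np.repeat(starts, reps) + 1
    labels = (periods <= np.repeat(t_floor, reps)).astype(int)

    frame = dataset.features.iloc[src].reset_index(drop=True)
    frame.insert(0, SOURCE_COL, dataset.ids[src])
    frame.insert(1, PERIOD_COL, periods.astype(int))
    frame.insert(2, LABEL_COL, labels)
    return AugmentedDataset(frame, P, dataset.feature_names)


def class_ratio(dataset: SurvivalDataset, P: int) -> float:
    """Fraction of survived (positive) rows in the augmented dataset.

    Closed form: every record contributes ``min(floor(t), P)`` positive rows,
    while only event records contribute negatives, so

        ratio = sum_i min(floor(t_i), P) / (|E|*P + sum_{censored} min(floor(t_i), P)).

    Equals the empirical positive fraction of :func:`augment` by construction.
    """
    P = _check_horizon(P)
    t_floor = dataset.floor_time
    positives = np.minimum(t_floor, P)
    denom = int(np.where(dataset.event == 1, P, positives).sum())
    if denom == 0:
        raise ValidationError("augmented dataset is empty; class ratio undefined")
    return float(positives.sum() / denom)


def expand_for_prediction(record: Mapping | pd.Series | pd.DataFrame,
                          P: int,
                          source_id: str = "test") -> pd.DataFrame:
    """Replicate one unlabeled record across all periods ``1..P``.

    At prediction time the future is unknown, so the record is propagated
    through every period; the classifier scored on these rows yields the
    subject's survival profile.  Accepts a Series/mapping of feature values
    (one subject) or a one-row DataFrame.
    """
    P = _check_horizon(P)
    if isinstance(record, pd.DataFrame):
        if len(record) != 1:
            raise ValidationError("expand_for_prediction expects a single record")
        row = record.iloc[0]
    else:
        row = pd.Series(dict(record)) if not isinstance(record, pd.Series) else record
    frame = pd.DataFrame([row.to_dict()] * P)
    frame.insert(0, SOURCE_COL, source_id)
    frame.insert(1, PERIOD_COL, np.arange(1, P + 1))
    return frame


def expand_dataset_for_prediction(dataset: SurvivalDataset, P: int) -> pd.DataFrame:
    """Vectorised :func:`expand_for_prediction` over a whole dataset."""
    P = _check_horizon(P)
    src = np.repeat(np.arange(dataset.n), P)
    frame = dataset.features.iloc[src].reset_index(drop=True)
    frame.insert(0, SOURCE_COL, dataset.ids[src])
    frame.insert(1, PERIOD_COL, np.tile(np.arange(1, P + 1), dataset.n))
    return frame


def survival_feature_columns(P: int) -> list[str]:
    return [f"prob_{tau}" for tau in range(1, P + 1)]


def attach_survival_features(dataset: SurvivalDataset, curves) -> pd.DataFrame:
    """De-augmentation: original features joined with the P per-period
    survival probabilities (``D_survival``), one row per subject.

    ``curves`` maps subject id -> :class:`casesurv.curves.SurvivalCurve`
    (or any object with a ``probabilities`` vector).  Subject order of the
    dataset is preserved; a missing or wrong-length curve is an error.
    """
    if not isinstance(curves, Mapping):
        curves = {c.subject_id: c for c in curves}
    P = None
    rows = []
    for sid in dataset.ids:
        if sid not in curves:
            raise ValidationError(f"no survival curve for subject {sid!r}")
        probs = np.asarray(curves[sid].probabilities, dtype=float)
        if P is None:
            P = len(probs)
        elif len(probs) != P:
            raise ValidationError(
                f"curve for subject {sid!r} has length {len(probs)}, expected {P}"
            )
        rows.append(probs)
    mat = np.asarray(rows) if rows else np.empty((0, 0))
    prob_frame = pd.DataFrame(mat, columns=survival_feature_columns(P or 0))
    out = pd.concat([dataset.features.reset_index(drop=True), prob_frame], axis=1)
    out.index = pd.Index(dataset.ids, name=ID_COL)
    return out
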