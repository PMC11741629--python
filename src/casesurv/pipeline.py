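"""End-to-end orchestration of the CASE workflow.

Stages, in order: person-period augmentation -> temporal-stratified
cross-validated classifier scores -> ABBQ calibration (bin count tuned on a
held-out fold) -> individual survival curves -> survival-time point
estimates -> evaluation metrics -> temporal importance.  Every stage is a
plain function over the previous stage's artifact, and the whole run is
deterministic for a fixed seed and classifier family.

Also provides the classifier-adapter contract (any probabilistic binary
classifier can drive CASE), raw-table preparation (missing-data pruning,
imputation, one-hot encoding) and the comparison harness against standard
survival baselines (Kaplan-Meier internally; Cox and random survival
forest via scikit-survival).
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .augment import (EVENT_COL, ID_COL, PERIOD_COL, TIME_COL, AugmentedDataset,
                      SurvivalDataset, attach_survival_features, augment,
                      class_ratio)
from .calibrate import CalibrationMap, apply_abbq, fit_abbq, tune_bin_count
from .curves import SurvivalCurve, km_baseline, predict_curves
from .importance import TemporalImportanceProfile, temporal_importance
from .metrics import (concordance_index, ece, integrated_brier, mausc,
                      time_dependent_auc)
from .timepoint import (estimate_gradient, estimate_threshold,
                        fit_time_regressor, predict_time, windowed_accuracy)
from .validation import FoldAssignment, tsk_fold

logger = logging.getLogger("casesurv")

__all__ = ["ClassifierAdapter", "XGBoostAdapter", "RandomForestAdapter",
           "make_classifier", "RunConfig", "PipelineResult", "prepare",
           "PreparationReport", "run_pipeline", "evaluate_against_baselines"]


# ---------------------------------------------------------------------------
# Classifier adapters


class ClassifierAdapter:
    """Contract: ``fit(X, y, seed)`` then ``score(X)`` -> P(survive) in [0,1].

    ``attribute(X)`` returns per-row additive feature contributions and the
    base value, when the family supports it.
    """

    def fit(self, X: pd.DataFrame, y, seed: int = 0):  # pragma: no cover
        raise NotImplementedError

    def score(self, X: pd.DataFrame) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def attribute(self, X: pd.DataFrame):
        raise NotImplementedError(
            f"{type(self).__name__} has no additive attribution backend")


class XGBoostAdapter(ClassifierAdapter):
    """Gradient-boosted trees (xgboost), the default CASE classifier.

    Fixed, documented hyperparameters; single-threaded histogram trees so
    repeated runs with one seed are bit-reproducible.
    """

    def __init__(self, n_estimators: int = 200, max_depth: int = 4,
                 learning_rate: float = 0.1, **kwargs):
        self.params = dict(n_estimators=n_estimators, max_depth=max_depth,
                           learning_rate=learning_rate, tree_method="hist",
                           n_jobs=1, **kwargs)
        self.model = None
        self.columns: Optional[list] = None

    def fit(self, X, y, seed: int = 0):
        from xgboost import XGBClassifier
        self.model = XGBClassifier(random_state=seed, **self.params)
        self.columns = list(X.columns)
        self.model.fit(X, np.asarray(y))
        self._booster = self.model.get_booster()
        return self

    def _check(self, X):
        if getattr(self, "_booster", None) is None:
            raise RuntimeError("adapter not fitted")
        if list(X.columns) != self.columns:
            raise ValueError(f"feature schema mismatch: expected {self.columns}")

    def _dmatrix(self, X):
        import xgboost as xgb
        return xgb.DMatrix(X, feature_names=self.columns)

    def score(self, X):
        self._check(X)
        return self._booster.predict(self._dmatrix(X))

    def margin(self, X):
        """Raw log-odds output (the space in which attributions add up)."""
        self._check(X)
        return self._booster.predict(self._dmatrix(X), output_margin=True)

    def attribute(self, X):
        """Exact tree-path attributions (TreeSHAP) in log-odds space."""
        self._check(X)
        contrib = self._booster.predict(self._dmatrix(X), pred_contribs=True)
        return contrib[:, :-1], float(contrib[0, -1])

    def save(self, path) -> None:
        self._check_fitted_for_save()
        self._booster.save_model(str(path))

    def _check_fitted_for_save(self):
        if getattr(self, "_booster", None) is None:
            raise RuntimeError("adapter not fitted")

    @classmethod
    def load(cls, path, columns) -> "XGBoostAdapter":
        import xgboost as xgb
        adapter = cls()
        booster = xgb.Booster()
        booster.load_model(str(path))
        adapter._booster = booster
        adapter.columns = list(columns)
        return adapter


class RandomForestAdapter(ClassifierAdapter):
    """Random-forest family via scikit-learn; Monte-Carlo attributions."""

    def __init__(self, n_estimators: int = 300, min_samples_leaf: int = 5,
                 attribution_permutations: int = 16, **kwargs):
        self.params = dict(n_estimators=n_estimators,
                           min_samples_leaf=min_samples_leaf, n_jobs=1, **kwargs)
        self.n_perm = attribution_permutations
        self.model = None
        self.columns: Optional[list] = None
        self._seed = 0
        self._background: Optional[np.ndarray] = None

    def fit(self, X, y, seed: int = 0):
        from sklearn.ensemble import RandomForestClassifier
        self.model = RandomForestClassifier(random_state=seed, **self.params)
        self.columns = list(X.columns)
        self._seed = seed
        self.model.fit(X.to_numpy(dtype=float), np.asarray(y))
        rng = np.random.default_rng(seed)
        arr = X.to_numpy(dtype=float)
        take = rng.choice(len(arr), size=min(64, len(arr)), replace=False)
        self._background = arr[take]
        return self

    def score(self, X):
        if self.model is None:
            raise RuntimeError("adapter not fitted")
        if list(X.columns) != self.columns:
            raise ValueError(f"feature schema mismatch: expected {self.columns}")
        return self.model.predict_proba(X.to_numpy(dtype=float))[:, 1]

    def attribute(self, X):
        from .importance import sampling_attributions
        if self.model is None:
            raise RuntimeError("adapter not fitted")
        fn = lambda arr: self.model.predict_proba(arr)[:, 1]
        return sampling_attributions(fn, X.to_numpy(dtype=float),
                                     self._background, self.n_perm, self._seed)


_FAMILIES = {"gradient-boosted-trees": XGBoostAdapter,
             "xgboost": XGBoostAdapter,
             "random-forest": RandomForestAdapter}


def make_classifier(family: str, **kwargs) -> ClassifierAdapter:
    try:
        return _FAMILIES[family](**kwargs)
    except KeyError:
        raise ValueError(f"unknown classifier family {family!r}; "
                         f"choose from {sorted(_FAMILIES)}") from None


# ---------------------------------------------------------------------------
# Data preparation


@dataclass
class PreparationReport:
    dropped: list
    imputed: dict
    encoded: list


def prepare(raw: pd.DataFrame, missing_threshold: float = 0.8,
            keep_list: Sequence[str] = ()) -> tuple[SurvivalDataset, PreparationReport]:
    """Clean a raw survival table into a modelling-ready dataset.

    Feature columns with a missing fraction above ``missing_threshold`` are
    dropped unless named on ``keep_list`` (for variables retained on
    subject-matter grounds despite sparseness).  Remaining numeric columns
    are mean-imputed, categoricals mode-imputed and one-hot encoded.
    """
    for col in (ID_COL, TIME_COL, EVENT_COL):
        if col not in raw.columns:
            raise ValueError(f"missing mandatory column {col!r}")
    feats = raw.drop(columns=[ID_COL, TIME_COL, EVENT_COL]).copy()
    dropped, imputed, encoded = [], {}, []
    for col in list(feats.columns):
        frac = feats[col].isna().mean()
        if frac > missing_threshold and col not in keep_list:
            dropped.append(col)
            feats = feats.drop(columns=[col])
            logger.info("prepare: dropped %r (%.0f%% missing)", col, 100 * frac)
    for col in list(feats.columns):
        if feats[col].isna().any():
            if pd.api.types.is_numeric_dtype(feats[col]):
                fill = feats[col].mean()
            else:
                fill = feats[col].mode(dropna=True).iloc[0]
            feats[col] = feats[col].fillna(fill)
            imputed[col] = fill
            logger.info("prepare: imputed %r with %r", col, fill)
    cat_cols = [c for c in feats.columns
                if not pd.api.types.is_numeric_dtype(feats[c])]
    if cat_cols:
        encoded = cat_cols
        feats = pd.get_dummies(feats, columns=cat_cols, dtype=float)
    dataset = SurvivalDataset(raw[ID_COL].to_numpy(dtype=str),
                              raw[TIME_COL].to_numpy(dtype=float),
                              raw[EVENT_COL].to_numpy(), feats)
    return dataset, PreparationReport(dropped, imputed, encoded)


# ---------------------------------------------------------------------------
# Run configuration and orchestration


@dataclass(frozen=True)
class RunConfig:
    """All knobs of an end-to-end run; validated up front."""

    horizon: int
    classifier: str = "gradient-boosted-trees"
    bin_candidates: tuple = (5, 10, 15, 20, 30, 50)
    k: int = 5
    repeats: int = 1
    grouped: bool = False
    theta: float = 0.5
    window: float = 5.0
    grid_step: float = 0.01
    seed: int = 0
    importance_cap: int = 2000
    compute_importance: bool = True

    def __post_init__(self):
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if self.classifier not in _FAMILIES:
            raise ValueError(f"unknown classifier family {self.classifier!r}")
        if not 0 < self.theta < 1:
            raise ValueError("theta must lie in (0, 1)")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not self.bin_candidates:
            raise ValueError("bin_candidates must be non-empty")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "bin_candidates" in doc:
            doc["bin_candidates"] = tuple(doc["bin_candidates"])
        return cls(**doc)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    augmented: AugmentedDataset
    assignment: FoldAssignment
    oof_scores: np.ndarray
    calibration: CalibrationMap
    model: ClassifierAdapter
    curves: dict
    d_survival: pd.DataFrame
    estimates: pd.DataFrame
    metrics: dict
    importance: Optional[TemporalImportanceProfile]
    manifest: dict


def _stage(name):
    logger.info("stage: %s", name)


def run_pipeline(config: RunConfig, dataset: SurvivalDataset) -> PipelineResult:
    """Execute the full CASE workflow on one dataset.

    Cross-validated (out-of-fold) raw scores drive calibration so the
    calibration map never sees scores of rows the scorer was trained on;
    the bin count is tuned with fold 0 as the validation split.  The final
    classifier is refitted on all augmented rows, and curves, point
    estimates, metrics and the importance profile are derived from it.
    """
    P, seed = config.horizon, config.seed
    try:
        _stage("augment")
        augmented = augment(dataset, P)
        ratio = class_ratio(dataset, P)

        _stage("tsk-fold")
        assignment = tsk_fold(augmented, config.k, seed=seed,
                              repeats=config.repeats, grouped=config.grouped)

        _stage("cross-validated scores")
        fold = assignment.fold_of(0)
        oof = np.empty(augmented.n_rows)
        fold_auc = []
        from sklearn.metrics import roc_auc_score
        for f in range(config.k):
            test = fold == f
            clf = make_classifier(config.classifier)
            clf.fit(augmented.X[~test], augmented.y[~test], seed=seed)
            oof[test] = clf.score(augmented.X[test])
            y_test = augmented.y[test]
            if 0 < y_test.sum() < y_test.size:
                fold_auc.append(float(roc_auc_score(y_test, oof[test])))

        _stage("calibration")
        val = fold == 0
        best_m = tune_bin_count(oof[~val], augmented.y[~val],
                                oof[val], augmented.y[val], config.bin_candidates)
        calibration = fit_abbq(oof, augmented.y, best_m)
        ece_raw = ece(oof, augmented.y)
        ece_cal = ece(apply_abbq(calibration, oof), augmented.y)

        _stage("final fit + curves")
        model = make_classifier(config.classifier)
        model.fit(augmented.X, augmented.y, seed=seed)
        curves = predict_curves(model, calibration, dataset, P)

        _stage("survival-time estimation")
        d_survival = attach_survival_features(dataset, curves)
        est_rows = []
        for sid in dataset.ids:
            est_rows.append((sid, estimate_threshold(curves[sid], config.theta),
                             estimate_gradient(curves[sid])))
        estimates = pd.DataFrame(est_rows, columns=["subject_id", "threshold", "gradient"])
        ev = dataset.event == 1
        reg_metrics = {}
        if ev.any():
            reg = fit_time_regressor(d_survival, dataset, seed=seed)
            estimates["regression"] = predict_time(reg, d_survival.loc[dataset.ids])
            actual = dataset.time[ev]
            sub = estimates.set_index("subject_id").loc[dataset.ids[ev]]
            for method in ("threshold", "gradient", "regression"):
                reg_metrics[f"windowed_accuracy_{method}"] = windowed_accuracy(
                    sub[method].to_numpy(), actual, window=config.window)

        _stage("metrics")
        metrics = {
            "class_ratio": ratio,
            "n_augmented_rows": int(augmented.n_rows),
            "abbq_bins": int(best_m),
            "ece_raw": ece_raw,
            "ece_calibrated": ece_cal,
            "fold_auc_mean": float(np.mean(fold_auc)) if fold_auc else None,
            "fold_auc_sd": float(np.std(fold_auc)) if fold_auc else None,
            **reg_metrics,
        }
        if ev.any():
            metrics["mausc"] = mausc(curves, dataset, P, config.grid_step)

        importance = None
        if config.compute_importance:
            _stage("temporal importance")
            try:
                importance = temporal_importance(model, dataset, P,
                                                 max_subjects=config.importance_cap,
                                                 seed=seed)
            except (NotImplementedError, TypeError) as exc:
                warnings.warn(f"importance stage skipped: {exc}")

        manifest = {
            "config": asdict(config),
            "config_hash": config.digest(),
            "seed": seed,
            "versions": {"casesurv": _pkg_version, "numpy": np.__version__,
                         "pandas": pd.__version__},
        }
        return PipelineResult(augmented, assignment, oof, calibration, model,
                              curves, d_survival, estimates, metrics,
                              importance, manifest)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed: {exc}") from exc


# ---------------------------------------------------------------------------
# Baseline comparison harness


def _eval_model(name: str, surv_at, train: SurvivalDataset, test: SurvivalDataset,
                P: int, times: np.ndarray, grid_step: float) -> dict:
    """Shared metric block: curves evaluated at `times` plus mAUSC."""
    probs = np.asarray([surv_at(i, times) for i in range(test.n)])
    risk = 1.0 - probs[:, -1]
    out = {"model": name}
    try:
        out["c_index"] = concordance_index(test, risk)
    except Exception as exc:  # KM constant risk, ties, etc.
        out["c_index"] = None
    out["ibs"] = integrated_brier(train, test, probs, times)
    out["t_auc"] = time_dependent_auc(train, test, 1.0 - probs, times)
    curves = {sid: SurvivalCurve(sid, np.clip(surv_at(i, np.arange(1, P + 1)), 0, 1))
              for i, sid in enumerate(test.ids)}
    out["mausc"] = mausc(curves, test, P, grid_step)
    return out


def evaluate_against_baselines(train: SurvivalDataset, test: SurvivalDataset,
                               case_curves: dict, P: int, seed: int = 0,
                               grid_step: float = 0.01) -> pd.DataFrame:
    """Compare CASE curves with KM, Cox and RSF on one train/test split.

    KM is the in-package product-limit estimate (a single population
    curve, hence no C-index); Cox and the random survival forest come from
    scikit-survival.  A baseline whose fit fails is skipped with a
    warning.  Time grid: integer periods inside the test follow-up range.
    """
    t_max = min(P, float(test.time.max()) - 1e-8)
    times = np.arange(1, int(np.floor(t_max)) + 1, dtype=float)
    if times.size == 0:
        raise ValueError("test follow-up too short to build an evaluation grid")
    rows = []

    case_mat = {i: case_curves[sid] for i, sid in enumerate(test.ids)}
    rows.append(_eval_model(
        "CASE", lambda i, ts: np.asarray([case_mat[i](t) for t in np.atleast_1d(ts)]),
        train, test, P, times, grid_step))
    # KM has a single population curve: every test subject shares it.
    km = km_baseline(train)
    km_row = _eval_model("KM", lambda i, ts: km.at(ts), train, test, P, times, grid_step)
    km_row["c_index"] = None
    rows.append(km_row)

    Xtr = train.features.to_numpy(dtype=float)
    Xte = test.features.to_numpy(dtype=float)
    from sksurv.util import Surv
    y_tr = Surv.from_arrays(event=train.event.astype(bool), time=train.time)

    def step_eval(fns):
        # sksurv StepFunctions reject queries outside their domain; clamp.
        def ev(i, ts):
            lo, hi = fns[i].domain
            tsa = np.clip(np.atleast_1d(np.asarray(ts, dtype=float)), lo, hi)
            return fns[i](tsa)
        return ev

    try:
        from sksurv.linear_model import CoxPHSurvivalAnalysis
        cox = CoxPHSurvivalAnalysis(alpha=0.1).fit(Xtr, y_tr)
        rows.append(_eval_model("Cox", step_eval(cox.predict_survival_function(Xte)),
                                train, test, P, times, grid_step))
    except Exception as exc:
        warnings.warn(f"Cox baseline skipped: {exc}")

    try:
        from sksurv.ensemble import RandomSurvivalForest
        rsf = RandomSurvivalForest(n_estimators=100, min_samples_leaf=15,
                                   random_state=seed, n_jobs=1).fit(Xtr, y_tr)
        rows.append(_eval_model("RSF", step_eval(rsf.predict_survival_function(Xte)),
                                train, test, P, times, grid_step))
    except Exception as exc:
        warnings.warn(f"RSF baseline skipped: {exc}")

    return pd.DataFrame(rows)
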