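"""Temporal variable importance from additive feature attributions.

For each period ``tau`` the fitted classifier is explained on the rows
``(x_i, tau)`` of the subjects observed to survive ``tau`` periods
(``I_tau = {i : floor(t_i) >= tau}``).  The per-feature attribution
``phi_{i,j}(tau)`` is averaged over ``I_tau`` to give the population
importance trajectory ``phibar_{j,tau}``; individual trajectories are kept
so single subjects can be contrasted with the population mean.

Attributions for gradient-boosted trees use the exact tree-path algorithm
built into xgboost (contributions in log-odds margin space, satisfying the
additive decomposition sum(phi) + base = margin exactly).  Other model
families fall back to a seeded Monte-Carlo permutation estimate of Shapley
values on the probability output.  The period feature itself receives an
attribution; it is tracked separately from the covariates.

Because every period re-explains up to the full cohort, subjects are
subsampled to a configurable cap before attribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .augment import PERIOD_COL, SurvivalDataset

__all__ = ["TemporalImportanceProfile", "temporal_importance",
           "individual_trajectory", "sampling_attributions"]


@dataclass(frozen=True)
class TemporalImportanceProfile:
    """Per-feature, per-period mean attributions plus raw trajectories."""

    feature_names: list
    periods: np.ndarray              # 1..P
    mean_values: np.ndarray          # (F, P); NaN where I_tau is empty
    period_importance: np.ndarray    # (P,) mean attribution of the period feature
    n_survivors: np.ndarray          # (P,) |I_tau|
    per_subject: dict                # tau -> DataFrame(index=subject ids, cols=features+period)

    def to_frame(self) -> pd.DataFrame:
        rows = [(f, int(tau), self.mean_values[j, k], int(self.n_survivors[k]))
                for j, f in enumerate(self.feature_names)
                for k, tau in enumerate(self.periods)]
        return pd.DataFrame(rows, columns=["feature", "period", "mean_shap", "n_survivors"])


def temporal_importance(model, dataset: SurvivalDataset, P: int,
                        max_subjects: int = 2000, seed: int = 0) -> TemporalImportanceProfile:
    """Compute the temporal importance profile of a fitted classifier.

    ``model`` must expose ``attribute(X) -> (contributions, base)`` per the
    classifier-adapter contract.  ``max_subjects`` caps the cohort by a
    seeded subsample before attribution.
    """
    if not hasattr(model, "attribute"):
        raise TypeError("model does not provide an additive attribution backend")
    data = dataset
    if dataset.n > max_subjects:
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(dataset.n, size=max_subjects, replace=False))
        data = dataset.subset(keep)

    F = len(data.feature_names)
    t_floor = data.floor_time
    mean_values = np.full((F, P), np.nan)
    period_imp = np.full(P, np.nan)
    n_surv = np.zeros(P, dtype=int)
    per_subject: dict[int, pd.DataFrame] = {}

    for tau in range(1, P + 1):
        mask = t_floor >= tau
        n_surv[tau - 1] = int(mask.sum())
        if not mask.any():
            continue
        X = data.features.loc[mask].copy()
        X[PERIOD_COL] = tau
        contrib, _base = model.attribute(X)
        contrib = np.asarray(contrib, dtype=float)  # (n, F+1): features then period
        mean_values[:, tau - 1] = contrib[:, :F].mean(axis=0)
        period_imp[tau - 1] = contrib[:, F].mean()
        per_subject[tau] = pd.DataFrame(
            contrib, index=data.ids[mask],
            columns=list(data.feature_names) + [PERIOD_COL])

    return TemporalImportanceProfile(list(data.feature_names), np.arange(1, P + 1),
                                     mean_values, period_imp, n_surv, per_subject)


def individual_trajectory(profile: TemporalImportanceProfile,
                          subject_id: str, feature: str) -> np.ndarray:
    """phi_{i,j}(tau) for tau = 1..(periods the subject survived)."""
    if feature != PERIOD_COL and feature not in profile.feature_names:
        raise KeyError(f"unknown feature {feature!r}")
    vals = []
    for tau in profile.periods:
        frame = profile.per_subject.get(int(tau))
        if frame is None or subject_id not in frame.index:
            break
        vals.append(frame.loc[subject_id, feature])
    if not vals:
        raise KeyError(f"subject {subject_id!r} not present in the profile")
    return np.asarray(vals, dtype=float)


def sampling_attributions(predict_fn, X: np.ndarray, background: np.ndarray,
                          n_permutations: int = 32, seed: int = 0):
    """Seeded Monte-Carlo permutation estimate of Shapley values.

    For each random feature ordering, features of each explained row are
    switched from a background row's values to the row's own values one at
    a time; the marginal change in ``predict_fn`` output accumulates into
    that feature's attribution.  Returns (contributions, base) where base
    is the mean prediction over the background sample.
    """
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    background = np.asarray(background, dtype=float)
    n, F = X.shape
    contrib = np.zeros((n, F))
    for _ in range(n_permutations):
        order = rng.permutation(F)
        bg = background[rng.integers(len(background), size=n)]
        current = bg.copy()
        prev = np.asarray(predict_fn(current), dtype=float)
        for j in order:
            current[:, j] = X[:, j]
            nxt = np.asarray(predict_fn(current), dtype=float)
            contrib[:, j] += nxt - prev
            prev = nxt
    base = float(np.mean(predict_fn(background)))
    return contrib / n_permutations, base
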