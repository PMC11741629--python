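"""Temporal feature importance: additivity, aggregation and signal shape."""

import numpy as np
import pytest

from casesurv import (XGBoostAdapter, augment, generate, individual_trajectory,
                      temporal_importance)
from casesurv.augment import PERIOD_COL
from casesurv.synthdata import SyntheticConfig


P = 8


@pytest.fixture(scope="module")
def fitted():
    """Cohort with one strong feature (x0), one late-activating feature (x1,
    effect switches on after period 5) and one pure-noise feature (x2)."""
    beta = np.zeros((3, P))
    beta[0, :] = 0.8
    beta[1, 5:] = 1.5   # acts on hazards of periods 6..8 only
    cfg = SyntheticConfig(4000, 3, P, baseline_logit=-2.0, effects=beta,
                          followup_window=(2 * P, 3 * P), seed=42)
    dataset, _ = generate(cfg)
    aug = augment(dataset, P)
    model = XGBoostAdapter().fit(aug.X, aug.y, seed=0)
    return model, dataset, aug


@pytest.fixture(scope="module")
def profile(fitted):
    model, dataset, _ = fitted
    return temporal_importance(model, dataset, P, max_subjects=400, seed=1)


class TestAttributionContract:
    def test_additivity_to_margin_output(self, fitted):
        model, dataset, _ = fitted
        X = dataset.features.iloc[:50].copy()
        X[PERIOD_COL] = 3
        contrib, base = model.attribute(X)
        total = contrib.sum(axis=1) + base
        assert np.allclose(total, model.margin(X), atol=1e-4)

    def test_requires_attribution_backend(self, fitted):
        _, dataset, _ = fitted

        class NoAttr:
            pass

        with pytest.raises(TypeError):
            temporal_importance(NoAttr(), dataset, P)


class TestProfile:
    def test_aggregation_identity_exact(self, profile):
        for tau in profile.periods:
            frame = profile.per_subject.get(int(tau))
            if frame is None:
                continue
            for j, name in enumerate(profile.feature_names):
                assert profile.mean_values[j, tau - 1] == pytest.approx(
                    frame[name].mean(), rel=1e-12)

    def test_survivor_sets_shrink(self, profile):
        assert (np.diff(profile.n_survivors) <= 0).all()

    def test_survivor_set_matches_positive_rows(self, fitted):
        model, dataset, aug = fitted
        prof = temporal_importance(model, dataset, P,
                                   max_subjects=10**9, seed=0)
        for tau in range(1, P + 1):
            n_pos = int(aug.labels[aug.periods == tau].sum())
            assert prof.n_survivors[tau - 1] == n_pos

    def test_noise_feature_attribution_near_zero(self, profile):
        noise = np.abs(profile.mean_values[2])
        strong = np.abs(profile.mean_values[0])
        assert np.nanmax(noise) < 0.15
        assert np.nanmax(noise) < 0.25 * np.nanmax(strong)

    def test_late_activating_feature_shifts_profile(self, profile):
        late = np.abs(profile.mean_values[1])
        # hazard effect starts at period 6, so survival through tau >= 6
        # depends on x1 while earlier periods do not
        assert late[5:].mean() > 3 * late[:5].mean()

    def test_subsampling_cap_respected_and_seeded(self, fitted):
        model, dataset, _ = fitted
        p1 = temporal_importance(model, dataset, P, max_subjects=100, seed=5)
        p2 = temporal_importance(model, dataset, P, max_subjects=100, seed=5)
        assert p1.per_subject[1].shape[0] <= 100
        assert np.allclose(p1.mean_values, p2.mean_values, equal_nan=True)


class TestTrajectories:
    def test_length_equals_survived_periods(self, profile, fitted):
        _, dataset, _ = fitted
        lookup = dict(zip(dataset.ids, dataset.floor_time))
        sid = profile.per_subject[1].index[0]
        traj = individual_trajectory(profile, sid, "x0")
        assert len(traj) == min(lookup[sid], P)

    def test_mean_of_trajectories_equals_profile(self, profile):
        frame = profile.per_subject[2]
        vals = [individual_trajectory(profile, sid, "x0")[1]
                for sid in frame.index]
        assert np.mean(vals) == pytest.approx(
            profile.mean_values[0, 1], rel=1e-9)

    def test_opposite_covariate_signs_give_opposite_attributions(self, fitted):
        model, dataset, _ = fitted
        X = dataset.features.iloc[:2].copy()
        X.iloc[0] = [2.5, 0.0, 0.0]
        X.iloc[1] = [-2.5, 0.0, 0.0]
        X[PERIOD_COL] = 4
        contrib, _ = model.attribute(X)
        assert contrib[0, 0] * contrib[1, 0] < 0

    def test_unknown_subject_or_feature(self, profile):
        with pytest.raises(KeyError):
            individual_trajectory(profile, "nope", "x0")
        with pytest.raises(KeyError):
            individual_trajectory(profile, profile.per_subject[1].index[0], "zz")


def test_sampling_attributions_additive_for_linear_model():
    from casesurv.importance import sampling_attributions
    rng = np.random.default_rng(0)
    w = np.array([1.0, -2.0, 0.5])
    f = lambda A: A @ w
    X = rng.standard_normal((20, 3))
    bg = rng.standard_normal((50, 3))
    contrib, base = sampling_attributions(f, X, bg, n_permutations=500, seed=1)
    # linear model: exact Shapley value is w_j * (x_j - E[background_j]);
    # Monte-Carlo noise ~ |w_j| sd(bg_j) / sqrt(permutations)
    expected = w * (X - bg.mean(axis=0))
    assert np.allclose(contrib, expected, atol=0.4)
    assert base == pytest.approx(f(bg).mean())
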