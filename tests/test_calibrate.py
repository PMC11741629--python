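"""ABBQ calibration: binning, the intra-bin term, tuning and round trips."""

import numpy as np
import pytest
from scipy.special import expit, logit

from casesurv import CalibrationMap, apply_abbq, fit_abbq, tune_bin_count
from casesurv.metrics import ece


def distorted_scores(n=5000, seed=0, gamma=2.5):
    """Sigmoid-distorted scores with Bernoulli labels from the true rate."""
    rng = np.random.default_rng(seed)
    p_true = rng.uniform(0.02, 0.98, size=n)
    labels = (rng.random(n) < p_true).astype(int)
    raw = expit(gamma * logit(p_true))
    return raw, labels


class TestFit:
    def test_equal_quantile_split(self):
        rng = np.random.default_rng(1)
        cal = fit_abbq(rng.random(100), rng.integers(0, 2, 100), 10)
        assert cal.bin_n.tolist() == [10] * 10

    def test_uneven_split_differs_by_at_most_one(self):
        rng = np.random.default_rng(2)
        cal = fit_abbq(rng.random(103), rng.integers(0, 2, 103), 10)
        assert cal.bin_n.sum() == 103
        assert cal.bin_n.max() - cal.bin_n.min() <= 1

    def test_empirical_probability_per_bin(self):
        cal = fit_abbq([0.1, 0.2, 0.3, 0.4], [1, 1, 1, 0], 1)
        assert cal.p_emp[0] == pytest.approx(0.75)

    def test_single_bin_all_survived(self):
        cal = fit_abbq([0.2, 0.5, 0.9], [1, 1, 1], 1)
        assert cal.p_emp[0] == 1.0

    def test_too_few_observations(self):
        with pytest.raises(ValueError, match="smaller M"):
            fit_abbq([0.1, 0.2], [1, 0], 5)


class TestApply:
    @pytest.fixture
    def cal(self):
        # ten bins [k/10, k/10 + 0.09]; first bin p_emp=0.6, last p_emp=0.2
        p_emp = np.array([0.6, 0.5, 0.5, 0.5, 0.5, 0.4, 0.4, 0.3, 0.3, 0.2])
        lo = np.arange(10) / 10
        return CalibrationMap(10, lo, lo + 0.09, p_emp,
                              np.full(10, 10), (p_emp * 10).astype(int))

    def test_bin_minimum_returns_empirical_probability(self, cal):
        assert apply_abbq(cal, 0.0) == pytest.approx(0.6)

    def test_bin_maximum_adds_one_over_m(self, cal):
        assert apply_abbq(cal, 0.09) == pytest.approx(0.6 + 0.1)

    def test_partway_through_bin(self, cal):
        # 40% through [0.0, 0.09] with p_emp 0.6, M=10 -> 0.64
        assert apply_abbq(cal, 0.036) == pytest.approx(0.64)

    def test_clipping_at_one(self, cal):
        # near-certain bin plus the intra-bin term would exceed 1: clipped
        high = CalibrationMap(10, cal.score_min, cal.score_max,
                              np.full(10, 0.98), cal.bin_n, cal.bin_n_survive)
        assert apply_abbq(high, 0.09) == 1.0

    def test_out_of_range_scores_clamp_to_edge_bins(self, cal):
        assert apply_abbq(cal, -0.3) == pytest.approx(0.6)     # first bin, pos 0
        assert apply_abbq(cal, 1.5) == pytest.approx(0.2 + 0.1)  # last bin, pos 1

    def test_degenerate_bin_uses_midpoint(self):
        # zero score range: normalized position defined as 0.5
        cal = fit_abbq([0.5, 0.5, 0.5, 0.5], [1, 0, 0, 0], 1)
        assert apply_abbq(cal, 0.5) == pytest.approx(0.25 + 0.5)

    def test_centered_mode_removes_mean_shift(self):
        rng = np.random.default_rng(3)
        s = rng.random(200)
        y = rng.integers(0, 2, 200)
        plain = apply_abbq(fit_abbq(s, y, 10), s)
        centered = apply_abbq(fit_abbq(s, y, 10, centered=True), s)
        assert np.mean(plain) - np.mean(centered) == pytest.approx(0.05, abs=0.01)

    def test_within_bin_monotone_and_bounded(self):
        raw, labels = distorted_scores(seed=5)
        cal = fit_abbq(raw, labels, 20)
        grid = np.sort(np.random.default_rng(0).uniform(size=500))
        out = apply_abbq(cal, grid)
        assert ((out >= 0) & (out <= 1)).all()
        bins = cal.assign(grid)
        for b in np.unique(bins):
            vals = out[bins == b]
            assert (np.diff(vals) >= -1e-12).all()

    def test_one_observation_per_bin_stays_in_unit_interval(self):
        rng = np.random.default_rng(8)
        s = rng.random(40)
        y = rng.integers(0, 2, 40)
        cal = fit_abbq(s, y, 40)
        out = apply_abbq(cal, rng.random(100))
        assert ((out >= 0) & (out <= 1)).all()


class TestCalibrationQuality:
    def test_ece_improves_on_distorted_scores(self):
        raw, labels = distorted_scores(n=5000, seed=42)
        fit_half = slice(0, 2500)
        eval_half = slice(2500, None)
        cal = fit_abbq(raw[fit_half], labels[fit_half], 20)
        before = ece(raw[eval_half], labels[eval_half])
        after = ece(apply_abbq(cal, raw[eval_half]), labels[eval_half])
        assert after < before


class TestTuning:
    def test_returns_minimal_ece_candidate(self):
        raw, labels = distorted_scores(n=4000, seed=9)
        tr, va = slice(0, 2000), slice(2000, None)
        cands = (5, 10, 20, 50, 100)
        best = tune_bin_count(raw[tr], labels[tr], raw[va], labels[va], cands)
        errs = {m: ece(apply_abbq(fit_abbq(raw[tr], labels[tr], m), raw[va]),
                       labels[va]) for m in cands}
        assert best == min(cands, key=lambda m: (errs[m], m))

    def test_single_candidate(self):
        raw, labels = distorted_scores(n=200, seed=1)
        assert tune_bin_count(raw, labels, raw, labels, [7]) == 7

    def test_empty_candidates_error(self):
        with pytest.raises(ValueError):
            tune_bin_count([0.5], [1], [0.5], [1], [])


def test_json_round_trip():
    raw, labels = distorted_scores(n=300, seed=2)
    cal = fit_abbq(raw, labels, 12)
    back = CalibrationMap.from_json(cal.to_json())
    probe = np.linspace(0, 1, 57)
    assert np.allclose(apply_abbq(cal, probe), apply_abbq(back, probe))
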