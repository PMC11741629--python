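"""Person-period augmentation: labels, cardinality and de-augmentation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from casesurv import (SurvivalCurve, SurvivalDataset, ValidationError,
                      attach_survival_features, augment, class_ratio,
                      expand_for_prediction)
from conftest import make_dataset, random_dataset


class TestWorkedExamples:
    def test_censored_record_replicates_to_its_censoring_time(self):
        ds = make_dataset(["p7"], [6.0], [0])
        aug = augment(ds, 20)
        assert aug.n_rows == 6
        assert list(aug.periods) == [1, 2, 3, 4, 5, 6]
        assert aug.labels.tolist() == [1] * 6

    def test_event_record_replicates_to_the_horizon(self):
        ds = make_dataset(["p8"], [6.0], [1])
        aug = augment(ds, 20)
        assert aug.n_rows == 20
        assert aug.labels[:6].tolist() == [1] * 6
        assert aug.labels[6:].tolist() == [0] * 14

    def test_long_censoring_caps_at_horizon(self):
        aug = augment(make_dataset(["c"], [25.0], [0]), 20)
        assert aug.n_rows == 20
        assert aug.labels.tolist() == [1] * 20

    def test_empty_dataset_augments_to_empty(self):
        ds = SurvivalDataset(np.array([], dtype=str), np.array([]),
                             np.array([], dtype=int), pd.DataFrame({"x0": []}))
        assert augment(ds, 5).n_rows == 0


class TestContracts:
    def test_fractional_times_floor_to_completed_periods(self):
        aug = augment(make_dataset(["c"], [6.4], [0]), 20)
        assert aug.n_rows == 6

    def test_censored_before_one_period_contributes_nothing(self):
        assert augment(make_dataset(["c"], [0.9], [0]), 10).n_rows == 0

    def test_event_before_one_period_contributes_all_negatives(self):
        aug = augment(make_dataset(["e"], [0.4], [1]), 10)
        assert aug.n_rows == 10 and aug.labels.sum() == 0

    def test_features_copied_unchanged_and_rows_ordered(self):
        ds = make_dataset(["a", "b"], [3.0, 2.0], [1, 0], n_features=2)
        aug = augment(ds, 4)
        assert aug.source_ids.tolist() == ["a"] * 4 + ["b"] * 2
        assert aug.periods.tolist() == [1, 2, 3, 4, 1, 2]
        for j in ("x0", "x1"):
            assert (aug.frame[j][:4] == ds.features[j][0]).all()

    @pytest.mark.parametrize("times,events,err", [
        ([-1.0], [0], "negative"),
        ([2.0], [2], "event indicator"),
    ])
    def test_invalid_records_are_named(self, times, events, err):
        with pytest.raises(ValidationError):
            make_dataset(["bad"], times, events)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValidationError, match="unique"):
            make_dataset(["a", "a"], [1.0, 2.0], [0, 0])

    def test_horizon_must_be_positive(self):
        with pytest.raises(ValidationError):
            augment(make_dataset(["a"], [1.0], [0]), 0)


class TestProperties:
    def test_cardinality_and_label_identity_on_random_datasets(self):
        """|D_CASE| and each label match the closed forms exactly."""
        rng = np.random.default_rng(11)
        for _ in range(200):
            ds = random_dataset(rng, max_n=50)
            P = int(rng.integers(1, 26))
            aug = augment(ds, P)
            floor_t = np.floor(ds.time).astype(int)
            expected = int(np.where(ds.event == 1, P,
                                    np.minimum(P, floor_t)).sum())
            assert aug.n_rows == expected
            # label identity: y=1 iff tau <= floor(t) of the source record
            lookup = dict(zip(ds.ids, floor_t))
            src_floor = np.array([lookup[s] for s in aug.source_ids])
            assert np.array_equal(aug.labels, (aug.periods <= src_floor).astype(int))

    def test_class_ratio_equals_empirical_positive_fraction(self):
        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(200):
            ds = random_dataset(rng)
            P = int(rng.integers(1, 26))
            aug = augment(ds, P)
            if aug.n_rows == 0:
                with pytest.raises(ValidationError):
                    class_ratio(ds, P)
                continue
            assert class_ratio(ds, P) == pytest.approx(aug.labels.mean(), abs=0)
            checked += 1
        assert checked > 100

    def test_single_record_ratios(self):
        assert class_ratio(make_dataset(["e"], [6.0], [1]), 20) == pytest.approx(0.30)
        assert class_ratio(make_dataset(["c"], [6.0], [0]), 20) == pytest.approx(1.0)

    @given(st.integers(1, 20), st.floats(0.0, 30.0))
    def test_adding_a_censored_record_never_reduces_positive_rows(self, P, t):
        base = make_dataset(["a", "b"], [4.0, 9.0], [1, 1])
        extra = make_dataset(["a", "b", "z"], [4.0, 9.0, t], [1, 1, 0])
        assert augment(extra, P).labels.sum() >= augment(base, P).labels.sum()


class TestExpandForPrediction:
    def test_replicates_one_record_across_periods(self):
        row = pd.Series({"x0": 1.5, "x1": -2.0})
        out = expand_for_prediction(row, 20)
        assert len(out) == 20
        assert out["period"].tolist() == list(range(1, 21))
        assert (out["x0"] == 1.5).all() and (out["x1"] == -2.0).all()
        assert "label" not in out.columns

    def test_single_period(self):
        out = expand_for_prediction({"x0": 0.0}, 1)
        assert len(out) == 1 and out["period"].iloc[0] == 1


class TestAttachSurvivalFeatures:
    def test_shape_and_column_values(self):
        ds = make_dataset([f"s{i}" for i in range(4)], [3, 5, 2, 8],
                          [1, 0, 1, 0], n_features=5)
        P = 10
        rng = np.random.default_rng(0)
        curves = {sid: SurvivalCurve(sid, rng.uniform(size=P)) for sid in ds.ids}
        table = attach_survival_features(ds, curves)
        assert table.shape == (4, 15)
        for k in range(P):
            for sid in ds.ids:
                assert table.loc[sid, f"prob_{k+1}"] == curves[sid].probabilities[k]

    def test_matches_manual_join(self):
        ds = make_dataset(["a", "b", "c"], [1, 2, 3], [1, 1, 0], n_features=2)
        curves = {"a": SurvivalCurve("a", [0.9, 0.8]),
                  "b": SurvivalCurve("b", [0.7, 0.6]),
                  "c": SurvivalCurve("c", [0.5, 0.4])}
        table = attach_survival_features(ds, curves)
        manual = pd.concat(
            [ds.features.set_axis(ds.ids),
             pd.DataFrame([[0.9, 0.8], [0.7, 0.6], [0.5, 0.4]],
                          index=ds.ids, columns=["prob_1", "prob_2"])], axis=1)
        pd.testing.assert_frame_equal(table, manual, check_names=False)

    def test_missing_or_misaligned_curves_error(self):
        ds = make_dataset(["a", "b"], [1, 2], [1, 1])
        curves = {"a": SurvivalCurve("a", [0.9, 0.8])}
        with pytest.raises(ValidationError, match="b"):
            attach_survival_features(ds, curves)
        curves["b"] = SurvivalCurve("b", [0.5])
        with pytest.raises(ValidationError, match="length"):
            attach_survival_features(ds, curves)
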