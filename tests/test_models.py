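import math

import numpy as np
import pandas as pd
import pytest

from esiquant.errors import InsufficientDataError, UnavailableConditionError
from esiquant.models import (
    closest_eluting_baseline,
    equal_rf_baseline,
    fit_interpretive_tree,
    fit_simplified_linear,
    load_model_set,
    predict_log_rf,
    predict_tree,
    render_tree,
    save_model_set,
    train_model_set,
)
from esiquant.tables import ConditionKey, ResponseFactorRecord

POS27 = ConditionKey("positive", 2.7)
POS80 = ConditionKey("positive", 8.0)


def _rf(cid, log_rf, cond=POS27, mean_rt=5.0):
    return ResponseFactorRecord(cid, cond, 10.0**log_rf, log_rf, mean_rt, 5)


def _descriptor_frame(rng, n, ratio8=None):
    """Random but sentinel-free descriptor rows for n compounds."""
    df = pd.DataFrame(
        {
            "compound_id": [f"c{i:03d}" for i in range(n)],
            "ratio_ph2_7": rng.normal(0, 2, n),
            "ratio_ph8_0": ratio8 if ratio8 is not None else rng.normal(0, 2, n),
            "ratio_ph10_0": rng.normal(0, 2, n),
            "rt_ph2_7": rng.uniform(2, 18, n),
            "rt_ph8_0": rng.uniform(2, 18, n),
            "rt_ph10_0": rng.uniform(2, 18, n),
            "d_rt_8_minus_2_7": rng.normal(0, 1, n),
            "d_rt_8_minus_10": rng.normal(0, 1, n),
            "mz": rng.uniform(100, 900, n),
            "na_adduct": rng.integers(0, 2, n),
            "detected_neg": rng.integers(0, 2, n),
            "mz_parity": rng.integers(0, 2, n),
        }
    )
    return df


class TestTrainAndPredict:
    def test_constant_target_predicts_the_constant(self, rng):
        df = _descriptor_frame(rng, 20)
        rf = [_rf(c, 15.0) for c in df["compound_id"]]
        ms = train_model_set(df, rf, seed=0, n_estimators=50, cv_folds=3)
        for _, row in df.iterrows():
            assert predict_log_rf(ms, row, POS27) == pytest.approx(15.0)

    def test_learnable_target_fits_with_high_r2(self, rng):
        df = _descriptor_frame(rng, 200)
        target = 14.0 + 0.8 * df["ratio_ph8_0"].to_numpy()
        rf = [_rf(c, t) for c, t in zip(df["compound_id"], target)]
        ms = train_model_set(df, rf, seed=1, n_estimators=100, cv_folds=3)
        pred = np.array([predict_log_rf(ms, row, POS27) for _, row in df.iterrows()])
        ss_res = np.sum((pred - target) ** 2)
        ss_tot = np.sum((target - target.mean()) ** 2)
        assert 1 - ss_res / ss_tot >= 0.9

    def test_small_condition_is_skipped(self, rng):
        df = _descriptor_frame(rng, 20)
        rf = [_rf(c, 15.0) for c in df["compound_id"]]
        rf += [_rf(c, 14.0, POS80) for c in df["compound_id"][:5]]
        ms = train_model_set(df, rf, seed=0, n_estimators=20, cv_folds=3)
        assert POS27 in ms.models and POS80 not in ms.models
        with pytest.raises(UnavailableConditionError):
            predict_log_rf(ms, df.iloc[0], POS80)

    def test_no_trainable_condition_raises(self, rng):
        df = _descriptor_frame(rng, 5)
        rf = [_rf(c, 15.0) for c in df["compound_id"]]
        with pytest.raises(InsufficientDataError):
            train_model_set(df, rf, seed=0)

    def test_predictions_regress_toward_training_mean(self, rng):
        df = _descriptor_frame(rng, 60)
        target = rng.normal(15, 1.5, 60)
        rf = [_rf(c, t) for c, t in zip(df["compound_id"], target)]
        ms = train_model_set(df, rf, seed=2, n_estimators=50, cv_folds=3)
        pred = [predict_log_rf(ms, row, POS27) for _, row in df.iterrows()]
        assert min(pred) >= target.min() - 1e-9
        assert max(pred) <= target.max() + 1e-9

    def test_bundle_round_trip(self, rng, tmp_path):
        df = _descriptor_frame(rng, 15)
        rf = [_rf(c, 15.0) for c in df["compound_id"]]
        ms = train_model_set(df, rf, seed=3, n_estimators=20, cv_folds=3)
        path = tmp_path / "bundle.joblib"
        save_model_set(ms, path)
        loaded = load_model_set(path)
        assert loaded.conditions() == ms.conditions()
        assert loaded.seed == ms.seed
        row = df.iloc[0]
        assert predict_log_rf(loaded, row, POS27) == predict_log_rf(ms, row, POS27)


class TestEqualRfBaseline:
    def test_geometric_mean_of_two(self):
        rf = [_rf("a", 14.0), _rf("b", 16.0)]
        assert equal_rf_baseline(rf, POS27) == pytest.approx(1.0e15)

    def test_single_standard_is_identity(self):
        rf = [_rf("a", math.log10(3.0e16))]
        assert equal_rf_baseline(rf, POS27) == pytest.approx(3.0e16)

    def test_three_decades(self):
        rf = [_rf("a", 12.0), _rf("b", 14.0), _rf("c", 16.0)]
        assert equal_rf_baseline(rf, POS27) == pytest.approx(1.0e14)

    def test_invariant_to_duplication_and_order(self):
        rf = [_rf("a", 13.0), _rf("b", 16.5), _rf("c", 15.2)]
        base = equal_rf_baseline(rf, POS27)
        assert equal_rf_baseline(rf[::-1] + rf, POS27) == pytest.approx(base)

    def test_empty_training_set_raises(self):
        with pytest.raises(InsufficientDataError):
            equal_rf_baseline([], POS27)


class TestClosestElutingBaseline:
    def test_exact_rt_match_returns_that_standard(self):
        rf = [_rf("a", 14.0, mean_rt=3.0), _rf("b", 16.0, mean_rt=9.0)]
        assert closest_eluting_baseline(rf, 9.0, POS27) == pytest.approx(1e16)

    def test_nearest_neighbor_lookup(self):
        # diazinon-like query at 13.9 min against a carbazole-like
        # standard at 13.6 min holding RF 6.0e12
        rf = [
            _rf("carbazole", math.log10(6.0e12), mean_rt=13.6),
            _rf("early", 16.0, mean_rt=2.0),
        ]
        assert closest_eluting_baseline(rf, 13.9, POS27) == pytest.approx(6.0e12)

    def test_midpoint_tie_breaks_to_earlier_eluting(self):
        rf = [_rf("early", 14.0, mean_rt=4.0), _rf("late", 16.0, mean_rt=6.0)]
        assert closest_eluting_baseline(rf, 5.0, POS27) == pytest.approx(1e14)

    def test_output_is_member_of_training_multiset(self, rng):
        rf = [
            _rf(f"s{i}", float(rng.uniform(12, 17)), mean_rt=float(rng.uniform(1, 19)))
            for i in range(20)
        ]
        pool = {r.rf for r in rf}
        for q in rng.uniform(0, 20, 50):
            assert closest_eluting_baseline(rf, float(q), POS27) in pool


class TestSimplifiedLinearModel:
    def test_exact_line_is_recovered(self, rng):
        df = _descriptor_frame(rng, 30)
        rf = [
            _rf(c, 14.0 + 0.5 * r, POS80)
            for c, r in zip(df["compound_id"], df["ratio_ph8_0"])
        ]
        m = fit_simplified_linear(rf, df)
        assert m.intercept == pytest.approx(14.0)
        assert m.slope == pytest.approx(0.5)
        assert m.r_squared == pytest.approx(1.0)
        assert m.predict(2.0) == pytest.approx(15.0)

    def test_sentinel_ratios_are_excluded(self, rng):
        df = _descriptor_frame(rng, 20)
        df.loc[:9, "ratio_ph8_0"] = 999.0  # pos-only compounds
        rf = [
            _rf(c, 14.0 + 0.5 * r if abs(r) < 900 else 20.0, POS80)
            for c, r in zip(df["compound_id"], df["ratio_ph8_0"])
        ]
        m = fit_simplified_linear(rf, df)
        assert m.n_compounds == 10
        assert m.slope == pytest.approx(0.5)

    def test_two_usable_compounds_raise(self, rng):
        df = _descriptor_frame(rng, 5)
        df.loc[:2, "ratio_ph8_0"] = 999.0
        rf = [_rf(c, 15.0, POS80) for c in df["compound_id"]]
        with pytest.raises(InsufficientDataError):
            fit_simplified_linear(rf, df)


class TestInterpretiveTree:
    def test_single_split_target_splits_on_that_descriptor(self, rng):
        df = _descriptor_frame(rng, 60)
        target = np.where(df["ratio_ph8_0"] > 0, 16.0, 13.0)
        rf = [_rf(c, float(t)) for c, t in zip(df["compound_id"], target)]
        tree = fit_interpretive_tree(df, rf, POS27, max_depth=2, seed=0)
        assert tree["descriptor"] == "ratio_ph8_0"
        assert abs(tree["threshold"]) < 1.0
        text = render_tree(tree)
        assert "ratio_ph8_0" in text and "log10 RF" in text

    def test_depth_zero_is_the_mean_leaf(self, rng):
        df = _descriptor_frame(rng, 12)
        rf = [_rf(c, float(v)) for c, v in zip(df["compound_id"], rng.normal(15, 1, 12))]
        tree = fit_interpretive_tree(df, rf, POS27, max_depth=0)
        assert set(tree) == {"value", "n"}
        assert tree["value"] == pytest.approx(np.mean([r.log_rf for r in rf]))

    def test_tree_refines_the_constant_model(self, rng):
        df = _descriptor_frame(rng, 50)
        y = rng.normal(15, 1, 50)
        rf = [_rf(c, float(v)) for c, v in zip(df["compound_id"], y)]
        tree = fit_interpretive_tree(df, rf, POS27, max_depth=3, seed=1)
        pred = np.array(
            [predict_tree(tree, row) for _, row in df.iterrows()]
        )
        mse_tree = np.mean((pred - y) ** 2)
        mse_const = np.var(y)
        assert mse_tree <= mse_const + 1e-12
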