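"""End-to-end orchestration: simulate -> calibrate -> featurize -> train ->
predict -> evaluate, with intermediate CSVs as the contracts between stages.

``run_pipeline`` generates a synthetic training set (calibration standards)
and test set, calibrates response factors for the standards, trains the
per-condition forests, quantifies the test compounds with three methods —
the trained model set, the equal-RF baseline, and the closest-eluting
baseline (the latter restricted to positive mode at pH 2.7, where it was
defined) — and writes one evaluation summary per method. Everything is
deterministic under the configured seed.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from . import calibration, descriptors, models, quantify, simulate, tables
from .errors import UnavailableConditionError, ValidationError

logger = logging.getLogger(__name__)

PREDICTION_COLUMNS = (
    "method",
    "compound_id",
    "mode",
    "ph",
    "dilution_factor",
    "area",
    "rf_pred",
    "c_predicted_M",
)


@dataclass(frozen=True, slots=True)
class RunConfig:
    """Flat, file-backed configuration of a full pipeline run."""

    out_dir: str = "esiquant_run"
    seed: int = 0
    n_train: int = 150
    n_test: int = 50
    noise_cv: float = 0.1
    lod_area: float = 1.0e4
    frac_neg_detectable: float = 0.5
    rt_rf_coupling: float = 0.3
    ph_trend_pos: float = 0.5
    n_estimators: int = models.N_ESTIMATORS
    cv_folds: int = models.CV_FOLDS
    error_threshold: float = 10.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValidationError("run config must be a flat mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {f.name: getattr(self, f.name) for f in fields(self)},
                sort_keys=False,
            )
        )

    def simulation_config(self) -> simulate.SimulationConfig:
        return simulate.SimulationConfig(
            n_compounds=self.n_train + self.n_test,
            seed=self.seed,
            noise_cv=self.noise_cv,
            lod_area=self.lod_area,
            frac_neg_detectable=self.frac_neg_detectable,
            rt_rf_coupling=self.rt_rf_coupling,
            ph_trend_pos=self.ph_trend_pos,
        )


def predict_concentrations_model(
    model_set: models.ModelSet,
    descriptor_table: pd.DataFrame,
    records: Iterable[tables.PeakRecord],
) -> pd.DataFrame:
    """Quantify every detected datapoint with the per-condition forests."""
    desc_by_id = {
        row["compound_id"]: row for _, row in descriptor_table.iterrows()
    }
    rows = []
    for r in sorted(
        records,
        key=lambda r: (r.compound_id, r.condition._sort_key, r.dilution_factor),
    ):
        if not r.detected or r.compound_id not in desc_by_id:
            continue
        try:
            log_rf = models.predict_log_rf(
                model_set, desc_by_id[r.compound_id], r.condition
            )
        except UnavailableConditionError:
            continue
        rf_pred = 10.0 ** log_rf
        rows.append(_prediction_row("model", r, rf_pred))
    return pd.DataFrame(rows, columns=list(PREDICTION_COLUMNS))


def predict_concentrations_equal_rf(
    rf_train: list[tables.ResponseFactorRecord],
    records: Iterable[tables.PeakRecord],
) -> pd.DataFrame:
    """Quantify with one geometric-mean RF per condition."""
    rf_by_cond = {}
    for cond in tables.all_conditions():
        try:
            rf_by_cond[cond] = models.equal_rf_baseline(rf_train, cond)
        except Exception:
            continue
    rows = [
        _prediction_row("equal_rf", r, rf_by_cond[r.condition])
        for r in sorted(
            records,
            key=lambda r: (r.compound_id, r.condition._sort_key, r.dilution_factor),
        )
        if r.detected and r.condition in rf_by_cond
    ]
    return pd.DataFrame(rows, columns=list(PREDICTION_COLUMNS))


def predict_concentrations_closest(
    rf_train: list[tables.ResponseFactorRecord],
    records: Iterable[tables.PeakRecord],
    conditions: tuple[tables.ConditionKey, ...] = (
        tables.ConditionKey("positive", 2.7),
    ),
) -> pd.DataFrame:
    """Quantify with the closest-eluting standard's RF.

    By default only positive mode at pH 2.7 is quantified, matching how
    the closest-eluting approach is defined; pass other conditions
    explicitly to generalize.
    """
    recs = [r for r in records if r.condition in conditions]
    by_cc: dict[tuple[str, tables.ConditionKey], list[tables.PeakRecord]] = {}
    for r in recs:
        by_cc.setdefault((r.compound_id, r.condition), []).append(r)
    rows = []
    for (cid, cond), group in sorted(
        by_cc.items(), key=lambda kv: (kv[0][0], kv[0][1]._sort_key)
    ):
        detected = [r for r in group if r.detected]
        if not detected:
            continue
        query_rt = tables.mean_retention_time(detected)
        try:
            rf = models.closest_eluting_baseline(rf_train, query_rt, cond)
        except Exception:
            continue
        for r in sorted(detected, key=lambda r: r.dilution_factor):
            rows.append(_prediction_row("closest_eluting", r, rf))
    return pd.DataFrame(rows, columns=list(PREDICTION_COLUMNS))


def _prediction_row(
    method: str, r: tables.PeakRecord, rf_pred: float
) -> dict:
    return {
        "method": method,
        "compound_id": r.compound_id,
        "mode": r.condition.mode,
        "ph": r.condition.ph,
        "dilution_factor": r.dilution_factor,
        "area": r.area,
        "rf_pred": rf_pred,
        "c_predicted_M": quantify.estimate_concentration(r.area, rf_pred),
    }


def aggregate_prediction_ranges(pred: pd.DataFrame) -> pd.DataFrame:
    """Per (method, compound, dilution) concentration range over conditions."""
    rows = []
    for (method, cid, d), sub in pred.groupby(
        ["method", "compound_id", "dilution_factor"], sort=True
    ):
        est = quantify.aggregate_estimates(
            cid,
            {
                tables.ConditionKey(m, ph): c
                for m, ph, c in zip(sub["mode"], sub["ph"], sub["c_predicted_M"])
            },
        )
        rows.append(
            {
                "method": method,
                "compound_id": cid,
                "dilution_factor": d,
                "range_min_M": est.range_min,
                "range_median_M": est.range_median,
                "range_max_M": est.range_max,
                "n_conditions": len(est.per_condition),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "method", "compound_id", "dilution_factor",
            "range_min_M", "range_median_M", "range_max_M", "n_conditions",
        ],
    )


def evaluate_predictions(
    pred: pd.DataFrame,
    truth: Mapping[tuple[str, float], float],
    threshold: float = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score predictions against known concentrations.

    Returns (evaluation frame with one row per datapoint, summary frame
    with one row per method).
    """
    eval_rows = []
    for row in pred.itertuples(index=False):
        key = (row.compound_id, float(row.dilution_factor))
        if key not in truth:
            continue
        c_actual = truth[key]
        eval_rows.append(
            {
                "method": row.method,
                "compound_id": row.compound_id,
                "mode": row.mode,
                "ph": row.ph,
                "dilution_factor": row.dilution_factor,
                "c_predicted_M": row.c_predicted_M,
                "c_actual_M": c_actual,
                "fold_error": quantify.fold_error(row.c_predicted_M, c_actual),
            }
        )
    eval_df = pd.DataFrame(
        eval_rows,
        columns=[
            "method", "compound_id", "mode", "ph", "dilution_factor",
            "c_predicted_M", "c_actual_M", "fold_error",
        ],
    )
    summary_rows = []
    for method, sub in eval_df.groupby("method", sort=True):
        recs = [
            quantify.EvaluationRecord(
                compound_id=t.compound_id,
                condition=tables.ConditionKey(t.mode, float(t.ph)),
                c_predicted=t.c_predicted_M,
                c_actual=t.c_actual_M,
                fold_error=t.fold_error,
            )
            for t in sub.itertuples(index=False)
        ]
        s = quantify.summarize_errors(recs, threshold=threshold)
        summary_rows.append(
            {
                "method": method,
                "mean_fold": s.mean_fold,
                "median_fold": s.median_fold,
                "max_fold": s.max_fold,
                "frac_below_10": s.frac_below_10,
                "n": s.n,
            }
        )
    summary = pd.DataFrame(
        summary_rows,
        columns=["method", "mean_fold", "median_fold", "max_fold",
                 "frac_below_10", "n"],
    )
    return eval_df, summary


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Run the full chain, write all artifacts under ``config.out_dir``.

    Returns the per-method error summary (also written as summary.csv).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation_config()

    def _stage(name):
        logger.info("stage %s", name)
        return time.monotonic()

    t0 = _stage("simulate")
    profiles = simulate.simulate_compounds(sim)
    train_profiles = profiles[: config.n_train]
    test_profiles = profiles[config.n_train:]
    if not train_profiles or not test_profiles:
        raise ValidationError("n_train and n_test must both be >= 1")
    train_records, train_truth = simulate.simulate_feature_table(
        train_profiles, sim, sim.dilution_factors_train, rng_stream=1
    )
    test_records, test_truth = simulate.simulate_feature_table(
        test_profiles, sim, sim.dilution_factors_test, rng_stream=2
    )
    tables.write_feature_table(train_records, out / "train_features.csv")
    tables.write_feature_table(test_records, out / "test_features.csv")
    simulate.standards_frame(train_truth).to_csv(
        out / "train_standards.csv", index=False
    )
    simulate.standards_frame(test_truth).to_csv(
        out / "test_standards.csv", index=False
    )
    simulate.ground_truth_table(profiles).to_csv(
        out / "true_log_rf.csv", index=False
    )

    _stage("calibrate (%.1fs)" % (time.monotonic() - t0))
    train_merged = tables.merge_split_peaks(train_records)
    rf_train = calibration.build_training_table(train_merged, train_truth)
    tables.write_rf_table(rf_train, out / "rf_train.csv")

    t0 = _stage("featurize")
    desc_train = descriptors.build_descriptor_table(train_merged)
    test_merged = tables.merge_split_peaks(test_records)
    desc_test = descriptors.build_descriptor_table(test_merged)
    descriptors.write_descriptor_table(desc_train, out / "descriptors_train.csv")
    descriptors.write_descriptor_table(desc_test, out / "descriptors_test.csv")

    t0 = _stage("train")
    model_set = models.train_model_set(
        desc_train,
        rf_train,
        seed=config.seed,
        n_estimators=config.n_estimators,
        cv_folds=config.cv_folds,
    )
    models.save_model_set(model_set, out / "model_set.joblib")

    _stage("train done (%.1fs); predict" % (time.monotonic() - t0))
    pred = pd.concat(
        [
            predict_concentrations_model(model_set, desc_test, test_merged),
            predict_concentrations_equal_rf(rf_train, test_merged),
            predict_concentrations_closest(rf_train, test_merged),
        ],
        ignore_index=True,
    )
    pred.to_csv(out / "predictions.csv", index=False)
    aggregate_prediction_ranges(pred).to_csv(
        out / "prediction_ranges.csv", index=False
    )

    _stage("evaluate")
    eval_df, summary = evaluate_predictions(
        pred, test_truth, threshold=config.error_threshold
    )
    eval_df.to_csv(out / "evaluation.csv", index=False)
    summary.to_csv(out / "summary.csv", index=False)
    return summary
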