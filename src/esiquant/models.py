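"""Response-factor regressors and baselines.

One random-forest regressor per (polarity, mobile-phase pH) condition
predicts log10 RF from the 12 LC/MS descriptors; hyperparameters are tuned
by k-fold cross-validation over a small grid. Two formula-defined baselines
serve as references: the *equal-RF* baseline (geometric mean of the
training RFs) and the *closest-eluting* baseline (RF of the training
standard with the nearest mean retention time). A one-variable linear model
on the pH 8.0 positive/negative area ratio covers compounds ionizing in
both modes, and shallow regression trees provide an interpretable view of
what the forests learn.

Sentinel-coded descriptors (+-999) are passed to the trees untransformed:
values far outside the continuous range act as their own "missing" branch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance as _sk_permutation_importance
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.tree import DecisionTreeRegressor

from .descriptors import DESCRIPTOR_NAMES
from .errors import InsufficientDataError, UnavailableConditionError, ValidationError
from .tables import ConditionKey, ResponseFactorRecord, all_conditions

logger = logging.getLogger(__name__)

#: Minimum training compounds required to fit a per-condition model.
MIN_TRAINING_COMPOUNDS = 10

#: Trees per forest.
N_ESTIMATORS = 500

#: Cross-validation folds for hyperparameter tuning.
CV_FOLDS = 5

#: Hyperparameter grid: features considered per split, minimum leaf size.
DEFAULT_GRID: dict[str, list] = {
    "max_features": [4, 8, 12],
    "min_samples_leaf": [1, 3],
}

BUNDLE_FORMAT_VERSION = 1


@dataclass
class ModelSet:
    """Fitted per-condition regressors plus their tuning records."""

    models: dict[ConditionKey, RandomForestRegressor]
    hyperparameters: dict[ConditionKey, dict]
    training_ids: dict[ConditionKey, list[str]]
    seed: int

    def conditions(self) -> list[ConditionKey]:
        return sorted(self.models)


@dataclass(frozen=True, slots=True)
class SimplifiedLinearModel:
    """log10 RF_pos(pH 8.0) = intercept + slope * log10(pos/neg area ratio)."""

    intercept: float
    slope: float
    r_squared: float
    n_compounds: int

    def predict(self, ratio: float) -> float:
        return self.intercept + self.slope * ratio


def _training_frame(
    descriptor_table: pd.DataFrame,
    rf_records: Iterable[ResponseFactorRecord],
    condition: ConditionKey,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    rf_by_id = {
        r.compound_id: r.log_rf for r in rf_records if r.condition == condition
    }
    sub = descriptor_table[descriptor_table["compound_id"].isin(rf_by_id)]
    ids = sub["compound_id"].tolist()
    X = sub[list(DESCRIPTOR_NAMES)].to_numpy(dtype=float)
    y = np.array([rf_by_id[c] for c in ids], dtype=float)
    return X, y, ids


def _condition_seed(seed: int, condition: ConditionKey) -> int:
    idx = all_conditions().index(condition)
    return (seed * 7 + idx) % (2**31 - 1)


def train_model_set(
    descriptor_table: pd.DataFrame,
    rf_records: Iterable[ResponseFactorRecord],
    seed: int = 0,
    n_estimators: int = N_ESTIMATORS,
    cv_folds: int = CV_FOLDS,
    grid: Mapping[str, list] | None = None,
    min_training_compounds: int = MIN_TRAINING_COMPOUNDS,
) -> ModelSet:
    """Fit one forest per condition with enough training compounds.

    Conditions with fewer than ``min_training_compounds`` calibrated
    standards are skipped with a log message; if no condition is trainable
    an :class:`InsufficientDataError` is raised. Deterministic under
    ``seed``.
    """
    rf_records = list(rf_records)
    grid = dict(grid) if grid is not None else dict(DEFAULT_GRID)
    models: dict[ConditionKey, RandomForestRegressor] = {}
    hyper: dict[ConditionKey, dict] = {}
    train_ids: dict[ConditionKey, list[str]] = {}
    for condition in all_conditions():
        X, y, ids = _training_frame(descriptor_table, rf_records, condition)
        if len(ids) < min_training_compounds:
            if ids:
                logger.info(
                    "skip %s: %d training compounds (< %d)",
                    condition, len(ids), min_training_compounds,
                )
            continue
        cseed = _condition_seed(seed, condition)
        base = RandomForestRegressor(
            n_estimators=n_estimators, random_state=cseed, n_jobs=1
        )
        grid_here = {
            k: [v for v in vs if k != "max_features" or v <= X.shape[1]]
            for k, vs in grid.items()
        }
        search = GridSearchCV(
            base,
            grid_here,
            scoring="neg_mean_squared_error",
            cv=KFold(n_splits=min(cv_folds, len(ids)), shuffle=True,
                     random_state=cseed),
            n_jobs=1,
            refit=True,
        )
        search.fit(X, y)
        models[condition] = search.best_estimator_
        hyper[condition] = dict(search.best_params_)
        train_ids[condition] = ids
    if not models:
        raise InsufficientDataError("no condition had enough training compounds")
    return ModelSet(models=models, hyperparameters=hyper,
                    training_ids=train_ids, seed=seed)


def predict_log_rf(
    model_set: ModelSet,
    descriptors: Mapping[str, float] | pd.Series,
    condition: ConditionKey,
) -> float:
    """Predicted log10 RF for one compound under one condition."""
    if condition not in model_set.models:
        raise UnavailableConditionError(f"no model for {condition}")
    x = np.array([[float(descriptors[n]) for n in DESCRIPTOR_NAMES]])
    return float(model_set.models[condition].predict(x)[0])


def permutation_importance_report(
    model_set: ModelSet,
    descriptor_table: pd.DataFrame,
    rf_records: Iterable[ResponseFactorRecord],
    n_repeats: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean increase in squared error when each descriptor is permuted.

    Returns a long frame (mode, ph, descriptor, importance, rank) with 12
    rows per fitted model; rank 1 is the most important descriptor.
    """
    rf_records = list(rf_records)
    rows = []
    for condition in model_set.conditions():
        X, y, ids = _training_frame(descriptor_table, rf_records, condition)
        if not ids:
            continue
        result = _sk_permutation_importance(
            model_set.models[condition],
            X,
            y,
            scoring="neg_mean_squared_error",
            n_repeats=n_repeats,
            random_state=_condition_seed(seed, condition),
            n_jobs=1,
        )
        order = np.argsort(-result.importances_mean)
        rank = np.empty_like(order)
        rank[order] = np.arange(1, len(order) + 1)
        for j, name in enumerate(DESCRIPTOR_NAMES):
            rows.append(
                {
                    "mode": condition.mode,
                    "ph": condition.ph,
                    "descriptor": name,
                    "importance": float(result.importances_mean[j]),
                    "importance_se": float(
                        result.importances_std[j] / np.sqrt(n_repeats)
                    ),
                    "rank": int(rank[j]),
                }
            )
    return pd.DataFrame(
        rows, columns=["mode", "ph", "descriptor", "importance",
                       "importance_se", "rank"]
    )


# ---------------------------------------------------------------------------
# Baselines
# ---------------------------------------------------------------------------


def equal_rf_baseline(
    rf_records: Iterable[ResponseFactorRecord], condition: ConditionKey
) -> float:
    """Geometric-mean RF of the training standards in one condition (M^-1)."""
    logs = [r.log_rf for r in rf_records if r.condition == condition]
    if not logs:
        raise InsufficientDataError(f"no training RF for {condition}")
    return float(10.0 ** np.mean(logs))


def closest_eluting_baseline(
    rf_records: Iterable[ResponseFactorRecord],
    query_rt: float,
    condition: ConditionKey,
) -> float:
    """RF of the training standard with the nearest mean retention time.

    Ties break toward the earlier-eluting (smaller mean RT) standard.
    """
    candidates = [
        r for r in rf_records
        if r.condition == condition and np.isfinite(r.mean_rt)
    ]
    if not candidates:
        raise InsufficientDataError(f"no training RF with RT for {condition}")
    best = min(candidates, key=lambda r: (abs(r.mean_rt - query_rt), r.mean_rt))
    return float(best.rf)


def fit_simplified_linear(
    rf_records: Iterable[ResponseFactorRecord],
    descriptor_table: pd.DataFrame,
    ph: float = 8.0,
) -> SimplifiedLinearModel:
    """OLS of positive-mode log10 RF on the pos/neg area ratio at one pH.

    Only compounds detected in both modes at that pH (finite, non-sentinel
    ratio) enter the fit; requires at least three such compounds.
    """
    condition = ConditionKey("positive", ph)
    ratio_col = f"ratio_ph{str(ph).replace('.', '_')}"
    rf_by_id = {
        r.compound_id: r.log_rf for r in rf_records if r.condition == condition
    }
    sub = descriptor_table[descriptor_table["compound_id"].isin(rf_by_id)]
    ratios = sub[ratio_col].to_numpy(dtype=float)
    usable = np.abs(ratios) < 900.0
    if int(usable.sum()) < 3:
        raise InsufficientDataError(
            f"only {int(usable.sum())} compounds detected in both modes at pH {ph}"
        )
    x = ratios[usable]
    y = np.array(
        [rf_by_id[c] for c in sub["compound_id"].to_numpy()[usable]], dtype=float
    )
    res = stats.linregress(x, y)
    return SimplifiedLinearModel(
        intercept=float(res.intercept),
        slope=float(res.slope),
        r_squared=float(res.rvalue) ** 2,
        n_compounds=int(usable.sum()),
    )


# ---------------------------------------------------------------------------
# Interpretive regression trees
# ---------------------------------------------------------------------------


def fit_interpretive_tree(
    descriptor_table: pd.DataFrame,
    rf_records: Iterable[ResponseFactorRecord],
    condition: ConditionKey,
    max_depth: int = 3,
    seed: int = 0,
) -> dict:
    """A depth-limited regression tree as a nested, serializable dict.

    Internal nodes carry ``descriptor``, ``threshold``, ``left`` (<=) and
    ``right`` (>) subtrees; leaves carry ``value`` (mean log10 RF) and
    ``n`` (training compounds reaching the leaf).
    """
    X, y, ids = _training_frame(descriptor_table, list(rf_records), condition)
    if len(ids) < MIN_TRAINING_COMPOUNDS:
        raise InsufficientDataError(
            f"{condition}: {len(ids)} training compounds (< {MIN_TRAINING_COMPOUNDS})"
        )
    if max_depth < 0:
        raise ValidationError("max_depth must be >= 0")
    if max_depth == 0:
        return {"value": float(np.mean(y)), "n": len(ids)}
    tree = DecisionTreeRegressor(
        max_depth=max_depth, random_state=_condition_seed(seed, condition)
    ).fit(X, y)
    t = tree.tree_

    def node(i: int) -> dict:
        if t.children_left[i] == -1:
            return {"value": float(t.value[i][0][0]), "n": int(t.n_node_samples[i])}
        return {
            "descriptor": DESCRIPTOR_NAMES[t.feature[i]],
            "threshold": float(t.threshold[i]),
            "left": node(t.children_left[i]),
            "right": node(t.children_right[i]),
        }

    return node(0)


def render_tree(tree: dict, indent: str = "") -> str:
    """Plain-text rendering of a tree from :func:`fit_interpretive_tree`."""
    if "value" in tree:
        return f"{indent}-> log10 RF = {tree['value']:.3f} (n={tree['n']})\n"
    out = f"{indent}{tree['descriptor']} <= {tree['threshold']:.4g}?\n"
    out += render_tree(tree["left"], indent + "  ")
    out += f"{indent}{tree['descriptor']} > {tree['threshold']:.4g}?\n"
    out += render_tree(tree["right"], indent + "  ")
    return out


def predict_tree(tree: dict, descriptors: Mapping[str, float]) -> float:
    """Evaluate a serialized interpretive tree on one descriptor mapping."""
    while "value" not in tree:
        if float(descriptors[tree["descriptor"]]) <= tree["threshold"]:
            tree = tree["left"]
        else:
            tree = tree["right"]
    return float(tree["value"])


# ---------------------------------------------------------------------------
# Bundle serialization
# ---------------------------------------------------------------------------


def save_model_set(model_set: ModelSet, path: str | Path) -> None:
    """Serialize a fitted model set (versioned joblib archive)."""
    payload = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "seed": model_set.seed,
        "descriptor_names": DESCRIPTOR_NAMES,
        "conditions": [(c.mode, c.ph) for c in model_set.conditions()],
        "models": {(c.mode, c.ph): m for c, m in model_set.models.items()},
        "hyperparameters": {
            (c.mode, c.ph): h for c, h in model_set.hyperparameters.items()
        },
        "training_ids": {
            (c.mode, c.ph): ids for c, ids in model_set.training_ids.items()
        },
    }
    joblib.dump(payload, path)


def load_model_set(path: str | Path) -> ModelSet:
    payload = joblib.load(path)
    if payload.get("format_version") != BUNDLE_FORMAT_VERSION:
        raise ValidationError(
            f"unsupported bundle version {payload.get('format_version')!r}"
        )
    return ModelSet(
        models={ConditionKey(m, ph): v for (m, ph), v in payload["models"].items()},
        hyperparameters={
            ConditionKey(m, ph): v
            for (m, ph), v in payload["hyperparameters"].items()
        },
        training_ids={
            ConditionKey(m, ph): v for (m, ph), v in payload["training_ids"].items()
        },
        seed=payload["seed"],
    )
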