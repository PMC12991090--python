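"""Gradient-boosted decision-tree comparator on fixed per-read features.

The 122-dimensional feature vector per read: 19 percentiles of the read's
own methylation distribution, 84 Pearson correlations between the read's
methylation and each cell type's atlas values over shared sites, and 19
percentiles of per-CpG sample-rank values (each CpG's methylation ranked
against its site's stored sample percentiles).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import xgboost as xgb

from .classifier import Split, evaluate_auc
from .features import FeatureSet
from .types import N_ATLAS_CELL_TYPES, N_PERCENTILES, PERCENTILE_GRID

logger = logging.getLogger(__name__)

N_GBT_FEATURES = 2 * N_PERCENTILES + N_ATLAS_CELL_TYPES


def extract_gbt_features(fs: FeatureSet, rank_method: str = "strict") -> np.ndarray:
    """122-vector of fixed features; undefined entries are NaN (native to GBT).

    The sample rank of a CpG is the fraction of its site's 19 stored
    percentile values strictly below its methylation ("strict"), or the
    midrank variant counting ties as half ("midrank").
    """
    meth = fs.meth.astype(np.float64)
    own_pct = np.percentile(meth, PERCENTILE_GRID)

    atlas = fs.atlas.astype(np.float64)
    present = ~fs.atlas_missing
    corr = np.full(N_ATLAS_CELL_TYPES, np.nan)
    for j in range(atlas.shape[1]):
        m = present[:, j]
        if m.sum() < 2:
            continue
        x, y = meth[m], atlas[m, j]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        corr[j] = np.corrcoef(x, y)[0, 1]

    pct = fs.site_percentiles.astype(np.float64)
    below = (pct < meth[:, None]).sum(axis=1)
    if rank_method == "midrank":
        ties = np.isclose(pct, meth[:, None]).sum(axis=1)
        ranks = (below + 0.5 * ties) / N_PERCENTILES
    else:
        ranks = below / N_PERCENTILES
    rank_pct = np.percentile(ranks, PERCENTILE_GRID)
    return np.concatenate([own_pct, corr, rank_pct])


def feature_matrix(feature_sets: Sequence[FeatureSet], rank_method: str = "strict"):
    X = np.vstack([extract_gbt_features(fs, rank_method) for fs in feature_sets])
    y = np.array([fs.label if fs.label is not None else -1 for fs in feature_sets])
    return X, y


FULL_GRID = {
    "max_depth": [5, 7, 9, 11],
    "subsample": [0.25, 0.5, 0.6, 0.8, 1.0],
    "min_child_weight": [3, 5, 10, 25],
    "colsample_bytree": [0.25, 0.5, 0.75, 1.0],
}
LEARNING_RATE = 0.01
N_BOOST_ROUNDS = 15_000
EARLY_STOP_FRACTION = 0.1
EARLY_STOP_ROUNDS = 100


@dataclass
class GBTSweepResult:
    model: xgb.Booster
    best_params: dict
    validation_auc: float
    auc_table: list[tuple[dict, float]] = field(default_factory=list)


def sweep_and_train(
    train_sets: Sequence[FeatureSet],
    val_sets: Sequence[FeatureSet],
    seed: int = 0,
    desk_grid_size: Optional[int] = None,
    n_boost_rounds: int = N_BOOST_ROUNDS,
    rank_method: str = "strict",
) -> GBTSweepResult:
    """Hyperparameter sweep over the fixed grid, best model by validation AUC.

    A random 10% of the training reads is held out for boosting early
    stopping (seeded).  ``desk_grid_size`` subsamples the exhaustive grid
    for CPU-scale runs.
    """
    X_tr, y_tr = feature_matrix(train_sets, rank_method)
    X_va, y_va = feature_matrix(val_sets, rank_method)
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training set must contain both classes")
    rng = np.random.default_rng(seed)
    n = len(X_tr)
    es_idx = rng.choice(n, size=max(1, int(EARLY_STOP_FRACTION * n)), replace=False)
    es_mask = np.zeros(n, bool)
    es_mask[es_idx] = True
    if len(np.unique(y_tr[~es_mask])) < 2 or len(np.unique(y_tr[es_mask])) < 2:
        raise ValueError("early-stopping holdout lacks a class; too few reads")
    d_fit = xgb.DMatrix(X_tr[~es_mask], label=y_tr[~es_mask])
    d_es = xgb.DMatrix(X_tr[es_mask], label=y_tr[es_mask])
    d_val = xgb.DMatrix(X_va, label=y_va)

    combos = [dict(zip(FULL_GRID, vals)) for vals in itertools.product(*FULL_GRID.values())]
    if desk_grid_size is not None and desk_grid_size < len(combos):
        pick = rng.choice(len(combos), size=desk_grid_size, replace=False)
        combos = [combos[i] for i in sorted(pick)]

    best: Optional[GBTSweepResult] = None
    table = []
    for combo in combos:
        params = dict(
            objective="binary:logistic",
            eval_metric="auc",
            tree_method="hist",
            learning_rate=LEARNING_RATE,
            seed=seed,
            **combo,
        )
        booster = xgb.train(
            params,
            d_fit,
            num_boost_round=n_boost_rounds,
            evals=[(d_es, "stop")],
            early_stopping_rounds=EARLY_STOP_ROUNDS,
            verbose_eval=False,
        )
        val_auc = evaluate_auc(y_va, booster.predict(d_val, iteration_range=(0, booster.best_iteration + 1)))
        table.append((combo, val_auc))
        if best is None or val_auc > best.validation_auc:
            best = GBTSweepResult(booster, combo, val_auc)
    assert best is not None
    best.auc_table = table
    logger.info("best GBT params %s (val AUC %.4f)", best.best_params, best.validation_auc)
    return best


def predict(result: GBTSweepResult, feature_sets: Sequence[FeatureSet],
            rank_method: str = "strict") -> np.ndarray:
    X, _ = feature_matrix(feature_sets, rank_method)
    return result.model.predict(
        xgb.DMatrix(X), iteration_range=(0, result.model.best_iteration + 1)
    )


def train_on_split(
    feature_sets: Sequence[FeatureSet],
    seed: int = 0,
    desk_grid_size: Optional[int] = 8,
    n_boost_rounds: int = N_BOOST_ROUNDS,
    split: Optional[Split] = None,
):
    """Chromosome-held-out sweep; returns (result, parts)."""
    split = split or Split()
    parts = split.divide([fs for fs in feature_sets if fs.label is not None])
    result = sweep_and_train(
        parts["train"], parts["validation"], seed=seed,
        desk_grid_size=desk_grid_size, n_boost_rounds=n_boost_rounds,
    )
    return result, parts
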