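"""Random-forest ranking of markers by mean decrease Gini (MDG).

A 500-tree forest (bootstrap per tree, Gini splitting) scores every feature
by the sum of node-proportion-weighted Gini impurity decreases at the nodes
that split on it, averaged over trees.  The size of the random predictor
subset drawn at each node (mtry) is tuned by repeated stratified 10-fold
cross-validation over a neighbourhood of sqrt(p).  The forest itself is
scikit-learn's; this module fixes the defaults, the MDG normalization and
the deterministic tuning protocol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold

from .errors import ConfigurationError, DesignError


@dataclass
class ForestConfig:
    ntree: int = 500
    mtry: int | str = "tune"
    min_node_size: int = 1
    seed: int | None = None
    cv_folds: int = 10
    cv_repeats: int = 3
    mtry_grid: tuple | None = None   # default: floor(sqrt(p)) +/- 2, clipped to [1, p]

    def validate(self, n_features: int | None = None) -> None:
        if self.ntree < 1:
            raise ConfigurationError("ntree must be >= 1")
        if self.cv_folds < 2:
            raise ConfigurationError("cv_folds must be >= 2")
        if isinstance(self.mtry, int) and n_features is not None:
            if not 1 <= self.mtry <= n_features:
                raise ConfigurationError(
                    f"mtry must lie in [1, {n_features}], got {self.mtry}"
                )

    def grid(self, n_features: int) -> list:
        if self.mtry_grid is not None:
            vals = [m for m in self.mtry_grid if 1 <= m <= n_features]
            if not vals:
                raise ConfigurationError("mtry_grid has no value in [1, n_features]")
            return sorted(set(vals))
        center = int(math.floor(math.sqrt(n_features)))
        return sorted({min(max(center + d, 1), n_features) for d in range(-2, 3)})


@dataclass
class ForestImportance:
    mdg: pd.Series                   # per-feature mean decrease Gini
    mtry: int
    oob_error: float


def gini_impurity(counts) -> float:
    """Gini impurity 1 - sum(p_k^2) of a node with the given class counts."""
    counts = np.asarray(counts, float)
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts / total
    return float(1.0 - (p ** 2).sum())


def gini_decrease(parent_counts, left_counts, right_counts) -> float:
    """Impurity decrease of a split, weighted by child node proportions."""
    parent = np.asarray(parent_counts, float)
    left = np.asarray(left_counts, float)
    right = np.asarray(right_counts, float)
    n = parent.sum()
    return float(
        gini_impurity(parent)
        - left.sum() / n * gini_impurity(left)
        - right.sum() / n * gini_impurity(right)
    )


def _check_xy(x: np.ndarray, y: np.ndarray) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise DesignError("labels must be binary")
    if counts.min() < 2:
        raise DesignError("each class needs at least 2 samples")


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    arr = np.asarray(X, float)
    return pd.DataFrame(arr, columns=[f"f{j}" for j in range(arr.shape[1])])


def _tree_mdg(forest: RandomForestClassifier) -> np.ndarray:
    """Node-proportion-weighted Gini decreases summed per feature, per tree,
    averaged over the trees of the forest."""
    total = np.zeros(forest.n_features_in_)
    for est in forest.estimators_:
        total += est.tree_.compute_feature_importances(normalize=False)
    return total / len(forest.estimators_)


def grow_forest(X, y, config: ForestConfig | None = None) -> tuple[RandomForestClassifier, ForestImportance]:
    """Fit the forest and return it with per-feature MDG and the OOB error."""
    config = config or ForestConfig()
    xdf = _as_frame(X)
    y = np.asarray(y)
    _check_xy(xdf.to_numpy(), y)
    config.validate(n_features=xdf.shape[1])

    if config.mtry == "tune":
        mtry, _table = tune_mtry(xdf, y, config)
    else:
        mtry = int(config.mtry)
        if not 1 <= mtry <= xdf.shape[1]:
            raise ConfigurationError(f"mtry must lie in [1, {xdf.shape[1]}], got {mtry}")

    forest = RandomForestClassifier(
        n_estimators=config.ntree,
        criterion="gini",
        max_features=mtry,
        min_samples_leaf=config.min_node_size,
        bootstrap=True,
        oob_score=True,
        random_state=_seed_int(config.seed),
        n_jobs=1,
    )
    forest.fit(xdf.to_numpy(), y)
    importance = ForestImportance(
        mdg=pd.Series(_tree_mdg(forest), index=xdf.columns, name="mdg"),
        mtry=mtry,
        oob_error=float(1.0 - forest.oob_score_),
    )
    return forest, importance


def _seed_int(seed) -> int | None:
    if seed is None:
        return None
    return int(seed) % (2 ** 31)


def tune_mtry(X, y, config: ForestConfig | None = None) -> tuple[int, pd.DataFrame]:
    """Choose mtry by repeated stratified k-fold CV accuracy (ties -> smallest).

    Returns the chosen value and the per-fold accuracy table.  When the
    smaller class has fewer members than ``cv_folds`` the fold count degrades
    to that class size (as-even-as-possible folds).
    """
    config = config or ForestConfig()
    xdf = _as_frame(X)
    y = np.asarray(y)
    _check_xy(xdf.to_numpy(), y)
    grid = config.grid(xdf.shape[1])

    min_class = int(np.unique(y, return_counts=True)[1].min())
    n_splits = min(config.cv_folds, min_class)
    if n_splits < 2:
        raise DesignError("smallest class too small for cross-validation")
    cv = RepeatedStratifiedKFold(n_splits=n_splits, n_repeats=config.cv_repeats,
                                 random_state=_seed_int(config.seed))
    splits = list(cv.split(xdf.to_numpy(), y))

    xarr = xdf.to_numpy()
    rows = []
    for mtry in grid:
        for fold_id, (train, test) in enumerate(splits):
            clf = RandomForestClassifier(
                n_estimators=config.ntree, criterion="gini", max_features=mtry,
                min_samples_leaf=config.min_node_size, bootstrap=True,
                random_state=_seed_int(config.seed), n_jobs=1,
            )
            clf.fit(xarr[train], y[train])
            acc = float((clf.predict(xarr[test]) == y[test]).mean())
            rows.append({"mtry": mtry, "fold": fold_id, "accuracy": acc})
    table = pd.DataFrame(rows)
    means = table.groupby("mtry")["accuracy"].mean()
    chosen = int(min(m for m in grid if means[m] == means.max()))
    return chosen, table


def rank_importance(importance: ForestImportance, top_k: int = 15) -> pd.DataFrame:
    """Features sorted by MDG descending (ties by probe id); top_k rows."""
    if importance.mdg.empty:
        raise ConfigurationError("importance table is empty")
    frame = importance.mdg.rename("mdg").rename_axis("probe_id").reset_index()
    frame = frame.sort_values(["mdg", "probe_id"], ascending=[False, True],
                              kind="mergesort").reset_index(drop=True)
    frame["rank"] = np.arange(1, len(frame) + 1)
    return frame.head(top_k)
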