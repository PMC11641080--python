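"""Multiclass random forest integrating biomarkers with covariates.

Protocol: stratified 70/30 split (per class, ceil(0.7·n) into
training), a 1000-tree forest with nodesize 1, mtry tuned over 1…20 by
out-of-bag accuracy, per-sample vote vectors normalized by the number
of trees, and multi-indicator feature importance (permutation
importance, impurity decrease, minimal depth, times-a-root).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from .constants import TREATMENT_CLASSES

logger = logging.getLogger(__name__)


@dataclass
class RFConfig:
    """Forest and split protocol parameters."""

    ntree: int = 1000
    nodesize: int = 1
    mtry_grid: tuple = tuple(range(1, 21))
    train_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if min(self.mtry_grid) < 1:
            raise ValueError("mtry grid must start at >= 1")


def stratified_split(
    labels, fraction: float = 0.7, seed: int = 0
) -> tuple[list, list]:
    """Per-class ceil(fraction·n) training split, remainder test.

    Sampling is without replacement within each class; the split is
    reproducible given the seed.  Raises if the test set is empty.
    """
    y = pd.Series(labels)
    rng = np.random.default_rng(seed)
    train_idx: list = []
    for cls in sorted(y.unique(), key=str):
        members = list(y.index[y == cls])
        if not members:
            raise ValueError(f"class {cls!r} is empty")
        k = int(np.ceil(fraction * len(members)))
        chosen = rng.choice(len(members), size=k, replace=False)
        train_idx.extend(members[i] for i in sorted(chosen))
    test_idx = [i for i in y.index if i not in set(train_idx)]
    if not test_idx:
        raise ValueError("split leaves an empty test set")
    return train_idx, test_idx


def encode_covariates(cohort: pd.DataFrame) -> pd.DataFrame:
    """Sex and the five ATC treatment classes as a 6-column binary block."""
    required = ["sex", *TREATMENT_CLASSES]
    missing = [c for c in required if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort missing columns: {missing}")
    bad = ~cohort["sex"].isin(["M", "F"])
    if bad.any():
        raise ValueError(
            f"unknown sex category for samples: {list(cohort.index[bad])[:5]}"
        )
    out = pd.DataFrame(index=cohort.index)
    out["sex_male"] = (cohort["sex"] == "M").astype(int)
    for t in TREATMENT_CLASSES:
        vals = cohort[t]
        if not vals.isin([0, 1, True, False]).all():
            bad_samples = list(cohort.index[~vals.isin([0, 1, True, False])])
            raise ValueError(f"non-binary treatment flag {t!r} for {bad_samples[:5]}")
        out[t] = vals.astype(int)
    return out


@dataclass
class RFModel:
    """A tuned forest with its schema and tuning trace."""

    forest: RandomForestClassifier
    feature_names: list
    classes: list
    chosen_mtry: int
    oob_accuracy: dict[int, float]
    train_medians: pd.Series = field(default=None, repr=False)


def _impute(X: pd.DataFrame, medians: pd.Series) -> np.ndarray:
    Xv = X[medians.index].to_numpy(dtype=float)
    fill = medians.to_numpy(dtype=float)
    nan = np.isnan(Xv)
    if nan.any():
        Xv[nan] = np.broadcast_to(fill, Xv.shape)[nan]
    return Xv


def train_rf(features: pd.DataFrame, labels, config: RFConfig | None = None) -> RFModel:
    """Fit the forest, tuning mtry by out-of-bag accuracy.

    For each mtry in the grid (capped at the feature count) a
    ``ntree``-tree forest with ``nodesize`` minimum leaf size is fitted
    with bootstrap sampling; the mtry maximizing OOB accuracy is chosen
    (ties go to the smallest).  Missing values are imputed with
    training-set medians (logged).
    """
    config = config or RFConfig()
    y = pd.Series(labels, index=features.index) if not isinstance(labels, pd.Series) else labels
    if y.nunique() < 2:
        raise ValueError("training data must contain >= 2 classes")
    medians = features.median(axis=0, skipna=True)
    n_missing = int(features.isna().sum().sum())
    if n_missing:
        logger.info("imputed %d missing feature values with training medians", n_missing)
    X = _impute(features, medians)

    grid = [m for m in config.mtry_grid if m <= X.shape[1]]
    if not grid:
        grid = [X.shape[1]]
    oob: dict[int, float] = {}
    models: dict[int, RandomForestClassifier] = {}
    for m in grid:
        forest = RandomForestClassifier(
            n_estimators=config.ntree,
            min_samples_leaf=config.nodesize,
            max_features=m,
            bootstrap=True,
            oob_score=True,
            random_state=config.seed,
            n_jobs=1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # small classes may miss OOB coverage
            forest.fit(X, y.to_numpy())
        oob[m] = float(forest.oob_score_)
        models[m] = forest
    best = max(oob, key=lambda m: (oob[m], -m))
    logger.info("chosen mtry=%d (OOB accuracy %.3f)", best, oob[best])
    return RFModel(
        forest=models[best],
        feature_names=list(medians.index),
        classes=list(models[best].classes_),
        chosen_mtry=best,
        oob_accuracy=oob,
        train_medians=medians,
    )


def predict_votes(model: RFModel, X: pd.DataFrame) -> pd.DataFrame:
    """Per-sample class-vote vectors (tree votes / number of trees).

    Columns follow the model's class order; each row sums to 1.
    Raises if feature columns do not match the training schema.
    """
    missing = [c for c in model.feature_names if c not in X.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    votes = model.forest.predict_proba(_impute(X, model.train_medians))
    out = pd.DataFrame(votes, index=X.index, columns=model.classes)
    return out


def predicted_classes(votes: pd.DataFrame) -> pd.Series:
    return votes.idxmax(axis=1)


def evaluate_multiclass(
    predictions, truth
) -> tuple[pd.DataFrame, float, pd.DataFrame]:
    """Confusion matrix, accuracy and one-vs-rest Se/Sp per class."""
    pred = pd.Series(predictions)
    true = pd.Series(truth)
    if len(pred) != len(true):
        raise ValueError("predictions and truth differ in length")
    classes = sorted(set(true.unique()), key=str)
    unknown = set(pred.unique()) - set(classes)
    if unknown:
        raise ValueError(f"predicted labels outside truth set: {sorted(unknown)}")
    conf = pd.crosstab(true.to_numpy(), pred.to_numpy()).reindex(
        index=classes, columns=classes, fill_value=0
    )
    conf.index.name = "truth"
    conf.columns.name = "predicted"
    total = conf.to_numpy().sum()
    accuracy = float(np.trace(conf.to_numpy()) / total)
    rows = {}
    for cls in classes:
        tp = conf.loc[cls, cls]
        fn = conf.loc[cls].sum() - tp
        fp = conf[cls].sum() - tp
        tn = total - tp - fn - fp
        rows[cls] = {
            "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
            "specificity": tn / (tn + fp) if tn + fp else np.nan,
        }
    return conf, accuracy, pd.DataFrame.from_dict(rows, orient="index")


def _tree_depth_stats(tree, n_features: int) -> tuple[np.ndarray, int, int]:
    """(min depth per feature, tree max depth, root feature or −1)."""
    feat = tree.feature
    left, right = tree.children_left, tree.children_right
    min_depth = np.full(n_features, np.inf)
    max_depth = 0
    stack = [(0, 0)]
    while stack:
        node, depth = stack.pop()
        max_depth = max(max_depth, depth)
        f = feat[node]
        if f >= 0:
            min_depth[f] = min(min_depth[f], depth)
            stack.append((left[node], depth + 1))
            stack.append((right[node], depth + 1))
    root_feature = int(feat[0]) if feat[0] >= 0 else -1
    return min_depth, max_depth, root_feature


def feature_importance(
    model: RFModel,
    X_test: pd.DataFrame,
    y_test,
    n_repeats: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Multi-indicator importance table.

    Columns: permutation importance (mean accuracy drop on the test
    data), impurity decrease (mean decrease in Gini), mean minimal
    depth over trees (features absent from a tree are penalised with
    that tree's depth + 1) and times-a-root counts.
    """
    Xv = _impute(X_test, model.train_medians)
    y = pd.Series(y_test).to_numpy()
    perm = permutation_importance(
        model.forest, Xv, y, n_repeats=n_repeats, random_state=seed, n_jobs=1
    ).importances_mean
    impurity = model.forest.feature_importances_
    p = len(model.feature_names)
    depth_sum = np.zeros(p)
    root_count = np.zeros(p, dtype=int)
    for est in model.forest.estimators_:
        min_depth, max_depth, root = _tree_depth_stats(est.tree_, p)
        min_depth[~np.isfinite(min_depth)] = max_depth + 1
        depth_sum += min_depth
        if root >= 0:
            root_count[root] += 1
    table = pd.DataFrame(
        {
            "permutation_importance": perm,
            "impurity_decrease": impurity,
            "mean_min_depth": depth_sum / len(model.forest.estimators_),
            "times_a_root": root_count,
        },
        index=pd.Index(model.feature_names, name="feature"),
    )
    return table
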