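"""Two-layer random-forest classification of MCI vs NC.

Layer 1 ranks the 124 features (4 cognitive scores, 4 global metrics and
116 nodal betweenness values at one sparsity) by out-of-bag permutation
importance; layer 2 trains on the top N features inside a stratified
10-fold-outer / 5-fold-inner nested cross-validation that tunes the
number of trees and the maximum depth, reporting pooled accuracy,
sensitivity, specificity and AUC.

By default the layer-1 ranking is recomputed inside every outer training
fold, so feature selection never sees the held-out subjects.  The
``global_ranking`` flag switches to a single global ranking computed on the
full table before the CV, the optimistically biased variant some studies
describe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

SCORE_COLUMNS = ("ADAS13", "CDRSB", "MMSE", "FAQ")
GLOBAL_COLUMNS = ("C", "L", "GE", "SW")


def feature_columns(n_rois: int = 116) -> list[str]:
    return list(SCORE_COLUMNS) + list(GLOBAL_COLUMNS) + [f"bc_{i + 1}" for i in range(n_rois)]


DEFAULT_N_ESTIMATORS_GRID = (100, 200, 500)
DEFAULT_MAX_DEPTH_GRID = (2, 3, 5, None)


@dataclass
class FeatureTable:
    """Subjects x 124 features at one sparsity, plus group labels."""

    features: pd.DataFrame
    labels: np.ndarray  # 1 = MCI (positive class), 0 = NC
    sparsity: float | None = None

    def __post_init__(self) -> None:
        expected = feature_columns(len([c for c in self.features.columns if c.startswith("bc_")]))
        if list(self.features.columns) != expected:
            raise ValueError("feature columns must be scores, globals, then bc_1..bc_N in order")
        if self.features.isna().any().any():
            raise ValueError("feature table contains missing values")
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape[0] != len(self.features):
            raise ValueError("labels length mismatch")
        if np.unique(self.labels).size < 2:
            raise ValueError("both classes must be present")

    @property
    def n_features(self) -> int:
        return self.features.shape[1]


@dataclass
class FoldResult:
    fold: int
    test_index: np.ndarray
    selected_features: list[str]
    n_estimators: int
    max_depth: int | None
    accuracy: float


@dataclass
class CVReport:
    sparsity: float | None
    top_n: int | None
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    folds: list[FoldResult]
    ranking: list[tuple[str, float]] = field(default_factory=list)
    seed: int = 0

    def summary(self) -> dict:
        return {
            "sparsity": self.sparsity,
            "top_n": self.top_n,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
        }


def build_feature_table(
    meta: pd.DataFrame,
    global_metrics: pd.DataFrame,
    nodal_bc: pd.DataFrame,
    sparsity: float,
) -> FeatureTable:
    """Assemble the per-subject feature table at one sparsity.

    ``meta``: subject_id, group and the four scores; ``global_metrics``:
    subject_id, C, L, GE, SW; ``nodal_bc``: subject_id, bc_1..bc_N (raw
    per-subject betweenness on individual networks).
    """
    merged = meta.merge(global_metrics, on="subject_id", how="left").merge(
        nodal_bc, on="subject_id", how="left"
    )
    cols = feature_columns(sum(c.startswith("bc_") for c in nodal_bc.columns))
    missing = merged[cols].isna().any(axis=1)
    if missing.any():
        bad = merged.loc[missing, "subject_id"].tolist()
        raise ValueError(f"missing metrics for subject(s): {bad}")
    labels = (merged["group"] == "MCI").astype(int).to_numpy()
    return FeatureTable(
        features=merged[cols].reset_index(drop=True), labels=labels, sparsity=sparsity
    )


# --- layer 1: feature ranking --------------------------------------------


def _oob_indices(tree_random_state: int, n_samples: int) -> np.ndarray:
    """Out-of-bag row indices of one forest member.

    Reproduces scikit-learn's bootstrap draw: a RandomState seeded with
    the tree's random_state drawing n_samples integers with replacement.
    Verified against ``oob_decision_function_`` in the test suite.
    """
    rs = np.random.RandomState(tree_random_state)
    sampled = rs.randint(0, n_samples, n_samples)
    mask = np.ones(n_samples, dtype=bool)
    mask[sampled] = False
    return np.flatnonzero(mask)


def oob_permutation_importance(
    forest: RandomForestClassifier, x: np.ndarray, y: np.ndarray, seed: int
) -> np.ndarray:
    """Mean OOB error increase per feature when that feature is permuted.

    For each tree the OOB rows are recovered, every feature column is
    permuted in turn (one draw per tree and feature) and the tree's OOB
    misclassification increase is averaged over trees.
    """
    n, n_feat = x.shape
    rng = np.random.default_rng(seed)
    importance = np.zeros(n_feat)
    used = 0
    for tree in forest.estimators_:
        oob = _oob_indices(tree.random_state, n)
        if oob.size < 2:
            continue
        xo = x[oob]
        yo = y[oob]
        base_err = np.mean(tree.predict(xo) != yo)
        stacked = np.repeat(xo[None, :, :], n_feat, axis=0)
        for f in range(n_feat):
            stacked[f, :, f] = xo[rng.permutation(oob.size), f]
        preds = tree.predict(stacked.reshape(n_feat * oob.size, n_feat))
        errs = (preds.reshape(n_feat, oob.size) != yo[None, :]).mean(axis=1)
        importance += errs - base_err
        used += 1
    if used == 0:
        raise ValueError("no tree had out-of-bag samples")
    return importance / used


def rank_features_layer1(
    table: FeatureTable,
    seed: int = 0,
    n_estimators: int = 500,
    importance: str = "permutation_oob",
    rows: np.ndarray | None = None,
    columns: list[str] | None = None,
) -> list[tuple[str, float]]:
    """Rank features by decreasing random-forest importance.

    ``importance`` is "permutation_oob" (default) or "impurity"; ties are
    broken by column order, so the ranking is deterministic given the
    seed.
    """
    cols = columns if columns is not None else list(table.features.columns)
    x = table.features[cols].to_numpy(float)
    y = table.labels
    if rows is not None:
        x, y = x[rows], y[rows]
    if np.unique(y).size < 2:
        raise ValueError("single-class input")
    forest = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, oob_score=False, bootstrap=True
    )
    forest.fit(x, y)
    if importance == "impurity":
        scores = forest.feature_importances_
    elif importance == "permutation_oob":
        scores = oob_permutation_importance(forest, x, y, seed=seed + 1)
    else:
        raise ValueError(f"unknown importance method {importance!r}")
    order = np.lexsort((np.arange(len(cols)), -scores))
    return [(cols[i], float(scores[i])) for i in order]


# --- layer 2: nested cross-validation ------------------------------------


def _grid_search(
    x: np.ndarray,
    y: np.ndarray,
    seed: int,
    n_estimators_grid: tuple[int, ...],
    max_depth_grid: tuple[int | None, ...],
    inner_folds: int,
) -> tuple[int, int | None]:
    """Best (n_estimators, max_depth) by mean inner-CV accuracy; ties go
    to the earlier grid entry (fewer trees, shallower)."""
    inner = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    splits = list(inner.split(x, y))
    best = (-np.inf, None)
    for ne in n_estimators_grid:
        for md in max_depth_grid:
            accs = []
            for tr, te in splits:
                clf = RandomForestClassifier(n_estimators=ne, max_depth=md, random_state=seed)
                clf.fit(x[tr], y[tr])
                accs.append(np.mean(clf.predict(x[te]) == y[te]))
            mean_acc = float(np.mean(accs))
            if mean_acc > best[0]:
                best = (mean_acc, (ne, md))
    return best[1]


def nested_cv(
    table: FeatureTable,
    top_n: int | None,
    seed: int = 0,
    outer_folds: int = 10,
    inner_folds: int = 5,
    n_estimators_grid: tuple[int, ...] = DEFAULT_N_ESTIMATORS_GRID,
    max_depth_grid: tuple[int | None, ...] = DEFAULT_MAX_DEPTH_GRID,
    global_ranking: bool = False,
    ranking_n_estimators: int = 500,
    importance: str = "permutation_oob",
    feature_subset: list[str] | None = None,
    report_ranking: bool = True,
    outer_splits: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> CVReport:
    """Stratified nested CV of the two-layer forest.

    ``top_n=None`` (or a subset covering all columns) disables layer-1
    selection.  With selection enabled the ranking is recomputed on each
    outer training fold unless ``global_ranking`` is set.
    """
    cols = feature_subset if feature_subset is not None else list(table.features.columns)
    x_all = table.features[cols].to_numpy(float)
    y_all = table.labels
    n = y_all.size
    if n < 20:
        raise ValueError("need at least 20 subjects for a 10-fold nested CV")
    if top_n is not None and not (1 <= top_n <= len(cols)):
        raise ValueError("top_n out of range")
    select = top_n is not None and top_n < len(cols)

    shared_ranking: list[tuple[str, float]] | None = None
    if select and global_ranking:
        shared_ranking = rank_features_layer1(
            table, seed=seed + 11, n_estimators=ranking_n_estimators,
            importance=importance, columns=cols,
        )

    if outer_splits is None:
        outer = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=seed)
        class_counts = np.bincount(y_all)
        if class_counts.min() < outer_folds:
            raise ValueError("stratification failure: a class has fewer members than outer folds")
        outer_splits = list(outer.split(x_all, y_all))

    pooled_pred = np.empty(n, dtype=int)
    pooled_proba = np.empty(n, dtype=float)
    folds: list[FoldResult] = []
    for f, (tr, te) in enumerate(outer_splits):
        if select:
            if global_ranking:
                ranking = shared_ranking
            else:
                ranking = rank_features_layer1(
                    table, seed=seed + 100 + f, n_estimators=ranking_n_estimators,
                    importance=importance, rows=tr, columns=cols,
                )
            selected = [name for name, _ in ranking[:top_n]]
        else:
            selected = list(cols)
        sel_idx = [cols.index(c) for c in selected]
        x_tr, x_te = x_all[np.ix_(tr, sel_idx)], x_all[np.ix_(te, sel_idx)]
        ne, md = _grid_search(
            x_tr, y_all[tr], seed + 200 + f, n_estimators_grid, max_depth_grid, inner_folds
        )
        clf = RandomForestClassifier(n_estimators=ne, max_depth=md, random_state=seed + 300 + f)
        clf.fit(x_tr, y_all[tr])
        pooled_pred[te] = clf.predict(x_te)
        pooled_proba[te] = clf.predict_proba(x_te)[:, list(clf.classes_).index(1)]
        folds.append(
            FoldResult(
                fold=f,
                test_index=te,
                selected_features=selected,
                n_estimators=ne,
                max_depth=md,
                accuracy=float(np.mean(pooled_pred[te] == y_all[te])),
            )
        )

    tp = int(np.sum((pooled_pred == 1) & (y_all == 1)))
    tn = int(np.sum((pooled_pred == 0) & (y_all == 0)))
    fp = int(np.sum((pooled_pred == 1) & (y_all == 0)))
    fn = int(np.sum((pooled_pred == 0) & (y_all == 1)))
    ranking_out: list[tuple[str, float]] = []
    if report_ranking and select:
        ranking_out = shared_ranking if global_ranking else rank_features_layer1(
            table, seed=seed + 11, n_estimators=ranking_n_estimators,
            importance=importance, columns=cols,
        )
    return CVReport(
        sparsity=table.sparsity,
        top_n=top_n,
        accuracy=(tp + tn) / n,
        sensitivity=tp / max(1, tp + fn),
        specificity=tn / max(1, tn + fp),
        auc=float(roc_auc_score(y_all, pooled_proba)),
        folds=folds,
        ranking=ranking_out,
        seed=seed,
    )


def sweep_top_n(
    table: FeatureTable,
    n_values: range | list[int] = range(5, 31),
    seed: int = 0,
    **cv_kwargs,
) -> tuple[list[CVReport], CVReport]:
    """One nested CV per candidate N; best N by accuracy, ties to smaller N."""
    reports = [nested_cv(table, top_n=int(n), seed=seed, **cv_kwargs) for n in n_values]
    best = max(reports, key=lambda r: (r.accuracy, -r.top_n))
    return reports, best


def compare_scores_only(table: FeatureTable, seed: int = 0, **cv_kwargs) -> CVReport:
    """Nested CV on the four cognitive scores alone (no layer-1 selection)."""
    return nested_cv(
        table, top_n=None, seed=seed, feature_subset=list(SCORE_COLUMNS), **cv_kwargs
    )
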