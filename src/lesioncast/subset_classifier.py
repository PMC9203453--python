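"""Predicting a subject's lesion subset from non-imaging features alone.

Pipeline: drop features with excessive missingness (median-impute the rest),
keep features with a significant subset effect (Kruskal-Wallis), project the
survivors onto the minimal set of principal components explaining >= 95% of
the variance of the standardized features, and fit a random forest whose
hyperparameters are tuned to maximize the multiclass Matthews correlation
coefficient (ties broken by correct rate) over repeated stratified 75/25
resampling with threefold cross-validation on each training side.

Once fitted, the classifier assigns new subjects to subset 1/2/3 from their
clinical-test scores only — no imaging input is required.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.preprocessing import StandardScaler

__all__ = [
    "drop_sparse_features",
    "screen_features_kw",
    "reduce_dimensions",
    "DimReduction",
    "multiclass_mcc",
    "fit_subset_classifier",
    "predict_subset",
    "SubsetClassifier",
    "fit_subset_pipeline",
]

DEFAULT_GRID: dict[str, Sequence] = {
    "n_estimators": (100, 300),
    "max_depth": (None, 5, 10),
    "max_features": ("sqrt", None),
}


def drop_sparse_features(
    table: pd.DataFrame, max_missing_fraction: float = 0.2
) -> tuple[pd.DataFrame, list[str], pd.Series]:
    """Remove features missing in more than ``max_missing_fraction`` of subjects.

    The surviving features have their remaining missing values replaced by
    the per-feature median.  Returns ``(imputed_table, dropped_names,
    medians)``; the medians are needed to impute new subjects consistently.
    """
    if table.empty:
        raise ValueError("feature table is empty")
    frac = table.isna().mean(axis=0)
    dropped = list(frac.index[frac > max_missing_fraction])
    kept = table.drop(columns=dropped)
    if kept.shape[1] == 0:
        raise ValueError("all features dropped by missingness filter")
    medians = kept.median(axis=0)
    return kept.fillna(medians), dropped, medians


def screen_features_kw(
    table: pd.DataFrame, labels: Sequence[int], alpha: float = 0.05
) -> pd.DataFrame:
    """Keep features whose Kruskal-Wallis p across the subsets is below alpha."""
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) < 2 or min((labels == g).sum() for g in groups) < 2:
        raise ValueError("need >=2 groups with >=2 members each")
    keep = []
    for col in table.columns:
        vals = table[col].to_numpy(dtype=float)
        samples = [vals[labels == g] for g in groups]
        pooled = np.concatenate(samples)
        if np.all(pooled == pooled[0]):
            continue  # constant feature: H = 0, p = 1
        _, p = stats.kruskal(*samples)
        if p < alpha:
            keep.append(col)
    return table[keep]


@dataclass
class DimReduction:
    """Standardization + PCA projection retaining a variance target."""

    feature_names: list[str]
    scaler: StandardScaler
    pca: PCA
    n_components: int
    variance_target: float

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        x = self.scaler.transform(table[self.feature_names].to_numpy(dtype=float))
        return self.pca.transform(x)[:, : self.n_components]


def reduce_dimensions(
    table: pd.DataFrame, variance_target: float = 0.95
) -> tuple[np.ndarray, DimReduction]:
    """Standardize features and keep the minimal PCs reaching the variance target.

    Returns the component scores for the fitted subjects and the fitted
    reduction (reusable on new subjects).
    """
    if table.shape[1] < 2 or table.shape[0] < 2:
        raise ValueError("need at least 2 features and 2 subjects")
    x = table.to_numpy(dtype=float)
    if np.all(x.std(axis=0) == 0):
        raise ValueError("all features have zero variance")
    scaler = StandardScaler().fit(x)
    xs = scaler.transform(x)
    pca = PCA(svd_solver="full").fit(xs)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    n_comp = min(n_comp, len(cum))
    red = DimReduction(
        feature_names=list(table.columns),
        scaler=scaler,
        pca=pca,
        n_components=n_comp,
        variance_target=variance_target,
    )
    return pca.transform(xs)[:, :n_comp], red


def multiclass_mcc(confusion: np.ndarray) -> float:
    """Generalized (multiclass) Matthews correlation coefficient from a k x k
    confusion matrix (rows = truth, columns = prediction).

    Uses the covariance form: MCC = (c*s - sum_k t_k p_k) /
    sqrt((s^2 - sum p_k^2)(s^2 - sum t_k^2)) where c = trace, s = total,
    t = row sums, p = column sums.  Returns 0 when a marginal is degenerate
    (all truth or all predictions in one class).
    """
    m = np.asarray(confusion, dtype=float)
    if m.size == 0 or m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("confusion matrix must be a nonempty square matrix")
    if np.any(m < 0):
        raise ValueError("confusion counts must be nonnegative")
    s = m.sum()
    c = np.trace(m)
    t = m.sum(axis=1)  # true class totals
    p = m.sum(axis=0)  # predicted class totals
    denom2 = (s**2 - (p**2).sum()) * (s**2 - (t**2).sum())
    if denom2 <= 0:
        return 0.0
    return float((c * s - (t * p).sum()) / math.sqrt(denom2))


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, classes: np.ndarray) -> np.ndarray:
    k = len(classes)
    idx = {c: i for i, c in enumerate(classes)}
    m = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true, y_pred):
        m[idx[t], idx[p]] += 1
    return m


@dataclass
class SubsetClassifier:
    """A fitted subset classifier with its preprocessing state and tuning record."""

    dropped_features: list[str]
    medians: pd.Series
    screened_features: list[str]
    reduction: DimReduction
    forest: RandomForestClassifier
    best_params: dict
    tuning_record: pd.DataFrame
    seed: int

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return predict_subset(self, table)


def fit_subset_classifier(
    scores: np.ndarray,
    labels: Sequence[int],
    seed: int = 0,
    grid: dict[str, Sequence] | None = None,
    n_resamples: int = 100,
    train_fraction: float = 0.75,
    inner_folds: int = 3,
) -> tuple[RandomForestClassifier, dict, pd.DataFrame]:
    """Tune and fit a random forest on component scores.

    For every hyperparameter candidate, ``n_resamples`` stratified
    ``train_fraction`` splits are drawn; the training side of each is
    evaluated by ``inner_folds``-fold stratified cross-validation.  Candidate
    quality is the mean multiclass MCC over all validation folds, with ties
    broken by the mean correct rate.  The winner is refit on all data.

    Returns ``(forest, best_params, tuning_record)``.
    """
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 3:
        raise ValueError("need at least 3 classes present")
    grid = dict(grid) if grid is not None else dict(DEFAULT_GRID)
    keys = list(grid)
    candidates = [dict(zip(keys, combo)) for combo in product(*(grid[k] for k in keys))]

    records = []
    for ci, params in enumerate(candidates):
        mccs, accs = [], []
        splitter = StratifiedShuffleSplit(
            n_splits=n_resamples, train_size=train_fraction, random_state=seed
        )
        for tr_idx, _ in splitter.split(scores, y):
            x_tr, y_tr = scores[tr_idx], y[tr_idx]
            cv = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
            for fit_idx, val_idx in cv.split(x_tr, y_tr):
                rf = RandomForestClassifier(random_state=seed, **params)
                rf.fit(x_tr[fit_idx], y_tr[fit_idx])
                pred = rf.predict(x_tr[val_idx])
                m = _confusion(y_tr[val_idx], pred, classes)
                mccs.append(multiclass_mcc(m))
                accs.append(float(np.trace(m)) / m.sum())
        records.append(
            {"candidate": ci, **params, "mcc": float(np.mean(mccs)), "correct_rate": float(np.mean(accs))}
        )
    record = pd.DataFrame(records)
    # highest MCC; ties resolved by the higher correct rate
    best_i = record.sort_values(
        ["mcc", "correct_rate"], ascending=False, kind="stable"
    ).index[0]
    best_params = candidates[int(record.loc[best_i, "candidate"])]
    forest = RandomForestClassifier(random_state=seed, **best_params)
    forest.fit(scores, y)
    return forest, best_params, record


def fit_subset_pipeline(
    features: pd.DataFrame,
    labels: Sequence[int],
    seed: int = 0,
    max_missing_fraction: float = 0.2,
    alpha: float = 0.05,
    variance_target: float = 0.95,
    grid: dict[str, Sequence] | None = None,
    n_resamples: int = 100,
) -> SubsetClassifier:
    """Full preprocessing + tuning pipeline returning a reusable classifier."""
    imputed, dropped, medians = drop_sparse_features(features, max_missing_fraction)
    screened = screen_features_kw(imputed, labels, alpha=alpha)
    if screened.shape[1] < 2:
        # too few significant features to reduce; fall back to all imputed ones
        screened = imputed
    scores, red = reduce_dimensions(screened, variance_target)
    forest, best_params, record = fit_subset_classifier(
        scores, labels, seed=seed, grid=grid, n_resamples=n_resamples
    )
    return SubsetClassifier(
        dropped_features=dropped,
        medians=medians,
        screened_features=list(screened.columns),
        reduction=red,
        forest=forest,
        best_params=best_params,
        tuning_record=record,
        seed=seed,
    )


def predict_subset(model: SubsetClassifier, table: pd.DataFrame) -> np.ndarray:
    """Subset label (1..k) per subject from non-imaging features only."""
    needed = model.screened_features
    missing = [f for f in needed if f not in table.columns]
    if missing:
        raise ValueError(f"missing retained features: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    x = table[needed].copy()
    x = x.fillna(model.medians.reindex(needed))
    scores = model.reduction.transform(x)
    return model.forest.predict(scores)
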