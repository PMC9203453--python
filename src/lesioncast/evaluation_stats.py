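"""Evaluation metrics and hypothesis tests for the lesion-estimation pipeline.

Per-region classification quality is summarized by accuracy, specificity and
sensitivity with a Fisher exact test of the truth-by-prediction contingency
table.  Group comparisons use nonparametric tests throughout: Kruskal-Wallis
with a Tukey-Kramer post hoc on rank means across the three estimation
methods, the Wilcoxon rank-sum (normal approximation, tie-corrected) for
modified-vs-direct comparisons, and Spearman rank correlation for the
true-vs-predicted subset dispersion check.

Undefined ratios (zero denominators, e.g. sensitivity in a region with no
true presences) are reported as missing (NaN), never as 0, and excluded
from medians.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .lesion_metrics import coefficient_of_variation

__all__ = [
    "RegionPerformance",
    "confusion_metrics",
    "fisher_exact_2x2",
    "kruskal_wallis",
    "tukey_kramer_posthoc",
    "wilcoxon_rank_sum",
    "spearman_corr",
    "evaluate_predictions",
    "cv_correlation",
]


@dataclass(frozen=True)
class RegionPerformance:
    region_id: int | str
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    specificity: float
    sensitivity: float
    fisher_p: float


def confusion_metrics(truth, pred, region_id: int | str = -1) -> RegionPerformance:
    """Confusion counts and the three ratio metrics for one region.

    Accuracy = (TP+TN)/n, specificity = TN/(TN+FP), sensitivity =
    TP/(TP+FN); a ratio with zero denominator is NaN.
    """
    t = np.asarray(truth).astype(int)
    p = np.asarray(pred).astype(int)
    if len(t) != len(p):
        raise ValueError("truth and prediction lengths differ")
    tp = int(np.sum((t == 1) & (p == 1)))
    fp = int(np.sum((t == 0) & (p == 1)))
    tn = int(np.sum((t == 0) & (p == 0)))
    fn = int(np.sum((t == 1) & (p == 0)))
    n = len(t)
    acc = (tp + tn) / n if n else np.nan
    spe = tn / (tn + fp) if (tn + fp) else np.nan
    sen = tp / (tp + fn) if (tp + fn) else np.nan
    fisher_p = fisher_exact_2x2([[tn, fp], [fn, tp]])
    return RegionPerformance(region_id, tp, fp, tn, fn, acc, spe, sen, fisher_p)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 contingency table.

    Sum of hypergeometric probabilities not exceeding that of the observed
    table; a zero margin gives p = 1 by convention.
    """
    m = np.asarray(table)
    if m.shape != (2, 2) or np.any(m < 0):
        raise ValueError("need a nonnegative 2x2 table")
    _, p = stats.fisher_exact(m, alternative="two-sided")
    return float(p)


def kruskal_wallis(groups: list) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p; (H, df, p).

    All pooled values identical gives H = 0, p = 1.
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >=2 nonempty groups")
    df = len(groups) - 1
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    if np.all(pooled == pooled[0]):
        return 0.0, df, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), df, float(p)


def tukey_kramer_posthoc(groups: list, labels: list | None = None, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise comparisons on rank means with Tukey-Kramer critical values.

    Follows the common practice of applying the Tukey-Kramer procedure
    (unequal group sizes supported) to the rank-transformed pooled data after
    a Kruskal-Wallis test.  Returns a table with one row per unordered pair:
    group1, group2, meandiff (rank means), p_adj, reject.
    """
    if len(groups) < 2:
        raise ValueError("need >=2 groups")
    labels = labels if labels is not None else [f"g{i+1}" for i in range(len(groups))]
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    ranks = stats.rankdata(pooled)
    tags = np.concatenate([[labels[i]] * len(g) for i, g in enumerate(groups)])
    if np.all(pooled == pooled[0]):
        rows = []
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                rows.append({"group1": labels[i], "group2": labels[j],
                             "meandiff": 0.0, "p_adj": 1.0, "reject": False})
        return pd.DataFrame(rows)
    res = pairwise_tukeyhsd(ranks, tags, alpha=alpha)
    frame = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    return pd.DataFrame(
        {
            "group1": frame["group1"],
            "group2": frame["group2"],
            "meandiff": frame["meandiff"].astype(float),
            "p_adj": frame["p-adj"].astype(float),
            "reject": frame["reject"].astype(bool),
        }
    )


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (z, p), normal approximation with tie
    correction and continuity correction off."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var == 0:
        return 0.0, 1.0
    z = (u1 - mu) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation (rho, p) with tie handling; constant input
    gives (NaN, NaN)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return np.nan, np.nan
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def evaluate_predictions(
    truth: pd.DataFrame, pred: pd.DataFrame
) -> pd.DataFrame:
    """Region-wise performance table for aligned truth/prediction matrices.

    Both are subject x region 0/1 frames on the same index; only regions
    present in both are evaluated.
    """
    if not truth.index.equals(pred.index):
        raise ValueError("misaligned subject ids between truth and predictions")
    rows = []
    for rid in pred.columns:
        if rid not in truth.columns:
            continue
        perf = confusion_metrics(truth[rid], pred[rid], region_id=rid)
        rows.append(asdict(perf))
    cols = ["region_id", "tp", "fp", "tn", "fn",
            "accuracy", "specificity", "sensitivity", "fisher_p"]
    return pd.DataFrame(rows, columns=cols)


def cv_correlation(
    lesion_table: pd.DataFrame,
    true_subsets: pd.Series,
    pred_subsets: pd.Series,
) -> tuple[float, float]:
    """Spearman correlation between region-wise CVs computed in the true vs
    the predicted subsets.

    For every (subset, region) cell with at least two subjects in both
    groupings, the coefficient of variation of lesion degrees is computed
    under the true and the predicted grouping; the paired CVs are rank
    correlated.
    """
    xs, ys = [], []
    for label in sorted(true_subsets.unique()):
        true_ids = true_subsets.index[true_subsets == label]
        pred_ids = pred_subsets.index[pred_subsets == label]
        if len(true_ids) < 2 or len(pred_ids) < 2:
            continue
        for rid in lesion_table.columns:
            xs.append(coefficient_of_variation(lesion_table.loc[true_ids, rid].to_numpy()))
            ys.append(coefficient_of_variation(lesion_table.loc[pred_ids, rid].to_numpy()))
    return spearman_corr(np.asarray(xs), np.asarray(ys))
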