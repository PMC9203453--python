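"""Per-region lesion-occurrence models: logistic regression with nested
cross-validation, resampling, and AIC-based model selection.

For every atlas region the lesion degree is binarized (presence iff
degree > 0%) and modelled as a Bernoulli outcome of the non-imaging
features,

    P(presence | x) = 1 / (1 + exp(-(a.x + b))),

with three estimation variants:

* ``none`` — plain maximum likelihood on features pre-selected by a
  Kendall tau-b screen (p < 0.05 against the binarized outcome);
* ``l1`` / ``l2`` — LASSO / Ridge penalized fits on min-max normalized
  features, with the penalty weight (lambda) tuned in the inner loop.

Candidate models come from a 4x3-fold nested cross-validation repeated over
100 re-randomized resamplings of the fold assignment: each of the 4 outer
training folds contributes one candidate per repeat (400 candidates in
total).  The inner 3 folds either pick the feature set with the highest
validation sensitivity (``none``) or the lambda with the best validation
likelihood (``l1``/``l2``).  Every candidate carries its AIC computed on its
outer-training fit; the final model per region is the lowest-AIC candidate.
Regions with fewer than 4 presence subjects skip the CV machinery and get a
single model fitted on all data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "FitConfig",
    "RegionModel",
    "MinMaxScalerParams",
    "select_features_kendall",
    "normalize_features",
    "fit_logistic",
    "aic",
    "nested_cv_fit",
    "select_best_model",
    "predict_region",
    "fit_all_regions",
    "RegionFitResult",
]

COEF_CAP = 20.0  # separation guard: |a| capped here, flagged, deterministic
_EPS = 1e-12


@dataclass(frozen=True)
class FitConfig:
    """Knobs of the per-region modeling pipeline.

    ``resamples`` re-randomizations of the ``outer_folds`` x ``inner_folds``
    nested CV give ``outer_folds * resamples`` candidate models; regions with
    fewer than ``min_presence`` lesioned subjects take the single-model path.
    """

    method: str = "none"  # {'none', 'l1', 'l2'}
    outer_folds: int = 4
    inner_folds: int = 3
    resamples: int = 100
    min_presence: int = 4
    alpha: float = 0.05
    lambda_grid: tuple[float, ...] = tuple(np.logspace(-4, 2, 20))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("none", "l1", "l2"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass(frozen=True)
class MinMaxScalerParams:
    """Per-feature train min/max for [0, 1] scaling; constants are flagged.

    Applying train parameters to new data may produce values outside [0, 1];
    they are passed through unclipped so the linear predictor stays an affine
    function of the raw feature.
    """

    names: tuple[str, ...]
    mins: np.ndarray
    maxs: np.ndarray
    constant: tuple[str, ...]

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        x = table[list(self.names)].to_numpy(dtype=float)
        span = self.maxs - self.mins
        span = np.where(span == 0, 1.0, span)
        return pd.DataFrame((x - self.mins) / span, index=table.index, columns=self.names)


@dataclass(frozen=True)
class RegionModel:
    """One fitted logistic lesion-presence model for one region."""

    region_id: int
    method: str
    feature_names: tuple[str, ...]
    coef: np.ndarray
    intercept: float
    log_likelihood: float
    n_params: int
    aic: float
    lam: float | None = None
    scaler: MinMaxScalerParams | None = None
    separation_flag: bool = False
    provenance: dict = field(default_factory=dict)

    @property
    def validation_sensitivity(self) -> float | None:
        return self.provenance.get("validation_sensitivity")


def _kendall_tau_b_binary(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Tau-b and asymptotic tie-corrected p for every column of x against a
    binary y, via rank-sum algebra (agrees with the pairwise definition:
    S = conc - disc = 2*U - n1*n0).  Vectorized over columns."""
    n, p = x.shape
    n1 = int(y.sum())
    n0 = n - n1
    ranks = stats.rankdata(x, axis=0)
    r1 = ranks[y == 1].sum(axis=0)
    s = 2.0 * (r1 - n1 * (n1 + 1) / 2.0) - n1 * n0
    npairs = n * (n - 1) / 2.0
    ty = n0 * (n0 - 1) / 2.0 + n1 * (n1 - 1) / 2.0
    # per-column tie statistics from sorted values
    xs = np.sort(x, axis=0)
    new_run = np.ones_like(xs, dtype=bool)
    new_run[1:] = xs[1:] != xs[:-1]
    tx = np.empty(p)
    vt = np.empty(p)
    v1x = np.empty(p)
    v2x = np.empty(p)
    for j in range(p):
        cnt = np.diff(np.append(np.flatnonzero(new_run[:, j]), n))
        tx[j] = (cnt * (cnt - 1) / 2.0).sum()
        vt[j] = (cnt * (cnt - 1) * (2 * cnt + 5)).sum()
        v1x[j] = (cnt * (cnt - 1)).sum()
        v2x[j] = (cnt * (cnt - 1) * (cnt - 2)).sum()
    denom = np.sqrt((npairs - tx) * (npairs - ty))
    with np.errstate(divide="ignore", invalid="ignore"):
        tau = np.where(denom > 0, s / denom, np.nan)
    v0 = n * (n - 1) * (2 * n + 5)
    vy = n0 * (n0 - 1) * (2 * n0 + 5) + n1 * (n1 - 1) * (2 * n1 + 5)
    v1y = n0 * (n0 - 1) + n1 * (n1 - 1)
    v2y = n0 * (n0 - 1) * (n0 - 2) + n1 * (n1 - 1) * (n1 - 2)
    var = (
        (v0 - vt - vy) / 18.0
        + v1x * v1y / (2.0 * n * (n - 1))
        + v2x * v2y / (9.0 * n * (n - 1) * (n - 2))
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, s / np.sqrt(var), 0.0)
    pval = 2.0 * stats.norm.sf(np.abs(z))
    return tau, pval


def select_features_kendall(
    table: pd.DataFrame, y: np.ndarray, alpha: float = 0.05
) -> list[str]:
    """Features with a significant Kendall tau-b association with binary y.

    Constant features (tau undefined) are excluded by convention.  The
    screen is vectorized over columns; a binary outcome always carries
    ties, so the p-value is the standard tie-corrected normal
    approximation (matching scipy's asymptotic method).
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class; screen undefined")
    x = table.to_numpy(dtype=float)
    if set(np.unique(y)) <= {0, 1}:
        tau, pval = _kendall_tau_b_binary(x, y)
        keep_mask = np.isfinite(tau) & (pval < alpha)
        return [c for c, k in zip(table.columns, keep_mask) if k]
    keep = []
    for j, col in enumerate(table.columns):
        xi = x[:, j]
        if np.all(xi == xi[0]):
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tau, p = stats.kendalltau(xi, y, variant="b")
        if np.isfinite(tau) and p < alpha:
            keep.append(col)
    return keep


def normalize_features(table: pd.DataFrame) -> tuple[pd.DataFrame, MinMaxScalerParams]:
    """Min-max scale each feature to [0, 1] on the given data.

    Constant features are scaled to 0 and flagged; regularized fits exclude
    them.
    """
    x = table.to_numpy(dtype=float)
    mins = x.min(axis=0)
    maxs = x.max(axis=0)
    constant = tuple(c for c, lo, hi in zip(table.columns, mins, maxs) if lo == hi)
    params = MinMaxScalerParams(
        names=tuple(table.columns), mins=mins, maxs=maxs, constant=constant
    )
    return params.transform(table), params


def _bernoulli_loglik(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, _EPS, 1 - _EPS)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def fit_logistic(
    x: np.ndarray, y: np.ndarray, method: str = "none", lam: float = 1.0
) -> tuple[np.ndarray, float, float, int, bool]:
    """Fit the logistic model; returns (coef, intercept, loglik, n_params, sep_flag).

    ``method='none'`` is an unpenalized maximum-likelihood fit; under perfect
    separation the coefficients diverge, so they are deterministically capped
    at |a| <= 20 and flagged.  ``l1``/``l2`` penalize with weight ``lam``
    (glmnet-style: the sklearn inverse-regularization is C = 1/(n*lam)).
    The returned log-likelihood is always the unpenalized Bernoulli one;
    ``n_params`` counts the intercept plus (for penalized fits) only the
    nonzero slopes.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 1 and len(y) > 1:
        x = x.T
    y = np.asarray(y)
    n = len(y)
    if len(np.unique(y)) < 2:
        # degenerate single-class data: intercept-only at the capped logit
        b = COEF_CAP if y[0] == 1 else -COEF_CAP
        coef = np.zeros(x.shape[1])
        ll = _bernoulli_loglik(y, _sigmoid(np.full(n, b)))
        return coef, float(b), ll, 1, True
    if x.shape[1] == 0:
        # intercept-only model: closed form b = logit(mean(y))
        p0 = y.mean()
        b = float(np.log(p0 / (1 - p0)))
        ll = _bernoulli_loglik(y, np.full(n, p0))
        return np.zeros(0), b, ll, 1, False
    if method == "none":
        clf = LogisticRegression(penalty=None, solver="lbfgs", max_iter=2000, tol=1e-10)
    elif method == "l1":
        clf = LogisticRegression(
            penalty="l1", solver="liblinear", C=1.0 / (n * lam), max_iter=2000, tol=1e-8
        )
    elif method == "l2":
        clf = LogisticRegression(
            penalty="l2", solver="lbfgs", C=1.0 / (n * lam), max_iter=2000, tol=1e-8
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(x, y)
    coef = clf.coef_[0].copy()
    b = float(clf.intercept_[0])
    sep = bool(np.any(np.abs(coef) > COEF_CAP) or abs(b) > COEF_CAP)
    coef = np.clip(coef, -COEF_CAP, COEF_CAP)
    b = float(np.clip(b, -COEF_CAP, COEF_CAP))
    ll = _bernoulli_loglik(y, _sigmoid(x @ coef + b))
    if method == "none":
        n_params = 1 + x.shape[1]
    else:
        n_params = 1 + int(np.sum(np.abs(coef) > 1e-8))
    return coef, b, ll, n_params, sep


def aic(log_likelihood: float, n_params: int) -> float:
    """Akaike information criterion, 2k - 2 ln L."""
    if not np.isfinite(log_likelihood):
        raise ValueError("log-likelihood must be finite")
    return 2.0 * n_params - 2.0 * log_likelihood


def _sensitivity(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    pos = y_true == 1
    if pos.sum() == 0:
        return np.nan
    return float((y_pred[pos] == 1).mean())


def _predict_from(coef: np.ndarray, b: float, x: np.ndarray) -> np.ndarray:
    # probabilities kept strictly inside (0, 1) so saturated (capped) fits
    # stay finite in likelihoods and downstream logs
    return np.clip(_sigmoid(np.atleast_2d(x) @ coef + b), _EPS, 1 - _EPS)


def _make_model(
    region_id: int,
    method: str,
    names: tuple[str, ...],
    coef: np.ndarray,
    b: float,
    ll: float,
    k: int,
    sep: bool,
    lam: float | None,
    scaler: MinMaxScalerParams | None,
    provenance: dict,
) -> RegionModel:
    return RegionModel(
        region_id=region_id,
        method=method,
        feature_names=names,
        coef=coef,
        intercept=b,
        log_likelihood=ll,
        n_params=k,
        aic=aic(ll, k),
        lam=lam,
        scaler=scaler,
        separation_flag=sep,
        provenance=provenance,
    )


def _fit_single(
    table: pd.DataFrame, y: np.ndarray, config: FitConfig, region_id: int
) -> RegionModel:
    """Single-model path: one fit on all data, no CV or resampling."""
    if config.method == "none":
        feats = select_features_kendall(table, y, config.alpha) if len(np.unique(y)) > 1 else []
        x = table[feats].to_numpy(dtype=float) if feats else np.zeros((len(y), 0))
        coef, b, ll, k, sep = fit_logistic(x, y, "none")
        return _make_model(
            region_id, "none", tuple(feats), coef, b, ll, k, sep, None, None,
            {"path": "single"},
        )
    scaled, scaler = normalize_features(table)
    usable = [c for c in scaled.columns if c not in scaler.constant]
    x = scaled[usable].to_numpy(dtype=float)
    best = None
    for lam in config.lambda_grid:
        coef, b, ll, k, sep = fit_logistic(x, y, config.method, lam)
        a = aic(ll, k)
        if best is None or a < best[0]:
            best = (a, lam, coef, b, ll, k, sep)
    _, lam, coef, b, ll, k, sep = best
    return _make_model(
        region_id, config.method, tuple(usable), coef, b, ll, k, sep, lam, scaler,
        {"path": "single"},
    )


def nested_cv_fit(
    table: pd.DataFrame, y: np.ndarray, config: FitConfig, region_id: int = -1
) -> list[RegionModel]:
    """Candidate models from resampled nested cross-validation.

    With presence count >= ``config.min_presence`` this yields exactly
    ``outer_folds * resamples`` candidates, each an outer-training-fold fit
    whose inner 3-fold loop chose either the feature set with the highest
    validation sensitivity (``none``) or the best-likelihood lambda
    (``l1``/``l2``).  Below the presence threshold, a single all-data model
    is returned.
    """
    y = np.asarray(y).astype(int)
    presence = int(y.sum())
    if presence < config.min_presence or (len(y) - presence) < config.min_presence:
        return [_fit_single(table, y, config, region_id)]

    candidates: list[RegionModel] = []
    rng = np.random.default_rng(config.seed)
    for rep in range(config.resamples):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        outer = StratifiedKFold(
            n_splits=config.outer_folds, shuffle=True, random_state=rep_seed
        )
        for fold_i, (tr_idx, te_idx) in enumerate(outer.split(table, y)):
            tr_tab, tr_y = table.iloc[tr_idx], y[tr_idx]
            model = _fit_outer_candidate(
                tr_tab, tr_y, config, region_id, rep_seed, rep, fold_i
            )
            # outer-test sensitivity recorded as provenance
            probs, pred = predict_region(model, table.iloc[te_idx])
            model.provenance["outer_test_sensitivity"] = _sensitivity(y[te_idx], pred)
            candidates.append(model)
    return candidates


def _fit_outer_candidate(
    tr_tab: pd.DataFrame,
    tr_y: np.ndarray,
    config: FitConfig,
    region_id: int,
    rep_seed: int,
    rep: int,
    fold_i: int,
) -> RegionModel:
    inner = StratifiedKFold(n_splits=config.inner_folds, shuffle=True, random_state=rep_seed)
    prov = {"repeat": rep, "outer_fold": fold_i}
    if config.method == "none":
        # each inner fold proposes the feature set screened on its training
        # part; the set with the highest inner-validation sensitivity wins
        best = None
        for in_tr, in_val in inner.split(tr_tab, tr_y):
            feats = select_features_kendall(tr_tab.iloc[in_tr], tr_y[in_tr], config.alpha)
            x_tr = tr_tab.iloc[in_tr][feats].to_numpy(float) if feats else np.zeros((len(in_tr), 0))
            coef, b, *_ = fit_logistic(x_tr, tr_y[in_tr], "none")
            x_val = tr_tab.iloc[in_val][feats].to_numpy(float) if feats else np.zeros((len(in_val), 0))
            p_val = _predict_from(coef, b, x_val)
            sens = _sensitivity(tr_y[in_val], (p_val >= 0.5).astype(int))
            sens = -1.0 if np.isnan(sens) else sens
            if best is None or sens > best[0]:
                best = (sens, feats)
        sens, feats = best
        x = tr_tab[feats].to_numpy(float) if feats else np.zeros((len(tr_y), 0))
        coef, b, ll, k, sep = fit_logistic(x, tr_y, "none")
        prov["validation_sensitivity"] = sens
        return _make_model(region_id, "none", tuple(feats), coef, b, ll, k, sep, None, None, prov)

    # regularized path: min-max normalize on the outer-training fold, tune
    # lambda by mean inner-validation log-likelihood
    scaled, scaler = normalize_features(tr_tab)
    usable = [c for c in scaled.columns if c not in scaler.constant]
    xs = scaled[usable].to_numpy(float)
    lam_scores = []
    splits = list(inner.split(xs, tr_y))
    for lam in config.lambda_grid:
        lls = []
        for in_tr, in_val in splits:
            coef, b, *_ = fit_logistic(xs[in_tr], tr_y[in_tr], config.method, lam)
            p_val = _predict_from(coef, b, xs[in_val])
            lls.append(_bernoulli_loglik(tr_y[in_val], p_val))
        lam_scores.append(float(np.mean(lls)))
    best_lam = config.lambda_grid[int(np.argmax(lam_scores))]
    coef, b, ll, k, sep = fit_logistic(xs, tr_y, config.method, best_lam)
    p_in = _predict_from(coef, b, xs)
    prov["validation_sensitivity"] = _sensitivity(tr_y, (p_in >= 0.5).astype(int))
    return _make_model(
        region_id, config.method, tuple(usable), coef, b, ll, k, sep, best_lam, scaler, prov
    )


def select_best_model(candidates: list[RegionModel]) -> RegionModel:
    """Lowest-AIC candidate; ties go to fewer parameters, then to higher
    validation sensitivity."""
    if not candidates:
        raise ValueError("empty candidate list")

    def key(m: RegionModel):
        vs = m.validation_sensitivity
        vs = -1.0 if vs is None or np.isnan(vs) else vs
        return (m.aic, m.n_params, -vs)

    return min(candidates, key=key)


def predict_region(
    model: RegionModel, table: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Lesion-presence probability and 0/1 class per subject.

    Class is presence iff P >= 0.5 (the boundary counts as presence:
    screening prioritizes sensitivity).
    """
    missing = [f for f in model.feature_names if f not in table.columns]
    if missing:
        raise ValueError(f"missing required features: {missing}")
    if model.scaler is not None:
        x = model.scaler.transform(table)[list(model.feature_names)].to_numpy(float)
    else:
        x = table[list(model.feature_names)].to_numpy(float)
    if x.shape[1] == 0:
        x = np.zeros((len(table), 0))
    probs = _predict_from(model.coef, model.intercept, x)
    return probs, (probs >= 0.5).astype(int)


@dataclass
class RegionFitResult:
    """Outcome of fitting all regions: selected models plus skipped regions."""

    models: dict[int, RegionModel]
    candidate_counts: dict[int, int]
    unmodellable: dict[int, str]

    def predictions(self, features: pd.DataFrame) -> pd.DataFrame:
        """Subject x region 0/1 prediction matrix over the modelled regions."""
        cols = {}
        for rid, model in self.models.items():
            _, pred = predict_region(model, features)
            cols[rid] = pred
        return pd.DataFrame(cols, index=features.index)


def fit_all_regions(
    lesion_table: pd.DataFrame,
    features: pd.DataFrame,
    config: FitConfig,
    region_ids: list[int] | None = None,
) -> RegionFitResult:
    """Fit one selected model per modellable region.

    ``lesion_table`` is subjects x regions (percent degrees, columns are
    region ids); ``features`` is subjects x non-imaging variables on the same
    index.  Regions with no lesion presence (or no absence) across subjects
    are recorded as unmodellable.
    """
    if not lesion_table.index.equals(features.index):
        raise ValueError("lesion table and feature table must share the subject index")
    ids = region_ids if region_ids is not None else list(lesion_table.columns)
    models: dict[int, RegionModel] = {}
    counts: dict[int, int] = {}
    unmodellable: dict[int, str] = {}
    rng = np.random.default_rng(config.seed)
    for rid in ids:
        y = (lesion_table[rid].to_numpy(dtype=float) > 0).astype(int)
        if y.sum() == 0:
            unmodellable[rid] = "no presence"
            continue
        if y.sum() == len(y):
            unmodellable[rid] = "no absence"
            continue
        region_cfg = replace(config, seed=int(rng.integers(0, 2**31 - 1)))
        cands = nested_cv_fit(features, y, region_cfg, region_id=int(rid) if np.isreal(rid) else -1)
        counts[rid] = len(cands)
        models[rid] = select_best_model(cands)
    return RegionFitResult(models=models, candidate_counts=counts, unmodellable=unmodellable)
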