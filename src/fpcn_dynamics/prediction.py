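"""Composite scores and cross-validated ridge prediction with permutation inference.

Cognitive-battery measures are combined by the first principal component
(standardized measures; sign oriented so the mean loading is positive).
Integration features predict the composite by ridge regression (penalty
lambda = 1 by default) under two-fold-by-sample or leave-one-out
cross-validation; significance comes from re-running the full
cross-validation on row-permuted feature matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .network_metrics import residualize

logger = logging.getLogger(__name__)


@dataclass
class PredictionResult:
    """Out-of-fold ridge predictions and their accuracy."""

    predicted: np.ndarray
    observed: np.ndarray
    r_pred: float
    scheme: str
    ridge_penalty: float
    weights_by_fold: list[np.ndarray]
    p_perm: float | None = None
    n_perm: int | None = None


def first_pc(scores: np.ndarray, return_model: bool = False):
    """First-principal-component composite of a subject x measure table.

    Measures are z-scored; zero-variance measures are dropped with a warning.
    Scores are oriented so the mean loading is positive and scaled to unit
    variance of the projection weights (eigenvector norm 1).
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a subject x measure table with >= 2 measures")
    if np.any(~np.isfinite(X)):
        raise ValueError("scores contain missing values")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not np.all(keep):
        logger.warning("dropping zero-variance measure(s) %s", list(np.flatnonzero(~keep)))
        X = X[:, keep]
        sd = sd[keep]
        if X.shape[1] < 2:
            raise ValueError("fewer than 2 informative measures remain")
    Z = (X - X.mean(axis=0)) / sd
    cov = np.cov(Z.T, ddof=1)
    vals, vecs = np.linalg.eigh(cov)
    loading = vecs[:, -1]
    if loading.mean() < 0:
        loading = -loading
    composite = Z @ loading
    if return_model:
        explained = float(vals[-1] / vals.sum())
        return composite, {"loading": loading, "explained_variance": explained}
    return composite


def ridge_fit(
    features: np.ndarray, outcome: np.ndarray, ridge_penalty: float = 1.0
) -> tuple[np.ndarray, dict]:
    """Ridge weights on standardized features; unpenalized intercept.

    Returns ``(weights, model)`` where ``model`` carries the training
    standardization (means, sds, outcome mean) needed to predict new data.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if ridge_penalty < 0:
        raise ValueError("ridge penalty must be >= 0")
    if X.ndim != 2 or len(X) != len(y) or len(y) < 2:
        raise ValueError("features must be subject x feature, aligned with outcome")
    if np.any(~np.isfinite(X)) or np.any(~np.isfinite(y)):
        raise ValueError("NaN/inf in features or outcome")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X - mu) / sd
    y_mean = y.mean()
    G = Z.T @ Z + ridge_penalty * np.eye(Z.shape[1])
    w = np.linalg.solve(G, Z.T @ (y - y_mean))
    return w, {"feature_mean": mu, "feature_sd": sd, "outcome_mean": y_mean}


def ridge_predict(features: np.ndarray, w: np.ndarray, model: dict) -> np.ndarray:
    Z = (np.asarray(features, dtype=float) - model["feature_mean"]) / model["feature_sd"]
    return model["outcome_mean"] + Z @ w


def _folds(n: int, scheme: str, fold_labels) -> list[np.ndarray]:
    if scheme == "two_fold_by_sample":
        if fold_labels is None:
            raise ValueError("two_fold_by_sample requires fold_labels")
        labels = np.asarray(fold_labels)
        levels = np.unique(labels)
        if len(levels) != 2:
            raise ValueError(f"fold_labels must have exactly 2 levels, got {len(levels)}")
        return [np.flatnonzero(labels == lv) for lv in levels]
    if scheme == "leave_one_out":
        return [np.array([i]) for i in range(n)]
    raise ValueError(f"unknown scheme {scheme!r}")


def crossval_predict(
    features: np.ndarray,
    outcome: np.ndarray,
    scheme: str = "two_fold_by_sample",
    ridge_penalty: float = 1.0,
    fold_labels=None,
) -> PredictionResult:
    """Out-of-fold ridge predictions pooled into a single accuracy correlation.

    Standardization parameters and weights come from the training fold only;
    no test-fold outcome ever enters training.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(outcome, dtype=float)
    n = len(y)
    folds = _folds(n, scheme, fold_labels)
    if scheme == "two_fold_by_sample" and any(len(f) < 3 for f in folds):
        raise ValueError("each fold needs at least 3 subjects")
    predicted = np.full(n, np.nan)
    weights = []
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        w, model = ridge_fit(X[train_idx], y[train_idx], ridge_penalty)
        predicted[test_idx] = ridge_predict(X[test_idx], w, model)
        weights.append(w)
    if np.std(predicted) == 0 or np.std(y) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(predicted, y)[0, 1])
    return PredictionResult(
        predicted=predicted,
        observed=y.copy(),
        r_pred=r,
        scheme=scheme,
        ridge_penalty=ridge_penalty,
        weights_by_fold=weights,
    )


def permutation_p(
    features: np.ndarray,
    outcome: np.ndarray,
    scheme: str = "two_fold_by_sample",
    ridge_penalty: float = 1.0,
    fold_labels=None,
    n_perm: int = 1000,
    seed: "int | np.random.Generator | None" = 0,
) -> tuple[float, PredictionResult]:
    """Permutation p-value for the cross-validated prediction accuracy.

    Rows of the feature matrix are permuted jointly and the full
    cross-validation is re-run per permutation;
    ``p = (1 + #{perm r >= observed r}) / (1 + n_perm)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    X = np.asarray(features, dtype=float)
    if np.allclose(X.std(axis=0), 0.0):
        raise ValueError("degenerate features: identical for all subjects")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = crossval_predict(X, outcome, scheme, ridge_penalty, fold_labels)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(outcome))
        r = crossval_predict(X[perm], outcome, scheme, ridge_penalty, fold_labels).r_pred
        if r >= observed.r_pred:
            count += 1
    p = (1 + count) / (1 + n_perm)
    observed.p_perm = p
    observed.n_perm = n_perm
    return p, observed


def tms_composite(
    frontal_effects: np.ndarray, control_effects: np.ndarray
) -> np.ndarray:
    """General stimulation-susceptibility composite.

    Per measure (column), the frontal-site effect is residualized on the
    paired control-site effect; the residualized effects are combined by
    their first principal component.
    """
    F = np.asarray(frontal_effects, dtype=float)
    S = np.asarray(control_effects, dtype=float)
    if F.shape != S.shape or F.ndim != 2:
        raise ValueError("frontal and control effect tables must share a shape")
    resid = np.column_stack(
        [residualize(F[:, j], S[:, j]) for j in range(F.shape[1])]
    )
    # a frontal effect fully explained by its control leaves no signal
    scale = np.maximum(np.abs(F).max(axis=0), 1.0)
    degenerate = resid.std(axis=0) <= 1e-10 * scale
    resid[:, degenerate] = 0.0
    if degenerate.all():
        logger.warning("all frontal effects fully explained by control effects")
        return np.zeros(F.shape[0])
    return first_pc(resid)
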