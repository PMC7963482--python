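"""ROI-level GLM: condition activations and z-scored activation profiles.

Each run is grand-mean scaled so its mean signal is 100, then fit by ordinary
least squares (optionally with AR(1) prewhitening via a Cochrane-Orcutt
transform, the autocorrelation estimated per ROI from OLS residuals).  Runs
are modeled separately with per-run intercepts; condition betas are averaged
across runs.  Profiles are the eight condition betas z-scored within each
subject x ROI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .task_design import CONDITIONS, ContrastMatrix, TaskDesign
from .timeseries import RoiTimeSeries

logger = logging.getLogger(__name__)


@dataclass
class GlmResult:
    """Condition-wise betas per ROI with residual statistics."""

    betas: np.ndarray  # condition x ROI
    condition_labels: tuple[str, ...]
    roi_labels: tuple[str, ...]
    residual_sd: np.ndarray  # per ROI
    dof: int
    ar1: np.ndarray | None = None  # per-ROI AR(1) coefficient used

    def contrast_estimates(self, contrasts: ContrastMatrix) -> np.ndarray:
        """``contrast x ROI`` estimates, exactly C_regressor . betas."""
        return contrasts.weights @ self.betas


@dataclass
class ActivationProfile:
    """``subject x ROI x 8`` z-scored condition activations."""

    z_betas: np.ndarray
    roi_labels: tuple[str, ...]
    condition_labels: tuple[str, ...] = CONDITIONS

    @property
    def n_subjects(self) -> int:
        return self.z_betas.shape[0]

    def stacked(self) -> np.ndarray:
        """``(subjects * conditions) x ROI`` matrix for profile-space analyses."""
        return np.transpose(self.z_betas, (0, 2, 1)).reshape(-1, len(self.roi_labels))


def grand_mean_scale(data: np.ndarray, target: float = 100.0) -> np.ndarray:
    """Scale a run so its run-wide mean signal equals ``target``."""
    mean = data.mean()
    if mean == 0:
        raise ValueError("cannot grand-mean scale a zero-mean run")
    return data * (target / mean)


def _ols(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns: those whose removal restores full rank
        bad = []
        for j in range(X.shape[1]):
            keep = [k for k in range(X.shape[1]) if k != j]
            if np.linalg.matrix_rank(X[:, keep]) == rank:
                bad.append(j)
        raise ValueError(f"rank-deficient design: columns {bad} are redundant")
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return beta, resid, X.shape[0] - rank


def fit_roi_glm(
    runs: "RoiTimeSeries | list[RoiTimeSeries]",
    designs: "TaskDesign | list[TaskDesign]",
    confounds: "list[np.ndarray | None] | None" = None,
    scale: bool = True,
    ar1_prewhiten: bool = False,
) -> GlmResult:
    """Fit the condition GLM per ROI, averaging betas across runs.

    Parameters
    ----------
    runs, designs:
        One series + design per run (a single pair is accepted bare).
    confounds:
        Optional per-run nuisance columns appended to each run's design.
    ar1_prewhiten:
        Estimate a lag-1 residual autocorrelation per ROI from an initial OLS
        pass and refit on Cochrane-Orcutt-transformed data.
    """
    if isinstance(runs, RoiTimeSeries):
        runs = [runs]
    if isinstance(designs, TaskDesign):
        designs = [designs]
    if len(runs) != len(designs):
        raise ValueError("need one design per run")
    if confounds is None:
        confounds = [None] * len(runs)

    roi_labels = runs[0].roi_labels
    cond_labels = designs[0].condition_labels
    per_run_betas = []
    ssr = np.zeros(len(roi_labels))
    total_dof = 0
    ar1_all = []
    for ts, design, conf in zip(runs, designs, confounds):
        if ts.n_timepoints != design.n_scans:
            raise ValueError(
                f"series has {ts.n_timepoints} timepoints but design has {design.n_scans}"
            )
        Y = ts.data
        if np.any(~np.isfinite(Y)):
            raise ValueError("series contains NaN/inf values")
        if scale:
            Y = grand_mean_scale(Y)
        X = design.full_matrix(intercept=True)  # per-run intercept
        if conf is not None and np.size(conf):
            X = np.column_stack([X, conf])
        beta, resid, dof = _ols(X, Y)
        if ar1_prewhiten:
            # negligible residual variance (noise-free fit) counts as white
            scale = Y.var(axis=0)
            rho = np.array(
                [
                    _lag1_autocorr(resid[:, j])
                    if resid[:, j].var() > 1e-12 * max(scale[j], 1e-300)
                    else 0.0
                    for j in range(resid.shape[1])
                ]
            )
            ar1_all.append(rho)
            betas_w = np.empty_like(beta)
            resid_w = np.empty_like(resid[1:])
            for j, r in enumerate(rho):
                Xw = X[1:] - r * X[:-1]
                yw = Y[1:, j] - r * Y[:-1, j]
                bj, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
                betas_w[:, j] = bj
                resid_w[:, j] = yw - Xw @ bj
            beta, resid, dof = betas_w, resid_w, resid_w.shape[0] - np.linalg.matrix_rank(X)
        n_cond = len(cond_labels)
        per_run_betas.append(beta[:n_cond])
        ssr += (resid**2).sum(axis=0)
        total_dof += dof
    betas = np.mean(per_run_betas, axis=0)
    return GlmResult(
        betas=betas,
        condition_labels=cond_labels,
        roi_labels=roi_labels,
        residual_sd=np.sqrt(ssr / max(total_dof, 1)),
        dof=total_dof,
        ar1=np.mean(ar1_all, axis=0) if ar1_all else None,
    )


def _lag1_autocorr(x: np.ndarray) -> float:
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0:
        return 0.0
    return float(x[1:] @ x[:-1] / denom)


def make_profiles(
    glm_results: list[GlmResult], conditions: tuple[str, ...] = CONDITIONS
) -> ActivationProfile:
    """z-score each subject x ROI's eight condition betas (ddof=1)."""
    roi_labels = glm_results[0].roi_labels
    n_subj = len(glm_results)
    z = np.zeros((n_subj, len(roi_labels), len(conditions)))
    for s, res in enumerate(glm_results):
        idx = [res.condition_labels.index(c) for c in conditions]
        b = res.betas[idx].T  # ROI x condition
        mu = b.mean(axis=1, keepdims=True)
        sd = b.std(axis=1, ddof=1, keepdims=True)
        degenerate = sd[:, 0] == 0
        if np.any(degenerate):
            logger.warning(
                "constant condition betas for subject %d ROIs %s; profile set to zero",
                s, [roi_labels[j] for j in np.flatnonzero(degenerate)],
            )
        sd[sd == 0] = 1.0
        z[s] = (b - mu) / sd
    return ActivationProfile(z_betas=z, roi_labels=roi_labels, condition_labels=conditions)
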