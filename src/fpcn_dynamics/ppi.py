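"""Context-dependent effective connectivity via psychophysiological interaction.

For each ordered (source -> target) ROI pair the target series is modeled as

    Y_target = B_conn * Y_source + B_uni X + B_dep (bin(X) C .* Y_source)

in a single least-squares fit, where X is the task design (plus nuisance and
intercept columns), bin(X) the binarized condition boxcars, and C the contrast
matrix.  Including the contrast *inside* the model (one interaction regressor
per contrast) avoids the attenuation bias that arises when per-condition
interaction coefficients are estimated first and contrasted afterwards
(:func:`fit_ppi_posthoc`, kept for bias comparison).

A lag-1 ridge vector-autoregression (:func:`estimate_static_ec`) provides a
plumbing estimator of static directed coupling restricted to a candidate
connectivity scaffold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .task_design import ContrastMatrix, TaskDesign
from .timeseries import RoiTimeSeries

#: reject designs whose stacked regressor matrix exceeds this condition number
CONDITION_NUMBER_LIMIT = 1e6

#: PPI contrast set: the spatial row is the exact negation of the verbal row,
#: so interaction models carry a single stimulus-domain regressor
PPI_CONTRAST_NAMES: tuple[str, ...] = (
    "temporal",
    "contextual",
    "sensorimotor",
    "verbal",
    "contextual_x_domain",
)


def ppi_contrasts(contrasts: ContrastMatrix | None = None) -> ContrastMatrix:
    """Restrict a contrast matrix to the PPI-estimable set (one domain row)."""
    if contrasts is None:
        from .task_design import define_contrasts

        contrasts = define_contrasts()
    return contrasts.subset([n for n in PPI_CONTRAST_NAMES if n in contrasts.names])


@dataclass
class PpiResult:
    """Per-connection PPI coefficients."""

    source: str
    target: str
    b_conn: float
    b_uni: np.ndarray
    b_dep: dict[str, float]
    dof: int
    residual_sd: float
    method: str = "in_model"


@dataclass
class EcMatrix:
    """Directed coupling matrix, source rows x target columns."""

    A: np.ndarray
    roi_labels: tuple[str, ...]
    estimator_tag: str = "lag1_ridge"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        n = len(self.roi_labels)
        if self.A.shape != (n, n):
            raise ValueError(f"A is {self.A.shape}, expected {(n, n)}")
        if not np.all(np.isfinite(self.A)):
            raise ValueError("EC matrix contains non-finite entries")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.A, index=list(self.roi_labels), columns=list(self.roi_labels))


def project_out(y: np.ndarray, confounds: np.ndarray | None) -> np.ndarray:
    """OLS residuals of ``y`` after regressing out confound columns + intercept."""
    n = len(y)
    if confounds is None or (hasattr(confounds, "size") and confounds.size == 0):
        return y - y.mean()
    Z = np.column_stack([np.ones(n), np.asarray(confounds, dtype=float)])
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    return y - Z @ beta


def _check_design(M: np.ndarray, names: list[str]) -> None:
    cond = np.linalg.cond(M)
    if cond > CONDITION_NUMBER_LIMIT:
        # name the most collinear regressor pair for the error message
        Mc = M - M.mean(axis=0)
        sd = Mc.std(axis=0)
        Z = Mc / np.where(sd == 0, 1.0, sd)
        R = np.abs(Z.T @ Z) / M.shape[0]
        np.fill_diagonal(R, 0.0)
        i, j = np.unravel_index(np.argmax(R), R.shape)
        raise ValueError(
            f"design condition number {cond:.3g} exceeds {CONDITION_NUMBER_LIMIT:.0e}; "
            f"most collinear pair: {names[i]!r} and {names[j]!r} (|r|={R[i, j]:.4f})"
        )


def _interaction_columns(
    design: TaskDesign, contrasts: ContrastMatrix, source: np.ndarray,
    center_psych: bool = False,
) -> tuple[np.ndarray, list[str]]:
    binX = design.binarized_design
    cols, names = [], []
    for k, name in enumerate(contrasts.names):
        psych = binX @ contrasts.weights[k]
        if center_psych:
            psych = psych - psych.mean()
        cols.append(psych * source)
        names.append(f"ppi_{name}")
    return np.column_stack(cols), names


def _base_columns(design: TaskDesign, source: np.ndarray) -> tuple[np.ndarray, list[str]]:
    X = design.full_matrix(intercept=True)
    names = (
        ["source"]
        + list(design.condition_labels)
        + list(design.nuisance_names)
        + ["intercept"]
    )
    return np.column_stack([source, X]), names


def fit_ppi(
    target: np.ndarray,
    source: np.ndarray,
    design: TaskDesign,
    contrasts: ContrastMatrix,
    confounds: np.ndarray | None = None,
    source_name: str = "source",
    target_name: str = "target",
    center_psych: bool = False,
) -> PpiResult:
    """In-model-contrast PPI: one interaction regressor per contrast.

    ``center_psych`` mean-centers each psychological regressor before the
    multiplication with the source (off by default, matching the model as
    written).
    """
    target = np.asarray(target, dtype=float)
    source = np.asarray(source, dtype=float)
    if target.shape != source.shape:
        raise ValueError("source and target series must have equal length")
    if np.allclose(source.std(), 0.0):
        raise ValueError("zero-variance source series")
    if confounds is not None:
        target = project_out(target, confounds)
        source = project_out(source, confounds)
    base, base_names = _base_columns(design, source)
    inter, inter_names = _interaction_columns(design, contrasts, source, center_psych)
    M = np.column_stack([base, inter])
    names = base_names + inter_names
    _check_design(M, names)
    beta, _, _, _ = np.linalg.lstsq(M, target, rcond=None)
    resid = target - M @ beta
    dof = len(target) - np.linalg.matrix_rank(M)
    n_base = base.shape[1]
    b_dep = {name: float(beta[n_base + k]) for k, name in enumerate(contrasts.names)}
    return PpiResult(
        source=source_name,
        target=target_name,
        b_conn=float(beta[0]),
        b_uni=beta[1:n_base],
        b_dep=b_dep,
        dof=int(dof),
        residual_sd=float(np.sqrt(resid @ resid / max(dof, 1))),
        method="in_model",
    )


def fit_ppi_posthoc(
    target: np.ndarray,
    source: np.ndarray,
    design: TaskDesign,
    contrasts: ContrastMatrix,
    confounds: np.ndarray | None = None,
    source_name: str = "source",
    target_name: str = "target",
    normalize_contrast: bool = False,
) -> PpiResult:
    """Legacy PPI variant: per-condition interactions first, contrasts after.

    By default the contrast is applied to the per-condition interaction
    coefficients with its raw weights (the legacy convention, whose units
    scale with the contrast norm).  ``normalize_contrast`` divides by
    ``c'c``, expressing the result per unit modulation so it is directly
    comparable to the in-model coefficient: in the noise-free, full-rank
    case the two estimators are then algebraically identical.
    """
    target = np.asarray(target, dtype=float)
    source = np.asarray(source, dtype=float)
    if target.shape != source.shape:
        raise ValueError("source and target series must have equal length")
    if np.allclose(source.std(), 0.0):
        raise ValueError("zero-variance source series")
    if confounds is not None:
        target = project_out(target, confounds)
        source = project_out(source, confounds)
    base, base_names = _base_columns(design, source)
    binX = design.binarized_design
    inter = binX * source[:, None]
    inter_names = [f"ppi_{c}" for c in design.condition_labels]
    M = np.column_stack([base, inter])
    _check_design(M, base_names + inter_names)
    beta, _, _, _ = np.linalg.lstsq(M, target, rcond=None)
    resid = target - M @ beta
    dof = len(target) - np.linalg.matrix_rank(M)
    n_base = base.shape[1]
    per_condition = beta[n_base:]
    b_dep = {}
    for k, name in enumerate(contrasts.names):
        c = contrasts.weights[k]
        val = float(c @ per_condition)
        if normalize_contrast:
            val /= float(c @ c)
        b_dep[name] = val
    return PpiResult(
        source=source_name,
        target=target_name,
        b_conn=float(beta[0]),
        b_uni=beta[1:n_base],
        b_dep=b_dep,
        dof=int(dof),
        residual_sd=float(np.sqrt(resid @ resid / max(dof, 1))),
        method="posthoc",
    )


def fit_ppi_all(
    ts: RoiTimeSeries,
    design: TaskDesign,
    contrasts: ContrastMatrix,
    candidate: np.ndarray | None = None,
    confounds: np.ndarray | None = None,
    method: str = "in_model",
) -> pd.DataFrame:
    """Fit PPIs for every ordered candidate pair of one subject's series.

    Solves all targets that share a source in one least-squares call.  Returns
    a long table with columns (source, target, contrast, b_dep, b_conn).
    """
    n = ts.n_rois
    if candidate is None:
        candidate = ~np.eye(n, dtype=bool)
    data = ts.data
    if confounds is not None:
        data = np.column_stack([project_out(data[:, j], confounds) for j in range(n)])
    rows = []
    for i, src_label in enumerate(ts.roi_labels):
        targets = [j for j in range(n) if j != i and candidate[i, j]]
        if not targets:
            continue
        source = data[:, i]
        base, base_names = _base_columns(design, source)
        if method == "in_model":
            inter, inter_names = _interaction_columns(design, contrasts, source)
        elif method == "posthoc":
            inter = design.binarized_design * source[:, None]
            inter_names = [f"ppi_{c}" for c in design.condition_labels]
        else:
            raise ValueError(f"unknown method {method!r}")
        M = np.column_stack([base, inter])
        _check_design(M, base_names + inter_names)
        Y = data[:, targets]
        beta, _, _, _ = np.linalg.lstsq(M, Y, rcond=None)
        n_base = base.shape[1]
        for col, j in enumerate(targets):
            if method == "in_model":
                b_dep = {
                    name: float(beta[n_base + k, col])
                    for k, name in enumerate(contrasts.names)
                }
            else:
                per_cond = beta[n_base:, col]
                b_dep = {
                    name: float(contrasts.weights[k] @ per_cond)
                    for k, name in enumerate(contrasts.names)
                }
            for cname, val in b_dep.items():
                rows.append(
                    (src_label, ts.roi_labels[j], cname, val, float(beta[0, col]))
                )
    return pd.DataFrame(rows, columns=["source", "target", "contrast", "b_dep", "b_conn"])


def b_dep_matrix(long: pd.DataFrame, contrast: str, roi_labels: tuple[str, ...]) -> np.ndarray:
    """Pivot one contrast's long-format estimates into a source x target matrix."""
    n = len(roi_labels)
    out = np.full((n, n), np.nan)
    idx = {r: k for k, r in enumerate(roi_labels)}
    sub = long[long["contrast"] == contrast]
    for row in sub.itertuples():
        out[idx[row.source], idx[row.target]] = row.b_dep
    return out


def estimate_static_ec(
    ts: RoiTimeSeries,
    candidate: np.ndarray | None = None,
    ridge_penalty: float = 1.0,
    confounds: np.ndarray | None = None,
) -> EcMatrix:
    """Static directed coupling via candidate-restricted lag-1 ridge regression.

    For each target ROI, its series is regressed on the lagged series of its
    candidate sources (plus its own lag); the discrete propagator estimate is
    mapped back to a continuous-time coupling rate ``(Phi - I) / TR``.
    Non-candidate entries are exactly 0.
    """
    n = ts.n_rois
    if candidate is None:
        candidate = ~np.eye(n, dtype=bool)
    candidate = np.asarray(candidate, dtype=bool)
    if candidate.shape != (n, n):
        raise ValueError(
            f"candidate matrix is {candidate.shape} but series has {n} ROIs"
        )
    data = ts.data
    if confounds is not None:
        data = np.column_stack([project_out(data[:, j], confounds) for j in range(n)])
    data = data - data.mean(axis=0)
    past, present = data[:-1], data[1:]
    phi = np.zeros((n, n))
    for j in range(n):
        sources = [i for i in range(n) if i == j or candidate[i, j]]
        if len(past) < len(sources) + 2:
            raise ValueError(
                f"only {len(past)} lagged timepoints for {len(sources)} candidate "
                f"sources of target {ts.roi_labels[j]!r}"
            )
        Z = past[:, sources]
        G = Z.T @ Z + ridge_penalty * np.eye(len(sources))
        w = np.linalg.solve(G, Z.T @ present[:, j])
        for i, src in enumerate(sources):
            phi[src, j] = w[i]
    A = (phi - np.eye(n)) / ts.repetition_time
    A[~(candidate | np.eye(n, dtype=bool))] = 0.0
    return EcMatrix(A, ts.roi_labels, estimator_tag="lag1_ridge",
                    meta={"ridge_penalty": ridge_penalty})


def ppi_replicability(
    results_a: pd.DataFrame, results_b: pd.DataFrame
) -> dict[str, float]:
    """Pearson correlation of cohort-averaged per-connection coefficients.

    Inputs are long tables as produced by :func:`fit_ppi_all` (optionally
    pooled over subjects); both cohorts must cover the same connection set.
    """
    key = ["source", "target", "contrast"]
    mean_a = results_a.groupby(key, sort=True)["b_dep"].mean()
    mean_b = results_b.groupby(key, sort=True)["b_dep"].mean()
    if not mean_a.index.equals(mean_b.index):
        raise ValueError("connection/contrast sets differ between the two cohorts")
    out = {}
    for contrast in mean_a.index.get_level_values("contrast").unique():
        a = mean_a.xs(contrast, level="contrast").to_numpy()
        b = mean_b.xs(contrast, level="contrast").to_numpy()
        out[contrast] = float(np.corrcoef(a, b)[0, 1])
    return out
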