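"""Network-level aggregation of directed coupling estimates.

Summaries follow the source-role logic of directed control: entries of a
source x target coupling (or modulation) matrix are pooled into 3 x 3
network cells (diagonal self-connections excluded), lobe-wise |EC|
magnitudes, static/dynamic integration indices (between- minus
within-network means), abstraction-gradient mixed models, and the
within/between x contrast repeated-measures ANOVA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NETWORKS: tuple[str, ...] = ("TC", "CC", "SC")
LOBES: tuple[str, ...] = ("PFC", "PPC")


@dataclass
class NetworkAssignment:
    """ROI -> control network, lobe, and (optional) abstraction score."""

    networks: dict[str, str]
    lobes: dict[str, str]
    abstraction: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for roi, net in self.networks.items():
            if net not in NETWORKS:
                raise ValueError(f"ROI {roi!r} has unknown network {net!r}")
        for roi, lobe in self.lobes.items():
            if lobe not in LOBES:
                raise ValueError(f"ROI {roi!r} has unknown lobe {lobe!r}")

    @classmethod
    def default(cls) -> "NetworkAssignment":
        from .synthetic_data import DEFAULT_ROI_TABLE

        return cls(
            networks={r.roi: r.network for r in DEFAULT_ROI_TABLE.itertuples()},
            lobes={r.roi: r.lobe for r in DEFAULT_ROI_TABLE.itertuples()},
        )


@dataclass
class NetworkSummary:
    """3 x 3 source x target network cell means with exact recomposition info."""

    cell_means: pd.DataFrame  # source network x target network
    cell_sums: pd.DataFrame
    cell_counts: pd.DataFrame
    within_mean: float  # entry-weighted over diagonal cells
    between_mean: float  # entry-weighted over off-diagonal cells


def _resolve(matrix, roi_labels) -> tuple[np.ndarray, tuple[str, ...]]:
    if hasattr(matrix, "A") and hasattr(matrix, "roi_labels"):
        return np.asarray(matrix.A, dtype=float), tuple(matrix.roi_labels)
    if roi_labels is None:
        raise ValueError("roi_labels required for a bare matrix")
    return np.asarray(matrix, dtype=float), tuple(roi_labels)


def lobe_magnitude(matrix, assign: NetworkAssignment, roi_labels=None) -> pd.DataFrame:
    """Mean |coupling| per (source lobe, target lobe); diagonal excluded."""
    A, labels = _resolve(matrix, roi_labels)
    out = pd.DataFrame(np.nan, index=list(LOBES), columns=list(LOBES))
    for ls in LOBES:
        for lt in LOBES:
            vals = [
                abs(A[i, j])
                for i, ri in enumerate(labels)
                for j, rj in enumerate(labels)
                if i != j and assign.lobes[ri] == ls and assign.lobes[rj] == lt
            ]
            if not vals:
                logger.warning("empty lobe cell %s->%s", ls, lt)
                continue
            out.loc[ls, lt] = float(np.mean(vals))
    return out


def network_summary(matrix, assign: NetworkAssignment, roi_labels=None) -> NetworkSummary:
    """Pool matrix entries into source x target network cells.

    Self-connections (matrix diagonal) are excluded; within/between means are
    entry-weighted (every connection counts once).
    """
    A, labels = _resolve(matrix, roi_labels)
    missing = [r for r in labels if r not in assign.networks]
    if missing:
        raise ValueError(f"unassigned ROI(s): {missing}")
    net_idx = np.array([NETWORKS.index(assign.networks[r]) for r in labels])
    n = len(labels)
    valid = np.isfinite(A) & ~np.eye(n, dtype=bool)
    ii, jj = np.nonzero(valid)
    k = len(NETWORKS)
    sums_np = np.zeros((k, k))
    counts_np = np.zeros((k, k), dtype=int)
    np.add.at(sums_np, (net_idx[ii], net_idx[jj]), A[ii, jj])
    np.add.at(counts_np, (net_idx[ii], net_idx[jj]), 1)
    sums = pd.DataFrame(sums_np, index=list(NETWORKS), columns=list(NETWORKS))
    counts = pd.DataFrame(counts_np, index=list(NETWORKS), columns=list(NETWORKS))
    means = sums / counts.replace(0, np.nan)
    diag = np.eye(len(NETWORKS), dtype=bool)
    w_sum = float(sums.to_numpy()[diag].sum())
    w_n = int(counts.to_numpy()[diag].sum())
    b_sum = float(sums.to_numpy()[~diag].sum())
    b_n = int(counts.to_numpy()[~diag].sum())
    return NetworkSummary(
        cell_means=means,
        cell_sums=sums,
        cell_counts=counts,
        within_mean=w_sum / w_n if w_n else np.nan,
        between_mean=b_sum / b_n if b_n else np.nan,
    )


def integration_index(
    summary: NetworkSummary, network: str, entry_weighted: bool = True
) -> float:
    """Static integration of one network: outgoing between- minus within-mean.

    Uses the network's outgoing cells (source = ``network``); ``entry_weighted``
    pools connections, otherwise cell means are averaged unweighted.
    """
    if network not in summary.cell_means.index:
        raise ValueError(f"network {network!r} not in summary")
    others = [n for n in summary.cell_means.columns if n != network]
    if entry_weighted:
        b_sum = summary.cell_sums.loc[network, others].sum()
        b_n = summary.cell_counts.loc[network, others].sum()
        between = b_sum / b_n
    else:
        between = summary.cell_means.loc[network, others].mean()
    within = summary.cell_means.loc[network, network]
    return float(between - within)


def dynamic_integration_index(summary: NetworkSummary) -> float:
    """Dynamic integration of one contrast: pooled between- minus within-mean."""
    return float(summary.between_mean - summary.within_mean)


def residualize(values: np.ndarray, covariates) -> np.ndarray:
    """OLS residuals of ``values`` on covariates (intercept included)."""
    y = np.asarray(values, dtype=float)
    Z = np.asarray(covariates, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if len(y) <= Z.shape[1] + 1:
        raise ValueError("need more observations than covariates + 1")
    X = np.column_stack([np.ones(len(y)), Z])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def abstraction_gradient_model(long_table: pd.DataFrame) -> pd.DataFrame:
    """Mixed model of coupling on source/target abstraction with quadratics.

    ``long_table`` columns: subject, source_abs, target_abs, ec.  Abstraction
    is mean-centered before squaring; the model is
    ``ec ~ s + t + s:t + s^2 + t^2`` with a random intercept per subject,
    falling back to subject-clustered OLS if the mixed fit is singular.
    Returns a tidy table (term, estimate, se, stat, df, p).
    """
    import statsmodels.api as sm

    df = long_table.copy()
    for col in ("subject", "source_abs", "target_abs", "ec"):
        if col not in df.columns:
            raise ValueError(f"long_table missing column {col!r}")
    if df["subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    if df["source_abs"].std() == 0 or df["target_abs"].std() == 0:
        raise ValueError("abstraction values do not vary")
    s = df["source_abs"] - df["source_abs"].mean()
    t = df["target_abs"] - df["target_abs"].mean()
    X = pd.DataFrame(
        {
            "source": s,
            "target": t,
            "source_x_target": s * t,
            "source_sq": s**2,
            "target_sq": t**2,
        }
    )
    if np.allclose(df["ec"].std(), 0.0):
        out = pd.DataFrame(
            {"term": X.columns, "estimate": 0.0, "se": np.nan, "stat": 0.0,
             "df": len(df) - X.shape[1] - 1, "p": 1.0}
        )
        return out
    exog = sm.add_constant(X)
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(df["ec"].to_numpy(), exog, groups=df["subject"].to_numpy())
            fit = model.fit(reml=True)
        singular = np.any(~np.isfinite(fit.bse)) or not fit.converged
    except Exception:
        singular = True
    if singular:
        logger.info("singular mixed fit; falling back to subject-clustered OLS")
        fit = sm.OLS(df["ec"].to_numpy(), exog).fit(
            cov_type="cluster", cov_kwds={"groups": df["subject"].to_numpy()}
        )
    params = fit.params
    bse = fit.bse
    tvals = fit.tvalues
    pvals = fit.pvalues
    dof = len(df) - exog.shape[1]
    rows = []
    for term in exog.columns:
        if term == "const":
            continue
        rows.append(
            (term, float(params[term]), float(bse[term]), float(tvals[term]),
             dof, float(pvals[term]))
        )
    return pd.DataFrame(rows, columns=["term", "estimate", "se", "stat", "df", "p"])


def within_between_anova(indices: pd.DataFrame) -> pd.DataFrame:
    """Repeated-measures 2 x k ANOVA on integration values.

    ``indices`` columns: subject, connectivity (within/between), contrast,
    value; the design must be balanced (one value per cell per subject).
    Returns a tidy F table (term, F, df_num, df_den, p).
    """
    from statsmodels.stats.anova import AnovaRM

    required = {"subject", "connectivity", "contrast", "value"}
    if not required <= set(indices.columns):
        raise ValueError(f"indices must have columns {sorted(required)}")
    cells = indices.groupby(["subject", "connectivity", "contrast"]).size()
    if (cells != 1).any():
        raise ValueError("unbalanced design: need exactly one value per cell")
    if np.allclose(indices["value"].std(), 0.0):
        terms = ["connectivity", "contrast", "connectivity:contrast"]
        return pd.DataFrame(
            {"term": terms, "F": 0.0, "df_num": np.nan, "df_den": np.nan, "p": 1.0}
        )
    res = AnovaRM(
        indices, depvar="value", subject="subject",
        within=["connectivity", "contrast"],
    ).fit()
    tab = res.anova_table.reset_index().rename(
        columns={
            "index": "term", "F Value": "F", "Num DF": "df_num",
            "Den DF": "df_den", "Pr > F": "p",
        }
    )
    tab["term"] = tab["term"].str.replace(":", ":", regex=False)
    return tab[["term", "F", "df_num", "df_den", "p"]]


def parcellation_overlap(mask: np.ndarray, parcels: np.ndarray) -> dict:
    """Percent of mask cells falling in each parcel label."""
    mask = np.asarray(mask, dtype=bool)
    parcels = np.asarray(parcels)
    if mask.shape != parcels.shape:
        raise ValueError("mask and parcel arrays must share a shape")
    total = mask.sum()
    if total == 0:
        raise ValueError("empty mask")
    out = {}
    for label in np.unique(parcels):
        out[label] = 100.0 * float(np.sum(mask & (parcels == label))) / float(total)
    return out
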