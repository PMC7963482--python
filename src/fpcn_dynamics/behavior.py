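"""Trial filtering, present/future behavior vectors, and brain-behavior models.

Sub-task-phase reaction times are "present behavior" (concurrent with the
modeled activation); return-trial reaction times are "future behavior" (the
performance the sub-task phase prepared).  Filtering keeps correct trials,
drops anticipatory (<200 ms) and inattentive (>2000 ms) responses, then
removes one-sided outliers beyond mean + 2.5 SD of each condition cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .task_design import CONDITIONS

logger = logging.getLogger(__name__)

ANTICIPATORY_MS = 200.0
INATTENTIVE_MS = 2000.0
OUTLIER_SD = 2.5

PHASES = ("baseline1", "subtask", "return", "transition")


@dataclass
class BehaviorVectors:
    """Per-subject 8-condition mean RTs, z-scored within phase."""

    present: np.ndarray  # subject x 8 (sub-task phase)
    future: np.ndarray  # subject x 8 (return trials)
    subjects: tuple
    condition_labels: tuple[str, ...] = CONDITIONS


def filter_rts(
    trials: pd.DataFrame, two_sided: bool = False
) -> tuple[pd.DataFrame, dict]:
    """Apply the RT filter cascade; return surviving trials and a report.

    Order: correct-only -> absolute thresholds (200/2000 ms) -> per
    (subject, condition, phase) SD pass at mean + 2.5 SD (one-sided high by
    default) computed on the post-threshold set.
    """
    n_input = len(trials)
    correct = trials[trials["correct"].astype(bool)].copy()
    n_error = n_input - len(correct)
    anticipatory = correct["rt"] < ANTICIPATORY_MS
    inattentive = correct["rt"] > INATTENTIVE_MS
    kept = correct[~anticipatory & ~inattentive].copy()

    keys = [k for k in ("subject", "condition", "phase") if k in kept.columns]
    grouped = kept.groupby(keys)["rt"]
    mu = grouped.transform("mean")
    sd = grouped.transform("std")
    guard = sd.fillna(0.0) > 0
    ok = ~guard | (kept["rt"] <= mu + OUTLIER_SD * sd)
    if two_sided:
        ok &= ~guard | (kept["rt"] >= mu - OUTLIER_SD * sd)
    out = kept[ok]
    n_outlier = int((~ok).sum())
    flagged = [
        key for key, g in out.groupby(keys) if len(g) < 3
    ]
    if flagged:
        logger.warning("cells with <3 surviving trials: %s", flagged)
    n_correct = len(correct)
    report = {
        "n_input": n_input,
        "n_error": int(n_error),
        "n_anticipatory": int(anticipatory.sum()),
        "n_inattentive": int(inattentive.sum()),
        "n_outlier": n_outlier,
        "n_kept": len(out),
        "fraction_removed_of_correct": (
            (n_correct - len(out)) / n_correct if n_correct else np.nan
        ),
        "low_count_cells": flagged,
    }
    return out.copy(), report


def behavior_vectors(trials: pd.DataFrame) -> BehaviorVectors:
    """Condition-mean RTs per phase, z-scored (ddof=1) within subject x phase."""
    subjects = tuple(sorted(trials["subject"].unique()))
    out = {}
    for phase in ("subtask", "return"):
        sub = trials[trials["phase"] == phase]
        mat = np.zeros((len(subjects), len(CONDITIONS)))
        for si, s in enumerate(subjects):
            g = sub[sub["subject"] == s]
            means = g.groupby("condition")["rt"].mean()
            missing = [c for c in CONDITIONS if c not in means.index]
            if missing:
                raise ValueError(
                    f"subject {s!r} phase {phase!r} missing condition(s) {missing}"
                )
            v = means.reindex(list(CONDITIONS)).to_numpy()
            sd = v.std(ddof=1)
            if sd == 0:
                raise ValueError(
                    f"degenerate behavior vector (constant means) for subject {s!r} "
                    f"phase {phase!r}"
                )
            mat[si] = (v - v.mean()) / sd
        out[phase] = mat
    return BehaviorVectors(present=out["subtask"], future=out["return"], subjects=subjects)


def _within_center(mat: np.ndarray) -> np.ndarray:
    return mat - mat.mean(axis=1, keepdims=True)


def rm_correlation(
    x: np.ndarray, y: np.ndarray, partial_out: np.ndarray | None = None
) -> tuple[float, int, float]:
    """Repeated-measures correlation (ANCOVA formulation, subject strata).

    ``x`` and ``y`` are subject x condition matrices.  The common
    within-subject correlation is the correlation of the within-subject
    centered values; ``partial_out`` (same shape) is residualized out of both
    within the same stratified model, costing one further df.  Returns
    ``(r_rm, df, p)`` with ``df = N - n_subjects - 1 - n_partial``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 2:
        raise ValueError("x and y must be subject x condition matrices of equal shape")
    n_subj, n_cond = x.shape
    if n_subj < 2 or n_cond < 3:
        raise ValueError("need >= 2 subjects and >= 3 conditions")
    xc = _within_center(x).ravel()
    yc = _within_center(y).ravel()
    if np.allclose(xc, 0) or np.allclose(yc, 0):
        raise ValueError("x or y constant within all subjects")
    n_partial = 0
    if partial_out is not None:
        z = _within_center(np.asarray(partial_out, dtype=float)).ravel()
        denom = z @ z
        if denom > 0:
            xc = xc - (xc @ z / denom) * z
            yc = yc - (yc @ z / denom) * z
            n_partial = 1
    df = x.size - n_subj - 1 - n_partial
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        return r, df, 0.0
    t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, df, float(p)


def brain_behavior_slopes(
    activation: np.ndarray, vectors: BehaviorVectors
) -> pd.DataFrame:
    """Per-subject simultaneous regression of activation on present + future RT.

    ``activation`` is subject x 8 (one ROI, condition order as in the
    vectors).  Returns a table (subject, present_slope, future_slope).
    """
    act = np.asarray(activation, dtype=float)
    if act.shape != vectors.present.shape:
        raise ValueError("activation must be subject x 8, aligned with the vectors")
    rows = []
    for si, s in enumerate(vectors.subjects):
        p, f = vectors.present[si], vectors.future[si]
        r_pf = np.corrcoef(p, f)[0, 1]
        if abs(r_pf) > 0.999:
            logger.warning("present/future vectors nearly collinear for subject %s", s)
        X = np.column_stack([np.ones(len(p)), p, f])
        beta, _, _, _ = np.linalg.lstsq(X, act[si], rcond=None)
        rows.append((s, float(beta[1]), float(beta[2])))
    return pd.DataFrame(rows, columns=["subject", "present_slope", "future_slope"])


def slope_abstraction_lmm(
    slopes: pd.DataFrame, abstraction: dict[str, float], value_col: str = "slope"
) -> pd.DataFrame:
    """Mixed model: behavior slope ~ abstraction + (abstraction | subject).

    ``slopes`` is long format (subject, roi, <value_col>); falls back to
    per-subject OLS slopes with a one-sample t-test when the random-effects
    fit fails to converge.  Returns a one-row tidy table for the abstraction
    effect (term, estimate, se, stat, df, p).
    """
    import statsmodels.api as sm

    df = slopes.copy()
    if df["subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    if df["roi"].nunique() < 3:
        raise ValueError("need at least 3 ROIs")
    df["abstraction"] = df["roi"].map(abstraction)
    if df["abstraction"].isna().any():
        missing = sorted(df.loc[df["abstraction"].isna(), "roi"].unique())
        raise ValueError(f"no abstraction score for ROI(s) {missing}")
    exog = sm.add_constant(df[["abstraction"]])
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.MixedLM(
                df[value_col].to_numpy(), exog, groups=df["subject"].to_numpy(),
                exog_re=exog,
            ).fit(reml=True)
        ok = fit.converged and np.all(np.isfinite(fit.bse[:2]))
    except Exception:
        ok = False
    if ok:
        est = float(fit.params["abstraction"])
        se = float(fit.bse["abstraction"])
        dof = len(df) - 2
        stat = est / se
        p = 2.0 * stats.t.sf(abs(stat), dof)
    else:
        logger.info("mixed fit did not converge; per-subject OLS fallback")
        per = []
        for _, g in df.groupby("subject"):
            X = np.column_stack([np.ones(len(g)), g["abstraction"]])
            b, _, _, _ = np.linalg.lstsq(X, g[value_col].to_numpy(), rcond=None)
            per.append(b[1])
        per = np.asarray(per)
        est = float(per.mean())
        se = float(per.std(ddof=1) / np.sqrt(len(per)))
        dof = len(per) - 1
        stat = est / se if se > 0 else 0.0
        p = 2.0 * stats.t.sf(abs(stat), dof)
    return pd.DataFrame(
        [("abstraction", est, se, float(stat), dof, float(p))],
        columns=["term", "estimate", "se", "stat", "df", "p"],
    )
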