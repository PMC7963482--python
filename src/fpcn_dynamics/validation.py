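"""Recovery, bias, and calibration experiments on ground-truth simulations.

Each function runs a self-contained study against planted truth and returns
the summary statistics a reviewer would ask for (recovery error, bias curve,
win rate, type-I rate).  They are deliberately seeded and sized so the whole
battery completes on one CPU in minutes; the methods note records the
problem sizes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import synthetic_data as synth
from .behavior import (
    behavior_vectors,
    brain_behavior_slopes,
    filter_rts,
    rm_correlation,
    slope_abstraction_lmm,
)
from .network_metrics import (
    NetworkAssignment,
    NETWORKS,
    abstraction_gradient_model,
    dynamic_integration_index,
    integration_index,
    network_summary,
    residualize,
)
from .ppi import (
    estimate_static_ec,
    fit_ppi,
    fit_ppi_all,
    fit_ppi_posthoc,
    ppi_contrasts,
)
from .prediction import crossval_predict, first_pc, permutation_p
from .profiling import classical_mds
from .rest_scaffold import cost_threshold
from .task_design import build_design, default_block_spec, define_contrasts

#: abstraction scores of the planted gradient: temporal-control ROIs are the
#: most abstract, sensory-motor-control ROIs the most concrete
PLANTED_ABSTRACTION = {"TC": 1.0, "CC": 0.0, "SC": -1.0}


def _default_design(repetition_time: float = 2.0):
    spec_map, total_s = default_block_spec()
    return build_design(spec_map, repetition_time, int(total_s / repetition_time))


def ppi_exactness_experiment(
    n_connections: int = 45, n_subjects: int = 20, seed: int = 0
) -> dict:
    """Noise-free closed-loop recovery of (B_conn, B_dep) for every connection.

    Targets are generated directly from the interaction model (HRF off,
    noise off); the fitted coefficients must match both the planted values
    and an independently coded normal-equations solution.
    """
    from .ppi import _base_columns, _interaction_columns

    design = _default_design()
    contrasts = ppi_contrasts()
    weights = {n: contrasts.row(n) for n in contrasts.names}
    rng = np.random.default_rng(seed)
    max_err_planted = 0.0
    max_err_oracle = 0.0
    n_fits = 0
    for _ in range(n_subjects):
        for _ in range(n_connections):
            b_conn = rng.uniform(-0.8, 0.8)
            b_dep = {n: rng.uniform(-0.5, 0.5) for n in contrasts.names}
            src, tgt = synth.simulate_ppi_pair(
                design, weights, b_conn=b_conn, b_dep=b_dep, noise_sd=0.0, seed=rng,
            )
            res = fit_ppi(tgt, src, design, contrasts)
            err = abs(res.b_conn - b_conn)
            for n in contrasts.names:
                err = max(err, abs(res.b_dep[n] - b_dep[n]))
            max_err_planted = max(max_err_planted, err)
            base, _ = _base_columns(design, src)
            inter, _ = _interaction_columns(design, contrasts, src)
            M = np.column_stack([base, inter])
            beta = np.linalg.solve(M.T @ M, M.T @ tgt)
            n_base = base.shape[1]
            for k, n in enumerate(contrasts.names):
                max_err_oracle = max(max_err_oracle, abs(res.b_dep[n] - beta[n_base + k]))
            max_err_oracle = max(max_err_oracle, abs(res.b_conn - beta[0]))
            n_fits += 1
    return {
        "max_abs_error_vs_planted": float(max_err_planted),
        "max_abs_error_vs_oracle": float(max_err_oracle),
        "n_fits": n_fits,
    }


def ppi_bias_experiment(
    n_seeds: int = 200,
    grid: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8),
    seed: int = 0,
) -> dict:
    """Coupling-dependent bias of post-hoc vs in-model contrast estimation.

    Planted B_dep = 0 throughout; the source carries condition-dependent
    innovation variance plus measurement noise (the attenuation mechanism),
    and the mean estimated contextual B_dep is tracked across the planted
    B_conn grid for both estimators.
    """
    design = _default_design()
    contrasts = ppi_contrasts()
    weights = {n: contrasts.row(n) for n in contrasts.names}
    row = contrasts.row("contextual")
    cond = synth.bias_study_conditions(row)
    rng = np.random.default_rng(seed)
    posthoc_means, inmodel_means = [], []
    for b in grid:
        ph, im = [], []
        for _ in range(n_seeds):
            src, tgt = synth.simulate_ppi_pair(
                design, weights, b_conn=b, b_dep={}, seed=rng, **cond,
            )
            ph.append(fit_ppi_posthoc(tgt, src, design, contrasts).b_dep["contextual"])
            im.append(fit_ppi(tgt, src, design, contrasts).b_dep["contextual"])
        posthoc_means.append(float(np.mean(ph)))
        inmodel_means.append(float(np.mean(im)))
    rho = float(stats.spearmanr(grid, posthoc_means).statistic)
    return {
        "grid": list(grid),
        "posthoc_mean_bdep": posthoc_means,
        "inmodel_mean_bdep": inmodel_means,
        "posthoc_spearman_rho": rho,
        "inmodel_max_abs_mean": float(np.max(np.abs(inmodel_means))),
        "n_seeds": n_seeds,
    }


def contrast_orthogonality() -> dict:
    """Exact integer Gram matrix of the five contrasts-of-interest."""
    C = define_contrasts()
    five = [C.names.index(n) for n in
            ("temporal", "contextual", "sensorimotor", "verbal", "contextual_x_domain")]
    W = C.weights[five].astype(int)
    G = W @ W.T
    off = G - np.diag(np.diag(G))
    return {
        "max_abs_off_diagonal": int(np.abs(off).max()),
        "row_sums_max_abs": int(np.abs(W.sum(axis=1)).max()),
    }


def integration_recovery_experiment(
    n_cohorts: int = 100, n_subjects: int = 24, seed: int = 0
) -> dict:
    """Recovery of the planted integrator/segregator network architecture.

    Per cohort: simulate the full task run for every subject, estimate static
    EC (lag-1 ridge) and in-model PPI modulations, and check that (a) the
    contextual-control network's static integration index is the largest and
    (b) the dynamic integration index is largest for the contextual contrast
    (whose planted modulation matrix is between-network).
    """
    design = _default_design()
    contrasts = ppi_contrasts()
    assign = NetworkAssignment.default()
    cc_wins = 0
    dyn_wins = 0
    for c in range(n_cohorts):
        truth = synth.default_truth(seed=seed * 100003 + c)
        spec = synth.CohortSpec(n_subjects=n_subjects, n_timepoints=design.n_scans)
        runs, _ = synth.simulate_task_timeseries(truth, design, spec)
        static_idx = {n: [] for n in NETWORKS}
        dyn_idx: dict[str, list[float]] = {}
        for ts in runs:
            ec = estimate_static_ec(ts, ridge_penalty=1.0)
            summ = network_summary(ec.A, assign, ts.roi_labels)
            for net in NETWORKS:
                static_idx[net].append(integration_index(summ, net))
            long = fit_ppi_all(ts, design, contrasts)
            from .ppi import b_dep_matrix

            for cname in ("temporal", "contextual", "verbal"):
                mat = b_dep_matrix(long, cname, ts.roi_labels)
                ds = network_summary(mat, assign, ts.roi_labels)
                dyn_idx.setdefault(cname, []).append(dynamic_integration_index(ds))
        means = {n: float(np.mean(v)) for n, v in static_idx.items()}
        if means["CC"] > means["TC"] and means["CC"] > means["SC"]:
            cc_wins += 1
        dmeans = {n: float(np.mean(v)) for n, v in dyn_idx.items()}
        if dmeans["contextual"] == max(dmeans.values()):
            dyn_wins += 1
    return {
        "cc_static_win_rate": cc_wins / n_cohorts,
        "contextual_dynamic_win_rate": dyn_wins / n_cohorts,
        "n_cohorts": n_cohorts,
        "n_subjects": n_subjects,
    }


def abstraction_gradient_experiment(
    n_seeds: int = 100, n_subjects: int = 24, seed: int = 0
) -> dict:
    """Power of the gradient models at the planted effects.

    (a) mixed model on coupling with a planted negative quadratic
    source-abstraction effect (-0.2, noise SD 0.3); (b) the full behavioral
    chain (trial simulation -> RT filter -> behavior vectors -> per-subject
    slopes -> random-slope mixed model) with the generator's planted
    present/future activation slopes (negative/positive along abstraction).
    """
    quad_hits = present_hits = future_hits = 0
    abstraction_10 = None
    for s in range(n_seeds):
        rng = np.random.default_rng(seed * 7919 + s)
        # (a) planted quadratic source-abstraction effect in coupling
        a_vals = np.linspace(-1.0, 1.0, 10)
        rows = []
        for subj in range(n_subjects):
            icpt = rng.normal(0, 0.1)
            for i, sa in enumerate(a_vals):
                for j, ta in enumerate(a_vals):
                    if i == j:
                        continue
                    ec = 0.3 * sa * ta - 0.2 * sa**2 + icpt + rng.normal(0, 0.3)
                    rows.append((subj, sa, ta, ec))
        long = pd.DataFrame(rows, columns=["subject", "source_abs", "target_abs", "ec"])
        out = abstraction_gradient_model(long).set_index("term")
        if out.loc["source_sq", "estimate"] < 0 and out.loc["source_sq", "p"] < 0.05:
            quad_hits += 1

        # (b) behavioral chain with the generator's planted slopes
        truth = synth.default_truth(seed=seed * 7919 + s)
        if abstraction_10 is None:
            assign = NetworkAssignment.default()
            abstraction_10 = {
                r: PLANTED_ABSTRACTION[assign.networks[r]] for r in truth.roi_labels
            }
        spec = synth.CohortSpec(n_subjects=n_subjects, n_timepoints=100)
        acts = truth.drive + rng.normal(0, 0.2, size=(n_subjects, *truth.drive.shape))
        acts = (acts - acts.mean(axis=2, keepdims=True)) / acts.std(
            axis=2, ddof=1, keepdims=True
        )
        trials = synth.simulate_behavior(
            truth, acts, spec, seed=rng, anticipatory_frac=0.02,
            inattentive_frac=0.01, error_frac=0.05,
        )
        filtered, _ = filter_rts(trials)
        vectors = behavior_vectors(filtered)
        slope_rows = []
        for ri, roi in enumerate(truth.roi_labels):
            sl = brain_behavior_slopes(acts[:, ri, :], vectors)
            for rec in sl.itertuples():
                slope_rows.append((rec.subject, roi, rec.present_slope, rec.future_slope))
        slopes = pd.DataFrame(
            slope_rows, columns=["subject", "roi", "present_slope", "future_slope"]
        )
        lm_p = slope_abstraction_lmm(slopes, abstraction_10, value_col="present_slope")
        lm_f = slope_abstraction_lmm(slopes, abstraction_10, value_col="future_slope")
        if lm_p["estimate"].iloc[0] < 0 and lm_p["p"].iloc[0] < 0.05:
            present_hits += 1
        if lm_f["estimate"].iloc[0] > 0 and lm_f["p"].iloc[0] < 0.05:
            future_hits += 1
    return {
        "quadratic_power": quad_hits / n_seeds,
        "present_slope_power": present_hits / n_seeds,
        "future_slope_power": future_hits / n_seeds,
        "n_seeds": n_seeds,
        "n_subjects": n_subjects,
    }


def rm_corr_experiments(
    n_oracle: int = 25, n_null: int = 500, seed: int = 0
) -> dict:
    """Oracle equivalence and type-I calibration of the rm-correlation."""
    rng = np.random.default_rng(seed)
    max_diff = 0.0
    for _ in range(n_oracle):
        n_subj = int(rng.integers(3, 8))
        n_cond = int(rng.integers(4, 9))
        x = rng.normal(size=(n_subj, n_cond))
        y = rng.normal(size=(n_subj, n_cond))
        r, _, _ = rm_correlation(x, y)
        # stratified-regression oracle: project out subject dummies explicitly
        D = np.kron(np.eye(n_subj), np.ones((n_cond, 1)))
        P = np.eye(n_subj * n_cond) - D @ np.linalg.pinv(D)
        xr, yr = P @ x.ravel(), P @ y.ravel()
        r_oracle = float(xr @ yr / np.sqrt((xr @ xr) * (yr @ yr)))
        max_diff = max(max_diff, abs(r - r_oracle))
    rejections = 0
    for _ in range(n_null):
        x = rng.normal(size=(8, 8))
        y = rng.normal(size=(8, 8))
        _, _, p = rm_correlation(x, y)
        rejections += p < 0.05
    return {
        "max_abs_diff_vs_oracle": float(max_diff),
        "type1_rate": rejections / n_null,
        "n_null": n_null,
    }


def prediction_chain_experiment(
    n_seeds: int = 100,
    n_perm: int = 200,
    n_fold_a: int = 24,
    n_fold_b: int = 25,
    multiple_r: float = 0.5,
    seed: int = 0,
) -> dict:
    """End-to-end power and false-positive calibration of the prediction chain.

    Cohort features are simulated with the planted sign structure (static
    integration negative, dynamic positive) at a per-feature correlation
    giving the requested multiple correlation with latent ability; features
    are residualized on head motion, then two-fold ridge (penalty 1) with a
    row-permutation test is run against the battery composite.
    """
    # per-feature |r| giving multiple R: R^2 = 2 rho^2 / (1 + rho^2);
    # referenced to the measured battery composite, whose correlation with
    # latent g is attenuated by test reliability (loadings 0.7, noise 0.5,
    # 5 tests -> corr(composite, g) ~ 0.95)
    composite_reliability = 0.953
    rho = float(np.sqrt(multiple_r**2 / (2.0 - multiple_r**2))) / composite_reliability
    n = n_fold_a + n_fold_b
    folds = np.array([0] * n_fold_a + [1] * n_fold_b)
    sig = 0
    null_sig = 0
    r_preds = []
    for s in range(n_seeds):
        rng = np.random.default_rng(seed * 104729 + s)
        for planted, counter in (("effect", None), ("null", None)):
            truth = synth.default_truth(seed=int(rng.integers(2**31)))
            truth.ability_integration_corr = rho if planted == "effect" else 0.0
            feats = synth.simulate_cohort_features(
                truth, n, np.full(5, 0.7), seed=rng
            )
            battery = feats[[c for c in feats.columns if c.startswith("battery_")]]
            composite = first_pc(battery.to_numpy())
            X = np.column_stack([
                residualize(feats["static_integration"].to_numpy(),
                            feats["rms_fd"].to_numpy()),
                residualize(feats["dynamic_integration"].to_numpy(),
                            feats["rms_fd"].to_numpy()),
            ])
            p, res = permutation_p(
                X, composite, scheme="two_fold_by_sample", ridge_penalty=1.0,
                fold_labels=folds, n_perm=n_perm, seed=rng,
            )
            if planted == "effect":
                r_preds.append(res.r_pred)
                sig += p < 0.05
            else:
                null_sig += p < 0.05
    return {
        "power": sig / n_seeds,
        "null_false_positive_rate": null_sig / n_seeds,
        "mean_r_pred": float(np.mean(r_preds)),
        "n_seeds": n_seeds,
        "n_subjects": n,
    }


def plumbing_checks(seed: int = 0) -> dict:
    """Deterministic fixture checks: RT filter, 3-of-4 rule, ridge, MDS."""
    rng = np.random.default_rng(seed)
    # RT filter fixture: 1 anticipatory, 1 inattentive, 1 high outlier
    trials = pd.DataFrame({
        "subject": 0,
        "condition": "SB",
        "phase": "subtask",
        "rt": [150.0, 2500.0] + [590.0] * 50 + [610.0] * 50 + [800.0],
        "correct": True,
    })
    _, report = filter_rts(trials)
    # candidate 3-of-4 rule on enumerated counts
    from .rest_scaffold import CandidateMatrix

    rule_ok = True
    for counts in range(5):
        mat = np.array([[0, counts], [counts, 0]])
        cand = CandidateMatrix(
            counts=mat, candidate=(mat >= 3) & ~np.eye(2, dtype=bool),
            roi_labels=("A", "B"),
        )
        rule_ok &= bool(cand.candidate[0, 1]) == (counts >= 3)
    # ridge at zero penalty equals OLS
    from .prediction import ridge_fit

    X = rng.normal(size=(40, 3))
    y = X @ np.array([1.0, -1.0, 0.5]) + rng.normal(size=40)
    w0, model = ridge_fit(X, y, ridge_penalty=0.0)
    Z = (X - model["feature_mean"]) / model["feature_sd"]
    w_ols = np.linalg.solve(Z.T @ Z, Z.T @ (y - y.mean()))
    ridge_diff = float(np.max(np.abs(w0 - w_ols)))
    # classical MDS reconstructs toy dissimilarities
    D = np.array([[0.0, 0.2, 0.2], [0.2, 0.0, 0.4], [0.2, 0.4, 0.0]])
    coords, _ = classical_mds(D)
    rec = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    mds_err = float(np.max(np.abs(rec - D)))
    # cost-threshold rank rule (correlation ladder 0.01..1.00)
    ct = cost_threshold(np.arange(1.0, 101.0) / 100.0, c=18.0)
    return {
        "rt_filter_counts": {
            "anticipatory": report["n_anticipatory"],
            "inattentive": report["n_inattentive"],
            "outlier": report["n_outlier"],
            "kept": report["n_kept"],
        },
        "candidate_rule_exact": bool(rule_ok),
        "ridge_ols_max_abs_diff": ridge_diff,
        "mds_reconstruction_max_abs_err": mds_err,
        "cost_threshold_r": ct.r,
    }
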