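"""PPI estimator exactness, bias behavior, and the static-EC plumbing estimator."""

import numpy as np
import pandas as pd
import pytest

from fpcn_dynamics import (
    CohortSpec,
    RoiTimeSeries,
    estimate_static_ec,
    fit_ppi,
    fit_ppi_all,
    fit_ppi_posthoc,
    ppi_replicability,
    simulate_ppi_pair,
    simulate_rest_timeseries,
)
from fpcn_dynamics.synthetic_data import DEFAULT_ROIS, SyntheticTruth
from fpcn_dynamics.task_design import ContrastMatrix


def _weights(ppi_c):
    return {n: ppi_c.row(n) for n in ppi_c.names}


def _normal_equations_oracle(M, y):
    """Independent closed-form solution (X'X)^-1 X'y."""
    return np.linalg.solve(M.T @ M, M.T @ y)


class TestFitPpi:
    def test_recovers_planted_coefficients_exactly(self, design, ppi_c):
        src, tgt = simulate_ppi_pair(
            design, _weights(ppi_c), b_conn=0.3,
            b_dep={"contextual": 0.5}, noise_sd=0.0, seed=1,
        )
        res = fit_ppi(tgt, src, design, ppi_c)
        assert res.b_conn == pytest.approx(0.3, abs=1e-8)
        assert res.b_dep["contextual"] == pytest.approx(0.5, abs=1e-8)
        for name in ("temporal", "sensorimotor", "verbal"):
            assert res.b_dep[name] == pytest.approx(0.0, abs=1e-8)

    def test_null_modulation_estimated_as_zero(self, design, ppi_c):
        src, tgt = simulate_ppi_pair(
            design, _weights(ppi_c), b_conn=0.7, b_dep={}, noise_sd=0.0, seed=2,
        )
        res = fit_ppi(tgt, src, design, ppi_c)
        for v in res.b_dep.values():
            assert v == pytest.approx(0.0, abs=1e-8)

    def test_matches_normal_equations_oracle_on_random_instances(self, design, ppi_c, rng):
        from fpcn_dynamics.ppi import _base_columns, _interaction_columns

        for _ in range(5):
            src = rng.normal(size=design.n_scans)
            tgt = rng.normal(size=design.n_scans)
            res = fit_ppi(tgt, src, design, ppi_c)
            base, _ = _base_columns(design, src)
            inter, _ = _interaction_columns(design, ppi_c, src)
            M = np.column_stack([base, inter])
            beta = _normal_equations_oracle(M, tgt)
            assert res.b_conn == pytest.approx(beta[0], abs=1e-8)
            n_base = base.shape[1]
            for k, name in enumerate(ppi_c.names):
                assert res.b_dep[name] == pytest.approx(beta[n_base + k], abs=1e-8)

    def test_contrast_row_order_does_not_change_estimates(self, design, ppi_c, rng):
        src = rng.normal(size=design.n_scans)
        tgt = rng.normal(size=design.n_scans)
        res1 = fit_ppi(tgt, src, design, ppi_c)
        perm = [2, 0, 4, 1, 3]
        shuffled = ContrastMatrix(
            ppi_c.weights[perm], tuple(ppi_c.names[i] for i in perm),
            ppi_c.condition_labels,
        )
        res2 = fit_ppi(tgt, src, design, shuffled)
        for name in ppi_c.names:
            assert res1.b_dep[name] == pytest.approx(res2.b_dep[name], abs=1e-10)

    def test_scale_equivariance(self, design, ppi_c, rng):
        src = rng.normal(size=design.n_scans)
        tgt = rng.normal(size=design.n_scans)
        res1 = fit_ppi(tgt, src, design, ppi_c)
        res2 = fit_ppi(7.3 * tgt, 7.3 * src, design, ppi_c)
        assert res2.b_conn == pytest.approx(res1.b_conn, abs=1e-9)
        for name in ppi_c.names:
            assert res2.b_dep[name] == pytest.approx(res1.b_dep[name], abs=1e-9)

    def test_zero_variance_source_rejected(self, design, ppi_c):
        with pytest.raises(ValueError, match="zero-variance"):
            fit_ppi(np.ones(design.n_scans), np.ones(design.n_scans), design, ppi_c)

    def test_collinear_design_rejected_with_pair_named(self, design, contrasts, rng):
        # full 6-contrast matrix: verbal and spatial interactions are negations
        src = rng.normal(size=design.n_scans)
        tgt = rng.normal(size=design.n_scans)
        with pytest.raises(ValueError, match="ppi_verbal.*ppi_spatial"):
            fit_ppi(tgt, src, design, contrasts)


class TestFitPpiPosthoc:
    def test_zero_signal_gives_zero_coefficients(self, design, ppi_c, rng):
        src = rng.normal(size=design.n_scans)
        res = fit_ppi_posthoc(np.zeros(design.n_scans), src, design, ppi_c)
        assert res.b_conn == pytest.approx(0.0, abs=1e-10)
        for v in res.b_dep.values():
            assert v == pytest.approx(0.0, abs=1e-10)

    def test_normalized_contrast_matches_in_model_when_noise_free(self, design, ppi_c):
        # algebraic equivalence: both models span the same column space
        src, tgt = simulate_ppi_pair(
            design, _weights(ppi_c), b_conn=0.4,
            b_dep={"contextual": 0.5, "temporal": -0.2}, noise_sd=0.0, seed=3,
        )
        res_in = fit_ppi(tgt, src, design, ppi_c)
        res_ph = fit_ppi_posthoc(tgt, src, design, ppi_c, normalize_contrast=True)
        for name in ("contextual", "temporal"):
            assert res_ph.b_dep[name] == pytest.approx(res_in.b_dep[name], abs=1e-6)

    def test_posthoc_contrast_negatively_biased_when_strongly_coupled(self, design, ppi_c):
        # the in-model variant's motivation: with planted B_dep = 0 and strong
        # coupling, the after-the-fact contrast drifts negative
        from fpcn_dynamics.synthetic_data import bias_study_conditions

        cond = bias_study_conditions(ppi_c.row("contextual")[
            [list(ppi_c.condition_labels).index(c) for c in design.condition_labels]
        ])
        rng = np.random.default_rng(11)
        vals = []
        for _ in range(60):
            src, tgt = simulate_ppi_pair(
                design, _weights(ppi_c), b_conn=0.8, b_dep={}, seed=rng, **cond,
            )
            vals.append(fit_ppi_posthoc(tgt, src, design, ppi_c).b_dep["contextual"])
        mean = np.mean(vals)
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert mean < 0 and mean / se < -2.0


class TestStaticEc:
    def _truth(self, n=4, seed=0):
        A = -0.9 * np.eye(n)
        A[0, 1] = 0.5
        A[2, 3] = -0.4
        A[1, 2] = 0.3
        return SyntheticTruth(
            coupling_matrix=A,
            modulation_matrices={},
            present_slope_by_roi={},
            future_slope_by_roi={},
            ability_integration_corr=0.0,
            seed=seed,
            roi_labels=DEFAULT_ROIS[:n],
        )

    def test_recovers_planted_coupling_pattern(self):
        truth = self._truth(seed=42)
        spec = CohortSpec(n_subjects=1, n_timepoints=2000, noise_sd=0.05,
                          hrf_enabled=False, network_assignment={}, oversampling=4)
        ts = simulate_rest_timeseries(truth, spec, 1)[0]
        ec = estimate_static_ec(ts, ridge_penalty=1.0)
        mask = ~np.eye(4, dtype=bool)
        r = np.corrcoef(ec.A[mask], truth.coupling_matrix[mask])[0, 1]
        assert r >= 0.9

    def test_independent_rois_estimated_near_zero(self):
        means = []
        for seed in range(30):
            truth = self._truth(seed=seed)
            truth.coupling_matrix = -0.9 * np.eye(4)
            spec = CohortSpec(n_subjects=1, n_timepoints=500, noise_sd=0.0,
                              hrf_enabled=False, network_assignment={}, oversampling=4)
            ts = simulate_rest_timeseries(truth, spec, 1)[0]
            ec = estimate_static_ec(ts)
            means.append(ec.A[~np.eye(4, dtype=bool)].mean())
        assert abs(np.mean(means)) < 0.02

    def test_non_candidate_entries_exactly_zero(self):
        truth = self._truth(seed=7)
        spec = CohortSpec(n_subjects=1, n_timepoints=300, noise_sd=0.1,
                          hrf_enabled=False, network_assignment={}, oversampling=4)
        ts = simulate_rest_timeseries(truth, spec, 1)[0]
        cand = np.zeros((4, 4), dtype=bool)
        cand[0, 1] = cand[1, 0] = True
        ec = estimate_static_ec(ts, cand)
        assert ec.A[0, 2] == 0.0 and ec.A[2, 3] == 0.0 and ec.A[0, 1] != 0.0

    def test_too_few_timepoints_rejected(self):
        ts = RoiTimeSeries(np.random.default_rng(0).normal(size=(4, 3)),
                           DEFAULT_ROIS[:3], 2.0)
        with pytest.raises(ValueError, match="lagged timepoints"):
            estimate_static_ec(ts)


class TestReplicability:
    def _long(self, values, contrast="contextual"):
        rows = []
        k = 0
        for s in ("A", "B", "C"):
            for t in ("A", "B", "C"):
                if s == t:
                    continue
                rows.append((s, t, contrast, values[k], 0.0))
                k += 1
        return pd.DataFrame(rows, columns=["source", "target", "contrast", "b_dep", "b_conn"])

    def test_identical_inputs_give_unit_correlation(self, rng):
        a = self._long(rng.normal(size=6))
        assert ppi_replicability(a, a.copy())["contextual"] == pytest.approx(1.0)

    def test_independent_null_cohorts_give_small_correlation(self):
        rng = np.random.default_rng(0)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            # 45-connection null draws
            a = pd.DataFrame({
                "source": np.repeat(np.arange(45), 1).astype(str),
                "target": "t", "contrast": "c",
                "b_dep": rng.normal(size=45), "b_conn": 0.0,
            })
            b = a.copy()
            b["b_dep"] = rng.normal(size=45)
            hits += abs(ppi_replicability(a, b)["c"]) < 0.3
        # null r has SD ~ 1/sqrt(44) = 0.15, so P(|r| < 0.3) ~ 0.95; allow
        # binomial fluctuation around that expectation
        assert hits >= 0.91 * n_rep

    def test_mismatched_connection_sets_rejected(self, rng):
        a = self._long(rng.normal(size=6))
        b = self._long(rng.normal(size=6))
        b.loc[0, "source"] = "Z"
        with pytest.raises(ValueError, match="differ"):
            ppi_replicability(a, b)


class TestFitPpiAll:
    def test_matches_single_pair_fit(self, design, ppi_c, rng):
        data = rng.normal(size=(design.n_scans, 3))
        ts = RoiTimeSeries(data, DEFAULT_ROIS[:3], 2.0)
        long = fit_ppi_all(ts, design, ppi_c)
        single = fit_ppi(data[:, 1], data[:, 0], design, ppi_c)
        row = long[(long["source"] == DEFAULT_ROIS[0]) &
                   (long["target"] == DEFAULT_ROIS[1]) &
                   (long["contrast"] == "contextual")].iloc[0]
        assert row["b_dep"] == pytest.approx(single.b_dep["contextual"], abs=1e-10)
        assert row["b_conn"] == pytest.approx(single.b_conn, abs=1e-10)
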