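"""Network-cell aggregation, integration indices, ANOVA, and gradient models."""

import numpy as np
import pandas as pd
import pytest

from fpcn_dynamics import (
    NetworkAssignment,
    abstraction_gradient_model,
    dynamic_integration_index,
    integration_index,
    lobe_magnitude,
    network_summary,
    parcellation_overlap,
    residualize,
    within_between_anova,
)
from fpcn_dynamics.synthetic_data import DEFAULT_ROIS


@pytest.fixture(scope="module")
def assign():
    return NetworkAssignment.default()


class TestLobeMagnitude:
    def test_constant_matrix_gives_constant_cells(self, assign):
        A = np.full((10, 10), 0.2)
        out = lobe_magnitude(A, assign, DEFAULT_ROIS)
        assert np.allclose(out.to_numpy(), 0.2)

    def test_pfc_sources_stronger(self, assign):
        # |EC| 0.5 from PFC sources, 0.1 from PPC sources
        A = np.zeros((10, 10))
        signs = np.where(np.arange(100).reshape(10, 10) % 2 == 0, 1.0, -1.0)
        for i, roi in enumerate(DEFAULT_ROIS):
            mag = 0.5 if assign.lobes[roi] == "PFC" else 0.1
            A[i, :] = mag * signs[i]
        out = lobe_magnitude(A, assign, DEFAULT_ROIS)
        assert np.allclose(out.loc["PFC"], 0.5)
        assert np.allclose(out.loc["PPC"], 0.1)

    def test_sign_flip_invariant(self, assign, rng):
        A = rng.normal(size=(10, 10))
        a = lobe_magnitude(A, assign, DEFAULT_ROIS)
        b = lobe_magnitude(-A, assign, DEFAULT_ROIS)
        pd.testing.assert_frame_equal(a, b)


class TestNetworkSummary:
    def test_block_constant_matrix(self, assign):
        nets = [assign.networks[r] for r in DEFAULT_ROIS]
        A = np.array([[1.0 if nets[i] == nets[j] else -0.5 for j in range(10)]
                      for i in range(10)])
        s = network_summary(A, assign, DEFAULT_ROIS)
        assert s.within_mean == pytest.approx(1.0)
        assert s.between_mean == pytest.approx(-0.5)

    def test_toy_two_network_cells_hand_computed(self):
        # 4 ROIs: FPl,MFG in TC; VLPFC,cMFG in CC
        assign = NetworkAssignment(
            networks={"FPl": "TC", "MFG": "TC", "VLPFC": "CC", "cMFG": "CC"},
            lobes={r: "PFC" for r in ("FPl", "MFG", "VLPFC", "cMFG")},
        )
        A = np.array([
            [9.0, 0.2, 0.3, 0.5],
            [0.4, 9.0, -0.1, 0.1],
            [0.6, -0.2, 9.0, 0.8],
            [0.0, 0.2, 0.6, 9.0],
        ])
        s = network_summary(A, assign, ("FPl", "MFG", "VLPFC", "cMFG"))
        assert s.cell_means.loc["TC", "TC"] == pytest.approx((0.2 + 0.4) / 2)
        assert s.cell_means.loc["TC", "CC"] == pytest.approx((0.3 + 0.5 - 0.1 + 0.1) / 4)
        assert s.cell_means.loc["CC", "TC"] == pytest.approx((0.6 - 0.2 + 0.0 + 0.2) / 4)
        assert s.cell_means.loc["CC", "CC"] == pytest.approx((0.8 + 0.6) / 2)
        # diagonal self-connections (9.0) excluded everywhere
        assert not np.any(s.cell_means.to_numpy() > 1.0)

    def test_roi_permutation_invariance(self, assign, rng):
        A = rng.normal(size=(10, 10))
        perm = rng.permutation(10)
        s1 = network_summary(A, assign, DEFAULT_ROIS)
        s2 = network_summary(A[np.ix_(perm, perm)], assign,
                             tuple(DEFAULT_ROIS[i] for i in perm))
        pd.testing.assert_frame_equal(s1.cell_means, s2.cell_means)

    def test_unassigned_roi_rejected(self, assign, rng):
        with pytest.raises(ValueError, match="unassigned"):
            network_summary(rng.normal(size=(2, 2)),
                            NetworkAssignment(networks={}, lobes={}),
                            ("X", "Y"))

    def test_within_between_recompose_to_grand_mean(self, assign, rng):
        A = rng.normal(size=(10, 10))
        s = network_summary(A, assign, DEFAULT_ROIS)
        n_w = int(s.cell_counts.to_numpy()[np.eye(3, dtype=bool)].sum())
        n_b = int(s.cell_counts.to_numpy()[~np.eye(3, dtype=bool)].sum())
        grand = (s.within_mean * n_w + s.between_mean * n_b) / (n_w + n_b)
        mask = ~np.eye(10, dtype=bool)
        assert grand == pytest.approx(A[mask].mean(), abs=1e-10)


class TestIntegrationIndex:
    def test_equal_within_between_gives_zero(self, assign):
        A = np.full((10, 10), 0.3)
        s = network_summary(A, assign, DEFAULT_ROIS)
        assert integration_index(s, "CC") == pytest.approx(0.0, abs=1e-12)
        assert dynamic_integration_index(s) == pytest.approx(0.0, abs=1e-12)

    def test_arithmetic_example(self):
        # CC within 0.8; CC->TC 0.3; CC->SC 0.5 -> index 0.4 - 0.8 = -0.4
        assign = NetworkAssignment(
            networks={"FPl": "TC", "MFG": "TC", "VLPFC": "CC", "cMFG": "CC",
                      "IFJ": "SC", "SFS": "SC"},
            lobes={r: "PFC" for r in ("FPl", "MFG", "VLPFC", "cMFG", "IFJ", "SFS")},
        )
        rois = ("FPl", "MFG", "VLPFC", "cMFG", "IFJ", "SFS")
        A = np.zeros((6, 6))
        idx = {r: i for i, r in enumerate(rois)}
        for s_roi in ("VLPFC", "cMFG"):
            for t_roi in rois:
                if t_roi == s_roi:
                    continue
                net_t = assign.networks[t_roi]
                A[idx[s_roi], idx[t_roi]] = {"CC": 0.8, "TC": 0.3, "SC": 0.5}[net_t]
        summ = network_summary(A, assign, rois)
        assert integration_index(summ, "CC") == pytest.approx(0.4 - 0.8, abs=1e-12)


class TestResidualize:
    def test_orthogonal_covariate_returns_centered_values(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        z = np.array([1.0, -1.0, -1.0, 1.0])  # orthogonal to the linear trend
        res = residualize(y, z)
        np.testing.assert_allclose(res, y - y.mean(), atol=1e-12)

    def test_residuals_uncorrelated_with_covariate(self, rng):
        z = rng.normal(size=50)
        y = 2.0 * z + rng.normal(size=50)
        res = residualize(y, z)
        assert abs(np.corrcoef(res, z)[0, 1]) < 1e-10

    def test_hand_worked_example_matches_normal_equations(self):
        y = np.array([2.0, 4.0, 5.0, 4.0, 5.0])
        z = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        X = np.column_stack([np.ones(5), z])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(residualize(y, z), y - X @ beta, atol=1e-12)

    def test_rank_deficiency_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            residualize(np.arange(5.0), np.column_stack([np.ones(5), np.ones(5)]))


def _rm_anova_oracle(df):
    """Independent sum-of-squares partition for a balanced 2x3 within design."""
    subjects = sorted(df["subject"].unique())
    a_levels = sorted(df["connectivity"].unique())
    b_levels = sorted(df["contrast"].unique())
    n, a, b = len(subjects), len(a_levels), len(b_levels)
    y = np.zeros((n, a, b))
    for i, s in enumerate(subjects):
        for j, al in enumerate(a_levels):
            for k, bl in enumerate(b_levels):
                y[i, j, k] = df[(df.subject == s) & (df.connectivity == al)
                                & (df.contrast == bl)]["value"].iloc[0]
    grand = y.mean()
    ss_a = n * b * ((y.mean(axis=(0, 2)) - grand) ** 2).sum()
    ss_b = n * a * ((y.mean(axis=(0, 1)) - grand) ** 2).sum()
    cell = y.mean(axis=0)
    ss_ab = n * ((cell - y.mean(axis=(0, 2))[:, None] - y.mean(axis=(0, 1))[None, :]
                  + grand) ** 2).sum()
    subj = y.mean(axis=(1, 2))
    sa = y.mean(axis=2)
    sb = y.mean(axis=1)
    ss_as = b * ((sa - y.mean(axis=(0, 2))[None, :] - subj[:, None] + grand) ** 2).sum()
    ss_bs = a * ((sb - y.mean(axis=(0, 1))[None, :] - subj[:, None] + grand) ** 2).sum()
    ss_abs = ((y - sa[:, :, None] - sb[:, None, :] - cell[None] + subj[:, None, None]
               + y.mean(axis=(0, 2))[None, :, None] + y.mean(axis=(0, 1))[None, None, :]
               - grand) ** 2).sum()
    f_a = (ss_a / (a - 1)) / (ss_as / ((a - 1) * (n - 1)))
    f_b = (ss_b / (b - 1)) / (ss_bs / ((b - 1) * (n - 1)))
    f_ab = (ss_ab / ((a - 1) * (b - 1))) / (ss_abs / ((a - 1) * (b - 1) * (n - 1)))
    return f_a, f_b, f_ab


class TestWithinBetweenAnova:
    def _table(self, values):
        rows = []
        k = 0
        for s in range(values.shape[0]):
            for conn in ("within", "between"):
                for con in ("temporal", "contextual", "domain"):
                    rows.append((s, conn, con, values[s, k % 6]))
                    k += 1
        return pd.DataFrame(rows, columns=["subject", "connectivity", "contrast", "value"])

    def test_identical_cells_give_zero_f(self):
        df = self._table(np.full((6, 6), 2.0))
        out = within_between_anova(df)
        assert np.allclose(out["F"], 0.0)

    def test_matches_sum_of_squares_oracle(self, rng):
        df = self._table(rng.normal(size=(8, 6)))
        out = within_between_anova(df).set_index("term")
        f_a, f_b, f_ab = _rm_anova_oracle(df)
        assert out.loc["connectivity", "F"] == pytest.approx(f_a, abs=1e-8)
        assert out.loc["contrast", "F"] == pytest.approx(f_b, abs=1e-8)
        assert out.loc["connectivity:contrast", "F"] == pytest.approx(f_ab, abs=1e-8)

    def test_missing_cell_rejected(self, rng):
        df = self._table(rng.normal(size=(4, 6))).iloc[:-1]
        with pytest.raises(ValueError, match="unbalanced"):
            within_between_anova(df)


class TestAbstractionGradientModel:
    def _long(self, rng, n_subj=10, quad=0.0, inter=0.0, noise=0.1):
        rois = np.linspace(-1.0, 1.0, 8)
        rows = []
        for s in range(n_subj):
            for i, sa in enumerate(rois):
                for j, ta in enumerate(rois):
                    if i == j:
                        continue
                    ec = inter * sa * ta + quad * sa**2 + rng.normal(0, noise)
                    rows.append((s, sa, ta, ec))
        return pd.DataFrame(rows, columns=["subject", "source_abs", "target_abs", "ec"])

    def test_planted_negative_quadratic_recovered(self, rng):
        df = self._long(rng, quad=-0.5, inter=0.3)
        out = abstraction_gradient_model(df).set_index("term")
        assert out.loc["source_sq", "estimate"] < 0
        assert out.loc["source_sq", "p"] < 0.05
        assert out.loc["source_x_target", "p"] < 0.05

    def test_interaction_only_leaves_quadratics_null(self, rng):
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            r = np.random.default_rng(rep)
            df = self._long(r, quad=0.0, inter=0.4)
            out = abstraction_gradient_model(df).set_index("term")
            hits += abs(out.loc["source_sq", "stat"]) < 2
        assert hits >= 0.8 * n_rep

    def test_zero_variance_outcome_gives_zero_slopes(self, rng):
        df = self._long(rng, noise=0.0)
        df["ec"] = 1.0
        out = abstraction_gradient_model(df)
        assert np.allclose(out["estimate"], 0.0)

    def test_single_subject_rejected(self, rng):
        df = self._long(rng, n_subj=1)
        with pytest.raises(ValueError, match="2 subjects"):
            abstraction_gradient_model(df)


class TestParcellationOverlap:
    def test_mask_inside_one_parcel(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1:3, 1:3] = True
        parcels = np.full((4, 4), 1)
        parcels[1:3, 1:3] = 3
        out = parcellation_overlap(mask, parcels)
        assert out[3] == 100.0 and out[1] == 0.0

    def test_split_mask_percentages(self):
        mask = np.zeros(20, dtype=bool)
        mask[:10] = True
        parcels = np.array([1] * 4 + [2] * 16)
        out = parcellation_overlap(mask, parcels)
        assert out[1] == pytest.approx(40.0)
        assert out[2] == pytest.approx(60.0)

    def test_percentages_sum_to_100_when_parcels_tile(self, rng):
        mask = rng.random(50) > 0.4
        parcels = rng.integers(0, 4, size=50)
        out = parcellation_overlap(mask, parcels)
        assert sum(out.values()) == pytest.approx(100.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            parcellation_overlap(np.zeros(5, dtype=bool), np.zeros(5, dtype=int))
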