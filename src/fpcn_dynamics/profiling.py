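"""Classical multidimensional scaling of ROI activation profiles.

Dissimilarity between ROIs is 1 - r (Pearson correlation across the stacked
subjects x conditions dimension).  Classical (Torgerson) MDS double-centers
-1/2 D^2 and eigendecomposes; the first dimension operationalizes the
abstraction gradient (sensory-motor-proximal to distal), the second the
stimulus-domain axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .roi_glm import ActivationProfile


@dataclass
class MdsEmbedding:
    """Classical-MDS coordinates of the ROIs with eigen spectrum."""

    coordinates: np.ndarray  # ROI x dimension (positive-eigenvalue dims)
    eigenvalues: np.ndarray  # all eigenvalues, sorted descending
    variance_fraction: np.ndarray  # per retained (positive) dimension
    roi_labels: tuple[str, ...]

    @property
    def abstraction(self) -> dict[str, float]:
        """Per-ROI loading on the first dimension (abstraction axis)."""
        return {r: float(self.coordinates[i, 0]) for i, r in enumerate(self.roi_labels)}


def classical_mds(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Torgerson scaling of a symmetric dissimilarity matrix.

    Returns (coordinates over positive-eigenvalue dimensions, all
    eigenvalues sorted descending).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(vals.max(), 0) * 1e-12
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    return coords, vals


def mds_profiles(
    profiles: ActivationProfile,
    sensorimotor_rois: "tuple[str, ...] | None" = None,
) -> MdsEmbedding:
    """Embed ROIs by the correlation distance of their stacked profiles.

    ``sensorimotor_rois`` fixes the sign convention: dimension 1 is oriented
    so those ROIs score negative (the concrete end of the abstraction axis).
    Without labels, the dimension is oriented so its mean cube is positive
    (a deterministic, data-driven tie-break).
    """
    M = profiles.stacked()  # (subjects*conditions) x ROI
    if M.shape[1] < 3:
        raise ValueError("need at least 3 ROIs for MDS")
    sd = M.std(axis=0)
    if np.any(sd == 0):
        bad = [profiles.roi_labels[j] for j in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant profile column(s) for ROI(s) {bad}")
    R = np.corrcoef(M.T)
    if np.any(~np.isfinite(R)):
        raise ValueError("non-finite correlations among ROI profiles")
    D = 1.0 - R
    np.fill_diagonal(D, 0.0)
    coords, vals = classical_mds(D)
    pos = vals[vals > max(vals.max(), 0) * 1e-12]
    var_frac = pos / pos.sum()
    # deterministic sign orientation per dimension
    for d in range(coords.shape[1]):
        col = coords[:, d]
        if d == 0 and sensorimotor_rois:
            idx = [profiles.roi_labels.index(r) for r in sensorimotor_rois]
            if col[idx].mean() > 0:
                coords[:, d] = -col
        elif np.sum(col**3) < 0:
            coords[:, d] = -col
    return MdsEmbedding(
        coordinates=coords,
        eigenvalues=vals,
        variance_fraction=var_frac,
        roi_labels=profiles.roi_labels,
    )
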