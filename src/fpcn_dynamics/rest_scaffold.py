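"""Candidate-connectivity scaffold from resting-state runs.

A pair of ROIs is a candidate connection when, in at least 3 of the 4
(seed, run) tests over two runs, the pairwise correlation exceeds the seed's
cost threshold: the correlation value such that the top ``c`` percent of the
seed's (non-excluded) correlations exceed it (the graph-cost convention;
``c = 18`` by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .timeseries import RoiTimeSeries

logger = logging.getLogger(__name__)


@dataclass
class CostThreshold:
    """Correlation cutoff retaining the top ``cost`` percent of connections."""

    cost: float  # percent
    r: float

    def __post_init__(self) -> None:
        if not 0.0 < self.cost < 100.0:
            raise ValueError("cost must lie in (0, 100)")
        if not -1.0 <= self.r <= 1.0:
            raise ValueError("r must lie in [-1, 1]")


@dataclass
class CandidateMatrix:
    """Symmetric candidate scaffold with its (seed x run) tally counts."""

    counts: np.ndarray  # ROI x ROI int, 0..4
    candidate: np.ndarray  # ROI x ROI bool
    roi_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if np.any(self.candidate != self.candidate.T):
            raise ValueError("candidate matrix must be symmetric")
        if np.any(np.diag(self.candidate)):
            raise ValueError("candidate diagonal must be False")


def bandpass(
    ts: RoiTimeSeries, low_hz: float = 0.009, high_hz: float = 0.08
) -> RoiTimeSeries:
    """Zero-phase second-order Butterworth band-pass filter."""
    nyquist = 0.5 / ts.repetition_time
    if not 0.0 < low_hz < high_hz < nyquist:
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must lie inside (0, {nyquist}) Hz"
        )
    b, a = butter(2, [low_hz / nyquist, high_hz / nyquist], btype="bandpass")
    out = ts.copy()
    out.data = filtfilt(b, a, ts.data, axis=0)
    return out


def cost_threshold(corr_values: np.ndarray, c: float = 18.0) -> CostThreshold:
    """Correlation value exceeded by (at most) the top ``c`` percent of entries.

    With ``n`` sorted values, the threshold is the value at descending rank
    ``floor(c * n / 100)``; ties at the threshold count as exceeding it.
    """
    if not 0.0 < c < 100.0:
        raise ValueError("c must lie in (0, 100)")
    v = np.asarray(corr_values, dtype=float).ravel()
    if v.size == 0 or np.any(~np.isfinite(v)):
        raise ValueError("corr_values must be a nonempty finite vector")
    desc = np.sort(v)[::-1]
    k = min(int(np.floor(c * v.size / 100.0)), v.size - 1)
    return CostThreshold(cost=c, r=float(desc[k]))


def candidate_matrix(
    rest_runs: list[RoiTimeSeries],
    roi_coords: np.ndarray | None = None,
    c: float = 18.0,
    exclusion_radius_mm: float = 15.0,
) -> CandidateMatrix:
    """Tally seed-wise cost-threshold tests over runs into a candidate scaffold.

    For every run and every seed ROI, the seed's correlations to all other
    ROIs (excluding ROIs within ``exclusion_radius_mm`` of the seed, when
    coordinates are given) form the percentile pool; a pair passes that
    (seed, run) test when its correlation exceeds the seed's cost threshold.
    With two runs this yields 4 tests per pair; >= 3 passes (3/4 of the
    tests in general) makes the pair a candidate.
    """
    if len(rest_runs) < 2:
        raise ValueError("need at least 2 resting runs")
    labels = rest_runs[0].roi_labels
    n = len(labels)
    excluded = np.zeros((n, n), dtype=bool)
    if roi_coords is not None:
        coords = np.asarray(roi_coords, dtype=float)
        dist = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
        excluded = (dist < exclusion_radius_mm) & ~np.eye(n, dtype=bool)
        for i, j in zip(*np.nonzero(np.triu(excluded))):
            logger.info(
                "ROI %s within %.1f mm of seed %s; excluded from its percentile pool",
                labels[j], exclusion_radius_mm, labels[i],
            )
    counts = np.zeros((n, n), dtype=int)
    for ts in rest_runs:
        if ts.roi_labels != labels:
            raise ValueError("runs must share the same ROI set")
        R = np.corrcoef(ts.data.T)
        for seed in range(n):
            pool = [j for j in range(n) if j != seed and not excluded[seed, j]]
            if not pool:
                continue
            thr = cost_threshold(R[seed, pool], c).r
            for j in pool:
                if R[seed, j] > thr:  # strictly exceed the cost threshold
                    counts[seed, j] += 1
    pair_counts = counts + counts.T  # seed-A tests + seed-B tests
    total_tests = 2 * len(rest_runs)
    need = int(np.ceil(0.75 * total_tests))
    cand = pair_counts >= need
    np.fill_diagonal(cand, False)
    np.fill_diagonal(pair_counts, 0)
    return CandidateMatrix(counts=pair_counts, candidate=cand, roi_labels=labels)
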