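"""Factorial task design: condition regressors, binarization, and contrasts.

The task crosses stimulus domain (spatial/verbal) with three block types that
load on distinct control processes, yielding eight conditions-of-interest in
the fixed order ``SB, VB, SS, VS, SP, VP, SD, VD`` (S/V = spatial/verbal;
B/S/P/D = baseline, switching, planning, dual).  Condition epochs are modeled
as boxcars on the acquisition grid, convolved with a canonical hemodynamic
response; a binarized copy of the unconvolved boxcars (``bin(X)``) is kept for
interaction (PPI) regressors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: canonical ordering of the eight conditions-of-interest
CONDITIONS: tuple[str, ...] = ("SB", "VB", "SS", "VS", "SP", "VP", "SD", "VD")

#: contrast names in canonical order
CONTRAST_NAMES: tuple[str, ...] = (
    "temporal",
    "contextual",
    "sensorimotor",
    "verbal",
    "spatial",
    "contextual_x_domain",
)


def canonical_hrf(
    dt: float,
    duration: float = 32.0,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled every ``dt`` seconds.

    The kernel is the difference of two gamma densities (peak at ~6 s,
    undershoot at ~16 s, undershoot-to-peak ratio 1/6) normalized so that its
    discrete sum is 1 (unit area at resolution ``dt``), making convolution
    preserve the integral of a boxcar.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    from scipy.stats import gamma as gamma_dist

    t = np.arange(0, duration, dt)
    # shape parameters: gamma with scale 1 peaks at (shape - 1)
    h = gamma_dist.pdf(t, peak_delay, scale=1.0) - ratio * gamma_dist.pdf(
        t, undershoot_delay, scale=1.0
    )
    s = h.sum()
    if s != 0:
        h = h / s
    return h


def dct_highpass_basis(n_scans: int, repetition_time: float, cutoff_s: float = 128.0) -> np.ndarray:
    """Discrete-cosine high-pass drift basis (cutoff period ``cutoff_s``).

    Returns an ``n_scans x K`` matrix of cosine regressors with periods longer
    than ``cutoff_s`` seconds (the constant term is excluded; an intercept is
    handled separately by the GLM).
    """
    total_s = n_scans * repetition_time
    order = int(np.floor(2.0 * total_s / cutoff_s))
    if order < 1:
        return np.zeros((n_scans, 0))
    t = np.arange(n_scans)
    basis = np.column_stack(
        [np.cos(np.pi * k * (2 * t + 1) / (2 * n_scans)) for k in range(1, order + 1)]
    )
    return basis * np.sqrt(2.0 / n_scans)


@dataclass
class TaskDesign:
    """HRF-convolved condition regressors plus their binarized boxcars.

    Attributes
    ----------
    condition_labels:
        Names of the condition columns, canonical order.
    regressor_matrix:
        ``n_scans x n_conditions`` HRF-convolved boxcars (X).
    binarized_design:
        ``n_scans x n_conditions`` unconvolved boxcars thresholded at 0
        (bin(X)); entries are exactly 0 or 1.
    nuisance:
        Optional ``n_scans x n_nuisance`` extra columns (drift basis,
        transients); excluded from contrasts.
    """

    condition_labels: tuple[str, ...]
    onsets: dict[str, np.ndarray]
    durations: dict[str, np.ndarray]
    repetition_time: float
    regressor_matrix: np.ndarray
    binarized_design: np.ndarray
    nuisance: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    nuisance_names: tuple[str, ...] = ()

    @property
    def n_scans(self) -> int:
        return self.regressor_matrix.shape[0]

    def full_matrix(self, intercept: bool = True) -> np.ndarray:
        """Condition regressors stacked with nuisance columns (and intercept)."""
        cols = [self.regressor_matrix]
        if self.nuisance.size:
            cols.append(self.nuisance)
        if intercept:
            cols.append(np.ones((self.n_scans, 1)))
        return np.hstack(cols)


@dataclass
class ContrastMatrix:
    """Condition-space contrast weights, one row per named contrast."""

    weights: np.ndarray  # contrast x condition
    names: tuple[str, ...]
    condition_labels: tuple[str, ...] = CONDITIONS

    def row(self, name: str) -> np.ndarray:
        return self.weights[self.names.index(name)]

    def subset(self, names: "list[str] | tuple[str, ...]") -> "ContrastMatrix":
        idx = [self.names.index(n) for n in names]
        return ContrastMatrix(self.weights[idx].copy(), tuple(names), self.condition_labels)


def _boxcar(onsets, durations, n_scans, tr):
    box = np.zeros(n_scans)
    t = np.arange(n_scans) * tr
    for onset, dur in zip(onsets, durations):
        if onset < 0:
            raise ValueError(f"negative onset {onset}")
        if dur < 0:
            raise ValueError(f"negative duration {dur}")
        end = onset + dur
        if end > n_scans * tr:
            logger.warning("epoch [%s, %s) extends past the series end; truncated", onset, end)
        box[(t >= onset) & (t < end)] = 1.0
    return box


def build_design(
    block_spec: dict,
    repetition_time: float,
    n_scans: int,
    hrf: np.ndarray | None = None,
    oversampling: int = 16,
    highpass_cutoff_s: float | None = None,
) -> TaskDesign:
    """Build the condition design from epoch lists.

    Parameters
    ----------
    block_spec:
        Mapping ``condition -> list of (onset_s, duration_s)`` epochs.
        Epochs within a condition must not overlap.
    hrf:
        Optional kernel sampled at ``repetition_time / oversampling``;
        defaults to the canonical double-gamma.
    highpass_cutoff_s:
        If given, append a discrete-cosine drift basis with this cutoff as
        nuisance columns.
    """
    unknown = [c for c in block_spec if c not in CONDITIONS]
    labels = tuple(c for c in CONDITIONS if c in block_spec) + tuple(unknown)
    dt = repetition_time / oversampling
    if hrf is None:
        hrf = canonical_hrf(dt)

    n_fine = n_scans * oversampling
    t_fine = np.arange(n_fine) * dt
    X = np.zeros((n_scans, len(labels)))
    binX = np.zeros((n_scans, len(labels)))
    onsets_out, durations_out = {}, {}
    for j, cond in enumerate(labels):
        epochs = sorted(block_spec[cond])
        for (o1, d1), (o2, _d2) in zip(epochs, epochs[1:]):
            if o1 + d1 > o2:
                raise ValueError(f"overlapping epochs in condition {cond!r}")
        onsets = np.array([e[0] for e in epochs], dtype=float)
        durations = np.array([e[1] for e in epochs], dtype=float)
        onsets_out[cond] = onsets
        durations_out[cond] = durations

        fine_box = np.zeros(n_fine)
        for onset, dur in zip(onsets, durations):
            if onset < 0:
                raise ValueError(f"negative onset {onset} in condition {cond!r}")
            end = onset + dur
            if end > n_scans * repetition_time:
                logger.warning(
                    "condition %s epoch [%s, %s) extends past the series end; truncated",
                    cond, onset, end,
                )
            fine_box[(t_fine >= onset) & (t_fine < end)] = 1.0
        conv = np.convolve(fine_box, hrf)[:n_fine]
        X[:, j] = conv[::oversampling]
        # bin(X): threshold the unconvolved boxcar on the acquisition grid
        binX[:, j] = (_boxcar(onsets, durations, n_scans, repetition_time) > 0).astype(float)

    nuisance = np.zeros((n_scans, 0))
    nuis_names: tuple[str, ...] = ()
    if highpass_cutoff_s is not None:
        nuisance = dct_highpass_basis(n_scans, repetition_time, highpass_cutoff_s)
        nuis_names = tuple(f"dct{k + 1}" for k in range(nuisance.shape[1]))

    return TaskDesign(
        condition_labels=labels,
        onsets=onsets_out,
        durations=durations_out,
        repetition_time=repetition_time,
        regressor_matrix=X,
        binarized_design=binX,
        nuisance=nuisance,
        nuisance_names=nuis_names,
    )


def define_contrasts() -> ContrastMatrix:
    """The five orthogonal contrasts-of-interest plus the domain interaction.

    In condition order (SB, VB, SS, VS, SP, VP, SD, VD):

    - temporal: dual + planning > switching + baseline
    - contextual: dual + switching > planning + baseline
    - sensorimotor: dual + baseline > planning + switching
    - verbal: verbal cells > spatial cells; spatial is its negation
    - contextual_x_domain: elementwise product of contextual and verbal rows
    """
    temporal = np.array([-1, -1, -1, -1, +1, +1, +1, +1], dtype=float)
    contextual = np.array([-1, -1, +1, +1, -1, -1, +1, +1], dtype=float)
    sensorimotor = np.array([+1, +1, -1, -1, -1, -1, +1, +1], dtype=float)
    verbal = np.array([-1, +1, -1, +1, -1, +1, -1, +1], dtype=float)
    spatial = -verbal
    ctx_by_domain = contextual * verbal
    weights = np.vstack([temporal, contextual, sensorimotor, verbal, spatial, ctx_by_domain])
    return ContrastMatrix(weights=weights, names=CONTRAST_NAMES)


def default_block_spec(
    n_cycles: int = 3,
    epoch_s: float = 20.0,
    gap_s: float = 10.0,
    start_s: float = 10.0,
) -> tuple[dict, float]:
    """A balanced blocked layout cycling through all eight conditions.

    Returns the epoch mapping and the total duration in seconds (including a
    trailing gap for the hemodynamic tail).
    """
    spec: dict = {c: [] for c in CONDITIONS}
    t = start_s
    for _ in range(n_cycles):
        for cond in CONDITIONS:
            spec[cond].append((t, epoch_s))
            t += epoch_s + gap_s
    return spec, t + 20.0
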