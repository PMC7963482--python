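"""Ground-truth-tagged synthetic inputs for every pipeline stage.

The neural model is a discrete-time bilinear system integrated with an Euler
step of TR/16 and decimated to the repetition time:

    z_t = z_{t-1} + dt * [A z_{t-1} + sum_k m_k(t) (B_k z_{t-1}) + D u(t)]
          + sqrt(dt) * eta_t

where ``A`` is the static coupling matrix, oriented source-row x target-column
throughout the package (``A[i, j]`` is the influence of ROI ``i`` on ROI ``j``;
negative diagonal = self-decay),
``B_k`` is the modulation matrix of task contrast ``k``, ``m_k(t)`` is the
contrast-weighted binarized condition indicator, ``D u(t)`` is condition-locked
driving input, and ``eta`` is white state noise.  The observed BOLD-like
signal is the decimated latent state, optionally convolved with a canonical
hemodynamic response, plus white measurement noise.

All generators take a ``numpy.random.Generator`` (or an integer seed) and are
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .task_design import CONDITIONS, TaskDesign, canonical_hrf
from .timeseries import RoiTimeSeries

#: the ten frontoparietal ROIs with their control-network and lobe labels
#: (networks: TC temporal, CC contextual, SC sensory-motor control) and
#: MNI coordinates (mm) of the sample-1 activation peaks.
DEFAULT_ROI_TABLE = pd.DataFrame(
    [
        ("FPl", "TC", "PFC", -44, 48, 4),
        ("MFG", "TC", "PFC", -38, 28, 44),
        ("VLPFC", "CC", "PFC", -52, 20, 28),
        ("cMFG", "CC", "PFC", -34, 10, 60),
        ("IFJ", "SC", "PFC", -38, 6, 26),
        ("SFS", "SC", "PFC", -22, 0, 54),
        ("IPL", "TC", "PPC", -54, -50, 44),
        ("mIPS", "CC", "PPC", -28, -60, 42),
        ("aIPS", "SC", "PPC", -34, -40, 46),
        ("SPL", "SC", "PPC", -14, -52, 64),
    ],
    columns=["roi", "network", "lobe", "x", "y", "z"],
)

DEFAULT_ROIS: tuple[str, ...] = tuple(DEFAULT_ROI_TABLE["roi"])


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class SyntheticTruth:
    """Planted parameters echoed verbatim alongside every generated dataset."""

    coupling_matrix: np.ndarray
    modulation_matrices: dict[str, np.ndarray]
    present_slope_by_roi: dict[str, float]
    future_slope_by_roi: dict[str, float]
    ability_integration_corr: float
    seed: int
    roi_labels: tuple[str, ...] = DEFAULT_ROIS
    drive: np.ndarray | None = None  # ROI x condition input weights
    state_noise_sd: float = 1.0
    condition_noise_gain: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        A = np.asarray(self.coupling_matrix, dtype=float)
        n = len(self.roi_labels)
        if A.shape != (n, n):
            raise ValueError(
                f"coupling_matrix is {A.shape} but roi_labels has {n} entries"
            )
        if np.any(np.diag(A) > 0):
            raise ValueError("coupling_matrix diagonal must be <= 0 (self-decay)")
        for name, B in self.modulation_matrices.items():
            B = np.asarray(B, dtype=float)
            if B.shape != (n, n):
                raise ValueError(
                    f"modulation matrix {name!r} is {B.shape}, expected {(n, n)}"
                )
            if np.any(np.diag(B) != 0):
                raise ValueError(f"modulation matrix {name!r} must be zero on the diagonal")
            self.modulation_matrices[name] = B
        if not -1.0 <= self.ability_integration_corr <= 1.0:
            raise ValueError("ability_integration_corr must lie in [-1, 1]")
        self.coupling_matrix = A

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)


@dataclass
class CohortSpec:
    """Cohort-level simulation settings."""

    n_subjects: int = 24
    n_timepoints: int = 360
    repetition_time: float = 2.0
    noise_sd: float = 0.5
    hrf_enabled: bool = True
    network_assignment: dict[str, tuple[str, str]] = field(
        default_factory=lambda: {
            r.roi: (r.network, r.lobe) for r in DEFAULT_ROI_TABLE.itertuples()
        }
    )
    oversampling: int = 16

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_timepoints < 18:
            raise ValueError("n_timepoints must leave room for the design regressors")


def default_truth(seed: int = 0, pfc_gain: float = 1.2) -> SyntheticTruth:
    """The study-condition truth: an integrator CC network between segregator
    TC and SC networks, with PFC sources stronger than PPC sources.

    Within-network coupling is positive for all three networks; between-network
    coupling is positive when the source is contextual-control (CC) and
    negative when the source is temporal (TC) or sensory-motor (SC) control.
    Contextual-control demand modulates between-network coupling upward
    (dynamic integration); temporal demand modulates within-network coupling.
    """
    rois = DEFAULT_ROIS
    net = {r.roi: r.network for r in DEFAULT_ROI_TABLE.itertuples()}
    lobe = {r.roi: r.lobe for r in DEFAULT_ROI_TABLE.itertuples()}
    n = len(rois)
    A = np.zeros((n, n))
    for i, src in enumerate(rois):
        for j, tgt in enumerate(rois):
            if i == j:
                A[i, j] = -1.0
            elif net[src] == net[tgt]:
                A[i, j] = 0.10
            elif net[src] == "CC":
                A[i, j] = 0.08
            else:
                A[i, j] = -0.06
        if lobe[src] == "PFC":
            A[i, [j for j in range(n) if j != i]] *= pfc_gain
    between = np.array(
        [[net[s] != net[t] and s != t for t in rois] for s in rois], dtype=float
    )
    within = np.array(
        [[net[s] == net[t] and s != t for t in rois] for s in rois], dtype=float
    )
    modulations = {
        "contextual": 0.05 * between,
        "temporal": 0.04 * within,
        "verbal": 0.01 * (between - within),
    }
    # sensory-motor-proximal areas track present behavior, distal areas future
    present = {"FPl": -0.2, "MFG": -0.2, "IPL": -0.2, "VLPFC": 0.4, "cMFG": 0.4,
               "mIPS": 0.4, "IFJ": 0.6, "SFS": 0.6, "aIPS": 0.6, "SPL": 0.6}
    future = {"FPl": 0.6, "MFG": 0.6, "IPL": 0.6, "VLPFC": 0.4, "cMFG": 0.4,
              "mIPS": 0.4, "IFJ": 0.0, "SFS": 0.0, "aIPS": 0.0, "SPL": 0.0}
    # condition-locked drive: each network's ROIs are driven by the conditions
    # loading on their control process (evoked activity for the GLM stage)
    drive = np.zeros((n, len(CONDITIONS)))
    cond_idx = {c: k for k, c in enumerate(CONDITIONS)}
    loads = {
        "TC": ["SP", "VP", "SD", "VD"],
        "CC": ["SS", "VS", "SD", "VD"],
        "SC": ["SB", "VB", "SD", "VD"],
    }
    for i, roi in enumerate(rois):
        for c in loads[net[roi]]:
            drive[i, cond_idx[c]] = 0.6
        drive[i, :] += 0.2  # shared task-on drive
    return SyntheticTruth(
        coupling_matrix=A,
        modulation_matrices=modulations,
        present_slope_by_roi=present,
        future_slope_by_roi=future,
        ability_integration_corr=0.5,
        seed=seed,
        roi_labels=rois,
        drive=drive,
    )


def _check_dims(truth: SyntheticTruth, spec: CohortSpec) -> None:
    n_assign = len(spec.network_assignment)
    if n_assign and n_assign != truth.n_rois:
        raise ValueError(
            f"network_assignment covers {n_assign} ROIs but truth has "
            f"{truth.n_rois} (roi dimension mismatch)"
        )


def _check_stable(A: np.ndarray, dt: float) -> None:
    if not A.any():
        return  # degenerate null system (no recurrence) is allowed
    prop = np.eye(A.shape[0]) + dt * A
    rho = np.max(np.abs(np.linalg.eigvals(prop)))
    if rho >= 1.0:
        raise ValueError(f"unstable coupling: spectral radius {rho:.3f} >= 1")


def _fine_indicators(design: TaskDesign, oversampling: int) -> np.ndarray:
    """Condition boxcars on the fine integration grid (n_fine x n_cond)."""
    n_fine = design.n_scans * oversampling
    dt = design.repetition_time / oversampling
    t = np.arange(n_fine) * dt
    out = np.zeros((n_fine, len(design.condition_labels)))
    for j, cond in enumerate(design.condition_labels):
        for onset, dur in zip(design.onsets[cond], design.durations[cond]):
            out[(t >= onset) & (t < onset + dur), j] = 1.0
    return out


def _observe(z: np.ndarray, spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    y = z
    if spec.hrf_enabled:
        h = canonical_hrf(spec.repetition_time)
        y = np.apply_along_axis(lambda c: np.convolve(c, h)[: len(c)], 0, y)
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=y.shape)
    return y


def simulate_task_timeseries(
    truth: SyntheticTruth,
    design: TaskDesign,
    spec: CohortSpec,
    contrast_weights: dict[str, np.ndarray] | None = None,
) -> tuple[list[RoiTimeSeries], SyntheticTruth]:
    """Simulate one task run per subject from the bilinear neural model.

    ``contrast_weights`` maps each modulation name in the truth to its
    condition-space contrast row (defaults to the canonical contrasts); the
    effective modulatory input is ``m_k(t) = bin(X)(t) . c_k``.
    """
    _check_dims(truth, spec)
    dt = spec.repetition_time / spec.oversampling
    _check_stable(truth.coupling_matrix, dt)
    if contrast_weights is None:
        from .task_design import define_contrasts

        C = define_contrasts()
        contrast_weights = {
            name: C.row(name) for name in truth.modulation_matrices if name in C.names
        }
    missing = set(truth.modulation_matrices) - set(contrast_weights)
    if missing:
        raise ValueError(f"no contrast weights supplied for modulations {sorted(missing)}")

    n = truth.n_rois
    n_fine = design.n_scans * spec.oversampling
    ind = _fine_indicators(design, spec.oversampling)  # n_fine x n_cond
    mods = {k: ind @ contrast_weights[k] for k in truth.modulation_matrices}
    drive = truth.drive if truth.drive is not None else np.zeros((n, ind.shape[1]))
    u = ind @ drive.T  # n_fine x n_roi
    cond_gain = np.ones(n_fine)
    for cond, g in truth.condition_noise_gain.items():
        j = list(design.condition_labels).index(cond)
        cond_gain[ind[:, j] > 0] = g

    rng = _as_rng(truth.seed)
    subject_rngs = rng.spawn(spec.n_subjects)
    A = truth.coupling_matrix
    Bs = list(truth.modulation_matrices.items())
    # per-subject state noise, stacked for a subject-vectorized Euler loop
    noise = np.empty((n_fine, spec.n_subjects, n))
    for s, srng in enumerate(subject_rngs):
        noise[:, s, :] = srng.normal(
            0.0, truth.state_noise_sd * np.sqrt(dt), size=(n_fine, n)
        )
    noise *= cond_gain[:, None, None]
    z = np.empty((n_fine, spec.n_subjects, n))
    state = np.zeros((spec.n_subjects, n))
    for t in range(n_fine):
        eff = A
        for name, B in Bs:
            m = mods[name][t]
            if m != 0.0:
                eff = eff + m * B
        # row-vector states: s_new = s + dt * (s @ A_eff + u)  (A is source x target)
        state = state + dt * (state @ eff + u[t]) + noise[t]
        z[t] = state
    z_tr = z[:: spec.oversampling]
    out = []
    for s, srng in enumerate(subject_rngs):
        y = _observe(z_tr[:, s, :], spec, srng)
        out.append(
            RoiTimeSeries(
                y, truth.roi_labels, spec.repetition_time, subject=s,
                meta={"seed": truth.seed, "kind": "task"},
            )
        )
    return out, truth


def simulate_rest_timeseries(
    truth: SyntheticTruth, spec: CohortSpec, n_runs: int = 2
) -> list[RoiTimeSeries]:
    """Stationary resting runs from the static (A-only) model."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    _check_dims(truth, spec)
    dt = spec.repetition_time / spec.oversampling
    _check_stable(truth.coupling_matrix, dt)
    n = truth.n_rois
    n_fine = spec.n_timepoints * spec.oversampling
    rng = _as_rng(truth.seed)
    run_rngs = rng.spawn(n_runs)
    prop = np.eye(n) + dt * truth.coupling_matrix  # acts on row-vector states
    out = []
    for r, rrng in enumerate(run_rngs):
        noise = rrng.normal(0.0, truth.state_noise_sd * np.sqrt(dt), size=(n_fine, n))
        z = np.zeros((n_fine, n))
        state = np.zeros(n)
        for t in range(n_fine):
            state = state @ prop + noise[t]
            z[t] = state
        y = _observe(z[:: spec.oversampling], spec, rrng)
        out.append(
            RoiTimeSeries(
                y, truth.roi_labels, spec.repetition_time, run=r,
                meta={"seed": truth.seed, "kind": "rest"},
            )
        )
    return out


def simulate_ppi_pair(
    design: TaskDesign,
    contrast_weights: dict[str, np.ndarray],
    b_conn: float,
    b_dep: dict[str, float],
    b_uni: np.ndarray | None = None,
    noise_sd: float = 0.0,
    source_noise_sd: float = 0.0,
    source_cond_sd: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate a (source, target) pair directly from the interaction model.

    The target obeys the observation-level equation
    ``y = b_conn * s + X b_uni + sum_k b_dep_k (bin(X) c_k) . s + noise``
    exactly, which makes it the ground truth for estimator-exactness checks.
    ``source_cond_sd`` optionally scales the source's innovation SD per
    condition (length-8, applied where that condition's boxcar is on), the
    mechanism that elicits attenuation bias in post-hoc-contrast estimators
    when ``source_noise_sd`` (ROI measurement noise) is nonzero.

    Returns ``(observed_source, observed_target)``.
    """
    rng = _as_rng(seed)
    n_t = design.n_scans
    binX = design.binarized_design
    sd = np.ones(n_t)
    if source_cond_sd is not None:
        for j in range(binX.shape[1]):
            on = binX[:, j] > 0
            sd[on] = source_cond_sd[j]
    s_true = rng.normal(0.0, 1.0, size=n_t) * sd
    X = design.full_matrix(intercept=True)
    if b_uni is None:
        b_uni = np.zeros(X.shape[1])
    y = b_conn * s_true + X @ np.asarray(b_uni, dtype=float)
    for name, coef in b_dep.items():
        psych = binX @ contrast_weights[name]
        y = y + coef * psych * s_true
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n_t)
    s_obs = s_true
    if source_noise_sd > 0:
        s_obs = s_true + rng.normal(0.0, source_noise_sd, size=n_t)
    return s_obs, y


def bias_study_conditions(contrast_row: np.ndarray) -> dict:
    """Study conditions under which post-hoc-contrast PPI shows its
    coupling-proportional negative bias while the in-model variant does not.

    The source innovation SD is higher during the contrast's negative
    conditions (1.2) than its positive conditions (0.85) and the observed
    source carries measurement noise (SD 0.25): per-condition attenuation of
    the interaction coefficients then no longer cancels in an
    after-the-fact contrast.
    """
    sd = np.where(np.asarray(contrast_row) > 0, 0.85, 1.2)
    return {"source_cond_sd": sd, "source_noise_sd": 0.25, "noise_sd": 0.3}


def simulate_behavior(
    truth: SyntheticTruth,
    activations: np.ndarray,
    spec: CohortSpec,
    n_trials_per_cell: int = 20,
    base_rt_ms: float = 600.0,
    ms_per_z: float = 60.0,
    subject_sd_ms: float = 40.0,
    trial_sd_ms: float = 50.0,
    anticipatory_frac: float = 0.0,
    inattentive_frac: float = 0.0,
    error_frac: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Trial table with planted activation->RT slopes.

    ``activations`` is ``n_subjects x n_rois x 8`` (z-units).  Per subject and
    condition, the present (sub-task) RT mean is a linear function of the
    planted present slopes times the activations, and likewise for future
    (return-trial) RTs; contamination fractions append anticipatory (<200 ms),
    inattentive (>2000 ms), and error trials for filter testing.
    """
    if trial_sd_ms < 0 or subject_sd_ms < 0:
        raise ValueError("noise scales must be >= 0")
    act = np.asarray(activations, dtype=float)
    if act.ndim != 3 or act.shape[2] != len(CONDITIONS):
        raise ValueError(
            f"activations must be (subjects, rois, {len(CONDITIONS)}); got {act.shape}"
        )
    if act.shape[1] != truth.n_rois:
        raise ValueError("activation roi dimension does not match the truth")
    rng = _as_rng(truth.seed if seed is None else seed)
    p_slope = np.array([truth.present_slope_by_roi[r] for r in truth.roi_labels])
    f_slope = np.array([truth.future_slope_by_roi[r] for r in truth.roi_labels])
    rows = []
    n_subj = act.shape[0]
    intercepts = rng.normal(0.0, subject_sd_ms, size=n_subj)
    for s in range(n_subj):
        for k, cond in enumerate(CONDITIONS):
            mu_present = base_rt_ms + intercepts[s] + ms_per_z * float(p_slope @ act[s, :, k])
            mu_future = base_rt_ms + intercepts[s] + ms_per_z * float(f_slope @ act[s, :, k])
            for phase, mu, n_tr in (
                ("subtask", mu_present, n_trials_per_cell),
                ("return", mu_future, max(1, n_trials_per_cell // 4)),
            ):
                rts = mu + rng.normal(0.0, trial_sd_ms, size=n_tr)
                rts = np.clip(rts, 201.0, 1999.0)
                correct = rng.random(n_tr) >= error_frac
                for rt, ok in zip(rts, correct):
                    rows.append((s, cond, phase, float(rt), bool(ok)))
                n_ant = int(round(anticipatory_frac * n_tr))
                n_inat = int(round(inattentive_frac * n_tr))
                for _ in range(n_ant):
                    rows.append((s, cond, phase, float(rng.uniform(50, 199)), True))
                for _ in range(n_inat):
                    rows.append((s, cond, phase, float(rng.uniform(2001, 3000)), True))
    return pd.DataFrame(rows, columns=["subject", "condition", "phase", "rt", "correct"])


def simulate_cohort_features(
    truth: SyntheticTruth,
    n: int,
    battery_loadings: np.ndarray,
    noise_sd: float = 0.5,
    confound_corr: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Individual-difference table with a planted integration-ability link.

    Latent ability g ~ N(0,1); battery scores load on g; the dynamic
    integration feature correlates with g at ``+ability_integration_corr`` and
    the static feature at ``-ability_integration_corr`` (integration-on-demand
    helps, stationary integration hurts).  ``rms_fd`` is a head-motion
    confound, by default independent of g.
    """
    if n < 4:
        raise ValueError("n must be >= 4")
    loadings = np.asarray(battery_loadings, dtype=float)
    if loadings.ndim != 1 or np.any(loadings == 0):
        raise ValueError("battery_loadings must be a vector of nonzero loadings")
    rho = truth.ability_integration_corr
    rng = _as_rng(truth.seed if seed is None else seed)
    g = rng.normal(size=n)

    def _with_corr(r: float) -> np.ndarray:
        e = rng.normal(size=n)
        return r * g + np.sqrt(max(0.0, 1.0 - r**2)) * e

    static = _with_corr(-rho)
    dynamic = _with_corr(rho)
    rms_fd = np.abs(0.10 + 0.04 * _with_corr(confound_corr))
    battery = np.outer(g, loadings) + rng.normal(0.0, noise_sd, size=(n, len(loadings)))
    out = pd.DataFrame(
        {
            "static_integration": static,
            "dynamic_integration": dynamic,
            "rms_fd": rms_fd,
            "g": g,
        }
    )
    for j in range(len(loadings)):
        out[f"battery_{j + 1}"] = battery[:, j]
    return out
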