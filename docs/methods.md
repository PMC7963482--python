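# Methods

This package re-implements, on simulated data with known ground truth, the
network-dynamics analysis chain of a frontoparietal cognitive-control fMRI
study: a 2×2×2 factorial blocked task, ROI-level GLMs, activation-profile
multidimensional scaling, a resting-state candidate-connectivity scaffold,
psychophysiological-interaction (PPI) effective connectivity, network
integration indices, brain–behavior timescale models, and cross-validated
ridge prediction of individual differences.

## The simulated system

Ten left-hemisphere PFC/PPC regions are grouped into three control networks
— temporal control (TC: FPl, MFG, IPL), contextual control (CC: VLPFC, cMFG,
mIPS), and sensory-motor control (SC: IFJ, SFS, aIPS, SPL) — across two
lobes (PFC/PPC). Latent neural states follow a discrete-time bilinear
system, Euler-integrated at dt = TR/16 and decimated to the repetition time
(TR = 2 s):

    z_t = z_{t-1} + dt·[A z_{t-1} + Σ_k m_k(t)·B_k z_{t-1} + D u(t)] + √dt·η_t

All coupling matrices are oriented source-row × target-column. `A` is the
static coupling: self-decay −1.0 s⁻¹ on the diagonal, +0.10 within networks,
+0.08 from CC sources to other networks (the planted *integrator*), −0.06
from TC/SC sources to other networks (the planted *segregators*), with
PFC-source rows scaled by 1.2 (the planted lobe asymmetry). `B_k` are
contrast-specific modulations: +0.05 on between-network connections for the
contextual contrast, +0.04 within-network for the temporal contrast, ±0.01
for stimulus domain. `m_k(t)` is the contrast-weighted binarized condition
indicator, `D u(t)` condition-locked driving input (each network driven by
the conditions loading on its control process), and `η` white state noise
(SD 1.0). These amplitudes were fixed once for stability of the discrete
propagator under every condition-wise combination of modulation signs
(largest real eigenvalue ≤ −0.15 across all eight conditions); they are the
package's study conditions, not tuning knobs.

Observation: the decimated state, optionally convolved with a canonical
double-gamma hemodynamic response (delay parameters 6 s and 16 s, undershoot
ratio 1/6, unit discrete area; the positive lobe peaks near 5 s), plus white
measurement noise (default SD 0.5, chosen so the lag-1 ridge estimator
recovers the coupling pattern at r ≈ 0.9 on long noise-light runs — a
calibration the design requires, since no SNR is otherwise defined for ROI
series). The generator does not model physiological noise, hemodynamic
heterogeneity across regions, or head motion beyond a scalar RMS-FD
confound column; passing tests therefore certify estimator logic and power
under white-noise conditions, not robustness to structured fMRI artifacts.

All randomness flows from a single integer seed through numpy generator
spawning; identical seeds reproduce every output byte-for-byte.

## Task design and contrasts

Eight conditions (SB, VB, SS, VS, SP, VP, SD, VD: spatial/verbal ×
baseline/switching/planning/dual) are modeled as boxcars on the acquisition
grid, convolved with the HRF (oversampling 16); `bin(X)` thresholds the
*unconvolved* boxcars at zero. The six contrast rows use ±1 weights:
temporal = dual+planning − switching−baseline, contextual = dual+switching −
planning−baseline, sensorimotor = dual+baseline − planning−switching, verbal
= verbal − spatial cells, spatial its negation, and a contextual×domain
product row. The five contrasts-of-interest are exactly orthogonal in
integer arithmetic. Nuisance columns (discrete-cosine drift basis, 128 s
cutoff) are supported but excluded from contrasts. The default blocked
layout cycles all eight conditions (20 s epochs, 10 s gaps, three cycles,
750 s total) — long enough for every condition to appear with rest gaps,
short enough for desk-scale simulation batteries.

## PPI estimation

For each ordered connection, one least-squares fit of

    Y_target = B_conn·Y_source + B_uni·X + Σ_k B_dep,k·(bin(X)·c_k)∘Y_source

with the contrast inside the model (one interaction regressor per contrast).
Because the spatial contrast is the exact negation of the verbal one, PPI
models carry a single stimulus-domain row (five interaction regressors).
Designs with condition number above 1e6 are rejected with the most collinear
regressor pair named. The psychological regressor is not mean-centered by
default (matching the model as written); a switch exists. Confounds can be
projected out of both series before fitting.

The legacy variant fits one interaction regressor per condition and applies
the contrast afterwards. Its raw-weight contrast scales with the contrast
norm; a `normalize_contrast` option divides by c'c, in which case the two
estimators are algebraically identical on full-rank noise-free data.

**Bias mechanism.** The study's motivating observation — post-hoc contrasts
grow negatively biased as two regions couple more strongly, while in-model
contrasts do not — is reproduced here with an explicit planted mechanism:
the source's innovation SD differs by condition (1.2 in the contrast's
negative conditions, 0.85 in its positive ones) and the observed source
carries measurement noise (SD 0.25). Per-condition errors-in-variables
attenuation λ_j = s_j/(s_j+v) then differs across conditions, so the
after-the-fact contrast Σ_j c_j λ_j·B_conn is negative and proportional to
B_conn, while the single in-model contrast regressor is far less exposed
(empirically |mean bias| < 0.02 across the grid). This is one sufficient
mechanism, not a claim about the unique cause in real data.

**Static EC plumbing.** Time-invariant directed coupling is estimated by
candidate-restricted lag-1 ridge regression (penalty 1.0); the discrete
propagator estimate maps to a rate via (Φ − I)/TR, and non-candidate entries
are fixed at zero. This estimator stands in for a generative-model inversion
of fMRI cross-spectra, which is out of scope; an externally estimated EC
matrix can be supplied as input instead.

## ROI GLM, profiles, and MDS

Runs are grand-mean scaled to 100, fit by OLS with per-run intercepts
(optional per-ROI AR(1) Cochrane–Orcutt prewhitening; a noise-free fit
counts as white), and condition betas averaged across runs. Profiles
z-score the eight condition betas within subject × ROI (ddof = 1; constant
rows become zero with a warning). MDS stacks (subjects·conditions) × ROI,
takes D = 1 − Pearson r, double-centers −½D², and eigendecomposes; variance
fractions use positive eigenvalues only (negative eigenvalues of
non-Euclidean D are dropped and reported in the eigenvalue spectrum).
Dimension 1 is oriented so sensory-motor ROIs score negative; without
labels, a deterministic cube-sum rule applies. Abstraction scores are
passed downstream in coordinate units, unstandardized.

## Candidate scaffold

Resting runs from the A-only model (optionally band-passed, zero-phase
second-order Butterworth, 0.009–0.08 Hz) yield per-seed correlation pools.
The cost threshold is the value at descending rank ⌊c·n/100⌋ (c = 18 by
default): the top c% of the pool strictly exceed it; ties sit at the
threshold and do not pass. With two runs, the four (seed, run) tests per
pair follow the published tally — the apparent duplication in the printed
list of four counts is read as both-seeds × both-runs — and ≥ 3 passes
(3/4 of tests in general) make a pair a candidate. ROIs within 15 mm of a
seed are excluded from that seed's percentile pool. At the percentile's
granular extremes the rule behaves asymptotically: as c → 100 every pair
above its pool minimum qualifies; as c → 0 none do.

## Network metrics

Matrix entries pool into 3×3 source × target network cells, self-connections
excluded; within/between means are entry-weighted (each connection counts
once), so they recompose exactly to the grand mean. A network's *static
integration index* is its outgoing between-network mean minus its
within-network mean (source-role logic; an unweighted-cell variant exists).
The *dynamic integration index* of a contrast pools all networks: between
minus within mean of its modulation matrix. Residualization is OLS with
intercept. The abstraction-gradient model regresses coupling on source and
target abstraction (mean-centered before squaring), their interaction, and
both quadratics, with a subject random intercept (subject-clustered OLS
fallback when the mixed fit is singular). The within/between × contrast
analysis is a balanced two-way repeated-measures ANOVA (statsmodels
AnovaRM), unit-tested against an explicit sum-of-squares partition.

## Behavior

Trial filtering keeps correct trials, drops RT < 200 ms (anticipatory) and
RT > 2000 ms (inattentive), then removes RTs above mean + 2.5 SD of their
(subject, condition, phase) cell — one-sided high, read literally from the
rule "greater than 2.5 SD of the mean"; a two-sided switch exists. The SD
pass uses post-threshold statistics and is applied once (re-application
could remove more; single-pass semantics are the contract). Present/future
vectors are condition-mean RTs of sub-task and return trials, z-scored
within phase, pooled over stimulus domains. The repeated-measures
correlation is the ANCOVA formulation (within-subject centering;
df = N − n_subjects − 1, minus one per partialed covariate, the covariate
residualized out of both variables within the same strata); it is verified
against an independent projection-matrix oracle and against the established
rm-correlation implementation in pingouin. Per subject × ROI, present and
future vectors are regressed simultaneously onto activations; the slopes
feed a random-intercept-and-slope mixed model on abstraction, with a
per-subject OLS + t-test fallback.

## Prediction

Battery scores are standardized and combined by the first principal
component (sign: mean loading positive; zero-variance measures dropped).
Ridge uses standardized features, unpenalized intercept, penalty λ = 1 by
default (λ = 0 reproduces OLS; sensitivity runs up to λ = 100 behave
monotonically). Cross-validation is two-fold-by-sample (fold labels = the
two cohorts, predictions pooled into a single correlation — the pooled
variant was chosen where the text permits either) or leave-one-out;
standardization parameters come from the training fold only, verified by a
leakage test that corrupts test-fold outcomes. Permutation inference
permutes feature rows jointly, re-runs the full cross-validation, and uses
the add-one estimator p = (1 + #{r_perm ≥ r_obs})/(1 + n_perm). The
stimulation-susceptibility composite residualizes each frontal-site effect
on its control-site effect before the PCA; fully explained effects yield a
zero composite.

## Validation battery and problem sizes

`fpcn_dynamics.validation` runs the recovery/calibration studies that
`tests/test_acceptance.py` asserts and `scripts/acceptance.py` reports:
estimator exactness on 45 connections × 20 subjects (noise-free, ≤ 1e−6);
the bias curve over B_conn ∈ {0,…,0.8} × 200 seeds; 100 cohorts of 24
subjects for integration recovery; 100 seeds of the gradient models (the
quadratic study plants −0.2 with noise SD 0.3 at the metric level; the
slope study runs the full trial-simulation → filter → vectors → slopes →
mixed-model chain on the generator's planted slopes); 500 null simulations
for rm-correlation calibration; and 100 seeds × 200 permutations for the
prediction chain at planted multiple correlation 0.5 (referenced to the
measured battery composite), n = 24 + 25. The whole battery completes in a
few minutes on one CPU.

## Known limitations

- The bilinear discrete-time generator is a transparent stand-in for a
  continuous-time hemodynamic generative model; absolute coupling units are
  not comparable to published effective-connectivity estimates.
- PPI regression on dynamically generated (lagged, HRF-smoothed) data is
  deliberately misspecified, as in practice; recovered modulations are
  attenuated, and the validation asserts sign/ordering patterns, not
  magnitudes.
- The printed replicability and prediction correlations of the original
  human samples depend on that data and are not desk-reproducible; the
  battery here validates properties (exactness, bias direction, power,
  calibration) instead.
- Lobe/network summaries assume every ROI has exactly one network and lobe
  label; overlapping parcellations are out of scope.
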