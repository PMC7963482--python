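# fpcn-dynamics

Network dynamics of frontoparietal cognitive control, re-implemented as a
tested pipeline on simulated BOLD data with known ground truth.

Cognitive control is supported by a frontoparietal control network (FPCN)
that fractionates into sub-networks ordered along an abstraction gradient:
a concrete, present-oriented sensory-motor control network (SC), an
intermediary contextual control network (CC), and an abstract,
future-oriented temporal control network (TC). Two questions drive the
analysis chain here: whether directed (effective) connectivity shows the
CC network *integrating* the others — exciting between-network targets
while TC/SC suppress them — both statically and "on demand" under
contextual-control load; and whether individual differences in those
integration indices predict higher-level cognitive ability. Because the
original human samples are not bundled, every stage runs against a
synthetic-data module that plants this architecture and the package
validates recovery, bias, power, and calibration instead of reproducing
sample-specific numbers.

## What is implemented

- **Task design** (`task_design`): 2×2×2 factorial blocked design (spatial/
  verbal × baseline/switching/planning/dual), HRF-convolved boxcars, the
  binarized design `bin(X)`, and five mutually orthogonal ±1 contrasts
  (temporal, contextual, sensory-motor, stimulus domain, domain×contextual).
- **Synthetic data** (`synthetic_data`): a bilinear neural model
  `z' = A z + Σ_k m_k(t) B_k z + D u(t)` (Euler dt = TR/16, decimated to TR,
  double-gamma HRF, white noise) with an integrator-CC / segregator-TC,SC
  coupling truth; trial-level RT tables with planted present/future
  activation slopes; individual-difference cohorts with a planted
  integration–ability correlation.
- **ROI GLM + profiles** (`roi_glm`): grand-mean scaling to 100, per-run
  intercepts, optional AR(1) prewhitening, z-scored 8-condition profiles.
- **MDS profiling** (`profiling`): classical MDS of 1 − r profile
  dissimilarities; dimension 1 is the abstraction axis.
- **Rest scaffold** (`rest_scaffold`): Butterworth band-pass, cost-percentile
  correlation thresholds (c = 18), and the 3-of-4 (seed × run) candidate
  connectivity rule.
- **PPI / effective connectivity** (`ppi`): the in-model-contrast PPI
  `Y_target = B_conn Y_source + B_uni X + B_dep (bin(X)·C ∘ Y_source)`, the
  legacy post-hoc-contrast variant (for bias comparison), and a
  candidate-restricted lag-1 ridge estimator of static directed coupling.
- **Network metrics** (`network_metrics`): lobe-wise |EC| magnitudes, 3×3
  source×target network summaries, static/dynamic integration indices
  (between − within), residualization, the quadratic abstraction-gradient
  mixed model, and the within/between × contrast repeated-measures ANOVA.
- **Behavior** (`behavior`): RT filtering (200/2000 ms, one-sided 2.5 SD),
  present/future behavior vectors, repeated-measures (partial) correlation,
  per-subject brain–behavior slopes, and the slope-by-abstraction mixed
  model.
- **Prediction** (`prediction`): PCA composites, two-fold-by-sample and
  leave-one-out ridge (λ = 1), row-permutation inference, and the
  stimulation-susceptibility composite.
- **Pipeline + CLI** (`cli_io`): TSV/JSON formats, seed-deterministic
  manifests, and a `fpcn` command with `simulate … predict, run-all`
  subcommands.

See `docs/methods.md` for the model, parameter choices, and limitations.

## Worked example

```python
import fpcn_dynamics as f

cfg = f.Config(seed=1, out_dir="demo", n_subjects=6, n_perm=100)
out = f.run_pipeline(cfg)        # simulate -> design -> glm -> mds ->
                                 # scaffold -> ppi -> integrate -> behavior
                                 # -> predict, ~2 s
import json
print(json.loads((out / "prediction.json").read_text()))
```

prints

```
{'r_pred': 0.5812695129648249, 'p_perm': 0.009900990099009901,
 'n_perm': 100, 'scheme': 'two_fold_by_sample', 'ridge_penalty': 1.0}
```

i.e. with this seed the planted integration–ability structure yields
out-of-fold ridge predictions correlating r = 0.58 with the battery
composite, and none of the 100 row-permutations reached that accuracy
(p = 1/101). The `demo/` directory holds every stage's TSV outputs (ROI
time series, betas, the MDS embedding, candidate matrix, per-contrast
modulation matrices, integration indices, the ANOVA table, RT-filter
report) plus a manifest of SHA-256 checksums; re-running with the same
seed reproduces every file byte-for-byte.

The same pipeline is available from the shell:

```bash
fpcn run-all --seed 1 --out demo
fpcn predict --features features.tsv --outcome outcome.tsv --lambda 1 --n-perm 1000 --seed 0
```

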