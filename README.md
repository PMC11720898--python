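# dfnckit

Dynamic functional network connectivity (dFNC) analysis for neonatal
resting-state fMRI.

Neonatal functional MRI studies ask how the connectivity between resting-state
networks (RSNs) is shaped by gestational age at birth (GA), postnatal age
(PNA), and preterm birth — not just on average over a scan (static FNC), but
moment to moment. `dfnckit` implements the full desk-side analysis chain for
such studies, together with a synthetic-cohort generator so every stage can be
validated against planted ground truth without access-controlled infant data.

The pipeline:

1. **Motion QC** (`dfnckit.motionqc`) — Power framewise displacement
   FD(t) = Σᵢ|Δdᵢ| + 50 mm · Σⱼ|Δθⱼ| from rigid-body realignment parameters;
   outliers flagged at FD > Q₇₅ + 1.5·IQR; selection of the contiguous
   lowest-motion segment (default 1600 volumes); subjects excluded when the
   segment holds >10 % outlier volumes or mean FD > 0.5 mm.
2. **Network time series** (`dfnckit.rsnx`) — nuisance regression (6 motion +
   WM + CSF), zero-phase Butterworth band-pass (0.01–0.1 Hz), group spatial
   ICA (FastICA, 30 components), and two-stage **dual regression** mapping
   group RSN maps to subject time courses and maps.
3. **FNC** (`dfnckit.fnc`) — static Pearson FNC; sliding-window dFNC
   (w = 50 TR = 19.6 s at TR 0.392 s, default step 20 TR → 78 windows per
   1600-volume scan); per-edge variance of FNC across windows (Fisher-z by
   default); aggregation at edge / network / whole-brain levels.
4. **Brain states** (`dfnckit.states`) — k-means over pooled windowed-FNC
   edge vectors, cluster count validated by the gap statistic (PCA-rotated
   uniform reference, B = 50) and silhouette over k = 2…4; windows assigned to
   centroids by Pearson correlation; fractional windows, mean dwell time,
   transition counts and the empirical transition matrix per subject.
5. **Cross-subject GLMs** (`dfnckit.stats`) —
   `FNC ~ β₀ + β₁·GA + β₂·sex + β₃·motion` (term infants scanned < 1 wk after
   birth), the analogous PNA model (GA = 40 wk subgroup), and the
   preterm-vs-term contrast with PMA, sex and motion covariates; Bonferroni
   (or max-T permutation) family-wise error control; Cohen's d = 2t/√df and
   effect-size r = |d|/√(d²+4) for group contrasts.

The sklearn-style estimators (`SlidingWindowFNC`, `ConnectivityStates`,
`DualRegression`) compose with scikit-learn pipelines; every operation is also
available as a plain function.

## Worked example

Forty synthetic subjects whose network series switch between a weakly- and a
strongly-connected covariance state, with a planted GA effect of
+0.02 r-units/week on one edge:

```python
import numpy as np
from dfnckit import (synth, make_windows, fit_states, state_metrics,
                     static_fnc, fit_glm)
from dfnckit.stats import validate_cohort

table, series, truth = synth.gen_cohort(
    40, effect_spec={(0, 1): {"ga": 0.02}}, K=10, T=800, seed=5)
windows = [make_windows(ts, window=50, step=20) for ts in series]

model = fit_states(np.vstack([w.z_edges() for w in windows]),
                   k=2, seed=0, n_init=20)
print(np.round(np.tanh(model.cluster_centers_.mean(axis=1)), 3))
# [0.163 0.415]   <- state 1 weakly, state 2 strongly connected

m = state_metrics(model.predict(windows[0]), n_states=2,
                  step_seconds=20 * 0.392)
print(np.round(m.fractional_windows, 3), m.n_transitions)
# [0.711 0.289] 8   <- subject 0 spends 71% of windows in state 1

t = validate_cohort(table)
y = np.array([static_fnc(ts).values[0, 1] for ts in series])
res = fit_glm(y, t, "ga")
print(f"beta={res.beta:.4f} t={res.t:.2f} p={res.p:.2e}")
# beta=0.0226 t=9.99 p=6.36e-12   <- recovers the planted 0.02 slope
```

The centroid means recover the generator's 0.1 / 0.45 state connectivity
levels (attenuated toward each other by window-level state mixing), and the
GLM confidence interval covers the injected slope.

## Command line

```bash
dfnckit simulate --subjects 10 --volumes 1600 --networks 17 --seed 0 --out sim/
dfnckit qc --motion sim/sub-000_motion.par --length 1600 --report qc.tsv
dfnckit fnc --ts sim/sub-000_ts.tsv --window 50 --step 20 --out sub000/
dfnckit states-fit --windows 'sub*/windows_zedges.tsv' --k auto --seed 0 --out centroids.tsv
dfnckit glm --cohort sim/cohort.tsv --outcomes outcomes.tsv --model ga --out glm.tsv
```

## Acceptance script

`scripts/acceptance.py` regenerates the two-state windowed-FNC simulation
(200 windows, K = 10, weak vs strong off-diagonal correlation 0.1 / 0.45),
runs the gap + silhouette cluster-number validity analysis over k = 2…4, and
writes the selected number of connectivity states as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Documentation

`docs/methods.md` describes the models, the synthetic-data assumptions, the
numerical conventions, and known limitations.
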