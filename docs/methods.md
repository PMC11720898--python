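# Methods

This note documents the models and procedures `dfnckit` implements, the
assumptions behind its synthetic data, and the numerical conventions chosen
where the underlying methodology leaves them open.

## Motion quality control

Framewise displacement follows the Power convention: the sum of absolute
scan-to-scan changes in the three translations (mm) plus the three rotations
converted to arc length on a 50 mm sphere (radians × 50 mm). FD of the first
volume is 0 by convention. Motion outliers are volumes with
FD > Q₇₅ + 1.5·IQR, quantiles by linear interpolation — the common numpy
default; no quantile convention is canonical for this rule, and the choice
moves the threshold by far less than the spike amplitudes it is meant to
catch. The outlier threshold is computed over the **full** series; the
subject-level exclusion rule (more than 10 % outlier volumes) is evaluated
**within** the selected lowest-motion segment, because the 10 % figure is
defined relative to the cropped 1600-volume dataset. Segment selection
minimises the outlier count over all contiguous windows of the target length
with a single running-sum pass; ties resolve to the earliest start, making
the result deterministic.

A subject is excluded when the selected segment holds more than
`outlier_fraction_limit × length` outliers (default: more than 160 of 1600)
**or** the full-series mean FD exceeds 0.5 mm. Both thresholds are
parameters.

## Network extraction

Nuisance regression residualises voxel (or network) time series against the
eight standard confounds (six motion parameters, white-matter and CSF
signals) by joint OLS with an intercept; residuals are exactly orthogonal to
the confound columns. Temporal filtering is a zero-phase (forward–backward)
Butterworth band-pass, order 5, 0.01–0.1 Hz at the acquisition sampling rate
(TR 0.392 s ⇒ fs ≈ 2.551 Hz). Only the band is methodologically fixed; the
filter family and order are our choice, and order 5 gives < 5 % passband
ripple with > 99 % stopband rejection at 0.5 Hz (verified spectrally in the
tests). Confounds should be filtered identically to the data before
regression so that the regression cannot reintroduce filtered-out variance;
the CLI `extract` command does this.

Group ICA is PCA whitening followed by FastICA (fixed-point), dimensionality
30 by default, deterministic for a fixed seed. Components are identified
only up to sign and permutation; `match_components` provides the greedy
|r|-ranking against reference maps used for manual labelling. Automatic
component classification is deliberately out of scope.

Dual regression is the standard two-stage least squares: stage 1 regresses
each volume's voxel vector jointly on the group maps (variance-normalised by
default, the FSL convention, with an intercept), yielding T×K time courses;
stage 2 regresses each voxel's time course on those series, yielding subject
maps. Because both stages are joint multiple regressions, overlapping
(correlated) maps are resolved exactly: on noiseless simulated 4D data the
round trip reproduces the generating series and maps to machine precision.

## Static and dynamic FNC

Static FNC is the Pearson correlation matrix of the K network time courses.
Dynamic FNC uses rectangular sliding windows (no taper) of w = 50 TR
(19.6 s), long enough to straddle the ~5–10 s state persistence seen in
neonatal data. The number of windows is W = ⌊(T − w)/s⌋ + 1.

**Step-size convention.** The methodological source material quotes both "a
step of 2 TRs" and "78 windows" for T = 1600, w = 50 — which are mutually
inconsistent (step 2 gives 776 windows). We default to s = 20 TR, which
reproduces the 78 windows the downstream state analysis is calibrated to;
s = 2 remains available via the `step` parameter.

Edge values are Fisher r-to-z transformed before variance computation,
averaging and GLMs (variance stabilisation; matches reporting of z-valued
connectivity). Raw-r mode is available everywhere. The per-edge variance of
dFNC across windows uses the sample variance (ddof = 1); for a stationary
series it approaches the sampling variance of z, ≈ 1/(w−3), which the tests
use as an analytic yardstick.

Aggregation levels: *edge* = upper-triangle vector (K(K−1)/2 values);
*network* = mean of a network's K−1 off-diagonal connections; *whole* = mean
over the upper triangle.

## Connectivity states

States are k-means centroids (squared Euclidean distance, k-means++
initialisation, 100 restarts by default, seeded) over pooled reference-group
window vectors on the z scale. Centroids are reordered by ascending mean
edge strength, giving a deterministic labelling: state 1 is the
weakly-connected, state 2 the strongly-connected pattern.

The cluster count is validated over k = 2…4 with the gap statistic and the
mean silhouette. The gap statistic draws B = 50 uniform reference sets over
the data's bounding box **in the principal-component frame**: Fisher-z edge
vectors are strongly correlated across edges, and with the axis-aligned box
the reference is so over-dispersed that the gap curve rises monotonically in
k regardless of the true structure (we measured k = 4 selected on data with
two planted states); the PCA-rotated box is the variant recommended in the
original gap-statistic work for exactly this geometry and recovers k = 2.
Selection uses the standard rule — the smallest k with
gap(k) ≥ gap(k+1) − s_{k+1} — with one extra k computed past the top of the
range so the rule is evaluable there.

Subject windows are assigned to the centroid with the highest Pearson
correlation. This similarity is offset- and positive-scale-invariant, which
is the intended behaviour (subjects with globally shifted connectivity are
still classified by pattern); zero-variance window vectors fall back to
Euclidean distance and are flagged. Temporal metrics per subject: fractional
windows (occupancy), mean dwell time in windows (convertible to seconds via
step × TR; reported in windows by default), number of transitions
(= runs − 1), and the row-normalised empirical first-order transition
matrix. Rows of states never left are undefined (NaN), not imputed.

## Cross-subject GLMs

Three model families, fitted by OLS (statsmodels): GA and PNA models with
sex and motion covariates, and the preterm-vs-term contrast with PMA, sex
and motion covariates. Subgroup filters mirror the study designs: the GA
model restricts to term infants scanned within one week of birth; the PNA
model to term infants with GA in [39.5, 40.5) weeks (the "40-week GA"
subgroup as a tolerance window); the group model expects a pre-matched
table. Sex is coded F = 0 / M = 1 and group term = 0 / preterm = 1; an
intercept is always included; the effect of interest is the first
non-intercept regressor, tested two-sided against t with the residual df.

Family-wise error control is Bonferroni by default — the exact FWE procedure
used in the source study is unnamed, and Bonferroni is deterministic and
conservative; a seeded max-T permutation variant is provided. Correction is
applied within each (level × outcome-family).

Group contrasts are summarised by Cohen's d = 2t/√df (df = n₁ + n₂ − 2) and
the effect-size correlation r = |d|/√(d² + 4). These formulas were inferred
by matching every row of the published group-difference table from its
printed t value at n₁ = n₂ = 36; d carries the sign of t while r is reported
unsigned, matching the published table's convention.

## Synthetic data: what it emulates, and what it does not

The generator's world: K network time courses (default K = 17, T = 1600,
TR = 0.392 s) drawn per volume from a zero-mean multivariate normal whose
covariance is set by a hidden state; the hidden state follows a first-order
Markov chain at volume resolution, started from its stationary distribution,
with self-transition probability 0.98 per volume (mean dwell ≈ 50 volumes ≈
19.6 s, the window scale). A Markov chain is the minimal process with the
required window-scale persistence; no empirical dwell distribution exists to
fit, so these defaults are plausible rather than fitted.

The two default states have mean off-diagonal correlation 0.1 (weak) and
0.45 (strong) exactly, but carry distinct block patterns: the weak state's
connectivity is concentrated within the "primary" block (first ⌈K/2⌉
networks, boost +0.15), the strong state's within the "association" block.
A pure level difference would be unidentifiable to correlation-based
assignment — Pearson similarity is offset-invariant by design — so states
must differ in pattern, as empirical connectivity states do. (A
"between-block stronger than within-block" pattern is not positive definite,
hence the within-block placement.) Constant-correlation states remain
available via `constant_correlation` and are what the desk-scale
cluster-number benchmark uses, since k-means itself separates level-shifted
clusters without difficulty.

`gen_cohort` draws GA ~ U[37, 44] weeks, PNA ~ U[0, 4] weeks, balanced sex,
and injects covariate effects by shifting a chosen edge's correlation in
*every* state's covariance linearly in the covariate (centred at GA 40.5 wk
/ PNA 2 wk). Because the shift is state-uniform and observation noise
defaults to zero, the subject's static-FNC edge inherits the injected slope
exactly, giving a clean oracle for GLM recovery. Slopes that break positive
definiteness are rejected with a diagnosis.

Motion traces are smooth per-channel sinusoidal drifts (rotations ~1/50 the
amplitude of translations) with planted single-volume translation spikes;
spike indices are exported so the FD outlier rule can be scored against
truth. 4D fixtures mix spatial maps (smoothed zero-mean Gaussian fields,
approximately mutually orthogonal, like ICA maps) with the network series
plus white voxel noise.

**Not emulated:** hemodynamic response convolution, spatial autocorrelation
of noise, scanner artefacts, arousal-state drift, realistic map geometry. A
green test therefore establishes that the pipeline's estimators recover the
statistical structure they target (state covariances, occupancies, linear
covariate effects) at realistic SNR and sample sizes — not that they are
robust to acquisition physics outside this model.

## Numerical conventions

- Fisher z uses arctanh with |r| clipped at 1 − 10⁻¹² so duplicated columns
  stay finite.
- k-means ties and restarts are controlled by explicit seeds; all generator
  output is bit-reproducible given a seed.
- Correlation-assignment ties (after rounding to 12 decimals) go to the
  lower-numbered state.
- Degenerate inputs raise informative errors rather than propagating NaN:
  constant time series name the offending network, rank-deficient designs
  name collinear columns, too-short scans name the required segment length.

## Known limitations

- Hidden-state dynamics are memoryless by construction; dwell distributions
  are geometric, which real brain-state sequences need not follow.
- The gap statistic's selection can be sensitive to the reference geometry;
  we report both gap and silhouette curves so disagreement is visible rather
  than silently resolved.
- The max-T permutation FWE variant expects the caller to supply the
  permutation-null statistics; it does not build the permutation scheme for
  arbitrary designs.
- Group ICA operates on temporally concatenated data and assumes the
  reference group shares spatial organisation; no back-reconstruction
  variants (e.g. GICA3) are implemented since dual regression serves that
  role here.
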