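# Methods

This note documents the models and procedures implemented in `whiterest`,
the assumptions behind them, the parameters that matter, and the design
choices made where the method family leaves room for interpretation.

## Functionnectome projection

The projection carries grey-matter (GM) BOLD into white matter (WM) through
a sparse table of structural connection probabilities `prior(v_wm, v_gm) ∈
(0, 1]`. For WM voxel `v` with weights `w_g = prior(v, g)`:

    out(v, t) = Σ_g w_g · series(g, t) / Σ_g w_g

The combination is a weighted **mean**, not a weighted sum: dividing by the
total weight keeps the projected signal on the GM signal scale and makes
every output sample a convex combination of its inputs (the convexity bound
is asserted in the tests at 1e-10, along with exact linearity). An
alternative normalisation by tractography visitation counts would need
information the priors table does not carry. WM voxels with no prior
coverage produce an all-zero series and a logged warning rather than an
error — real priors leave parts of the white matter uncovered, and a
hard failure would make whole-brain runs impossible.

Temporal preprocessing is deliberately light: per-voxel linear detrend,
zero-phase Butterworth band-pass (order 4, applied forward and backward),
and optional mask-restricted Gaussian smoothing with
`sigma = FWHM / (2·√(2·ln 2))`. Defaults are the standard resting-state
band 0.01–0.1 Hz and no smoothing. Nuisance regression (motion, CSF/WM
regressors, despiking) is treated as upstream preprocessing and is out of
scope. One numerical detail: `sosfiltfilt` is run with even-reflection
padding sized to ~3 time constants of the slow band edge; the default
(short, odd-reflection) padding leaves visible edge transients at a
0.01 Hz cutoff, which the stop-band test exposes.

## Network extraction

**Composite series.** Each subject's GM series and WM projection are
spatially concatenated into one voxel set (GM first), with an invertible
compartment index (`split ∘ concat` is the identity, asserted exactly).

**Model order.** The number of components per subject maximises the
Laplace-approximated evidence of a probabilistic-PCA model (Minka's
criterion) computed on the eigen-spectrum of the time-by-time covariance,
voxels acting as samples. Two guards matter at phantom scale:

- voxels with zero temporal variance (prior-uncovered WM) are excluded —
  counting them overstates the sample count and makes the empirical noise
  bulk wider than the isotropic model predicts, which drives the estimate
  to the cap;
- the spectrum is truncated to its strictly positive part, and data of
  exact low rank r (zero residual variance, where the evidence diverges)
  return `min(r, k_max)` directly.

With these guards the criterion returns the planted order (3) on the
default phantom and 1 on pure noise.

**Spatial ICA.** FastICA (logcosh, fixed-point) maximises the
non-Gaussianity of the *spatial* maps: the data matrix is voxels × time,
sources are maps, the mixing matrix columns are time courses. Whitening is
done in-house — per-voxel temporal demeaning followed by eigendecomposition
of the temporal covariance — because letting the ICA library whiten would
demean each time point *across voxels*, i.e. subtract the mean map, which
lies inside the signal subspace and can silently absorb a whole network.
Maps are z-scored over the live analysis mask (flat voxels stay exactly 0),
sign-oriented so their skewness is non-negative, and split into GM/WM
volumes. Non-convergence triggers exactly one retry with a derived seed,
then a hard error; everything is deterministic given the seed.

**Clustering.** Components are grouped across subjects by greedy centroid
agglomeration on the Pearson correlation of their GM maps (GM only — the
WM map tags along as the other half of the same component): seed with the
best-correlated unassigned cross-subject pair (requiring r ≥ `r_min`,
default 0.4), then repeatedly add the best-correlated unassigned component
from a subject not yet in the group, recomputing the centroid after each
addition; at most one component per subject per group. Groups covering
fewer than `coverage_min` (default 0.5) of the subjects are discarded.
Selection is always by a global argmax over candidates, so the result is
invariant to subject order up to exact correlation ties (asserted on the
phantom). An empty *input* is an error; a run where no pair clears `r_min`
returns an empty list with a warning.

**Group maps.** The default aggregation is Stouffer's combination,
`z = Σ_s z_s / √n`, applied per compartment: it is the calibrated standard
for combining z-maps, and its null background remains N(0, 1) no matter
how consistent the members are. The one-sample-t alternative
(`method="t"`: t across members mapped to a normal quantile through the t
cumulative probability) is provided and tested, but it is a poor default
for small groups — t(n−1) tails cap the attainable z near 9 for n = 8, and
because t is scale-free it amplifies any tiny offset shared by the members
(such as the negative background bias that mean-removal imprints on
z-scored maps) into large spurious |z|. Zero-variance voxels map to 0 when
the common value is 0, otherwise to ±38, the normal-quantile overflow
guard; 38 is far above the atlas threshold of 7, so downstream statistics
are unaffected.

## Atlas overlap statistics

Maps are thresholded with a strict inequality (z > 7 by default — a
deliberately conservative support estimate), binarized and summed into an
overlap-count map. Conservation (total count = Σ support sizes) is an
exact integer identity, and raising the threshold is monotone non-
increasing voxelwise; both are asserted. Sharing distributions report the
fraction of a tissue mask at exactly k networks and cumulatively at ≥ k;
boxplot-style pathway profiles use linear-interpolation (type-7)
quantiles and 1.5·IQR whiskers.

## Lesion scoring

**Disconnectome.** The per-voxel probability that a lesion disconnects the
pathways through that voxel is a prior-based surrogate for streamline
tracking: the WM×GM priors table is read symmetrically, and each voxel
gets the probability of its strongest connection into the lesion
(`max` over lesion voxels); lesion voxels themselves get probability 1.
The probabilistic-union alternative `1 − Π(1 − p)` is available behind
`method="union"`; `max` is the default because it is stable under lesion
discretisation (splitting a lesion voxel in two cannot change the score).

**DiscROver.** Membership `v ∈ RSN` is the strict suprathreshold support
of the network's WM z-map at the atlas threshold (default 7), each member
weighted by its raw z value. The score is a convex combination of
probabilities scaled to [0, 100], hence bounded; it is exactly 100 under a
full disconnectome and 0 under a null one, invariant to positive rescaling
of the z-map, and monotone under lesion growth. The threshold is
configurable because the method family does not pin down whether scoring
uses thresholded or continuous maps; thresholded-with-z-weighting is the
reading consistent with presenting the atlas thresholded at z > 7.

**Presence.** `raw(RSN) = Σ` of suprathreshold z inside the ROI;
percentages normalise raw across networks to sum to 100 (all zero, with a
warning, when no network reaches the ROI). The sum-to-100 convention is an
interpretation choice, documented here because alternatives (e.g.
normalising by each network's total mass) answer different questions.

## Cohort statistics

Deficit scores are the first principal component of the standardised
clinical columns (correlation-matrix PCA — clinical scales differ in
units), sign-oriented to correlate non-negatively with the mean of the
standardised columns, then min–max scaled to [0, 1]. Fits are ordinary
least squares with Pearson r, R² = r², and the exact two-sided t-test
p-value. The covariate-corrected R²-c is the squared **partial**
correlation: residualise both the score and the deficit on the covariates
(with intercept) and square the correlation of the residuals; the
semi-partial/hierarchical ΔR² variant is available behind a flag since
"corrected by controlling for" is ambiguous between the two. Confidence
bands are percentile bootstrap over patient resamples (default 1000
resamples, 95%), deterministic given the seed; degenerate resamples with
constant x are redrawn and counted. Dual-impact selection is strict
(`> threshold`, default 33) on both networks' DiscROver columns.

## The phantom

The synthetic world emulates, at 24³ scale, the data the real pipeline
consumes. A spherical brain holds a cortex-like GM shell (default
thickness 2 voxels) whose voxels carry only noise; network "hubs" are
spheres (default radius 2) placed by rejection sampling with a 1-voxel
disjointness gap; each network's hubs (default 3 networks × 3 hubs) are
pairwise joined by straight WM bundles (default tube radius 1); the rest
of the interior is prior-uncovered white matter. Priors connect each
bundle voxel to all GM voxels of its two endpoint hubs with probability
`p_on` (default 1). Each network has one latent time course — white noise
band-passed to 0.01–0.1 Hz at TR = 0.72 s and standardised — shared by its
hub voxels, plus i.i.d. Gaussian noise (default sd 0.5) on all GM voxels;
the default series length is 300 frames. Three hubs per network reflect
that real RSNs are multi-node circuits, and give planted networks enough
spatial support on a 24³ grid for recovered group maps to be meaningfully
correlated against the ground truth; with two hubs the support fraction
alone caps that correlation near 0.75 regardless of recovery quality.

Cohorts draw spherical lesions centred on random WM voxels (radius 1–4
voxels); for each network the latent deficit is
`slope · DiscROver/100 + N(0, noise_sd)` and each clinical column adds
independent N(0, 0.1) measurement noise — with 7 columns per deficit this
puts the first-PC variance share in the 70–95% range typical of real
neurobehavioral batteries. `target_r` solves for the noise level that
makes the latent deficit correlate with DiscROver at a requested level
given the realised DiscROver spread. Covariates (age, sex, chronicity)
are drawn independently of everything, so they are pure noise with respect
to the deficit; the corrected-R² machinery is exercised against them and
against analytically constructed confounds in the tests.

What the phantom does **not** emulate — and what passing tests therefore
do not show about real data: haemodynamics and autocorrelated
physiological noise, head motion, registration error, inter-subject
anatomical variability (all subjects share one anatomy), overlapping
networks sharing hubs, graded (non-binary) network membership, and
realistic tractography priors with distance-dependent attenuation and
false-positive streamlines.

## Problem sizes and determinism

The test bench uses the default phantom (24³, 3 networks, 8 subjects,
300 frames) for the end-to-end recovery checks, 16³ phantoms for the
projection contract, and 20 simulated cohorts of 131 patients for the
statistics recovery; the full suite runs in about half a minute on one
core. Every stochastic step (placement, series, ICA, cohorts, bootstrap)
takes an explicit integer seed and is bit-reproducible given it.

## Known limitations

- The greedy clustering is a simplification of reproducibility-based IC
  classification schemes: no consensus over ICA restarts, no artefact
  detection, and a single similarity threshold.
- The disconnectome surrogate ignores streamline geometry: a lesion
  disconnects only what its own voxels' priors reach, so two voxels of the
  same bundle are not linked unless the priors say so.
- Order estimation assumes isotropic Gaussian noise after the exclusions
  described above; strongly heteroscedastic noise across voxels biases k
  upward.
- Group z-maps assume member maps are comparable after per-subject
  z-scoring; no variance normalisation across subjects is attempted.
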