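# Methods

`intrav1` re-implements, on fully synthetic data, an analysis chain that
asks whether the *topology* of correlations inside primary visual cortex
(V1) carries information about observed Navon figures — compound stimuli in
which a Global letter (E or U) is built from Local letters.  The four
stimulus conditions are EG, EL, UG, UL (letter × level).  This note
documents the models, the parameters that matter, the numerical choices,
and what the synthetic experiments do and do not show.

## Experimental design being emulated

A blocked fMRI design: 44 s blocks (1 s cue, 19 s baseline, 20 s of letter
repetitions, 4 s report), 12 blocks per run (3 per condition) in
randomized order, 4–5 runs per subject, TR = 2.5 s, 26 subjects.  Only V1
vertices mapping the central 4 degrees of visual angle (DVA) are modeled.
Because 44 s is not a multiple of the TR, stimulation windows are extracted
by rounding the lag-shifted onset to the nearest TR; each 20 s window gives
8 samples, hence 120 concatenated samples per condition for 5 runs and 96
for 4 runs.

## Synthetic-data generator

Each subject's run is a sum of three sources on a vertex grid placed by a
jittered golden-angle spiral per hemifield (uniform in visual-field area;
cortical magnification is deliberately not modeled — topology, not
geometry, is what downstream code consumes):

1. **Common response** — one standard-normal spatial pattern per condition,
   shared by the whole cohort, times the canonical-HRF-convolved
   stimulation boxcar, scaled by `common_gain` (default 0.5 in the
   level-network preset).
2. **Idiosyncratic evoked response** — the same regressor times a
   subject-specific multiplicative gain jitter (`idio_gain_sd`, default
   0.2) plus a small subject-specific spatial pattern (`idio_pattern_sd`,
   default 0.1).
3. **Background activity** — AR(1) noise (coefficient 0.3, a typical fMRI
   residual autocorrelation) with unit marginal variance, scaled by
   `bg_sd` (default 1.0).  During the lag-shifted stimulation epochs of a
   condition, the vertex covariance carries that condition's planted
   network: correlation increments (default ±0.3) on disjoint vertex-pair
   matchings drawn inside named edge groups.  Matchings keep the
   covariance positive definite for any |rho| < 1; dense per-group
   increments would not be.  The positive-control preset plants
   interhemispheric coupling for Global conditions and intra-hemispheric
   coupling for Local conditions, mirroring the qualitative topology the
   decoding analysis is designed to detect.

Six slow random-walk "pseudo-motion" confounds are appended per run and
leak weakly into the data (amplitude 0.1 × `bg_sd`, so the noise-free
limit is exactly the shared evoked signal).

The generator does **not** emulate: cortical surface geometry,
physiological (cardiac/respiratory) noise, scanner drift beyond the DCT
band, subject motion as image displacement, or behavioral responses.
Passing tests therefore demonstrate correctness of the statistical
machinery under a known generative model, not performance on real fMRI.

## Preprocessing

Per run, in order: (1) nuisance regression — OLS projection onto the
supplied confounds, an intercept, and a discrete-cosine drift basis up to
the 128 s cutoff (the standard high-pass implemented inside the GLM);
(2) optionally a deconvolution GLM fit per vertex on the whole run:
*HRFc* uses one 20 s boxcar ⊛ canonical HRF regressor per condition,
*FIR* uses 19 unit sticks per condition anchored at the stimulation onset
(lags 0–18 TR, spanning 47.5 s); residuals are kept; (3) segmentation of
the 20 s stimulation windows shifted by the hemodynamic lag (default 5 s =
2 TRs, near the canonical peak; configurable), linear detrending of each
segment (slope *and* mean removed), and concatenation across runs per
condition.  Deconvolution always precedes segmentation; the two orders are
not equivalent.

The canonical HRF is the standard double gamma (peak delay 6 s, undershoot
delay 16 s, dispersions 1 s, peak:undershoot 6, 32 s support), normalized
to unit sum.

## Connectivity features

Within-subject matrices are Pearson correlations over a condition's
concatenated samples.  Common-response (CR) matrices correlate one
subject's series with the grand average of the remaining subjects'
same-condition series, in both directions, averaged to a symmetric matrix
— this suppresses idiosyncratic activity and residual noise.  Matrices are
vectorized over the fixed row-major upper triangle (V(V−1)/2 edges),
Fisher r-to-z transformed, and negatives are set to zero.  Rectification
is applied in z-space; because atanh is sign-preserving the edge set
zeroed is identical in r-space.  |r| within 1e−7 of 1 is clipped before
atanh.  The diagonal is excluded.

Edges are partitioned into ten sub-networks by the unordered pair of
visual-field quadrants of their endpoints: four within-quadrant classes
(ULq, URq, LoLeq, LoRq) and six between-quadrant classes (LRup, LRlo,
UDle, UDr, DiagP, DiagS).  The four classes crossing the vertical meridian
(LRup, LRlo, DiagP, DiagS) are interhemispheric under the contralateral
mapping.  The three class names not fixed by convention (upper-quadrant
within/between) are assigned systematically.

## Classification

A linear soft-margin SVM (C = 1, no feature standardization — rectified z
features are already commensurate) on edges retained by a per-edge
two-sample Student t-test (p < 0.01, equal variances; Welch available via
flag) computed on the training data only.  If nothing survives, the single
best edge is kept so the fit stays defined.

* **Specific (inter-subject) tests** — leave-one-subject-out: per fold,
  selection + training on 2(n−1) samples, testing on the held-out
  subject's 2 samples; accuracy is the fold mean.  The two instances of
  each family (level within E / within U; letter within Global / Local)
  are averaged and their permutation p-values combined with Fisher's
  formula (−2Σ ln p ~ χ² with 2k df).
* **Abstract (cross-classification) tests** — train on one condition pair
  (e.g. EG vs EL), test on the other (UG vs UL), both directions, averaged;
  no cross-validation is needed because train and test data are disjoint
  condition pairs.

Permutation inference randomizes training labels only (1000 iterations by
default), recomputing the full selection + fit; p-values use the add-one
estimator, which can never return 0.  Label randomization exchanges the
two condition labels *within* each subject (a coin flip per subject):
because every subject contributes exactly one sample per condition, this
is the exchangeability group of the paired design, and unrestricted
shuffling of the paired labels was measurably miscalibrated in our null
simulations.  LOSO permutations flip labels inside each fold's training
set.  Class coding puts the second class (Local, or U) on the positive
side of the decision function.

## Weight-map interpretation

Classifier weights are backward-model coefficients; for interpretation
they are converted to forward-model activations with the Haufe transform.
For a single linear discriminant the activation is a ∝ Σ_X·w with Σ_X the
training-feature covariance of the retained edges (the latent variance is
a scalar and cannot change rankings or percentile cuts); non-retained
edges get 0.

Stability: 1000 participant-bootstrap replicates retrain the two
direction-specific Level classifiers and Haufe-transform each.
Concordance between the two directions is Kendall's W per replicate
(midrank ties with tie correction; for two raters W = (1+ρ_Spearman)/2, so
chance is 0.5), ranked over the union of edges retained in either
direction (edges retained by neither are excluded, not midranked at zero).
95% bias-corrected and accelerated (BCa) intervals summarize W, with the
acceleration from a leave-one-subject-out jackknife.  The per-replicate
direction-averaged maps are reduced to a per-edge median; the top and
bottom 2.5% of *nonzero* median weights (ceiling counts, threshold ties
broken by edge index) are the Local- and Global-supporting significant
edges.  Counts per sub-network assemble into a 3 schemes × 2 levels × 10
sub-networks contingency table.  Heterogeneity of the sub-network
distributions across margins is tested with a chi-square homogeneity test,
switching to a Monte-Carlo p-value (add-one) when any expected count is
below 5; this is a deliberate, documented substitute for the loglinear
machinery used in the original analysis and its p-values are not claimed
to match.

## Gaze simulation

V1 is modeled as a Gabor pyramid: five frequencies (1, 2, 4, 8, 16
cycles/FOV), eight orientations, two phases, tiled at 2, 8, 16, 64, 256
positions (grids 2×1, 4×2, 4×4, 8×8, 16×16) — 346 position nodes.
Kernels use σ = λ/2 with support ≈ ±λ, truncated to fit the field of view
at the coarsest levels, and even-phase kernels are DC-corrected; images
are mean-removed before filtering so a uniform field drives nothing and
responses are contrast-polarity invariant.  Per fixation the screen image
is translated so the fixated point sits at the center (retina-centered;
saccades in flight are ignored), filtered, and collapsed per position by
quadrature energy over phases summed over orientations.  Responses are
held for each fixation's duration on a 1 ms grid, convolved with the
canonical HRF — computed exactly via the kernel's cumulative step response
rather than a dense convolution — and sampled at the TR.  No noise is
added.  Node×node correlation matrices then enter the identical feature
and classification pipeline.

The synthetic gaze generator scatters fixations around the stimulus
centroid with Gaussian dispersion and log-normal durations truncated to
the 20 s epoch; it is a stand-in for eye-tracker recordings and reproduces
only the central concentration of real fixation maps, not their
idiosyncratic structure.  The negative-control experiment drives all four
"conditions" with one shared stimulus image so that the gaze channel is
the only possible source of condition information; with condition-
identical gaze statistics the cross-classification p-values are then
uniform.  With condition-distinct stimuli the simulator does recover
stimulus-driven structure (the specific classifications exceed chance),
which is exactly the confound the simulation is designed to expose.

## Fixation-heatmap statistics

Fixations are projected as duration-weighted deltas on the screen,
smoothed with a 2D Gaussian (5/10/20/40 px SDs), and block-summed to a
0.25 downscale (the normalized kernel conserves total duration away from
borders).  Each nonzero pixel is fit with the mixed model
`Fix ~ 1 + Level + Letter + TrialOrder + Level:Letter + (1|participant)`
by maximum likelihood.  The solver profiles the variance ratio
θ = σ²_participant/σ²_residual per pixel; because all pixels share the
grouping structure, the GLS algebra vectorizes across pixels (and, for
balanced designs, across bootstrap replicates), making whole-map refits
cheap.  It matches `statsmodels` MixedLM (ML) coefficients to ~1e−5 on
test fixtures.  Wald z statistics with normal p-values are reported;
effects are effect-coded (±0.5) and trial order is centered.

Cluster-mass inference: p-maps are thresholded at α/n_nonzero_pixels
(α ∈ {0.05, 0.1, 0.2}), supra-threshold pixels form 8-connected clusters,
and a cluster's mass is the sum of the tested effect's coefficients within
it.  The null distribution is the maximum |mass| over participant
bootstrap resamples of null-centered data (the fitted contribution of the
tested effect is subtracted before resampling); the max-statistic null
gives family-wise control, with a pooled-null variant available.

## Problem sizes used in the validation suite

Simulation-based checks run at reduced but statistically adequate sizes
chosen for a single-CPU workflow: permutation calibration uses 200 null
cohorts (10 subjects, 50 vertices, 4 runs, 199 permutations); cluster-mass
calibration uses 500 noise experiments (18 participants — the control
experiment's sample size — with 8 trials each, 6×8-pixel downscaled
grids, 199 bootstrap replicates); the end-to-end
positive control uses 26 subjects, 100 vertices, 5 runs, 199 permutations
and 200 bootstrap replicates over 20 generator seeds; the gaze-simulation
controls use a 4-level bank on a 128×96 screen over 50 seeds.  Binomial
bands quoted in the tests account for the Monte-Carlo error at these
sizes.

## Known limitations

* The planted network uses pair matchings, which makes mean correlation
  increments smaller than a dense same-rho block; effect sizes quoted for
  the generator are per-edge, not network-average.
* Permutation p-values are discrete and mildly conservative under heavy
  ties (small cohorts), a generic property of resampling tests on coarse
  accuracy grids.
* The LMM solver supports a single random intercept only — exactly the
  model used here; random slopes would need a different profiling scheme.
* The participant bootstrap behind the cluster-mass null turns
  conservative for very small cohorts (measured rejection ~0.016 at six
  participants); calibration is near-nominal at the study's 18.
* CR matrices inherit the sign conventions of the shared response; with a
  zero common gain they estimate pure noise correlations and are expected
  to carry no signal.
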