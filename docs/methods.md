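# Methods

`loclab` is a simulation and validation toolkit for blocked fMRI
reading-localizer paradigms. It exists to answer a methodological
question with known ground truth: if two versions of a language
localizer differ only in presentation rate (and hence in run length and
block length), does the analysis chain — first-level GLM,
parcel-constrained subject-specific fROIs, cross-validated response
extraction, topographic-similarity metrics, group mixed models — behave
as expected, and does it recover injected effects without bias? Every
stage of the chain is therefore implemented against a synthetic-data
generator whose ground truth is known exactly.

## Paradigm timing

Three task versions are modeled as blocked designs:

| version   | word rate | trial | block          | fixation | blocks (exp+fix) | run   |
|-----------|-----------|-------|----------------|----------|------------------|-------|
| standard  | 450 ms    | 6 s   | 18 s (3 trials)| 14 s     | 16 + 5           | 358 s |
| speeded   | 200 ms    | 3 s   | 9 s (3 trials) | 14 s     | 16 + 5           | 214 s |
| spatialWM | —         | 8 s   | 32 s (4 trials)| 16 s     | 12 + 4           | 448 s |

A reading trial is a 100 ms blank, twelve words/nonwords at the
version's rate, a 400 ms button-press cue, and a 100 ms blank. All
onsets are computed on an integer millisecond clock, so run durations
are exact, not accumulations of binary floats.

Design choices where the design was genuinely open:

* **Fixation placement.** The five fixation blocks sit at run start,
  run end, and at evenly spaced boundaries between groups of four
  experimental blocks — the symmetric, conventional layout for blocked
  localizers.
* **Counterbalancing.** Run 1 is a seeded balanced pseudo-random
  order; run 2 is its reverse. Reversal cancels linear time-in-run
  confounds between conditions.
* **Working-memory trial internals.** The fixation cross, location
  flashes, choice and feedback phases are collapsed into one fixed 8-s
  event, because the GLM models whole condition blocks, not sub-trial
  events.
* **Stimulus text is opaque.** Items are deterministic pseudo-token
  strings (5 sets × 48 sentences + 48 nonword sequences, 12 tokens
  each). Only timing, condition labels, and item identity (for
  no-repetition bookkeeping) enter the analysis. Each subject draws
  from a single set, with no item repeated across that subject's two
  runs of the same version.

## Synthetic BOLD generator

The generator emulates the features of multi-subject localizer data the
analysis depends on, and nothing more:

* **Parcels.** Nine spherical parcels (radius 3 voxels) on a 24×24×24
  grid of 2-mm voxels, world origin at the grid center: five
  left-hemisphere "language" parcels (LIFG, LIFGorb, LMFG, LAntTemp,
  LPostTemp) and four "MD" parcels (two per hemisphere). The default
  grid keeps whole-pipeline runs at ~0.5 s per subject; geometry, not
  anatomy, is what matters here.
* **Selective voxels with inter-subject jitter.** Within each parcel a
  smooth Gaussian-blob weight field, displaced per subject
  (sd 4 mm), is thresholded so the top 20 % of parcel voxels are
  "selective". A smaller per-version displacement (sd 1 mm) makes
  topographies version-specific, so within-version map similarity
  exceeds between-version similarity in expectation — the effect
  structure the topography module is meant to detect.
* **Amplitudes.** Selective language voxels respond (percent signal
  change at block peak) sentences 3.8 / nonwords 1.0 in the standard
  version and 4.4 / 0.2 in the speeded version; MD voxels respond
  hard 4.0 / easy 1.4, with a weak nonwords>sentences pattern for
  standard reading that disappears under speeded reading. A
  per-subject lognormal gain (sd 0.15 log units) supplies
  between-subject magnitude variability. After the default 4-mm
  smoothing dilutes the small selective clusters (~×0.5), extracted
  fROI responses land at realistic magnitudes (contrast ≈1.5 %
  standard, ≈2.2 % speeded).
* **Noise.** Per-voxel AR(1) noise (ρ = 0.2, stationary
  initialization), sd 3 % of baseline — chosen so run-to-run map
  reliability within a version is high but imperfect (r ≈ 0.8), as in
  real localizer data — plus a 0.5 % cosine drift with a 200-s period.
  The period deliberately exceeds the GLM's 128-s high-pass cutoff
  only partially, so the drift regressors are actually exercised.
  Noise is spatially independent by default (an optional smoothing
  FWHM emulates spatial correlation), which keeps null distributions
  analytically checkable.
* **Steady state.** Real acquisitions discard the first seconds of
  each run; the simulator simply never generates pre-steady-state
  scans — the schedule clock and the acquisition clock both start at 0.

What the generator does **not** emulate: head motion, physiological
noise, EPI distortion, anatomical variability in parcel shape,
condition-correlated noise, or session effects. Tests passing on this
generator therefore validate the *estimators* (unbiasedness,
calibration, selection-bias avoidance), not robustness to artifacts of
real acquisitions.

## First-level GLM

Per run: each condition is a boxcar at 0.1-s resolution convolved with
the canonical double-gamma HRF (peak delay 6 s, undershoot delay 16 s,
dispersions 1 s, peak:undershoot ratio 6, 32-s kernel,
peak-normalized), sampled at scan onsets (TR = 2 s). Fixation is
modeled implicitly. Temporal derivatives (centered finite differences,
orthogonalized against their parent regressor so condition betas stay
interpretable) are included by default. Drift is handled inside the
model by a discrete-cosine basis with ⌊2T/cutoff⌋ columns
(cutoff 128 s; components with full period at or above the cutoff, the
SPM/nilearn convention), plus a constant. User-supplied nuisance
regressors (e.g., motion or outlier-scan indicators from a real
pipeline) are accepted as an opaque matrix.

Each voxel's series is scaled to percent of its temporal mean; data and
design are then premultiplied by the fixed AR(1) whitening matrix
(a = 0.2; row i is y_i − 0.2·y_{i−1}, first row scaled by √(1−0.04)),
and the whitened system is solved by ordinary least squares — the GLS
estimator under that noise model. No ReML variance-component
estimation: the AR coefficient is fixed by convention, so ReML would
add machinery without changing the estimand materially.

**Scaling convention.** Convolved condition regressors are rescaled to
unit peak within the run, so a beta of b means a peak response of b
percent. Because the temporal mean itself contains task signal,
percent-of-mean betas carry a small (~1 %) multiplicative bias;
contrast *effect maps* are therefore reported as percent of the
estimated baseline (cᵀβ normalized by the constant-term coefficient),
which recovers injected simulator amplitudes exactly in the noiseless
limit. The t statistic is computed from the raw whitened contrast and
is invariant to this per-voxel rescaling.

Spatial smoothing (separable Gaussian, default FWHM 4 mm,
σ = FWHM/(2√(2 ln 2))) is applied to the data before fitting,
mirroring the usual preprocess-then-fit order.

## fROIs and cross-validated extraction

Subject-specific fROIs are the top fraction (default 10 %) of parcel
voxels by the defining contrast's t value; the count is
max(1, ⌊fraction·n⌋) and ties break by ascending linear voxel index, so
selection is deterministic across platforms. Right-hemisphere parcels
are obtained by reflecting labels across the mid-sagittal plane in
world coordinates through the affine.

Responses for the conditions that define an fROI are extracted with
across-runs cross-validation: one run defines the fROI, the held-out
run's per-condition effect values are averaged (unweighted) over the
fROI voxels, and the two folds are averaged. The validation suite
demonstrates why: on null data the circular estimate
(define-and-extract on the same run) is positively biased while the
cross-validated estimate centers on zero.

## Topographic similarity

Voxelwise Pearson correlations of contrast maps restricted to a parcel,
Fisher-transformed (atanh, inputs clipped at |r| = 1 − 1e-7 so
degenerate simulations stay finite) and averaged across parcels.
Correlations use *effect* maps by default — t maps conflate effect and
variance — with the t-map variant available as a switch. Within-version
similarity correlates a version's two runs; between-version similarity
averages the four pairwise run combinations, matching the amount of
data per comparison. Dice overlap (2|A∩B|/(|A|+|B|)) of fROIs is
computed at selection fractions 10/20/30 % with the same
within/between structure. Whole-brain variants are supported by passing
a full-grid mask.

## Group statistics

The group model is a Gaussian linear mixed model with crossed random
intercepts for participant and fROI:
y = Xβ + Z₁b₁ + Z₂b₂ + ε. The likelihood is profiled over β and σ²
and optimized over the two log variance ratios with bounded L-BFGS-B
from two starting points (tolerance 1e-12 on the deviance); a variance
component reaching the boundary is flagged, not raised. Fixed-effect
factors use treatment coding with sorted levels (so
`condition[sentences]` is sentences − nonwords and
`version[standard]` is standard − speeded).

Reported coefficients use REML; likelihood-ratio tests for the
condition×version interaction refit both models by ML, since REML
likelihoods are not comparable across fixed-effect structures. Wald
statistics are referred to a standard normal by default; a
Satterthwaite-style degrees-of-freedom approximation (delta method on
the finite-difference Hessian of the REML criterion) is available as an
option — at this design's scale the two differ negligibly. R² follows
the variance-decomposition (Nakagawa–Schielzeth) formulation. Paired
and one-sample t tests are classical Student statistics.

In the default simulation the parcels are statistically exchangeable
(identical spheres), so the fROI variance component legitimately sits
near the boundary; the participant component is positive through the
per-subject gain.

## Validation suite and problem sizes

`tests/test_acceptance.py` and `scripts/acceptance.py` recompute, from
scratch: exact design-timing arithmetic; equivalence of the prewhitened
GLM with a dense GLS oracle (< 1e-8); type-I calibration of null
contrast t tests (rate in [0.03, 0.07]); brute-force equivalence of
fROI selection for parcel sizes 1–1000 at fractions 0.1/0.2/0.3;
non-circularity over 200 null subjects; recovery of the injected
sentences−nonwords amplitude within 5 % relative bias over 100 run
pairs at default noise; mixed-model recovery (100 replicates of the
24-subject × 5-fROI design) and null-interaction LRT calibration
(500 replicates); and directional reproduction of the expected
findings — sentences > nonwords in both versions, larger contrast in
the speeded version, within ≥ between topographic similarity,
significant interaction — across 50 seeded pipeline replicates.

Problem sizes are the package's own choices: the repeated-seed pipeline
replicates use 8 subjects each (power for the injected interaction is
essentially 1 well below 24 subjects), the LRT null calibration uses
12 subjects × 4 fROIs, and the small-grid recovery simulations use a
single parcel, which isolates the estimator chain from multi-parcel
bookkeeping. The recovery check runs unsmoothed and extracts within
the true selective population: smoothing dilutes small clusters
spatially (a partial-volume effect, not an estimator bias), so
recovery is assessed where the injected amplitude is the defined truth.

## Known limitations

* Fixed-coefficient prewhitening (no ReML) and a fixed canonical HRF;
  HRF mismatch is representable only through the derivative columns.
* The LMM supports exactly the crossed-intercepts structure the
  analysis needs — no random slopes, no non-Gaussian families.
* Satterthwaite degrees of freedom use finite-difference Hessians and
  should be treated as approximate for small designs.
* Synthetic parcels are spheres with exchangeable statistics; between-
  fROI heterogeneity of real data is not emulated by default.
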