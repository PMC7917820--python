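# Methods

This note records the models, numerical choices and known limitations of
the spikesom pipeline, in the order the data flow through it.

## Channel model

All analyses operate on 32 channels: centre-of-mass x/y/z (metres),
left/right hip-knee-ankle flexion, left/right shoulder
ab/adduction + horizontal ab/adduction + internal/external rotation and
elbow flexion (degrees), and pelvis/spine/thorax/neck/head 3-DOF segment
angles.  The registry fixes column order everywhere; limb-subset
analyses (lower = 6, upper = 8 channels) exclude the CoM coordinates,
which belong only to the whole-body set.  That exclusion is a design
choice — CoM position is not a limb degree of freedom — and subset
membership is driven by the registry's group tags, so it is easy to
revisit.

## Preprocessing

* **Filtering.** "4th-order zero-lag Butterworth" is implemented as a
  2nd-order filter run forward and backward (`scipy.signal.filtfilt`),
  the standard biomechanics convention: the dual pass doubles the
  effective order and cancels phase lag.  Reflective padding of 3x the
  filter order suppresses endpoint transients on short trials.  Cutoff
  default 10 Hz at 180 Hz sampling; the squared magnitude response of
  the dual pass at the cutoff is 1/2 (amplitude gain 0.5), which the
  tests verify against the analytic response.
* **Events.** The plant frame is the first frame with both heel markers
  below 30 mm *and* vertical speed magnitude below 50 mm/s; ball impact
  is the global minimum of the wrist-marker Y acceleration, rejected as
  unreliable if shallower than 1000 mm/s² (the published definitions are
  verbal; these thresholds are exposed parameters).  Events may also be
  supplied per trial in the manifest, which takes precedence — useful
  when marker traces are unavailable.
* **Velocity order of operations.** Angular velocities are computed by
  central differences at the original 180 Hz on the trimmed window, and
  *then* time-normalised to 101 points alongside the angles.
  Differentiating after time-normalisation would rescale every trial's
  velocities by its duration; differentiating first preserves physical
  units (deg/s, m/s).
* **Outcome labels.** A spike is faulty iff the attacker was blocked,
  ball speed < 50 km/h, the ball touched the block and slowed below
  50 km/h, or it landed out — a pure disjunction, property-tested as
  such.

## SOM

* **Input.** Per-channel range normalisation to [−1, 1] uses pooled
  min/max over all sequences and time points (constant channels map to 0
  and are flagged); the transform is stored and invertible.  Training
  samples are the pooled per-time-point state vectors of all sequences —
  successful and faulty patterns share one map.
* **Map size.** Base unit count ceil(5·sqrt(N)) for N pooled samples
  (the SOM-toolbox heuristic), scaled by 1/4, 1 or 4 (small / normal /
  big; big is the applied default).  The side ratio follows
  sqrt(lambda1/lambda2) of the two leading data-covariance eigenvalues,
  with a square fallback for degenerate covariance.
* **Lattice.** Hexagonal with odd-row offset 0.5 and row spacing
  sqrt(3)/2, so nearest-neighbour distance is exactly 1 and the
  BMU-trajectory distances are in interpretable lattice units.
* **Training.** Two-phase sequential updates
  w_j += alpha(t)·h_cj(t)·(x − w_j) with Gaussian neighbourhood
  h_cj = exp(−d²/(2 sigma²)) on lattice distance.  Phase 1 (ordering):
  alpha 0.5→0.05, sigma max(rows, cols)/4→1, 5 passes; phase 2
  (fine-tuning): alpha 0.05→0.01, sigma 3→1, 10 passes.  Both schedules
  decay linearly per step.  The pass counts are package defaults in the
  toolbox rough/fine-tune spirit; all schedule fields are configuration.
  Sample order is reshuffled each pass from a fixed seed, so training is
  bit-reproducible.  Batch training (Voronoi-mean update), bubble /
  cut-off-Gaussian / Epanechnikov neighbourhoods and a rectangular
  lattice are available for sensitivity analysis.
* **Initialisation.** Deterministic linear initialisation spanning the
  first two principal components (sign-fixed SVD), which also gives the
  quantisation-error baseline the training tests compare against.
* **BMU trajectory distance.** The bracket in the summed squared
  BMU difference is interpreted as Euclidean distance between lattice
  *coordinates* — unit indices are meaningless as numbers on a 2D grid,
  and weight-space distance would measure something else (it remains
  available via `space="weight"`).  Ties in BMU search break to the
  lowest unit index.

## Clustering

A hand-written Lance–Williams agglomerator covers single, complete,
average (the applied default), median, centroid and Ward linkage, with
lexicographic tie-breaking on cluster indices.  It runs directly on the
squared-distance trajectory matrix; for median/centroid/Ward this means
the recurrence operates on squared-distance semantics, where centroid
and median can produce height inversions — a documented caveat, not a
bug.  Average linkage is monotone.  The implementation is verified to
1e−9 against `scipy.cluster.hierarchy` on random instances (feeding
scipy the square-rooted matrix and squaring its heights for the
geometric linkages, which scipy defines on the distance scale).
Dendrograms serialise to Newick with each merge node at half its merge
height.

## SPM

* **t field.** Node-wise pooled-variance two-sample t over the 101-node
  cycle, df = n1 + n2 − 2; exact agreement with the scalar test is
  asserted.
* **Smoothness.** Residuals (group-centred observations) are normalised
  node-wise to unit sum of squares; the mean squared node-axis gradient
  v estimates the derivative variance of a unit-variance field and
  FWHM = sqrt(4 ln 2 / v), clamped to [1, 1000] nodes.  On unsmoothed
  white noise the discrete gradient makes the estimator read ≈ 2 nodes
  (a floor, not a bias at realistic smoothness); with Gaussian smoothing
  at FWHM 10–40 it recovers the kernel width within Monte-Carlo error.
* **Threshold.**  The two-tailed critical value solves, per tail,
  alpha/2 = S_t(u; df) + R·sqrt(4 ln 2)/(2 pi)·(1 + u²/df)^(−(df−1)/2)
  with R = (101−1)/FWHM resels — the expected Euler characteristic of a
  smooth t field's excursion set — by Brent root-finding to 1e−8,
  bracketed from the uncorrected quantile (so the corrected threshold is
  never below it; as R→0 it reduces to the uncorrected value).
  Monte-Carlo calibration at n = 10 vs 9, FWHM 20 puts the family-wise
  false-positive rate at the nominal 0.05 within ±0.01.
* **Aggregation.** The pipeline's SPM compares *channel-averaged*
  normalised velocity waveforms per channel group (one 1D field per
  group), successful vs faulty condition means across players.  Testing
  velocity waveforms (rather than BMU-trajectory coordinates) is the
  default because the limb-level findings are stated on velocities;
  both inputs are supported.  Two-tailed inference with alpha/2 per
  tail.  A node-wise Shapiro–Wilk normality check is recorded as the
  fraction of nodes passing at p > 0.05 but never gates inference.

## Synthetic cohorts

The generator emulates the study design the pipeline assumes: 10
players x 6 spikes, fault probability 1/3 with every player keeping at
least one trial of each label except player 2 (index 1), who never
faults — hence 19 condition-mean sequences.

* **Templates.** Each player's channel curves are sums of 4 random
  harmonics with 1/h amplitude fall-off, scaled to 12 deg (angles) /
  0.25 m (CoM).  The 15 trunk/neck/head channels mix in a shared
  within-player curve with weight sqrt(0.8) (pointwise correlation 0.8):
  stacked axial segments tilt together.  This coupling matters
  statistically — it keeps the between-player variance of the
  *whole-body* channel average from collapsing by sqrt(32), which is
  what confines the detectable successful/faulty difference to the
  upper-limb analysis, as the design intends.
* **Trial noise.** White noise convolved with a Gaussian kernel of FWHM
  20 samples, SD 2 deg (angles) / 0.02 m (CoM), trunk channels sharing a
  common component as above.  FWHM 20 keeps the time-normalised fields
  in the smoothness regime the RFT inference assumes.
* **Effect.** Faulty trials add, to all 8 upper-limb channels, an angle
  perturbation whose time derivative is a velocity bump of amplitude
  3x the velocity SD implied by the trial noise (≈ 90 deg/s at the
  defaults), supported on the 35–45% and 76–100% windows of the
  movement with 4%-wide half-cosine tapers centred on the window edges
  (inside the ±5% confinement margin; the window ending at 100% keeps
  full amplitude to impact).  Injecting on the angle and letting
  preprocessing differentiate keeps psi and phi consistent.  A
  back-of-envelope power check at these defaults: the channel-averaged
  upper-limb group SD is ≈ 1.2x the velocity-noise SD, so the expected
  peak t is ≈ 5, comfortably above the RFT threshold (≈ 3.6–3.8) —
  which is why recovery succeeds in essentially all seeds while the
  onset estimate lands within ~2% of the window edge.
* **Markers and metadata.** Heel traces decelerate to just below the
  30 mm threshold exactly at the scripted plant frame; the wrist trace
  has a step drop in per-frame displacement at impact, so event
  detection recovers the scripted frames exactly.  Faulty outcomes
  always carry ball speed < 50 km/h, with blocked/touched/out flags
  drawn at small probabilities for classifier coverage.
* **What it does not emulate.** No ball-contact or muscle dynamics, no
  real physiological ranges per joint, no marker occlusion or soft-tissue
  artefact, no left/right asymmetries or handedness effects.  Passing
  tests therefore demonstrate that the pipeline recovers structure *of
  the kind assumed*, not that real spike data contain that structure.

## Problem sizes

Defaults used by tests and the acceptance script: SPM calibration with
5000 null replicates; effect recovery over 20 cohorts; SOM tests run on
quarter-size maps with shortened schedules (3 + 5 passes), which
exercises the identical code path as the full configuration.  Full-size
(big map) training of all nine analyses on a 19-sequence cohort takes a
few minutes and is the CLI default.

## Known limitations

* The RFT threshold uses the two-term EC approximation; at very low
  smoothness (FWHM ≲ 3 nodes) the approximation and the gradient-based
  FWHM estimator both degrade — the estimator's clamp floor marks that
  regime rather than hiding it.
* Centroid/median linkage on squared distances can invert; dendrogram
  plots of those linkages should use care.
* C3D ingestion is not provided; trials enter as wide CSV plus a
  manifest.  Joint angles are assumed already computed upstream — the
  package does not implement a marker-to-angle model.
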