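# Methods

This note documents the models, conventions and numerical choices behind
`ringcompass`, in the order data flow through the pipeline.

## Conventions

All angles are radians, times seconds. The anatomical frame is `x_lr`
(left positive), `y_rc` (rostral positive), `z` (dorsal). A ROI's ring
angle α and the network phase φ share one convention: caudal = 0,
left = +π/2, right = −π/2, increasing clockwise when the horizontal plane
is viewed from above. Tail laterality is positive for rightward swims, so
integrated heading rises with right turns while φ — which rotates
clockwise after left swims — moves the opposite way; their anticorrelation
is a property of the circuit, not a sign error.

## Synthetic sessions (`synthio`)

The generator produces the study conditions every test runs under. It is a
kinematic model: the bump is imposed, not produced by connectivity.

* **Swims.** A Poisson process (default 0.3 Hz) with a 1 s refractory gap.
  Lateralities come from a symmetric trimodal mixture — forward
  N(0, 0.1 rad) with weight 0.5, left/right N(∓0.6, 0.2 rad) with weight
  0.25 each — and directional swims chain: the side repeats with
  probability 0.8. Turn chaining is a documented feature of larval
  swimming and is what carries the bump around the full ring within a
  10-min session; without it a 600-s random walk frequently parks in one
  sector, and no decoder can recover a phase the data never visit. The
  fitted trimodal classification threshold under these defaults is
  ≈ 0.24 rad, matching the reference operating point (±0.239 rad) that the
  behavior module ships as its fallback constant.
* **Phase.** Each swim moves the phase set point by
  `phase_gain × laterality` (default gain −0.7, i.e. a typical directional
  swim rotates the bump ≈ 0.4–0.5 rad); the phase relaxes to the set point
  with a 1-s time constant, mimicking the smooth bump translation seen in
  recordings, and is constant otherwise. An optional gaze term
  (`gaze_coupling`, default −0.2) adds the saccade-driven wobble used by
  the regression analyses.
* **Tail.** Each bout is the laterality index plus a decaying sinusoidal
  oscillation (amplitude 0.6 rad, envelope τ = 0.25 s, duration
  0.15–0.30 s). The carrier is 2/0.070 ≈ 28.6 Hz so that an integer number
  of cycles falls inside the 70-ms laterality window; the windowed mean
  then equals the programmed laterality and is first-order insensitive to
  the few-ms onset-detection delay. The oscillation's own windowed mean is
  subtracted at synthesis, making the encoding exact.
* **Calcium.** Ring drive `amplitude · ½(1 + cos(φ − α))` (or von Mises),
  convolved with a causal single-exponential kernel of unit DC gain
  (default decay 1.8 s, GCaMP6s-like: slower than the 5 Hz frame rate,
  faster than inter-swim intervals), plus i.i.d. Gaussian noise (default
  s.d. 0.15 of the unit peak). Raw fluorescence is rendered as
  `F₀(1 + activity)` with F₀ = 100, optionally bleached.
* **Distractors.** 30% of ROIs lie outside the ring ellipse; half are pure
  noise, half follow a calcium-filtered left- or right-swim event train,
  exercising both selection stages and the motor-regressor classification.
* **Anatomy stand-ins.** `make_mirrored_skeletons` builds synthetic
  IPN-projecting neurons whose axon targets the mirror position of the
  antiphase partner's dendrite (`axon_x = dendrite_x − pitch`), giving
  exactly anticorrelated midline distances and a constant dendrite–axon
  separation; `simulate_mirrored_plane` renders a synthetic neuropil movie
  in which pixels separated by a fixed frontal offset share their signal.
  Both are labeled synthetic and exist because the reconstructed EM
  skeletons and two-photon movies are not redistributable at desk scale.

What the generator does *not* emulate: motion artifacts, neuropil
contamination, slow network-state changes, bump deformation during
rotation, realistic saccade kinematics, or any connectivity. Passing tests
therefore certify the analysis chain — selection, embedding, decoding,
statistics — under a faithful signal model, not robustness to every
nuisance found in real recordings.

## Preprocessing (`traceprep`)

ΔF/F uses a centered rolling-mean baseline (default window 900 s). The
window has constant length and is clamped inside the recording: a
shrinking edge window would high-pass the slow bump signal unevenly across
the session (measured ≈ 0.5 rad of decoded-phase bias on 600-s sessions).
For traces shorter than the window this reduces to the global mean. A
rolling-percentile baseline is available behind `baseline_statistic`.
Traces are then median-filtered (default 3 frames) and z-scored;
zero-variance ROIs are dropped with a warning. The whole chain is
invariant to per-ROI positive rescaling of the raw fluorescence.

## Behavior (`behavior`)

Vigor is the rolling 50-ms standard deviation of the tail angle
(right-aligned, start padded with the first sample). Swims are maximal
supra-threshold (0.1) vigor episodes merged across gaps < 100 ms; the
laterality window starts at the threshold crossing. Classification fits
`w_c N(0, σ_c) + w_s N(+μ, σ_s) + w_s N(−μ, σ_s)` to the 61-bin laterality
histogram by least squares and uses the positive crossing of the central
and side component densities as the threshold; if the fit fails or no
crossing exists the packaged fallback (0.239 rad) applies. Gaze is the
mean of the two eye angles; saccades are velocity threshold crossings
merged within 100 ms.

## Ring selection (`ringdetect`)

A ROI enters the provisional selection iff its minimum pairwise trace
correlation is ≤ a threshold (default −0.6; an optional scan over
[−0.75, −0.5] maximizes the ring-quality score
1 − CV(embedding radii), replacing per-fish manual tuning). The second
pass sorts the selection by provisional PC angle and excludes ROIs whose
row of the sorted correlation matrix correlates < 0.5 with the ideal
template cos(αᵢ − αⱼ) — a reproducible surrogate for curation by visual
discontinuity. Anatomy is deliberately not used, to keep the selection
independent of the anatomical claims tested later.

## Circular embedding (`rpcspace`)

Two PCA views: state-space (time points as observations; the first two
components should carry ≥ 80% of variance) and the neuron embedding (ROIs
as observations over time). Both pin `svd_solver="full"` for bit-exact
reproducibility. The neuron embedding is normalized by an algebraic hyper
least-squares circle fit (unbiased to leading order; cross-checked against
an iterative geometric fit) and anchored anatomically: anchor vectors are
embedding-coordinate averages weighted by the mean-centered rostro-caudal
and rightward coordinates, and an exhaustive 0.1°-grid search over
rotations × {identity, reflection} minimizes |θ₁| + |θ₂|, the angular
misfits of the rostral anchor to π and the rightward anchor to −π/2, with
ties broken toward the smaller rotation. Anatomical organization is
quantified by the Fisher–Lee T-linear circular correlation

    ρ_T = Σ_{i<j} sin(αᵢ−αⱼ) sin(θᵢ−θⱼ) / √(Σ sin²(αᵢ−αⱼ) · Σ sin²(θᵢ−θⱼ)),

pinned in code and tested against a brute-force double loop, plus
per-axis sinusoid fits of the coordinates over α compared with
coordinate-reshuffled controls.

## Phase decoding (`phasedyn`)

`compute_phase` clips each trace to its 2nd/98th percentiles (per ROI over
the recording by default — frame-wise percentiles over ~10² ROIs are
unstable; the frame-wise variant is available via `clip_mode`), subtracts
the across-ROI mean at every frame (Σfᵢ(t) = 0) and takes the angle of
v(t). The pipeline feeds it median-filtered ΔF/F rather than the z-scored
traces: z-scoring subtracts each ROI's temporal mean, which under
finite-session phase occupancy correlates with ring position and biases
the decoded angle toward the most-occupied phase (~0.5 rad on 600-s
sessions); the z-scored traces are used for PCA, selection, profile and
tuning, where per-ROI affine scale is irrelevant. An optional
`subtract_trough` normalization removes per-ROI offsets using the lower
clip bound; it requires every ROI's anti-preferred phase to be visited and
is off by default.

The bump profile interpolates traces over α onto 100 bins (periodic linear
interpolation), shifts each frame by −φ(t) and averages; a non-interpolated
variant (α-sorted ROIs, nearest-bin shift) is computed alongside and must
agree (bin-wise correlation > 0.98 in the tests). FWHM takes the profile
minimum as baseline — the profile need not decay to zero — and locates the
half-level crossings flanking the peak by linear interpolation on the
circle. Tuning curves are per-ROI means binned by wrapped phase (36 bins);
empty bins are interpolated periodically for the width estimate only.

## Heading and coupling (`headnav`)

Heading is the exact cumulative sum of laterality at swim onsets,
resampled to the imaging clock by zero-order hold (it is piecewise
constant by construction). Window correlations use a 300-s window stepped
by window/10 = 30 s; the shuffle correlates each phase window with a
randomly placed non-overlapping 5-min heading epoch, and the two
correlation populations are compared with a two-sided Mann–Whitney test.
Because overlapping windows are strongly dependent, the test is
anticonservative under the null; a non-overlapping variant
(`window_step_s = window_s`) is provided and is what the null-calibration
test uses. Triggered averages subtract the 10-s pre-event mean and require
≥ 3 events per class. The post-swim regression takes each signal's change
from its value at onset to its mean over the 15–20 s window and fits
Δphase on Δheading by ordinary least squares. Swim-onset phase occupancy
is tested per class with the Rayleigh statistic and across classes with a
Mardia–Watson–Wheeler uniform-scores test. Regressors convolve event
indicators (and gaze traces) with a causal exp(−t/3 s) kernel of unit
peak; motor ROIs use the dual 0.7-correlation rule; the cross-validated
regression fits the median-filtered central-difference phase derivative on
a random 5-min epoch and scores the Pearson correlation on a disjoint
5-min epoch, 500 times, for gaze-only, motor-only and combined models.

## Anatomy (`ipnmap`)

SWC files are read as the canonical 7-column table and validated as a
single connected tree; compartments come from the SWC type codes or a
sidecar table. Branching points are nodes with ≥ 2 children; compartment
centroids are unweighted means of branching-point coordinates, with an
optional all-node fallback for unbranched compartments, and midline
distances are |x − midline|. The midline is a configured constant plane of
the dataset's frame. The pairwise branch-point offset histogram bins
signed per-axis offsets of all ordered pairs (total N(N−1)). The 2-D
autocorrelation averages pixels into 3.5 µm bins inside the mask, z-scores
each bin trace, excludes zero-variance bins with pair bookkeeping, and
averages the pairwise Pearson correlations by signed bin offset; the map
is exactly point-symmetric because all ordered pairs enter.

## Pipeline and bundles (`bundleio`, `pipeline`, `report`)

A session bundle (raw fluorescence, ROI table, tail, optional gaze,
optional condition table, optional ground truth, metadata with seed) is
stored either as one HDF5 file or a directory of CSVs plus YAML metadata;
the dialects are tested for equivalence. `PipelineConfig` rejects unknown
keys at construction and is echoed into every result for provenance;
stage failures carry the stage name and an input digest. Runs are
deterministic given config and seed.

## Problem sizes

The reference conditions used throughout the tests and the acceptance
script are five 600-s sessions of 80 ring neurons (plus 34 distractors) at
5 Hz imaging and 400 Hz behavior, chosen so a full suite run completes in
well under a minute of compute per session while leaving every statistic
far from its acceptance boundary (e.g. two-component variance ≈ 92%
against the 80% bound, decoded-phase RMSE ≈ 0.13 rad against 0.15).

## Known limitations

* The decoder inherits the calcium kernel's lag; during rapid swim
  sequences the decoded phase trails the true phase by up to ~0.5 rad, the
  dominant term in its RMSE.
* The neuron embedding is an ellipse whenever phase occupancy is uneven
  (the PCA axes scale with the occupancy second moments), warping α by up
  to ~0.2 rad on 600-s sessions; anchoring corrects orientation, not
  eccentricity.
* The trimodal histogram fit needs a few hundred swims to be stable; the
  pipeline falls back to the fixed threshold below 30 events or on
  non-convergence.
* Ring detectability itself (what fraction of animals would show the
  network) is not modeled; the generator always contains a ring.
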