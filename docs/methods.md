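# Methods

This note documents the models, numerical choices, and calibration behind
`xenphys`, and what the synthetic tests do and do not demonstrate about
real recordings.

## Imaging model and ΔF/F₀

A recording is a T×H×W stack at 2 frames/s for 30 min (3600 frames).
The baseline F₀ is the per-pixel temporal median over the *full* recording
(even frame counts: mean of the two central order statistics), and
ΔF/F₀% = 100 (F − F₀)/F₀. Pixels with F₀ ≤ 0 carry no signal and are
flagged invalid (NaN) rather than zeroed; every trace averages only valid
pixels, so invalid pixels cannot bias means silently. Coordinates are
(row, col), 0-based; masks are pixel-center membership. Because F₀ scales
with the movie, ΔF/F₀ is exactly invariant to a global intensity rescaling
(tested).

## Calcium-active ROI segmentation

Full correlation-based segmentation suites are substantial algorithms in
their own right; `segment_active_rois` is a deliberately simple method that
preserves the correlation-based character: the masked area is tiled into
4×4-pixel blocks, each tile's mean trace is computed, 4-connected adjacent
tiles with pairwise Pearson r ≥ 0.7 are merged with union-find, and
components of ≥ 4 tiles become ROIs. Zero-variance tiles never merge.
Labels are assigned in raster order of each component's first tile, so
segmentation is deterministic. All three parameters are exposed; the
defaults are this package's own choices.

## Event detection

Whole-brain traces are high-pass filtered at 0.005 Hz to remove slow
baseline drift. The filter is a 2nd-order Butterworth applied
forward-backward (`sosfiltfilt`): zero phase, so peak times are not
shifted; the effective magnitude response is 4th-order. Traces shorter
than ~3 warm-up lengths (3/cutoff seconds) are processed but tagged with a
warning.

The detection threshold is global and control-derived: all filtered
control traces are concatenated into one pool and the threshold is
`multiplier × SD(pool)` with multiplier 3 and the population (n)
denominator — fixed once, applied to every replicate and group, never
adapted per trace.

Peak logic, in order: (1) all local maxima (a plateau contributes its
first sample); (2) maxima whose width at half prominence is < 5 s are
dropped; (3) among survivors closer than 5 s the higher wins (ties →
earlier); (4) peaks whose filtered value exceeds the threshold are events.
The 5 s width constraint is what makes the 3σ cutoff safe against noise:
single-sample noise excursions have sub-second half-prominence widths, and
the measured false-positive rate on pure pool-matched Gaussian noise is
≪ 0.5 events per 30-min recording (Monte-Carlo tested).

**Amplitude readout.** Events are *detected* on the filtered trace but
*reported* as the raw ΔF/F₀% value at the peak sample
(`amplitude_source="raw"`, configurable). The reason is quantitative: a
zero-phase 0.005 Hz high-pass attenuates the peak of a 12 s-decay
transient by ~18% and of a two-minute transient by 40–50%, because it
subtracts the event's own slow content — filtered-trace amplitudes are
filter artifacts as much as physiology. Raw readout keeps amplitudes in
physical ΔF/F₀% units and makes the planted amplitude recoverable. The
cost is that slow drift at the peak instant leaks into single-event
amplitudes (zero-mean across events; ±0.5 ΔF/F₀% at the default drift).

## Spectral analysis

Per-ROI traces are linearly detrended and transformed with a rectangular-
window one-sided periodogram. The normalization is the standard density
one — power in (ΔF/F₀)²/Hz whose integral over (0, Nyquist] equals the
trace variance (Parseval; tested to 5% through the grid). Spectra are
resampled onto a fixed 0.01–1 Hz grid with 0.001 Hz spacing
(bit-identical array for every spectrum in a run). Resampling is
*integral-conserving*: each grid point carries the spectral energy of its
0.001 Hz cell divided by the cell width, so a narrowband line keeps its
area exactly (plain linear interpolation onto a grid coarser than the
native resolution, 1/1800 Hz for a 30-min trace, would inflate line
features by the spacing ratio). If a grid is requested finer than the
native resolution, linear interpolation is used instead, with
out-of-support points set to zero and a warning. ROI spectra are averaged
per animal; integrated low-frequency power is the trapezoidal area over
0.01–1 Hz; group spectra carry pointwise t-based 95% confidence envelopes.
PSD input is the raw (detrended) trace, not the 0.005 Hz-filtered one: the
grid starts at 0.01 Hz, so content below the cutoff is largely excluded
anyway, and filtering would distort the 0.01–0.02 Hz band edge. A Hann
window is available but not default.

## Synchrony

Each region's signal comes from a fixed-area circular ROI at the region's
geometric centroid (mean of member pixel coordinates): the ROI is exactly
the `area_px` (default 500) pixels nearest the centroid, ties broken in
row-major order — equivalent to growing the nominal radius √(area/π) and
trimming back by distance rank, and exact by construction. Circles are not
clipped to the region by default (a concave region's centroid can fall
outside it; `clip_to_region=True` restricts candidates to member pixels).
Correlations are Pearson coefficients between raw ΔF/F₀% centroid traces;
zero-variance traces yield NaN entries, never a silent 0. The 4×4 matrix
is summarized by the four named couplings: left–right midbrain, left–right
forebrain, and the two within-hemisphere midbrain–forebrain pairs.

## Locomotion

Input is a 50 fps centroid table in mm. Instantaneous velocity is
frame-to-frame displacement × fps, smoothed with a centered 5-frame moving
average (edges truncated) to suppress single-frame centroid jitter.
Darting is the percentage of frames whose smoothed velocity exceeds a
fixed threshold, 20 mm/s by default; the commercial tracker this
re-operationalizes does not publish its detector internals, so the
threshold is an explicit config value shared across every cohort in a
comparison. Velocity metrics are exactly invariant to rigid transforms of
the track (tested), and darting is non-increasing in the threshold.

## Cohort statistics

Group summaries are mean, SD (n−1) and SEM. The published comparisons name
hybrid procedures ("unpaired t-test with Mann–Whitney"), resolved here as
an explicit policy: Shapiro–Wilk at α = 0.05 gates each metric (n < 3 →
nonparametric); normal data get Welch's unequal-variance t, otherwise
Mann–Whitney U (unpaired) or Wilcoxon signed-rank (paired, zero
differences dropped). Both tests are always computed and stored alongside
the gate's choice. Exact small-sample p-values: Mann–Whitney for
min(n₁,n₂) ≤ 8 without ties, Wilcoxon for ≤ 12 nonzero pairs without tied
|d|; otherwise tie-corrected normal approximations. All tests are
two-sided; no multiple-testing correction is applied (none is used in the
comparisons this mirrors). Exactness is verified against full enumeration
oracles, and empirical type-I error is checked at 0.05 ± 0.01 over 10⁴
null simulations per test.

## Synthetic cohorts: what is measured and what is calibrated

Each simulated animal's whole-brain trace is

    x(t) = Σᵢ aᵢ k(t − tᵢ) + drift + noise,

with event times a Poisson draw thinned to a 10 s minimum separation
(the generator refuses rates where thinning would distort the realized
rate), amplitudes truncated-at-zero normal, and
k(t) = (e^(−t/τ_decay) − e^(−t/τ_rise)) normalized to unit peak. Drift is
a 0.5 ΔF/F₀% sinusoid with a 600 s period — below the 0.005 Hz cutoff, so
the high-pass removes it and the 0.01–1 Hz band barely sees it. Noise is
white Gaussian.

Preset parameters fall in two classes:

* **Measured (published cohort means):** event rates per 30 min (control
  1.67, CRISPant 3.46, treated 2.30), event amplitudes (3.94, 8.20, 7.32
  ΔF/F₀%), homotopic synchrony targets (midbrain 0.96/0.79, forebrain
  0.88/0.72), cohort sizes (12/13/10), post-treatment swim velocity
  (0.11 mm/s).
* **Calibrated (chosen once, by population Monte-Carlo at ≥10³ simulated
  animals, so the full pipeline reproduces the published statistics):**
  amplitude SD = 25% of the mean (keeps cohort means identifiable);
  kernel kinetics — control rise 2 s / decay 12 s; CRISPant rise 4 s /
  decay 120 s, which realizes the reported multi-minute event persistence
  and places the right share of spectral energy above 0.01 Hz (population
  integrated power 0.62 vs published 0.58); treated rise 1 s / decay
  3.1 s, encoding the reported suppression of slow fluctuations
  (population 0.229 vs published 0.230); and noise SD 0.155 ΔF/F₀%,
  which closes the control power budget (events contribute ≈ 0.086,
  noise ≈ 0.024, total ≈ 0.11 as published). These kinetics are
  calibration constants, not biophysical estimates.

Synchrony is realized two ways. The trace-space mixing path,
left = √ρ·z + √(1−ρ)·n_L (z the standardized shared trace, n white unit
noise), has expected Pearson r exactly ρ and is used wherever exactness
matters. The movie path plants events bilaterally with probability
`p_shared` over a static F₀ pattern with pixel noise — more realistic,
only approximately at target synchrony. Movies default to 96×96 px with
four elliptical regions, keeping a 30-min float32 movie under 150 MB.

Trajectories are random-heading walks (heading SD 0.2 rad/frame) at a
constant cruising speed with Poisson-scheduled darts (40 mm/s, 0.3 s),
reflected at a 7.8 mm arena wall (24-well plate well). The treated preset
cruises at 0.11 mm/s with darting suppressed; per-frame displacement then
equals the cruise speed exactly, so mean velocity recovery is sharp.

**What passing tests show — and don't.** Parameter recovery on these
cohorts demonstrates that the pipeline is calibrated and unbiased *under
the generator's assumptions*: stationary Poisson events, stereotyped
kinetics, additive Gaussian noise, sinusoidal drift. Real recordings add
photobleaching, motion, hemodynamic contamination, inter-animal rate
heterogeneity, and non-stereotyped events — none of which the generator
emulates (deliberately; see Non-goals in the module docstrings). Recovery
here is necessary, not sufficient, evidence for accuracy on real data.

## Reproducibility and problem sizes

Every random quantity derives from `numpy.random.default_rng` seeded via
`SeedSequence`; one master seed expands to per-animal seeds through fixed
per-cohort offsets, so whole cohorts are bit-reproducible.
`scripts/acceptance.py` runs the trace-space cohorts (35 animals of 3600
samples plus 50 mixing pairs and 11 one-hour 50 fps trajectories) in well
under a minute. The test suite exercises movies at reduced sizes (48×48,
2–4 min) and the Monte-Carlo suites at 10³–10⁴ replicates — sizes chosen
to make the statistical assertions sharp while keeping the default run
fast. With the presets fixed, the 10-animal treated cohort's mean
integrated power has an SD of ≈ 0.05 (event-count scatter dominates), so
a fixed-seed draw occasionally lands ~2 SD from the published mean; that
is sampling variation, not miscalibration.

## Known limitations

* The CalciSeg-style segmenter is a simplified substitute: tile-based,
  no refinement, no sub-tile boundaries.
* Event amplitudes of overlapping CRISPant events stack; with 120 s decay
  ~20% of events ride on a predecessor's tail, biasing detected
  amplitudes slightly upward (visible as cohort means ~0.5–1 ΔF/F₀% above
  the planted mean).
* The darting threshold and smoothing are documented stand-ins for a
  commercial tracker's unpublished detectors; cohort equivalence is by
  calibration, not reimplementation.
* No motion correction, photobleaching correction, or optics/PSF
  modelling anywhere in the pipeline.
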