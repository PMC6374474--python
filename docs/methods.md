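# Methods

This note documents the models, defaults and numerical choices behind
`calwave`, and what the synthetic studies do and do not establish about
real recordings.

## Signal model

A recording is a calibrated stack I(t, y, x) (counts; frame interval in
seconds, pixel size in µm).  All amplitude statistics are fold changes
(I − I₀)/I₀ against a resting baseline I₀, which makes them invariant
under detector gain and laser-power rescaling.  Three signal classes are
modelled:

**Oscillations.**  Tissue-wide multiplicative pulses
I = I₀ · (1 + a·g(t)), with g a unit Gaussian kernel parameterized by its
FWHM (= 2√(2 ln 2) σ) and a the amplitude fold change.  Inter-pulse gaps
are truncated-normal with lower bound one FWHM, so consecutive pulses
remain distinct events.  Defaults: mean gap 1320 s, SD 515 s, FWHM 291 s,
a = 0.5, baseline 1000 counts, dt = 5 s — the regime reported for
spontaneous SAM oscillations.

**Spikes.**  Per-cell rectangular transients of amplitude fold change 1.0
(no published value exists for spike amplitude; 1.0 sits between the
oscillation and wave amplitudes and gives a comfortable detection margin —
changing it only rescales the detection threshold).  Durations come from a
three-component uniform mixture, default weights 0.70 / 0.17 / 0.13 on
(1, 5] / (5, 10] / (10, 20] s; onsets are uniform (homogeneous point
process), with per-cell overlaps resolved by rejection so every event has
an unambiguous rendered support.  The default rate, 1/3000 per cell per
second, corresponds to one spike per 100 cells per 30 s.  Frames integrate
the signal over their exposure interval, so edge frames carry fractional
amplitude — this is what makes interpolated event durations unbiased at
bin boundaries.

**Waves.**  A front expands radially from the stimulus pixel at v_fast
(default 2 µm/s) until the temporal midpoint of the propagation, then at
v_slow (default 0.5 µm/s); a cell activates when the front reaches its
centroid, rises over 1.5 s to fold change 2.3, and plateaus.  During the
crescent window (default onset 23 s after the stimulus, duration 16 s)
activated cells strictly between an inner radius (one cell diameter) and
the current front fall to baseline, reproducing the transient dark annulus
seen behind real wave fronts.  All cells switch off (1 s ramp) at the
programmed decay time (default 73 s after the stimulus); cells within the
inner radius switch off 12 s later, as the cells hugging the stimulation
site are the last to dim.  The switch-off is a sharp ramp pinned at the
decay time rather than a fitted exponential tail: it realizes the same
observable (global fold change below 10% of peak at the decay time)
without an implicit calibration loop, at the cost of a steeper tail than
real indicator kinetics.

**Tissue and noise.**  Cells are a Voronoi tessellation of jittered grid
seeds clipped to a centred disk (target cell diameter 4 µm — one cell
diameter per 2 s at the fast wave speed); background outside the disk sits
at 10% of the tissue baseline.  Noise is independent additive Gaussian per
pixel, clipped at zero; the default studies use 5% of baseline
(oscillations, waves) and 10% of spike amplitude.  Poisson shot noise and
detector gain calibration are deliberately out of scope: per-cell traces
average tens to hundreds of pixels, so only the noise scale, not its
distribution, reaches the detectors.

## Analysis choices

- **Smoothing** uses scipy's natural cubic smoothing spline; the penalty
  is user-set, with generalized cross-validation as the default.  Penalty
  0 interpolates; the penalty → ∞ limit is the least-squares line (reached
  numerically near λ ≈ 1e9 on typical traces; far larger penalties
  degrade the banded solve).
- **Baseline** is a centred rolling lower percentile (default 10th,
  window 1455 s = 5 expected FWHM) followed by mild box smoothing; a
  constant global-percentile mode serves short traces and spike movies.
  Wave analyses instead use the pre-stimulus mean, because cells near the
  origin can be active for most of the recording, which starves a
  percentile baseline.
- **Peak detection** thresholds prominence at 0.2 of the dynamic range
  (max minus median baseline), making counts invariant under positive
  affine intensity maps.  The minimum peak separation defaults to an
  adaptive one-median-FWHM floor (two detection passes): the generative
  gap distribution is truncated at one FWHM, so a larger floor censors the
  shortest genuine gaps and inflates the inter-peak mean.  Peak pairs
  closer than ~2.7 σ remain unresolvable by any threshold; at the default
  conditions these are ~3% of gaps and bias the pooled inter-peak mean by
  well under one standard error (and the pooled FWHM upward by a few
  percent, since a merged pair reads as one broad peak).
- **FWHM** is measured against the local baseline (half level =
  baseline + height/2) with linearly interpolated crossings; events whose
  half level is never crossed on one side are flagged truncated and
  excluded from summaries.  Inter-peak intervals are never computed across
  recording boundaries.
- **Spike events** are maximal threshold runs (default fold change 0.5,
  minimum duration 1 s) with runs separated by ≤ max_gap_s (default 2 s)
  merged; events clipped by the recording edges are censored and excluded
  from duration fractions.  Repeatedly spiking cells stay resolvable by
  setting the merge gap to zero.
- **Wave front** tracking uses the running maximum of a percentile of
  origin-distances among activated cells, with percentile 100 (the
  farthest activated cell) as default: for a radial wave the cumulative
  95th percentile underestimates the front radius by ≈ √0.95 early on and
  saturates once the front nears the tissue boundary, biasing the late
  velocity; the maximum is exact in the noise-free case.  Lower
  percentiles remain available as a robustness option against spurious
  early activations.  Velocities are least-squares slopes on the two
  temporal halves of the activation interval, after discarding the first
  5% as burn-in; the curve ends at the last activation so a flat
  post-propagation tail never dilutes the late slope.
- **Crescent detection** scans frames within the propagation interval
  (stimulus to last activation) and, among activated cells between the
  inner exclusion radius and the current front, takes the longest
  contiguous run where more than half lie below fold change 0.2.  The
  search is restricted to the propagation interval because after global
  decay the whole tissue is dark and the annulus criterion degenerates.
- **Decay time** is the first post-peak time the global fold change drops
  to 10% of its maximum (linearly interpolated), relative to the stimulus;
  traces that never decay are reported censored.
- **Comparisons** default to the KS test plus a permutation test on the
  mean difference: exact enumeration when the number of assignments is at
  most 10⁵ (p = count/total; the identity split guarantees p ≥ 1/total),
  otherwise seeded Monte-Carlo with the add-one correction
  p = (1 + #extreme)/(1 + N).

## Study sizes

The validation studies are sized to the reported experiments while staying
desk-scale: 19 recordings × 11000 s (dt 5 s, 64×64 px — oscillations are
global, so spatial extent is irrelevant) giving ~123 pooled inter-peak
intervals; a 512×512, 0.5 µm/px wave with 800 cells for velocity recovery;
a 160×160 SAM-scale wave (300 cells) in which propagation completes before
the 73 s decay, for crescent/decay/amplitude timing; and 292 spikes on 100
cells for the duration mixture.

## What the synthetic studies do and do not show

Passing tests demonstrate that the estimators recover the programmed
statistics from rendered movies under additive noise — i.e. the analysis
chain is unbiased and correctly calibrated at the stated conditions.  The
generator does not emulate photobleaching, z-drift, cell growth, indicator
on/off kinetics, saturating sensors, segmentation error, or spatially
correlated noise; real-data baselines and thresholds therefore still need
visual sanity checks.  Cell segmentation itself is an input (a label
image), not something the package computes.

## Degenerate inputs and tie-breaks

Empty masks, non-positive baselines, non-uniform grids, stimuli outside
the tissue or after the movie end, and fewer than three activated cells
all raise errors rather than returning silent defaults.  A movie too short
for one oscillation pulse yields a valid constant movie with an empty
truth table and a warning.  Ties in peak plateaus follow scipy's
`find_peaks` convention; events at recording edges are censored rather
than guessed.
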