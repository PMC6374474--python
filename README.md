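# calwave

Quantification of cytoplasmic Ca²⁺ dynamics in time-lapse fluorescence
movies of the *Arabidopsis* shoot apical meristem (SAM), aimed at plant
cell biologists working with genetically encoded calcium sensors such as
R-GECO1 or GCaMP6f.

SAM recordings show three distinct kinds of calcium signal, and `calwave`
measures all three from calibrated multi-page TIFF stacks:

- **Global oscillations** — tissue-wide intensity pulses recurring every
  ~10–30 min.  The pipeline detects peaks on a spline-smoothed
  region-of-interest trace and reports inter-peak times, peak height above
  a rolling-percentile baseline, and event duration as full width at half
  maximum (FWHM), each summarized as mean ± relative standard error.
- **Single-cell spikes** — sporadic transients lasting seconds.  Per-cell
  fold-change traces (I − I₀)/I₀ are thresholded into events with
  interpolated onsets/offsets, classified into duration bins
  (1–5 s, 5–10 s, >10 s) and normalized into a rate per 100 cells.
- **Mechanically induced waves** — a radial front of elevated Ca²⁺
  spreading from a stimulus.  From per-cell activation times the pipeline
  builds a front-distance curve, fits a two-phase velocity (fast early
  phase, slow late phase, split at the temporal midpoint of propagation),
  and times the transient "dark crescent" of low Ca²⁺ behind the front and
  the global decay of the response.

Because raw SAM movies are rarely shareable, the package includes a
first-class synthetic-movie generator (`calwave.synthetic`): a Voronoi cell
mosaic on a disk, rendered oscillation/spike/wave signals with shot-like
additive noise, and a ground-truth event table for every rendered
transient.  Its defaults encode the observed statistics (22 min inter-peak,
291 s FWHM, amplitude 0.5; 70%/17%/13% spike duration mixture; 2 → 0.5 µm/s
wave with fold change 2.3, crescent at 23 s for 16 s, decay by 73 s), so
detector output can be validated against known truth at realistic
conditions.

## Core statistics

For a trace I(t) with baseline I₀(t):

- fold change: (I − I₀)/I₀ (dimensionless; scale invariant)
- FWHM: width of a peak at I₀ + height/2, crossings linearly interpolated;
  for a Gaussian pulse of width σ, FWHM = 2√(2 ln 2) σ
- inter-peak time: difference of consecutive peak times within one
  recording, pooled across recordings
- wave velocity: least-squares slope of the front-distance curve d(t) on
  each temporal half of the propagation
- condition contrasts: two-sided two-sample Kolmogorov–Smirnov test plus a
  permutation test on the mean difference (exact enumeration when
  feasible), reporting each p and the smallest.

## Worked example

Simulate a mechanically stimulated wave on a SAM-scale tissue
(160×160 px at 0.5 µm/px, 300 cells, dt = 1 s), add noise, and quantify it:

```python
import numpy as np
import calwave as cw
from calwave.pipeline import analyze_wave

tissue = cw.make_tissue(cw.TissueSpec(
    image_size_px=(160, 160), pixel_size_um=0.5, n_cells=300, seed=1))
row = 80
col = int(np.argmax(tissue.labels[row] > 0)) + 2   # left rim of the disk
params = cw.WaveParams(origin_px=(row, col))
movie, truth = cw.simulate_wave(tissue, params, duration_s=100.0,
                                frame_interval_s=1.0)
movie = cw.add_noise(movie, 50.0, seed=3)          # 5% of baseline

kinematics, activation, _ = analyze_wave(movie, tissue)
print(f"front speed, early phase : {kinematics.v_first_half_um_s:.2f} um/s")
print(f"front speed, late phase  : {kinematics.v_second_half_um_s:.2f} um/s")
print(f"max fold change (I-I0)/I0: {kinematics.max_fold_change:.2f}")
print(f"dark crescent            : onset {kinematics.crescent_onset_s:.0f} s, "
      f"duration {kinematics.crescent_duration_s:.0f} s")
print(f"global decay time        : {kinematics.decay_time_s:.1f} s")
```

prints

```
front speed, early phase : 2.00 um/s
front speed, late phase  : 0.50 um/s
max fold change (I-I0)/I0: 2.30
dark crescent            : onset 23 s, duration 17 s
global decay time        : 73.9 s
```

i.e. the analysis recovers the programmed two-phase front (2 then
0.5 µm/s), the wave amplitude (fold change 2.3), the dark-crescent window
(23 s onset, programmed duration 16 s recovered to within one frame) and
the decay time (73 s) from the noisy rendered movie.

## Command line

```sh
calwave simulate  --kind wave --config config.toml --seed 1 --out sim/
calwave wave      --input sim/wave_movie.tif --labels sim/labels.tif \
                  --origin 80,10 --stim-time 5 --config config.toml --out out/
calwave oscillations --input movie.tif --labels labels.tif --config config.toml --out out/
calwave spikes    --input movie.tif --labels labels.tif --config config.toml --out out/
calwave compare   --a a.csv --b b.csv --metric interpeak_s --n-perm 9999 --seed 1
calwave run-all   --config config.toml --seed 1 --out out/
```

The TOML config carries the instrument calibration (`pixel_size_um`,
`frame_interval_s` — required, never defaulted), generator parameters and
analysis thresholds; `run-all` executes simulate → extract → analyze →
compare and writes a machine-readable run report with artifact checksums.
Outputs are byte-reproducible for a fixed config and seed.

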