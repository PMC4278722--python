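# mitostorm

Correlative live-cell + STORM analysis of mitochondrial dynamics, as a
tested, reusable Python pipeline.

Mitochondria move, touch, and remodel on timescales of seconds, while
their outer-membrane protein organization lives at scales far below the
diffraction limit. Correlative imaging tackles both at once: a cell is
imaged live at high frame rate (10–20 frames/s), then fixed and imaged
by STORM (stochastic optical reconstruction microscopy), and each
organelle is characterized jointly — how it moved, how large it is, and
how densely the outer-membrane translocase Tom20 is labeled. This
package implements the complete computational side of that workflow for
researchers in super-resolution microscopy and organelle biology:

- **Localization** — threshold-based spot detection and symmetric 2D
  Gaussian fitting of blinking single molecules in raw movie stacks.
- **Post-processing** — drift correction by cross-correlating
  super-resolution images of 500–1000-frame movie subsets against the
  first subset; fiducial-bead registration of sequentially acquired
  color channels; histogram/Gaussian rendering of final images.
- **Per-organelle quantification** — outline area (px² → µm² at
  0.157 µm/px), Tom20 localization density ρ = N/A, median-normalized
  density, and image resolution
  `R = sqrt(R₁² + R₂²)`, where `R₁ = 2/√ρ` is the Nyquist label-density
  limit and `R₂` is the localization precision measured from repeated
  fiducial localizations.
- **Dynamics** — centroid tracking, maximum displacement from the start
  over a 500-frame window, mean/peak speeds, processive-run detection,
  and classification into stationary / dynamic-slow / dynamic-fast and
  interacting / isolated.
- **Statistics** — two-tailed unpooled (Welch) t-tests at α = 0.001,
  2×3 category tables with percent-of-total cells, per-category
  summaries.
- **Synthetic data** — a ground-truthed generator for STORM movies
  (membrane-band labels on tube-like organelle geometries, Bernoulli
  blinking, Poisson noise, stage drift, fiducials) and live-cell tracks
  in the three motion regimes (confined ~192 nm, confined ~414 nm,
  processive ~700 nm/s), so every stage is testable without microscope
  data.

## Worked example

Simulate a small two-organelle STORM acquisition, localize it, estimate
the precision from the beads, and quantify each mitochondrion:

```python
import numpy as np
import mitostorm as ms

cfg = ms.SimulationConfig(rng_seed=1, n_frames=400, field_size_px=(48, 48),
                          n_organelles=2, n_fiducials=2)
outlines = ms.simulate_mitochondria(cfg)
rng = np.random.default_rng(1)
emitters = np.vstack([ms.scatter_labels(o, cfg.label_density_per_um2,
                                        cfg.pixel_size_um, rng) for o in outlines])
beads = ms.plant_fiducials(cfg, avoid=outlines)[0]
stack, truth = ms.simulate_storm_movie(cfg, emitters, fiducials_px=beads)
molecules = ms.localize_movie(stack, ms.DetectionParams())
print(f"{len(molecules)} localizations in {stack.n_frames} frames")

from mitostorm.localization import identify_beads, estimate_localization_precision
centres, bead_locs, _ = identify_beads(molecules, cfg.n_frames)
r2 = estimate_localization_precision(bead_locs, cfg.pixel_size_um)
print(f"localization precision R2 = {r2:.1f} nm from {len(centres)} beads")

records = ms.quantify_organelles(molecules, outlines, cfg.pixel_size_um, r2)
print(records.round(3).to_string(index=False))
```

This prints:

```
1230 localizations in 400 frames
localization precision R2 = 0.9 nm from 2 beads
 id  area_um2  n_locs  density  norm_density   R1_nm  R2_nm    R_nm
  0     1.279     133  104.024           1.3 196.094  0.913 196.096
  1     1.823     102   55.960           0.7 267.357  0.913 267.359
```

At 400 frames each label has blinked only ~0.2 times on average, so the
localization density (~100/µm²) and hence the Nyquist term R₁ dominate
the resolution. Real acquisitions integrate tens of thousands of
frames, pushing densities into the thousands per µm² and R into the
tens of nanometres; the normalized density column is what comparative
analyses use, since absolute densities are inflated by repeated
blinking and multiple antibodies per target.

Motion classification works the same way from tracks:

```python
cfg = ms.SimulationConfig(rng_seed=4, n_frames=500)
tracks, labels = ms.simulate_tracks(cfg, 300)
pred = ms.MotionClassifier().fit().predict(tracks)
cm, recall = ms.recover_classes(labels, pred)
```

A command-line interface mirrors the library
(`mitostorm simulate|localize|driftcorrect|register|render|quantify|classify|report|run`);
`mitostorm run --seed 1 --out-dir run1` executes the whole synthetic
preset end to end and writes a manifest with per-file checksums.

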