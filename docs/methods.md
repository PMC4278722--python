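# Methods

This note documents the models implemented by `mitostorm`, the defaults
and why they were chosen, what the synthetic data does and does not
emulate, and the numerical conventions that matter when comparing
results.

## Coordinate and unit conventions

Camera coordinates are 0-based pixels with a pixel-centre convention;
the camera pixel size defaults to 0.157 µm/px in each direction and is
the single conversion factor between pixels and physical length.
Molecule lists are tables with columns
`frame, x_px, y_px, photons, sigma_px, background, channel`; tracks
carry positions in nm with timestamps in seconds. All tabular artifacts
are CSV, movies are multi-page grayscale TIFF, and every file write is
atomic (temp file + rename).

## Synthetic data generator

The generator produces the statistical structure the analysis assumes,
not optical realism.

**Geometry.** Mitochondria are capsules (line segments buffered to a
rounded tube) with width 0.2–1 µm and length 0.5–5 µm, placed by
rejection sampling so shapes stay inside the field and overlap by less
than 5 % of the smaller area.

**Labels.** Tom20 is an outer-membrane protein, so emitters are
scattered uniformly in a 40-nm-wide band straddling the polygon
boundary (membrane plus antibody linkage error) rather than in the
interior; this reproduces the hollow outline appearance of
super-resolved mitochondria. The count is Poisson with mean
`density × band area`. Because the band straddles the outline, roughly
half of the scattered labels fall inside the polygon proper — relevant
when comparing a measured in-polygon density against the scattering
density.

**STORM movies.** Each frame activates an independent Bernoulli subset
of emitters (duty cycle 5×10⁻⁴ by default; no dark-state memory —
photokinetic realism is a non-goal). Active emitters and fiducial beads
(10× a single event's brightness, present in every frame) are rendered
as integrable 2D Gaussians (σ = 1 px ≈ 157 nm) on a uniform background,
positions offset by the cumulative stage drift, and the expected image
is Poisson-sampled to 16-bit counts. Expected photons per event default
to 5000, background to 10 counts/px — a bright organic-dye regime.
Fiducials can be planted clear of organelle outlines (≥ 8 px); bright
beads otherwise bias single-molecule fits within the fit window, which
is also why experimentalists use beads on clean coverslip regions.
Omitted on purpose: aberrations, z-dependence, EM-gain noise, 3D PSFs,
photobleaching.

**Live-cell tracks.** Confined motion is an AR(1)
(Ornstein–Uhlenbeck-style) walk anchored at the start. Per track, the
realized maximum displacement from the start over the 500-frame
classification window is rescaled to a target drawn about the class
mean — 192 nm for stationary (docked), 414 nm for dynamic-slow — with
15 % lognormal track-level variation. The larger spreads reported for
real organelles include biological heterogeneity (organelle size,
anchoring state) that this generator deliberately does not model; the
classification-recovery tests therefore measure the procedure, not the
irreducible overlap of real populations. The confinement relaxation
time defaults to 5 s for the stationary class and scales with the
square of the class amplitude, which keeps frame-to-frame path speeds
comparable across the confined classes (~300–400 nm/s), matching the
observation that docked and slow organelles have similar average speeds
and differ only in range. Dynamic-fast tracks add one constant-velocity
processive run at 700 nm/s whose net displacement is drawn about
1570 nm (floored at 1.1 µm). Live-cell movies render organelles as
single filled Gaussian blobs per centroid — a matrix-dye assumption;
membrane-band structure is not resolvable at this resolution anyway.

**Determinism.** One master seed; per-component streams (geometry,
labels, movie, fiducials, tracks) are derived via named
`SeedSequence` spawn keys, so identical configs give bit-identical
output.

## Localization

Detection finds local maxima whose amplitude above the locally
estimated background (median of the fit-window border) exceeds a
threshold (default 80 counts); candidates closer than 3 px merge to the
brighter one. No threshold value is prescribed by the workflow this
reimplements, so the default is a calibration choice: simulated single
events at the default photon budget are detected at ≥ 95 % recall while
background maxima stay far below it.

Each candidate's 7×7 window is fit with a symmetric 2D Gaussian plus
constant background by bounded nonlinear least squares (analytic
Jacobian, centroid/border-median initialization, ≤ 100 iterations,
1e-8 parameter tolerance); photons = 2πσ²·amplitude. Flat windows are
flagged non-converged and skipped. Overlapping emitters are **not**
deconvolved: co-active emitters within ~5 px produce merged or biased
fits, and recall statements therefore apply to isolated events.

Localization precision (the R₂ of the resolution formula) is the pooled
scatter of repeated fiducial localizations: per bead, per-axis standard
deviations combined as √((σx²+σy²)/2), variances averaged across beads,
converted to nm. A config override accepts a user-supplied constant
when no usable bead exists.

## Drift correction, registration, rendering

Drift is estimated by splitting the movie into 500-frame subsets (the
standard 500–1000 range is accepted; a short tail merges into the
previous subset), rendering each subset's localizations as a 2D
histogram, and cross-correlating against the first subset. Two
numerical choices matter and are deliberate deviations from the
simplest convention:

- subset images are rendered at **4×** the camera pixel and smoothed
  with a 2-bin Gaussian before correlating — raw sparse histograms show
  correlation-peak pixel-locking that leaves ~30 nm subset errors;
- per-frame corrections are linearly interpolated between subset
  midpoints and **linearly extrapolated** beyond the first and last
  midpoints — steady stage drift does not stop at the subset midpoints,
  and constant extrapolation leaves an uncorrected ramp at the movie
  ends.

The correlation peak is refined by per-axis 3-point quadratic
interpolation. Subsets with fewer than 50 localizations are skipped
with a warning. The estimated trace is defined relative to the
reference subset's mean position — comparisons against a known drift
remove the constant offset (`drift_residual_rms_nm`). With these
defaults, an injected 0.5 nm/frame linear drift over 5000 frames is
recovered to ~6 nm RMS and a zero-drift null stays below 0.05 render
px.

Channel registration matches beads across channels by mutual nearest
neighbour within 500 nm and reports the mean per-bead offset with its
residual RMS (outliers stay visible); only a translation is estimated.
Rendering is a 2D histogram at the render pixel (default 15.7 nm);
histogram mode conserves mass exactly, Gaussian-splat mode smooths
while preserving the total.

## Per-organelle quantification

Area is the shoelace polygon area in px² times the pixel area. Counting
is boundary-inclusive (`covers`): half-open conventions make points
exactly on vertices seed-dependent. Density is count/area; the
normalized density divides by the dataset median (midpoint convention
for even n), so the median normalized density is 1 by construction.
Resolution combines the Nyquist label-density limit `R₁ = 2/√ρ` (the
mean localization spacing must be at most half the resolved scale; the
factor is configurable) with the fiducial-based precision R₂ in
quadrature. Absolute densities overestimate protein density — each
fluorophore blinks repeatedly and each target may carry several
antibodies — so comparative analyses use normalized densities, where
the inflation cancels under the assumption that it is uniform across
categories.

## Motion and interaction classification

Per track, over the first 500 frames: maximum displacement from the
starting position, mean speed (path length / duration), peak 1-s-window
speed, net displacement, and a processive-run flag (some ≥ 1 s window
sustains ≥ 500 nm/s with directional persistence — mean cosine between
successive ~0.25 s coarse steps ≥ 0.5; coarse steps suppress
frame-to-frame jitter that would mask real runs). Classification:
dynamic-fast if a run was detected and net displacement ≥ 1 µm;
otherwise stationary below 290 nm maximum displacement, dynamic-slow
above. The 290-nm boundary is the crossing point of Gaussian envelopes
fitted to the two reported displacement populations (192±91 and
414±261 nm); no explicit threshold was published, and all thresholds
are exposed in the config. Interaction is geometric: an organelle is
interacting if its super-resolved boundary comes within 100 nm
(inclusive) of another's, isolated otherwise. Tracking of live movies
is nearest-neighbour linking with a 2 µm/frame gate — organelles are
sparse and slow relative to the frame rate — with sub-10-frame tracks
dropped.

## Statistics

Group comparisons are two-tailed unpooled (Welch) t-tests with
Satterthwaite degrees of freedom at α = 0.001, with no multiplicity
correction by default (an optional Holm correction is provided for
users who want it). Category tables report cell percentages of the
grand total rounded half-up to one decimal, matching printed-table
style; raw percentages sum to 100 exactly.

## Problem sizes in tests and the acceptance script

The test-suite and acceptance simulations are sized for a desk-scale
run: 400–1000-frame movies on 40–64 px fields with 2–3 organelles for
localization and pipeline checks, 5000-frame molecule lists for drift,
300 tracks of 500 frames for classification, 10⁵ replicates for the
type-I-error calibration. These sizes keep every statistical check
well-powered while the full suite completes in well under a minute of
simulation time; the physical parameter defaults (pixel size, frame
interval, photon budget, densities, motion-class parameters) are the
acquisition regime described above, not scaled.

## Known limitations

- Single-emitter fitting only: overlapping activations are merged or
  biased, so measured densities saturate at very high duty cycles.
- Translation-only channel registration; no affine or chromatic
  warping.
- The track generator's within-class spread (15 % CV) is narrower than
  real between-organelle variability; recovery rates on synthetic data
  are upper bounds for real data.
- Automatic outlining of real STORM images is out of scope; outlines
  come from ground truth (synthetic) or manual polygon files.
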