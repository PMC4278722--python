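"""Ground-truthed synthetic STORM and live-cell data.

The forward model emulates the data the analysis pipeline consumes:

* tube-like mitochondrial geometries (closed polygons in camera px);
* outer-membrane labels scattered in a narrow band around each outline
  (Tom20 is an outer-membrane protein, so localizations trace a hollow
  outline rather than a filled body);
* STORM movies of sparsely blinking emitters rendered as 2D Gaussians
  with Poisson photon noise, Poisson camera background, stage drift and
  bright persistent fiducial beads;
* live-cell centroid tracks in three motion regimes — docked
  (confined ~192 nm), mobile-but-confined (~414 nm) and processive
  (~700 nm/s runs with ~1570 nm net transport).

Everything is driven by one master seed; per-component streams are
derived deterministically so identical configs give bit-identical
output.
"""

from __future__ import annotations

import math
import zlib

import numpy as np
import shapely
from scipy.signal import lfilter
from shapely.geometry import LineString, Polygon

from .config import SimulationConfig
from .datatypes import FrameStack, GroundTruth, OrganelleOutline, Track

#: Motion-class labels, in (stationary, dynamic-slow, dynamic-fast) order.
MOTION_CLASSES = ("stationary", "dynamic-slow", "dynamic-fast")

#: Brightness of fiducial beads relative to a single blinking event.
FIDUCIAL_BRIGHTNESS = 10.0


def rng_stream(master_seed: int, name: str) -> np.random.Generator:
    """Derive a named, reproducible random stream from the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(master_seed), spawn_key=(zlib.crc32(name.encode()),))
    )


# ----------------------------------------------------------------------
# Organelle geometry
# ----------------------------------------------------------------------

def _capsule(center_px, length_px, width_px, angle_rad, n_arc: int = 16) -> Polygon:
    """A tube: a line segment buffered to half the width (rounded caps)."""
    half = length_px / 2.0
    dx, dy = math.cos(angle_rad) * half, math.sin(angle_rad) * half
    seg = LineString(
        [(center_px[0] - dx, center_px[1] - dy), (center_px[0] + dx, center_px[1] + dy)]
    )
    return seg.buffer(width_px / 2.0, quad_segs=n_arc)


def simulate_mitochondria(
    config: SimulationConfig,
    n_organelles: int | None = None,
    rng: np.random.Generator | None = None,
    max_overlap_frac: float = 0.05,
    max_attempts: int = 500,
) -> list[OrganelleOutline]:
    """Place tube-like organelle outlines in the field without overlap.

    Shapes are capsules with width 0.2–1 µm and length 0.5–5 µm (ranges
    set in the config), placed by rejection sampling so that pairwise
    overlap stays below ``max_overlap_frac`` of the smaller shape.

    Raises
    ------
    RuntimeError
        If the requested count cannot be placed within ``max_attempts``
        tries per organelle.
    ValueError
        If the field is too small to contain even the smallest shape.
    """
    if n_organelles is None:
        n_organelles = config.n_organelles
    if rng is None:
        rng = rng_stream(config.rng_seed, "geometry")
    w_px, h_px = config.field_size_px
    px = config.pixel_size_um
    min_len_px = config.organelle_length_um[0] / px
    if min(w_px, h_px) < min_len_px + config.organelle_width_um[0] / px:
        raise ValueError(
            f"field {config.field_size_px} px too small for organelles of "
            f">= {config.organelle_length_um[0]} um at {px} um/px"
        )

    placed: list[Polygon] = []
    outlines: list[OrganelleOutline] = []
    for oid in range(n_organelles):
        ok = False
        for _ in range(max_attempts):
            length = rng.uniform(*config.organelle_length_um) / px
            width = rng.uniform(*config.organelle_width_um) / px
            angle = rng.uniform(0, math.pi)
            # Keep the whole shape inside the field.
            margin = (length + width) / 2.0 + 1.0
            if 2 * margin >= min(w_px, h_px):
                continue
            cx = rng.uniform(margin, w_px - margin)
            cy = rng.uniform(margin, h_px - margin)
            poly = _capsule((cx, cy), length, width, angle)
            if any(
                poly.intersection(p).area > max_overlap_frac * min(poly.area, p.area)
                for p in placed
            ):
                continue
            placed.append(poly)
            verts = np.asarray(poly.exterior.coords)[:-1]  # drop closing duplicate
            outlines.append(OrganelleOutline(organelle_id=oid, vertices_px=verts))
            ok = True
            break
        if not ok:
            raise RuntimeError(
                f"could not place organelle {oid + 1}/{n_organelles} in a "
                f"{w_px}x{h_px} px field without overlap; reduce count or size"
            )
    return outlines


def scatter_labels(
    outline: OrganelleOutline | np.ndarray,
    density_per_um2: float,
    pixel_size_um: float,
    rng: np.random.Generator,
    band_nm: float = 40.0,
) -> np.ndarray:
    """Scatter emitter positions in a membrane band around an outline.

    The label count is Poisson with mean ``density × band area``; the
    band is a strip of total width ``band_nm`` straddling the polygon
    boundary (membrane plus antibody linkage error), and positions are
    uniform within it.  Returns an (n, 2) array of camera-px positions.
    """
    if density_per_um2 <= 0:
        if density_per_um2 == 0:
            return np.empty((0, 2))
        raise ValueError("density must be >= 0")
    verts = outline.vertices_px if isinstance(outline, OrganelleOutline) else np.asarray(outline)
    poly = Polygon(verts)
    if not poly.is_valid or poly.area == 0:
        raise ValueError("geometry has zero area or is invalid")
    half_band_px = (band_nm / 2.0) * 1e-3 / pixel_size_um
    band = poly.buffer(half_band_px).difference(poly.buffer(-half_band_px))
    area_um2 = band.area * pixel_size_um**2
    if area_um2 <= 0:
        raise ValueError("membrane band has zero area")
    n = rng.poisson(density_per_um2 * area_um2)
    if n == 0:
        return np.empty((0, 2))
    minx, miny, maxx, maxy = band.bounds
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        m = max(4 * (n - filled), 64)
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        keep = shapely.contains_xy(band, xs, ys)
        k = min(int(keep.sum()), n - filled)
        out[filled : filled + k, 0] = xs[keep][:k]
        out[filled : filled + k, 1] = ys[keep][:k]
        filled += k
    return out


# ----------------------------------------------------------------------
# STORM movie rendering
# ----------------------------------------------------------------------

def _render_gaussians(
    image: np.ndarray, positions: np.ndarray, photons, sigma_px: float
) -> None:
    """Add normalized 2D Gaussians (total mass = photons) into ``image``."""
    h, w = image.shape
    half = int(math.ceil(5 * sigma_px))
    photons = np.broadcast_to(np.asarray(photons, dtype=float), (len(positions),))
    for (x0, y0), ph in zip(positions, photons):
        ix, iy = int(round(x0)), int(round(y0))
        x_lo, x_hi = max(ix - half, 0), min(ix + half + 1, w)
        y_lo, y_hi = max(iy - half, 0), min(iy + half + 1, h)
        if x_lo >= x_hi or y_lo >= y_hi:
            continue
        xs = np.arange(x_lo, x_hi) - x0
        ys = np.arange(y_lo, y_hi) - y0
        gx = np.exp(-(xs**2) / (2 * sigma_px**2))
        gy = np.exp(-(ys**2) / (2 * sigma_px**2))
        image[y_lo:y_hi, x_lo:x_hi] += (ph / (2 * math.pi * sigma_px**2)) * np.outer(gy, gx)


def drift_trace_px(config: SimulationConfig, n_frames: int | None = None) -> np.ndarray:
    """Cumulative (dx, dy) drift per frame in px from the configured rate."""
    if n_frames is None:
        n_frames = config.n_frames
    rate_px = np.asarray(config.drift_rate_nm_per_frame) * 1e-3 / config.pixel_size_um
    return np.arange(n_frames)[:, None] * rate_px[None, :]


def simulate_storm_movie(
    config: SimulationConfig,
    emitters_px: np.ndarray,
    drift_px: np.ndarray | None = None,
    fiducials_px: np.ndarray | None = None,
    poisson_noise: bool = True,
    rng: np.random.Generator | None = None,
) -> tuple[FrameStack, GroundTruth]:
    """Render a blinking-emitter movie with drift, noise and fiducials.

    Each frame activates an independent Bernoulli subset of emitters
    (``config.duty_cycle``); active emitters and fiducials are rendered
    as 2D Gaussians of width ``psf_sigma_px`` shifted by the cumulative
    drift, on a uniform background.  With ``poisson_noise`` the expected
    image is Poisson-sampled into 16-bit counts; without it the noiseless
    expectation is returned (float frames), which is useful for oracle
    tests.
    """
    emitters_px = np.asarray(emitters_px, dtype=float)
    if emitters_px.size == 0:
        raise ValueError("emitters must be non-empty; use background-only configs instead")
    if rng is None:
        rng = rng_stream(config.rng_seed, "movie")
    w, h = config.field_size_px
    n_frames = config.n_frames
    if drift_px is None:
        drift_px = drift_trace_px(config, n_frames)
    drift_px = np.asarray(drift_px, dtype=float)
    if len(drift_px) != n_frames:
        raise ValueError("drift trace length must equal n_frames")

    frames = np.empty((n_frames, h, w), dtype=np.uint16 if poisson_noise else float)
    active_sets: list[np.ndarray] = []
    scratch = np.empty((h, w), dtype=float)
    for t in range(n_frames):
        scratch[:] = config.background_per_px
        active = np.flatnonzero(rng.random(len(emitters_px)) < config.duty_cycle)
        active_sets.append(active)
        if len(active):
            _render_gaussians(
                scratch,
                emitters_px[active] + drift_px[t],
                config.photons_per_event,
                config.psf_sigma_px,
            )
        if fiducials_px is not None and len(fiducials_px):
            _render_gaussians(
                scratch,
                np.asarray(fiducials_px) + drift_px[t],
                FIDUCIAL_BRIGHTNESS * config.photons_per_event,
                config.psf_sigma_px,
            )
        if poisson_noise:
            frames[t] = np.minimum(rng.poisson(scratch), 65535).astype(np.uint16)
        else:
            frames[t] = scratch

    stack = FrameStack(frames, config.pixel_size_um, config.frame_interval_s)
    truth = GroundTruth(
        emitter_positions_px=emitters_px,
        active_sets=active_sets,
        drift_px=drift_px,
        fiducial_positions_px={} if fiducials_px is None else {0: np.asarray(fiducials_px)},
    )
    return stack, truth


# ----------------------------------------------------------------------
# Fiducial beads
# ----------------------------------------------------------------------

def plant_fiducials(
    config: SimulationConfig,
    true_shift_nm: tuple[float, float] = (0.0, 0.0),
    rng: np.random.Generator | None = None,
    avoid: list[OrganelleOutline] | None = None,
    avoid_margin_px: float = 8.0,
) -> dict[int, np.ndarray]:
    """Place the same physical bead set in two channels with a known shift.

    Returns ``{0: positions_px, 1: positions_px + shift}``; the shift is
    the ground-truth inter-channel offset the registration stage must
    recover.  Pass organelle outlines as ``avoid`` to keep beads clear
    of labeled structures (beads are much brighter than single events
    and would mask molecules underneath).
    """
    if config.n_fiducials < 1:
        raise ValueError("n_fiducials must be >= 1")
    if rng is None:
        rng = rng_stream(config.rng_seed, "fiducials")
    w, h = config.field_size_px
    margin = 5.0
    avoid_polys = [Polygon(o.vertices_px).buffer(avoid_margin_px) for o in (avoid or [])]
    pos = np.empty((config.n_fiducials, 2))
    for i in range(config.n_fiducials):
        for _ in range(1000):
            x = rng.uniform(margin, w - margin)
            y = rng.uniform(margin, h - margin)
            if all(not p.covers(shapely.points(x, y)) for p in avoid_polys):
                pos[i] = (x, y)
                break
        else:
            raise RuntimeError("could not place fiducials clear of organelles")
    shift_px = np.asarray(true_shift_nm) * 1e-3 / config.pixel_size_um
    return {0: pos, 1: pos + shift_px}


def fiducial_localizations(
    positions_px: np.ndarray,
    n_repeats: int,
    sigma_nm: float,
    pixel_size_um: float,
    rng: np.random.Generator,
    channel: int = 0,
):
    """Repeated localizations of persistent beads with Gaussian scatter.

    Emulates what the localization stage produces for beads visible in
    every frame: ``n_repeats`` localizations per bead with isotropic
    scatter ``sigma_nm``.  Returns a molecule-list DataFrame.
    """
    import pandas as pd

    positions_px = np.asarray(positions_px, dtype=float)
    sigma_px = sigma_nm * 1e-3 / pixel_size_um
    rows = []
    for frame in range(n_repeats):
        noisy = positions_px + rng.normal(0.0, sigma_px, positions_px.shape)
        for x, y in noisy:
            rows.append((frame, x, y, 5e4, 1.0, 0.0, channel))
    return pd.DataFrame(
        rows, columns=["frame", "x_px", "y_px", "photons", "sigma_px", "background", "channel"]
    )


# ----------------------------------------------------------------------
# Live-cell tracks
# ----------------------------------------------------------------------

def _confined_walk(n_frames: int, dt_s: float, tau_s: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-amplitude 2D confined walk (AR(1) / Ornstein–Uhlenbeck), from 0."""
    a = math.exp(-dt_s / tau_s)
    noise = rng.standard_normal((n_frames, 2)) * math.sqrt(1 - a * a)
    noise[0] = 0.0  # start exactly at the anchor
    x = lfilter([1.0], [1.0, -a], noise[:, 0])
    y = lfilter([1.0], [1.0, -a], noise[:, 1])
    return np.column_stack([x, y])


def _lognormal_about(mean: float, cv: float, rng: np.random.Generator) -> float:
    s = math.sqrt(math.log(1 + cv * cv))
    return mean * math.exp(rng.normal(0.0, s) - s * s / 2.0)


def simulate_tracks(
    config: SimulationConfig,
    n_tracks: int,
    rng: np.random.Generator | None = None,
    window_frames: int = 500,
) -> tuple[list[Track], list[str]]:
    """Generate organelle centroid tracks in the three motion regimes.

    Stationary and dynamic-slow tracks are confined walks rescaled so
    that the maximum displacement from the start over the first
    ``window_frames`` frames hits a per-track target drawn about the
    class mean (192 and 414 nm) with lognormal track-level variation
    (``track_level_cv``).  Dynamic-fast tracks add one constant-velocity
    processive run at ``run_speed_nm_s`` whose net displacement is drawn
    about ``run_net_disp_nm``.  The confinement relaxation time is
    scaled per class so frame-to-frame path speeds stay comparable
    across confined classes.
    """
    if config.n_frames < window_frames:
        raise ValueError(f"n_frames must be >= the {window_frames}-frame classification window")
    fr = config.motion_class_fractions
    if abs(sum(fr) - 1.0) > 1e-9:
        raise ValueError("motion_class_fractions must sum to 1")
    if rng is None:
        rng = rng_stream(config.rng_seed, "tracks")
    dt = config.frame_interval_s
    n = config.n_frames
    t_s = np.arange(n) * dt

    labels = [MOTION_CLASSES[i] for i in rng.choice(3, size=n_tracks, p=fr)]
    tracks: list[Track] = []
    for tid, label in enumerate(labels):
        if label == "stationary":
            mu = config.stationary_max_disp_nm
        else:
            mu = config.slow_max_disp_nm
        # Comparable step sizes across confined classes: tau grows with
        # the square of the confinement amplitude.
        ratio = mu / config.stationary_max_disp_nm if config.stationary_max_disp_nm > 0 else 1.0
        tau = config.confinement_tau_s * max(ratio, 1e-6) ** 2
        walk = _confined_walk(n, dt, tau, rng)
        m_real = np.hypot(walk[:window_frames, 0], walk[:window_frames, 1]).max()
        target = _lognormal_about(mu, config.track_level_cv, rng)
        pos = walk * (target / m_real if m_real > 0 else 0.0)

        if label == "dynamic-fast":
            run_disp = max(_lognormal_about(config.run_net_disp_nm, config.track_level_cv, rng),
                           1100.0)
            run_frames = max(int(round(run_disp / config.run_speed_nm_s / dt)), 2)
            pad = max(int(0.05 * window_frames), 5)
            latest = max(window_frames - run_frames - pad, pad + 1)
            onset = int(rng.integers(pad, latest))
            theta = rng.uniform(0, 2 * math.pi)
            direction = np.array([math.cos(theta), math.sin(theta)])
            ramp = np.clip(np.arange(n) - onset, 0, run_frames) * (run_disp / run_frames)
            pos = pos + ramp[:, None] * direction[None, :]

        # Anchor each track at a random field position (metrics are
        # translation invariant; rendering needs in-field coordinates).
        field_nm = np.asarray(config.field_size_px) * config.pixel_size_um * 1e3
        anchor = rng.uniform(0.15, 0.85, 2) * field_nm
        pos = pos - pos[0] + anchor
        tracks.append(Track(track_id=tid, t_s=t_s, x_nm=pos[:, 0], y_nm=pos[:, 1]))
    return tracks, labels


def simulate_livecell_movie(
    config: SimulationConfig,
    tracks: list[Track],
    blob_sigma_um: float = 0.4,
    peak_photons: float = 2000.0,
    rng: np.random.Generator | None = None,
    poisson_noise: bool = True,
) -> FrameStack:
    """Render tracks as diffraction-limited moving blobs.

    Organelles are rendered filled (a single Gaussian blob per centroid),
    emulating a matrix dye; the membrane-band geometry used for the STORM
    channel is not resolvable at this resolution anyway.
    """
    if rng is None:
        rng = rng_stream(config.rng_seed, "livecell")
    w, h = config.field_size_px
    n = min(config.n_frames, min(len(t) for t in tracks))
    sigma_px = blob_sigma_um / config.pixel_size_um
    frames = np.empty((n, h, w), dtype=np.uint16 if poisson_noise else float)
    scratch = np.empty((h, w), dtype=float)
    for t in range(n):
        scratch[:] = config.background_per_px
        pos_px = np.array(
            [[tr.x_nm[t] * 1e-3 / config.pixel_size_um,
              tr.y_nm[t] * 1e-3 / config.pixel_size_um] for tr in tracks]
        )
        _render_gaussians(scratch, pos_px, peak_photons, sigma_px)
        frames[t] = (
            np.minimum(rng.poisson(scratch), 65535).astype(np.uint16)
            if poisson_noise else scratch
        )
    return FrameStack(frames, config.pixel_size_um, config.frame_interval_s)
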