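"""Drift correction, channel registration, and super-resolution rendering.

Drift is estimated by splitting the movie into frame subsets (500–1000
frames), reconstructing a super-resolution image per subset, and
cross-correlating each against the first subset's image; per-frame
corrections are linearly interpolated between subset midpoints.
Sequentially acquired channels are registered by comparing localized
fiducial beads and shifting one channel by the mean bead offset.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.interpolate import interp1d
from scipy.ndimage import gaussian_filter
from scipy.signal import fftconvolve

from .datatypes import ChannelShift, DriftTrace, StormImage, validate_molecule_list

log = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# Rendering
# ----------------------------------------------------------------------

def render(
    molecules: pd.DataFrame,
    render_px_um: float,
    pixel_size_um: float,
    field_size_px: tuple[int, int] | None = None,
    mode: str = "histogram",
    splat_sigma_nm: float = 20.0,
) -> StormImage:
    """Render a molecule list into a super-resolution image.

    Histogram mode bins localization positions on the render grid, so
    the image sums to the number of in-bounds localizations exactly.
    Gaussian-splat mode smooths the histogram with a kernel of width
    ``splat_sigma_nm`` while preserving total mass.
    """
    if render_px_um > pixel_size_um:
        raise ValueError("render pixel must be <= camera pixel")
    validate_molecule_list(molecules)
    bin_px = render_px_um / pixel_size_um  # render bin size in camera px
    if field_size_px is None:
        if len(molecules) == 0:
            field_size_px = (1, 1)
        else:
            field_size_px = (
                int(np.ceil(molecules["x_px"].max())) + 1,
                int(np.ceil(molecules["y_px"].max())) + 1,
            )
    nx = int(np.ceil(field_size_px[0] / bin_px))
    ny = int(np.ceil(field_size_px[1] / bin_px))
    if len(molecules) == 0:
        return StormImage(np.zeros((ny, nx)), render_px_um)
    grid, _, _ = np.histogram2d(
        molecules["y_px"].to_numpy(),
        molecules["x_px"].to_numpy(),
        bins=(ny, nx),
        range=((0, ny * bin_px), (0, nx * bin_px)),
    )
    if mode == "gaussian":
        sigma_bins = splat_sigma_nm * 1e-3 / render_px_um
        grid = gaussian_filter(grid, sigma_bins, mode="constant")
    elif mode != "histogram":
        raise ValueError(f"unknown render mode {mode!r}")
    return StormImage(grid, render_px_um)


# ----------------------------------------------------------------------
# Drift estimation
# ----------------------------------------------------------------------

def _quadratic_peak(c: np.ndarray) -> tuple[float, float]:
    """Sub-pixel peak of a correlation surface by 3-point quadratic fits."""
    iy, ix = np.unravel_index(np.argmax(c), c.shape)
    out = [float(iy), float(ix)]
    for axis, idx in ((0, iy), (1, ix)):
        if 0 < idx < c.shape[axis] - 1:
            sel = [slice(None)] * 2
            vals = []
            for off in (-1, 0, 1):
                sel2 = list(sel)
                sel2[axis] = idx + off
                sel2[1 - axis] = (ix if axis == 0 else iy)
                vals.append(float(c[tuple(sel2)]))
            denom = vals[0] - 2 * vals[1] + vals[2]
            if denom < 0:
                out[axis] = idx + 0.5 * (vals[0] - vals[2]) / denom
    return out[0], out[1]


def _subset_bounds(n_frames: int, subset_size: int) -> list[tuple[int, int]]:
    """Frame subsets of ~subset_size; a short tail (< half) merges back."""
    bounds = []
    start = 0
    while start < n_frames:
        end = min(start + subset_size, n_frames)
        bounds.append((start, end))
        start = end
    if len(bounds) > 1 and bounds[-1][1] - bounds[-1][0] < subset_size / 2:
        last = bounds.pop()
        prev = bounds.pop()
        bounds.append((prev[0], last[1]))
    return bounds


def estimate_drift(
    molecules: pd.DataFrame,
    n_frames: int,
    pixel_size_um: float,
    subset_size: int = 500,
    field_size_px: tuple[int, int] | None = None,
    upsample: float = 4.0,
    smooth_sigma_bins: float = 2.0,
    min_locs_per_subset: int = 50,
) -> DriftTrace:
    """Estimate per-frame drift by subset-image cross-correlation.

    Subset images are rendered at ``upsample``x the camera pixel,
    smoothed with a ``smooth_sigma_bins``-bin Gaussian (suppresses
    pixel-locking of the correlation peak on sparse histograms) and
    correlated against the first subset (the reference); the correlation
    peak is refined by per-axis 3-point quadratic interpolation.  The
    returned trace holds per-frame *corrections* (the negated measured
    displacement), zero for the reference subset midpoint, linearly
    interpolated between subset midpoints and linearly extrapolated
    beyond the first/last midpoint (a steady stage drift does not stop
    at the subset midpoints).
    """
    if not (500 <= subset_size <= 1000):
        warnings.warn(
            f"subset_size {subset_size} outside the standard 500-1000 frame range",
            stacklevel=2,
        )
    validate_molecule_list(molecules)
    bounds = _subset_bounds(n_frames, subset_size)
    if len(bounds) < 2:
        raise ValueError("movie must span at least two subsets for drift estimation")
    render_px_um = pixel_size_um / upsample
    if field_size_px is None and len(molecules):
        field_size_px = (
            int(np.ceil(molecules["x_px"].max())) + 2,
            int(np.ceil(molecules["y_px"].max())) + 2,
        )

    images = []
    for start, end in bounds:
        sub = molecules[(molecules["frame"] >= start) & (molecules["frame"] < end)]
        if len(sub) < min_locs_per_subset:
            warnings.warn(
                f"subset frames [{start}, {end}) has only {len(sub)} localizations; skipped",
                stacklevel=2,
            )
            images.append(None)
            continue
        grid = render(sub, render_px_um, pixel_size_um, field_size_px).grid
        if smooth_sigma_bins > 0:
            grid = gaussian_filter(grid, smooth_sigma_bins)
        images.append(grid)

    ref = next((im for im in images if im is not None), None)
    if ref is None:
        raise ValueError("no subset has enough localizations for drift estimation")
    ref_zm = ref - ref.mean()

    mids, shifts = [], []
    for (start, end), im in zip(bounds, images):
        if im is None:
            continue
        if im is ref:
            mids.append((start + end - 1) / 2.0)
            shifts.append((0.0, 0.0))
            continue
        corr = fftconvolve(im - im.mean(), ref_zm[::-1, ::-1], mode="full")
        py, px_ = _quadratic_peak(corr)
        dy = (py - (ref.shape[0] - 1)) * (render_px_um / pixel_size_um)
        dx = (px_ - (ref.shape[1] - 1)) * (render_px_um / pixel_size_um)
        mids.append((start + end - 1) / 2.0)
        shifts.append((dx, dy))

    mids_arr = np.asarray(mids)
    shifts_arr = np.asarray(shifts)  # measured displacement of subset vs reference, camera px
    frames = np.arange(n_frames, dtype=float)
    if len(mids_arr) >= 2:
        interp = interp1d(mids_arr, shifts_arr, axis=0, kind="linear",
                          fill_value="extrapolate", assume_sorted=True)
        disp = interp(frames)
    else:
        disp = np.repeat(shifts_arr, n_frames, axis=0)
    dx, dy = -disp[:, 0], -disp[:, 1]
    log.info("drift estimated over %d subsets, max |shift| %.3f px",
             len(mids), float(np.abs(shifts_arr).max()))
    return DriftTrace(dx, dy, subset_bounds=bounds)


def drift_residual_rms_nm(
    trace: DriftTrace, true_drift_px: np.ndarray, pixel_size_um: float
) -> float:
    """RMS disagreement (nm) between a trace and a known drift.

    The estimated trace is only defined up to a constant (its zero is
    the reference subset's mean position, not frame 0), so the constant
    offset is removed before comparing.
    """
    true_drift_px = np.asarray(true_drift_px, dtype=float)
    est = np.column_stack([trace.dx_px, trace.dy_px])
    if len(true_drift_px) != len(est):
        raise ValueError("trace and true drift must cover the same frames")
    err = est + true_drift_px  # corrections are negated drift
    err = err - err.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(err**2, axis=1))) * pixel_size_um * 1e3)


def apply_drift(molecules: pd.DataFrame, trace: DriftTrace) -> pd.DataFrame:
    """Apply per-frame drift corrections to a molecule list.

    Positions are shifted by the frame's (dx, dy) correction; all other
    columns are untouched and the row count is preserved.
    """
    validate_molecule_list(molecules)
    out = molecules.copy()
    if len(out) == 0:
        return out
    frames = out["frame"].to_numpy().astype(int)
    if frames.min() < 0 or frames.max() >= trace.n_frames:
        raise ValueError(
            f"molecule frames [{frames.min()}, {frames.max()}] outside drift trace "
            f"of length {trace.n_frames}"
        )
    out["x_px"] = out["x_px"].to_numpy() + trace.dx_px[frames]
    out["y_px"] = out["y_px"].to_numpy() + trace.dy_px[frames]
    return out


# ----------------------------------------------------------------------
# Channel registration
# ----------------------------------------------------------------------

def register_channels(
    beads_a: np.ndarray,
    beads_b: np.ndarray,
    pixel_size_um: float,
    match_radius_nm: float = 500.0,
) -> ChannelShift:
    """Estimate the translation between two channels from matched beads.

    Beads are matched by mutual nearest neighbour within
    ``match_radius_nm``; the shift is the mean per-bead difference
    (channel b minus channel a) in nm, with the residual RMS reported so
    outliers are visible.
    """
    a = np.asarray(beads_a, dtype=float).reshape(-1, 2)
    b = np.asarray(beads_b, dtype=float).reshape(-1, 2)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both channels need at least one localized bead")
    nm_per_px = pixel_size_um * 1e3
    radius_px = match_radius_nm / nm_per_px
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    nearest_b = d2.argmin(axis=1)
    nearest_a = d2.argmin(axis=0)
    pairs = [
        (i, int(nearest_b[i]))
        for i in range(len(a))
        if nearest_a[nearest_b[i]] == i and d2[i, nearest_b[i]] <= radius_px**2
    ]
    if not pairs:
        raise ValueError(f"no beads matched within {match_radius_nm} nm")
    diffs_nm = np.array([(b[j] - a[i]) * nm_per_px for i, j in pairs])
    shift = diffs_nm.mean(axis=0)
    residual = float(np.sqrt(np.mean(np.sum((diffs_nm - shift) ** 2, axis=1))))
    return ChannelShift(float(shift[0]), float(shift[1]), n_beads=len(pairs),
                        residual_rms_nm=residual)


def apply_channel_shift(
    molecules_b: pd.DataFrame, shift: ChannelShift, pixel_size_um: float
) -> pd.DataFrame:
    """Shift channel-b molecules into channel-a's coordinate frame."""
    validate_molecule_list(molecules_b)
    out = molecules_b.copy()
    nm_per_px = pixel_size_um * 1e3
    out["x_px"] = out["x_px"] - shift.dx_nm / nm_per_px
    out["y_px"] = out["y_px"] - shift.dy_nm / nm_per_px
    return out
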