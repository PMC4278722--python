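"""Single-molecule detection and sub-pixel localization.

Each frame is scanned for local maxima whose amplitude above the
locally estimated background exceeds a threshold; every candidate is
then fit with a symmetric 2D Gaussian plus constant background by
bounded nonlinear least squares, yielding sub-pixel positions, photon
counts and fitted widths.  Overlapping emitters are not deconvolved:
merged candidates yield single (possibly biased) fits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import least_squares

from .datatypes import MOLECULE_COLUMNS, FrameStack, empty_molecule_list, validate_molecule_list

log = logging.getLogger(__name__)


@dataclass
class DetectionParams:
    """Spot-detection settings.

    ``intensity_threshold`` is in counts *above the local background*
    (the median of the fit-window border), not absolute counts.
    """

    intensity_threshold: float = 80.0
    min_separation_px: float = 3.0
    fit_window_px: int = 7

    def __post_init__(self) -> None:
        if self.intensity_threshold < 0:
            raise ValueError("intensity_threshold must be >= 0")
        if self.fit_window_px < 5 or self.fit_window_px % 2 == 0:
            raise ValueError("fit_window_px must be an odd integer >= 5")


@dataclass
class GaussianFit:
    """Result of one 2D Gaussian fit (ROI coordinates)."""

    x_px: float
    y_px: float
    photons: float
    sigma_px: float
    background: float
    converged: bool


def _border_median(roi: np.ndarray) -> float:
    border = np.concatenate([roi[0, :], roi[-1, :], roi[1:-1, 0], roi[1:-1, -1]])
    return float(np.median(border))


def detect_spots(frame: np.ndarray, params: DetectionParams) -> list[tuple[int, int]]:
    """Find candidate emitter pixels in one frame.

    Returns integer (x, y) positions of local maxima whose
    background-subtracted amplitude exceeds the threshold; candidates
    closer than ``min_separation_px`` are merged to the brighter one.
    An empty or flat frame yields an empty list.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0 or frame.ndim != 2:
        return []
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite values")

    size = max(3, int(round(params.min_separation_px)))
    is_max = frame == ndimage.maximum_filter(frame, size=size, mode="nearest")
    half = params.fit_window_px // 2
    ys, xs = np.nonzero(is_max)
    candidates: list[tuple[int, int, float]] = []
    h, w = frame.shape
    for y, x in zip(ys, xs):
        y_lo, y_hi = max(y - half, 0), min(y + half + 1, h)
        x_lo, x_hi = max(x - half, 0), min(x + half + 1, w)
        roi = frame[y_lo:y_hi, x_lo:x_hi]
        if roi.shape[0] < 3 or roi.shape[1] < 3:
            continue
        amp = frame[y, x] - _border_median(roi)
        if amp > params.intensity_threshold:
            candidates.append((x, y, amp))

    # Merge near-duplicates, brighter one wins.
    candidates.sort(key=lambda c: -c[2])
    kept: list[tuple[int, int, float]] = []
    min_sep2 = params.min_separation_px**2
    for c in candidates:
        if all((c[0] - k[0]) ** 2 + (c[1] - k[1]) ** 2 >= min_sep2 for k in kept):
            kept.append(c)
    return [(x, y) for x, y, _ in kept]


def fit_gaussian(roi: np.ndarray, max_iter: int = 100, xtol: float = 1e-8) -> GaussianFit:
    """Least-squares fit of a symmetric 2D Gaussian + constant background.

    The model is ``b + A exp(-((x-x0)^2 + (y-y0)^2) / (2 sigma^2))``
    evaluated at pixel centres.  Initialization uses the intensity
    centroid and the border median; parameters are bounded to the
    window.  A flat ROI (no peak above background) is flagged as
    non-converged.
    """
    roi = np.asarray(roi, dtype=float)
    h, w = roi.shape
    b0 = _border_median(roi)
    amp0 = float(roi.max() - b0)
    if amp0 <= 0 or not np.all(np.isfinite(roi)):
        return GaussianFit(np.nan, np.nan, 0.0, np.nan, b0, converged=False)

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    weights = np.clip(roi - b0, 0, None)
    total = weights.sum()
    x0 = float((weights * xx).sum() / total) if total > 0 else (w - 1) / 2
    y0 = float((weights * yy).sum() / total) if total > 0 else (h - 1) / 2

    def resid(p):
        a, x, y, s, b = p
        return (b + a * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * s * s)) - roi).ravel()

    def jac(p):
        a, x, y, s, b = p
        dx2 = (xx - x) ** 2 + (yy - y) ** 2
        g = np.exp(-dx2 / (2 * s * s))
        cols = np.empty((g.size, 5))
        cols[:, 0] = g.ravel()
        cols[:, 1] = (a * g * (xx - x) / (s * s)).ravel()
        cols[:, 2] = (a * g * (yy - y) / (s * s)).ravel()
        cols[:, 3] = (a * g * dx2 / s**3).ravel()
        cols[:, 4] = 1.0
        return cols

    p0 = [amp0, x0, y0, 1.2, b0]
    lo = [0.0, -1.0, -1.0, 0.3, 0.0]
    hi = [np.inf, w, h, max(h, w), np.inf]
    p0 = np.clip(p0, lo, hi)
    try:
        res = least_squares(resid, p0, jac=jac, bounds=(lo, hi), max_nfev=max_iter * 6,
                            xtol=xtol)
    except Exception:  # singular Jacobian etc.
        return GaussianFit(np.nan, np.nan, 0.0, np.nan, b0, converged=False)
    a, x, y, s, b = res.x
    converged = bool(res.success) and a > 0
    photons = float(2 * np.pi * s * s * a)
    return GaussianFit(float(x), float(y), photons, float(s), float(b), converged)


def localize_movie(
    stack: FrameStack, params: DetectionParams, channel: int = 0
) -> pd.DataFrame:
    """Detect and fit all molecules in a movie, returning a molecule list.

    Per-frame candidate order is stable (brightness-sorted); fits that
    fail to converge or land outside the frame are skipped and counted
    in the log.
    """
    half = params.fit_window_px // 2
    rows = []
    n_skipped = 0
    for t in range(stack.n_frames):
        frame = np.asarray(stack.frames[t], dtype=float)
        h, w = frame.shape
        for cx, cy in detect_spots(frame, params):
            y_lo, y_hi = cy - half, cy + half + 1
            x_lo, x_hi = cx - half, cx + half + 1
            if y_lo < 0 or x_lo < 0 or y_hi > h or x_hi > w:
                n_skipped += 1
                continue
            fit = fit_gaussian(frame[y_lo:y_hi, x_lo:x_hi])
            if not fit.converged or fit.photons <= 0:
                n_skipped += 1
                continue
            x_px, y_px = fit.x_px + x_lo, fit.y_px + y_lo
            if not (0 <= x_px <= w - 1 and 0 <= y_px <= h - 1):
                n_skipped += 1
                continue
            rows.append((t, x_px, y_px, fit.photons, fit.sigma_px, fit.background, channel))
    log.info("localized %d molecules (%d candidates skipped)", len(rows), n_skipped)
    if not rows:
        return empty_molecule_list()
    return pd.DataFrame(rows, columns=MOLECULE_COLUMNS)


# ----------------------------------------------------------------------
# Fiducial-based localization precision
# ----------------------------------------------------------------------

def identify_beads(
    molecules: pd.DataFrame, n_frames: int, min_fraction: float = 0.9, radius_px: float = 2.0
) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame]:
    """Split a molecule list into persistent beads and blinking molecules.

    Fiducial beads are bright and visible in essentially every frame, so
    any position localized in >= ``min_fraction`` of frames is a bead.
    Returns (bead centres (k, 2) px, bead localizations, the rest).
    """
    validate_molecule_list(molecules)
    if len(molecules) == 0:
        return np.empty((0, 2)), molecules, molecules
    xy = molecules[["x_px", "y_px"]].to_numpy()
    # Coarse occupancy grid; a bead fills one or a few adjacent cells.
    cells = np.round(xy).astype(int)
    grid_w = cells.max(axis=0) + 2
    occ = np.zeros((grid_w[1] + 1, grid_w[0] + 1), dtype=int)
    frames_seen: dict[tuple[int, int], set] = {}
    fr = molecules["frame"].to_numpy()
    for (cx, cy), f in zip(cells, fr):
        frames_seen.setdefault((cx, cy), set()).add(int(f))
    for (cx, cy), fs in frames_seen.items():
        occ[cy, cx] = len(fs)
    hot = occ >= max(1, int(np.ceil(min_fraction * n_frames / 4)))
    labeled, n_lab = ndimage.label(hot, structure=np.ones((3, 3), dtype=int))
    centres = []
    for lab in range(1, n_lab + 1):
        ys, xs = np.nonzero(labeled == lab)
        member = np.zeros(len(molecules), dtype=bool)
        for cy, cx in zip(ys, xs):
            member |= (cells[:, 0] == cx) & (cells[:, 1] == cy)
        locs = molecules[member]
        if locs["frame"].nunique() >= min_fraction * n_frames:
            centres.append(locs[["x_px", "y_px"]].mean().to_numpy())
    if not centres:
        return np.empty((0, 2)), molecules.iloc[:0], molecules
    centres_arr = np.asarray(centres)
    d2 = ((xy[:, None, :] - centres_arr[None, :, :]) ** 2).sum(axis=2)
    nearest = d2.argmin(axis=1)
    is_bead = d2[np.arange(len(xy)), nearest] <= radius_px**2
    return centres_arr, molecules[is_bead], molecules[~is_bead]


def estimate_localization_precision(
    bead_locs: pd.DataFrame,
    pixel_size_um: float,
    bead_positions_px: np.ndarray | None = None,
    min_repeats: int = 20,
) -> float:
    """Localization precision (nm) from repeated fiducial localizations.

    Per bead, the per-axis standard deviations of repeated localizations
    are combined as ``sqrt((sx^2 + sy^2) / 2)``; beads are pooled by
    averaging variances.  Requires at least ``min_repeats`` repeats of
    at least one bead.
    """
    validate_molecule_list(bead_locs)
    xy = bead_locs[["x_px", "y_px"]].to_numpy()
    if bead_positions_px is None:
        if len(xy) == 0:
            raise ValueError(
                f"need >= {min_repeats} repeated localizations of >= 1 persistent "
                "fiducial; supply the precision in the config instead"
            )
        # Cluster by nearest seed taken from the first frame present.
        first = bead_locs["frame"].min()
        bead_positions_px = bead_locs.loc[bead_locs["frame"] == first, ["x_px", "y_px"]].to_numpy()
    bead_positions_px = np.asarray(bead_positions_px, dtype=float)
    d2 = ((xy[:, None, :] - bead_positions_px[None, :, :]) ** 2).sum(axis=2)
    assign = d2.argmin(axis=1)
    variances = []
    for b in range(len(bead_positions_px)):
        pts = xy[assign == b]
        if len(pts) < min_repeats:
            continue
        sx2 = pts[:, 0].var(ddof=1)
        sy2 = pts[:, 1].var(ddof=1)
        variances.append((sx2 + sy2) / 2.0)
    if not variances:
        raise ValueError(
            f"need >= {min_repeats} repeated localizations of >= 1 persistent "
            "fiducial; supply the precision in the config instead"
        )
    sigma_px = float(np.sqrt(np.mean(variances)))
    return sigma_px * pixel_size_um * 1e3
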