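"""Organelle motility: tracking, displacement metrics, classification.

Each organelle's live-cell trajectory is summarized over a 500-frame
window by its maximum displacement from the starting position, its mean
and peak speeds, and whether it sustains a processive run.  Organelles
are classified as stationary (docked, confined to ~192 nm), dynamic-slow
(confined but mobile, ~414 nm range) or dynamic-fast (processive runs at
~700 nm/s), and as interacting vs isolated from their super-resolved
boundary geometry.

No explicit thresholds were published for the motion classes; the
defaults here put the stationary/slow boundary at 290 nm (the crossing
point of Gaussian envelopes fitted to the two reported displacement
distributions, 192±91 and 414±261 nm) and call a run any >= 1 s stretch
sustaining >= 500 nm/s with directional persistence.  All thresholds are
configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Polygon

from .datatypes import FrameStack, OrganelleOutline, Track

log = logging.getLogger(__name__)

MOTION_CLASSES = ("stationary", "dynamic-slow", "dynamic-fast")
INTERACTION_CLASSES = ("interacting", "isolated")


@dataclass
class DynamicsMetrics:
    """Displacement and speed summary of one track (nm, nm/s)."""

    max_displacement_nm: float
    mean_speed_nm_s: float
    peak_run_speed_nm_s: float
    net_displacement_nm: float
    run_detected: bool
    window_truncated: bool = False


def compute_metrics(
    track: Track,
    window_frames: int = 500,
    run_speed_threshold_nm_s: float = 500.0,
    run_min_duration_s: float = 1.0,
    run_persistence_min_cos: float = 0.5,
) -> DynamicsMetrics:
    """Compute displacement/speed metrics over the classification window.

    * max displacement: largest distance from the starting position
      within the first ``window_frames`` frames;
    * mean speed: path length / elapsed time over the window;
    * peak run speed: largest net displacement over any sliding window
      of ``run_min_duration_s``, per second;
    * run detected: some such window sustains
      ``run_speed_threshold_nm_s`` with directional persistence (mean
      cosine between successive coarse steps >= the threshold).

    Tracks shorter than the window are evaluated on what is available
    and flagged ``window_truncated``.
    """
    n = min(len(track), window_frames)
    truncated = len(track) < window_frames
    pos = track.positions_nm[:n]
    t = track.t_s[:n]
    disp = np.linalg.norm(pos - pos[0], axis=1)
    max_disp = float(disp.max())
    net_disp = float(disp[-1])

    steps = np.diff(pos, axis=0)
    path = float(np.linalg.norm(steps, axis=1).sum())
    duration = float(t[-1] - t[0])
    mean_speed = path / duration if duration > 0 else 0.0

    dt = float(np.median(np.diff(t)))
    win = max(int(round(run_min_duration_s / dt)), 1)
    peak_speed = 0.0
    run_detected = False
    if n > win:
        net = np.linalg.norm(pos[win:] - pos[:-win], axis=1)
        win_speed = net / (win * dt)
        peak_speed = float(win_speed.max())
        # Directional persistence on ~0.25 s coarse steps to suppress
        # frame-to-frame jitter.
        sub = max(int(round(0.25 / dt)), 1)
        for start in np.flatnonzero(win_speed >= run_speed_threshold_nm_s):
            seg = pos[start : start + win + 1 : sub]
            v = np.diff(seg, axis=0)
            norms = np.linalg.norm(v, axis=1)
            ok = norms > 0
            v = v[ok]
            norms = norms[ok]
            if len(v) < 2:
                continue
            cosines = np.sum(v[:-1] * v[1:], axis=1) / (norms[:-1] * norms[1:])
            if float(np.mean(cosines)) >= run_persistence_min_cos:
                run_detected = True
                break
    return DynamicsMetrics(max_disp, mean_speed, peak_speed, net_disp, run_detected, truncated)


def classify_motion(
    metrics: DynamicsMetrics,
    confinement_threshold_nm: float = 290.0,
    fast_net_disp_threshold_nm: float = 1000.0,
) -> str:
    """Assign a motion class from a track's metrics.

    Dynamic-fast requires a detected processive run with enough net
    transport; otherwise the max displacement decides stationary vs
    dynamic-slow.
    """
    if metrics.run_detected and metrics.net_displacement_nm >= fast_net_disp_threshold_nm:
        return "dynamic-fast"
    if metrics.max_displacement_nm <= confinement_threshold_nm:
        return "stationary"
    return "dynamic-slow"


class MotionClassifier:
    """Threshold-based motion classifier with a fit/predict-style API.

    ``fit`` only records the class set (the rule is fixed a priori);
    ``predict`` maps tracks to motion-class labels.  Parameters mirror
    :func:`compute_metrics` and :func:`classify_motion`.
    """

    def __init__(
        self,
        window_frames: int = 500,
        confinement_threshold_nm: float = 290.0,
        run_speed_threshold_nm_s: float = 500.0,
        run_min_duration_s: float = 1.0,
        run_persistence_min_cos: float = 0.5,
        fast_net_disp_threshold_nm: float = 1000.0,
    ):
        self.window_frames = window_frames
        self.confinement_threshold_nm = confinement_threshold_nm
        self.run_speed_threshold_nm_s = run_speed_threshold_nm_s
        self.run_min_duration_s = run_min_duration_s
        self.run_persistence_min_cos = run_persistence_min_cos
        self.fast_net_disp_threshold_nm = fast_net_disp_threshold_nm

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in (
            "window_frames", "confinement_threshold_nm", "run_speed_threshold_nm_s",
            "run_min_duration_s", "run_persistence_min_cos", "fast_net_disp_threshold_nm")}

    def set_params(self, **params) -> "MotionClassifier":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, tracks=None, y=None) -> "MotionClassifier":
        self.classes_ = np.asarray(MOTION_CLASSES)
        return self

    def metrics(self, track: Track) -> DynamicsMetrics:
        return compute_metrics(
            track,
            window_frames=self.window_frames,
            run_speed_threshold_nm_s=self.run_speed_threshold_nm_s,
            run_min_duration_s=self.run_min_duration_s,
            run_persistence_min_cos=self.run_persistence_min_cos,
        )

    def predict(self, tracks: list[Track]) -> list[str]:
        if not hasattr(self, "classes_"):
            self.fit()
        return [
            classify_motion(
                self.metrics(tr),
                confinement_threshold_nm=self.confinement_threshold_nm,
                fast_net_disp_threshold_nm=self.fast_net_disp_threshold_nm,
            )
            for tr in tracks
        ]


# ----------------------------------------------------------------------
# Interaction classification
# ----------------------------------------------------------------------

def classify_interaction(
    outlines: list[OrganelleOutline],
    pixel_size_um: float,
    contact_distance_nm: float = 100.0,
) -> dict[int, str]:
    """Interacting vs isolated from boundary-to-boundary distances.

    An organelle is interacting if its boundary comes within
    ``contact_distance_nm`` (inclusive) of any other organelle's
    boundary; a lone organelle is isolated.
    """
    if not outlines:
        raise ValueError("need at least one outline")
    polys = [Polygon(o.vertices_px) for o in outlines]
    nm_per_px = pixel_size_um * 1e3
    thresh_px = contact_distance_nm / nm_per_px
    out: dict[int, str] = {}
    for i, oi in enumerate(outlines):
        interacting = any(
            polys[i].distance(polys[j]) <= thresh_px for j in range(len(polys)) if j != i
        )
        out[oi.organelle_id] = "interacting" if interacting else "isolated"
    return out


# ----------------------------------------------------------------------
# Centroid tracking
# ----------------------------------------------------------------------

def detect_blob_centroids(
    stack: FrameStack, threshold_factor: float = 3.0, min_area_px: int = 4
) -> list[np.ndarray]:
    """Intensity-weighted blob centroids per frame, in nm.

    Frames are thresholded at median + ``threshold_factor`` x MAD-based
    sigma; connected components above ``min_area_px`` contribute one
    centroid each.
    """
    nm_per_px = stack.pixel_size_um * 1e3
    out = []
    for t in range(stack.n_frames):
        frame = np.asarray(stack.frames[t], dtype=float)
        med = np.median(frame)
        sigma = 1.4826 * np.median(np.abs(frame - med))
        # noise floor from MAD, but never below a fifth of the peak
        # height (noiseless frames have MAD ~ 0)
        thr = max(threshold_factor * sigma, 0.2 * (frame.max() - med))
        if thr <= 0:
            out.append(np.empty((0, 2)))
            continue
        mask = frame > med + thr
        labeled, n_lab = ndimage.label(mask)
        cents = []
        for lab in range(1, n_lab + 1):
            sel = labeled == lab
            if sel.sum() < min_area_px:
                continue
            cy, cx = ndimage.center_of_mass(frame - med, labeled, lab)
            cents.append((cx * nm_per_px, cy * nm_per_px))
        out.append(np.asarray(cents).reshape(-1, 2))
    return out


def track_centroids(
    detections_nm: list[np.ndarray],
    frame_interval_s: float,
    max_step_nm: float = 2000.0,
    min_length: int = 10,
) -> list[Track]:
    """Link per-frame centroid detections into tracks.

    Frame-to-frame nearest-neighbour linking with a maximum step gate;
    unlinked detections start new tracks and tracks shorter than
    ``min_length`` frames are dropped.
    """
    active: list[dict] = []  # each: {"frames": [...], "pos": [...]}
    finished: list[dict] = []
    for t, dets in enumerate(detections_nm):
        dets = np.asarray(dets, dtype=float).reshape(-1, 2)
        unmatched = set(range(len(dets)))
        still_active = []
        for tr in active:
            last = tr["pos"][-1]
            best, best_d = None, max_step_nm
            for j in unmatched:
                d = float(np.hypot(*(dets[j] - last)))
                if d <= best_d:
                    best, best_d = j, d
            if best is not None:
                tr["frames"].append(t)
                tr["pos"].append(dets[best])
                unmatched.discard(best)
                still_active.append(tr)
            else:
                finished.append(tr)
        for j in sorted(unmatched):
            still_active.append({"frames": [t], "pos": [dets[j]]})
        active = still_active
    finished.extend(active)

    tracks = []
    n_dropped = 0
    for tid, tr in enumerate(finished):
        if len(tr["frames"]) < min_length:
            n_dropped += 1
            continue
        pos = np.asarray(tr["pos"])
        t_s = np.asarray(tr["frames"], dtype=float) * frame_interval_s
        tracks.append(Track(track_id=tid, t_s=t_s, x_nm=pos[:, 0], y_nm=pos[:, 1]))
    if n_dropped:
        log.info("dropped %d tracks shorter than %d frames", n_dropped, min_length)
    return tracks


# ----------------------------------------------------------------------
# Classification validation
# ----------------------------------------------------------------------

def recover_classes(
    true_labels: list[str], predicted_labels: list[str]
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Confusion matrix (rows = truth) and per-class recall."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label lists must have equal length")
    truth = pd.Categorical(true_labels, categories=MOTION_CLASSES)
    pred = pd.Categorical(predicted_labels, categories=MOTION_CLASSES)
    cm = pd.crosstab(truth, pred, dropna=False)
    cm = cm.reindex(index=MOTION_CLASSES, columns=MOTION_CLASSES, fill_value=0)
    recall = {}
    for cls in MOTION_CLASSES:
        total = int(cm.loc[cls].sum())
        if total > 0:
            recall[cls] = float(cm.loc[cls, cls] / total)
    return cm, recall
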