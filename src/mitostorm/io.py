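"""File formats: molecule lists, tracks, outlines, drift traces, TIFF stacks.

Everything tabular is plain CSV with documented headers; movies are
multi-page grayscale TIFF.  All writes are atomic (write to a temporary
file in the same directory, then rename), so a crashed run never leaves
a half-written artifact.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .datatypes import (
    MOLECULE_COLUMNS,
    DriftTrace,
    FrameStack,
    OrganelleOutline,
    Track,
    empty_molecule_list,
    validate_molecule_list,
)

TRACK_COLUMNS = ["track_id", "frame", "t_s", "x_nm", "y_nm"]
OUTLINE_COLUMNS = ["organelle_id", "vertex_index", "x_px", "y_px"]
DRIFT_COLUMNS = ["frame", "dx_px", "dy_px"]


def _atomic_write(path: str | Path, writer) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def _read_csv_checked(path: str | Path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as e:
        raise ValueError(f"malformed CSV {path}: {e}") from e
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


# -- molecule lists ----------------------------------------------------

def write_molecule_list(molecules: pd.DataFrame, path: str | Path) -> None:
    """Write a molecule list as CSV at full float precision.

    Unknown extra columns are preserved after the canonical ones.
    """
    validate_molecule_list(molecules)
    extra = [c for c in molecules.columns if c not in MOLECULE_COLUMNS]
    ordered = molecules[MOLECULE_COLUMNS + extra]
    _atomic_write(path, lambda tmp: ordered.to_csv(tmp, index=False, float_format="%.17g"))


def read_molecule_list(path: str | Path) -> pd.DataFrame:
    df = _read_csv_checked(path, MOLECULE_COLUMNS)
    if len(df) == 0:
        return empty_molecule_list()
    return df.astype({"frame": int, "channel": int})


# -- tracks ------------------------------------------------------------

def write_tracks(tracks: list[Track], path: str | Path) -> None:
    frames_per_track = [np.round(t.t_s / np.median(np.diff(t.t_s))).astype(int) for t in tracks]
    rows = []
    for tr, fr in zip(tracks, frames_per_track):
        for f, t_s, x, y in zip(fr, tr.t_s, tr.x_nm, tr.y_nm):
            rows.append((tr.track_id, int(f), t_s, x, y))
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    _atomic_write(path, lambda tmp: df.to_csv(tmp, index=False, float_format="%.17g"))


def read_tracks(path: str | Path) -> list[Track]:
    df = _read_csv_checked(path, TRACK_COLUMNS)
    tracks = []
    for tid, grp in df.groupby("track_id"):
        grp = grp.sort_values("frame")
        tracks.append(
            Track(track_id=int(tid), t_s=grp["t_s"].to_numpy(),
                  x_nm=grp["x_nm"].to_numpy(), y_nm=grp["y_nm"].to_numpy())
        )
    return tracks


# -- outlines ----------------------------------------------------------

def write_outlines(outlines: list[OrganelleOutline], path: str | Path) -> None:
    rows = []
    for o in outlines:
        for i, (x, y) in enumerate(o.vertices_px):
            rows.append((o.organelle_id, i, x, y))
    df = pd.DataFrame(rows, columns=OUTLINE_COLUMNS)
    _atomic_write(path, lambda tmp: df.to_csv(tmp, index=False, float_format="%.17g"))


def read_outlines(path: str | Path) -> list[OrganelleOutline]:
    df = _read_csv_checked(path, OUTLINE_COLUMNS)
    outlines = []
    for oid, grp in df.groupby("organelle_id"):
        grp = grp.sort_values("vertex_index")
        outlines.append(
            OrganelleOutline(organelle_id=int(oid),
                             vertices_px=grp[["x_px", "y_px"]].to_numpy())
        )
    return outlines


# -- drift traces ------------------------------------------------------

def write_drift_trace(trace: DriftTrace, path: str | Path) -> None:
    df = pd.DataFrame(
        {"frame": np.arange(trace.n_frames), "dx_px": trace.dx_px, "dy_px": trace.dy_px}
    )
    _atomic_write(path, lambda tmp: df.to_csv(tmp, index=False, float_format="%.17g"))


def read_drift_trace(path: str | Path) -> DriftTrace:
    df = _read_csv_checked(path, DRIFT_COLUMNS)
    df = df.sort_values("frame")
    return DriftTrace(df["dx_px"].to_numpy(), df["dy_px"].to_numpy())


# -- TIFF stacks -------------------------------------------------------

def write_stack(stack: FrameStack, path: str | Path) -> None:
    """Write a movie as multi-page 16-bit (or 32-bit float) grayscale TIFF."""
    frames = stack.frames
    if frames.dtype not in (np.uint16, np.float32):
        frames = (
            frames.astype(np.float32)
            if np.issubdtype(frames.dtype, np.floating)
            else np.clip(frames, 0, 65535).astype(np.uint16)
        )
    _atomic_write(path, lambda tmp: tifffile.imwrite(tmp, frames, photometric="minisblack"))


def read_stack(path: str | Path, pixel_size_um: float, frame_interval_s: float) -> FrameStack:
    """Read a multi-page grayscale TIFF as a movie.

    Acquisition metadata (pixel size, frame interval) comes from the
    caller's config, not TIFF tags.  RGB or malformed files raise.
    """
    try:
        frames = tifffile.imread(path)
    except Exception as e:
        raise ValueError(f"cannot read TIFF {path}: {e}") from e
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None, :, :]
    if frames.ndim != 3:
        raise ValueError(f"{path}: expected grayscale pages, got shape {frames.shape}")
    return FrameStack(frames, pixel_size_um, frame_interval_s)


# -- shift report ------------------------------------------------------

def write_shift_report(shift, path: str | Path) -> None:
    text = (
        f"dx_nm: {shift.dx_nm:.6g}\n"
        f"dy_nm: {shift.dy_nm:.6g}\n"
        f"n_beads: {shift.n_beads}\n"
        f"residual_rms_nm: {shift.residual_rms_nm:.6g}\n"
    )
    _atomic_write(path, lambda tmp: Path(tmp).write_text(text))
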