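"""Core in-memory containers shared across the pipeline.

Molecule lists are plain :class:`pandas.DataFrame` objects with the
canonical column set ``frame, x_px, y_px, photons, sigma_px, background,
channel`` (see :data:`MOLECULE_COLUMNS`).  Coordinates are 0-based
camera pixels with a pixel-centre convention; conversions to nm always
go through a pixel size in µm/px.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical molecule-list columns, in file order.
MOLECULE_COLUMNS = ["frame", "x_px", "y_px", "photons", "sigma_px", "background", "channel"]


def empty_molecule_list() -> pd.DataFrame:
    """Return an empty molecule list with the canonical columns."""
    return pd.DataFrame({c: pd.Series(dtype=float) for c in MOLECULE_COLUMNS}).astype(
        {"frame": int, "channel": int}
    )


def validate_molecule_list(molecules: pd.DataFrame) -> pd.DataFrame:
    """Check the canonical columns are present; raise ``ValueError`` otherwise."""
    missing = [c for c in MOLECULE_COLUMNS if c not in molecules.columns]
    if missing:
        raise ValueError(f"molecule list missing required column(s): {missing}")
    return molecules


@dataclass
class FrameStack:
    """A raw movie: frames indexed (t, y, x) with acquisition metadata."""

    frames: np.ndarray  # (n_frames, height, width)
    pixel_size_um: float
    frame_interval_s: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be 3D (t, y, x), got shape {self.frames.shape}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape


@dataclass
class Track:
    """Per-frame centroid positions of one organelle, in nm.

    Timestamps must be strictly increasing and a track has at least two
    points.
    """

    track_id: int
    t_s: np.ndarray
    x_nm: np.ndarray
    y_nm: np.ndarray

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.x_nm = np.asarray(self.x_nm, dtype=float)
        self.y_nm = np.asarray(self.y_nm, dtype=float)
        n = len(self.t_s)
        if n < 2:
            raise ValueError("a track needs at least 2 points")
        if len(self.x_nm) != n or len(self.y_nm) != n:
            raise ValueError("t_s, x_nm, y_nm must have equal length")
        if np.any(np.diff(self.t_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t_s)

    @property
    def positions_nm(self) -> np.ndarray:
        return np.column_stack([self.x_nm, self.y_nm])


@dataclass
class DriftTrace:
    """Per-frame (dx, dy) drift correction in camera pixels.

    The correction for the reference subset (the first) is (0, 0); the
    trace length equals the movie frame count.
    """

    dx_px: np.ndarray
    dy_px: np.ndarray
    subset_bounds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dx_px = np.asarray(self.dx_px, dtype=float)
        self.dy_px = np.asarray(self.dy_px, dtype=float)
        if self.dx_px.shape != self.dy_px.shape:
            raise ValueError("dx_px and dy_px must have the same length")

    @property
    def n_frames(self) -> int:
        return len(self.dx_px)

    def negated(self) -> "DriftTrace":
        return DriftTrace(-self.dx_px, -self.dy_px, list(self.subset_bounds))


@dataclass
class StormImage:
    """Super-resolution render: a 2D count grid at a fine pixel size.

    In histogram mode the grid sums to the number of rendered
    localizations exactly.
    """

    grid: np.ndarray
    render_px_um: float
    origin_px: tuple[float, float] = (0.0, 0.0)  # camera-px position of grid[0, 0] corner

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("grid must be 2D")
        if np.any(self.grid < 0):
            raise ValueError("grid counts must be non-negative")


@dataclass
class ChannelShift:
    """Translation between two sequentially acquired channels, from beads."""

    dx_nm: float
    dy_nm: float
    n_beads: int
    residual_rms_nm: float

    def __post_init__(self) -> None:
        if self.residual_rms_nm < 0:
            raise ValueError("residual RMS must be >= 0")


@dataclass
class OrganelleOutline:
    """Closed polygon outline of one mitochondrion, camera-px vertices."""

    organelle_id: int
    vertices_px: np.ndarray  # (n, 2) x, y; closed implicitly (last != first required)
    channel: int = 0

    def __post_init__(self) -> None:
        self.vertices_px = np.asarray(self.vertices_px, dtype=float)
        if self.vertices_px.ndim != 2 or self.vertices_px.shape[1] != 2:
            raise ValueError("vertices_px must be (n, 2)")
        if len(self.vertices_px) < 3:
            raise ValueError("a polygon needs at least 3 vertices")


@dataclass
class GroundTruth:
    """Validation scaffold recorded by the simulator.

    Every rendered photon event maps to one ground-truth emitter;
    ``drift_px`` has one row per frame.
    """

    emitter_positions_px: np.ndarray  # (n_emitters, 2)
    active_sets: list[np.ndarray]  # per frame: indices of active emitters
    drift_px: np.ndarray  # (n_frames, 2) cumulative drift
    fiducial_positions_px: dict = field(default_factory=dict)  # channel -> (n, 2)
    track_labels: list[str] = field(default_factory=list)
    tracks: list = field(default_factory=list)
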