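"""Configuration objects for simulation and pipeline runs.

All tunable parameters live here with physical units in their names.
Configs round-trip losslessly through YAML (`to_yaml` / `from_yaml`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: Camera pixel size in the sample plane (µm per pixel, each direction).
DEFAULT_PIXEL_SIZE_UM = 0.157


@dataclass
class SimulationConfig:
    """Parameters of the synthetic STORM / live-cell forward model.

    The defaults describe the acquisition regime the analysis targets:
    a 0.157 µm camera pixel, 20 frames/s live imaging, a ~150 nm PSF
    sigma, bright organic-dye photon budgets, and sparse Bernoulli
    blinking.  Motion-class parameters describe three regimes of
    mitochondrial movement: docked organelles confined to ~192 nm,
    mobile-but-confined organelles ranging over ~414 nm, and organelles
    undergoing processive runs at ~700 nm/s with ~1570 nm net transport.
    """

    rng_seed: int = 0
    field_size_px: tuple[int, int] = (64, 64)
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    n_frames: int = 2000
    frame_interval_s: float = 0.05
    psf_sigma_px: float = 1.0
    photons_per_event: float = 5000.0
    background_per_px: float = 10.0
    label_density_per_um2: float = 3000.0
    drift_rate_nm_per_frame: tuple[float, float] = (0.0, 0.0)
    n_fiducials: int = 5
    channel_shift_nm: tuple[float, float] = (50.0, -30.0)
    motion_class_fractions: tuple[float, float, float] = (0.105, 0.836, 0.059)

    # Blinking: per-frame independent Bernoulli activation, no dark-state
    # memory.  Photokinetic realism is a non-goal.
    duty_cycle: float = 5e-4

    # Organelle geometry (tube-like shapes).
    n_organelles: int = 5
    organelle_width_um: tuple[float, float] = (0.2, 1.0)
    organelle_length_um: tuple[float, float] = (0.5, 5.0)
    membrane_band_nm: float = 40.0

    # Motion model: confined walk with exponential relaxation plus, for the
    # fast class, one constant-velocity processive run.
    stationary_max_disp_nm: float = 192.0
    slow_max_disp_nm: float = 414.0
    run_speed_nm_s: float = 700.0
    run_net_disp_nm: float = 1570.0
    track_level_cv: float = 0.15
    confinement_tau_s: float = 5.0

    def __post_init__(self) -> None:
        self.field_size_px = tuple(int(v) for v in self.field_size_px)
        self.drift_rate_nm_per_frame = tuple(float(v) for v in self.drift_rate_nm_per_frame)
        self.channel_shift_nm = tuple(float(v) for v in self.channel_shift_nm)
        self.organelle_width_um = tuple(float(v) for v in self.organelle_width_um)
        self.organelle_length_um = tuple(float(v) for v in self.organelle_length_um)
        self.motion_class_fractions = tuple(float(v) for v in self.motion_class_fractions)
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        for name in ("n_frames", "n_fiducials", "n_organelles"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("photons_per_event", "background_per_px", "label_density_per_um2", "duty_cycle"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if abs(sum(self.motion_class_fractions) - 1.0) > 1e-9:
            raise ValueError("motion_class_fractions must sum to 1 within 1e-9")
        if any(f < 0 for f in self.motion_class_fractions):
            raise ValueError("motion_class_fractions must be non-negative")

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class PipelineConfig:
    """End-to-end run configuration binding all analysis stages.

    Every stage parameter has a default so an empty config runs the full
    synthetic preset.  ``stages`` toggles individual steps.
    """

    seed: int = 0
    out_dir: str = "mitostorm_run"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    stages: dict = field(
        default_factory=lambda: {
            "simulate": True,
            "localize": True,
            "driftcorrect": True,
            "register": True,
            "render": True,
            "quantify": True,
            "classify": True,
            "report": True,
        }
    )

    # Localization stage
    intensity_threshold: float = 80.0
    min_separation_px: float = 3.0
    fit_window_px: int = 7

    # Post-processing stage
    drift_subset_frames: int = 500
    render_px_um: float = 0.0157
    bead_match_radius_nm: float = 500.0

    # Quantification stage
    precision_nm_override: float | None = None
    nyquist_factor: float = 2.0

    # Dynamics stage
    window_frames: int = 500
    confinement_threshold_nm: float = 290.0
    run_speed_threshold_nm_s: float = 500.0
    run_min_duration_s: float = 1.0
    run_persistence_min_cos: float = 0.5
    fast_net_disp_threshold_nm: float = 1000.0
    contact_distance_nm: float = 100.0

    # Statistics stage
    alpha: float = 0.001
    holm_correction: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = self.simulation.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "simulation" in d and isinstance(d["simulation"], dict):
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
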