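"""Shared fixtures: small ground-truthed synthetic datasets.

The expensive STORM simulation + localization run is session-scoped so
fidelity, precision and invariant tests share one movie.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as hyp_settings

import mitostorm as ms

hyp_settings.register_profile("deterministic", derandomize=True)
hyp_settings.load_profile("deterministic")
from mitostorm.config import SimulationConfig
from mitostorm.datatypes import MOLECULE_COLUMNS


def make_molecule_list(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=MOLECULE_COLUMNS)


def drifting_molecule_list(
    n_frames: int,
    drift_rate_px: tuple[float, float],
    n_emitters: int = 200,
    events_per_frame: float = 2.0,
    loc_sigma_px: float = 8.0 / 157.0,
    seed: int = 11,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Molecule list of blinking emitters under known cumulative drift.

    Returns (molecules, true cumulative drift (n_frames, 2) in px).
    """
    rng = np.random.default_rng(seed)
    pts = rng.uniform(10, 50, (n_emitters, 2))
    rate = np.asarray(drift_rate_px)
    rows = []
    for t in range(n_frames):
        k = rng.poisson(events_per_frame)
        idx = rng.integers(0, n_emitters, k)
        xy = pts[idx] + rate * t + rng.normal(0, loc_sigma_px, (k, 2))
        for x, y in xy:
            rows.append((t, x, y, 5000.0, 1.0, 10.0, 0))
    true = np.arange(n_frames)[:, None] * rate[None, :]
    return make_molecule_list(rows), true


@dataclass
class StormSim:
    config: SimulationConfig
    outlines: list
    emitters_px: np.ndarray
    fiducials_px: np.ndarray
    stack: object
    truth: object
    molecules: pd.DataFrame


@pytest.fixture(scope="session")
def storm_sim() -> StormSim:
    """One localized synthetic STORM movie with known emitters."""
    cfg = SimulationConfig(
        rng_seed=2, n_frames=400, field_size_px=(48, 48), n_organelles=2, n_fiducials=2
    )
    outlines = ms.simulate_mitochondria(cfg)
    rng = np.random.default_rng(2)
    emitters = np.vstack(
        [ms.scatter_labels(o, cfg.label_density_per_um2, cfg.pixel_size_um, rng)
         for o in outlines]
    )
    fiducials = ms.plant_fiducials(cfg, avoid=outlines)[0]
    stack, truth = ms.simulate_storm_movie(cfg, emitters, fiducials_px=fiducials)
    molecules = ms.localize_movie(stack, ms.DetectionParams())
    return StormSim(cfg, outlines, emitters, fiducials, stack, truth, molecules)


def match_events(sim: StormSim, radius_px: float = 1.0, isolated_only: bool = True,
                 isolation_px: float = 5.0):
    """Match localized molecules to ground-truth blink events.

    With ``isolated_only`` the denominator is restricted to events with
    no co-active emitter within ``isolation_px`` — overlapping emitters
    are not deconvolved by single-Gaussian fitting, so only isolated
    events are in scope for the recall contract.
    Returns (n_events, n_matched, matched distances in px).
    """
    n_events = 0
    dists = []
    for t, active in enumerate(sim.truth.active_sets):
        sub = sim.molecules[sim.molecules["frame"] == t][["x_px", "y_px"]].to_numpy()
        for i in active:
            if isolated_only and len(active) > 1:
                others = sim.emitters_px[[j for j in active if j != i]]
                if np.hypot(*(others - sim.emitters_px[i]).T).min() <= isolation_px:
                    continue
            n_events += 1
            if len(sub):
                d = np.hypot(*(sub - sim.emitters_px[i]).T)
                if d.min() <= radius_px:
                    dists.append(float(d.min()))
    return n_events, len(dists), np.asarray(dists)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
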