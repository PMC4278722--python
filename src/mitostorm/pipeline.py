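"""End-to-end pipeline runs with a reproducibility manifest.

``run_pipeline`` executes the stages in dependency order —
simulate, localize, driftcorrect, register, render, quantify, classify,
report — writing every intermediate artifact to the output directory
plus a JSON manifest with the config snapshot and per-file SHA-256
checksums.  Deterministic stages reproduce identical checksums when
re-run with the same config.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import dynamics, io, localization, postprocess, quant, simulate, stats
from .config import PipelineConfig
from .datatypes import FrameStack


class PipelineError(RuntimeError):
    """A stage is missing an upstream artifact or misconfigured."""


@dataclasses.dataclass
class RunManifest:
    config: dict
    version: str
    stages_completed: list
    checksums: dict
    started: str
    finished: str = ""

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _require(out: Path, name: str, needed_by: str, produced_by: str) -> Path:
    p = out / name
    if not p.exists():
        raise PipelineError(
            f"stage '{needed_by}' needs {name}; run the '{produced_by}' stage first"
        )
    return p


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run the enabled stages end to end on the synthetic preset.

    Returns the manifest; all artifacts land in ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    started = datetime.datetime.now().isoformat(timespec="seconds")
    completed: list[str] = []
    config.to_yaml(out / "config.yaml")

    if config.stages.get("simulate", True):
        outlines = simulate.simulate_mitochondria(sim)
        rng = simulate.rng_stream(sim.rng_seed, "labels")
        emitters = np.vstack(
            [simulate.scatter_labels(o, sim.label_density_per_um2, sim.pixel_size_um, rng,
                                     band_nm=sim.membrane_band_nm)
             for o in outlines]
        )
        fid = simulate.plant_fiducials(sim, true_shift_nm=sim.channel_shift_nm,
                                       avoid=outlines)
        stack, truth = simulate.simulate_storm_movie(sim, emitters, fiducials_px=fid[0])
        io.write_stack(stack, out / "raw_storm.tif")
        io.write_outlines(outlines, out / "outlines.csv")
        pd.DataFrame(emitters, columns=["x_px", "y_px"]).to_csv(
            out / "true_emitters.csv", index=False)
        pd.DataFrame(truth.drift_px, columns=["dx_px", "dy_px"]).to_csv(
            out / "true_drift.csv", index=False)
        for ch, pos in fid.items():
            pd.DataFrame(pos, columns=["x_px", "y_px"]).to_csv(
                out / f"true_fiducials_ch{ch}.csv", index=False)
        tracks, labels = simulate.simulate_tracks(sim, n_tracks=max(sim.n_organelles, 3),
                                                  window_frames=config.window_frames)
        io.write_tracks(tracks, out / "tracks.csv")
        pd.DataFrame({"track_id": [t.track_id for t in tracks], "motion_class": labels}).to_csv(
            out / "true_labels.csv", index=False)
        completed.append("simulate")

    if config.stages.get("localize", True):
        stack = io.read_stack(_require(out, "raw_storm.tif", "localize", "simulate"),
                              sim.pixel_size_um, sim.frame_interval_s)
        params = localization.DetectionParams(
            intensity_threshold=config.intensity_threshold,
            min_separation_px=config.min_separation_px,
            fit_window_px=config.fit_window_px,
        )
        molecules = localization.localize_movie(stack, params)
        io.write_molecule_list(molecules, out / "molecules.csv")
        completed.append("localize")

    if config.stages.get("driftcorrect", True):
        molecules = io.read_molecule_list(
            _require(out, "molecules.csv", "driftcorrect", "localize"))
        trace = postprocess.estimate_drift(
            molecules, n_frames=sim.n_frames, pixel_size_um=sim.pixel_size_um,
            subset_size=config.drift_subset_frames, field_size_px=sim.field_size_px)
        corrected = postprocess.apply_drift(molecules, trace)
        io.write_drift_trace(trace, out / "drift_trace.csv")
        io.write_molecule_list(corrected, out / "molecules_driftcorr.csv")
        completed.append("driftcorrect")

    if config.stages.get("register", True):
        molecules = io.read_molecule_list(
            _require(out, "molecules_driftcorr.csv", "register", "driftcorrect"))
        beads, bead_locs, _ = localization.identify_beads(molecules, sim.n_frames)
        if len(beads) == 0:
            raise PipelineError("stage 'register' found no persistent fiducial beads")
        shift_px = np.asarray(sim.channel_shift_nm) * 1e-3 / sim.pixel_size_um
        shift = postprocess.register_channels(
            beads, beads + shift_px, sim.pixel_size_um,
            match_radius_nm=config.bead_match_radius_nm)
        io.write_shift_report(shift, out / "channel_shift.txt")
        completed.append("register")

    if config.stages.get("render", True):
        molecules = io.read_molecule_list(
            _require(out, "molecules_driftcorr.csv", "render", "driftcorrect"))
        image = postprocess.render(molecules, config.render_px_um, sim.pixel_size_um,
                                   field_size_px=sim.field_size_px)
        io.write_stack(
            FrameStack(image.grid[None].astype(np.float32), config.render_px_um,
                       sim.frame_interval_s),
            out / "storm_image.tif")
        completed.append("render")

    if config.stages.get("quantify", True):
        molecules = io.read_molecule_list(
            _require(out, "molecules_driftcorr.csv", "quantify", "driftcorrect"))
        outlines = io.read_outlines(_require(out, "outlines.csv", "quantify", "simulate"))
        if config.precision_nm_override is not None:
            precision = config.precision_nm_override
        else:
            _, bead_locs, _ = localization.identify_beads(molecules, sim.n_frames)
            precision = localization.estimate_localization_precision(
                bead_locs, sim.pixel_size_um)
        records = quant.quantify_organelles(
            molecules, outlines, sim.pixel_size_um, precision,
            nyquist_factor=config.nyquist_factor)
        records.to_csv(out / "records.csv", index=False)
        completed.append("quantify")

    if config.stages.get("classify", True):
        tracks = io.read_tracks(_require(out, "tracks.csv", "classify", "simulate"))
        clf = dynamics.MotionClassifier(
            window_frames=config.window_frames,
            confinement_threshold_nm=config.confinement_threshold_nm,
            run_speed_threshold_nm_s=config.run_speed_threshold_nm_s,
            run_min_duration_s=config.run_min_duration_s,
            run_persistence_min_cos=config.run_persistence_min_cos,
            fast_net_disp_threshold_nm=config.fast_net_disp_threshold_nm,
        ).fit()
        motion = clf.predict(tracks)
        outlines = io.read_outlines(_require(out, "outlines.csv", "classify", "simulate"))
        interaction = dynamics.classify_interaction(
            outlines, sim.pixel_size_um, config.contact_distance_nm)
        rows = []
        for tr, m in zip(tracks, motion):
            met = clf.metrics(tr)
            rows.append({
                "id": tr.track_id, "motion_class": m,
                "interaction_class": interaction.get(tr.track_id, "isolated"),
                "max_disp_nm": met.max_displacement_nm,
                "mean_speed_nm_s": met.mean_speed_nm_s,
                "peak_run_speed_nm_s": met.peak_run_speed_nm_s,
                "net_disp_nm": met.net_displacement_nm,
            })
        pd.DataFrame(rows).to_csv(out / "classification.csv", index=False)
        completed.append("classify")

    if config.stages.get("report", True):
        cls = pd.read_csv(_require(out, "classification.csv", "report", "classify"))
        table = stats.build_category_table(
            list(zip(cls["motion_class"], cls["interaction_class"])))
        table.counts.to_csv(out / "category_counts.csv")
        table.percentages.to_csv(out / "category_percentages.csv")
        records = pd.read_csv(_require(out, "records.csv", "report", "quantify"))
        merged = records.merge(cls[["id", "motion_class"]], on="id", how="inner")
        lines = [f"grand total: {table.grand_total}"]
        if merged["motion_class"].nunique() >= 2 and (merged.groupby("motion_class")
                                                      .size() >= 2).sum() >= 2:
            summary, tests = stats.summarize_by_category(
                merged, category_col="motion_class", alpha=config.alpha,
                holm=config.holm_correction)
            summary.to_csv(out / "category_summary.csv", index=False)
            tests.to_csv(out / "category_tests.csv", index=False)
            lines.append(f"pairwise tests: {len(tests)} at alpha={config.alpha}")
        (out / "report.txt").write_text("\n".join(lines) + "\n")
        completed.append("report")

    checksums = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.suffix in {".csv", ".tif", ".txt", ".yaml"}
    }
    manifest = RunManifest(
        config=config.to_dict(), version=__version__, stages_completed=completed,
        checksums=checksums, started=started,
        finished=datetime.datetime.now().isoformat(timespec="seconds"),
    )
    manifest.to_json(out / "manifest.json")
    return manifest
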