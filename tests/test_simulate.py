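"""Forward-model tests: geometry, labels, movies, fiducials, tracks."""

import numpy as np
import pytest

import mitostorm as ms
from mitostorm.config import SimulationConfig
from mitostorm.quant import polygon_area_um2
from mitostorm.simulate import (
    drift_trace_px,
    fiducial_localizations,
    rng_stream,
    simulate_livecell_movie,
)


class TestGeometry:
    def test_single_organelle_closed_polygon_with_plausible_area(self):
        cfg = SimulationConfig(rng_seed=1, field_size_px=(64, 64), n_organelles=1)
        outlines = ms.simulate_mitochondria(cfg)
        assert len(outlines) == 1
        area = polygon_area_um2(outlines[0], cfg.pixel_size_um)
        assert 0.1 <= area <= 5.0

    def test_same_seed_reproduces_identical_polygons(self):
        cfg = SimulationConfig(rng_seed=7, n_organelles=3)
        a = ms.simulate_mitochondria(cfg)
        b = ms.simulate_mitochondria(cfg)
        for oa, ob in zip(a, b):
            np.testing.assert_array_equal(oa.vertices_px, ob.vertices_px)

    def test_many_organelles_stay_inside_field_bounds(self):
        cfg = SimulationConfig(
            rng_seed=3, field_size_px=(256, 256), n_organelles=50,
            organelle_length_um=(0.5, 2.0),
        )
        outlines = ms.simulate_mitochondria(cfg)
        assert len(outlines) == 50
        for o in outlines:
            v = o.vertices_px
            assert v[:, 0].min() >= 0 and v[:, 0].max() <= 256
            assert v[:, 1].min() >= 0 and v[:, 1].max() <= 256

    def test_impossible_placement_fails_informatively(self):
        cfg = SimulationConfig(rng_seed=1, field_size_px=(48, 48), n_organelles=200)
        with pytest.raises(RuntimeError, match="could not place"):
            ms.simulate_mitochondria(cfg)

    def test_field_too_small_for_shape_errors(self):
        cfg = SimulationConfig(rng_seed=1, field_size_px=(3, 3), n_organelles=1)
        with pytest.raises(ValueError, match="too small"):
            ms.simulate_mitochondria(cfg)


class TestScatterLabels:
    @pytest.fixture()
    def square_um2(self):
        # 2 um^2 band area: a band of width 0.04 um needs perimeter 50 um;
        # easier to check against the band area computed by shapely itself.
        cfg = SimulationConfig(rng_seed=5, field_size_px=(128, 128), n_organelles=1)
        return ms.simulate_mitochondria(cfg)[0], cfg

    def test_count_is_poisson_with_band_area_mean(self, square_um2):
        from shapely.geometry import Polygon

        outline, cfg = square_um2
        poly = Polygon(outline.vertices_px)
        half = 20e-3 / cfg.pixel_size_um
        band_area_um2 = (
            poly.buffer(half).difference(poly.buffer(-half)).area * cfg.pixel_size_um**2
        )
        density = 1000.0
        counts = [
            len(ms.scatter_labels(outline, density, cfg.pixel_size_um,
                                  np.random.default_rng(s)))
            for s in range(100)
        ]
        mean_expected = density * band_area_um2
        se = np.sqrt(mean_expected / 100)
        assert abs(np.mean(counts) - mean_expected) < 4 * se

    def test_doubling_density_doubles_mean_count(self, square_um2):
        outline, cfg = square_um2
        c1 = np.mean([
            len(ms.scatter_labels(outline, 500, cfg.pixel_size_um, np.random.default_rng(s)))
            for s in range(100)])
        c2 = np.mean([
            len(ms.scatter_labels(outline, 1000, cfg.pixel_size_um,
                                  np.random.default_rng(1000 + s)))
            for s in range(100)])
        assert c2 / c1 == pytest.approx(2.0, rel=0.1)

    def test_zero_density_gives_no_emitters(self, square_um2, rng):
        outline, cfg = square_um2
        assert len(ms.scatter_labels(outline, 0.0, cfg.pixel_size_um, rng)) == 0

    def test_zero_area_geometry_errors(self, rng):
        degenerate = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(ValueError):
            ms.scatter_labels(degenerate, 100.0, 0.157, rng)

    def test_labels_lie_in_membrane_band(self, square_um2, rng):
        from shapely.geometry import Polygon

        outline, cfg = square_um2
        pts = ms.scatter_labels(outline, 2000, cfg.pixel_size_um, rng, band_nm=40)
        poly = Polygon(outline.vertices_px)
        half = 20e-3 / cfg.pixel_size_um
        band = poly.buffer(half * 1.001).difference(poly.buffer(-half * 1.001))
        import shapely

        assert shapely.contains_xy(band, pts[:, 0], pts[:, 1]).all()


class TestStormMovie:
    def test_noiseless_single_emitter_centroid_matches_position(self):
        cfg = SimulationConfig(
            rng_seed=1, n_frames=3, field_size_px=(32, 32),
            duty_cycle=1.0, background_per_px=0.0,
        )
        pos = np.array([[15.3, 16.7]])
        stack, _ = ms.simulate_storm_movie(cfg, pos, poisson_noise=False)
        frame = stack.frames[0]
        yy, xx = np.mgrid[0:32, 0:32]
        cx = (frame * xx).sum() / frame.sum()
        cy = (frame * yy).sum() / frame.sum()
        assert cx == pytest.approx(15.3, abs=1e-6)
        assert cy == pytest.approx(16.7, abs=1e-6)

    def test_zero_photons_gives_pure_background(self):
        cfg = SimulationConfig(
            rng_seed=1, n_frames=50, field_size_px=(24, 24),
            photons_per_event=0.0, background_per_px=7.0, duty_cycle=0.5,
        )
        stack, _ = ms.simulate_storm_movie(cfg, np.array([[12.0, 12.0]]))
        mean = stack.frames.mean()
        se = np.sqrt(7.0 / stack.frames.size)
        assert abs(mean - 7.0) < 4 * se

    def test_zero_drift_config_records_zero_drift_truth(self):
        cfg = SimulationConfig(rng_seed=1, n_frames=20, field_size_px=(24, 24))
        _, truth = ms.simulate_storm_movie(cfg, np.array([[12.0, 12.0]]))
        assert np.all(truth.drift_px == 0)
        assert len(truth.drift_px) == 20

    def test_photon_conservation_over_frames(self):
        cfg = SimulationConfig(
            rng_seed=9, n_frames=150, field_size_px=(32, 32),
            photons_per_event=2000.0, background_per_px=5.0, duty_cycle=0.05,
        )
        emitters = np.random.default_rng(0).uniform(8, 24, (50, 2))
        stack, truth = ms.simulate_storm_movie(cfg, emitters)
        n_active = np.array([len(a) for a in truth.active_sets])
        expected = n_active * 2000.0 + 32 * 32 * 5.0
        totals = stack.frames.sum(axis=(1, 2)).astype(float)
        resid = totals - expected
        se = np.sqrt(expected.mean() / len(totals))  # Poisson: var = mean
        assert abs(resid.mean()) < 3 * se

    def test_identical_config_bit_identical_movie(self):
        cfg = SimulationConfig(rng_seed=4, n_frames=10, field_size_px=(24, 24))
        em = np.array([[10.0, 11.0], [15.0, 8.0]])
        s1, _ = ms.simulate_storm_movie(cfg, em)
        s2, _ = ms.simulate_storm_movie(cfg, em)
        np.testing.assert_array_equal(s1.frames, s2.frames)


class TestFiducials:
    def test_zero_shift_gives_identical_channels(self):
        cfg = SimulationConfig(rng_seed=2, n_fiducials=5)
        fid = ms.plant_fiducials(cfg, true_shift_nm=(0.0, 0.0))
        np.testing.assert_array_equal(fid[0], fid[1])

    def test_known_shift_is_exact_per_bead(self):
        cfg = SimulationConfig(rng_seed=2, n_fiducials=4)
        fid = ms.plant_fiducials(cfg, true_shift_nm=(50.0, -30.0))
        diff_nm = (fid[1] - fid[0]) * cfg.pixel_size_um * 1e3
        np.testing.assert_allclose(diff_nm, np.tile([50.0, -30.0], (4, 1)), atol=1e-9)

    def test_noisy_localizations_recover_shift_within_standard_error(self, rng):
        cfg = SimulationConfig(rng_seed=2, n_fiducials=5)
        fid = ms.plant_fiducials(cfg, true_shift_nm=(50.0, -30.0))
        sigma_nm = 10.0
        noisy_b = fid[1] + rng.normal(0, sigma_nm * 1e-3 / cfg.pixel_size_um, fid[1].shape)
        diff_nm = (noisy_b - fid[0]).mean(axis=0) * cfg.pixel_size_um * 1e3
        tol = 3 * sigma_nm / np.sqrt(5)
        assert abs(diff_nm[0] - 50.0) < tol
        assert abs(diff_nm[1] + 30.0) < tol

    def test_fiducial_localizations_scatter_matches_sigma(self, rng):
        beads = np.array([[10.0, 10.0]])
        locs = fiducial_localizations(beads, 2000, 8.0, 0.157, rng)
        sd_nm = locs["x_px"].std(ddof=1) * 157
        assert sd_nm == pytest.approx(8.0, rel=0.1)


class TestTracks:
    def test_stationary_mean_max_displacement_in_printed_envelope(self):
        cfg = SimulationConfig(rng_seed=6, n_frames=500,
                               motion_class_fractions=(1.0, 0.0, 0.0))
        tracks, labels = ms.simulate_tracks(cfg, 200)
        assert set(labels) == {"stationary"}
        maxes = [
            np.hypot(t.x_nm - t.x_nm[0], t.y_nm - t.y_nm[0]).max() for t in tracks
        ]
        assert 101 <= np.mean(maxes) <= 283

    def test_zero_amplitude_limit_gives_zero_displacement(self):
        cfg = SimulationConfig(
            rng_seed=6, n_frames=500, motion_class_fractions=(1.0, 0.0, 0.0),
            stationary_max_disp_nm=0.0, track_level_cv=0.0,
        )
        tracks, _ = ms.simulate_tracks(cfg, 5)
        for t in tracks:
            assert np.hypot(t.x_nm - t.x_nm[0], t.y_nm - t.y_nm[0]).max() == 0.0

    def test_fast_tracks_sustain_processive_speed(self):
        cfg = SimulationConfig(rng_seed=6, n_frames=500,
                               motion_class_fractions=(0.0, 0.0, 1.0))
        tracks, labels = ms.simulate_tracks(cfg, 30)
        assert set(labels) == {"dynamic-fast"}
        dt = cfg.frame_interval_s
        win = int(round(1.0 / dt))
        for t in tracks:
            pos = t.positions_nm
            net = np.linalg.norm(pos[win:] - pos[:-win], axis=1)
            assert (net / (win * dt)).max() >= 500.0

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(motion_class_fractions=(0.5, 0.5, 0.5))

    def test_short_movie_rejected(self):
        cfg = SimulationConfig(rng_seed=1, n_frames=100)
        with pytest.raises(ValueError, match="window"):
            ms.simulate_tracks(cfg, 5)

    def test_determinism_and_class_separability(self):
        cfg = SimulationConfig(rng_seed=8, n_frames=500,
                               motion_class_fractions=(0.5, 0.5, 0.0))
        t1, l1 = ms.simulate_tracks(cfg, 200)
        t2, l2 = ms.simulate_tracks(cfg, 200)
        assert l1 == l2
        np.testing.assert_array_equal(t1[0].x_nm, t2[0].x_nm)
        maxes = np.array([
            np.hypot(t.x_nm - t.x_nm[0], t.y_nm - t.y_nm[0]).max() for t in t1
        ])
        lab = np.array(l1)
        res = ms.welch_ttest(maxes[lab == "stationary"][:100],
                             maxes[lab == "dynamic-slow"][:100], alpha=0.01)
        assert res.p < 0.01


def test_drift_trace_follows_configured_rate():
    cfg = SimulationConfig(rng_seed=1, n_frames=100,
                           drift_rate_nm_per_frame=(0.5, -0.25))
    trace = drift_trace_px(cfg)
    np.testing.assert_allclose(
        trace[-1] * cfg.pixel_size_um * 1e3, [99 * 0.5, -99 * 0.25], rtol=1e-12
    )


def test_livecell_movie_renders_blobs_at_track_positions():
    cfg = SimulationConfig(rng_seed=3, n_frames=500, field_size_px=(48, 48))
    tracks, _ = ms.simulate_tracks(cfg, 2)
    movie = simulate_livecell_movie(cfg, tracks, poisson_noise=False)
    frame = np.asarray(movie.frames[0], dtype=float) - cfg.background_per_px
    # brightest pixel should be near one of the track starts
    iy, ix = np.unravel_index(frame.argmax(), frame.shape)
    starts = np.array([[t.x_nm[0], t.y_nm[0]] for t in tracks]) * 1e-3 / cfg.pixel_size_um
    assert np.hypot(starts[:, 0] - ix, starts[:, 1] - iy).min() < 2.0


def test_rng_streams_are_independent_and_stable():
    a = rng_stream(5, "movie").integers(0, 1 << 30, 3)
    b = rng_stream(5, "tracks").integers(0, 1 << 30, 3)
    a2 = rng_stream(5, "movie").integers(0, 1 << 30, 3)
    np.testing.assert_array_equal(a, a2)
    assert not np.array_equal(a, b)
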