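"""Track metrics, motion/interaction classification and tracking tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mitostorm as ms
from mitostorm.datatypes import OrganelleOutline, Track
from mitostorm.dynamics import DynamicsMetrics, detect_blob_centroids

PX = 0.157


def straight_track(speed_nm_per_frame=10.0, fps=20.0, n=500, tid=0):
    t = np.arange(n) / fps
    x = np.arange(n) * speed_nm_per_frame
    return Track(tid, t, x, np.zeros(n))


class TestMetrics:
    def test_constant_position_gives_all_zero_metrics(self):
        tr = Track(0, np.arange(500) / 20.0, np.full(500, 5.0), np.full(500, -3.0))
        m = ms.compute_metrics(tr)
        assert m.max_displacement_nm == 0
        assert m.mean_speed_nm_s == 0
        assert m.peak_run_speed_nm_s == 0
        assert m.net_displacement_nm == 0
        assert not m.run_detected

    def test_straight_track_closed_form_kinematics(self):
        tr = straight_track(10.0, 20.0, 500)
        m = ms.compute_metrics(tr)
        assert m.max_displacement_nm == pytest.approx(4990.0)
        assert m.mean_speed_nm_s == pytest.approx(200.0)
        assert m.net_displacement_nm == pytest.approx(4990.0)

    def test_circular_path_max_displacement_is_diameter(self):
        # circle of radius 100 nm through the start point
        theta = np.linspace(0, 4 * np.pi, 500)
        x = 100 * (1 - np.cos(theta))
        y = 100 * np.sin(theta)
        tr = Track(0, np.arange(500) / 20.0, x, y)
        m = ms.compute_metrics(tr)
        assert m.max_displacement_nm == pytest.approx(200.0, rel=1e-3)

    def test_short_track_flagged_truncated(self):
        tr = straight_track(n=100)
        m = ms.compute_metrics(tr, window_frames=500)
        assert m.window_truncated

    def test_net_displacement_never_exceeds_path_length(self, rng):
        pos = np.cumsum(rng.normal(0, 20, (300, 2)), axis=0)
        tr = Track(0, np.arange(300) / 20.0, pos[:, 0], pos[:, 1])
        m = ms.compute_metrics(tr)
        path = np.linalg.norm(np.diff(pos, axis=0), axis=1).sum()
        assert m.net_displacement_nm <= path

    @settings(deadline=None, max_examples=20)
    @given(
        angle=st.floats(0, 2 * np.pi),
        tx=st.floats(-1e4, 1e4),
        ty=st.floats(-1e4, 1e4),
    )
    def test_metrics_invariant_under_rigid_motion(self, angle, tx, ty):
        rng = np.random.default_rng(3)
        pos = np.cumsum(rng.normal(0, 15, (200, 2)), axis=0)
        t = np.arange(200) / 20.0
        rot = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
        moved = pos @ rot.T + [tx, ty]
        m0 = ms.compute_metrics(Track(0, t, pos[:, 0], pos[:, 1]))
        m1 = ms.compute_metrics(Track(0, t, moved[:, 0], moved[:, 1]))
        assert m1.max_displacement_nm == pytest.approx(m0.max_displacement_nm, rel=1e-9)
        assert m1.mean_speed_nm_s == pytest.approx(m0.mean_speed_nm_s, rel=1e-9)
        assert m1.net_displacement_nm == pytest.approx(m0.net_displacement_nm, rel=1e-9)

    def test_halving_frame_interval_doubles_speeds_keeps_displacements(self):
        rng = np.random.default_rng(5)
        pos = np.cumsum(rng.normal(0, 15, (400, 2)), axis=0)
        fast = ms.compute_metrics(Track(0, np.arange(400) / 40.0, pos[:, 0], pos[:, 1]))
        slow = ms.compute_metrics(Track(0, np.arange(400) / 20.0, pos[:, 0], pos[:, 1]))
        assert fast.mean_speed_nm_s == pytest.approx(2 * slow.mean_speed_nm_s, rel=1e-9)
        assert fast.max_displacement_nm == pytest.approx(slow.max_displacement_nm)


class TestClassifyMotion:
    def _metrics(self, max_disp, run=False, net=None):
        return DynamicsMetrics(
            max_displacement_nm=max_disp,
            mean_speed_nm_s=300.0,
            peak_run_speed_nm_s=700.0 if run else 100.0,
            net_displacement_nm=net if net is not None else max_disp,
            run_detected=run,
        )

    def test_confined_small_displacement_is_stationary(self):
        assert ms.classify_motion(self._metrics(150.0)) == "stationary"

    def test_larger_confined_displacement_is_dynamic_slow(self):
        assert ms.classify_motion(self._metrics(450.0)) == "dynamic-slow"

    def test_processive_run_with_large_net_transport_is_dynamic_fast(self):
        m = self._metrics(1570.0, run=True, net=1570.0)
        assert ms.classify_motion(m) == "dynamic-fast"

    def test_run_without_net_transport_is_not_fast(self):
        m = self._metrics(450.0, run=True, net=400.0)
        assert ms.classify_motion(m) == "dynamic-slow"

    @settings(deadline=None, max_examples=50)
    @given(d1=st.floats(0, 3000), d2=st.floats(0, 3000))
    def test_monotone_in_max_displacement(self, d1, d2):
        """More displacement never demotes dynamic-slow back to stationary."""
        lo, hi = sorted([d1, d2])
        c_lo = ms.classify_motion(self._metrics(lo))
        c_hi = ms.classify_motion(self._metrics(hi))
        rank = {"stationary": 0, "dynamic-slow": 1}
        assert rank[c_hi] >= rank[c_lo]

    def test_classifier_params_roundtrip(self):
        clf = ms.MotionClassifier(confinement_threshold_nm=300.0)
        clf2 = ms.MotionClassifier().set_params(**clf.get_params())
        assert clf2.get_params() == clf.get_params()
        with pytest.raises(ValueError):
            clf.set_params(bogus=1)


class TestInteraction:
    def square(self, x0, y0, oid, side=5.0):
        v = np.array([[x0, y0], [x0 + side, y0], [x0 + side, y0 + side], [x0, y0 + side]])
        return OrganelleOutline(oid, v)

    def test_overlapping_organelles_both_interacting(self):
        out = ms.classify_interaction(
            [self.square(0, 0, 0), self.square(3, 3, 1)], PX)
        assert out == {0: "interacting", 1: "interacting"}

    def test_distant_organelles_isolated(self):
        far = 5.0 / PX  # 5 um apart
        out = ms.classify_interaction(
            [self.square(0, 0, 0), self.square(far + 10, 0, 1)], PX)
        assert out == {0: "isolated", 1: "isolated"}

    def test_gap_exactly_at_contact_distance_counts_as_interacting(self):
        gap_px = 100e-3 / PX
        out = ms.classify_interaction(
            [self.square(0, 0, 0), self.square(5.0 + gap_px, 0, 1)], PX,
            contact_distance_nm=100.0)
        assert out == {0: "interacting", 1: "interacting"}

    def test_single_organelle_is_isolated(self):
        assert ms.classify_interaction([self.square(0, 0, 7)], PX) == {7: "isolated"}


class TestTracking:
    def test_single_stationary_blob_yields_one_full_track(self):
        dets = [np.array([[1000.0, 1000.0]])] * 60
        tracks = ms.track_centroids(dets, 0.05)
        assert len(tracks) == 1
        assert len(tracks[0]) == 60

    def test_two_distant_blobs_no_identity_swap(self):
        rng = np.random.default_rng(1)
        a = np.array([2000.0, 2000.0])
        b = np.array([12000.0, 2000.0])  # 10 um apart
        dets = [np.vstack([a + rng.normal(0, 20, 2), b + rng.normal(0, 20, 2)])
                for _ in range(50)]
        tracks = ms.track_centroids(dets, 0.05)
        assert len(tracks) == 2
        for tr in tracks:
            start = np.array([tr.x_nm[0], tr.y_nm[0]])
            spread = np.hypot(tr.x_nm - start[0], tr.y_nm - start[1]).max()
            assert spread < 500  # never jumps to the other blob

    def test_processive_blob_stays_linked(self):
        # 700 nm/s at 20 fps = 35 nm/frame, well under the 2 um/frame gate
        dets = [np.array([[1000.0 + 35.0 * t, 500.0]]) for t in range(100)]
        tracks = ms.track_centroids(dets, 0.05)
        assert len(tracks) == 1
        assert len(tracks[0]) == 100

    def test_short_tracks_dropped(self):
        dets = [np.array([[100.0, 100.0]])] * 5 + [np.empty((0, 2))] * 20
        assert ms.track_centroids(dets, 0.05, min_length=10) == []

    def test_blob_centroids_from_livecell_movie(self):
        cfg = ms.SimulationConfig(rng_seed=3, n_frames=500, field_size_px=(48, 48))
        tracks, _ = ms.simulate_tracks(cfg, 2)
        from mitostorm.simulate import simulate_livecell_movie

        movie = simulate_livecell_movie(cfg, tracks, poisson_noise=False)
        dets = detect_blob_centroids(movie)
        assert len(dets[0]) == 2
        truth = np.array([[t.x_nm[0], t.y_nm[0]] for t in tracks])
        d = np.abs(dets[0][:, None, :] - truth[None, :, :]).sum(axis=2).min(axis=1)
        assert (d < 200).all()


class TestRecovery:
    def test_canonical_tracks_give_diagonal_confusion_matrix(self):
        n, fps = 500, 20.0
        t = np.arange(n) / fps
        stationary = Track(0, t, 100 * np.sin(np.linspace(0, 20, n)), np.zeros(n))
        slow = Track(1, t, 350 * np.sin(np.linspace(0, 20, n)), np.zeros(n))
        fast = straight_track(35.0, fps, n, tid=2)  # 700 nm/s straight run
        clf = ms.MotionClassifier().fit()
        pred = clf.predict([stationary, slow, fast])
        cm, recall = ms.recover_classes(
            ["stationary", "dynamic-slow", "dynamic-fast"], pred)
        assert np.trace(cm.to_numpy()) == 3
        assert all(r == 1.0 for r in recall.values())

    def test_single_class_input_fills_one_row(self):
        clf = ms.MotionClassifier().fit()
        tracks = [straight_track(0.1, 20.0, 500, tid=i) for i in range(4)]
        pred = clf.predict(tracks)
        cm, _ = ms.recover_classes(["stationary"] * 4, pred)
        assert cm.loc["stationary"].sum() == 4
        assert cm.loc["dynamic-slow"].sum() == 0
        assert cm.loc["dynamic-fast"].sum() == 0

    def test_paper_parameterized_tracks_recovered_with_high_recall(self):
        cfg = ms.SimulationConfig(rng_seed=4, n_frames=500)
        tracks, labels = ms.simulate_tracks(cfg, 300)
        pred = ms.MotionClassifier().fit().predict(tracks)
        _, recall = ms.recover_classes(labels, pred)
        assert all(r >= 0.9 for r in recall.values())
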