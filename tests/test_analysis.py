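"""Contours, kymographs, MSD crossover, pseudopod events."""

import numpy as np
import pytest

from morphodyn.analysis import (
    DetectionThresholds,
    Kymograph,
    analytic_crossover,
    contour_curvature,
    curvature_kymograph,
    detect_pseudopod_events,
    extract_contour,
    msd_persistence,
    protrusion_speed_kymograph,
    pseudopod_statistics,
    run_and_tumble_track,
    time_averaged_msd,
)
from morphodyn.analysis.contour import ContourError

from conftest import disk_mask, tanh_disk


class TestExtractContour:
    def test_circle_curvature_everywhere_inverse_radius(self):
        c = extract_contour(tanh_disk(20), 128)
        k = contour_curvature(c)
        np.testing.assert_allclose(k, 1.0 / 20.0, rtol=0.05)

    def test_requested_point_count(self):
        c = extract_contour(tanh_disk(15), 93)
        assert c.n_points == 93

    def test_edge_touching_region_rejected(self):
        field = np.ones((32, 32))
        with pytest.raises(ContourError):
            extract_contour(field, 64)

    def test_multi_component_rejected(self):
        field = disk_mask(6, size=64, cx=16, cy=16) | disk_mask(6, size=64, cx=48, cy=48)
        with pytest.raises(ContourError):
            extract_contour(field.astype(float), 64)

    def test_empty_rejected(self):
        with pytest.raises(ContourError):
            extract_contour(np.zeros((32, 32)), 64)

    @pytest.mark.parametrize("radius", [12.0, 20.0, 33.0])
    def test_curvature_closure_is_one_turn(self, radius):
        c = extract_contour(tanh_disk(radius, size=160), 128)
        k = contour_curvature(c)
        ds = c.perimeter / c.n_points
        assert (k * ds).sum() == pytest.approx(2 * np.pi, rel=0.02)

    def test_closure_on_binary_mask(self):
        c = extract_contour(disk_mask(20, size=96).astype(float), 128)
        k = contour_curvature(c)
        ds = c.perimeter / c.n_points
        assert (k * ds).sum() == pytest.approx(2 * np.pi, rel=0.02)

    def test_contour_area_matches_pixel_count(self):
        mask = disk_mask(18, size=80)
        c = extract_contour(mask.astype(float), 128)
        assert abs(c.area) == pytest.approx(mask.sum(), rel=0.03)


class TestCurvatureKymograph:
    def test_static_disk_constant_inverse_radius(self):
        frames = [tanh_disk(20)] * 5
        kg = curvature_kymograph(frames, 128, times=np.arange(5.0))
        np.testing.assert_allclose(kg.values, 1 / 20.0, rtol=0.06)

    def test_static_square_has_four_persistent_corner_bands(self):
        sq = np.zeros((96, 96))
        sq[28:68, 28:68] = 1.0
        kg = curvature_kymograph([sq] * 6, 128, times=np.arange(6.0))
        cut = np.percentile(kg.values, 80)
        bands = kg.values > cut
        # the same boundary rows stay high-curvature in every frame
        from scipy import ndimage

        persistent = bands.all(axis=1)
        _, n = ndimage.label(np.r_[persistent, persistent[:2]])
        assert (bands[:, 0] == bands[:, -1]).mean() > 0.95
        assert 3 <= n <= 5

    @staticmethod
    def _band_shifts(kg):
        """Per-frame cyclic shift of the curvature profile (band drift)."""
        n_pts = kg.n_boundary
        shifts = []
        for t in range(1, kg.n_frames):
            fa = np.fft.rfft(kg.values[:, t - 1])
            fb = np.fft.rfft(kg.values[:, t])
            corr = np.fft.irfft(fa.conj() * fb, n=n_pts)
            shift = int(np.argmax(corr))
            shifts.append(shift - n_pts if shift > n_pts // 2 else shift)
        return shifts

    def test_translating_shape_bands_are_static_after_registration(self):
        # translation must be fully absorbed: corner bands stay put even
        # though the raw contour start point jumps between frames
        from skimage import draw

        tri = np.zeros((128, 128))
        rr, cc = draw.polygon([30, 95, 85], [50, 16, 86], shape=(128, 128))
        tri[rr, cc] = 1.0
        frames = [np.roll(tri, 3 * t, axis=1) for t in range(6)]
        kg = curvature_kymograph(frames, 144, times=np.arange(6.0))
        assert max(abs(s) for s in self._band_shifts(kg)) <= 1

    def test_rotating_shape_bands_drift_coherently(self):
        # minimal-displacement matching of a closed curve absorbs part of a
        # rigid rotation into the correspondence (gauge freedom); the bands
        # must still drift coherently at a constant rate not exceeding the
        # rotation rate, with no jumps
        from scipy import ndimage as ndi

        bar = np.zeros((128, 128))
        bar[54:74, 34:94] = 1.0
        rate_deg = 10.0
        n_pts = 144
        frames = [ndi.rotate(bar, rate_deg * t, reshape=False, order=1) >= 0.5
                  for t in range(6)]
        kg = curvature_kymograph(frames, n_pts, times=np.arange(6.0))
        shifts = self._band_shifts(kg)
        rate_pts = n_pts * rate_deg / 360.0
        assert max(abs(s) for s in shifts) <= rate_pts
        assert max(shifts) - min(shifts) <= 1  # constant drift, no jumps


class TestProtrusionSpeedKymograph:
    def test_uniform_expansion_recovers_rate(self):
        frames = [tanh_disk(15 + 0.5 * t) for t in range(8)]
        kg = protrusion_speed_kymograph(frames, 128, times=np.arange(8.0))
        np.testing.assert_allclose(kg.values[:, 1:], 0.5, rtol=0.1)

    def test_static_shape_zero_speed(self):
        frames = [tanh_disk(18)] * 5
        kg = protrusion_speed_kymograph(frames, 128, times=np.arange(5.0))
        assert np.abs(kg.values).max() < 0.02

    def test_translation_sign_pattern(self):
        frames = [tanh_disk(15, size=160) for _ in range(5)]
        frames = [np.roll(f, 2 * t, axis=1) for t, f in enumerate(frames)]
        kg = protrusion_speed_kymograph(frames, 128, times=np.arange(5.0))
        v = kg.values[:, 1:]
        assert v.max() > 1.5 and v.min() < -1.5       # front and rear bands
        assert abs(v.mean()) < 0.1                     # area is conserved
        # flank points (where |v| small) exist between front and rear
        assert (np.abs(v) < 0.3).any(axis=0).all()


class TestMSD:
    def test_straight_track_is_exactly_ballistic(self):
        track = np.arange(200)[:, None] * np.array([0.3, 0.4])
        res = msd_persistence(track, frame_interval=5.0)
        assert res.short_slope == pytest.approx(2.0, abs=1e-6)
        assert res.tau0 is None  # no crossover in a purely ballistic track
        lags, msd = time_averaged_msd(track, 5.0)
        np.testing.assert_allclose(msd, (0.5 * lags / 5.0) ** 2, rtol=1e-9)

    def test_lattice_random_walk_is_diffusive(self):
        rng = np.random.default_rng(42)
        tracks = [np.cumsum(rng.choice([-1.0, 1.0], size=(3000, 2)), axis=0)
                  for _ in range(32)]
        msds = []
        for tr in tracks:
            lags, msd = time_averaged_msd(tr, 1.0, max_lag_fraction=0.1)
            msds.append(msd)
        mean_msd = np.mean(msds, axis=0)
        long = lags >= 0.5 * lags[-1]
        slope = np.polyfit(np.log(lags[long]), np.log(mean_msd[long]), 1)[0]
        assert slope == pytest.approx(1.0, abs=0.1)

    @pytest.mark.parametrize("persistence", [50.0, 100.0, 200.0])
    def test_crossover_recovery_on_run_and_tumble(self, persistence):
        # oracle: the identical two-line construction applied to the
        # closed-form run-and-tumble MSD over the same lag grid
        frame, n = 5.0, 1200
        lags = np.arange(1, int(n * 0.25) + 1) * frame
        oracle = analytic_crossover(0.1, persistence, lags)
        taus = []
        for seed in range(20):
            tr = run_and_tumble_track(n, frame, speed=0.1,
                                      persistence_time=persistence, seed=seed)
            res = msd_persistence(tr, frame)
            if res.tau0 is not None:
                taus.append(res.tau0)
        assert len(taus) >= 15
        assert np.mean(taus) == pytest.approx(oracle, rel=0.2)

    def test_translation_rotation_invariance(self):
        rng = np.random.default_rng(5)
        track = np.cumsum(rng.normal(size=(400, 2)), axis=0)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = track @ R.T + np.array([123.4, -56.7])
        _, a = time_averaged_msd(track, 1.0)
        _, b = time_averaged_msd(moved, 1.0)
        np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            msd_persistence(np.zeros((20, 2)), 1.0)


def _kymo(values):
    v = np.asarray(values, dtype=float)
    return Kymograph(v, np.arange(v.shape[1], dtype=float) * 5.0, np.zeros(v.shape[1], int))


class TestPseudopodDetection:
    def test_isolated_burst_is_de_novo(self):
        v = np.zeros((64, 20))
        v[10:20, 5:10] = 1.0
        events = detect_pseudopod_events(_kymo(v))
        assert len(events) == 1
        assert events[0].event_type == "de_novo"
        assert 10 <= events[0].boundary_index < 20

    def test_burst_next_to_persisting_front_is_y_split(self):
        v = np.zeros((64, 20))
        v[30:38, :] = 1.0
        v[40:48, 8:14] = 1.0
        events = detect_pseudopod_events(_kymo(v))
        types = {e.event_type for e in events}
        assert "y_split" in types

    def test_burst_replacing_front_is_one_way_split(self):
        v = np.zeros((64, 20))
        v[30:38, 0:8] = 1.0
        v[40:48, 7:15] = 1.0
        events = detect_pseudopod_events(_kymo(v))
        assert any(e.event_type == "one_way_split" for e in events)

    def test_all_zero_kymograph_yields_no_events(self):
        assert detect_pseudopod_events(_kymo(np.zeros((64, 20)))) == []

    def test_wraparound_burst_counts_once(self):
        v = np.zeros((64, 20))
        v[60:, 3:9] = 1.0
        v[:4, 3:9] = 1.0
        events = detect_pseudopod_events(_kymo(v))
        assert len(events) == 1

    def test_short_blobs_filtered(self):
        v = np.zeros((64, 20))
        v[10:20, 5:6] = 1.0  # one-frame flicker
        th = DetectionThresholds(min_duration_frames=3)
        assert detect_pseudopod_events(_kymo(v), th) == []


class TestPseudopodStatistics:
    def _events(self, types):
        from morphodyn.analysis.pseudopod import PseudopodEvent

        return [PseudopodEvent(onset_time=5.0 * i, onset_frame=i, boundary_location=0.1,
                               boundary_index=3, event_type=t) for i, t in enumerate(types)]

    def test_all_de_novo_fraction_one(self):
        stats = pseudopod_statistics(self._events(["de_novo"] * 4), None,
                                     np.zeros((10, 2)), np.arange(10.0) * 5)
        assert stats["de_novo_fraction"] == 1.0

    def test_half_split_fraction(self):
        stats = pseudopod_statistics(
            self._events(["de_novo", "de_novo", "y_split", "one_way_split"]),
            None, np.zeros((10, 2)), np.arange(10.0) * 5)
        assert stats["de_novo_fraction"] == 0.5

    def test_extension_angle_parallel_and_antiparallel(self):
        from morphodyn.analysis.pseudopod import PseudopodEvent

        n_frames, nb = 8, 16
        times = np.arange(n_frames, dtype=float) * 5.0
        # boundary point 3 moves +y, centroid moves +y too -> 0 degrees
        contours = [np.tile(np.arange(nb)[:, None], (1, 2)).astype(float) + t
                    for t in range(n_frames)]
        centroids = np.column_stack([np.arange(n_frames, dtype=float),
                                     np.arange(n_frames, dtype=float)])
        ev = [PseudopodEvent(0.0, 0, 0.2, 3, "de_novo")]
        stats = pseudopod_statistics(ev, contours, centroids, times)
        assert stats["angles_deg"][0] == pytest.approx(0.0, abs=1e-4)
        # reverse the centroid motion -> 180 degrees
        stats = pseudopod_statistics(ev, contours, -centroids, times)
        assert stats["angles_deg"][0] == pytest.approx(180.0, abs=1e-4)

    def test_event_near_series_end_dropped(self):
        from morphodyn.analysis.pseudopod import PseudopodEvent

        times = np.arange(3, dtype=float) * 5.0
        contours = [np.zeros((8, 2))] * 3
        ev = [PseudopodEvent(10.0, 2, 0.0, 0, "de_novo")]
        stats = pseudopod_statistics(ev, contours, np.zeros((3, 2)), times)
        assert stats["angles_deg"] == []
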