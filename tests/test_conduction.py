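"""Single-vector conduction velocity, probe placement, isochrones."""

import warnings

import numpy as np
import pytest

import voltmap as vm
from voltmap.activation_repol import ActivationMap
from voltmap.conduction import (VectorProbe, auto_probe, isochrone_map,
                                single_vector_cv)

PITCH = 30.0 / 128


def _linear_map(slope_ms_per_px=0.25, shape=(128, 128)):
    """Left-to-right plane-wave activation field."""
    cols = np.arange(shape[1], dtype=float)
    vals = np.tile(10.0 + cols * slope_ms_per_px, (shape[0], 1))
    return ActivationMap(values=vals, valid=np.isfinite(vals), cl=400.0,
                         pixel_pitch=PITCH, window_length=400.0)


class TestSingleVectorCV:
    def test_distance_over_time_arithmetic(self):
        # 40 px apart, dt = 10 ms at 0.234375 mm/px -> 93.75 cm/s
        amap = _linear_map(slope_ms_per_px=0.25)
        probe = VectorProbe(p1=(64, 40), p2=(64, 80), pixel_pitch=PITCH)
        assert single_vector_cv(amap, probe) == pytest.approx(93.75)

    def test_swap_invariance(self):
        amap = _linear_map()
        a = single_vector_cv(amap, VectorProbe((64, 40), (64, 80), PITCH))
        b = single_vector_cv(amap, VectorProbe((64, 80), (64, 40), PITCH))
        assert a == pytest.approx(b)

    def test_rotation_invariance(self):
        amap = _linear_map()
        rot = ActivationMap(values=np.rot90(amap.values).copy(),
                            valid=np.rot90(amap.valid).copy(), cl=400.0,
                            pixel_pitch=PITCH, window_length=400.0)
        # (r, c) -> (nrows-1-c, r) under rot90
        n = 128
        p1, p2 = (64, 40), (64, 80)
        q1, q2 = (n - 1 - p1[1], p1[0]), (n - 1 - p2[1], p2[0])
        a = single_vector_cv(amap, VectorProbe(p1, p2, PITCH))
        b = single_vector_cv(rot, VectorProbe(q1, q2, PITCH))
        assert a == pytest.approx(b)

    def test_simultaneous_activation_rejected(self):
        vals = np.full((32, 32), 25.0)
        amap = ActivationMap(values=vals, valid=np.ones_like(vals, bool),
                             cl=400.0, pixel_pitch=PITCH, window_length=400.0)
        with pytest.raises(ValueError, match="too close in time"):
            single_vector_cv(amap, VectorProbe((5, 5), (5, 25), PITCH))

    def test_invalid_pixel_rejected(self):
        amap = _linear_map()
        amap.values[64, 40] = np.nan
        with pytest.raises(ValueError, match="valid"):
            single_vector_cv(amap, VectorProbe((64, 40), (64, 80), PITCH))

    def test_probe_length_independence_on_plane_wave(self, plane_maps):
        """Beyond 10 px the estimate varies < 2 % with probe length."""
        amap, _ = plane_maps
        cvs = []
        for half in (5, 10, 15, 20, 30):
            probe = VectorProbe((64, 64 - half), (64, 64 + half), PITCH)
            cvs.append(single_vector_cv(amap, probe))
        spread = (max(cvs) - min(cvs)) / np.mean(cvs)
        assert spread < 0.02


class TestAutoProbe:
    def test_axis_horizontal_for_left_right_wave(self, plane_maps):
        amap, _ = plane_maps
        probe = auto_probe(amap)
        dr = probe.p2[0] - probe.p1[0]
        dc = probe.p2[1] - probe.p1[1]
        angle = np.degrees(np.arctan2(abs(dr), abs(dc)))
        assert angle < 10.0
        assert probe.selection_mode == "auto"

    def test_recovers_true_velocity(self, plane_maps):
        amap, _ = plane_maps
        cv = single_vector_cv(amap, auto_probe(amap))
        assert cv == pytest.approx(60.0, rel=0.05)

    def test_auto_close_to_manual_on_noisy_wave(self, noisy_plane_result):
        res = noisy_plane_result
        amap, _ = res.maps[400.0]
        cv_auto = res.cv_by_cl[400.0]
        roi = vm.default_roi(amap.values.shape)
        manual = VectorProbe((64, roi[1]), (64, roi[3] - 1), PITCH)
        cv_manual = single_vector_cv(amap, manual)
        assert abs(cv_auto - cv_manual) / cv_manual < 0.05

    def test_radial_source_is_incoherent_or_centered(self):
        """A point source at the ROI center: either refuse (incoherent
        gradient) or return an axis through the source."""
        n = 96
        rr, cc = np.mgrid[0:n, 0:n]
        r = np.hypot(rr - n / 2, cc - n / 2)
        amap = ActivationMap(values=10.0 + r * 0.3,
                             valid=np.ones((n, n), bool), cl=400.0,
                             pixel_pitch=PITCH, window_length=400.0)
        try:
            probe = auto_probe(amap)
        except ValueError as exc:
            assert "incoherent" in str(exc) or "manual" in str(exc)
        else:
            # axis passes near the center
            p1, p2 = np.array(probe.p1), np.array(probe.p2)
            d = np.abs(np.cross(p2 - p1, np.array([n / 2, n / 2]) - p1)
                       ) / np.linalg.norm(p2 - p1)
            assert d < 8.0

    def test_sparse_map_rejected(self):
        vals = np.full((64, 64), np.nan)
        vals[0, 0] = 1.0
        amap = ActivationMap(values=vals, valid=np.isfinite(vals), cl=400.0,
                             pixel_pitch=PITCH, window_length=400.0)
        with pytest.raises(ValueError, match="50%"):
            auto_probe(amap)


class TestIsochrones:
    def test_plane_wave_contours_parallel_evenly_spaced(self, plane_maps):
        amap, _ = plane_maps
        iso = isochrone_map(amap, interval=4.0)
        assert iso.n_contours >= 5
        # each contour is a vertical line; spacing = cv * interval
        mean_cols = []
        for level, paths in zip(iso.levels, iso.contours):
            if not paths:
                continue
            allpts = np.vstack(paths)
            assert allpts[:, 1].std() < 1.5  # straight
            mean_cols.append(allpts[:, 1].mean())
        spacing_px = np.diff(sorted(mean_cols))
        expected = 0.6 * 4.0 / PITCH  # mm per isochrone / mm per px
        assert np.allclose(spacing_px, expected, rtol=0.15)

    def test_slower_wave_has_denser_contours(self):
        slow = _linear_map(slope_ms_per_px=0.75)   # ~31 cm/s
        fast = _linear_map(slope_ms_per_px=0.25)   # ~94 cm/s
        n_slow = isochrone_map(slow, 4.0).n_contours
        n_fast = isochrone_map(fast, 4.0).n_contours
        assert n_slow > n_fast

    def test_interval_wider_than_span_warns(self):
        amap = _linear_map(slope_ms_per_px=0.01)  # span ~1.3 ms
        with pytest.warns(UserWarning):
            iso = isochrone_map(amap, interval=50.0)
        assert iso.n_contours <= 1

    def test_flat_map_rejected(self):
        vals = np.full((32, 32), 7.0)
        amap = ActivationMap(values=vals, valid=np.ones_like(vals, bool),
                             cl=400.0, pixel_pitch=PITCH, window_length=400.0)
        with pytest.raises(ValueError, match="distinct"):
            isochrone_map(amap, 2.0)

    def test_render_writes_png(self, plane_maps, tmp_path):
        amap, _ = plane_maps
        iso = isochrone_map(amap, interval=4.0)
        out = tmp_path / "iso.png"
        iso.render(out, act_map=amap)
        assert out.exists() and out.stat().st_size > 0


class TestProbeValidation:
    def test_identical_points_rejected(self):
        with pytest.raises(ValueError):
            VectorProbe((3, 3), (3, 3), PITCH)

    def test_bad_pitch_rejected(self):
        with pytest.raises(ValueError):
            VectorProbe((0, 0), (1, 1), 0.0)
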