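"""Tests of spot detection, linking, nucleus traces and coordinates."""

import numpy as np
import pytest

import pcmotion as pm
from pcmotion.tracking import SpotDetection

from conftest import make_track


def gaussian_frame(shape, centers_rc, amplitude, sigma_px, background=0.0):
    h, w = shape
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    frame = np.full(shape, float(background))
    for r, c in np.atleast_2d(centers_rc):
        frame += amplitude * np.exp(-((rows - r) ** 2 + (cols - c) ** 2)
                                    / (2 * sigma_px ** 2))
    return frame


class TestMedianFilter:
    def test_constant_image_unchanged(self):
        img = np.full((16, 16), 3.5)
        assert np.array_equal(pm.median_filter_3x3(img), img)

    def test_impulse_removed(self):
        img = np.zeros((9, 9))
        img[4, 4] = 100.0
        assert pm.median_filter_3x3(img)[4, 4] == 0.0

    def test_matches_nine_element_sort(self, rng):
        img = rng.normal(size=(20, 20))
        out = pm.median_filter_3x3(img)
        for r in range(1, 19):
            for c in range(1, 19):
                window = np.sort(img[r - 1:r + 2, c - 1:c + 2].ravel())
                assert out[r, c] == window[4]

    def test_rejects_non_2d(self):
        with pytest.raises(ValueError):
            pm.median_filter_3x3(np.zeros((3, 3, 3)))


class TestDetectSpots:
    def test_blank_image_gives_no_detections(self):
        dets = pm.detect_spots(np.zeros((32, 32)), pixel_size_um=0.07,
                               smoothing_sigma_um=0.1, threshold=1.0,
                               min_separation_um=0.3)
        assert dets == []

    def test_subpixel_localization_under_tenth_pixel(self):
        true_rc = (15.34, 18.61)
        frame = gaussian_frame((32, 40), true_rc, amplitude=100.0, sigma_px=2.0,
                               background=5.0)
        dets = pm.detect_spots(frame, pixel_size_um=0.07,
                               smoothing_sigma_um=0.14, threshold=20.0,
                               min_separation_um=0.3)
        assert len(dets) == 1
        found_rc = dets[0].xy_um[::-1] / 0.07
        assert np.hypot(*(found_rc - np.array(true_rc))) < 0.1

    def test_two_separated_spots_both_found(self):
        frame = gaussian_frame((40, 40), [(10, 10), (28, 30)], amplitude=50.0,
                               sigma_px=1.5)
        dets = pm.detect_spots(frame, pixel_size_um=0.07,
                               smoothing_sigma_um=0.1, threshold=10.0,
                               min_separation_um=0.3)
        assert len(dets) == 2

    def test_translation_equivariance(self):
        frame = gaussian_frame((40, 40), (12.0, 14.0), amplitude=80.0,
                               sigma_px=1.5, background=2.0)
        shifted = np.roll(frame, (5, 7), axis=(0, 1))
        kwargs = dict(pixel_size_um=0.1, smoothing_sigma_um=0.15,
                      threshold=10.0, min_separation_um=0.5)
        d0 = pm.detect_spots(frame, **kwargs)
        d1 = pm.detect_spots(shifted, **kwargs)
        assert len(d0) == len(d1) == 1
        shift_um = np.array([7, 5]) * 0.1   # (x, y)
        assert np.allclose(d1[0].xy_um, d0[0].xy_um + shift_um, atol=1e-6)


class TestLinking:
    @staticmethod
    def _as_detections(paths_um):
        """paths_um: (n_objects, n_frames, 2) -> per-frame detection lists."""
        n_obj, n_frames, _ = paths_um.shape
        out = []
        for k in range(n_frames):
            out.append([SpotDetection(frame=k, xy_um=paths_um[i, k].copy(),
                                      peak_intensity=1.0, integrated_intensity=1.0)
                        for i in range(n_obj)])
        return out

    def test_single_moving_spot_gives_full_track(self):
        path = np.cumsum(np.full((1, 20, 2), 0.05), axis=1)
        tracks = pm.link_detections(self._as_detections(path),
                                    max_displacement_um=0.2)
        assert len(tracks) == 1 and tracks[0].n_frames == 20

    def test_two_static_spots_never_swap(self):
        paths = np.zeros((2, 30, 2))
        paths[1] += [3.0, 0.0]
        tracks = pm.link_detections(self._as_detections(paths),
                                    max_displacement_um=0.5)
        assert len(tracks) == 2
        for tr in tracks:
            assert np.ptp(tr.xy_um[:, 0]) == 0.0

    def test_rejects_nonpositive_max_displacement(self):
        with pytest.raises(ValueError):
            pm.link_detections([], max_displacement_um=0.0)

    def test_link_identity_on_simulation(self, rng):
        # nearest-neighbour spacing >= 4x the per-frame displacement:
        # links must agree with ground-truth identity >= 99% of the time
        n_obj, n_frames, step = 12, 40, 0.02
        anchors = np.stack(np.meshgrid(np.arange(4), np.arange(3)), -1
                           ).reshape(-1, 2) * 1.0
        paths = anchors[:, None, :] + np.cumsum(
            rng.normal(scale=step, size=(n_obj, n_frames, 2)), axis=1)
        tracks = pm.link_detections(self._as_detections(paths),
                                    max_displacement_um=0.3)
        full = [t for t in tracks if t.n_frames == n_frames]
        correct = 0
        for tr in full:
            start = tr.xy_um[0]
            truth_idx = np.argmin(np.linalg.norm(paths[:, 0] - start, axis=1))
            correct += np.all(np.linalg.norm(tr.xy_um - paths[truth_idx], axis=1)
                              < 1e-9)
        assert correct / n_obj >= 0.99

    def test_each_detection_used_once(self, rng):
        paths = rng.uniform(0, 10, size=(5, 1, 2)) + np.cumsum(
            rng.normal(scale=0.05, size=(5, 15, 2)), axis=1)
        dets = self._as_detections(paths)
        tracks = pm.link_detections(dets, max_displacement_um=0.5)
        n_used = sum(t.n_frames for t in tracks)
        n_total = sum(len(d) for d in dets)
        assert n_used == n_total


class TestNucleusTrace:
    def test_symmetric_nucleus_centroid(self):
        frame = gaussian_frame((41, 41), (20.0, 20.0), amplitude=50.0,
                               sigma_px=8.0)
        trace = pm.nucleus_center_trace(frame, pixel_size_um=0.1,
                                        frame_interval_s=1.0)
        assert np.allclose(trace.center_um[0], [2.0, 2.0], atol=0.01)

    def test_translation_equivariance(self):
        frame = gaussian_frame((60, 60), (25.0, 22.0), amplitude=50.0,
                               sigma_px=6.0)
        shifted = np.roll(frame, (4, 9), axis=(0, 1))
        a = pm.nucleus_center_trace(frame, pixel_size_um=0.1, frame_interval_s=1.0)
        b = pm.nucleus_center_trace(shifted, pixel_size_um=0.1,
                                    frame_interval_s=1.0)
        assert np.allclose(b.center_um[0] - a.center_um[0], [0.9, 0.4], atol=0.02)

    def test_disc_area_within_two_percent(self):
        h = w = 201
        rows = np.arange(h)[:, None] - 100
        cols = np.arange(w)[None, :] - 100
        disc = (np.hypot(rows, cols) <= 50).astype(float) * 100.0
        trace = pm.nucleus_center_trace(disc, pixel_size_um=0.1,
                                        frame_interval_s=1.0, threshold=50.0)
        assert abs(trace.area_um2[0] / (np.pi * 5.0 ** 2) - 1.0) < 0.02

    def test_empty_foreground_raises(self):
        with pytest.raises(ValueError):
            pm.nucleus_center_trace(np.zeros((10, 10)), pixel_size_um=0.1,
                                    frame_interval_s=1.0, threshold=1.0)


class TestRelativeCoordinates:
    def test_static_nucleus_is_identity(self):
        track = make_track(np.arange(10)[:, None] * [0.1, 0.0])
        trace = pm.NucleusTrace(nucleus_id=0, t_s=track.t_s,
                                center_um=np.zeros((10, 2)))
        rel = pm.to_relative([track], trace)[0]
        assert np.array_equal(rel.xy_um, track.xy_um)

    def test_common_drift_cancels(self, rng):
        drift = np.cumsum(rng.normal(scale=0.1, size=(20, 2)), axis=0)
        base = rng.normal(size=(20, 2))
        track = make_track(base + drift)
        trace = pm.NucleusTrace(nucleus_id=0, t_s=track.t_s, center_um=drift)
        rel = pm.to_relative([track], trace)[0]
        assert np.allclose(rel.xy_um, base)

    def test_track_equal_to_center_becomes_zero(self, rng):
        center = rng.normal(size=(15, 2))
        track = make_track(center)
        trace = pm.NucleusTrace(nucleus_id=0, t_s=track.t_s, center_um=center)
        assert np.allclose(pm.to_relative([track], trace)[0].xy_um, 0.0)

    def test_frame_mismatch_raises(self):
        track = make_track(np.zeros((10, 2)))
        trace = pm.NucleusTrace(nucleus_id=0, t_s=np.arange(9) * 0.25,
                                center_um=np.zeros((9, 2)))
        with pytest.raises(ValueError):
            pm.to_relative([track], trace)


class TestDropZ:
    def test_pure_z_motion_becomes_static(self):
        xyz = np.zeros((10, 3))
        xyz[:, 2] = np.arange(10) * 0.5
        flat = pm.drop_z([make_track(xyz)])[0]
        assert flat.ndim == 2 and np.all(flat.xy_um == 0.0)

    def test_2d_input_is_identity(self):
        track = make_track(np.random.default_rng(0).normal(size=(8, 2)))
        assert pm.drop_z([track])[0] is track

    def test_helix_msd_equals_xy_projection(self):
        t = np.arange(50) * 0.25
        helix = np.column_stack([np.cos(t), np.sin(t), t])
        flat = pm.drop_z([make_track(helix)])[0]
        msd_flat = pm.compute_msd(flat)
        msd_xy = pm.compute_msd(make_track(helix[:, :2]))
        assert np.allclose(msd_flat.msd_um2, msd_xy.msd_um2)
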