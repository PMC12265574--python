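"""Gaussian target rendering, keypoint extraction, track linking."""

import math

import numpy as np
import pytest
from scipy.optimize import curve_fit

import holoctc as h
from holoctc.detect import (Heatmap, Keypoint, Track, extract_keypoints,
                            link_tracks, render_targets, sigma_px)

OPTICS = h.OpticalConfig()          # full-scale defaults: 3.45 μm pitch, 10x
SMALL = h.OpticalConfig(roi_px=(256, 96), defocus_um=30.0)


def brute_force_keypoints(values, threshold, min_sep_px, stride=1):
    """Independent oracle: exhaustive local-maxima scan + greedy suppression."""
    hgt, wid = values.shape
    cands = []
    for r in range(hgt):
        for c in range(wid):
            v = values[r, c]
            if v < threshold:
                continue
            is_max = True
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < hgt and 0 <= cc < wid and values[rr, cc] >= v:
                        is_max = False
            if is_max:
                cands.append((r, c, v))
    cands.sort(key=lambda t: (-t[2], t[0], t[1]))
    off = (stride - 1) / 2.0
    kept = []
    for r, c, v in cands:
        rf, cf = stride * r + off, stride * c + off
        if all((rf - kr) ** 2 + (cf - kc) ** 2 >= min_sep_px ** 2
               for kr, kc, _ in kept):
            kept.append((rf, cf, v))
    return kept


class TestRenderTargets:
    def test_peak_value_one_at_keypoint(self):
        tm = render_targets([Keypoint(x_px=20, y_px=12)], (32, 48), OPTICS)
        assert tm.values[12, 20] == pytest.approx(1.0)
        assert tm.values.max() == pytest.approx(1.0)

    def test_value_at_one_sigma(self):
        s = sigma_px(OPTICS)          # ≈ 8.12 px at defaults
        tm = render_targets([Keypoint(x_px=30.0, y_px=30.0)], (64, 64), OPTICS)
        # sample along the row through the peak at distance sigma
        rows = np.arange(64)[:, None]
        cols = np.arange(64)[None, :]
        d = np.hypot(rows - 30.0, cols - 30.0)
        # nearest grid point to exactly sigma away
        idx = np.unravel_index(np.argmin(np.abs(d - s)), d.shape)
        expected = math.exp(-d[idx] ** 2 / (2 * s ** 2))
        assert tm.values[idx] == pytest.approx(expected, rel=1e-12)
        assert math.exp(-0.5) == pytest.approx(0.6065, abs=1e-4)

    def test_lsq_fit_recovers_sigma_um(self):
        # independent least-squares oracle on a lone rendered blob
        tm = render_targets([Keypoint(x_px=40.3, y_px=35.7)], (72, 80), OPTICS)
        rows, cols = np.mgrid[0:72, 0:80]

        def gauss(xy, x0, y0, s, a):
            r, c = xy
            return a * np.exp(-((c - x0) ** 2 + (r - y0) ** 2) / (2 * s ** 2))

        popt, _ = curve_fit(gauss, (rows.ravel(), cols.ravel()),
                            tm.values.ravel(), p0=(38, 38, 5.0, 0.9))
        fitted_um = popt[2] * OPTICS.pixel_pitch_um / OPTICS.magnification
        assert abs(fitted_um - 2.8) / 2.8 < 0.01

    def test_overlapping_blobs_combine_by_maximum(self):
        kps = [Keypoint(x_px=20, y_px=20), Keypoint(x_px=24, y_px=20)]
        tm = render_targets(kps, (40, 48), OPTICS)
        assert tm.values[20, 20] == pytest.approx(1.0)
        assert tm.values[20, 24] == pytest.approx(1.0)
        assert tm.values.max() <= 1.0 + 1e-12

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            render_targets([], (8, 8), OPTICS, sigma_um=0.0)


class TestExtractKeypoints:
    def test_empty_heatmap_gives_no_keypoints(self):
        hm = Heatmap(values=np.zeros((32, 32)), stride=1)
        assert extract_keypoints(hm, 0.1, OPTICS) == []

    def test_single_blob_found_at_argmax(self):
        tm = render_targets([Keypoint(x_px=21, y_px=13)], (32, 48), OPTICS)
        hm = Heatmap(values=0.9 * tm.values, stride=1)
        kps = extract_keypoints(hm, 0.5, OPTICS)
        assert len(kps) == 1
        assert (kps[0].x_px, kps[0].y_px) == (21, 13)
        assert kps[0].confidence == pytest.approx(0.9)

    def test_close_pair_suppressed_to_stronger(self):
        v = np.zeros((40, 40))
        t1 = render_targets([Keypoint(x_px=20, y_px=20)], (40, 40), OPTICS)
        t2 = render_targets([Keypoint(x_px=26, y_px=20)], (40, 40), OPTICS)
        v = np.maximum(0.9 * t1.values, 0.8 * t2.values)
        hm = Heatmap(values=v, stride=1)
        kps = extract_keypoints(hm, 0.5, OPTICS,
                                min_separation_um=2 * 2.8)
        # 6 px apart < 5.6 μm (16.2 px): only the stronger survives
        assert len(kps) == 1
        assert kps[0].confidence == pytest.approx(0.9)

    def test_invalid_threshold_rejected(self):
        hm = Heatmap(values=np.zeros((8, 8)))
        with pytest.raises(ValueError):
            extract_keypoints(hm, 1.5, OPTICS)

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(7)
        for trial in range(100):
            v = rng.uniform(size=(24, 24))
            thr = rng.uniform(0.3, 0.95)
            sep_px = rng.uniform(1.0, 6.0)
            hm = Heatmap(values=v, stride=1)
            got = extract_keypoints(hm, thr, OPTICS,
                                    min_separation_um=sep_px * OPTICS.object_pixel_um)
            want = brute_force_keypoints(v, thr, sep_px)
            assert [(k.y_px, k.x_px, k.confidence) for k in got] == \
                [(r, c, v_) for r, c, v_ in want]

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(3)
        v = rng.uniform(size=(32, 32))
        hm = Heatmap(values=v, stride=1)
        counts = [len(extract_keypoints(hm, t, OPTICS, min_separation_um=1.0))
                  for t in [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_render_extract_round_trip(self):
        kps = [Keypoint(x_px=30, y_px=20), Keypoint(x_px=90, y_px=50),
               Keypoint(x_px=140, y_px=25)]
        tm = render_targets(kps, (64, 160), OPTICS)
        hm = Heatmap(values=tm.values, stride=1)
        got = extract_keypoints(hm, 0.5, OPTICS)
        assert len(got) == len(kps)
        for kp in kps:
            d = min(math.hypot(g.x_px - kp.x_px, g.y_px - kp.y_px)
                    for g in got)
            assert d <= 1.0

    def test_stride_coordinate_mapping(self):
        v = np.zeros((16, 16))
        v[5, 7] = 0.8
        hm = Heatmap(values=v, stride=4)
        kps = extract_keypoints(hm, 0.5, OPTICS, min_separation_um=1.0)
        assert len(kps) == 1
        assert (kps[0].x_px, kps[0].y_px) == (4 * 7 + 1.5, 4 * 5 + 1.5)


class TestLinkTracks:
    def _transiting_detections(self, n_frames=5, y_px=48.0, conf=0.9):
        vel = 8000.0
        dx = vel / SMALL.frame_rate_hz / SMALL.object_pixel_um
        return [Keypoint(x_px=10 + k * dx, y_px=y_px, confidence=conf,
                         frame_index=k) for k in range(n_frames)]

    def test_single_cell_yields_one_track(self):
        det = self._transiting_detections(5)
        tracks = link_tracks(det, SMALL, velocity_prior_um_s=8000.0)
        assert len(tracks) == 1
        assert tracks[0].n_frames == 5
        assert tracks[0].confidence == pytest.approx(0.9)
        # mid-transit time: frames 0..4 -> frame 2 / fps
        assert tracks[0].mid_transit_time_s == pytest.approx(2 / 450)

    def test_two_cells_separated_in_y(self):
        gate = 5.6
        d1 = self._transiting_detections(4, y_px=20.0)
        d2 = self._transiting_detections(
            4, y_px=20.0 + 3 * gate / SMALL.object_pixel_um)
        tracks = link_tracks(d1 + d2, SMALL, velocity_prior_um_s=8000.0,
                             gate_um=gate)
        assert len(tracks) == 2
        assert sorted(t.n_frames for t in tracks) == [4, 4]

    def test_empty_detections_give_no_tracks(self):
        assert link_tracks([], SMALL) == []

    def test_nonpositive_gate_rejected(self):
        with pytest.raises(ValueError):
            link_tracks([], SMALL, gate_um=0.0)

    def test_gap_within_max_gap_bridged(self):
        det = self._transiting_detections(5)
        det = [k for k in det if k.frame_index != 2]  # drop middle frame
        tracks = link_tracks(det, SMALL, velocity_prior_um_s=8000.0,
                             max_gap=1)
        assert len(tracks) == 1
        assert tracks[0].n_frames == 4
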