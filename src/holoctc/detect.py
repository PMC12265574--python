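"""Heatmap detection: Gaussian targets, keypoint extraction, track linking.

Cells are localized as Gaussian keypoints on a probability heatmap rather
than with bounding boxes: holographic fringes have no crisp outline, so
supervision places an isotropic Gaussian blob (σ = 2.8 μm by default) at
each annotated cell center and detection reads out strict local maxima of
the predicted surface above a confidence threshold.  Because the camera
runs much faster than a cell's transit, one cell appears in several
consecutive frames; per-frame keypoints are deduplicated into tracks by
nearest-neighbor linking under a constant-velocity flow prior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .net import HeatmapNet
from .optics import OpticalConfig

__all__ = ["Heatmap", "Keypoint", "TargetMap", "Track", "SIGMA_UM_DEFAULT",
           "render_targets", "predict_heatmap", "extract_keypoints",
           "link_tracks"]

#: Default supervision blob standard deviation, object-plane μm.
SIGMA_UM_DEFAULT = 2.8


@dataclass
class Heatmap:
    """Per-pixel cell-presence probability at ``stride``-reduced resolution.

    Full-resolution coordinate of heatmap cell (i, j):
    ``stride * (i, j) + (stride - 1) / 2``.
    """

    values: np.ndarray
    stride: int = 1
    frame_index: int = 0

    def to_full_res(self, row: float, col: float) -> tuple[float, float]:
        off = (self.stride - 1) / 2.0
        return (self.stride * row + off, self.stride * col + off)


@dataclass(frozen=True)
class Keypoint:
    """A detected (or annotated) cell center at full resolution."""

    x_px: float
    y_px: float
    confidence: float = 1.0
    frame_index: int = 0


@dataclass
class TargetMap:
    """Gaussian-rendered supervision map; peak value 1 at each keypoint."""

    values: np.ndarray
    sigma_um: float = SIGMA_UM_DEFAULT
    stride: int = 1


@dataclass
class Track:
    """One physical cell: linked keypoints across consecutive frames."""

    track_id: int
    keypoints: list[Keypoint] = field(default_factory=list)
    mid_transit_time_s: float = 0.0

    @property
    def confidence(self) -> float:
        return max(k.confidence for k in self.keypoints)

    @property
    def n_frames(self) -> int:
        return len(self.keypoints)


def sigma_px(optics: OpticalConfig, sigma_um: float = SIGMA_UM_DEFAULT) -> float:
    """Supervision sigma in full-resolution pixels (≈8.12 px at defaults)."""
    return sigma_um * optics.magnification / optics.pixel_pitch_um


def render_targets(keypoints: Sequence[Keypoint], shape: tuple[int, int],
                   optics: OpticalConfig,
                   sigma_um: float = SIGMA_UM_DEFAULT,
                   stride: int = 1) -> TargetMap:
    """Render the supervision map for a set of keypoints.

    ``shape`` is the (rows, cols) of the output map at the given stride;
    keypoint coordinates are full-resolution pixels.  Overlapping blobs
    combine by maximum, so the peak value at each keypoint stays 1.
    """
    if sigma_um <= 0:
        raise ValueError("sigma_um must be > 0")
    s_px = sigma_px(optics, sigma_um)
    h, w = shape
    off = (stride - 1) / 2.0
    rows = (stride * np.arange(h) + off)[:, None]
    cols = (stride * np.arange(w) + off)[None, :]
    values = np.zeros((h, w))
    for kp in keypoints:
        d2 = (rows - kp.y_px) ** 2 + (cols - kp.x_px) ** 2
        np.maximum(values, np.exp(-d2 / (2.0 * s_px ** 2)), out=values)
    return TargetMap(values=values, sigma_um=sigma_um, stride=stride)


def predict_heatmap(model: HeatmapNet, normalized_image: np.ndarray,
                    frame_index: int = 0) -> Heatmap:
    """Run the detector on one normalized image.

    Deterministic for fixed weights; output bounded to [0, 1] by the
    sigmoid head.  Shapes not divisible by the network alignment are
    padded internally and the heatmap cropped back.
    """
    hm = model.predict_proba(np.asarray(normalized_image, dtype=float))
    return Heatmap(values=hm, stride=model.stride, frame_index=frame_index)


def extract_keypoints(heatmap: Heatmap, threshold: float,
                      optics: OpticalConfig,
                      min_separation_um: float = 2 * SIGMA_UM_DEFAULT) -> list[Keypoint]:
    """Strict local maxima above ``threshold``, greedily non-max suppressed.

    Candidates strictly greater than all 8 neighbours and ≥ threshold are
    accepted in descending confidence (ties broken by lowest (row, col))
    while rejecting any candidate within ``min_separation_um`` of an
    already accepted one.  Coordinates are mapped to full resolution.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    v = heatmap.values
    if v.size == 0:
        return []
    # strict 8-neighbour maxima: v > max of neighbours (padded with -inf)
    vp = np.pad(v, 1, constant_values=-np.inf)
    neigh = np.full(v.shape, -np.inf)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            np.maximum(neigh, vp[1 + di:1 + di + v.shape[0],
                                 1 + dj:1 + dj + v.shape[1]], out=neigh)
    cand = np.argwhere((v > neigh) & (v >= threshold))
    order = sorted(range(len(cand)),
                   key=lambda i: (-v[cand[i][0], cand[i][1]],
                                  cand[i][0], cand[i][1]))
    min_sep_px = min_separation_um / optics.object_pixel_um
    accepted: list[tuple[float, float, float]] = []   # (row_full, col_full, conf)
    for i in order:
        r, c = cand[i]
        rf, cf = heatmap.to_full_res(float(r), float(c))
        if any((rf - ar) ** 2 + (cf - ac) ** 2 < min_sep_px ** 2
               for ar, ac, _ in accepted):
            continue
        accepted.append((rf, cf, float(v[r, c])))
    return [Keypoint(x_px=cf, y_px=rf, confidence=conf,
                     frame_index=heatmap.frame_index)
            for rf, cf, conf in accepted]


def link_tracks(detections: Sequence[Keypoint], optics: OpticalConfig,
                velocity_prior_um_s: float = 45_000.0,
                gate_um: float = 2 * SIGMA_UM_DEFAULT,
                max_gap: int = 1) -> list[Track]:
    """Link per-frame keypoints into one track per physical cell.

    Open tracks are advanced by the flow prior (``velocity_prior`` along
    +x) and each detection is greedily associated with the nearest
    predicted position within ``gate_um``; unmatched detections start new
    tracks; tracks idle for more than ``max_gap`` frames are closed.
    """
    if gate_um <= 0:
        raise ValueError("gate_um must be > 0")
    by_frame: dict[int, list[Keypoint]] = {}
    for kp in detections:
        by_frame.setdefault(kp.frame_index, []).append(kp)
    dx_per_frame = velocity_prior_um_s / optics.frame_rate_hz / optics.object_pixel_um
    gate_px = gate_um / optics.object_pixel_um

    open_tracks: list[Track] = []
    done: list[Track] = []
    next_id = 0
    for frame in sorted(by_frame):
        still_open = []
        for tr in open_tracks:
            if frame - tr.keypoints[-1].frame_index > max_gap + 1:
                done.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open
        # greedy nearest association, smallest distance first
        pairs = []
        for ti, tr in enumerate(open_tracks):
            last = tr.keypoints[-1]
            px = last.x_px + dx_per_frame * (frame - last.frame_index)
            py = last.y_px
            for di, kp in enumerate(by_frame[frame]):
                d = math.hypot(kp.x_px - px, kp.y_px - py)
                if d <= gate_px:
                    pairs.append((d, ti, di))
        pairs.sort()
        used_t: set[int] = set()
        used_d: set[int] = set()
        for d, ti, di in pairs:
            if ti in used_t or di in used_d:
                continue
            open_tracks[ti].keypoints.append(by_frame[frame][di])
            used_t.add(ti)
            used_d.add(di)
        for di, kp in enumerate(by_frame[frame]):
            if di not in used_d:
                open_tracks.append(Track(track_id=next_id, keypoints=[kp]))
                next_id += 1
    done.extend(open_tracks)
    fps = optics.frame_rate_hz
    for tr in done:
        frames = [k.frame_index for k in tr.keypoints]
        tr.mid_transit_time_s = 0.5 * (min(frames) + max(frames)) / fps
    done.sort(key=lambda t: t.track_id)
    return done
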