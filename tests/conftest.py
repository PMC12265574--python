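"""Shared fixtures: a desk-scale synthetic corpus and a trained detector.

The fixture emulates the study conditions at reduced scale: a 256x96 px
field (same 0.345 μm object-plane sampling and 450 fps as the full
1440x256 station), 30 μm defocus so cells show clear fringe patterns,
shot noise at 1% of background and a slow 2% background drift.  Flow
velocity is slowed to ~8 mm/s so a cell still crosses the narrower field
in about five frame periods, preserving the multi-frame transit geometry
of the full-width system.

Training uses ten sessions (five cell-line-like positive, five
healthy-blood-like negative) of ~59 usable frames each — about 590
frames total — which trains the compact detector on one CPU in around a
minute.  The fixture is session-scoped: the model is trained once per
test run.
"""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest

import holoctc as h
from holoctc.detect import (Keypoint, extract_keypoints, predict_heatmap,
                            render_targets)
from holoctc.preprocess import (BackgroundState, calibrate_norm,
                                subtract_and_normalize, update_background)
from holoctc.train import SampleStream, TrainConfig, train_detector
from holoctc.validate import match_detections

FIXTURE_VELOCITY_UM_S = 8000.0
STRIDE = 4


@pytest.fixture(scope="session")
def fx_optics() -> h.OpticalConfig:
    return h.OpticalConfig(roi_px=(256, 96), defocus_um=30.0)


def build_stream(optics: h.OpticalConfig, session_id: str, kind: str,
                 seed: int, n_frames: int = 60, noise: float = 0.01,
                 rate: float = 140.0, label_drop_frac: float = 0.0,
                 drop_seed: int = 0):
    """Simulate one session and package it as a training stream.

    Returns ``(SampleStream, per_frame_true_keypoints)``.  Positive
    sessions contain only CTC-class cells (cell lines in buffer);
    negative sessions only RBC/WBC.  ``label_drop_frac`` removes whole
    cells from the *labels* (not the images), emulating pseudo-label
    omissions; the returned true keypoints are always complete.
    """
    dur = n_frames / optics.frame_rate_hz
    class_probs = {"CTC": 1.0} if kind == "positive" else {"RBC": 0.4, "WBC": 0.6}
    scene = h.random_scene(rate, dur, optics, seed=seed,
                           class_probs=class_probs,
                           velocity_um_s=FIXTURE_VELOCITY_UM_S, noise=noise,
                           background_drift={"amplitude": 0.02, "period_s": 0.3})
    frames, truth = h.simulate_session(scene, optics, session_id=session_id)
    norm = calibrate_norm([f.pixels for f in frames[:30]])
    state = BackgroundState()
    dropped: set[int] = set()
    if label_drop_frac and len(truth):
        drng = np.random.default_rng(drop_seed)
        ids = truth.cell_id.unique()
        dropped = set(ids[drng.random(len(ids)) < label_drop_frac])
    images, targets, true_kps, true_ids = [], [], [], []
    for fr in frames:
        if state.mean_image is None:
            state = update_background(state, fr)
            continue
        img = subtract_and_normalize(fr, state, norm)
        state = update_background(state, fr)
        sub = truth[truth.frame_index == fr.frame_index]
        kps_all = [Keypoint(float(r.x_px), float(r.y_px),
                            frame_index=fr.frame_index)
                   for r in sub.itertuples()]
        ids_all = [int(r.cell_id) for r in sub.itertuples()]
        kps_lab = [Keypoint(float(r.x_px), float(r.y_px),
                            frame_index=fr.frame_index)
                   for r in sub.itertuples() if r.cell_id not in dropped]
        shape = (img.shape[0] // STRIDE, img.shape[1] // STRIDE)
        if kind == "positive" and kps_lab:
            tgt = render_targets(kps_lab, shape, optics, stride=STRIDE).values
        else:
            tgt = np.zeros(shape)
        images.append(img)
        targets.append(tgt)
        true_kps.append(kps_all if kind == "positive" else [])
        true_ids.append(ids_all if kind == "positive" else [])
    return SampleStream(kind, session_id, images, targets), true_kps, true_ids


@pytest.fixture(scope="session")
def trained(fx_optics):
    """Detector trained on the 10-session desk-scale corpus."""
    streams = []
    for i in range(5):
        s, _, _ = build_stream(fx_optics, f"pos{i}", "positive", seed=100 + i)
        streams.append(s)
    for i in range(5):
        s, _, _ = build_stream(fx_optics, f"neg{i}", "negative", seed=200 + i)
        streams.append(s)
    cfg = TrainConfig(epochs=12, batch_size=8, seed=0)
    model, metrics = train_detector(streams, cfg)
    return SimpleNamespace(model=model, metrics=metrics, config=cfg,
                           streams=streams, optics=fx_optics)


@pytest.fixture(scope="session")
def fixture_eval(trained, fx_optics):
    """Held-out evaluation of the trained fixture detector.

    Computes, on a fresh positive session: per-frame keypoint matching at
    threshold 0.5 and per-cell maximum heatmap confidence at the true
    locations; and on noise-only frames: the false keypoint count.
    """
    optics = fx_optics
    model = trained.model
    vs, vk, vids = build_stream(optics, "valpos", "positive", seed=999)
    tp = fn = fp = 0
    cell_conf: dict[int, float] = {}
    heatmaps = []
    for fi, (img, kps, ids) in enumerate(zip(vs.images, vk, vids)):
        hm = predict_heatmap(model, img, frame_index=fi)
        heatmaps.append(hm)
        det = extract_keypoints(hm, 0.5, optics)
        m = match_detections(det, kps, radius_um=5.6, optics=optics)
        tp += m.true_positives
        fn += m.false_negatives
        fp += m.false_positives
        for kp, cid in zip(kps, ids):
            r = int(round((kp.y_px - (STRIDE - 1) / 2) / STRIDE))
            c = int(round((kp.x_px - (STRIDE - 1) / 2) / STRIDE))
            r = min(max(r, 0), hm.values.shape[0] - 1)
            c = min(max(c, 0), hm.values.shape[1] - 1)
            cell_conf[cid] = max(cell_conf.get(cid, 0.0),
                                 float(hm.values[r, c]))
    # 100 cell-free frames (noise only)
    scene = h.SceneSpec(cells=[], duration_s=101 / optics.frame_rate_hz,
                        noise=0.01, seed=5)
    empty_frames, _ = h.simulate_session(scene, optics)
    norm = calibrate_norm([f.pixels for f in empty_frames[:30]])
    state = BackgroundState()
    empty_fp = 0
    n_empty = 0
    for fr in empty_frames:
        if state.mean_image is None:
            state = update_background(state, fr)
            continue
        img = subtract_and_normalize(fr, state, norm)
        state = update_background(state, fr)
        empty_fp += len(extract_keypoints(predict_heatmap(model, img), 0.5,
                                          optics))
        n_empty += 1
    return SimpleNamespace(
        images=vs.images, true_kps=vk, heatmaps=heatmaps,
        tp=tp, fn=fn, fp=fp,
        recovery_at_05=tp / (tp + fn),
        cell_confidences=np.array(sorted(cell_conf.values())),
        empty_fp=empty_fp, n_empty=n_empty,
    )
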