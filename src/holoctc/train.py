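"""Detector training: asymmetric loss, pseudo-labels, mining, sessions.

Two complementary data streams drive training.  The *negative* stream is
healthy blood: every frame is labeled all-background, exposing the model
to the full repertoire of leukocytes, erythrocytes and debris.  The
*positive* stream is cancer cell lines in buffer, where every nucleated
object is a positive example; pixel labels come not from hand annotation
but from a pseudo-labeling model, so they may miss cells.  The asymmetric
binary cross-entropy

    L = -A * [ y*log(p) + (1-y)*log(1-p) ],
    A = 0.1 for apparent false positives on the positive stream, 1 otherwise

tolerates those pseudo-label omissions (a confident prediction on an
unlabeled cell-line cell is only lightly penalized) while keeping full
pressure against false calls on healthy blood.

Class imbalance is handled at two levels: a one-shot prefilter retains
only images the current model finds at least moderately suspicious
(max confidence ≥ 0.3), and each epoch draws batches preferentially from
imaging sessions with high mean loss in the previous epoch.  Sessions —
not images — are also the unit of the 80:20 train/validation split, so
repeated captures of one cell can never straddle the partition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .detect import Keypoint, TargetMap, extract_keypoints, predict_heatmap, render_targets
from .net import Adam, HeatmapNet, sigmoid
from .optics import OpticalConfig

__all__ = ["TrainConfig", "SampleStream", "SessionLossLedger",
           "asymmetric_bce", "make_pseudo_labels", "mine_hard_samples",
           "session_weighted_sampler", "split_sessions", "train_detector"]

_EPS = 1e-7


@dataclass
class TrainConfig:
    """Hyper-parameters of the detector training loop."""

    lr: float = 0.01
    lr_decay_per_epoch: float = 0.85
    loss_weight_A_fp_positive: float = 0.1
    loss_weight_default: float = 1.0
    mining_confidence: float = 0.3
    split_ratio: float = 0.8
    epochs: int = 10
    batch_size: int = 16
    seed: int = 0
    y_negative_cutoff: float = 0.5
    net_width: int = 16

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be > 0")
        if not (0 < self.lr_decay_per_epoch <= 1):
            raise ValueError("lr_decay_per_epoch must be in (0, 1]")
        if self.loss_weight_A_fp_positive <= 0 or self.loss_weight_default <= 0:
            raise ValueError("loss weights must be > 0")
        if not (0 <= self.mining_confidence <= 1):
            raise ValueError("mining_confidence must be in [0, 1]")

    def lr_at(self, epoch: int) -> float:
        return self.lr * self.lr_decay_per_epoch ** epoch


@dataclass
class SampleStream:
    """One imaging session's worth of training data.

    ``images`` are normalized frames, ``targets`` heatmap-resolution
    supervision maps.  Negative (healthy-blood) streams carry identically
    zero targets.
    """

    stream_kind: str                  # "positive" (cell line) | "negative"
    session_id: str
    images: list[np.ndarray]
    targets: list[np.ndarray]

    def __post_init__(self) -> None:
        if self.stream_kind not in ("positive", "negative"):
            raise ValueError("stream_kind must be 'positive' or 'negative'")
        if self.stream_kind == "negative":
            for t in self.targets:
                if np.any(t != 0):
                    raise ValueError("negative-stream targets must be all-zero")


@dataclass
class SessionLossLedger:
    """Per-session mean loss from the previous epoch -> sampling weights."""

    losses: dict[str, float] = field(default_factory=dict)

    def weights(self) -> tuple[list[str], np.ndarray]:
        ids = sorted(self.losses)
        vals = np.asarray([max(self.losses[s], 0.0) for s in ids])
        total = vals.sum()
        if total <= 0:
            w = np.full(len(ids), 1.0 / len(ids))
        else:
            w = vals / total
        return ids, w


def _asym_weights(y: np.ndarray, stream_kind: str, cfg: TrainConfig) -> np.ndarray:
    a = np.full(y.shape, cfg.loss_weight_default)
    if stream_kind == "positive":
        a[y < cfg.y_negative_cutoff] = cfg.loss_weight_A_fp_positive
    return a


def asymmetric_bce(p: np.ndarray, y: np.ndarray, stream_kind: str,
                   config: TrainConfig | None = None) -> float:
    """Mean asymmetric binary cross-entropy over pixels.

    ``A = 0.1`` where the stream is positive (cell line) and the target
    is below the negative cutoff — i.e. an apparent false positive that
    may simply be a pseudo-label omission — and ``A = 1`` otherwise.
    """
    cfg = config or TrainConfig()
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if p.shape != y.shape:
        raise ValueError("prediction/target shape mismatch")
    p = np.clip(p, _EPS, 1.0 - _EPS)
    a = _asym_weights(y, stream_kind, cfg)
    return float(np.mean(-a * (y * np.log(p) + (1.0 - y) * np.log(1.0 - p))))


def make_pseudo_labels(frames: Sequence[np.ndarray], pseudolabeler,
                       optics: OpticalConfig, threshold: float = 0.5,
                       stride: int | None = None) -> list[TargetMap]:
    """Label positive-stream frames with a companion model.

    ``pseudolabeler`` is either a trained :class:`HeatmapNet` or any
    callable mapping an image to a :class:`~holoctc.detect.Heatmap`
    (e.g. an oracle built from ground truth).  Detected keypoints are
    re-rendered as Gaussian targets at heatmap resolution.
    """
    if pseudolabeler is None:
        raise ValueError("pseudolabeler is not trained/available")
    targets: list[TargetMap] = []
    for i, img in enumerate(frames):
        if isinstance(pseudolabeler, HeatmapNet):
            hm = predict_heatmap(pseudolabeler, img, frame_index=i)
        else:
            hm = pseudolabeler(img)
        out_stride = stride if stride is not None else hm.stride
        kps = extract_keypoints(hm, threshold, optics)
        shape = (-(-img.shape[0] // out_stride), -(-img.shape[1] // out_stride))
        targets.append(render_targets(kps, shape, optics, stride=out_stride))
    return targets


def mine_hard_samples(images: Sequence[np.ndarray], model: HeatmapNet,
                      confidence: float = 0.3) -> list[int]:
    """Indices of images worth keeping: max heatmap value ≥ ``confidence``.

    A one-shot prefilter that discards frames the screening model finds
    trivially empty, enriching the set with informative examples.
    """
    kept = []
    for i, img in enumerate(images):
        hm = predict_heatmap(model, img)
        if hm.values.max() >= confidence:
            kept.append(i)
    return kept


def session_weighted_sampler(ledger: SessionLossLedger, seed: int,
                             n_draws: int = 1) -> list[str]:
    """Draw session ids with probability proportional to last-epoch loss."""
    if not ledger.losses:
        raise ValueError("ledger has no sessions")
    ids, w = ledger.weights()
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(ids), size=n_draws, p=w)
    return [ids[i] for i in picks]


def split_sessions(session_ids: Sequence[str], ratio: float = 0.8,
                   seed: int = 0) -> tuple[list[str], list[str]]:
    """Whole-session 80:20 partition into (train, validation).

    Every image of a session lands on the same side, so repeated captures
    of one cell can never leak across the split.
    """
    ids = list(session_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 sessions to split")
    rng = np.random.default_rng(seed)
    perm = list(rng.permutation(len(ids)))
    n_train = int(round(ratio * len(ids)))
    n_train = min(max(n_train, 1), len(ids) - 1)
    train = sorted(ids[i] for i in perm[:n_train])
    val = sorted(ids[i] for i in perm[n_train:])
    return train, val


def _loss_and_grad(model: HeatmapNet, images: np.ndarray, targets: np.ndarray,
                   stream_kind: str, cfg: TrainConfig) -> float:
    """One forward/backward pass; returns the batch mean loss."""
    z = model.forward_logits(images, train=True)
    p = sigmoid(z)
    y = targets
    a = _asym_weights(y, stream_kind, cfg)
    pc = np.clip(p, _EPS, 1.0 - _EPS)
    loss = float(np.mean(-a * (y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc))))
    dz = a * (p - y) / y.size
    model.backward(dz)
    return loss


def train_detector(streams: Sequence[SampleStream], config: TrainConfig,
                   model: HeatmapNet | None = None,
                   ) -> tuple[HeatmapNet, pd.DataFrame]:
    """Train the heatmap detector on positive + negative streams.

    Each epoch draws batches from sessions weighted by their previous-epoch
    mean loss (uniform in the first epoch), evaluates the asymmetric loss
    and takes an Adam step; the learning rate decays by the configured
    factor every epoch.  Fully deterministic for a fixed ``config.seed``.

    Returns the trained model and a per-epoch metrics table
    (epoch, lr, mean_loss).
    """
    kinds = {s.stream_kind for s in streams}
    if kinds != {"positive", "negative"}:
        raise ValueError("streams must include both positive and negative kinds")
    by_session = {s.session_id: s for s in streams}
    if len(by_session) != len(list(streams)):
        raise ValueError("duplicate session ids")
    model = model or HeatmapNet(seed=config.seed, width=config.net_width)
    opt = Adam(model.params(), lr=config.lr)
    rng = np.random.default_rng(config.seed + 1)
    ledger = SessionLossLedger(losses={sid: 1.0 for sid in by_session})

    n_images = sum(len(s.images) for s in streams)
    batches_per_epoch = max(1, n_images // config.batch_size)
    records = []
    for epoch in range(config.epochs):
        opt.lr = config.lr_at(epoch)
        epoch_losses: dict[str, list[float]] = {sid: [] for sid in by_session}
        ids, w = ledger.weights()
        for _ in range(batches_per_epoch):
            sid = ids[rng.choice(len(ids), p=w)]
            stream = by_session[sid]
            idx = rng.integers(0, len(stream.images), size=config.batch_size)
            imgs = np.stack([stream.images[i] for i in idx])[:, None]
            tgts = np.stack([stream.targets[i] for i in idx])[:, None]
            loss = _loss_and_grad(model, imgs, tgts, stream.stream_kind, config)
            if not math.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged (non-finite loss) at epoch {epoch}, "
                    f"session {sid}")
            opt.step(model.grads())
            epoch_losses[sid].append(loss)
        ledger = SessionLossLedger(losses={
            sid: (float(np.mean(v)) if v else ledger.losses[sid])
            for sid, v in epoch_losses.items()})
        all_losses = [x for v in epoch_losses.values() for x in v]
        records.append({"epoch": epoch, "lr": opt.lr,
                        "mean_loss": float(np.mean(all_losses))})
    return model, pd.DataFrame(records)
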