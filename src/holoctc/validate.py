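"""Validation statistics: detection matching, recovery, FPR, PPV.

Recovery (the true positive rate) is the fraction of known cells the
detector finds at a given operating threshold; the false positive rate is
expressed per millilitre of whole blood, the clinically meaningful unit
for rare-cell work; and the positive predictive value follows from both
under an assumed CTC abundance a (cells/mL):

    PPV(θ) = TPR(θ) · a / (TPR(θ) · a + FPR_per_mL(θ))

Detections are matched to reference cells by spatial proximity: greedy
one-to-one assignment in descending confidence, each prediction to the
nearest unmatched reference within a radius of twice the supervision
sigma (5.6 μm by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .detect import Keypoint, SIGMA_UM_DEFAULT
from .optics import OpticalConfig

__all__ = ["MatchResult", "RecoveryCurve", "match_detections",
           "recovery_curve", "fpr_per_ml", "ppv"]


@dataclass
class MatchResult:
    """Outcome of matching predicted keypoints to reference keypoints."""

    true_positives: int
    false_positives: int
    false_negatives: int
    pairs: list[tuple[int, int, float]] = field(default_factory=list)
    # (prediction index, reference index, distance in μm)

    @property
    def recall(self) -> float | None:
        n_ref = self.true_positives + self.false_negatives
        return self.true_positives / n_ref if n_ref else None

    @property
    def precision(self) -> float | None:
        n_pred = self.true_positives + self.false_positives
        return self.true_positives / n_pred if n_pred else None


@dataclass
class RecoveryCurve:
    """Recovery (TPR) and FPR/mL over a grid of operating thresholds."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr_per_ml: np.ndarray


def match_detections(predicted: Sequence[Keypoint],
                     reference: Sequence[Keypoint],
                     radius_um: float = 2 * SIGMA_UM_DEFAULT,
                     optics: OpticalConfig | None = None) -> MatchResult:
    """Greedy proximity matching of predictions to reference points.

    Predictions are taken in descending confidence (ties by position) and
    each grabs its nearest still-unmatched reference within ``radius_um``.
    Unmatched predictions are false positives; unmatched references false
    negatives.
    """
    if radius_um <= 0:
        raise ValueError("radius_um must be > 0")
    optics = optics or OpticalConfig()
    scale = optics.object_pixel_um
    order = sorted(range(len(predicted)),
                   key=lambda i: (-predicted[i].confidence,
                                  predicted[i].y_px, predicted[i].x_px))
    used_ref: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for i in order:
        p = predicted[i]
        best_j, best_d = None, radius_um
        for j, r in enumerate(reference):
            if j in used_ref:
                continue
            d = math.hypot(p.x_px - r.x_px, p.y_px - r.y_px) * scale
            if d <= best_d:
                best_j, best_d = j, d
        if best_j is not None:
            used_ref.add(best_j)
            pairs.append((i, best_j, best_d))
    tp = len(pairs)
    return MatchResult(
        true_positives=tp,
        false_positives=len(predicted) - tp,
        false_negatives=len(reference) - tp,
        pairs=pairs,
    )


def recovery_curve(true_cell_confidences: Sequence[float],
                   fp_confidences: Sequence[float],
                   volume_ml: float,
                   thresholds: Sequence[float]) -> RecoveryCurve:
    """Recovery and FPR/mL as the operating threshold sweeps.

    ``true_cell_confidences`` holds the per-cell maximum model confidence
    of each known true cell (0 for a missed cell); ``fp_confidences`` the
    confidences of false-positive events.  At each threshold θ,
    TPR = fraction of true cells with confidence > θ and
    FPR/mL = count of false positives with confidence > θ over volume.
    """
    thr = np.asarray(thresholds, dtype=float)
    if np.any((thr < 0) | (thr > 1)):
        raise ValueError("thresholds must lie in [0, 1]")
    if volume_ml <= 0:
        raise ValueError("volume_ml must be > 0")
    conf = np.asarray(true_cell_confidences, dtype=float)
    fps = np.asarray(fp_confidences, dtype=float)
    if conf.size:
        tpr = np.array([(conf > t).mean() for t in thr])
    else:
        tpr = np.full(thr.shape, np.nan)
    fpr = np.array([(fps > t).sum() / volume_ml for t in thr])
    return RecoveryCurve(thresholds=thr, tpr=tpr, fpr_per_ml=fpr)


def fpr_per_ml(n_false_positives: int, volume_ml: float) -> float:
    """False positives per millilitre of processed whole blood."""
    if volume_ml <= 0:
        raise ValueError("volume_ml must be > 0")
    if n_false_positives < 0:
        raise ValueError("count must be >= 0")
    return n_false_positives / volume_ml


def ppv(tpr: float, fpr_per_ml_rate: float,
        abundance_cells_per_ml: float) -> float | None:
    """Positive predictive value at an assumed CTC abundance.

    Returns None for the degenerate 0/0 case (no expected detections of
    either kind).
    """
    if not (0.0 <= tpr <= 1.0):
        raise ValueError("tpr must be in [0, 1]")
    if fpr_per_ml_rate < 0 or abundance_cells_per_ml < 0:
        raise ValueError("rates must be >= 0")
    num = tpr * abundance_cells_per_ml
    den = num + fpr_per_ml_rate
    if den == 0:
        return None
    return num / den
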