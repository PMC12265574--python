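"""Frame preprocessing: background subtraction, normalization, focus score.

The static fringe pattern of the channel (dust, beam profile) is removed
by subtracting an exponential moving average (EMA) of preceding frames of
the same imaging session; flowing cells are transient and contaminate the
average negligibly at the low concentrations of interest.  The residual
is then scaled by a fixed mean/std so the detector sees a consistent
intensity distribution across sessions and stations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import Frame

__all__ = ["BackgroundState", "NormSpec", "update_background",
           "subtract_and_normalize", "focus_metric", "calibrate_norm"]


@dataclass
class BackgroundState:
    """Running EMA background estimate for one imaging session."""

    mean_image: np.ndarray | None = None
    alpha: float = 0.05
    frames_seen: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must be in (0, 1]")


@dataclass(frozen=True)
class NormSpec:
    """Fixed normalization constants applied after background subtraction."""

    mean: float = 0.0
    std: float = 1.0

    def __post_init__(self) -> None:
        if not (self.std > 0):
            raise ValueError("std must be > 0")


def _pixels(frame) -> np.ndarray:
    return frame.pixels if isinstance(frame, Frame) else np.asarray(frame)


def update_background(state: BackgroundState, frame) -> BackgroundState:
    """EMA update: ``mean' = (1-alpha)*mean + alpha*frame``.

    The first frame of a session initializes the estimate exactly.
    Returns a new state; the input state is not mutated.
    """
    px = _pixels(frame).astype(float)
    if state.mean_image is None:
        mean = px.copy()
    else:
        if state.mean_image.shape != px.shape:
            raise ValueError("frame shape does not match background state")
        mean = (1.0 - state.alpha) * state.mean_image + state.alpha * px
    return BackgroundState(mean_image=mean, alpha=state.alpha,
                           frames_seen=state.frames_seen + 1)


def subtract_and_normalize(frame, state: BackgroundState,
                           norm: NormSpec) -> np.ndarray:
    """Background-subtract a frame and apply the fixed normalization."""
    if state.mean_image is None:
        raise ValueError("background not initialized; feed frames first")
    px = _pixels(frame).astype(float)
    if px.shape != state.mean_image.shape:
        raise ValueError("frame shape does not match background state")
    out = ((px - state.mean_image) - norm.mean) / norm.std
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite values after normalization")
    return out


def focus_metric(frame) -> float:
    """Mean squared gradient magnitude normalized by mean intensity squared.

    Scale-invariant: multiplying the frame by a constant leaves the score
    unchanged.  Sharper fringes give higher scores; an all-zero frame is
    defined to score 0.
    """
    px = _pixels(frame).astype(float)
    if px.size == 0:
        raise ValueError("empty frame")
    mean = px.mean()
    if mean == 0.0:
        return 0.0
    gy, gx = np.gradient(px)
    return float((gx ** 2 + gy ** 2).mean() / mean ** 2)


def calibrate_norm(frames, states=None, alpha: float = 0.05) -> NormSpec:
    """Derive a fixed :class:`NormSpec` from a calibration set of frames.

    Runs the EMA over the frames and measures the mean and std of the
    background-subtracted residuals of the second half (after the EMA has
    converged).  The result is meant to be frozen and reused.
    """
    frames = list(frames)
    if len(frames) < 2:
        raise ValueError("need at least 2 calibration frames")
    state = BackgroundState(alpha=alpha)
    residuals = []
    for i, f in enumerate(frames):
        if state.mean_image is not None and i >= len(frames) // 2:
            residuals.append(_pixels(f).astype(float) - state.mean_image)
        state = update_background(state, f)
    res = np.stack(residuals)
    std = float(res.std())
    return NormSpec(mean=float(res.mean()), std=std if std > 0 else 1.0)
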