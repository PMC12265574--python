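"""Synthetic in-flow holography and fluorescence data generation.

Emulates the data streams of the dual-modality station: sparse blood cells
(RBC-like, WBC-like, CTC-like) transit a 1440x256 px field of view at
constant velocity while an in-line hologram is recorded at 450 fps, and
marker-positive cells simultaneously produce broad pulses on two
photomultiplier (PMT) channels whose width equals the field-of-view
transit time.

The hologram formation model is scalar: each cell is a pure phase object
(a smooth cosine-tapered phase bump), the transmitted field is propagated
to the sensor conjugate plane by the angular-spectrum method, and the
recorded frame is the intensity of the propagated field plus shot noise.
At the default sampling (0.345 μm object-plane pixels, 405 nm light) the
representable spatial frequencies all lie inside the propagating band, so
the propagation operator is exactly unitary — a property the tests
exploit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .optics import OpticalConfig

__all__ = [
    "CellSpec", "SceneSpec", "Frame", "PMTTrace", "ChannelConfig",
    "angular_spectrum_propagate", "render_hologram", "simulate_session",
    "simulate_pmt", "random_scene", "CLASS_GEOMETRY", "MARKER_PROBS",
]

#: Per-class (radius_um_range, phase_peak_rad_range).  CTC-like cells are
#: larger and optically thicker than leukocytes, which in turn exceed
#: red cells — the separability the detector exploits.
CLASS_GEOMETRY = {
    "RBC": ((3.0, 4.0), (0.6, 1.0)),
    "WBC": ((4.0, 7.0), (0.9, 1.5)),
    "CTC": ((7.0, 12.0), (1.5, 2.5)),
}

#: Default marker-expression probabilities per class: (PSMA+, EpCAM+).
#: CTCs always express PSMA; 37% co-express EpCAM.  A small nonspecific
#: PSMA rate on WBCs models imperfect antibody specificity.
MARKER_PROBS = {
    "RBC": (0.0, 0.0),
    "WBC": (0.005, 0.0),
    "CTC": (1.0, 0.37),
}

#: Default flow speed: a cell crosses the 496.8 μm wide field in ~5 frame
#: periods at 450 fps.
DEFAULT_VELOCITY_UM_S = 45_000.0


@dataclass
class CellSpec:
    """Ground-truth description of one flowing cell."""

    cell_class: str
    center_um: tuple[float, float]          # (x, y) object-plane, μm, at t=0
    radius_um: float
    phase_peak_rad: float
    velocity_um_per_s: float
    psma_positive: bool = False
    epcam_positive: bool = False
    cell_id: int = 0

    def __post_init__(self) -> None:
        if self.cell_class not in CLASS_GEOMETRY:
            raise ValueError(f"unknown cell_class {self.cell_class!r}")
        if not (self.radius_um > 0):
            raise ValueError("radius_um must be > 0")
        if not (0.0 <= self.phase_peak_rad <= 2 * math.pi):
            raise ValueError("phase_peak_rad must be in [0, 2*pi]")
        if not (self.velocity_um_per_s > 0):
            raise ValueError("velocity must be > 0")
        if any(not math.isfinite(c) for c in self.center_um):
            raise ValueError("cell center must be finite")

    def position_at(self, t_s: float) -> tuple[float, float]:
        """Object-plane position at time ``t_s`` (flow along +x)."""
        x0, y0 = self.center_um
        return (x0 + self.velocity_um_per_s * t_s, y0)


@dataclass
class SceneSpec:
    """A full imaging session: cells, background behaviour, duration.

    ``background_drift`` is a slow multiplicative intensity modulation
    ``1 + amplitude * sin(2*pi*t/period_s)`` applied to each frame;
    ``noise`` is the shot-noise scale (std of per-pixel noise at unit
    intensity, in units of the background level).
    """

    cells: list[CellSpec] = field(default_factory=list)
    background_drift: dict = field(default_factory=lambda: {"amplitude": 0.0, "period_s": 1.0})
    noise: float = 0.0
    duration_s: float = 1.0
    seed: int = 0
    max_cells_per_frame: int = 12
    background_level: float = 1.0


@dataclass
class Frame:
    """One recorded hologram."""

    pixels: np.ndarray                       # (height, width), non-negative
    session_id: str = "s0"
    frame_index: int = 0
    time_s: float = 0.0


@dataclass
class PMTTrace:
    """One photomultiplier fluorescence time series."""

    channel: str                             # "PSMA" or "EpCAM"
    sample_rate_hz: float
    values: np.ndarray
    session_id: str = "s0"

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.sample_rate_hz


@dataclass
class ChannelConfig:
    """Synthesis parameters for one PMT channel."""

    channel: str = "PSMA"
    sample_rate_hz: float = 50_000.0
    pulse_amplitude: float = 1.0
    baseline: float = 0.1
    noise_sigma: float = 0.0
    drift_amplitude: float = 0.0
    drift_period_s: float = 2.0


def angular_spectrum_propagate(field_2d: np.ndarray, distance_um: float,
                               optics: OpticalConfig) -> np.ndarray:
    """Propagate a complex scalar field by the angular-spectrum method.

    Evanescent components (none representable at the default sampling)
    are suppressed, so within the propagating band the operator is
    unitary: total power is conserved.
    """
    lam = optics.wavelength_um
    dx = optics.object_pixel_um
    h, w = field_2d.shape
    fx = np.fft.fftfreq(w, d=dx)
    fy = np.fft.fftfreq(h, d=dx)
    fxx, fyy = np.meshgrid(fx, fy)
    arg = 1.0 - (lam * fxx) ** 2 - (lam * fyy) ** 2
    kz = 2.0 * np.pi / lam * np.sqrt(np.maximum(arg, 0.0))
    transfer = np.where(arg > 0, np.exp(1j * kz * distance_um), 0.0)
    return np.fft.ifft2(np.fft.fft2(field_2d) * transfer)


def _phase_field(cells: Sequence[CellSpec], optics: OpticalConfig) -> np.ndarray:
    w, h = optics.roi_px
    dx = optics.object_pixel_um
    phi = np.zeros((h, w))
    ys = (np.arange(h) * dx)[:, None]
    xs = (np.arange(w) * dx)[None, :]
    for cell in cells:
        xc, yc = cell.center_um
        if not (math.isfinite(xc) and math.isfinite(yc)):
            raise ValueError("cell center must be finite")
        # render only a local window around the cell
        r_px = int(math.ceil(cell.radius_um / dx)) + 2
        cx, cy = int(round(xc / dx)), int(round(yc / dx))
        x0, x1 = max(cx - r_px, 0), min(cx + r_px + 1, w)
        y0, y1 = max(cy - r_px, 0), min(cy + r_px + 1, h)
        if x0 >= x1 or y0 >= y1:
            continue
        r = np.hypot(xs[:, x0:x1] - xc, ys[y0:y1, :] - yc)
        bump = np.where(
            r < cell.radius_um,
            0.5 * cell.phase_peak_rad * (1.0 + np.cos(np.pi * r / cell.radius_um)),
            0.0,
        )
        phi[y0:y1, x0:x1] += bump
    return phi


def render_hologram(scene_at_instant: Sequence[CellSpec], optics: OpticalConfig,
                    seed: int, *, background: float = 1.0,
                    noise: float = 0.0) -> Frame:
    """Render one in-line hologram of the given cells.

    Each cell is a phase-only object; the transmitted field is propagated
    by ``optics.defocus_um`` and the intensity recorded.  ``noise`` is
    the relative shot-noise scale (per-pixel Gaussian with std
    ``noise * sqrt(I)``); zero noise is exactly deterministic.
    """
    for cell in scene_at_instant:
        if cell.radius_um <= 0 or cell.phase_peak_rad < 0:
            raise ValueError("invalid cell geometry")
    phi = _phase_field(scene_at_instant, optics)
    u0 = np.exp(1j * phi)
    if optics.defocus_um != 0.0 and len(scene_at_instant) > 0:
        u = angular_spectrum_propagate(u0, optics.defocus_um, optics)
    else:
        u = u0
    intensity = background * np.abs(u) ** 2
    if noise > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(
            scale=noise * np.sqrt(np.maximum(intensity, 0.0)))
        intensity = np.maximum(intensity, 0.0)
    return Frame(pixels=intensity)


def simulate_session(scene: SceneSpec, optics: OpticalConfig,
                     session_id: str = "s0") -> tuple[list[Frame], pd.DataFrame]:
    """Render a full session of frames plus the per-frame ground truth.

    Each cell advances by ``velocity / frame_rate`` per frame along +x.
    The ground-truth table lists, per frame, every cell whose center lies
    inside the field of view, with pixel coordinates.
    """
    if scene.duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    fps = optics.frame_rate_hz
    n_frames = int(round(scene.duration_s * fps))
    w_px, h_px = optics.roi_px
    dx = optics.object_pixel_um
    fov_w = w_px * dx
    drift = scene.background_drift or {}
    drift_amp = float(drift.get("amplitude", 0.0))
    drift_period = float(drift.get("period_s", 1.0))

    frames: list[Frame] = []
    rows: list[dict] = []
    margin = 25.0  # μm beyond the FOV within which fringes still matter
    for k in range(n_frames):
        t = k / fps
        visible: list[CellSpec] = []
        for cell in scene.cells:
            x, y = cell.position_at(t)
            if -margin <= x <= fov_w + margin:
                visible.append(CellSpec(
                    cell.cell_class, (x, y), cell.radius_um,
                    cell.phase_peak_rad, cell.velocity_um_per_s,
                    cell.psma_positive, cell.epcam_positive, cell.cell_id))
                if 0.0 <= x < fov_w:
                    rows.append({
                        "frame_index": k, "cell_id": cell.cell_id,
                        "x_px": x / dx, "y_px": y / dx,
                        "cell_class": cell.cell_class,
                        "psma": cell.psma_positive,
                        "epcam": cell.epcam_positive,
                    })
        if len(visible) > scene.max_cells_per_frame:
            visible = visible[: scene.max_cells_per_frame]
        level = scene.background_level * (
            1.0 + drift_amp * math.sin(2.0 * math.pi * t / drift_period))
        frame = render_hologram(visible, optics, seed=scene.seed + 1000 + k,
                                background=level, noise=scene.noise)
        frame.session_id = session_id
        frame.frame_index = k
        frame.time_s = t
        frames.append(frame)
    truth = pd.DataFrame(
        rows, columns=["frame_index", "cell_id", "x_px", "y_px",
                       "cell_class", "psma", "epcam"])
    return frames, truth


def simulate_pmt(ground_truth: pd.DataFrame, optics: OpticalConfig,
                 channel_config: ChannelConfig,
                 duration_s: float | None = None,
                 session_id: str = "s0") -> PMTTrace:
    """Synthesize one PMT channel from the session ground truth.

    Every cell positive for the channel's marker contributes a Gaussian
    pulse centered at its mid-transit time whose full width at half
    maximum equals its field-of-view transit time; marker-negative cells
    contribute nothing.  The baseline carries configurable slow drift and
    Gaussian noise.
    """
    chan = channel_config.channel
    if chan not in ("PSMA", "EpCAM"):
        raise ValueError(f"channel must be PSMA or EpCAM, got {chan!r}")
    fps = optics.frame_rate_hz
    if channel_config.sample_rate_hz < 10.0 * fps:
        raise ValueError("PMT sample rate must be at least 10x the frame rate")
    marker_col = "psma" if chan == "PSMA" else "epcam"
    if duration_s is None:
        duration_s = (ground_truth["frame_index"].max() + 1) / fps if len(ground_truth) else 1.0
    sr = channel_config.sample_rate_hz
    n = int(round(duration_s * sr))
    t = np.arange(n) / sr
    values = np.full(n, channel_config.baseline)
    if channel_config.drift_amplitude:
        values = values + channel_config.drift_amplitude * np.sin(
            2.0 * np.pi * t / channel_config.drift_period_s)
    if len(ground_truth):
        for cell_id, grp in ground_truth.groupby("cell_id"):
            if not bool(grp[marker_col].iloc[0]):
                continue
            t_first = grp["frame_index"].min() / fps
            t_last = grp["frame_index"].max() / fps
            t_mid = 0.5 * (t_first + t_last)
            transit = (t_last - t_first) + 1.0 / fps
            sigma = transit / (2.0 * math.sqrt(2.0 * math.log(2.0)))
            values = values + channel_config.pulse_amplitude * np.exp(
                -0.5 * ((t - t_mid) / sigma) ** 2)
    if channel_config.noise_sigma > 0:
        rng = np.random.default_rng(hash((chan, session_id)) % (2**31))
        values = values + rng.normal(scale=channel_config.noise_sigma, size=n)
    return PMTTrace(channel=chan, sample_rate_hz=sr, values=values,
                    session_id=session_id)


def random_scene(rate_per_s: float, duration_s: float, optics: OpticalConfig,
                 seed: int, *, class_probs: dict[str, float] | None = None,
                 marker_probs: dict[str, tuple[float, float]] | None = None,
                 velocity_um_s: float = DEFAULT_VELOCITY_UM_S,
                 noise: float = 0.0,
                 background_drift: dict | None = None) -> SceneSpec:
    """Draw a random session: Poisson cell arrivals at ``rate_per_s``.

    Arrival time is the instant a cell's center enters the field at x=0;
    arrivals slightly before t=0 are included so cells mid-transit at the
    session start appear.  Classes, geometry and marker status are drawn
    per :data:`CLASS_GEOMETRY` and :data:`MARKER_PROBS`.
    """
    rng = np.random.default_rng(seed)
    class_probs = class_probs or {"RBC": 0.3, "WBC": 0.5, "CTC": 0.2}
    marker_probs = marker_probs or MARKER_PROBS
    names = list(class_probs)
    probs = np.asarray([class_probs[c] for c in names], dtype=float)
    probs = probs / probs.sum()
    fov_w, fov_h = optics.fov_um
    transit_s = fov_w / velocity_um_s
    t_lo, t_hi = -transit_s, duration_s
    n = rng.poisson(rate_per_s * (t_hi - t_lo))
    cells: list[CellSpec] = []
    for i in range(n):
        t_arr = rng.uniform(t_lo, t_hi)
        cls = names[rng.choice(len(names), p=probs)]
        (r_lo, r_hi), (p_lo, p_hi) = CLASS_GEOMETRY[cls]
        p_psma, p_epcam = marker_probs[cls]
        y = rng.uniform(0.15 * fov_h, 0.85 * fov_h)
        cells.append(CellSpec(
            cell_class=cls,
            center_um=(-velocity_um_s * t_arr, y),
            radius_um=rng.uniform(r_lo, r_hi),
            phase_peak_rad=rng.uniform(p_lo, p_hi),
            velocity_um_per_s=velocity_um_s,
            psma_positive=bool(rng.random() < p_psma),
            epcam_positive=bool(rng.random() < p_epcam),
            cell_id=i,
        ))
    return SceneSpec(cells=cells, duration_s=duration_s, seed=seed,
                     noise=noise,
                     background_drift=background_drift or {"amplitude": 0.0, "period_s": 1.0})
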