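"""Optical configuration of the in-line (Gabor) holographic imaging station.

The station records in-line holograms: a collimated 405 nm beam passes
through the flow channel and the interference between the light scattered
by a cell and the unscattered beam is captured directly on the sensor,
without a separate reference arm.  All geometry downstream (object-plane
pixel size, field of view, transit times) derives from this configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class OpticalConfig:
    """Geometry and timing of the holographic imaging station.

    Parameters
    ----------
    wavelength_nm : float
        Laser wavelength in nanometres.
    magnification : float
        Objective magnification.
    na : float
        Numerical aperture of the objective.
    pixel_pitch_um : float
        Physical sensor pixel pitch in micrometres.
    frame_rate_hz : float
        Camera frame rate.
    roi_px : tuple[int, int]
        Capture region of interest as ``(width, height)`` in pixels.
    defocus_um : float
        Distance from the object plane to the focal plane used by the
        scalar propagation model.  Zero means in focus.
    """

    wavelength_nm: float = 405.0
    magnification: float = 10.0
    na: float = 0.30
    pixel_pitch_um: float = 3.45
    frame_rate_hz: float = 450.0
    roi_px: tuple[int, int] = (1440, 256)
    defocus_um: float = 0.0

    def __post_init__(self) -> None:
        for name in ("wavelength_nm", "magnification", "na",
                     "pixel_pitch_um", "frame_rate_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        w, h = self.roi_px
        if w <= 0 or h <= 0:
            raise ValueError("roi_px dimensions must be strictly positive")

    @property
    def object_pixel_um(self) -> float:
        """Object-plane pixel size (sensor pitch demagnified), in μm."""
        return self.pixel_pitch_um / self.magnification

    @property
    def fov_um(self) -> tuple[float, float]:
        """Field of view (width, height) in object-plane micrometres."""
        w, h = self.roi_px
        return (w * self.object_pixel_um, h * self.object_pixel_um)

    @property
    def wavelength_um(self) -> float:
        return self.wavelength_nm * 1e-3

    def um_to_px(self, um: float) -> float:
        """Convert an object-plane length in μm to full-resolution pixels."""
        return um / self.object_pixel_um

    def px_to_um(self, px: float) -> float:
        return px * self.object_pixel_um
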