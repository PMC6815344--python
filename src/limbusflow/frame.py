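"""Core image container for fluorescence confocal laser endomicroscopy (CLE) frames.

A frame is a single 2-D grayscale intensity image in arbitrary units (au)
together with its physical pixel pitch.  Coordinates follow the image
convention: 0-based, row-major, pixel centers, ``(row, col) == (y, x)`` with
``(0, 0)`` at the top-left.  All physical quantities carry explicit unit
suffixes (``_um``, ``_s``, ``_au``) throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FrameImage",
    "FOV_UM",
    "LATERAL_RESOLUTION_UM",
    "PSF_SIGMA_UM",
    "FWHM_PER_SIGMA",
]

#: Field of view of the fiber-optic microendoscope, in micrometres (square).
FOV_UM = 423.0

#: Lateral optical resolution (full width at half maximum), in micrometres.
LATERAL_RESOLUTION_UM = 3.5

#: FWHM = 2 * sqrt(2 ln 2) * sigma for a Gaussian profile.
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: Gaussian PSF standard deviation matching the lateral-resolution FWHM.
PSF_SIGMA_UM = LATERAL_RESOLUTION_UM / FWHM_PER_SIGMA


class InvalidFrameError(ValueError):
    """Raised when pixel data or pitch violate the frame contract."""


@dataclass
class FrameImage:
    """One 2-D CLE intensity frame.

    Parameters
    ----------
    pixels
        Rectangular array of finite, non-negative intensities (au).
    pitch_um
        Physical edge length of one pixel, micrometres; strictly positive.
    """

    pixels: np.ndarray
    pitch_um: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise InvalidFrameError("pixels must be a 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise InvalidFrameError("pixel intensities must be finite")
        if np.any(self.pixels < 0):
            raise InvalidFrameError("pixel intensities must be non-negative")
        if not (float(self.pitch_um) > 0):
            raise InvalidFrameError("pitch_um must be > 0")
        self.pitch_um = float(self.pitch_um)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def fov_um(self) -> tuple[float, float]:
        """Physical extent (height, width) in micrometres."""
        h, w = self.pixels.shape
        return (h * self.pitch_um, w * self.pitch_um)

    def total_au(self) -> float:
        return float(self.pixels.sum())
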