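"""Calibrated containers for time-lapse fluorescence stacks.

A movie is a ``T x H x W`` array of non-negative intensities plus the physical
calibration (pixel size in micrometres, frame interval in seconds) needed to
express wave metrics in physical units.  Nothing here knows about waves; it is
shared plumbing for the synthesis and analysis layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class GeometryError(ValueError):
    """A shape, calibration or region-of-interest parameter is invalid."""


@dataclass(frozen=True)
class StackGeometry:
    """Physical calibration of an image stack.

    Parameters
    ----------
    n_frames : int
        Number of time points; at least 2 for any dynamic analysis.
    height, width : int
        Frame size in pixels.
    pixel_size_um : float
        Lateral calibration, micrometres per pixel.
    frame_interval_s : float
        Time between consecutive frames, seconds.
    """

    n_frames: int
    height: int
    width: int
    pixel_size_um: float
    frame_interval_s: float

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise GeometryError("n_frames must be >= 2 for dynamic analysis")
        if self.height <= 0 or self.width <= 0:
            raise GeometryError("height and width must be positive")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise GeometryError("pixel_size_um and frame_interval_s must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_frames, self.height, self.width)

    @property
    def field_um(self) -> tuple[float, float]:
        """Physical field of view (height, width) in micrometres."""
        return (self.height * self.pixel_size_um, self.width * self.pixel_size_um)


@dataclass
class ImageStack:
    """A calibrated ``T x H x W`` fluorescence movie.

    ``data`` holds finite, non-negative float intensities; ``geometry`` carries
    the physical calibration and must be shape-consistent with ``data``.
    """

    data: np.ndarray
    geometry: StackGeometry
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise GeometryError("stack data must be 3-dimensional (T, H, W)")
        if self.data.shape != self.geometry.shape:
            raise GeometryError(
                f"data shape {self.data.shape} inconsistent with geometry "
                f"{self.geometry.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise GeometryError("stack intensities must be finite")
        if np.any(self.data < 0):
            raise GeometryError("stack intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.geometry.n_frames


@dataclass(frozen=True)
class DropletGeometry:
    """Circular droplet cross-section used for perimeter (rim) sampling.

    ``center`` is the (row, col) pixel position of the circle centre;
    ``radius_um`` the rim radius and ``rim_width_um`` the radial width of the
    membrane band, both in micrometres.
    """

    center: tuple[float, float]
    radius_um: float
    rim_width_um: float

    def __post_init__(self) -> None:
        if not (self.radius_um > self.rim_width_um > 0):
            raise GeometryError("require radius_um > rim_width_um > 0")

    def validate_in_frame(self, geom: StackGeometry) -> None:
        """Raise GeometryError unless the outer rim circle fits in the frame."""
        r_px = (self.radius_um + self.rim_width_um / 2) / geom.pixel_size_um
        row, col = self.center
        if (
            row - r_px < 0
            or col - r_px < 0
            or row + r_px > geom.height - 1
            or col + r_px > geom.width - 1
        ):
            raise GeometryError("droplet circle (incl. rim) exceeds the frame")
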