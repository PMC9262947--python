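"""Phenomenological surface-wave movie generators.

The patterns mimic what self-organized MinDE oscillations look like on a
supported lipid bilayer or a droplet rim: planar traveling waves, rotating
spirals, standing waves, and circling rim patches — optionally with an
anticorrelated second channel emulating FtsA-anchored FtsZ being displaced by
the Min wave.  The generators are phenomenological (a phase equation, not a
reaction-diffusion model), which is exactly what makes them usable as ground
truth for the kymograph analysis: wavelength, velocity, period and phase
relations are inputs, not emergent quantities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import signal

from minwaves.geometry import DropletGeometry, ImageStack, StackGeometry

__all__ = [
    "AliasingError",
    "WaveSimParams",
    "simulate_traveling_wave",
    "simulate_standing_wave",
    "simulate_droplet_pattern",
    "default_geometry",
]

#: Exponent of the raised-cosine arc profile used for droplet rim patches.
#: 4 gives a patch covering roughly a quarter of the rim.
PATCH_SHARPNESS = 4.0

# Fraction of the period over which the asymmetric sawtooth rises; the short
# falling edge emulates the sharp rear edge of MinE-driven membrane detachment.
SAWTOOTH_RISE_FRACTION = 0.85


class AliasingError(ValueError):
    """Requested pattern is not resolvable on the sampling grid."""


def default_geometry(
    n_frames: int = 60,
    height: int = 256,
    width: int = 256,
    pixel_size_um: float = 0.6,
    frame_interval_s: float = 5.0,
) -> StackGeometry:
    """Desk-scale default acquisition geometry (keeps >=2 wavelengths of a
    76 um wave in a 256-px frame)."""
    return StackGeometry(n_frames, height, width, pixel_size_um, frame_interval_s)


@dataclass
class WaveSimParams:
    """Ground-truth parameters for a synthetic surface-wave movie.

    Traveling patterns (``planar``, ``spiral``, ``droplet_ring``) are set by
    ``wavelength_um`` and ``velocity_um_s``; standing waves by
    ``wavelength_um`` and ``period_s``.  ``antiphase_channel`` requests a
    second channel phase-shifted by pi whose bright band is broadened by
    ``antiphase_width_factor`` (>= 1), emulating the broader intensity
    distribution of FtsZ relative to the Min signal.
    """

    pattern: Literal["planar", "spiral", "standing", "droplet_ring"] = "planar"
    wavelength_um: float = 76.0
    velocity_um_s: float = 0.5
    period_s: float = 105.0
    direction_deg: float = 0.0
    amplitude: float = 100.0
    baseline: float = 200.0
    profile: Literal["sinusoid", "asymmetric_sawtooth"] = "sinusoid"
    antiphase_channel: bool = False
    antiphase_width_factor: float = 1.0
    noise_sd: float = 0.0
    noise_model: Literal["gaussian", "poisson"] = "gaussian"
    seed: int = 0

    def validate(self, geom: StackGeometry | None = None) -> None:
        if self.wavelength_um <= 0:
            raise ValueError("wavelength_um must be positive")
        if self.pattern in ("planar", "spiral", "droplet_ring") and self.velocity_um_s <= 0:
            raise ValueError("velocity_um_s must be positive for traveling patterns")
        if self.pattern == "standing" and self.period_s <= 0:
            raise ValueError("period_s must be positive for standing waves")
        if self.amplitude < 0 or self.baseline < 0:
            raise ValueError("amplitude and baseline must be non-negative")
        if self.antiphase_width_factor < 1.0:
            raise ValueError("antiphase_width_factor must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if geom is not None:
            if self.wavelength_um < 2 * geom.pixel_size_um:
                raise AliasingError(
                    f"wavelength {self.wavelength_um} um below the Nyquist limit "
                    f"2 * {geom.pixel_size_um} um/px"
                )
            if self.pattern == "standing" and self.period_s < 2 * geom.frame_interval_s:
                raise AliasingError(
                    f"period {self.period_s} s below the temporal Nyquist limit "
                    f"2 * {geom.frame_interval_s} s/frame"
                )


def _profile(phase: np.ndarray, kind: str) -> np.ndarray:
    """Periodic wave profile in [-1, 1] as a function of phase (radians)."""
    if kind == "sinusoid":
        return np.cos(phase)
    if kind == "asymmetric_sawtooth":
        # slow rise, sharp fall: the rear edge of the traveling band is steep
        return signal.sawtooth(phase + np.pi, width=SAWTOOTH_RISE_FRACTION)
    raise ValueError(f"unknown profile {kind!r}")


def _antiphase_profile(phase: np.ndarray, width_factor: float) -> np.ndarray:
    """Pi-shifted band profile whose bright band broadens with width_factor.

    Reduces exactly to ``cos(phase + pi)`` at width_factor 1; larger factors
    flatten the bright band while keeping the pi phase offset of its centre.
    """
    band = (1.0 + np.cos(phase + np.pi)) / 2.0
    return 2.0 * band ** (1.0 / width_factor**2) - 1.0


def _apply_noise(clean: np.ndarray, params: WaveSimParams, rng: np.random.Generator) -> np.ndarray:
    if params.noise_model == "poisson":
        return rng.poisson(np.clip(clean, 0, None)).astype(float)
    if params.noise_sd == 0:
        return np.clip(clean, 0, None)
    noisy = clean + rng.normal(0.0, params.noise_sd, size=clean.shape)
    return np.clip(noisy, 0, None)


def _grid_um(geom: StackGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Row/col coordinate grids in micrometres."""
    rows = np.arange(geom.height)[:, None] * geom.pixel_size_um
    cols = np.arange(geom.width)[None, :] * geom.pixel_size_um
    return np.broadcast_to(rows, (geom.height, geom.width)), np.broadcast_to(
        cols, (geom.height, geom.width)
    )


def _phase_planar(params: WaveSimParams, geom: StackGeometry, t_s: float) -> np.ndarray:
    y_um, x_um = _grid_um(geom)
    theta = np.deg2rad(params.direction_deg)
    s = x_um * np.cos(theta) + y_um * np.sin(theta)
    return 2 * np.pi * (s - params.velocity_um_s * t_s) / params.wavelength_um


def _phase_spiral(params: WaveSimParams, geom: StackGeometry, t_s: float) -> np.ndarray:
    # single-armed Archimedean spiral: phase = k r - omega t + azimuth
    y_um, x_um = _grid_um(geom)
    cy = (geom.height - 1) / 2 * geom.pixel_size_um
    cx = (geom.width - 1) / 2 * geom.pixel_size_um
    r = np.hypot(x_um - cx, y_um - cy)
    azimuth = np.arctan2(y_um - cy, x_um - cx)
    return 2 * np.pi * (r - params.velocity_um_s * t_s) / params.wavelength_um + azimuth


def simulate_traveling_wave(
    params: WaveSimParams, geom: StackGeometry
) -> ImageStack | tuple[ImageStack, ImageStack]:
    """Generate a planar or spiral traveling-wave movie.

    Returns a single :class:`ImageStack`, or a ``(channel1, channel2)`` pair
    when ``params.antiphase_channel`` is set; channel 2 is the pi-shifted,
    possibly broadened, anticorrelated species.
    """
    if params.pattern not in ("planar", "spiral"):
        raise ValueError("simulate_traveling_wave requires pattern 'planar' or 'spiral'")
    params.validate(geom)
    rng = np.random.default_rng(params.seed)
    phase_fn = _phase_planar if params.pattern == "planar" else _phase_spiral

    ch1 = np.empty(geom.shape)
    ch2 = np.empty(geom.shape) if params.antiphase_channel else None
    for t in range(geom.n_frames):
        phase = phase_fn(params, geom, t * geom.frame_interval_s)
        ch1[t] = params.baseline + params.amplitude * _profile(phase, params.profile)
        if ch2 is not None:
            ch2[t] = params.baseline + params.amplitude * _antiphase_profile(
                phase, params.antiphase_width_factor
            )

    stack1 = ImageStack(_apply_noise(ch1, params, rng), geom, "channel1")
    if ch2 is None:
        return stack1
    stack2 = ImageStack(_apply_noise(ch2, params, rng), geom, "channel2")
    return stack1, stack2


def simulate_standing_wave(params: WaveSimParams, geom: StackGeometry) -> ImageStack:
    """Generate a standing-wave movie: a fixed spatial cosine whose amplitude
    oscillates in time with the requested period; the temporal mean of every
    pixel is the baseline."""
    if params.pattern != "standing":
        raise ValueError("simulate_standing_wave requires pattern 'standing'")
    params.validate(geom)
    rng = np.random.default_rng(params.seed)

    y_um, x_um = _grid_um(geom)
    theta = np.deg2rad(params.direction_deg)
    s = x_um * np.cos(theta) + y_um * np.sin(theta)
    spatial = np.cos(2 * np.pi * s / params.wavelength_um)
    t_s = np.arange(geom.n_frames) * geom.frame_interval_s
    temporal = np.cos(2 * np.pi * t_s / params.period_s)
    clean = params.baseline + params.amplitude * temporal[:, None, None] * spatial[None]
    return ImageStack(_apply_noise(clean, params, rng), geom, "standing")


def simulate_droplet_pattern(
    params: WaveSimParams, droplet: DropletGeometry, geom: StackGeometry
) -> tuple[ImageStack, ImageStack]:
    """Generate a two-channel circling rim pattern inside a droplet.

    Intensity is confined to an annulus of width ``rim_width_um`` around the
    droplet rim.  Each channel is a bright patch occupying an arc; the two
    patches sit on opposite sides of the rim (pi apart) and rotate together at
    angular speed ``velocity_um_s / radius_um``, emulating the chasing,
    anticorrelated Min/FtsZ domains seen in microdroplets.
    """
    if params.pattern != "droplet_ring":
        raise ValueError("simulate_droplet_pattern requires pattern 'droplet_ring'")
    params.validate(geom)
    droplet.validate_in_frame(geom)
    rng = np.random.default_rng(params.seed)

    y_um, x_um = _grid_um(geom)
    cy = droplet.center[0] * geom.pixel_size_um
    cx = droplet.center[1] * geom.pixel_size_um
    r = np.hypot(x_um - cx, y_um - cy)
    azimuth = np.arctan2(y_um - cy, x_um - cx)
    annulus = np.abs(r - droplet.radius_um) <= droplet.rim_width_um / 2
    omega = params.velocity_um_s / droplet.radius_um  # rad/s

    ch1 = np.zeros(geom.shape)
    ch2 = np.zeros(geom.shape)
    for t in range(geom.n_frames):
        patch_centre = omega * t * geom.frame_interval_s
        arc1 = ((1 + np.cos(azimuth - patch_centre)) / 2) ** PATCH_SHARPNESS
        arc2 = ((1 + np.cos(azimuth - patch_centre - np.pi)) / 2) ** PATCH_SHARPNESS
        ch1[t] = annulus * (params.baseline + params.amplitude * arc1)
        ch2[t] = annulus * (params.baseline + params.amplitude * arc2)

    stack1 = ImageStack(_apply_noise(ch1, params, rng), geom, "rim_channel1")
    stack2 = ImageStack(_apply_noise(ch2, params, rng), geom, "rim_channel2")
    return stack1, stack2
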