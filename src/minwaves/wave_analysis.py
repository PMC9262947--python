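"""Wave-descriptor extraction from kymographs.

Three analyses, matching how Min-type surface waves are quantified:

* **Traveling waves** — the kymograph is binarized with a Sobel edge filter
  and wavefront stripes are found with a linear Hough transform; the stripe
  slope gives the wave velocity and the stripe spacing along the space axis
  gives the wavelength.
* **Standing waves** — the temporal autocorrelation of every pixel is
  computed and the first peak after the first zero crossing gives that
  pixel's oscillation period; the field's period is the median over
  qualifying pixels.
* **Antiphase channels** — Pearson correlation plus the spatial
  cross-correlation lag between two co-registered kymographs, expressed as a
  fraction of the wavelength (0.5 = perfectly antiphase).

A brute-force 2D-FFT estimator of the dominant (spatial, temporal) frequency
pair is provided as an independent cross-check of the Hough route.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize
from skimage.transform import hough_line, hough_line_peaks
from sklearn.base import BaseEstimator

from minwaves.geometry import GeometryError, ImageStack
from minwaves.kymo import Kymograph, build_kymograph, estimate_wave_direction

__all__ = [
    "WavefrontLine",
    "WaveMetrics",
    "OscillationMetrics",
    "AntiphaseMetrics",
    "NoEdgesError",
    "InsufficientWavefrontsError",
    "NoOscillationError",
    "detect_wavefront_lines",
    "wave_metrics_from_lines",
    "fft_wave_estimate",
    "standing_wave_period",
    "antiphase_metrics",
    "TravelingWaveEstimator",
    "StandingWaveEstimator",
    "AntiphaseEstimator",
]


class NoEdgesError(ValueError):
    """Sobel binarization produced an empty edge map."""


class InsufficientWavefrontsError(ValueError):
    """Fewer than two wavefront lines in the dominant angular family."""


class NoOscillationError(ValueError):
    """No pixel shows a qualifying temporal autocorrelation peak."""


@dataclass(frozen=True)
class WavefrontLine:
    """A detected wavefront stripe in Hough normal form.

    ``col*cos(theta) + row*sin(theta) = rho`` with theta in [0, pi); the
    kymograph convention is rows = space, columns = time.  ``support`` is the
    number of edge pixels backing the line.
    """

    rho: float
    theta: float
    support: int

    def slope_rows_per_col(self) -> float:
        """Spatial advance per frame, in rows per column (inf if vertical)."""
        s = np.sin(self.theta)
        if abs(s) < 1e-9:
            return float("inf")
        return -np.cos(self.theta) / s

    def row_at(self, col: float) -> float:
        s = np.sin(self.theta)
        if abs(s) < 1e-9:
            return float("nan")
        return (self.rho - col * np.cos(self.theta)) / s


@dataclass
class WaveMetrics:
    """Traveling-wave descriptors of one kymograph."""

    wavelength_um: float
    velocity_um_s: float
    n_lines: int
    per_line_spacings: list[float] = field(default_factory=list)
    dominant_angle: float = float("nan")
    is_static: bool = False


@dataclass
class OscillationMetrics:
    """Standing-wave descriptors: median period and oscillating fraction."""

    period_s: float
    fraction_oscillating: float
    per_pixel_periods: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class AntiphaseMetrics:
    """Two-channel phase relation."""

    pearson_r: float
    phase_shift_fraction: float
    classification: str = "indeterminate"  # antiphase | in_phase | indeterminate


# ---------------------------------------------------------------------------
# traveling waves: Sobel + Hough
# ---------------------------------------------------------------------------


def _normalize_line(rho: float, theta: float) -> tuple[float, float]:
    """Map Hough (rho, theta) to the theta in [0, pi) convention."""
    if theta < 0:
        theta += np.pi
        rho = -rho
    elif theta >= np.pi:
        theta -= np.pi
        rho = -rho
    return rho, theta


def _refine_line(
    rho: float, theta: float, edge_rows: np.ndarray, edge_cols: np.ndarray, tol_px: float = 2.0
) -> tuple[float, float, int] | None:
    """Total-least-squares refit of a Hough line on its supporting edge pixels.

    The 1-degree / 1-px Hough quantization is too coarse for percent-level
    velocity estimates; refitting on the inlier pixels removes it.
    """
    dist = edge_cols * np.cos(theta) + edge_rows * np.sin(theta) - rho
    inliers = np.abs(dist) <= tol_px
    n = int(inliers.sum())
    if n < 3:
        return None
    r = edge_rows[inliers].astype(float)
    c = edge_cols[inliers].astype(float)
    rc, cc = r.mean(), c.mean()
    cov = np.cov(np.vstack([c - cc, r - rc]))
    eigvals, eigvecs = np.linalg.eigh(cov)
    normal = eigvecs[:, 0]  # eigenvector of the smaller eigenvalue
    new_theta = float(np.arctan2(normal[1], normal[0]))
    new_rho = float(cc * np.cos(new_theta) + rc * np.sin(new_theta))
    new_rho, new_theta = _normalize_line(new_rho, new_theta)
    return new_rho, new_theta, n


def _angular_distance(a: float, b: float) -> float:
    """Distance between undirected line angles (radians, period pi)."""
    d = abs(a - b) % np.pi
    return min(d, np.pi - d)


def _auto_smooth_sigma(data: np.ndarray) -> tuple[float, float]:
    """Noise-suppression scale matched to the dominant period of each axis.

    The Gaussian pre-smoothing must be strong enough to suppress pixel noise
    in the Sobel response yet much smaller than the stripe period; one tenth
    of the dominant spatial/temporal period (clamped to [1, 8] / [1, 4] px)
    satisfies both across the wavelength range of Min-type surface waves.
    """
    x = data - data.mean()
    ps = (np.abs(np.fft.rfft(x, axis=0)) ** 2).sum(axis=1)
    ps[0] = 0
    fs = np.fft.rfftfreq(data.shape[0])
    sigma_space = 1.0
    if ps.max() > 0 and fs[int(np.argmax(ps))] > 0:
        sigma_space = float(np.clip(1.0 / fs[int(np.argmax(ps))] / 10.0, 1.0, 8.0))
    pt = (np.abs(np.fft.rfft(x, axis=1)) ** 2).sum(axis=0)
    pt[0] = 0
    ft = np.fft.rfftfreq(data.shape[1])
    sigma_time = 1.0
    if pt.max() > 0 and ft[int(np.argmax(pt))] > 0:
        sigma_time = float(np.clip(1.0 / ft[int(np.argmax(pt))] / 10.0, 1.0, 4.0))
    return sigma_space, sigma_time


def detect_wavefront_lines(
    kymo: Kymograph,
    smooth_sigma: float | tuple[float, float] | str = "auto",
    peak_fraction: float = 0.3,
    min_rho_separation_px: int = 9,
    min_angle_separation_deg: int = 5,
    family_window_deg: float = 5.0,
    refine: bool = True,
) -> list[WavefrontLine]:
    """Detect wavefront stripes in a kymograph.

    Pipeline: Gaussian smoothing -> Sobel derivative along the space axis
    (rising edges only, so each wave period contributes exactly one edge
    line) -> Otsu binarization combined with non-maximum suppression along
    the space axis (edges localized to the 1-px ridge of the Sobel response,
    as in Canny's thinning step) -> linear Hough transform (1 degree / 1 px
    accumulator) -> peaks above ``peak_fraction`` of the maximum with
    non-maximum suppression -> retain the largest family of lines within
    ``family_window_deg`` of the modal angle -> per-line least-squares
    refinement.  Returns lines sorted by rho.
    """
    kymo.require_min_size()
    if isinstance(smooth_sigma, str):
        if smooth_sigma != "auto":
            raise ValueError("smooth_sigma must be a number, a pair, or 'auto'")
        smooth_sigma = _auto_smooth_sigma(kymo.data)
    # a rim kymograph's space axis is circular: honour it in smoothing,
    # differentiation and ridge comparison
    space_mode = "wrap" if kymo.periodic else "reflect"
    img = ndimage.gaussian_filter(
        kymo.data, smooth_sigma, mode=(space_mode, "reflect")
    )
    d = ndimage.sobel(img, axis=0, mode=space_mode)
    if np.ptp(d) == 0:
        raise NoEdgesError("constant kymograph: empty edge map")
    binary = d > threshold_otsu(d)
    if not binary.any():
        raise NoEdgesError("empty edge map after Otsu binarization")
    # localize each rising edge to the ridge of the Sobel response: a pixel
    # survives only if it is a local maximum of d along the space axis
    if kymo.periodic:
        ridge = (d >= np.roll(d, -1, axis=0)) & (d > np.roll(d, 1, axis=0))
    else:
        ridge = np.zeros_like(binary)
        ridge[1:-1, :] = (d[1:-1, :] >= d[2:, :]) & (d[1:-1, :] > d[:-2, :])
    skel = binary & ridge
    if not skel.any():
        raise NoEdgesError("empty edge map after non-maximum suppression")

    thetas = np.deg2rad(np.arange(-90.0, 90.0, 1.0))
    acc, angles, dists = hough_line(skel, theta=thetas)
    _, peak_thetas, peak_rhos = hough_line_peaks(
        acc,
        angles,
        dists,
        threshold=peak_fraction * float(acc.max()),
        min_distance=min_rho_separation_px,
        min_angle=min_angle_separation_deg,
    )
    raw = [_normalize_line(float(r), float(t)) for t, r in zip(peak_thetas, peak_rhos)]
    if len(raw) < 2:
        raise InsufficientWavefrontsError(
            f"found {len(raw)} wavefront line(s); need >= 2"
        )

    # largest family around the modal angle
    window = np.deg2rad(family_window_deg)
    counts = [
        sum(1 for _, t2 in raw if _angular_distance(t, t2) <= window) for _, t in raw
    ]
    modal_theta = raw[int(np.argmax(counts))][1]
    family = [(r, t) for r, t in raw if _angular_distance(t, modal_theta) <= window]
    if len(family) < 2:
        raise InsufficientWavefrontsError("dominant angular family has < 2 lines")

    edge_rows, edge_cols = np.nonzero(skel)
    # Gaussian smoothing bends edges near the time borders (boundary
    # reflection); keep refinement to the undistorted interior columns
    trim = int(np.ceil(2 * np.atleast_1d(smooth_sigma)[-1]))
    if kymo.n_time > 4 * trim:
        interior = (edge_cols >= trim) & (edge_cols < kymo.n_time - trim)
        if interior.sum() >= 10:
            edge_rows, edge_cols = edge_rows[interior], edge_cols[interior]
    lines: list[WavefrontLine] = []
    for rho, theta in family:
        if refine:
            refined = _refine_line(rho, theta, edge_rows, edge_cols)
            if refined is not None:
                rho, theta, support = refined
            else:
                support = 1
        else:
            support = 1
        lines.append(WavefrontLine(rho=rho, theta=theta, support=support))
    lines.sort(key=lambda ln: ln.rho)
    return lines


def wave_metrics_from_lines(
    lines: list[WavefrontLine],
    kymo: Kymograph,
    spacing_mode: str = "space_axis",
) -> WaveMetrics:
    """Convert wavefront lines to physical wave descriptors.

    Velocity is the median absolute stripe slope (rows/column) times
    ``dx/dt``.  Wavelength is the median spacing between rho-consecutive
    lines, measured along the space axis at fixed time (``space_axis`` mode,
    default — the spacing that is a physical wavelength independent of the
    wave speed) or perpendicular to the lines (``perpendicular`` mode).
    Lines parallel to the space axis (unbounded slope) flag a static pattern
    with undefined velocity.
    """
    if len(lines) < 2:
        raise InsufficientWavefrontsError("need >= 2 lines for wave metrics")
    if spacing_mode not in ("space_axis", "perpendicular"):
        raise ValueError("spacing_mode must be 'space_axis' or 'perpendicular'")

    slopes = np.array([ln.slope_rows_per_col() for ln in lines])
    dominant_angle = float(np.median([ln.theta for ln in lines]))
    if np.any(~np.isfinite(slopes)):
        return WaveMetrics(
            wavelength_um=float("nan"),
            velocity_um_s=float("nan"),
            n_lines=len(lines),
            per_line_spacings=[],
            dominant_angle=dominant_angle,
            is_static=True,
        )
    velocity = float(np.median(np.abs(slopes))) * kymo.dx_um / kymo.dt_s

    mid_col = (kymo.n_time - 1) / 2
    if spacing_mode == "space_axis":
        intercepts = np.sort([ln.row_at(mid_col) for ln in lines])
        spacings_px = np.diff(intercepts)
    else:
        rhos = np.sort([ln.rho for ln in lines])
        spacings_px = np.diff(rhos)
    spacings_um = spacings_px * kymo.dx_um
    wavelength = float(np.median(spacings_um))
    return WaveMetrics(
        wavelength_um=wavelength,
        velocity_um_s=velocity,
        n_lines=len(lines),
        per_line_spacings=[float(s) for s in spacings_um],
        dominant_angle=dominant_angle,
    )


def fft_wave_estimate(kymo: Kymograph, pad_factor: int = 8) -> tuple[float, float]:
    """Brute-force (wavelength um, velocity um/s) from the kymograph's
    dominant 2D-frequency pair.

    Hann-windowed, zero-padded 2D FFT; the strongest peak at nonzero spatial
    frequency gives wavelength dx/f_space and velocity |f_time/f_space| *
    dx/dt, with parabolic sub-bin interpolation on the log power.  Used as an
    independent oracle for the Hough route.
    """
    data = kymo.data - kymo.data.mean()
    s, t = data.shape
    win = np.outer(np.hanning(s), np.hanning(t))
    spec = np.fft.fft2(data * win, s=(s * pad_factor, t * pad_factor))
    power = np.abs(spec) ** 2
    f_space = np.fft.fftfreq(s * pad_factor, d=1.0)  # cycles per row
    f_time = np.fft.fftfreq(t * pad_factor, d=1.0)  # cycles per column

    # ignore (near-)zero spatial frequency: no wavelength there
    min_fs = 0.5 / s  # half of one pre-padding frequency bin
    mask = np.abs(f_space)[:, None] > min_fs
    masked = np.where(mask, power, 0.0)
    i, j = np.unravel_index(int(np.argmax(masked)), masked.shape)

    def _parabolic(vals: np.ndarray, idx: int, n: int) -> float:
        lo, mid, hi = vals[(idx - 1) % n], vals[idx], vals[(idx + 1) % n]
        denom = lo - 2 * mid + hi
        if denom == 0:
            return 0.0
        return float(np.clip(0.5 * (lo - hi) / denom, -1, 1))

    logp = np.log(power + 1e-300)
    di = _parabolic(logp[:, j], i, power.shape[0])
    dj = _parabolic(logp[i, :], j, power.shape[1])
    fs = f_space[i] + di / (s * pad_factor)
    ft = f_time[j] + dj / (t * pad_factor)

    wavelength_um = kymo.dx_um / abs(fs)
    velocity_um_s = abs(ft / fs) * kymo.dx_um / kymo.dt_s
    return float(wavelength_um), float(velocity_um_s)


# ---------------------------------------------------------------------------
# standing waves: per-pixel temporal autocorrelation
# ---------------------------------------------------------------------------


def _pixel_series(source: ImageStack | Kymograph) -> tuple[np.ndarray, float]:
    if isinstance(source, ImageStack):
        data = source.data.reshape(source.n_frames, -1).T  # pixels x T
        return data, source.geometry.frame_interval_s
    return source.data, source.dt_s


def standing_wave_period(
    source: ImageStack | Kymograph,
    min_peak: float = 0.2,
    variance_fraction: float = 0.1,
) -> OscillationMetrics:
    """Oscillation period via per-pixel temporal autocorrelation.

    For each pixel the temporal mean is removed and the normalized
    autocorrelation computed over lags ``1..T/2``; the pixel's period is the
    lag of the first local maximum with value >= ``min_peak`` occurring after
    the first zero crossing.
    Pixels qualify only if such a peak exists and their temporal variance is
    at least ``variance_fraction`` of the median pixel variance.  The field's
    period is the median over qualifying pixels.
    """
    series, dt = _pixel_series(source)
    n_pix, n_t = series.shape
    if n_t < 16:
        raise GeometryError("need >= 16 frames for period estimation")
    max_lag = n_t // 2
    # significance guard: a white-noise autocorrelation estimate has sd
    # ~1/sqrt(T), so a fixed low threshold would qualify pure noise on short
    # records; genuine oscillators sit far above 3 sigma
    min_peak = max(min_peak, 3.0 / np.sqrt(n_t))

    x = series - series.mean(axis=1, keepdims=True)
    var = np.mean(x**2, axis=1)
    med_var = float(np.median(var))
    var_ok = var >= variance_fraction * med_var if med_var > 0 else var > 0

    # unbiased normalized autocorrelation via FFT, lags 0..max_lag; the
    # unbiased (per-overlap) normalization keeps a pure cosine's peak at its
    # true period instead of tilting it toward shorter lags
    nfft = int(2 ** np.ceil(np.log2(2 * n_t)))
    spec = np.fft.rfft(x, n=nfft, axis=1)
    ac = np.fft.irfft(spec * np.conj(spec), n=nfft, axis=1)[:, : max_lag + 1]
    overlap = n_t - np.arange(max_lag + 1)
    ac = ac * (n_t / overlap)[None, :]
    denom = ac[:, :1].copy()
    denom[denom <= 0] = np.inf
    ac = ac / denom

    lags = np.arange(max_lag + 1)
    crossed = ac <= 0
    has_crossing = crossed[:, 1:].any(axis=1)
    first_zero = np.argmax(crossed[:, 1:], axis=1) + 1  # first lag with ac <= 0

    inner = ac[:, 1:-1]
    is_peak = (inner >= ac[:, 2:]) & (inner > ac[:, :-2]) & (inner >= min_peak)
    after_zero = lags[1:-1][None, :] > first_zero[:, None]
    candidates = is_peak & after_zero & has_crossing[:, None]

    has_peak = candidates.any(axis=1)
    peak_lag = np.argmax(candidates, axis=1) + 1  # back to absolute lag index

    qualifying = has_peak & var_ok
    if not qualifying.any():
        raise NoOscillationError("no oscillation detected")

    periods = peak_lag[qualifying] * dt

    return OscillationMetrics(
        period_s=float(np.median(periods)),
        fraction_oscillating=float(qualifying.sum() / n_pix),
        per_pixel_periods=periods,
    )


# ---------------------------------------------------------------------------
# two-channel antiphase metrics
# ---------------------------------------------------------------------------


def antiphase_metrics(
    kymo_a: Kymograph,
    kymo_b: Kymograph,
    wavelength_um: float | None = None,
    antiphase_r: float = -0.3,
    inphase_r: float = 0.3,
    shift_tolerance: float = 0.15,
) -> AntiphaseMetrics:
    """Phase relation between two co-registered kymographs.

    ``pearson_r`` is computed over all paired entries.  The phase shift is
    the spatial cross-correlation lag at fixed time (circular for periodic
    rim kymographs), expressed as a fraction of the wavelength in [0, 1).
    Classified antiphase when ``pearson_r < antiphase_r`` and the shift is
    within ``shift_tolerance`` of 0.5; in phase when ``pearson_r >
    inphase_r`` and the circular shift distance from 0 is below
    ``shift_tolerance``.
    """
    if kymo_a.data.shape != kymo_b.data.shape:
        raise GeometryError("kymograph shapes differ")
    if not (
        np.isclose(kymo_a.dx_um, kymo_b.dx_um)
        and np.isclose(kymo_a.dt_s, kymo_b.dt_s)
        and kymo_a.periodic == kymo_b.periodic
    ):
        raise GeometryError("kymograph calibrations differ")
    a = kymo_a.data - kymo_a.data.mean()
    b = kymo_b.data - kymo_b.data.mean()
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance kymograph: correlation undefined")

    pearson = float(np.corrcoef(a.ravel(), b.ravel())[0, 1])

    if wavelength_um is None:
        wavelength_um, _ = fft_wave_estimate(kymo_a)

    # column-wise demeaning isolates the spatial phase relation per frame
    ac = a - a.mean(axis=0, keepdims=True)
    bc = b - b.mean(axis=0, keepdims=True)
    n_space = ac.shape[0]
    if kymo_a.periodic:
        fa = np.fft.rfft(ac, axis=0)
        fb = np.fft.rfft(bc, axis=0)
        cc = np.fft.irfft(np.conj(fa) * fb, n=n_space, axis=0).sum(axis=1)
        lag = int(np.argmax(cc))  # b shifted by +lag rows relative to a
        shift_rows = lag
    else:
        cc = sum(
            signal.correlate(bc[:, t], ac[:, t], mode="full")
            for t in range(ac.shape[1])
        )
        lags = np.arange(-(n_space - 1), n_space)
        # restrict to shifts below one wavelength so the fraction is unique
        max_shift = min(n_space - 1, int(np.ceil(wavelength_um / kymo_a.dx_um)))
        window = np.abs(lags) <= max_shift
        shift_rows = int(lags[window][np.argmax(cc[window])])

    fraction = (shift_rows * kymo_a.dx_um / wavelength_um) % 1.0
    dist_half = abs(fraction - 0.5)
    dist_zero = min(fraction, 1.0 - fraction)
    if pearson < antiphase_r and dist_half <= shift_tolerance:
        label = "antiphase"
    elif pearson > inphase_r and dist_zero < shift_tolerance:
        label = "in_phase"
    else:
        label = "indeterminate"
    return AntiphaseMetrics(
        pearson_r=pearson, phase_shift_fraction=float(fraction), classification=label
    )


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------


def _centered_line(
    stack: ImageStack, direction_deg: float
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Longest centred line through the frame along ``direction_deg``."""
    geom = stack.geometry
    theta = np.deg2rad(direction_deg)
    dr, dc = np.sin(theta), np.cos(theta)
    r0, c0 = (geom.height - 1) / 2, (geom.width - 1) / 2

    t_lo, t_hi = -np.inf, np.inf
    for pos, delta, hi in ((r0, dr, geom.height - 1), (c0, dc, geom.width - 1)):
        if abs(delta) < 1e-12:
            continue
        bounds = sorted(((0 - pos) / delta, (hi - pos) / delta))
        t_lo, t_hi = max(t_lo, bounds[0]), min(t_hi, bounds[1])
    t_lo *= 0.999
    t_hi *= 0.999
    return ((r0 + t_lo * dr, c0 + t_lo * dc), (r0 + t_hi * dr, c0 + t_hi * dc))


class TravelingWaveEstimator(BaseEstimator):
    """Wavelength/velocity estimator for traveling surface waves.

    ``fit`` accepts a :class:`Kymograph` directly, or an :class:`ImageStack`
    from which a kymograph is built along ``direction_deg`` (estimated from
    the stack's power spectrum when None) through the frame centre.

    Attributes (after fit): ``wavelength_um_``, ``velocity_um_s_``,
    ``n_lines_``, ``lines_``, ``per_line_spacings_``, ``dominant_angle_``,
    ``is_static_``, ``kymograph_``.
    """

    def __init__(
        self,
        direction_deg: float | None = None,
        smooth_sigma: float | tuple[float, float] | str = "auto",
        peak_fraction: float = 0.3,
        min_rho_separation_px: int = 9,
        min_angle_separation_deg: int = 5,
        family_window_deg: float = 5.0,
        spacing_mode: str = "space_axis",
        refine: bool = True,
    ):
        self.direction_deg = direction_deg
        self.smooth_sigma = smooth_sigma
        self.peak_fraction = peak_fraction
        self.min_rho_separation_px = min_rho_separation_px
        self.min_angle_separation_deg = min_angle_separation_deg
        self.family_window_deg = family_window_deg
        self.spacing_mode = spacing_mode
        self.refine = refine

    def fit(self, X: ImageStack | Kymograph, y=None):
        if isinstance(X, ImageStack):
            direction = (
                self.direction_deg
                if self.direction_deg is not None
                else estimate_wave_direction(X)
            )
            kymo = build_kymograph(X, _centered_line(X, direction))
        else:
            kymo = X
        lines = detect_wavefront_lines(
            kymo,
            smooth_sigma=self.smooth_sigma,
            peak_fraction=self.peak_fraction,
            min_rho_separation_px=self.min_rho_separation_px,
            min_angle_separation_deg=self.min_angle_separation_deg,
            family_window_deg=self.family_window_deg,
            refine=self.refine,
        )
        metrics = wave_metrics_from_lines(lines, kymo, spacing_mode=self.spacing_mode)
        self.kymograph_ = kymo
        self.lines_ = lines
        self.wavelength_um_ = metrics.wavelength_um
        self.velocity_um_s_ = metrics.velocity_um_s
        self.n_lines_ = metrics.n_lines
        self.per_line_spacings_ = metrics.per_line_spacings
        self.dominant_angle_ = metrics.dominant_angle
        self.is_static_ = metrics.is_static
        return self


class StandingWaveEstimator(BaseEstimator):
    """Oscillation-period estimator for standing waves (see
    :func:`standing_wave_period`)."""

    def __init__(self, min_peak: float = 0.2, variance_fraction: float = 0.1):
        self.min_peak = min_peak
        self.variance_fraction = variance_fraction

    def fit(self, X: ImageStack | Kymograph, y=None):
        m = standing_wave_period(
            X, min_peak=self.min_peak, variance_fraction=self.variance_fraction
        )
        self.period_s_ = m.period_s
        self.fraction_oscillating_ = m.fraction_oscillating
        self.per_pixel_periods_ = m.per_pixel_periods
        return self


class AntiphaseEstimator(BaseEstimator):
    """Two-channel phase-relation classifier (see :func:`antiphase_metrics`).

    ``fit`` takes the pair ``(kymo_a, kymo_b)``.
    """

    def __init__(
        self,
        wavelength_um: float | None = None,
        antiphase_r: float = -0.3,
        inphase_r: float = 0.3,
        shift_tolerance: float = 0.15,
    ):
        self.wavelength_um = wavelength_um
        self.antiphase_r = antiphase_r
        self.inphase_r = inphase_r
        self.shift_tolerance = shift_tolerance

    def fit(self, X: tuple[Kymograph, Kymograph], y=None):
        kymo_a, kymo_b = X
        m = antiphase_metrics(
            kymo_a,
            kymo_b,
            wavelength_um=self.wavelength_um,
            antiphase_r=self.antiphase_r,
            inphase_r=self.inphase_r,
            shift_tolerance=self.shift_tolerance,
        )
        self.pearson_r_ = m.pearson_r
        self.phase_shift_fraction_ = m.phase_shift_fraction
        self.classification_ = m.classification
        return self
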