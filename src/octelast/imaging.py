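"""k-space phase-velocity estimation, 2D velocity mapping and summaries.

The wave-speed estimator follows the standard k-space route used in shear-
and Lamb-wave elastography: the (time, lateral) displacement map is 2D
Fourier transformed into the (frequency, wavenumber) plane, where a guided
mode appears as a ridge; at each frequency ``f`` the wavenumber of maximum
magnitude ``k*`` gives the phase velocity ``c(f) = 2*pi*f / k*``.

Velocity *maps* repeat this in overlapping lateral windows: each window
yields a dispersion curve and a dominant (spectral-peak) frequency, and the
phase velocity read at that frequency is assigned to the window centre.
Young's modulus follows from the thin fluid-loaded plate inversion
``E = 9 rho V_L^4 / (pi f H)^2`` (or, optionally, by root-matching the full
characteristic equation).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.signal import get_window

from .doppler import (
    DEFAULT_HIGHPASS_CUTOFF,
    DisplacementField,
    SpatioTemporalMap,
    highpass_filter,
    spatiotemporal_map,
)
from .lamb import (
    DispersionPoint,
    solve_modulus_from_velocity,
    youngs_modulus_from_velocity,
)

__all__ = [
    "KSpaceMap",
    "DispersionCurve",
    "VelocityMap",
    "ElasticityResult",
    "QuadraticFit",
    "kspace_transform",
    "extract_dispersion",
    "dominant_frequency",
    "local_velocity_map",
    "overlay_velocity_on_structure",
    "render_overlay_figure",
    "summarize_elasticity",
    "percent_increase",
    "quadratic_trend_fit",
]

logger = logging.getLogger(__name__)

#: Analysis band (Hz) for the low-frequency A0 regime.
DEFAULT_BAND = (400.0, 4000.0)
DEFAULT_PAD = (4, 4)
DEFAULT_TAPER = "hann"
DEFAULT_MIN_PEAK_FRACTION = 0.1
DEFAULT_WINDOW_WIDTH = 64
DEFAULT_WINDOW_STEP = 8


@dataclass
class KSpaceMap:
    """2D-FFT magnitude over (frequency, wavenumber).

    Frequency is one-sided (>= 0); wavenumber is signed with positive values
    corresponding to propagation toward increasing lateral coordinate, so
    the propagation direction is resolved.
    """

    magnitude: np.ndarray  # (n_freq, n_k), >= 0
    frequency_axis: np.ndarray  # Hz, monotone increasing
    wavenumber_axis: np.ndarray  # rad/m, monotone increasing
    zero_pad: tuple[int, int] = DEFAULT_PAD

    def __post_init__(self) -> None:
        if self.magnitude.shape != (self.frequency_axis.size, self.wavenumber_axis.size):
            raise ValueError("magnitude shape must match the axes")

    @property
    def wavenumber_bin(self) -> float:
        return float(self.wavenumber_axis[1] - self.wavenumber_axis[0])

    @property
    def frequency_bin(self) -> float:
        return float(self.frequency_axis[1] - self.frequency_axis[0])


@dataclass
class DispersionCurve:
    """Phase velocity versus frequency extracted from a k-space map."""

    points: list[DispersionPoint]
    frequency_band: tuple[float, float]
    source: str = "global"

    def __post_init__(self) -> None:
        freqs = self.frequencies
        if freqs.size and np.any(np.diff(freqs) <= 0):
            raise ValueError("frequencies must be strictly increasing")

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([p.frequency for p in self.points])

    @property
    def velocities(self) -> np.ndarray:
        return np.array([p.phase_velocity for p in self.points])

    def velocity_at(self, f: float) -> float:
        """Linear interpolation of the curve at ``f`` (clamped to the band)."""
        return float(np.interp(f, self.frequencies, self.velocities))

    def to_csv(self, path) -> None:
        from .lamb import dispersion_curve_to_csv

        dispersion_curve_to_csv(self.points, path)


@dataclass
class VelocityMap:
    """Phase-velocity distribution over (depth band, lateral position)."""

    velocity: np.ndarray  # m/s, (n_bands, n_lateral); NaN where invalid
    mask: np.ndarray  # bool, same shape; velocity finite wherever True
    dominant_frequency: np.ndarray  # Hz, same shape
    lateral_axis: np.ndarray  # m
    depth_bands: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if np.any(~np.isfinite(self.velocity[self.mask])):
            raise ValueError("velocity must be finite wherever mask is True")


@dataclass
class ElasticityResult:
    """Mean +/- SD phase velocity and Young's modulus across repeats."""

    label: str
    thickness: float  # m
    mean_velocity: float  # m/s
    velocity_sd: float
    mean_modulus: float  # Pa
    modulus_sd: float
    n_repeats: int

    def __post_init__(self) -> None:
        if self.velocity_sd < 0 or self.modulus_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class QuadraticFit:
    a: float
    b: float
    c: float
    r_squared: float

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.a * x**2 + self.b * x + self.c


def kspace_transform(
    stmap: SpatioTemporalMap,
    pad_t: int = DEFAULT_PAD[0],
    pad_x: int = DEFAULT_PAD[1],
    window: str = DEFAULT_TAPER,
) -> KSpaceMap:
    """2D Fourier transform of a wave map into (frequency, wavenumber).

    A separable taper is applied before zero-padded FFT along both axes.
    With the temporal transform convention ``exp(-i 2 pi f t)``, a wave
    propagating toward +x appears at positive frequency and positive
    wavenumber on the returned axes.
    """
    values = stmap.values
    nt, nx = values.shape
    if nt < 8 or nx < 8:
        raise ValueError(f"need >= 8 samples along each axis, got {values.shape}")
    if pad_t < 1 or pad_x < 1:
        raise ValueError("zero-pad factors must be >= 1")
    if window == "none":
        taper = np.ones((nt, nx))
    else:
        taper = np.outer(get_window(window, nt), get_window(window, nx))
    spec = np.fft.fft2(values * taper, s=(nt * pad_t, nx * pad_x))

    freqs = np.fft.fftfreq(nt * pad_t, d=stmap.dt)
    keep = freqs >= 0
    # wavenumber k = -2*pi*xi so that +x propagation maps to positive k
    k = -2 * math.pi * np.fft.fftfreq(nx * pad_x, d=stmap.dx)
    order = np.argsort(k)
    magnitude = np.abs(spec[keep][:, order])
    return KSpaceMap(magnitude, freqs[keep], k[order], zero_pad=(pad_t, pad_x))


def _parabolic_refine(axis: np.ndarray, values: np.ndarray, i: int) -> float:
    """Sub-bin peak position by a 3-point parabola around index ``i``."""
    if i <= 0 or i >= values.size - 1:
        return float(axis[i])
    y0, y1, y2 = values[i - 1], values[i], values[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(axis[i])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    step = axis[1] - axis[0]
    return float(axis[i] + delta * step)


def extract_dispersion(
    kspace: KSpaceMap,
    band: tuple[float, float] = DEFAULT_BAND,
    min_peak_fraction: float = DEFAULT_MIN_PEAK_FRACTION,
    direction: int = 1,
    refine: bool = True,
) -> DispersionCurve:
    """Trace the wave ridge: per-frequency wavenumber of maximum magnitude.

    For each frequency bin in ``band`` whose ridge peak reaches
    ``min_peak_fraction`` of the global (band, half-plane) maximum, the
    wavenumber of maximum magnitude is located (3-point parabolic sub-bin
    refinement; ties broken toward the smaller wavenumber, i.e. the faster
    velocity) and converted to phase velocity ``c = 2 pi f / k*``.  Only
    the wavenumber half-plane matching ``direction`` (+1 = toward +x) is
    searched, rejecting the counter-propagating mirror ridge.
    """
    f_lo, f_hi = band
    if f_lo >= f_hi:
        raise ValueError("band must be (low, high) with low < high")
    if not (kspace.frequency_axis[0] <= f_lo and f_hi <= kspace.frequency_axis[-1]):
        raise ValueError(f"band {band} outside frequency axis range")
    if direction not in (1, -1):
        raise ValueError("direction must be +1 or -1")

    k = kspace.wavenumber_axis
    if direction == 1:
        k_cols = np.nonzero(k > 0)[0]
    else:
        k_cols = np.nonzero(k < 0)[0][::-1]  # increasing |k|
    f_rows = np.nonzero(
        (kspace.frequency_axis >= f_lo) & (kspace.frequency_axis <= f_hi)
    )[0]
    sub = kspace.magnitude[np.ix_(f_rows, k_cols)]
    global_max = sub.max()
    if global_max <= 0:
        raise ValueError("no spectral energy in the requested band")

    k_half = k[k_cols]
    points: list[DispersionPoint] = []
    for row_idx, row in zip(f_rows, sub):
        peak = row.max()
        if peak < min_peak_fraction * global_max:
            continue
        candidates = np.nonzero(row == peak)[0]
        if candidates.size > 1:
            logger.debug(
                "k-space peak tie at f=%.1f Hz; choosing smaller |k|",
                kspace.frequency_axis[row_idx],
            )
        i = candidates[np.argmin(np.abs(k_half[candidates]))]
        if refine:
            k_star = abs(_parabolic_refine(k_half, row, int(i)))
        else:
            k_star = abs(float(k_half[i]))
        f_val = float(kspace.frequency_axis[row_idx])
        if k_star <= 0 or f_val <= 0:
            continue
        points.append(
            DispersionPoint(
                frequency=f_val,
                phase_velocity=2 * math.pi * f_val / k_star,
            )
        )
    if not points:
        raise ValueError(
            f"no frequency bin in {band} passed the peak-fraction threshold"
        )
    return DispersionCurve(points, band)


def dominant_frequency(
    stmap: SpatioTemporalMap,
    lateral_window: tuple[int, int] | None = None,
    pad: int = DEFAULT_PAD[0],
    refine: bool = True,
    band: tuple[float, float] | None = None,
) -> float:
    """Frequency of maximum temporal-spectrum magnitude over a lateral window.

    The power spectrum is averaged over the window's lateral columns; the
    spectral peak (DC excluded) is located with parabolic refinement.
    ``band`` restricts the search to the analysis band -- essential on
    differential Doppler data, whose broadband noise floor rises with
    frequency and would otherwise capture the argmax.
    """
    if lateral_window is None:
        lateral_window = (0, stmap.values.shape[1])
    j0, j1 = lateral_window
    if not (0 <= j0 < j1 <= stmap.values.shape[1]):
        raise ValueError(f"empty or out-of-bounds lateral window {lateral_window}")
    cols = stmap.values[:, j0:j1]
    nt = cols.shape[0]
    spec = np.abs(np.fft.rfft(cols * get_window("hann", nt)[:, None],
                              n=nt * pad, axis=0)) ** 2
    mean_spec = spec.mean(axis=1)
    freqs = np.fft.rfftfreq(nt * pad, d=stmap.dt)
    mean_spec[0] = 0.0  # exclude DC
    if band is not None:
        mean_spec = np.where((freqs >= band[0]) & (freqs <= band[1]), mean_spec, 0.0)
    if mean_spec.max() <= 0:
        raise ValueError("spectrum has no energy above DC in the search band")
    i = int(np.argmax(mean_spec))
    if refine:
        return _parabolic_refine(freqs, mean_spec, i)
    return float(freqs[i])


def local_velocity_map(
    field: DisplacementField,
    window_width: int = DEFAULT_WINDOW_WIDTH,
    window_step: int = DEFAULT_WINDOW_STEP,
    band: tuple[float, float] = DEFAULT_BAND,
    depth_bands: Sequence[tuple[int, int]] | None = None,
    *,
    time_start: int | None = None,
    cutoff_hz: float = DEFAULT_HIGHPASS_CUTOFF,
    pad: tuple[int, int] = DEFAULT_PAD,
    taper: str = DEFAULT_TAPER,
    min_peak_fraction: float = DEFAULT_MIN_PEAK_FRACTION,
    direction: int = 1,
    integrate: bool = True,
) -> VelocityMap:
    """Phase-velocity distribution from overlapping lateral windows.

    With ``integrate=True`` (default) the differential Doppler
    displacement is first cumulatively summed over time, recovering the
    tissue displacement proper: this restores the excitation's spectral
    shape (temporal differencing tilts both signal and noise spectra up
    by a factor f, which otherwise lets broadband phase noise capture the
    dominant-frequency estimate) while the high-pass filter removes the
    integrated noise drift.  Per depth band the displacement is reduced
    to a wave map, high-pass filtered, and optionally cropped to
    post-excitation times.  Each
    lateral window of ``window_width`` positions (advancing by
    ``window_step``) is transformed to k-space; its dispersion curve is
    read at the window's dominant frequency and the velocity assigned to
    the window centre.  Velocities are linearly interpolated between
    centres; windows whose extraction fails contribute NaN (with a logged
    warning), never an exception.
    """
    if window_width < 8:
        raise ValueError("window_width must be >= 8 positions")
    n_lat = field.lateral_axis.size
    if window_width > n_lat:
        raise ValueError(f"window_width {window_width} exceeds lateral extent {n_lat}")
    if integrate:
        from .doppler import cumulative_displacement

        field = cumulative_displacement(field)
    if depth_bands is None:
        depth_bands = [(0, field.displacement.shape[0])]
    depth_bands = [tuple(b) for b in depth_bands]

    starts = list(range(0, n_lat - window_width + 1, window_step))
    if starts[-1] != n_lat - window_width:
        starts.append(n_lat - window_width)

    n_bands = len(depth_bands)
    velocity = np.full((n_bands, n_lat), np.nan)
    freq_map = np.full((n_bands, n_lat), np.nan)

    for bi, (d0, d1) in enumerate(depth_bands):
        stmap = spatiotemporal_map(field, (d0, d1), reduce="mean_over_range")
        stmap = highpass_filter(stmap, cutoff_hz=cutoff_hz)
        if time_start is not None and time_start > 0:
            stmap = SpatioTemporalMap(
                stmap.values[time_start:],
                stmap.time_axis[time_start:],
                stmap.lateral_axis,
                stmap.depth_range,
                filtered=True,
            )
        centers: list[int] = []
        center_v: list[float] = []
        center_f: list[float] = []
        for s in starts:
            win = SpatioTemporalMap(
                stmap.values[:, s : s + window_width],
                stmap.time_axis,
                stmap.lateral_axis[s : s + window_width],
                stmap.depth_range,
                filtered=True,
            )
            center = s + window_width // 2
            try:
                f_dom = dominant_frequency(win, pad=pad[0], band=band)
                ks = kspace_transform(win, pad_t=pad[0], pad_x=pad[1], window=taper)
                curve = extract_dispersion(
                    ks, band=band, min_peak_fraction=min_peak_fraction,
                    direction=direction,
                )
                f_read = float(np.clip(f_dom, band[0], band[1]))
                v = curve.velocity_at(f_read)
            except ValueError as exc:
                logger.warning(
                    "velocity extraction failed in window at lateral index %d: %s",
                    center, exc,
                )
                continue
            centers.append(center)
            center_v.append(v)
            center_f.append(f_read)
        if centers:
            pos = np.arange(n_lat)
            velocity[bi] = np.interp(pos, centers, center_v)
            freq_map[bi] = np.interp(pos, centers, center_f)
        else:
            logger.warning("no valid window in depth band %s; band left as NaN",
                           (d0, d1))
    mask = np.isfinite(velocity)
    return VelocityMap(velocity, mask, freq_map, field.lateral_axis, list(depth_bands))


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def overlay_velocity_on_structure(
    structure: np.ndarray,
    vmap: VelocityMap,
    intensity_threshold: float,
    vmin: float | None = None,
    vmax: float | None = None,
    cmap: str = "jet",
) -> np.ndarray:
    """Paint velocities onto the structural B-scan; return an RGB image.

    The grayscale log-intensity image is colorised wherever (a) the pixel
    lies inside a velocity-map depth band, (b) its intensity reaches
    ``intensity_threshold`` (dB) and (c) the velocity there is finite.
    """
    structure = np.asarray(structure, dtype=float)
    if structure.ndim != 2 or structure.shape[1] != vmap.velocity.shape[1]:
        raise ValueError("structure and velocity map are not laterally aligned")
    from matplotlib import colormaps

    smin, smax = structure.min(), structure.max()
    gray = (structure - smin) / (smax - smin) if smax > smin else np.zeros_like(structure)
    rgb = np.repeat(gray[..., None], 3, axis=2)

    finite = vmap.velocity[np.isfinite(vmap.velocity)]
    if vmin is None:
        vmin = float(finite.min()) if finite.size else 0.0
    if vmax is None:
        vmax = float(finite.max()) if finite.size else 1.0
    span = vmax - vmin if vmax > vmin else 1.0
    cm = colormaps[cmap]
    for (d0, d1), v_row, m_row in zip(vmap.depth_bands, vmap.velocity, vmap.mask):
        region = structure[d0:d1] >= intensity_threshold
        colors = cm(np.clip((v_row - vmin) / span, 0, 1))[:, :3]  # (n_lat, 3)
        paint = region & m_row[None, :]
        block = rgb[d0:d1]
        block[paint] = np.broadcast_to(colors[None, :, :], block.shape)[paint]
        rgb[d0:d1] = block
    return (rgb * 255).astype(np.uint8)


def render_overlay_figure(
    structure: np.ndarray,
    vmap: VelocityMap,
    intensity_threshold: float,
    path,
    vmin: float | None = None,
    vmax: float | None = None,
    cmap: str = "jet",
    axial_pitch: float | None = None,
    title: str = "",
) -> None:
    """Save a publication-style overlay PNG with a velocity colorbar (m/s)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    from matplotlib import pyplot as plt

    rgb = overlay_velocity_on_structure(structure, vmap, intensity_threshold,
                                        vmin=vmin, vmax=vmax, cmap=cmap)
    finite = vmap.velocity[np.isfinite(vmap.velocity)]
    if vmin is None:
        vmin = float(finite.min()) if finite.size else 0.0
    if vmax is None:
        vmax = float(finite.max()) if finite.size else 1.0
    fig, ax = plt.subplots(figsize=(6, 3))
    extent = None
    if axial_pitch is not None:
        extent = [
            vmap.lateral_axis[0] * 1e3,
            vmap.lateral_axis[-1] * 1e3,
            structure.shape[0] * axial_pitch * 1e3,
            0,
        ]
        ax.set_xlabel("lateral (mm)")
        ax.set_ylabel("depth (mm)")
    ax.imshow(rgb, aspect="auto", extent=extent)
    sm = plt.cm.ScalarMappable(
        cmap=cmap, norm=matplotlib.colors.Normalize(vmin=vmin, vmax=vmax)
    )
    fig.colorbar(sm, ax=ax, label="phase velocity (m/s)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def summarize_elasticity(
    vmaps: Sequence[VelocityMap],
    thickness: float,
    density: float = 1000.0,
    f_mode: Literal["per_sample", "per_position"] = "per_sample",
    label: str = "",
    inversion: Literal["thin_plate", "full_dispersion"] = "thin_plate",
) -> ElasticityResult:
    """Velocity and modulus mean +/- SD across repeated measurements.

    Per repeat, the velocity is averaged over the map mask and converted
    to Young's modulus at the recorded dominant frequency -- either one
    global frequency per repeat (``per_sample``) or per lateral position
    with subsequent averaging (``per_position``).  ``inversion`` selects
    the thin-plate closed form (the conventional elastography estimate) or
    root-matching of the full fluid-loaded-plate dispersion relation,
    which avoids the thin-plate truncation error at higher
    frequency-thickness products.  SDs are sample SDs across repeats
    (0 for a single repeat).
    """
    if len(vmaps) < 1:
        raise ValueError("need at least one repeat")
    if inversion not in ("thin_plate", "full_dispersion"):
        raise ValueError(f"unknown inversion mode {inversion!r}")
    invert = (
        youngs_modulus_from_velocity
        if inversion == "thin_plate"
        else solve_modulus_from_velocity
    )

    v_means: list[float] = []
    e_means: list[float] = []
    for vm in vmaps:
        if not np.any(vm.mask):
            raise ValueError("velocity map has an empty mask")
        v = vm.velocity[vm.mask]
        f = vm.dominant_frequency[vm.mask]
        v_mean = float(v.mean())
        if f_mode == "per_sample":
            f_global = float(f.mean())
            e_mean = invert(v_mean, f_global, thickness, density)
        elif f_mode == "per_position":
            e_mean = float(
                np.mean([invert(vi, fi, thickness, density) for vi, fi in zip(v, f)])
            )
        else:
            raise ValueError(f"unknown f_mode {f_mode!r}")
        v_means.append(v_mean)
        e_means.append(e_mean)

    n = len(v_means)
    v_arr, e_arr = np.array(v_means), np.array(e_means)
    v_sd = float(v_arr.std(ddof=1)) if n > 1 else 0.0
    e_sd = float(e_arr.std(ddof=1)) if n > 1 else 0.0
    return ElasticityResult(
        label=label,
        thickness=thickness,
        mean_velocity=float(v_arr.mean()),
        velocity_sd=v_sd,
        mean_modulus=float(e_arr.mean()),
        modulus_sd=e_sd,
        n_repeats=n,
    )


def percent_increase(low: float, high: float) -> float:
    """Relative increase ``100*(high-low)/low``, reported to two decimals."""
    if not low > 0:
        raise ValueError(f"baseline must be > 0, got {low}")
    return round(100.0 * (high - low) / low, 2)


def quadratic_trend_fit(x: Sequence[float], y: Sequence[float]) -> QuadraticFit:
    """Ordinary least-squares quadratic fit with goodness-of-fit R^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 4:
        raise ValueError("need >= 4 points for a quadratic trend fit")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("y has zero variance; R^2 undefined")
    coeffs = np.polyfit(x, y, 2)
    residuals = y - np.polyval(coeffs, x)
    sse = float(np.sum(residuals**2))
    return QuadraticFit(
        a=float(coeffs[0]), b=float(coeffs[1]), c=float(coeffs[2]),
        r_squared=1.0 - sse / sst,
    )


def summary_csv_header() -> list[str]:
    return [
        "label", "thickness_um", "mean_velocity_m_s", "velocity_sd",
        "mean_modulus_kpa", "modulus_sd", "n_repeats",
    ]


def elasticity_to_row(res: ElasticityResult) -> list:
    return [
        res.label,
        f"{res.thickness * 1e6:.1f}",
        f"{res.mean_velocity:.4f}",
        f"{res.velocity_sd:.4f}",
        f"{res.mean_modulus / 1e3:.2f}",
        f"{res.modulus_sd / 1e3:.2f}",
        res.n_repeats,
    ]
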