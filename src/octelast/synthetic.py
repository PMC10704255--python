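"""Synthetic M-B-mode OCT data with a known, dispersive A0 Lamb wavefield.

Stands in for the instrument: produces complex OCT cubes whose phase
encodes a guided elastic wave launched by an acoustic-radiation-force push,
with controllable plate mechanics (including lateral stiffness contrast),
realistic interferometric phase noise, and the acquisition timing of a
50 kHz M-B protocol.

The wavefield is synthesised spectrally: the push is modelled as a
Gaussian-spectrum displacement source and each frequency component is
propagated with the phase velocity of the fluid-loaded plate's A0 mode
(solved from the characteristic equation in :mod:`octelast.lamb`).  The
ultrasound carrier itself (MHz) is far above the A-line rate and is not
represented -- only the induced tissue displacement matters to the Doppler
chain.  Geometric spreading and attenuation are omitted by default (an
optional exponential lateral decay is available); the estimators operate on
phase, not amplitude, so closure tests are unaffected.

Only the dispersion *solver* is shared with the analysis code; the
estimation path (Doppler, k-space, peak picking) never feeds back into the
simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .doppler import AcquisitionConfig, DisplacementField, MBScan
from .lamb import PlateMaterial, solve_a0_phase_velocity

__all__ = [
    "ExcitationSpec",
    "PhantomGeometry",
    "SimulatedScan",
    "simulate_wavefield",
    "displacement_to_mbscan",
    "make_iop_series",
]

#: Interferometric phase stability of the modelled system, rad (SD of the
#: per-A-line phase noise).
DEFAULT_PHASE_NOISE_SD = 0.1673

#: Spectral sampling of the synthesised pulse, Hz.  Chosen so the beat
#: period 1/df exceeds the post-push record length (no temporal wrap).
DEFAULT_FREQUENCY_STEP = 40.0

_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class ExcitationSpec:
    """Displacement source launched by the radiation-force push.

    The push is a short (sub-ms) force burst; at the kHz scale relevant to
    the guided wave it is represented by a Gaussian amplitude spectrum of
    given center frequency and FWHM bandwidth, scaled so the peak tissue
    displacement equals ``peak_displacement``.
    """

    center_frequency: float = 2000.0  # Hz
    bandwidth: float = 1500.0  # Hz, FWHM of the Gaussian amplitude spectrum
    push_position: float = 0.0  # m, lateral coordinate of the focus
    push_duration: float = 500e-6  # s (metadata; spectrum sets the shape)
    peak_displacement: float = 150e-9  # m

    def __post_init__(self) -> None:
        if not self.center_frequency - self.bandwidth / 2 > 0:
            raise ValueError("center_frequency - bandwidth/2 must be > 0")
        if not (self.peak_displacement >= 0 and self.push_duration > 0):
            raise ValueError("peak_displacement >= 0 and push_duration > 0 required")

    @property
    def sigma_f(self) -> float:
        return self.bandwidth / _FWHM_TO_SIGMA

    @property
    def sigma_t(self) -> float:
        """Temporal envelope width of the transform-limited packet, s."""
        return 1.0 / (2 * math.pi * self.sigma_f)

    def spectrum(self, f: np.ndarray) -> np.ndarray:
        """Gaussian amplitude spectrum (unnormalised) at frequencies ``f``."""
        return np.exp(-0.5 * ((f - self.center_frequency) / self.sigma_f) ** 2)


@dataclass(frozen=True)
class PhantomGeometry:
    """Laterally segmented plate phantom inside the OCT field of view.

    ``segments`` is a sequence of ``(width_m, PlateMaterial)`` tiles laid
    left to right; they must cover the scanned lateral extent.  The tissue
    occupies the depth-pixel band ``tissue_band`` (half-open) at
    ``tissue_intensity_db``; everything else is background.
    """

    segments: tuple[tuple[float, PlateMaterial], ...]
    depth_pixels: int = 32
    tissue_band: tuple[int, int] = (4, 28)
    tissue_intensity_db: float = 40.0
    background_intensity_db: float = 5.0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("need at least one segment")
        for width, _ in self.segments:
            if not width > 0:
                raise ValueError("segment widths must be > 0")
        d0, d1 = self.tissue_band
        if not (0 <= d0 < d1 <= self.depth_pixels):
            raise ValueError("tissue_band must be a non-empty range within depth")

    @classmethod
    def homogeneous(cls, material: PlateMaterial, width: float, **kwargs
                    ) -> "PhantomGeometry":
        return cls(segments=((width, material),), **kwargs)

    @property
    def total_width(self) -> float:
        return sum(w for w, _ in self.segments)

    @property
    def boundaries(self) -> np.ndarray:
        """Lateral coordinates of segment interfaces (excluding the ends)."""
        edges = np.cumsum([w for w, _ in self.segments])
        return edges[:-1]

    @property
    def tissue_band_pixels(self) -> int:
        d0, d1 = self.tissue_band
        return d1 - d0

    def thickness(self, config: AcquisitionConfig) -> float:
        """Geometric thickness of the tissue band, m."""
        return self.tissue_band_pixels * config.axial_pixel_pitch

    def with_material(self, material: PlateMaterial) -> "PhantomGeometry":
        """Same geometry with every segment set to ``material``."""
        segments = tuple((w, material) for w, _ in self.segments)
        return replace(self, segments=segments)


@dataclass
class SimulatedScan:
    """A labelled synthetic acquisition with its mechanical ground truth."""

    label: str
    repeat: int
    scan: MBScan
    truth: DisplacementField
    material: PlateMaterial
    seed: int


def _segment_phase(
    geom: PhantomGeometry,
    frequencies: np.ndarray,
    x: np.ndarray,
    x_push: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Accumulated propagation phase ``int k dl`` from the push to each x.

    Returns ``(phase[f, x], velocity_at_x[f, x])``.  Within each material
    segment the wavenumber is ``k(f) = 2 pi f / c_A0(f)`` from the plate's
    characteristic equation; the phase is integrated along the propagation
    path so it is continuous across segment interfaces.
    """
    widths = np.array([w for w, _ in geom.segments])
    edges = np.concatenate([[0.0], np.cumsum(widths)])
    k_seg = np.empty((frequencies.size, len(geom.segments)))
    for si, (_, material) in enumerate(geom.segments):
        for fi, f in enumerate(frequencies):
            try:
                point = solve_a0_phase_velocity(float(f), material)
            except ValueError as exc:
                raise ValueError(
                    f"A0 dispersion unsolvable at f={f:.1f} Hz in segment {si}: {exc}"
                ) from exc
            k_seg[fi, si] = point.wavenumber

    # path length through each segment from x_push to every x (|dl|)
    lengths = np.empty((x.size, len(geom.segments)))
    for si in range(len(geom.segments)):
        lo, hi = edges[si], edges[si + 1]
        a = np.minimum(x, x_push)
        b = np.maximum(x, x_push)
        lengths[:, si] = np.clip(b, lo, hi) - np.clip(a, lo, hi)
    phase = k_seg @ lengths.T  # (n_f, n_x)
    return phase, k_seg


def simulate_wavefield(
    geom: PhantomGeometry,
    exc: ExcitationSpec,
    config: AcquisitionConfig,
    seed: int = 0,
    frequency_step: float = DEFAULT_FREQUENCY_STEP,
    spectral_halfwidth_sigmas: float = 2.5,
    lateral_decay_alpha: float = 0.0,
) -> DisplacementField:
    """Ground-truth axial displacement field of the guided wave.

    The field is a superposition of frequency components::

        u(x, t) = sum_f A(f) cos( phi_f(x) - 2 pi f (t - t_push) )

    with ``phi_f`` the propagation phase accumulated from the push position
    (continuous across stiffness segments) and ``A(f)`` the Gaussian
    excitation spectrum rescaled so ``max |u| = peak_displacement``.  The
    source envelope is delayed by three temporal sigmas after the push
    onset, so the field is (to the Gaussian tail, <2%) already zero at the
    push time and the hard causality gate applied there introduces no
    appreciable broadband step.  The field is uniform over the tissue
    depth band and zero outside it.  The construction is deterministic;
    ``seed`` is accepted for interface symmetry with the noisy stages and
    is unused here.
    """
    del seed  # deterministic ground truth
    dt = config.dt
    nt = config.alines_per_position
    t = np.arange(nt) * dt
    x = np.arange(config.lateral_positions) * config.lateral_step
    if geom.total_width < x[-1]:
        raise ValueError(
            f"phantom width {geom.total_width:.4g} m does not cover the "
            f"scanned extent {x[-1]:.4g} m"
        )

    f_lo = max(exc.center_frequency - spectral_halfwidth_sigmas * exc.sigma_f, 50.0)
    f_hi = exc.center_frequency + spectral_halfwidth_sigmas * exc.sigma_f
    if exc.bandwidth < frequency_step:  # quasi-monochromatic source
        frequencies = np.array([exc.center_frequency])
        envelope_delay = 0.0  # steady oscillation from the push time on
    else:
        frequencies = np.arange(f_lo, f_hi + frequency_step / 2, frequency_step)
        # displacement builds during the force burst and radiates after it:
        # centring the packet push_duration + 3 sigma_t after the push onset
        # keeps the field ~zero both before the push and inside the
        # excitation artifact window that the analysis discards
        envelope_delay = exc.push_duration + 3.0 * exc.sigma_t
    amps = exc.spectrum(frequencies)

    u_xt = np.zeros((nt, x.size))
    if exc.peak_displacement > 0:
        phase, _ = _segment_phase(geom, frequencies, x, exc.push_position)
        t_rel = t - config.push_time - envelope_delay
        # accumulate per component to keep memory at one (n_t, n_x) buffer
        for a_f, f, phi in zip(amps, frequencies, phase):
            u_xt += a_f * np.cos(phi[None, :] - 2 * math.pi * f * t_rel[:, None])
        if lateral_decay_alpha > 0:
            u_xt *= np.exp(-lateral_decay_alpha * np.abs(x - exc.push_position))[None, :]
        u_xt[t < config.push_time, :] = 0.0
        peak = np.abs(u_xt).max()
        if peak > 0:
            u_xt *= exc.peak_displacement / peak

    u = np.zeros((geom.depth_pixels, nt, x.size))
    d0, d1 = geom.tissue_band
    u[d0:d1] = u_xt[None, :, :]
    return DisplacementField(u, t, x, config=config)


def displacement_to_mbscan(
    field: DisplacementField,
    geom: PhantomGeometry,
    config: AcquisitionConfig,
    phase_noise_sd: float = DEFAULT_PHASE_NOISE_SD,
    seed: int = 0,
    speckle_sigma: float = 0.5,
) -> MBScan:
    """Encode a displacement field into a complex OCT cube with noise.

    Each pixel carries a speckle-like log-normal amplitude, frozen in time,
    at the tissue or background intensity of the geometry; the optical
    phase advances as ``-4 pi n u / lambda0`` (so the Doppler chain reads
    positive displacement for motion toward the source), plus i.i.d.
    Gaussian phase noise of SD ``phase_noise_sd`` per A-line.  The structure
    image is the time-averaged log intensity.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    u = field.displacement
    n_depth, nt, n_lat = u.shape
    if n_depth != geom.depth_pixels:
        raise ValueError("field depth does not match geometry depth_pixels")

    amp_db = np.full((n_depth, n_lat), geom.background_intensity_db)
    d0, d1 = geom.tissue_band
    amp_db[d0:d1] = geom.tissue_intensity_db
    speckle = rng.lognormal(mean=0.0, sigma=speckle_sigma, size=(n_depth, n_lat))
    amplitude = 10.0 ** (amp_db / 20.0) * speckle

    phase = -4 * math.pi * config.refractive_index * u / config.center_wavelength
    if phase_noise_sd > 0:
        phase = phase + rng.normal(0.0, phase_noise_sd, size=u.shape)
    field_c = amplitude[:, None, :] * np.exp(1j * phase)
    return MBScan(field_c, config)


def make_iop_series(
    youngs_moduli: Sequence[float],
    geom: PhantomGeometry,
    exc: ExcitationSpec,
    config: AcquisitionConfig,
    repeats: int = 3,
    seed: int = 0,
    labels: Sequence[str] | None = None,
    phase_noise_sd: float = DEFAULT_PHASE_NOISE_SD,
    density: float = 1000.0,
) -> list[SimulatedScan]:
    """Simulated pressure-sweep series: one homogeneous phantom per level.

    Pressure mechanics are not modelled; each nominal level imposes its
    Young's modulus directly (``mu = E/3``) on a homogeneous copy of
    ``geom``.  Each (level, repeat) pair gets a distinct child seed for the
    speckle and phase noise; the ground-truth wavefield per level is shared
    across its repeats.
    """
    if len(youngs_moduli) == 0:
        raise ValueError("youngs_moduli must be non-empty")
    if labels is None:
        labels = [f"E={e / 1e3:.4g}kPa" for e in youngs_moduli]
    if len(labels) != len(youngs_moduli):
        raise ValueError("labels must match youngs_moduli in length")
    if len(set(labels)) != len(labels):
        raise ValueError("labels must be distinct")

    children = np.random.SeedSequence(seed).spawn(len(youngs_moduli) * repeats)
    out: list[SimulatedScan] = []
    idx = 0
    for label, e_level in zip(labels, youngs_moduli):
        material = PlateMaterial.from_youngs_modulus(
            e_level, density=density,
            thickness=geom.segments[0][1].thickness,
        )
        level_geom = geom.with_material(material)
        truth = simulate_wavefield(level_geom, exc, config)
        for rep in range(repeats):
            child_seed = int(children[idx].generate_state(1)[0] & 0x7FFFFFFF)
            idx += 1
            scan = displacement_to_mbscan(
                truth, level_geom, config,
                phase_noise_sd=phase_noise_sd, seed=child_seed,
            )
            out.append(
                SimulatedScan(
                    label=label, repeat=rep, scan=scan, truth=truth,
                    material=material, seed=child_seed,
                )
            )
    return out
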