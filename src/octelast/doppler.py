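"""Phase-resolved Doppler processing of M-B-mode OCT data.

An M-B acquisition repeats M-mode (many A-lines at one lateral position)
across lateral positions, so the complex OCT field is a cube
``(depth, time, lateral)``.  The phase of the lag-1 temporal autocorrelation
of that field encodes the axial tissue displacement between successive
A-lines:

    dphi[d, m, x] = angle( F[d, m, x] * conj(F[d, m+1, x]) )
    dd            = lambda0 * dphi / (4 * pi * n)

Sign convention: ``F`` advances in phase as ``exp(-i 4 pi n u / lambda0)``
for displacement ``u`` toward the beam source, so positive ``dd`` means
motion toward the source.  The convention is shared with the simulator in
:mod:`octelast.synthetic`, making the forward-inverse round trip exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Literal

import h5py
import numpy as np
from scipy import signal as sps

__all__ = [
    "AcquisitionConfig",
    "MBScan",
    "DisplacementField",
    "SpatioTemporalMap",
    "doppler_phase_shift",
    "phase_to_displacement",
    "unwrap_temporal",
    "cumulative_displacement",
    "spatiotemporal_map",
    "highpass_filter",
    "save_mbscan",
    "load_mbscan",
]

MBSCAN_FORMAT_VERSION = 1

#: Default temporal high-pass cutoff (Hz) removing bulk drift below the
#: elastic-wave band.
DEFAULT_HIGHPASS_CUTOFF = 200.0
DEFAULT_HIGHPASS_ORDER = 4


@dataclass(frozen=True)
class AcquisitionConfig:
    """Geometry and timing of the M-B acquisition.

    Defaults follow a 1300 nm swept-source system running at a 50 kHz
    A-line rate with 1000 A-lines per lateral position and the radiation
    force fired between A-lines 101 and 125 (1-based, inclusive).
    """

    center_wavelength: float = 1300e-9  # m
    aline_rate: float = 50e3  # Hz
    alines_per_position: int = 1000
    excitation_start_aline: int = 101  # 1-based, inclusive
    excitation_end_aline: int = 125
    lateral_positions: int = 256
    lateral_step: float = 25e-6  # m
    refractive_index: float = 1.38
    axial_pixel_pitch: float = 4e-6  # m

    def __post_init__(self) -> None:
        if not (1 <= self.excitation_start_aline < self.excitation_end_aline
                <= self.alines_per_position):
            raise ValueError(
                "require 1 <= excitation_start < excitation_end <= alines_per_position"
            )
        for name in ("center_wavelength", "aline_rate", "lateral_step",
                     "refractive_index", "axial_pixel_pitch"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.lateral_positions < 1 or self.alines_per_position < 1:
            raise ValueError("counts must be >= 1")

    @property
    def dt(self) -> float:
        """Inter-A-line interval, s."""
        return 1.0 / self.aline_rate

    @property
    def push_time(self) -> float:
        """Time of the start of the force push, s (A-line 1 at t=0)."""
        return (self.excitation_start_aline - 1) * self.dt

    @property
    def post_excitation_index(self) -> int:
        """First 0-based time index after the excitation window."""
        return self.excitation_end_aline

    @property
    def displacement_per_radian(self) -> float:
        """Axial displacement per radian of Doppler phase, m."""
        return self.center_wavelength / (4 * math.pi * self.refractive_index)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionConfig":
        valid = {f.name for f in fields(cls)}
        kwargs = {k: v for k, v in d.items() if k in valid}
        ints = {"alines_per_position", "excitation_start_aline",
                "excitation_end_aline", "lateral_positions"}
        for k in list(kwargs):
            kwargs[k] = int(kwargs[k]) if k in ints else float(kwargs[k])
        return cls(**kwargs)


@dataclass
class MBScan:
    """Complex M-B data cube plus acquisition metadata.

    ``complex_field`` has shape ``(depth, time, lateral)`` with
    ``time == config.alines_per_position``.  ``structure_image`` is the
    log-intensity B-scan ``20*log10(time-averaged |field|)`` used for
    masking and thickness measurement.
    """

    complex_field: np.ndarray
    config: AcquisitionConfig
    structure_image: np.ndarray | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.complex_field)
        if f.ndim != 3:
            raise ValueError("complex_field must be (depth, time, lateral)")
        if f.shape[1] != self.config.alines_per_position:
            raise ValueError(
                f"time axis {f.shape[1]} != alines_per_position "
                f"{self.config.alines_per_position}"
            )
        if f.shape[2] != self.config.lateral_positions:
            raise ValueError(
                f"lateral axis {f.shape[2]} != lateral_positions "
                f"{self.config.lateral_positions}"
            )
        self.complex_field = f
        if self.structure_image is None:
            self.structure_image = self.compute_structure()
        else:
            self.structure_image = np.asarray(self.structure_image, dtype=float)
            if self.structure_image.shape != (f.shape[0], f.shape[2]):
                raise ValueError("structure_image must be (depth, lateral)")

    def compute_structure(self) -> np.ndarray:
        mean_amp = np.abs(self.complex_field).mean(axis=1)
        return 20.0 * np.log10(np.maximum(mean_amp, 1e-30))


@dataclass
class DisplacementField:
    """Axial displacement over ``(depth, time, lateral)`` in metres.

    Produced either differentially by the Doppler chain (one sample per
    A-line *pair*) or as an absolute ground-truth field by the simulator;
    ``time_axis`` carries the sample times either way with step ``1/f_A``.
    """

    displacement: np.ndarray
    time_axis: np.ndarray
    lateral_axis: np.ndarray
    config: AcquisitionConfig | None = None

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        self.lateral_axis = np.asarray(self.lateral_axis, dtype=float)
        d = self.displacement
        if d.ndim != 3:
            raise ValueError("displacement must be (depth, time, lateral)")
        if d.shape[1] != self.time_axis.size or d.shape[2] != self.lateral_axis.size:
            raise ValueError("axis lengths inconsistent with displacement shape")
        if not np.all(np.isfinite(d)):
            raise ValueError("displacement contains non-finite values")


@dataclass
class SpatioTemporalMap:
    """Displacement reduced over depth: a ``(time, lateral)`` wave map."""

    values: np.ndarray
    time_axis: np.ndarray
    lateral_axis: np.ndarray
    depth_range: tuple[int, int]
    filtered: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.time_axis.size, self.lateral_axis.size):
            raise ValueError("values must be (time, lateral) matching the axes")

    @property
    def dt(self) -> float:
        return float(self.time_axis[1] - self.time_axis[0])

    @property
    def dx(self) -> float:
        return float(self.lateral_axis[1] - self.lateral_axis[0])


def doppler_phase_shift(scan: MBScan) -> np.ndarray:
    """Lag-1 Doppler phase of the complex cube, in ``(-pi, pi]``.

    Returns an array of shape ``(depth, time-1, lateral)`` where sample m is
    ``angle(F[m] * conj(F[m+1]))``.
    """
    f = scan.complex_field
    if f.shape[1] < 2:
        raise ValueError("need >= 2 A-lines per position for Doppler processing")
    prod = f[:, :-1, :] * np.conj(f[:, 1:, :])
    return np.angle(prod)


def phase_to_displacement(phase: np.ndarray, config: AcquisitionConfig) -> DisplacementField:
    """Convert Doppler phase (rad) to axial displacement (m), element-wise.

    ``dd = lambda0 * dphi / (4 pi n)`` -- an exactly linear map.
    """
    phase = np.asarray(phase, dtype=float)
    if not np.all(np.isfinite(phase)):
        raise ValueError("phase contains non-finite values")
    disp = config.displacement_per_radian * phase
    nt = disp.shape[1]
    time_axis = np.arange(nt) * config.dt
    lateral_axis = np.arange(disp.shape[2]) * config.lateral_step
    return DisplacementField(disp, time_axis, lateral_axis, config=config)


def unwrap_temporal(phase: np.ndarray, axis: int = 1) -> np.ndarray:
    """Unwrap phase along the time axis (successive diffs into (-pi, pi])."""
    return np.unwrap(np.asarray(phase, dtype=float), axis=axis)


def cumulative_displacement(field: DisplacementField) -> DisplacementField:
    """Integrate differential Doppler displacement into absolute displacement.

    The cumulative sum over time of the inter-A-line displacements
    reconstructs the tissue trajectory relative to the first A-line pair.
    """
    cum = np.cumsum(field.displacement, axis=1)
    return DisplacementField(cum, field.time_axis, field.lateral_axis, config=field.config)


def spatiotemporal_map(
    field: DisplacementField,
    depth_range: tuple[int, int],
    reduce: Literal["single_depth", "mean_over_range"] = "mean_over_range",
) -> SpatioTemporalMap:
    """Collapse the depth axis to a (time, lateral) wave-propagation map.

    ``depth_range`` is a half-open index interval ``[d0, d1)``; with
    ``reduce="single_depth"`` only row ``d0`` is used.
    """
    d0, d1 = depth_range
    n_depth = field.displacement.shape[0]
    if not (0 <= d0 < d1 <= n_depth):
        raise ValueError(f"empty or out-of-bounds depth range {depth_range}")
    if reduce == "single_depth":
        values = field.displacement[d0]
        used = (d0, d0 + 1)
    elif reduce == "mean_over_range":
        values = field.displacement[d0:d1].mean(axis=0)
        used = (d0, d1)
    else:
        raise ValueError(f"unknown reduce mode {reduce!r}")
    return SpatioTemporalMap(values, field.time_axis, field.lateral_axis, used)


def highpass_filter(
    stmap: SpatioTemporalMap,
    cutoff_hz: float = DEFAULT_HIGHPASS_CUTOFF,
    order: int = DEFAULT_HIGHPASS_ORDER,
) -> SpatioTemporalMap:
    """Zero-phase temporal high-pass, removing DC and low-frequency drift.

    A forward-backward Butterworth (``sosfiltfilt``) is applied along time
    to each lateral column; zero-phase filtering preserves wave arrival
    times.  ``cutoff_hz`` must be below the temporal Nyquist rate.
    """
    fs = 1.0 / stmap.dt
    if not 0 < cutoff_hz < fs / 2:
        raise ValueError(f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={fs / 2} Hz)")
    sos = sps.butter(order, cutoff_hz, btype="highpass", fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, stmap.values, axis=0)
    out = replace(stmap, values=filtered)
    out.filtered = True
    return out


# ---------------------------------------------------------------------------
# HDF5 container (format version 1): datasets /field_real, /field_imag,
# /structure; root attributes mirror AcquisitionConfig plus mbscan_format.
# ---------------------------------------------------------------------------

def save_mbscan(scan: MBScan, path) -> None:
    """Write an :class:`MBScan` to the versioned HDF5 container."""
    with h5py.File(path, "w") as h5:
        h5.create_dataset("field_real", data=scan.complex_field.real)
        h5.create_dataset("field_imag", data=scan.complex_field.imag)
        h5.create_dataset("structure", data=scan.structure_image)
        h5.attrs["mbscan_format"] = MBSCAN_FORMAT_VERSION
        for key, value in scan.config.to_dict().items():
            h5.attrs[key] = value


def load_mbscan(path) -> MBScan:
    """Read the HDF5 container, validating version and required datasets."""
    with h5py.File(path, "r") as h5:
        version = h5.attrs.get("mbscan_format")
        if version is None:
            raise ValueError(f"{path}: missing attribute 'mbscan_format'")
        if int(version) != MBSCAN_FORMAT_VERSION:
            raise ValueError(
                f"{path}: unsupported mbscan_format {version} "
                f"(expected {MBSCAN_FORMAT_VERSION})"
            )
        for name in ("field_real", "field_imag", "structure"):
            if name not in h5:
                raise ValueError(f"{path}: missing dataset '/{name}'")
        config = AcquisitionConfig.from_dict(dict(h5.attrs))
        field_c = h5["field_real"][()] + 1j * h5["field_imag"][()]
        structure = h5["structure"][()]
    return MBScan(field_c, config, structure)
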