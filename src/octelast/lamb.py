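"""A0 Lamb-wave physics for a thin elastic plate immersed in fluid.

The optic nerve head (and similar thin, fluid-bounded soft tissues) guides
low-frequency elastic waves as the zeroth-order antisymmetric (A0, flexural)
Lamb mode.  This module holds the dispersion relation of that mode for an
incompressible, fluid-loaded plate, its thin-plate closed form, the
fluid-loading velocity correction, and the elastic inversions between wave
speed and Young's modulus.

Conventions
-----------
* ``mu`` is the shear modulus (Pa); for incompressible soft tissue
  ``E = 3*mu = 3*rho*V_S**2`` with ``V_S`` the bulk shear wave speed.
* The characteristic equation uses the plate *half* thickness ``h``; the
  thin-plate closed form and the modulus inversion use the *full*
  thickness ``H = 2h`` (the thickness as tabulated from structural images).
  Both are carried explicitly and never silently interchanged.
* The fluid-loaded A0 phase velocity is bounded above by ``V_S``; roots are
  bracketed inside ``(0, V_S)``.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "PlateMaterial",
    "DispersionPoint",
    "a0_dispersion_residual",
    "solve_a0_phase_velocity",
    "a0_dispersion_curve",
    "lamb_velocity_low_freq",
    "fluid_correction",
    "youngs_modulus_from_velocity",
    "shear_velocity_from_modulus",
    "solve_modulus_from_velocity",
    "dispersion_curve_to_csv",
    "DISPERSION_CSV_HEADER",
]

#: Density assumed for soft tissue when none is given, kg/m^3.
DEFAULT_DENSITY = 1000.0

#: Default bracket for the A0 root, as fractions of the shear speed.
DEFAULT_BRACKET_FRACTIONS = (0.01, 0.99)

#: Default absolute tolerance on the phase-velocity root, m/s.
DEFAULT_VELOCITY_TOL = 1e-4

DISPERSION_CSV_HEADER = (
    "frequency_hz",
    "phase_velocity_m_per_s",
    "wavenumber_rad_per_m",
)


@dataclass(frozen=True)
class PlateMaterial:
    """Mechanical description of the tissue plate.

    Parameters
    ----------
    shear_modulus
        Shear elasticity ``mu`` in Pa; Young's modulus is ``3*mu``.
    density
        Mass density ``rho`` in kg/m^3 (soft-tissue default 1000).
    thickness
        Full plate thickness ``H`` in m.
    shear_viscosity
        Shear viscosity ``eta`` in Pa*s.  Stored for completeness; the
        dispersion solver implements the purely elastic case and requires
        it to be zero.
    immersed
        Whether the plate is fluid-loaded on both faces (the in-situ
        condition; the solver models only this case).
    """

    shear_modulus: float
    density: float = DEFAULT_DENSITY
    thickness: float = 500e-6
    shear_viscosity: float = 0.0
    immersed: bool = True

    def __post_init__(self) -> None:
        if not self.shear_modulus > 0:
            raise ValueError(f"shear_modulus must be > 0, got {self.shear_modulus}")
        if not self.density > 0:
            raise ValueError(f"density must be > 0, got {self.density}")
        if not self.thickness > 0:
            raise ValueError(f"thickness must be > 0, got {self.thickness}")
        if self.shear_viscosity < 0:
            raise ValueError("shear_viscosity must be >= 0")

    @property
    def half_thickness(self) -> float:
        """Half thickness ``h = H/2`` used by the characteristic equation."""
        return self.thickness / 2

    @property
    def shear_velocity(self) -> float:
        """Bulk shear wave speed ``V_S = sqrt(mu/rho)`` in m/s."""
        return math.sqrt(self.shear_modulus / self.density)

    @property
    def youngs_modulus(self) -> float:
        """``E = 3*mu`` for an incompressible solid, in Pa."""
        return 3.0 * self.shear_modulus

    @classmethod
    def from_youngs_modulus(
        cls,
        youngs_modulus: float,
        density: float = DEFAULT_DENSITY,
        thickness: float = 500e-6,
        **kwargs,
    ) -> "PlateMaterial":
        """Build a material from Young's modulus via ``mu = E/3``."""
        return cls(
            shear_modulus=youngs_modulus / 3.0,
            density=density,
            thickness=thickness,
            **kwargs,
        )


@dataclass(frozen=True)
class DispersionPoint:
    """One (frequency, phase velocity) sample of a dispersion curve."""

    frequency: float  # Hz
    phase_velocity: float  # m/s
    wavenumber: float = field(default=0.0)  # rad/m, 2*pi*f/c

    def __post_init__(self) -> None:
        if not self.frequency > 0:
            raise ValueError("frequency must be > 0")
        if not self.phase_velocity > 0:
            raise ValueError("phase_velocity must be > 0")
        if self.wavenumber == 0.0:
            object.__setattr__(
                self, "wavenumber", 2 * math.pi * self.frequency / self.phase_velocity
            )


def _validate_elastic_immersed(material: PlateMaterial) -> None:
    if not material.immersed:
        raise ValueError("dispersion relation implemented for the immersed plate only")
    if material.shear_viscosity != 0.0:
        raise ValueError(
            "elastic-only solver: shear_viscosity must be 0 "
            f"(got {material.shear_viscosity})"
        )


def a0_dispersion_residual(c: float, f: float, material: PlateMaterial) -> float:
    """Characteristic-equation residual of the A0 mode at trial velocity ``c``.

    For an incompressible elastic plate of half thickness ``h`` loaded by
    incompressible fluid on both faces, the antisymmetric mode satisfies::

        4 kL^3 beta cosh(kL h) sinh(beta h)
            = (2 kL^2 - kS^2)^2 sinh(kL h) cosh(beta h)
              + kS^4 cosh(kL h) cosh(beta h)

    with ``kL = 2 pi f / c``, ``kS = 2 pi f / V_S`` and
    ``beta = sqrt(kL^2 - kS^2)`` on the principal branch.  For numerical
    stability the equation is divided through by
    ``kS^4 cosh(kL h) cosh(beta h)`` (positive on ``0 < c < V_S``), giving
    the dimensionless, overflow-free form::

        [4 kL^3 beta tanh(beta h) - (2 kL^2 - kS^2)^2 tanh(kL h)] / kS^4 - 1

    whose sign pattern equals that of LHS - RHS.  The residual is reported
    as the real part (for ``0 < c < V_S`` all terms are real; the
    imaginary part of the complex intermediates is identically zero
    there).  It changes sign exactly once in ``(0, V_S)`` for the
    frequency-thickness products relevant here, at the A0 root.
    """
    if not (c > 0 and f > 0):
        raise ValueError(f"c and f must be > 0 (got c={c}, f={f})")
    _validate_elastic_immersed(material)

    h = material.half_thickness
    omega = 2 * math.pi * f
    k_l = omega / c
    k_s = omega / material.shear_velocity
    beta = np.sqrt(complex(k_l**2 - k_s**2))

    lhs = 4 * k_l**3 * beta * np.tanh(beta * h)
    rhs = (2 * k_l**2 - k_s**2) ** 2 * np.tanh(k_l * h)
    return float(((lhs - rhs) / k_s**4 - 1.0).real)


def a0_residual_term_scale(c: float, f: float, material: PlateMaterial) -> float:
    """Magnitude of the largest (normalised) term of the characteristic eq.

    Useful as a scale when judging how close a candidate velocity is to a
    true root of the dimensionless residual.
    """
    h = material.half_thickness
    omega = 2 * math.pi * f
    k_l = omega / c
    k_s = omega / material.shear_velocity
    beta = np.sqrt(complex(k_l**2 - k_s**2))
    terms = (
        4 * k_l**3 * beta * np.tanh(beta * h) / k_s**4,
        (2 * k_l**2 - k_s**2) ** 2 * np.tanh(k_l * h) / k_s**4,
        1.0,
    )
    return float(max(abs(t) for t in terms))


def solve_a0_phase_velocity(
    f: float,
    material: PlateMaterial,
    bracket: tuple[float, float] | None = None,
    tol: float = DEFAULT_VELOCITY_TOL,
) -> DispersionPoint:
    """Solve the characteristic equation for the A0 phase velocity at ``f``.

    Bracketed Brent root finding on ``c``; the default bracket spans
    ``(0.01, 0.99) * V_S``, which contains the single A0 root in the
    low-frequency regime.  Deterministic for fixed inputs.

    Raises
    ------
    ValueError
        If the residual does not change sign over the bracket (no A0 root
        in bracket) -- never silently extrapolates.
    """
    if not f > 0:
        raise ValueError(f"frequency must be > 0, got {f}")
    _validate_elastic_immersed(material)
    v_s = material.shear_velocity
    if bracket is None:
        bracket = (DEFAULT_BRACKET_FRACTIONS[0] * v_s, DEFAULT_BRACKET_FRACTIONS[1] * v_s)
    lo, hi = bracket
    r_lo = a0_dispersion_residual(lo, f, material)
    r_hi = a0_dispersion_residual(hi, f, material)
    if r_lo == 0.0:
        return DispersionPoint(frequency=f, phase_velocity=lo)
    if r_hi == 0.0:
        return DispersionPoint(frequency=f, phase_velocity=hi)
    if np.sign(r_lo) == np.sign(r_hi):
        raise ValueError(
            f"no A0 root in bracket ({lo:.4g}, {hi:.4g}) m/s at f={f:.4g} Hz"
        )
    c = brentq(a0_dispersion_residual, lo, hi, args=(f, material), xtol=tol)
    return DispersionPoint(frequency=f, phase_velocity=float(c))


def a0_dispersion_curve(
    frequencies: Iterable[float],
    material: PlateMaterial,
    tol: float = DEFAULT_VELOCITY_TOL,
) -> list[DispersionPoint]:
    """Model A0 dispersion curve over a set of frequencies."""
    return [solve_a0_phase_velocity(f, material, tol=tol) for f in frequencies]


def lamb_velocity_low_freq(f: float, thickness: float, shear_velocity: float) -> float:
    """Thin-plate (vacuum) A0 phase velocity ``sqrt(2 pi f H V_S / sqrt(3))``.

    ``thickness`` is the full plate thickness ``H``.  Valid when the
    wavelength is large compared with ``H`` (flexural regime).
    """
    if not (f > 0 and thickness > 0 and shear_velocity > 0):
        raise ValueError(
            "f, thickness and shear_velocity must be > 0 "
            f"(got {f}, {thickness}, {shear_velocity})"
        )
    return math.sqrt(2 * math.pi * f * thickness * shear_velocity / math.sqrt(3.0))


def fluid_correction(v_vacuum: float) -> float:
    """Fluid-loading correction of the thin-plate velocity: ``v / sqrt(2)``.

    Liquid on both faces of the plate mass-loads the flexural mode and slows
    it by the factor ``1/sqrt(2)`` relative to the vacuum plate.  This is
    the unique factor under which the thin-plate velocity and the modulus
    inversion below compose to the identity ``E -> E``.
    """
    if v_vacuum < 0:
        raise ValueError(f"velocity must be >= 0, got {v_vacuum}")
    return v_vacuum / math.sqrt(2.0)


def youngs_modulus_from_velocity(
    phase_velocity: float, f: float, thickness: float, density: float
) -> float:
    """Invert the fluid-loaded thin-plate velocity to Young's modulus.

    ``E = 9 rho V_L^4 / (pi f H)^2`` with ``V_L`` the measured (fluid-loaded)
    Lamb phase velocity at frequency ``f`` and ``H`` the full thickness.
    Exact closed form; ``V_L = 0`` maps to ``E = 0``.
    """
    if phase_velocity < 0:
        raise ValueError("phase_velocity must be >= 0")
    if not (f > 0 and thickness > 0 and density > 0):
        raise ValueError("f, thickness and density must be > 0")
    return 9.0 * density * phase_velocity**4 / (math.pi * f * thickness) ** 2


def shear_velocity_from_modulus(youngs_modulus: float, density: float) -> float:
    """``V_S = sqrt(E / (3 rho))`` for an incompressible solid."""
    if youngs_modulus < 0:
        raise ValueError("youngs_modulus must be >= 0")
    if not density > 0:
        raise ValueError("density must be > 0")
    return math.sqrt(youngs_modulus / (3.0 * density))


def solve_modulus_from_velocity(
    phase_velocity: float,
    f: float,
    thickness: float,
    density: float = DEFAULT_DENSITY,
    tol: float = 1e-3,
) -> float:
    """Invert a measured A0 phase velocity through the full dispersion relation.

    Finds the Young's modulus ``E`` whose fluid-loaded plate has A0 phase
    velocity ``phase_velocity`` at frequency ``f``.  Unlike
    :func:`youngs_modulus_from_velocity` this carries no thin-plate
    truncation error; it is the physically consistent inversion when the
    frequency-thickness product leaves the flexural regime.

    The A0 velocity is strictly increasing in ``E`` at fixed ``f``, so a
    bracketed root is unique.  ``E`` must exceed ``3 rho c^2`` (the mode is
    subsonic relative to shear), which anchors the lower bracket.
    """
    if not phase_velocity > 0:
        raise ValueError("phase_velocity must be > 0")
    if not (f > 0 and thickness > 0 and density > 0):
        raise ValueError("f, thickness and density must be > 0")

    def velocity_error(modulus: float) -> float:
        mat = PlateMaterial.from_youngs_modulus(modulus, density, thickness)
        return solve_a0_phase_velocity(f, mat).phase_velocity - phase_velocity

    e_min = 3.0 * density * phase_velocity**2 * 1.001
    e_hi = e_min * 4.0
    for _ in range(60):
        if velocity_error(e_hi) > 0:
            break
        e_hi *= 2.0
    else:
        raise ValueError("could not bracket the modulus inversion")
    e = brentq(velocity_error, e_min, e_hi, xtol=e_min * 1e-9, rtol=1e-10)
    return float(e)


def dispersion_curve_to_csv(points: Sequence[DispersionPoint], path) -> None:
    """Write a dispersion curve as CSV (frequency, velocity, wavenumber)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(DISPERSION_CSV_HEADER)
        for p in points:
            writer.writerow(
                [f"{p.frequency:.6g}", f"{p.phase_velocity:.8g}", f"{p.wavenumber:.8g}"]
            )
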