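"""Shared fixtures: compact acquisition geometries and simulated scans.

The "small" geometry keeps the physics of the study (50 kHz A-line rate,
496 um plate, 2 kHz Gaussian push) on a reduced grid so unit tests stay
fast; the "study" geometry used by the acceptance tests is wider and keeps
the full 1000-A-line record.
"""

from __future__ import annotations

import numpy as np
import pytest

from octelast import (
    AcquisitionConfig,
    ExcitationSpec,
    PhantomGeometry,
    PlateMaterial,
    displacement_to_mbscan,
    simulate_wavefield,
)

REFERENCE_THICKNESS = 496e-6


@pytest.fixture(scope="session")
def material_ref() -> PlateMaterial:
    """mu = 64 kPa (E = 192 kPa, V_S = 8 m/s), 496 um plate."""
    return PlateMaterial(shear_modulus=64e3, density=1000.0,
                         thickness=REFERENCE_THICKNESS)


@pytest.fixture(scope="session")
def acq_small() -> AcquisitionConfig:
    return AcquisitionConfig(
        alines_per_position=400,
        excitation_start_aline=41,
        excitation_end_aline=53,
        lateral_positions=96,
        lateral_step=25e-6,
        axial_pixel_pitch=16e-6,
    )


@pytest.fixture(scope="session")
def geom_small(material_ref, acq_small) -> PhantomGeometry:
    width = acq_small.lateral_positions * acq_small.lateral_step
    return PhantomGeometry.homogeneous(
        material_ref, width=width, depth_pixels=36, tissue_band=(2, 33)
    )


@pytest.fixture(scope="session")
def excitation() -> ExcitationSpec:
    return ExcitationSpec()


@pytest.fixture(scope="session")
def truth_small(geom_small, excitation, acq_small):
    return simulate_wavefield(geom_small, excitation, acq_small)


@pytest.fixture(scope="session")
def scan_small_noiseless(truth_small, geom_small, acq_small):
    return displacement_to_mbscan(
        truth_small, geom_small, acq_small, phase_noise_sd=0.0, seed=11
    )


@pytest.fixture(scope="session")
def scan_small_noisy(truth_small, geom_small, acq_small):
    return displacement_to_mbscan(truth_small, geom_small, acq_small, seed=11)


# -- study-scale geometry for end-to-end acceptance checks -------------------

@pytest.fixture(scope="session")
def acq_study() -> AcquisitionConfig:
    return AcquisitionConfig(
        lateral_positions=192,
        lateral_step=25e-6,
        axial_pixel_pitch=16e-6,
    )


@pytest.fixture(scope="session")
def geom_study(material_ref, acq_study) -> PhantomGeometry:
    width = acq_study.lateral_positions * acq_study.lateral_step
    return PhantomGeometry.homogeneous(
        material_ref, width=width, depth_pixels=40, tissue_band=(4, 35)
    )


def assert_relative(actual, expected, tol, label=""):
    __tracebackhide__ = True
    rel = abs(actual - expected) / abs(expected)
    assert rel <= tol, (
        f"{label}: {actual!r} differs from {expected!r} by {rel:.3%} (> {tol:.1%})"
    )
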