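"""k-space estimation, dispersion extraction, velocity maps, summaries."""

import logging
import math

import numpy as np
import pytest

from octelast import (
    ElasticityResult,
    VelocityMap,
    dominant_frequency,
    extract_dispersion,
    kspace_transform,
    local_velocity_map,
    overlay_velocity_on_structure,
    percent_increase,
    quadratic_trend_fit,
    solve_a0_phase_velocity,
    summarize_elasticity,
)
from octelast.doppler import DisplacementField, SpatioTemporalMap
from octelast.imaging import KSpaceMap, render_overlay_figure

from .conftest import assert_relative

FS = 50e3
DX = 25e-6


def wave_map(components, nt=500, nx=128, fs=FS, dx=DX):
    """Map built from plane-wave components [(amplitude, f_hz, c_m_s), ...]."""
    t = np.arange(nt) / fs
    x = np.arange(nx) * dx
    u = np.zeros((nt, nx))
    for amp, f, c in components:
        k = 2 * math.pi * f / c
        u += amp * np.cos(2 * math.pi * f * t[:, None] - k * x[None, :])
    return SpatioTemporalMap(u, t, x, (0, 1), filtered=True)


class TestKSpace:
    def test_plane_wave_peak_location(self):
        m = wave_map([(1.0, 2000.0, 8.0)])
        ks = kspace_transform(m)
        i, j = np.unravel_index(np.argmax(ks.magnitude), ks.magnitude.shape)
        assert abs(ks.frequency_axis[i] - 2000.0) <= ks.frequency_bin
        assert abs(ks.wavenumber_axis[j] - 2 * math.pi * 2000 / 8.0) \
            <= ks.wavenumber_bin

    def test_axes_monotone_and_nonnegative_magnitude(self):
        ks = kspace_transform(wave_map([(1.0, 1000.0, 6.0)]))
        assert np.all(np.diff(ks.frequency_axis) > 0)
        assert np.all(np.diff(ks.wavenumber_axis) > 0)
        assert np.all(ks.magnitude >= 0)

    def test_zero_map_zero_magnitude(self):
        m = wave_map([(0.0, 1000.0, 8.0)])
        assert kspace_transform(m).magnitude.max() == 0.0

    def test_parseval(self):
        m = wave_map([(1.0, 2000.0, 8.0)], nt=64, nx=32)
        ks_mag = kspace_transform(m, pad_t=1, pad_x=1, window="none").magnitude
        # one-sided in frequency: reassemble full-plane energy
        full = np.abs(np.fft.fft2(m.values)) ** 2
        assert np.sum(full) / m.values.size == pytest.approx(
            np.sum(m.values**2), rel=1e-9
        )
        assert ks_mag.max() == pytest.approx(np.abs(full).max() ** 0.5, rel=1e-9)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 8"):
            kspace_transform(wave_map([(1.0, 2000.0, 8.0)], nt=4, nx=32))


class TestExtractDispersion:
    def test_plane_wave_velocity(self):
        ks = kspace_transform(wave_map([(1.0, 2000.0, 8.0)]))
        curve = extract_dispersion(ks, band=(1500.0, 2500.0))
        v = curve.velocity_at(2000.0)
        k_true = 2 * math.pi * 2000 / 8.0
        v_half_bin = 2 * math.pi * 2000 / (k_true - ks.wavenumber_bin / 2) - 8.0
        assert abs(v - 8.0) <= v_half_bin

    def test_two_mode_field(self):
        m = wave_map([(1.0, 1200.0, 6.0), (1.0, 2600.0, 9.0)], nt=800)
        curve = extract_dispersion(kspace_transform(m), band=(800.0, 3200.0))
        ks = kspace_transform(m)
        for f0, c0 in [(1200.0, 6.0), (2600.0, 9.0)]:
            v = curve.velocity_at(f0)
            k0 = 2 * math.pi * f0 / c0
            tol = 2 * math.pi * f0 * (1 / (k0 - ks.wavenumber_bin) - 1 / k0)
            assert abs(v - c0) <= tol

    def test_matches_brute_force_argmax(self):
        """Refined peak is within half a bin of the plain per-row argmax."""
        rng = np.random.default_rng(42)
        mag = rng.random((60, 80))
        freqs = np.linspace(0.0, 5000.0, 60)
        k = np.linspace(-4000.0, 4000.0, 80)
        ks = KSpaceMap(mag, freqs, k)
        curve = extract_dispersion(ks, band=(500.0, 4500.0),
                                   min_peak_fraction=0.0)
        pos = k > 0
        bin_w = k[1] - k[0]
        for p in curve.points:
            row = mag[np.argmin(np.abs(freqs - p.frequency))]
            k_brute = k[pos][np.argmax(row[pos])]
            assert abs(p.wavenumber - k_brute) <= bin_w / 2 + 1e-9

    def test_counterpropagating_direction(self):
        m = wave_map([(1.0, 2000.0, 8.0)])
        mirrored = SpatioTemporalMap(
            m.values[:, ::-1], m.time_axis, m.lateral_axis, m.depth_range, True
        )
        ks = kspace_transform(mirrored)
        curve = extract_dispersion(ks, band=(1500.0, 2500.0), direction=-1)
        assert curve.velocity_at(2000.0) == pytest.approx(8.0, rel=0.1)

    def test_empty_curve_raises(self):
        ks = kspace_transform(wave_map([(1.0, 2000.0, 8.0)]))
        with pytest.raises(ValueError, match="threshold"):
            extract_dispersion(ks, band=(1500.0, 2500.0), min_peak_fraction=2.0)

    def test_model_curve_closure(self, truth_small, material_ref, geom_small):
        """Extracted dispersion matches the plate model over the excited band."""
        from octelast import spatiotemporal_map

        d0, d1 = geom_small.tissue_band
        st = spatiotemporal_map(truth_small, (d0, d1))
        crop = 53  # post-excitation samples only
        st = SpatioTemporalMap(st.values[crop:], st.time_axis[crop:],
                               st.lateral_axis, st.depth_range, filtered=True)
        curve = extract_dispersion(kspace_transform(st), band=(1200.0, 2800.0),
                                   min_peak_fraction=0.2)
        rel_err = [
            abs(p.phase_velocity
                - solve_a0_phase_velocity(p.frequency, material_ref).phase_velocity)
            / solve_a0_phase_velocity(p.frequency, material_ref).phase_velocity
            for p in curve.points
        ]
        assert np.median(rel_err) < 0.05


class TestDominantFrequency:
    def test_pure_tone(self):
        m = wave_map([(1.0, 1500.0, 8.0)], nt=1000)
        fd = dominant_frequency(m)
        assert abs(fd - 1500.0) <= FS / 1000  # one unpadded bin

    def test_gaussian_packet_center(self, truth_small, geom_small):
        from octelast import spatiotemporal_map

        d0, d1 = geom_small.tissue_band
        st = spatiotemporal_map(truth_small, (d0, d1))
        fd = dominant_frequency(st, band=(400.0, 4000.0))
        assert abs(fd - 2000.0) <= FS / st.values.shape[0]

    def test_zero_map_rejected(self):
        m = wave_map([(0.0, 1000.0, 8.0)])
        with pytest.raises(ValueError, match="no energy"):
            dominant_frequency(m)

    def test_window_bounds_checked(self):
        m = wave_map([(1.0, 1000.0, 8.0)])
        with pytest.raises(ValueError):
            dominant_frequency(m, lateral_window=(5, 5))


class TestLocalVelocityMap:
    def test_homogeneous_plate_uniform(
        self, truth_small, geom_small, acq_small, material_ref
    ):
        vm = local_velocity_map(
            truth_small, depth_bands=[geom_small.tissue_band],
            time_start=acq_small.post_excitation_index, integrate=False,
        )
        v = vm.velocity[vm.mask]
        assert v.std() / v.mean() < 0.05
        f_mean = float(np.nanmean(vm.dominant_frequency))
        c_true = solve_a0_phase_velocity(f_mean, material_ref).phase_velocity
        assert_relative(v.mean(), c_true, 0.05, "uniform plate velocity")

    def test_mirror_equivariance(self, truth_small, geom_small, acq_small):
        vm = local_velocity_map(
            truth_small, depth_bands=[geom_small.tissue_band],
            time_start=acq_small.post_excitation_index, integrate=False,
        )
        flipped = DisplacementField(
            truth_small.displacement[:, :, ::-1].copy(),
            truth_small.time_axis, truth_small.lateral_axis,
        )
        vm_flip = local_velocity_map(
            flipped, depth_bands=[geom_small.tissue_band],
            time_start=acq_small.post_excitation_index,
            direction=-1, integrate=False,
        )
        a, b = vm.velocity[0], vm_flip.velocity[0, ::-1]
        ok = np.isfinite(a) & np.isfinite(b)
        assert ok.sum() > a.size // 2
        np.testing.assert_allclose(a[ok], b[ok], rtol=0.02)

    def test_zero_field_all_nan_with_warning(self, caplog):
        zero = DisplacementField(
            np.zeros((4, 300, 64)), np.arange(300) / FS, np.arange(64) * DX
        )
        with caplog.at_level(logging.WARNING, logger="octelast.imaging"):
            vm = local_velocity_map(zero, depth_bands=[(0, 4)])
        assert np.all(np.isnan(vm.velocity))
        assert not vm.mask.any()
        assert any("failed" in r.message or "NaN" in r.message
                   for r in caplog.records)

    def test_window_width_validation(self, truth_small):
        with pytest.raises(ValueError, match="window_width"):
            local_velocity_map(truth_small, window_width=4)


class TestOverlay:
    def make_vmap(self, n_lat=32, value=5.0):
        v = np.full((1, n_lat), value)
        return VelocityMap(
            v, np.ones_like(v, bool), np.full_like(v, 2000.0),
            np.arange(n_lat) * DX, [(2, 8)],
        )

    def test_colored_pixels_match_mask(self):
        structure = np.full((12, 32), -20.0)
        structure[2:8, 4:20] = 30.0
        rgb = overlay_velocity_on_structure(structure, self.make_vmap(), 0.0)
        gray = (rgb[..., 0] == rgb[..., 1]) & (rgb[..., 1] == rgb[..., 2])
        colored = ~gray
        expected = np.zeros_like(structure, bool)
        expected[2:8, 4:20] = True
        np.testing.assert_array_equal(colored, expected)

    def test_uniform_map_single_color(self):
        structure = np.full((12, 32), 30.0)
        rgb = overlay_velocity_on_structure(structure, self.make_vmap(), 0.0,
                                            vmin=0.0, vmax=10.0)
        band = rgb[2:8]
        assert np.unique(band.reshape(-1, 3), axis=0).shape[0] == 1

    def test_png_round_trip(self, tmp_path):
        import imageio.v3 as iio

        structure = np.full((12, 32), -20.0)
        structure[2:8, 4:20] = 30.0
        rgb = overlay_velocity_on_structure(structure, self.make_vmap(), 0.0)
        path = tmp_path / "overlay_pixels.png"
        iio.imwrite(path, rgb)
        back = iio.imread(path)
        gray = (back[..., 0] == back[..., 1]) & (back[..., 1] == back[..., 2])
        assert (~gray).sum() == 6 * 16
        render_overlay_figure(structure, self.make_vmap(), 0.0,
                              tmp_path / "overlay_fig.png")
        assert (tmp_path / "overlay_fig.png").stat().st_size > 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="align"):
            overlay_velocity_on_structure(np.zeros((5, 7)), self.make_vmap(), 0.0)


class TestSummaries:
    def flat_vmap(self, velocity, f=2000.0, n_lat=16):
        v = np.full((1, n_lat), float(velocity))
        return VelocityMap(v, np.ones_like(v, bool), np.full_like(v, f),
                           np.arange(n_lat) * DX, [(0, 4)])

    def test_mean_and_sample_sd(self):
        res = summarize_elasticity(
            [self.flat_vmap(v) for v in (7.9, 8.0, 8.1)], 496e-6,
            f_mode="per_sample", label="x",
        )
        assert res.mean_velocity == pytest.approx(8.0)
        assert res.velocity_sd == pytest.approx(0.1)
        assert res.n_repeats == 3

    def test_single_repeat_flagged(self):
        res = summarize_elasticity([self.flat_vmap(8.0)], 496e-6)
        assert res.n_repeats == 1 and res.velocity_sd == 0.0

    def test_per_position_equals_per_sample_for_uniform_map(self):
        vmaps = [self.flat_vmap(8.0)]
        a = summarize_elasticity(vmaps, 496e-6, f_mode="per_sample")
        b = summarize_elasticity(vmaps, 496e-6, f_mode="per_position")
        assert a.mean_modulus == pytest.approx(b.mean_modulus, rel=1e-9)

    def test_empty_mask_rejected(self):
        vm = self.flat_vmap(8.0)
        vm.mask[:] = False
        with pytest.raises(ValueError, match="mask"):
            summarize_elasticity([vm], 496e-6)

    def test_bit_reproducible(self):
        vmaps = [self.flat_vmap(v) for v in (7.9, 8.0, 8.1)]
        a = summarize_elasticity(vmaps, 496e-6)
        b = summarize_elasticity(vmaps, 496e-6)
        assert (a.mean_modulus, a.modulus_sd) == (b.mean_modulus, b.modulus_sd)


class TestPercentIncrease:
    def test_reference_sweep_values(self):
        assert percent_increase(7.97, 10.56) == pytest.approx(32.50, abs=0.005)
        assert percent_increase(191.66, 439.76) == pytest.approx(129.45, abs=0.005)

    def test_no_change_zero(self):
        assert percent_increase(5.0, 5.0) == 0.0

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            percent_increase(0.0, 1.0)


class TestQuadraticTrend:
    def test_exact_parabola(self):
        x = np.arange(1.0, 6.0)
        fit = quadratic_trend_fit(x, x**2)
        assert fit.a == pytest.approx(1.0, abs=1e-10)
        assert fit.b == pytest.approx(0.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_line_has_zero_curvature(self):
        x = np.arange(1.0, 7.0)
        fit = quadratic_trend_fit(x, 2 * x + 1)
        assert abs(fit.a) < 1e-10 and fit.r_squared == pytest.approx(1.0)

    def test_reference_modulus_trend(self):
        # frozen normal-equations oracle on the bundled pressure-sweep table
        x = [10, 15, 20, 25, 30, 35]
        y = [191.66, 194.60, 210.61, 273.59, 369.98, 439.76]
        fit = quadratic_trend_fit(x, y)
        assert fit.r_squared == pytest.approx(0.988192, abs=1e-5)
        assert fit.a == pytest.approx(0.468371, abs=1e-5)

    def test_validation(self):
        with pytest.raises(ValueError):
            quadratic_trend_fit([1, 2, 3], [1, 4, 9])
        with pytest.raises(ValueError):
            quadratic_trend_fit([1, 2, 3, 4], [2, 2, 2, 2])


def test_elasticity_result_validation():
    with pytest.raises(ValueError):
        ElasticityResult("x", 496e-6, 8.0, -0.1, 192e3, 0.0, 3)
    with pytest.raises(ValueError):
        ElasticityResult("x", 496e-6, 8.0, 0.1, 192e3, 0.0, 0)
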