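# Methods

## Physical model

The tissue is modelled as a homogeneous, isotropic, incompressible elastic
plate of full thickness `H` (half thickness `h = H/2`), shear modulus `μ`,
density `ρ`, immersed in an incompressible, inviscid fluid on both faces.
For such a plate the zeroth-order antisymmetric (A0, flexural) guided mode
satisfies the characteristic equation

    4 k_L³ β cosh(k_L h) sinh(β h)
        = (2 k_L² − k_S²)² sinh(k_L h) cosh(β h)
          + k_S⁴ cosh(k_L h) cosh(β h),

with `k_L = ω/c` the Lamb wavenumber at phase velocity `c`,
`k_S = ω/V_S` the shear wavenumber (`V_S = √(μ/ρ)`), and
`β = √(k_L² − k_S²)` on the principal branch. In the 0.4–4 kHz band and
for `H ≈ 500 μm` this equation has exactly one root in `(0, V_S)`; the A0
velocity is strictly increasing in frequency there and bounded above by
the shear speed. Numerically the equation is evaluated in the form
obtained by dividing through by `k_S⁴ cosh(k_L h) cosh(β h)`: the `tanh`
terms saturate instead of overflowing, the residual is dimensionless and
O(1), and its sign pattern is unchanged, so bracketed root finding is
unaffected.

In the thin-plate (flexural) limit the vacuum-plate velocity reduces to
`V_vac = √(2πf·H·V_S/√3)`, and symmetric fluid loading slows the mode by
the factor `1/√2`. We use `1/√2` (not a factor 2) because it is the unique
factor under which the velocity formula and the modulus inversion

    E = 9 ρ V_L⁴ / (π f H)²

compose to the exact identity `E → E` (this round trip is enforced to
1e-9 relative accuracy in the tests). Note the convention split: the
characteristic equation uses the half thickness `h`, the closed forms and
the inversion use the full thickness `H`; both are explicit fields and
never interchanged silently.

Viscosity is stored on the material but the solver implements the purely
elastic case and rejects `η ≠ 0`; viscoelastic dispersion fitting is out
of scope. Density defaults to 1000 kg/m³ (soft-tissue convention) and is
overridable everywhere it appears.

## Two modulus inversions

`summarize_elasticity` supports:

* `thin_plate` (default) — the conventional closed-form inversion
  `E = 9ρV_L⁴/(πfH)²` at the recorded dominant frequency. This is exact
  only in the flexural limit `k_L h ≪ 1`. At the study's dominant
  frequency (~2 kHz) and `H ≈ 500 μm`, `k_L h` is of order one for soft
  plates, and because `E ∝ V⁴` even a small velocity-level truncation
  error is amplified four-fold in the modulus.
* `full_dispersion` — root-matching: find the modulus whose fluid-loaded
  plate has the measured A0 phase velocity at the measured frequency (the
  A0 velocity is strictly increasing in `E` at fixed frequency, so the
  root is unique and bracketed). This inversion is consistent with the
  full wave physics at any frequency-thickness product and is what the
  parameter-recovery checks use; it recovers imposed moduli across
  50–400 kPa where the closed form is reliable only near its sweet spot.

## Estimation pipeline

Order of operations: Doppler phase → displacement → temporal integration →
depth reduction → zero-phase high-pass → post-excitation crop → per-window
2D FFT → ridge extraction → velocity at the window's dominant frequency →
map interpolation → masking by structural intensity → summary.

Key choices, with defaults and rationale:

* **Doppler sign convention.** `Δφ = arg(F_m·F*_{m+1})`; positive
  displacement means motion toward the beam source, and the simulator
  encodes phase as `exp(−i·4πn·u/λ₀)` so the chain round-trips exactly
  (noiseless reconstruction error < 0.1 nm RMS). Refractive index
  n = 1.38, centre wavelength 1300 nm.
* **Integration before spectral analysis.** The Doppler chain yields the
  *differential* displacement between successive A-lines. Differencing
  multiplies every spectrum by ≈ 2πf/f_s, so white phase noise acquires an
  f² power ramp that can capture the spectral argmax; cumulatively summing
  back to absolute displacement restores the excitation's Gaussian
  spectrum, and the high-pass filter absorbs the integrated noise drift.
  Both routes are available (`integrate` flag); integration is the
  default.
* **High-pass filter.** 4th-order Butterworth, 200 Hz cutoff, applied
  forward-backward (`sosfiltfilt`) per lateral column so arrival times are
  not biased; removes DC and bulk drift below the wave band.
* **Analysis band.** 0.4–4 kHz — the low-frequency range in which the A0
  mode dominates; also the search range for the dominant frequency, which
  must be band-limited because the noise floor otherwise dominates at
  high frequency.
* **k-space.** Hann taper in both axes, zero-padding ×4 in both axes;
  frequency one-sided, wavenumber signed with the half-plane matching the
  propagation direction (away from the push) searched, which rejects the
  counter-propagating mirror ridge. Per-frequency peak: argmax over
  wavenumber with 3-point parabolic sub-bin refinement, ties broken toward
  the smaller wavenumber (faster velocity) and logged; frequency bins
  whose ridge peak is below 10% of the band's global maximum are omitted.
* **Windows.** 64 lateral positions (1.6 mm at the 25 μm step), advancing
  by 8. The window must span at least half the longest analysis
  wavelength (~2.3 mm at the stiffest level studied): below that the
  per-frequency spatial spectrum is an almost flat single lobe and the
  argmax collapses to the first wavenumber bin. Velocities are assigned
  to window centres and linearly interpolated between them; a window
  whose extraction fails contributes NaN and a logged warning, never an
  exception.
* **Dominant frequency.** Peak of the Hann-windowed temporal power
  spectrum averaged over the window's columns, DC excluded, parabolic
  refinement, restricted to the analysis band. Modulus summaries default
  to one global frequency per scan (`f_mode="per_sample"`); per-position
  conversion is available.
* **Thickness.** Measured from the structural image by intensity
  thresholding: per column, the extent between first and last
  above-threshold pixel; median across columns. The pixel pitch is
  treated as already expressed in tissue units; dividing by the
  refractive index is available but off by default.

## Synthetic data

The simulator emulates the study acquisition: 50 kHz A-line rate, 1000
A-lines per lateral position, push between A-lines 101 and 125, 1300 nm
centre wavelength. The push is represented as a Gaussian-spectrum
displacement source (centre 2 kHz, 1.5 kHz FWHM — chosen to land the
dominant frequency in the low-kHz range that produces the study's
velocity scale; the MHz ultrasound carrier is irrelevant at the A-line
rate and not simulated). Each spectral component (40 Hz spacing)
propagates with the wavenumber `k(f) = 2πf/c_A0(f)` from the
characteristic equation, with the propagation phase integrated across
stiffness segments so laterally heterogeneous phantoms are handled with
phase continuity at interfaces. The packet envelope is centred
`push_duration + 3σ_t` after the push onset, so the field is ~zero (to
the Gaussian tail) both before the push and inside the excitation-artifact
window that the analysis discards; the amplitude is rescaled so the peak
displacement equals the configured 150 nm. The complex OCT cube carries a
per-pixel log-normal speckle amplitude frozen in time and i.i.d. Gaussian
phase noise of 167.3 mrad SD per A-line (the modelled system's phase
stability). Pressure sweeps impose the stiffness directly per level
(μ = E/3) — pressure-to-stiffness mechanics are not modelled — with
distinct child seeds per repeat.

What the simulator does *not* emulate, and what passing tests therefore do
not show about real data: geometric spreading and attenuation (optional
exponential decay only), reflections at stiffness interfaces, depth
dependence of the wavefield, bulk motion, galvo desynchronisation,
viscoelastic dispersion, and the acoustic field of the transducer.

## Study conditions used by tests and the acceptance script

Grids are sized to keep the full suite fast while preserving the physics:
192 lateral positions × 25 μm (4.8 mm aperture), 40 depth pixels × 16 μm
with a 31-pixel tissue band (496 μm plate), full 1000-A-line records.
Parameter recovery uses 50/200/400 kPa with 3 noisy repeats each (167.3
mrad phase noise) and single noiseless runs; contrast localisation uses a
100|400 kPa two-segment phantom split at the aperture midpoint. Unit
tests use a further reduced 96-position, 400-A-line geometry.

## Known limitations

* Elastic, isotropic, homogeneous-per-segment model only; no viscosity
  inversion, no anisotropy, no higher-order or symmetric Lamb modes.
* The thin-plate inversion is kept as the default because it is the
  conventional estimate, but it should not be trusted for soft plates at
  kHz dominant frequencies; use `inversion="full_dispersion"` when the
  frequency-thickness product is not small.
* The dominant frequency is a property of the excitation and filtering,
  not of the tissue; moduli quoted at different dominant frequencies are
  not directly comparable under the thin-plate inversion.
* Boundary localisation in the velocity map is limited to roughly one
  analysis window; sharper transitions require narrower windows and
  therefore shorter wavelengths (stiffer plates trade off against this).
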