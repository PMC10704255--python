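# octelast

Phase-resolved optical-coherence-elastography (OCE) analysis for thin,
fluid-immersed tissue such as the optic nerve head (ONH): from complex
M-B-mode OCT data to guided-wave phase-velocity maps and Young's-modulus
estimates.

Elevated intraocular pressure stiffens the ONH, and that stiffening is a
candidate biomarker for glaucoma risk. Acoustic-radiation-force OCE probes
it non-destructively: a focused ultrasound push launches an elastic wave in
the tissue, a phase-sensitive OCT system tracks the nanometre-scale axial
displacement as the wave propagates laterally, and the wave's dispersion is
inverted for stiffness. Because the ONH is a thin (~500 μm) plate bounded
by fluid, the wave is the zeroth-order antisymmetric (A0) Lamb mode, which
is strongly dispersive at kHz frequencies — so the analysis must estimate
phase velocity as a function of frequency, not a single wave speed.

## Method

1. **Phase-resolved Doppler** — inter-A-line displacement from the complex
   OCT signal `F`:
   `Δφ = arg(F_m · F*_{m+1})`, `Δd = λ₀ Δφ / (4πn)`.
2. **Spatio-temporal map and k-space** — displacement over (time, lateral
   position) is high-pass filtered and 2D-Fourier transformed; the wave
   appears as a ridge in the (frequency f, wavenumber k) plane, and the
   phase velocity at each frequency is `c(f) = 2πf / k*(f)` with `k*` the
   wavenumber of maximum spectral magnitude.
3. **Velocity mapping** — the estimator runs in overlapping lateral
   windows; each window's velocity is read at its dominant (spectral-peak)
   frequency, producing a 2D phase-velocity distribution registered to the
   structural image.
4. **Modulus inversion** — for a thin incompressible plate of thickness
   `H` in vacuum, `V_vac = √(2πf·H·V_S/√3)`; fluid loading on both faces
   slows the mode by `1/√2`; eliminating the shear speed
   `V_S = √(E/3ρ)` gives

   `E = 9ρ V_L⁴ / (πfH)²`.

   The package also solves the full A0 characteristic equation of the
   fluid-loaded plate (`4k_L³β cosh(k_L h)sinh(βh) = (2k_L²−k_S²)²
   sinh(k_L h)cosh(βh) + k_S⁴cosh(k_L h)cosh(βh)`, with `h = H/2`,
   `β = √(k_L²−k_S²)`), both to generate exact model dispersion curves and
   as an alternative modulus inversion that avoids the thin-plate
   truncation error.

A synthetic-data module stands in for the instrument: it synthesises the
dispersive A0 wavefield of a phantom plate (homogeneous or laterally
segmented), encodes it into a speckled complex OCT cube with realistic
interferometric phase noise (167.3 mrad), and reproduces the M-B timing
(50 kHz A-line rate, 1000 A-lines per position, push between A-lines 101
and 125). Every stage of the pipeline is therefore testable against known
ground truth.

## Worked example

Process a simulated 192 kPa phantom with the default acquisition (no input
file means the phantom described by the config is simulated first):

```console
$ octelast process --label example --out demo
example: velocity 3.774 m/s, modulus 191.68 kPa (f_dom 1981 Hz, thickness 496 um)
  dispersion_csv: demo/example_dispersion.csv
  summary_csv: demo/example_summary.csv
  velocity_tiff: demo/example_velocity.tif
  overlay_png: demo/example_overlay.png
  manifest_json: demo/example_manifest.json
```

The wave in the 496 μm plate travels at 3.77 m/s at the ~2 kHz dominant
frequency of the push — far below the 8 m/s bulk shear speed, as expected
for the flexural mode — and inverts to 191.7 kPa against the imposed
192 kPa. The overlay PNG shows the velocity map painted over the
structural B-scan with a colour bar in m/s.

Summarising the bundled ex vivo ONH pressure-sweep table:

```console
$ octelast report --kind iop
...
velocity increase 32.50%  modulus increase 129.45%
modulus quadratic trend R^2 = 0.9882
```

i.e. from 10 to 35 mmHg the mean phase velocity rises 7.97 → 10.56 m/s
(+32.5%) and the modulus 191.66 → 439.76 kPa (+129.4%), with a clearly
quadratic pressure trend; across probe directions the modulus varies by at
most ~3.4 kPa, consistent with isotropy in the imaging plane.

The same operations are available as a library:

```python
import octelast as oe

material = oe.PlateMaterial(shear_modulus=64e3, thickness=496e-6)
oe.solve_a0_phase_velocity(2000.0, material).phase_velocity  # 3.7866 m/s
```

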