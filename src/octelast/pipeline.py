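"""End-to-end orchestration: configuration, single runs, and sweeps.

A *run* executes the full analysis on one M-B scan (measured container or
simulated phantom): Doppler phase -> displacement -> spatio-temporal map ->
high-pass filter -> k-space -> dispersion curve -> local velocity map ->
elasticity summary, writing CSV/TIFF/PNG artifacts plus a machine-readable
manifest.  A *sweep* aggregates labelled runs into the two experiment
designs of interest: a pressure (stiffness) sweep with percent-increase and
quadratic-trend statistics, and a direction sweep with a
constancy-of-modulus statistic.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from ._version import __version__ as _version
from .doppler import (
    AcquisitionConfig,
    MBScan,
    cumulative_displacement,
    doppler_phase_shift,
    highpass_filter,
    load_mbscan,
    phase_to_displacement,
    save_mbscan,
    spatiotemporal_map,
)
from .imaging import (
    DEFAULT_BAND,
    DEFAULT_MIN_PEAK_FRACTION,
    DEFAULT_PAD,
    DEFAULT_TAPER,
    DEFAULT_WINDOW_STEP,
    DEFAULT_WINDOW_WIDTH,
    DispersionCurve,
    ElasticityResult,
    QuadraticFit,
    VelocityMap,
    elasticity_to_row,
    extract_dispersion,
    kspace_transform,
    local_velocity_map,
    percent_increase,
    quadratic_trend_fit,
    render_overlay_figure,
    summarize_elasticity,
    summary_csv_header,
)
from .synthetic import (
    DEFAULT_PHASE_NOISE_SD,
    ExcitationSpec,
    PhantomGeometry,
    displacement_to_mbscan,
    simulate_wavefield,
)
from .lamb import PlateMaterial

__all__ = [
    "RunConfig",
    "ProcessResult",
    "SweepReport",
    "run_process",
    "run_sweep",
    "thickness_from_structure",
    "simulate_scan",
    "REFERENCE_IOP_SWEEP",
    "REFERENCE_DIRECTION_SWEEP",
    "reference_elasticity_results",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Reference ex vivo porcine optic-nerve-head measurement tables.  Pressure in
# mmHg / direction in degrees; thickness in um; velocity in m/s; modulus in
# kPa; three repeated measurements per row.  Used by the `report` command
# and by summary-statistics checks.
# ---------------------------------------------------------------------------

REFERENCE_IOP_SWEEP = pd.DataFrame(
    {
        "iop_mmhg": [10, 15, 20, 25, 30, 35],
        "thickness_um": [496, 530, 482, 560, 521, 530],
        "mean_velocity_m_s": [7.97, 8.02, 8.35, 8.70, 9.91, 10.56],
        "velocity_sd": [0.18, 0.33, 0.33, 0.27, 0.30, 0.15],
        "mean_modulus_kpa": [191.66, 194.60, 210.61, 273.59, 369.98, 439.76],
        "modulus_sd": [13.43, 16.28, 22.71, 30.46, 34.24, 30.39],
    }
)

REFERENCE_DIRECTION_SWEEP = pd.DataFrame(
    {
        "direction_deg": [0, 45, 90, 135],
        "thickness_um": [506, 473, 574, 527],
        "mean_velocity_m_s": [7.69, 7.75, 7.81, 7.77],
        "velocity_sd": [0.18, 0.33, 0.33, 0.50],
        "mean_modulus_kpa": [177.29, 183.11, 182.14, 180.24],
        "modulus_sd": [7.77, 15.91, 15.20, 22.46],
    }
)


def reference_elasticity_results(
    table: pd.DataFrame, label_column: str
) -> list[ElasticityResult]:
    """Wrap a reference summary table as :class:`ElasticityResult` rows."""
    out = []
    for _, row in table.iterrows():
        out.append(
            ElasticityResult(
                label=str(row[label_column]),
                thickness=row["thickness_um"] * 1e-6,
                mean_velocity=row["mean_velocity_m_s"],
                velocity_sd=row["velocity_sd"],
                mean_modulus=row["mean_modulus_kpa"] * 1e3,
                modulus_sd=row["modulus_sd"] * 1e3,
                n_repeats=3,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything needed to reproduce one run, serialisable to JSON/YAML."""

    label: str = "run"
    input_path: str | None = None  # HDF5 container; None -> simulate
    out_dir: str = "octelast_out"
    seed: int = 0
    log_level: str = "INFO"

    acquisition: AcquisitionConfig = field(
        default_factory=lambda: AcquisitionConfig(axial_pixel_pitch=16e-6)
    )

    # simulation spec (used when input_path is None)
    youngs_modulus: float = 192e3  # Pa
    density: float = 1000.0
    segment_widths: tuple[float, ...] = ()  # empty -> homogeneous full width
    segment_moduli: tuple[float, ...] = ()
    depth_pixels: int = 40
    tissue_band: tuple[int, int] = (4, 35)
    phase_noise_sd: float = DEFAULT_PHASE_NOISE_SD
    excitation_center_hz: float = 2000.0
    excitation_bandwidth_hz: float = 1500.0
    peak_displacement: float = 150e-9
    push_position: float = 0.0

    # processing parameters (defaults = documented design choices)
    cutoff_hz: float = 200.0
    window_width: int = DEFAULT_WINDOW_WIDTH
    window_step: int = DEFAULT_WINDOW_STEP
    band: tuple[float, float] = DEFAULT_BAND
    pad: tuple[int, int] = DEFAULT_PAD
    taper: str = DEFAULT_TAPER
    min_peak_fraction: float = DEFAULT_MIN_PEAK_FRACTION
    f_mode: Literal["per_sample", "per_position"] = "per_sample"
    inversion: Literal["thin_plate", "full_dispersion"] = "thin_plate"
    intensity_threshold_db: float = 20.0
    depth_bands: tuple[tuple[int, int], ...] | None = None  # None -> tissue mask
    thickness_override: float | None = None  # m; None -> from structure
    thickness_refractive_correction: bool = False
    analysis_after_excitation: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        d["acquisition"] = self.acquisition.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "acquisition" in d and isinstance(d["acquisition"], dict):
            d["acquisition"] = AcquisitionConfig.from_dict(d["acquisition"])
        names = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        d = {k: v for k, v in d.items() if k in names}
        for key in ("segment_widths", "segment_moduli", "tissue_band", "band", "pad"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("depth_bands") is not None:
            d["depth_bands"] = tuple(tuple(b) for b in d["depth_bands"])
        return cls(**d)

    def save(self, path) -> None:
        path = Path(path)
        data = self.to_dict()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            path.write_text(yaml.safe_dump(data, sort_keys=True))
        else:
            path.write_text(json.dumps(data, indent=2, sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data)

    # -- derived simulation objects --------------------------------------

    def phantom_geometry(self) -> PhantomGeometry:
        cfg = self.acquisition
        full_width = cfg.lateral_positions * cfg.lateral_step
        thickness = (self.tissue_band[1] - self.tissue_band[0]) * cfg.axial_pixel_pitch
        if self.segment_widths:
            if len(self.segment_widths) != len(self.segment_moduli):
                raise ValueError("segment_widths and segment_moduli must match")
            segments = tuple(
                (w, PlateMaterial.from_youngs_modulus(e, self.density, thickness))
                for w, e in zip(self.segment_widths, self.segment_moduli)
            )
        else:
            segments = (
                (
                    full_width,
                    PlateMaterial.from_youngs_modulus(
                        self.youngs_modulus, self.density, thickness
                    ),
                ),
            )
        return PhantomGeometry(
            segments=segments,
            depth_pixels=self.depth_pixels,
            tissue_band=tuple(self.tissue_band),
        )

    def excitation(self) -> ExcitationSpec:
        return ExcitationSpec(
            center_frequency=self.excitation_center_hz,
            bandwidth=self.excitation_bandwidth_hz,
            push_position=self.push_position,
            peak_displacement=self.peak_displacement,
        )


@dataclass
class ProcessResult:
    velocity_map: VelocityMap
    dispersion_curve: DispersionCurve
    elasticity: ElasticityResult
    thickness: float
    dominant_frequency: float
    outputs: dict[str, str]
    manifest: dict


@dataclass
class SweepReport:
    sweep_kind: str
    table: pd.DataFrame
    results: list[ElasticityResult]
    velocity_percent_increase: float | None = None
    modulus_percent_increase: float | None = None
    velocity_trend: QuadraticFit | None = None
    modulus_trend: QuadraticFit | None = None
    max_velocity_deviation: float | None = None
    max_modulus_deviation: float | None = None


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def thickness_from_structure(
    structure: np.ndarray,
    threshold_db: float,
    column_range: tuple[int, int] | None = None,
    axial_pixel_pitch: float = 4e-6,
    refractive_index: float = 1.0,
) -> float:
    """Tissue thickness from the log-intensity B-scan by thresholding.

    Per lateral column the extent between the first and last above-threshold
    depth pixel (inclusive) is converted to metres; the median over columns
    is returned.  ``refractive_index`` > 1 applies an optical-path
    correction (geometric thickness = optical / n); by default the pixel
    pitch is taken as already expressed in tissue units.
    """
    structure = np.asarray(structure, dtype=float)
    if structure.size == 0:
        raise ValueError("empty structure image")
    if column_range is None:
        column_range = (0, structure.shape[1])
    j0, j1 = column_range
    cols = structure[:, j0:j1]
    above = cols >= threshold_db
    widths = []
    for j in range(above.shape[1]):
        idx = np.nonzero(above[:, j])[0]
        if idx.size:
            widths.append(idx[-1] - idx[0] + 1)
    if not widths:
        raise ValueError(
            f"no pixels above {threshold_db} dB in columns [{j0}, {j1})"
        )
    return float(np.median(widths)) * axial_pixel_pitch / refractive_index


def simulate_scan(config: RunConfig) -> MBScan:
    """Generate the synthetic M-B scan described by ``config``."""
    geom = config.phantom_geometry()
    truth = simulate_wavefield(geom, config.excitation(), config.acquisition)
    return displacement_to_mbscan(
        truth, geom, config.acquisition,
        phase_noise_sd=config.phase_noise_sd, seed=config.seed,
    )


def _tissue_depth_band(scan: MBScan, threshold_db: float) -> tuple[int, int]:
    """Depth rows whose median lateral intensity clears the mask threshold."""
    med = np.median(scan.structure_image, axis=1)
    idx = np.nonzero(med >= threshold_db)[0]
    if idx.size == 0:
        raise ValueError(f"no depth row above {threshold_db} dB; cannot locate tissue")
    return int(idx[0]), int(idx[-1]) + 1


def run_process(
    config: RunConfig,
    scan: MBScan | None = None,
    write_outputs: bool = True,
) -> ProcessResult:
    """Execute the full analysis chain on one scan.

    Order: Doppler phase -> displacement -> depth reduction -> high-pass ->
    k-space -> global dispersion curve -> windowed velocity map -> mask by
    structural intensity -> elasticity summary.  Artifacts (dispersion CSV,
    summary CSV, velocity TIFF, overlay PNG, manifest JSON) are written to
    ``config.out_dir`` unless ``write_outputs`` is False.
    """
    cfg = config.acquisition
    if scan is None:
        if config.input_path is not None:
            scan = load_mbscan(config.input_path)
            cfg = scan.config
        else:
            logger.info("no input container given; simulating phantom '%s'",
                        config.label)
            scan = simulate_scan(config)

    phase = doppler_phase_shift(scan)
    disp = phase_to_displacement(phase, cfg)
    disp_cum = cumulative_displacement(disp)

    if config.depth_bands is not None:
        depth_bands = [tuple(b) for b in config.depth_bands]
    else:
        depth_bands = [_tissue_depth_band(scan, config.intensity_threshold_db)]

    time_start = cfg.post_excitation_index if config.analysis_after_excitation else None
    vmap = local_velocity_map(
        disp,
        window_width=config.window_width,
        window_step=config.window_step,
        band=config.band,
        depth_bands=depth_bands,
        time_start=time_start,
        cutoff_hz=config.cutoff_hz,
        pad=config.pad,
        taper=config.taper,
        min_peak_fraction=config.min_peak_fraction,
    )

    # restrict the map mask to laterally bright structure
    d0, d1 = depth_bands[0]
    bright = scan.structure_image[d0:d1].max(axis=0) >= config.intensity_threshold_db
    vmap.mask &= bright[None, :]

    # global (full-aperture) dispersion curve from the integrated map
    stmap = spatiotemporal_map(disp_cum, depth_bands[0], reduce="mean_over_range")
    stmap = highpass_filter(stmap, cutoff_hz=config.cutoff_hz)
    if time_start:
        from .doppler import SpatioTemporalMap

        stmap = SpatioTemporalMap(
            stmap.values[time_start:], stmap.time_axis[time_start:],
            stmap.lateral_axis, stmap.depth_range, filtered=True,
        )
    ks = kspace_transform(stmap, pad_t=config.pad[0], pad_x=config.pad[1],
                          window=config.taper)
    curve = extract_dispersion(ks, band=config.band,
                               min_peak_fraction=config.min_peak_fraction)
    from .imaging import dominant_frequency as _domfreq

    f_dom = float(
        np.clip(_domfreq(stmap, band=config.band), config.band[0], config.band[1])
    )

    if config.thickness_override is not None:
        thickness = config.thickness_override
    else:
        thickness = thickness_from_structure(
            scan.structure_image,
            config.intensity_threshold_db,
            axial_pixel_pitch=cfg.axial_pixel_pitch,
            refractive_index=(
                cfg.refractive_index if config.thickness_refractive_correction else 1.0
            ),
        )

    elasticity = summarize_elasticity(
        [vmap], thickness, density=config.density,
        f_mode=config.f_mode, label=config.label, inversion=config.inversion,
    )

    outputs: dict[str, str] = {}
    manifest = {
        "software": "octelast",
        "version": _version,
        "label": config.label,
        "seed": config.seed,
        "parameters": config.to_dict(),
        "thickness_m": thickness,
        "dominant_frequency_hz": f_dom,
    }
    if write_outputs:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stem = config.label.replace(" ", "_").replace("/", "_")

        curve_path = out / f"{stem}_dispersion.csv"
        curve.to_csv(curve_path)
        outputs["dispersion_csv"] = str(curve_path)

        summary_path = out / f"{stem}_summary.csv"
        with open(summary_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(summary_csv_header())
            writer.writerow(elasticity_to_row(elasticity))
        outputs["summary_csv"] = str(summary_path)

        import tifffile

        tiff_path = out / f"{stem}_velocity.tif"
        tifffile.imwrite(tiff_path, vmap.velocity.astype(np.float32))
        outputs["velocity_tiff"] = str(tiff_path)

        png_path = out / f"{stem}_overlay.png"
        render_overlay_figure(
            scan.structure_image, vmap, config.intensity_threshold_db,
            png_path, axial_pitch=cfg.axial_pixel_pitch, title=config.label,
        )
        outputs["overlay_png"] = str(png_path)

        manifest_path = out / f"{stem}_manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        outputs["manifest_json"] = str(manifest_path)

    return ProcessResult(
        velocity_map=vmap,
        dispersion_curve=curve,
        elasticity=elasticity,
        thickness=thickness,
        dominant_frequency=f_dom,
        outputs=outputs,
        manifest=manifest,
    )


def run_sweep(
    runs: Sequence[RunConfig] | Sequence[ElasticityResult],
    sweep_kind: Literal["iop", "direction"],
    write_outputs: bool = False,
    out_dir: str | None = None,
) -> SweepReport:
    """Aggregate labelled runs into a sweep report.

    ``runs`` may be RunConfigs (each is executed) or precomputed
    ElasticityResults (summaries injected directly).  For a pressure sweep
    the report carries first-to-last percent increases of velocity and
    modulus plus quadratic trend fits against the numeric labels; for a
    direction sweep, the maximum absolute deviation from the across-
    direction mean (the isotropy statistic).
    """
    if len(runs) < 2:
        raise ValueError("a sweep needs at least two labelled runs")
    if sweep_kind not in ("iop", "direction"):
        raise ValueError(f"unknown sweep kind {sweep_kind!r}")

    if isinstance(runs[0], ElasticityResult):
        results = list(runs)  # type: ignore[arg-type]
    else:
        results = []
        for rc in runs:  # type: ignore[assignment]
            if out_dir is not None:
                rc = replace(rc, out_dir=out_dir)
            results.append(run_process(rc, write_outputs=write_outputs).elasticity)

    labels = [r.label for r in results]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate labels in sweep: {labels}")

    table = pd.DataFrame(
        {
            "label": labels,
            "thickness_um": [r.thickness * 1e6 for r in results],
            "mean_velocity_m_s": [r.mean_velocity for r in results],
            "velocity_sd": [r.velocity_sd for r in results],
            "mean_modulus_kpa": [r.mean_modulus / 1e3 for r in results],
            "modulus_sd": [r.modulus_sd / 1e3 for r in results],
            "n_repeats": [r.n_repeats for r in results],
        }
    )
    report = SweepReport(sweep_kind=sweep_kind, table=table, results=results)

    velocities = np.array([r.mean_velocity for r in results])
    moduli = np.array([r.mean_modulus for r in results])
    if sweep_kind == "iop":
        report.velocity_percent_increase = percent_increase(
            velocities[0], velocities[-1]
        )
        report.modulus_percent_increase = percent_increase(moduli[0], moduli[-1])
        try:
            x = np.array([float(lbl) for lbl in labels])
            report.velocity_trend = quadratic_trend_fit(x, velocities)
            report.modulus_trend = quadratic_trend_fit(x, moduli / 1e3)
        except ValueError as exc:
            logger.warning("trend fit skipped: %s", exc)
    else:
        report.max_velocity_deviation = float(
            np.max(np.abs(velocities - velocities.mean()))
        )
        report.max_modulus_deviation = float(np.max(np.abs(moduli - moduli.mean())))

    if write_outputs and out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / f"sweep_{sweep_kind}_summary.csv", index=False)
    return report


def save_simulated_scan(config: RunConfig, path) -> None:
    """Simulate the configured phantom and write the HDF5 container."""
    save_mbscan(simulate_scan(config), path)
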