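"""Config-driven orchestration of the full in situ DVC study.

The study follows the experimental workflow: two repeat reference scans give
the zero-strain error analysis (subvolume sweep, power-law fits, selection
against the acceptable-error threshold); the loading scans
(unloaded → load1 → load2) are then correlated at the selected (or
explicitly configured) subvolume size, rigid-body corrected, differentiated
to strain, and summarised per component including the implant-vs-bone
micromotion report.

All randomness flows from one top-level seed, split with
``numpy.random.SeedSequence`` into per-stage child seeds (phantom texture,
the two repeat-noise realisations, per-load noise, micromotion sampling).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import __version__
from .dvc import DisplacementField, DVCConfig, build_grid, correlate
from .errors import (
    ErrorSweep,
    PowerLawFit,
    acceptable_error,
    fit_power_law,
    run_zero_strain_study,
    select_subvolume,
    strain_by_component,
)
from .fields import StrainField, compute_strain, fit_rigid_body, subtract_rigid
from .micromotion import (
    ComponentSummary,
    MicromotionReport,
    relative_micromotion,
    sample_scheme,
    summarize_components,
)
from .phantom import (
    DeformationModel,
    PhantomSpec,
    add_noise,
    generate_phantom,
    micromotion_model,
    warp_volume,
)
from .volume import ComponentMask, Volume3D, read_volume, write_field, write_volume

__all__ = [
    "RunConfig",
    "FixtureSuite",
    "LoadResult",
    "StudyResult",
    "split_seeds",
    "build_fixture_suite",
    "write_fixture_suite",
    "run_study",
    "run_study_from_config",
]

#: Defaults of the phantom study conditions.
NOMINAL_STRAINS = {"load1": 0.010, "load2": 0.025}
MICROMOTION_OFFSET_UM = (0.0, 0.0, -40.0)  # implant pushed down by 40 µm at load2
POISSON_RATIO = 0.3
NOISE_FRACTION = 0.01  # repeat-scan noise SD as a fraction of dynamic range


def split_seeds(seed: int, n: int = 8) -> list[int]:
    """Derive ``n`` independent child seeds (< 2^31) from one top-level seed."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


@dataclass
class RunConfig:
    """Study configuration (mirrors the YAML file)."""

    reference_path: Optional[str] = None
    repeat_reference_path: Optional[str] = None
    load_paths: dict[str, str] = dc_field(default_factory=dict)
    mask_path: Optional[str] = None
    voxel_size_um: float = 10.0
    dvc: DVCConfig = dc_field(default_factory=DVCConfig)
    sweep_sizes: tuple[int, ...] = (16, 32, 48, 64, 80)
    sweep_methods: tuple[str, ...] = ("FFT_DC",)
    overlap_fraction: float = 0.5
    nominal_strain: float = 0.025
    subvolume_size_vox: Optional[int] = None  # None -> select from the sweep
    selection_component: str = "cartilage"
    strain_window: int = 3
    n_slices: int = 5
    n_subvolumes: int = 3
    summary_min_correlation: float = 0.8
    # interior volume-of-interest for the loaded analysis, per axis (z, y, x):
    # near-face subvolumes have one-sided search ranges, and material next to
    # the moving platen leaves the imaged domain under load
    analysis_inset_vox: tuple[int, int, int] = (8, 4, 4)
    # fitted-rigid subtraction removes scan-to-scan registration drift; a
    # drift-free (synthetic) rig has none, and subtracting the fit from a
    # genuinely compressed field also removes part of the physical
    # translation (strains are unaffected, displacement magnitudes are not)
    rigid_correction_loads: bool = False
    output_dir: str = "results/run"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        dvc_block = raw.pop("dvc", {})
        try:
            cfg = cls(dvc=DVCConfig(**dvc_block), **raw)
        except TypeError as exc:
            raise ValueError(f"invalid run configuration: {exc}") from exc
        if cfg.nominal_strain <= 0:
            raise ValueError("nominal_strain must be positive")
        return cfg


@dataclass
class FixtureSuite:
    """The standard phantom suite: reference pair, two load states, mask and
    analytic ground truth."""

    reference: Volume3D
    repeat_reference: Volume3D
    loads: dict[str, Volume3D]
    mask: ComponentMask
    truth: dict  # per load: nominal strain, Poisson ratio, implant offset
    models: dict[str, DeformationModel]
    seed: int


def build_fixture_suite(
    seed: int = 0,
    shape: tuple[int, int, int] = (192, 160, 160),
    voxel_size_um: float = 10.0,
    noise_fraction: float = NOISE_FRACTION,
    micromotion_offset_um: Sequence[float] = MICROMOTION_OFFSET_UM,
) -> FixtureSuite:
    """Generate the in-memory phantom study: noiseless reference texture, two
    noisy repeat 'scans', a ~1% compression state (load1) and a 2.5%
    compression state with superposed implant micromotion (load2)."""
    s_tex, s_rep_a, s_rep_b, s_l1, s_l2, *_ = split_seeds(seed)
    spec = PhantomSpec(shape=shape, voxel_size_um=voxel_size_um, seed=s_tex)
    clean, mask = generate_phantom(spec)
    dyn = float(clean.intensities.max() - clean.intensities.min())
    sigma = noise_fraction * dyn

    nz, ny, nx = shape
    centre_x = nx * voxel_size_um / 2.0
    centre_y = ny * voxel_size_um / 2.0
    models = {
        "load1": DeformationModel(
            "uniaxial_compression",
            {
                "nominal_strain": NOMINAL_STRAINS["load1"],
                "poisson_ratio": POISSON_RATIO,
                "fixed_z_um": 0.0,
                "centre_x_um": centre_x,
                "centre_y_um": centre_y,
            },
        ),
        "load2": micromotion_model(
            nominal_strain=NOMINAL_STRAINS["load2"],
            poisson_ratio=POISSON_RATIO,
            offset_um=tuple(micromotion_offset_um),
            mask=mask,
            voxel_size_um=voxel_size_um,
            fixed_z_um=0.0,
        ),
    }
    # the shared lateral centre for load2's far-field compression
    models["load2"].params["centre_x_um"] = centre_x
    models["load2"].params["centre_y_um"] = centre_y

    loads: dict[str, Volume3D] = {}
    for i, (name, model) in enumerate(models.items()):
        warped, _ = warp_volume(clean, model, interpolation_order=3)
        loads[name] = add_noise(warped, sigma, seed=(s_l1 if i == 0 else s_l2))

    truth = {
        "voxel_size_um": voxel_size_um,
        "shape": list(shape),
        "noise_sigma": sigma,
        "loads": {
            "load1": {
                "nominal_strain": NOMINAL_STRAINS["load1"],
                "poisson_ratio": POISSON_RATIO,
                "implant_offset_um": [0.0, 0.0, 0.0],
            },
            "load2": {
                "nominal_strain": NOMINAL_STRAINS["load2"],
                "poisson_ratio": POISSON_RATIO,
                "implant_offset_um": list(micromotion_offset_um),
            },
        },
    }
    return FixtureSuite(
        reference=add_noise(clean, sigma, seed=s_rep_a),
        repeat_reference=add_noise(clean, sigma, seed=s_rep_b),
        loads=loads,
        mask=mask,
        truth=truth,
        models=models,
        seed=seed,
    )


def write_fixture_suite(suite: FixtureSuite, out_dir) -> list[Path]:
    """Write the suite as TIFF volumes plus mask and ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, vol in {
        "reference": suite.reference,
        "repeat_reference": suite.repeat_reference,
        **suite.loads,
    }.items():
        p = out / f"{name}.tif"
        write_volume(
            Volume3D(
                vol.intensities.astype(np.float32), vol.voxel_size_um, vol.origin_voxel
            ),
            p,
        )
        written.append(p)
    p = out / "mask.tif"
    write_volume(Volume3D(suite.mask.labels, suite.reference.voxel_size_um), p)
    written.append(p)
    p = out / "ground_truth.json"
    p.write_text(json.dumps({**suite.truth, "seed": suite.seed, "legend": {
        str(k): v for k, v in suite.mask.legend.items()
    }}, indent=2))
    written.append(p)
    return written


@dataclass
class LoadResult:
    """DVC products for one load step."""

    name: str
    field: DisplacementField
    strain: StrainField
    summaries: list[ComponentSummary]
    micromotion: Optional[MicromotionReport]
    mean_strain_by_component: dict[str, np.ndarray]  # six components


@dataclass
class StudyResult:
    sweep: ErrorSweep
    power_laws: dict[str, PowerLawFit]  # per component, MAER vs size (first method)
    threshold: float
    selected_size_vox: Optional[int]
    size_used_vox: int
    loads: dict[str, LoadResult]
    manifest: dict


def _mean_strain_by_component(
    fld: DisplacementField,
    strain: StrainField,
    mask: Optional[ComponentMask],
    min_correlation: float,
) -> dict[str, np.ndarray]:
    ok = fld.valid & strain.valid & (fld.correlation >= min_correlation)
    out: dict[str, np.ndarray] = {}
    if not ok.any():
        return out
    if mask is None:
        out["all"] = strain.components[ok].mean(axis=0)
        return out
    centres = fld.grid.centres
    labels = mask.labels[centres[:, 0], centres[:, 1], centres[:, 2]]
    for lab, name in mask.legend.items():
        sel = ok & (labels == lab)
        if sel.any():
            out[name] = strain.components[sel].mean(axis=0)
    return out


def run_study(
    config: RunConfig,
    reference: Volume3D,
    repeat_reference: Optional[Volume3D],
    loads: dict[str, Volume3D],
    mask: Optional[ComponentMask],
) -> StudyResult:
    """Execute the complete study on in-memory volumes (see module docstring)."""
    t0 = time.time()
    sweep = ErrorSweep()
    power_laws: dict[str, PowerLawFit] = {}
    threshold = acceptable_error(config.nominal_strain)
    selected: Optional[int] = None
    if repeat_reference is not None and config.sweep_sizes:
        sweep = run_zero_strain_study(
            reference,
            repeat_reference,
            mask,
            sizes=config.sweep_sizes,
            methods=config.sweep_methods,
            config=config.dvc,
            overlap_fraction=config.overlap_fraction,
            strain_window=config.strain_window,
        )
        method0 = config.sweep_methods[0]
        components = sorted({comp for (_, _, comp) in sweep.entries})
        for comp in components:
            series = sweep.series(method0, comp)
            if len(series) >= 3:
                power_laws[comp] = fit_power_law(
                    list(series), [m.maer for m in series.values()]
                )
        sel_comp = (
            config.selection_component
            if any(c == config.selection_component for (_, _, c) in sweep.entries)
            else components[0]
        )
        selected = select_subvolume(sweep, method0, sel_comp, threshold)

    size_used = config.subvolume_size_vox or selected
    if size_used is None:
        raise RuntimeError(
            "no subvolume size meets the acceptable-error threshold and none was configured"
        )

    grid = build_grid(
        reference.shape,
        size_used,
        config.overlap_fraction,
        reference.voxel_size_um,
        inset_vox=config.analysis_inset_vox,
    )
    mask_voi = mask
    seeds = split_seeds(config.seed, 16)
    load_results: dict[str, LoadResult] = {}
    for i, (name, vol) in enumerate(loads.items()):
        fld = correlate(reference, vol, grid, config.dvc)
        if config.rigid_correction_loads and fld.valid.sum() >= 3:
            fld = subtract_rigid(fld, fit_rigid_body(fld))
        if mask_voi is not None:
            strain = strain_by_component(
                fld, mask_voi, window=config.strain_window, pure_subvolumes=True
            )
        else:
            strain = compute_strain(fld, window=config.strain_window)
        summaries: list[ComponentSummary] = []
        report: Optional[MicromotionReport] = None
        if mask_voi is not None:
            samples = sample_scheme(
                fld,
                mask_voi,
                n_slices=config.n_slices,
                n_subvolumes=config.n_subvolumes,
                seed=seeds[8 + i],
                min_correlation=config.summary_min_correlation,
            )
            summaries = summarize_components(fld, strain, mask_voi, samples)
            names = {s.component for s in summaries}
            if {"implant", "bone"} <= names:
                report = relative_micromotion(summaries, "implant", "bone")
                report.seed = seeds[8 + i]
        load_results[name] = LoadResult(
            name=name,
            field=fld,
            strain=strain,
            summaries=summaries,
            micromotion=report,
            mean_strain_by_component=_mean_strain_by_component(
                fld, strain, mask_voi, config.summary_min_correlation
            ),
        )

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "voxel_size_um": reference.voxel_size_um,
        "threshold_strain": threshold,
        "selected_size_vox": selected,
        "size_used_vox": size_used,
        "sweep_sizes": list(config.sweep_sizes),
        "methods": list(config.sweep_methods),
        "dvc": vars(config.dvc),
        "elapsed_s": round(time.time() - t0, 2),
        "config_hash": hashlib.sha256(
            json.dumps(
                {k: v for k, v in vars(config).items() if k != "dvc"},
                default=str,
                sort_keys=True,
            ).encode()
        ).hexdigest()[:16],
    }
    return StudyResult(
        sweep=sweep,
        power_laws=power_laws,
        threshold=threshold,
        selected_size_vox=selected,
        size_used_vox=size_used,
        loads=load_results,
        manifest=manifest,
    )


def run_study_from_config(config: RunConfig) -> StudyResult:
    """Load volumes named in the config, run the study and write reports."""
    if config.reference_path is None:
        raise ValueError("reference_path is required")
    reference = read_volume(config.reference_path, config.voxel_size_um)
    repeat = (
        read_volume(config.repeat_reference_path, config.voxel_size_um)
        if config.repeat_reference_path
        else None
    )
    loads = {
        name: read_volume(p, config.voxel_size_um) for name, p in config.load_paths.items()
    }
    mask = None
    if config.mask_path:
        vol = read_volume(config.mask_path, config.voxel_size_um)
        from .phantom import LABEL_LEGEND

        mask = ComponentMask(vol.intensities.astype(np.int16), dict(LABEL_LEGEND))
    result = run_study(config, reference, repeat, loads, mask)
    write_reports(result, config.output_dir)
    return result


def write_reports(result: StudyResult, out_dir) -> None:
    """Write tidy CSVs, field exports and the JSON manifest."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if result.sweep.entries:
        result.sweep.to_dataframe(
            voxel_size_um=result.manifest.get("voxel_size_um")
        ).to_csv(out / "zero_strain_sweep.csv", index=False)
    if result.power_laws:
        pd.DataFrame(
            [
                {"component": c, "a": f.a, "b": f.b, "r_squared": f.r_squared}
                for c, f in result.power_laws.items()
            ]
        ).to_csv(out / "power_laws.csv", index=False)
    rows = []
    for name, lr in result.loads.items():
        write_field(lr.field, out / f"{name}_displacement.csv", "csv")
        for s in lr.summaries:
            rows.append(
                {
                    "load": name,
                    "component": s.component,
                    "mean_total_displacement_um": s.mean_total_displacement_um,
                    "sd_total_displacement_um": s.sd_total_displacement_um,
                    "mean_min_principal_strain": s.mean_min_principal_strain,
                    "sd_min_principal_strain": s.sd_min_principal_strain,
                    "n_samples": s.n_samples,
                }
            )
        if lr.micromotion is not None:
            (out / f"{name}_micromotion.json").write_text(
                json.dumps(
                    {
                        "moving": lr.micromotion.moving,
                        "reference": lr.micromotion.reference,
                        "relative_displacement_um": lr.micromotion.relative_displacement_um,
                        "per_slice_um": lr.micromotion.per_slice_um,
                        "seed": lr.micromotion.seed,
                    },
                    indent=2,
                )
            )
    if rows:
        pd.DataFrame(rows).to_csv(out / "component_summaries.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2, default=str))
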