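"""Zero-strain (constant-strain) error quantification.

Two consecutive scans of an unloaded specimen differ only by noise, so any
strain measured between them is error.  Accuracy is summarised by the mean
absolute error of strain

    MAER = (1/N) Σ_k ( (1/6) Σ_c |ε_c,k| )

and precision by its spread about the mean,

    SDER = sqrt( (1/N) Σ_k ( (1/6) Σ_c |ε_c,k| − MAER )² )

over the N valid measurement points k and the six strain components c
(population normalisation).  Random displacement error is the standard
deviation of each displacement component; systematic displacement error is
not defined in a zero-strain test because the true displacement is unknown
only up to the rigid correction.

The study sweeps subvolume size per DVC method, fits a power law
``error = a · size^b`` in log space, and selects the smallest subvolume
whose MAER and SDER both sit below the acceptable-error threshold
(10% of the nominal applied strain).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import dvc as _dvc
from .dvc import DisplacementField, DVCConfig, build_grid
from .fields import StrainField, compute_strain, fit_rigid_body, subtract_rigid
from .volume import ComponentMask, Volume3D

__all__ = [
    "ErrorMetrics",
    "ErrorSweep",
    "PowerLawFit",
    "compute_maer",
    "compute_sder",
    "strain_by_component",
    "metrics_by_component",
    "displacement_precision",
    "run_zero_strain_study",
    "fit_power_law",
    "acceptable_error",
    "select_subvolume",
]


@dataclass
class ErrorMetrics:
    """Strain accuracy/precision and displacement precision for one series."""

    maer: float  # strain fraction (dimensionless)
    sder: float
    displacement_sd_um: np.ndarray  # (3,) per component (x, y, z)
    n_points: int

    def __post_init__(self) -> None:
        if self.maer < 0 or self.sder < 0:
            raise ValueError("MAER and SDER are non-negative")
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")

    @property
    def maer_pct(self) -> float:
        return 100.0 * self.maer

    @property
    def maer_microstrain(self) -> float:
        return 1e6 * self.maer

    @property
    def sder_pct(self) -> float:
        return 100.0 * self.sder

    @property
    def sder_microstrain(self) -> float:
        return 1e6 * self.sder


@dataclass
class ErrorSweep:
    """Per (method, subvolume size, component) error metrics."""

    entries: dict[tuple[str, int, str], ErrorMetrics] = field(default_factory=dict)

    def add(self, method: str, size: int, component: str, metrics: ErrorMetrics) -> None:
        key = (method, int(size), component)
        if key in self.entries:
            raise KeyError(f"duplicate sweep entry {key}")
        self.entries[key] = metrics

    def series(self, method: str, component: str) -> dict[int, ErrorMetrics]:
        out = {
            size: m
            for (meth, size, comp), m in self.entries.items()
            if meth == method and comp == component
        }
        if not out:
            raise KeyError(f"no sweep series for method={method!r}, component={component!r}")
        return dict(sorted(out.items()))

    def to_dataframe(self, voxel_size_um: Optional[float] = None):
        import pandas as pd

        rows = []
        for (method, size, comp), m in sorted(self.entries.items()):
            rows.append(
                {
                    "method": method,
                    "size_vox": size,
                    "size_um": size * voxel_size_um if voxel_size_um else np.nan,
                    "component": comp,
                    "maer": m.maer,
                    "sder": m.sder,
                    "sd_ux_um": m.displacement_sd_um[0],
                    "sd_uy_um": m.displacement_sd_um[1],
                    "sd_uz_um": m.displacement_sd_um[2],
                    "n_points": m.n_points,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class PowerLawFit:
    """y = a · x^b, fitted as ln y = ln a + b ln x; R² in log space."""

    a: float
    b: float
    r_squared: float
    degenerate: bool = False


def _per_point_mean_abs(strain: StrainField) -> np.ndarray:
    mask = strain.valid & np.isfinite(strain.components).all(axis=1)
    if not mask.any():
        raise ValueError("no valid strain points")
    return np.abs(strain.components[mask]).mean(axis=1)


def compute_maer(strain: StrainField) -> float:
    """Mean over valid points of the mean absolute value of the six strain
    components (systematic error / accuracy)."""
    return float(_per_point_mean_abs(strain).mean())


def compute_sder(strain: StrainField) -> float:
    """Population standard deviation of per-point mean absolute strain about
    the MAER (random error / precision)."""
    pp = _per_point_mean_abs(strain)
    return float(np.sqrt(((pp - pp.mean()) ** 2).mean()))


def displacement_precision(fld: DisplacementField) -> np.ndarray:
    """Population SD of each displacement component (µm) over valid points."""
    mask = fld.valid & np.isfinite(fld.vectors_um).all(axis=1)
    if mask.sum() < 2:
        raise ValueError("displacement precision needs >= 2 valid points")
    return fld.vectors_um[mask].std(axis=0)


def acceptable_error(nominal_strain: float) -> float:
    """Maximum acceptable strain error: 10% of the nominal applied strain."""
    if not nominal_strain > 0:
        raise ValueError("nominal_strain must be positive")
    return 0.10 * nominal_strain


def fit_power_law(sizes: Sequence[float], errors: Sequence[float]) -> PowerLawFit:
    """Least-squares power-law fit in log space.

    Non-positive pairs are excluded with a warning; constant series are
    degenerate (b = 0, R² reported as 0 with the flag set).
    """
    x = np.asarray(sizes, dtype=np.float64)
    y = np.asarray(errors, dtype=np.float64)
    keep = (x > 0) & (y > 0) & np.isfinite(x) & np.isfinite(y)
    if keep.sum() < len(x):
        warnings.warn("excluding non-positive values from power-law fit", stacklevel=2)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("power-law fit needs >= 3 positive (x, y) pairs")
    lx, ly = np.log(x), np.log(y)
    if np.ptp(ly) == 0:
        return PowerLawFit(a=float(np.exp(ly[0])), b=0.0, r_squared=0.0, degenerate=True)
    A = np.column_stack([np.ones_like(lx), lx])
    coef, *_ = np.linalg.lstsq(A, ly, rcond=None)
    pred = A @ coef
    ss_res = float(((ly - pred) ** 2).sum())
    ss_tot = float(((ly - ly.mean()) ** 2).sum())
    return PowerLawFit(a=float(np.exp(coef[0])), b=float(coef[1]), r_squared=1.0 - ss_res / ss_tot)


def select_subvolume(
    sweep: ErrorSweep, method: str, component: str, threshold: float
) -> Optional[int]:
    """Smallest subvolume size whose MAER and SDER are both <= threshold.

    Returns None (with a diagnostic warning naming the closest size) when no
    size qualifies.
    """
    series = sweep.series(method, component)
    for size, m in series.items():
        if m.maer <= threshold and m.sder <= threshold:
            return size
    closest = min(series, key=lambda s: max(series[s].maer, series[s].sder))
    warnings.warn(
        f"no subvolume size meets threshold {threshold:g}; closest is {closest} "
        f"(MAER {series[closest].maer:.3g}, SDER {series[closest].sder:.3g})",
        stacklevel=2,
    )
    return None


# ---------------------------------------------------------------------------
# the full constant-strain study


def pure_subvolume_mask(grid, mask: ComponentMask, min_fraction: float = 0.9) -> np.ndarray:
    """True where at least ``min_fraction`` of a grid point's subvolume lies
    in its centre component: such subvolumes track that component's motion,
    while genuine straddlers measure a mixture of both sides."""
    size = grid.subvolume_size_vox
    centres = grid.centres
    pure = np.empty(grid.n_points, dtype=bool)
    for i, (start, centre) in enumerate(zip(grid.starts, centres)):
        block = mask.labels[
            start[0] : start[0] + size,
            start[1] : start[1] + size,
            start[2] : start[2] + size,
        ]
        own = mask.labels[centre[0], centre[1], centre[2]]
        pure[i] = (block == own).mean() >= min_fraction
    return pure


def strain_by_component(
    fld: DisplacementField,
    mask: ComponentMask,
    window: int = 3,
    min_correlation: float = 0.0,
    pure_subvolumes: bool = False,
) -> StrainField:
    """Strain field in which every point's gradient window was restricted to
    grid points of its own component (centre-voxel label).

    The single-volume analogue of differentiating separately extracted
    component stacks: a window mixing a well-textured tissue with
    texture-poor void points would otherwise charge the void's displacement
    noise — or a genuine inter-component discontinuity — to the tissue's
    strain.

    With ``pure_subvolumes`` the windows are further restricted to grid
    points whose whole subvolume lies inside the component (subvolumes that
    straddle a boundary measure a mixture of both sides' motion); components
    with too few pure points fall back to the centre-label rule.
    """
    centres = fld.grid.centres
    labels = mask.labels[centres[:, 0], centres[:, 1], centres[:, 2]]
    usable = fld.valid & (fld.correlation >= min_correlation)
    pure = pure_subvolume_mask(fld.grid, mask) if pure_subvolumes else None
    comps = np.full((fld.grid.n_points, 6), np.nan)
    valid = np.zeros(fld.grid.n_points, dtype=bool)
    for lab in np.unique(labels):
        sel = usable & (labels == lab)
        if pure is not None and (sel & pure).sum() >= 8:
            sel = sel & pure
        if sel.sum() < 4:
            continue
        sub = DisplacementField(fld.grid, fld.vectors_um, fld.correlation, sel)
        s = compute_strain(sub, window=window)
        take = sel & s.valid
        comps[take] = s.components[take]
        valid[take] = True
    return StrainField(fld.grid, comps, valid)


def metrics_by_component(
    fld: DisplacementField,
    mask: Optional[ComponentMask],
    strain_window: int = 3,
    min_correlation: float = 0.0,
) -> dict[str, ErrorMetrics]:
    """Per-component MAER/SDER/displacement SD, assigning each grid point to
    the component label at its centre voxel.

    Strain is computed separately per component, restricting the gradient
    windows to same-component grid points — the single-volume analogue of
    correlating individually extracted component stacks, and necessary
    because a window mixing bone with texture-poor void points would charge
    the void's displacement noise to the bone's strain error.  Without a
    mask a single ``"all"`` entry is returned.  Components with too few
    usable points are omitted with a warning.
    """
    centres = fld.grid.centres  # (n, 3) z, y, x
    usable = fld.valid & (fld.correlation >= min_correlation)
    if mask is None:
        groups = {"all": np.ones(len(centres), dtype=bool)}
    else:
        labels = mask.labels[centres[:, 0], centres[:, 1], centres[:, 2]]
        groups = {
            name: labels == lab
            for lab, name in mask.legend.items()
            if name != "background" and (labels == lab).any()
        }
    out: dict[str, ErrorMetrics] = {}
    for name, sel in groups.items():
        pick = sel & usable
        if pick.sum() < 4:
            warnings.warn(f"component {name!r} has too few grid points; omitted", stacklevel=2)
            continue
        sub_fld = DisplacementField(fld.grid, fld.vectors_um, fld.correlation, pick)
        strain = compute_strain(sub_fld, window=strain_window)
        strain_pick = pick & strain.valid
        if strain_pick.sum() < 1:
            warnings.warn(f"component {name!r} has no strain points; omitted", stacklevel=2)
            continue
        sub_strain = StrainField(strain.grid, strain.components, strain_pick)
        out[name] = ErrorMetrics(
            maer=compute_maer(sub_strain),
            sder=compute_sder(sub_strain),
            displacement_sd_um=displacement_precision(sub_fld),
            n_points=int(strain_pick.sum()),
        )
    return out


def run_zero_strain_study(
    ref_a: Volume3D,
    ref_b: Volume3D,
    mask: Optional[ComponentMask],
    sizes: Sequence[int],
    methods: Sequence[str],
    config: DVCConfig,
    overlap_fraction: float = 0.5,
    strain_window: int = 3,
    rigid_correction: bool = True,
) -> ErrorSweep:
    """Full DVC → rigid correction → strain → per-component metrics, for each
    method × subvolume size, on a repeat (zero-strain) pair."""
    if ref_a.shape != ref_b.shape:
        raise ValueError("repeat pair must be co-registered (same shape)")
    sweep = ErrorSweep()
    for method in methods:
        cfg = replace(config, method=method)
        for size in sizes:
            grid = build_grid(ref_a.shape, size, overlap_fraction, ref_a.voxel_size_um)
            fld = _dvc.correlate(ref_a, ref_b, grid, cfg)
            if rigid_correction and fld.valid.sum() >= 3:
                fld = subtract_rigid(fld, fit_rigid_body(fld))
            for comp, m in metrics_by_component(
                fld, mask, strain_window=strain_window, min_correlation=cfg.min_correlation
            ).items():
                sweep.add(method, size, comp, m)
    return sweep
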