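"""Per-component displacement/strain summaries and implant micromotion.

The sampling scheme mirrors collecting measurements at a few well-correlated
subvolumes on a handful of transverse slices through the analysed volume:
``n_slices`` evenly spaced grid levels, ``n_subvolumes`` seeded-random valid
points per component per level.  Micromotion is reported as the per-slice
absolute difference of mean total displacement between the moving component
(implant) and the reference component (bone) — normalising against bone by
subtraction, so any global rigid translation cancels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dvc import DisplacementField
from .errors import pure_subvolume_mask
from .fields import StrainField, principal_strains, total_displacement
from .volume import ComponentMask

__all__ = [
    "ComponentSummary",
    "MicromotionReport",
    "sample_scheme",
    "summarize_components",
    "relative_micromotion",
]


@dataclass
class ComponentSummary:
    component: str
    mean_total_displacement_um: float
    sd_total_displacement_um: float
    mean_min_principal_strain: float
    sd_min_principal_strain: float
    n_samples: int
    per_slice_mean_displacement_um: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sd_total_displacement_um < 0 or self.sd_min_principal_strain < 0:
            raise ValueError("SDs must be >= 0")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass
class MicromotionReport:
    moving: str
    reference: str
    relative_displacement_um: float
    per_slice_um: list[float]
    seed: int | None = None


def sample_scheme(
    fld: DisplacementField,
    mask: ComponentMask,
    n_slices: int = 5,
    n_subvolumes: int = 3,
    seed: int = 0,
    min_correlation: float = 0.8,
) -> dict[str, dict[int, np.ndarray]]:
    """Choose sample grid-point indices per component per slice.

    Slices are ``n_slices`` transverse (z) grid levels evenly spaced through
    the lattice; per slice and component, ``n_subvolumes`` points with
    correlation >= ``min_correlation`` are drawn by seeded uniform sampling
    (all qualifying points if fewer are available).  Mirroring a manual
    within-component selection, subvolumes lying entirely inside the
    component are preferred; points merely centred in it are used only when
    no pure subvolume exists at that slice.  Components absent at a slice
    are skipped for that slice with a warning.
    """
    grid = fld.grid
    nz = grid.grid_shape[0]
    levels = np.unique(np.round(np.linspace(0, nz - 1, n_slices)).astype(int))
    centres = grid.centres
    labels = mask.labels[centres[:, 0], centres[:, 1], centres[:, 2]]
    pure = pure_subvolume_mask(grid, mask)
    zidx = np.repeat(np.arange(nz), grid.grid_shape[1] * grid.grid_shape[2])
    usable = fld.valid & (fld.correlation >= min_correlation)

    rng = np.random.default_rng(seed)
    out: dict[str, dict[int, np.ndarray]] = {}
    for lab, name in mask.legend.items():
        if name == "background":
            continue
        comp_sel = labels == lab
        if not comp_sel.any():
            continue
        slices: dict[int, np.ndarray] = {}
        for lev in levels:
            idx = np.flatnonzero(comp_sel & usable & pure & (zidx == lev))
            if idx.size == 0:
                idx = np.flatnonzero(comp_sel & usable & (zidx == lev))
            if idx.size == 0:
                warnings.warn(f"component {name!r} absent at slice {lev}; skipped", stacklevel=2)
                continue
            take = min(n_subvolumes, idx.size)
            slices[int(lev)] = np.sort(rng.choice(idx, size=take, replace=False))
        if slices:
            out[name] = slices
    return out


def summarize_components(
    displacement: DisplacementField,
    strain: StrainField,
    mask: ComponentMask,
    samples: dict[str, dict[int, np.ndarray]],
) -> list[ComponentSummary]:
    """Mean/SD of total displacement and of minimum principal strain per
    component over the sampled points."""
    if displacement.grid.n_points != strain.grid.n_points:
        raise ValueError("displacement and strain must share a grid")
    tot = total_displacement(displacement)
    summaries = []
    for name, slices in samples.items():
        idx = np.concatenate(list(slices.values()))
        if idx.size == 0:
            continue
        disp = tot[idx]
        strain_idx = idx[strain.valid[idx]]
        if strain_idx.size:
            minp = principal_strains(strain.components[strain_idx])[:, 0]
            minp_mean, minp_sd = float(minp.mean()), float(minp.std())
        else:
            minp_mean = minp_sd = float("nan")
        summaries.append(
            ComponentSummary(
                component=name,
                mean_total_displacement_um=float(disp.mean()),
                sd_total_displacement_um=float(disp.std()),
                mean_min_principal_strain=minp_mean,
                sd_min_principal_strain=minp_sd,
                n_samples=int(idx.size),
                per_slice_mean_displacement_um={
                    lev: float(tot[pts].mean()) for lev, pts in slices.items()
                },
            )
        )
    return summaries


def relative_micromotion(
    summaries: list[ComponentSummary],
    moving: str = "implant",
    reference: str = "bone",
) -> MicromotionReport:
    """Per-slice |mean total displacement(moving) − mean(reference)|,
    averaged over slices where both components were sampled."""
    by_name = {s.component: s for s in summaries}
    for need in (moving, reference):
        if need not in by_name:
            raise KeyError(f"component {need!r} not summarised")
    mv = by_name[moving].per_slice_mean_displacement_um
    rf = by_name[reference].per_slice_mean_displacement_um
    common = sorted(set(mv) & set(rf))
    if not common:
        raise ValueError("moving and reference components share no slices")
    per_slice = [abs(mv[lev] - rf[lev]) for lev in common]
    return MicromotionReport(
        moving=moving,
        reference=reference,
        relative_displacement_um=float(np.mean(per_slice)),
        per_slice_um=per_slice,
    )
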