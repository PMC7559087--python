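"""Synthetic micro-CT phantoms of an osteochondral tissue-biomaterial system.

The generator builds a layered specimen the way an explanted osteochondral
plug with a printed scaffold presents in a reconstructed scan:

* a subchondral **bone** band carrying a trabecular-like speckle network
  (thresholded band-pass noise — the unique texture DVC tracks in bone),
* an articular **cartilage** band with low-amplitude stained-tissue speckle,
* a cylindrical defect containing a 0/90° log-pile **implant** lattice
  (struts of 200 µm diameter at 200 µm spacing by default),
* a **new_tissue** cap of intermediate speckle above the implant,
* the remaining defect space as a near-flat, poorly textured **void**.

A paired "deformed" state is produced by pull-back warping under a known
analytic displacement field, so every downstream stage has exact ground
truth.  Noise is additive Gaussian only (no ring or beam-hardening
artefacts); see docs/methods.md for what that does and does not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy import ndimage

from .volume import ComponentMask, Volume3D, COMPONENT_NAMES

__all__ = [
    "PhantomSpec",
    "DeformationModel",
    "GroundTruth",
    "generate_phantom",
    "warp_volume",
    "add_noise",
    "LABEL_LEGEND",
]

#: Fixed label assignment used by generated masks.
LABEL_LEGEND: Mapping[int, str] = {
    0: "background",
    1: "bone",
    2: "cartilage",
    3: "implant",
    4: "new_tissue",
    5: "void",
}

#: Default mean intensity and texture amplitude per component (8-bit-like scale).
DEFAULT_CONTRAST: Mapping[str, tuple[float, float]] = {
    "background": (20.0, 0.0),
    "bone": (150.0, 70.0),
    "cartilage": (90.0, 14.0),
    "implant": (140.0, 10.0),  # lattice geometry plus in-strut material speckle
    "new_tissue": (110.0, 22.0),
    "void": (40.0, 2.0),
}


@dataclass
class PhantomSpec:
    """Geometry, texture and noise parameters of a synthetic specimen.

    Defaults mirror the printed-scaffold system: 200 µm struts at 200 µm
    spacing, bone speckle grain ~3 voxels, a poorly textured void.
    """

    shape: tuple[int, int, int] = (128, 128, 128)
    voxel_size_um: float = 10.0
    strut_diameter_um: float = 200.0
    strut_spacing_um: float = 200.0
    speckle_grain_um: Mapping[str, float] = field(
        default_factory=lambda: {"bone": 90.0, "cartilage": 60.0, "new_tissue": 40.0, "void": 40.0}
    )
    component_contrast: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CONTRAST)
    )
    noise_sigma: float = 0.0
    psf_sigma_um: float = 10.0  # scanner point-spread blur (~1 voxel); 0 disables
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(v) for v in self.shape)
        if any(s < 1 for s in self.shape):
            raise ValueError("shape must be positive")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")
        if self.strut_diameter_um <= 0 or self.strut_spacing_um <= 0:
            raise ValueError("strut parameters must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def strut_period_vox(self) -> int:
        return int(round((self.strut_diameter_um + self.strut_spacing_um) / self.voxel_size_um))

    @property
    def background_intensity(self) -> float:
        return float(self.component_contrast["background"][0])


def _speckle(shape, grain_vox: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean unit-RMS smooth speckle at the stated grain size."""
    noise = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(noise, sigma=max(grain_vox / 2.0, 0.5))
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def _trabecular(shape, grain_vox: float, rng: np.random.Generator) -> np.ndarray:
    """Binarised band-pass noise: a two-phase trabecular-like network in [-1, 1]."""
    sm = _speckle(shape, grain_vox, rng)
    binary = np.where(sm > 0, 1.0, -1.0)
    # slight smoothing so the phase boundaries are resolvable for interpolation
    return ndimage.gaussian_filter(binary, sigma=0.7)


def generate_phantom(spec: PhantomSpec) -> tuple[Volume3D, ComponentMask]:
    """Build the reference (unloaded) phantom and its component mask.

    The returned volume is noiseless; apply :func:`add_noise` for repeat-scan
    realisations.  Identical ``spec.seed`` gives bit-identical output.
    """
    nz, ny, nx = spec.shape
    period = spec.strut_period_vox
    if min(spec.shape) * spec.voxel_size_um < spec.strut_diameter_um + spec.strut_spacing_um:
        raise ValueError(
            f"volume {spec.shape} at {spec.voxel_size_um} µm/voxel cannot contain one "
            f"strut period ({spec.strut_diameter_um + spec.strut_spacing_um} µm)"
        )
    rng = np.random.default_rng(spec.seed)

    zz, yy, xx = np.meshgrid(
        np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij", sparse=True
    )
    labels = np.full(spec.shape, 1, dtype=np.int16)  # bone everywhere to start

    z_cart = int(round(0.65 * nz))  # cartilage band on top
    labels[z_cart:] = 2

    # cylindrical defect through the bone, under the chondral surface
    # (a 5 mm punch in a ~10 mm sample)
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    r_def = 0.25 * min(ny, nx)
    in_defect = ((yy - cy) ** 2 + (xx - cx) ** 2 <= r_def**2) & (zz >= int(round(0.25 * nz))) & (
        zz < z_cart
    )
    labels[in_defect] = 5  # void by default: the gap under and around the implant

    # implant lattice: cut to near the defect width, sitting on the
    # underlying void left by over-reaming of the subchondral bone
    r_imp = 0.90 * r_def
    in_imp_region = ((yy - cy) ** 2 + (xx - cx) ** 2 <= r_imp**2) & (
        zz >= int(round(0.31 * nz))
    ) & (zz < int(round(0.61 * nz)))
    labels[in_imp_region] = 3

    # new tissue cap on top of the implant
    in_cap = ((yy - cy) ** 2 + (xx - cx) ** 2 <= r_imp**2) & (
        zz >= int(round(0.61 * nz))
    ) & (zz < z_cart)
    labels[in_cap] = 4

    # --- intensities -------------------------------------------------------
    strut_vox = max(int(round(spec.strut_diameter_um / spec.voxel_size_um)), 1)
    vol = np.empty(spec.shape, dtype=np.float64)
    vol[:] = spec.component_contrast["background"][0]

    grain = {
        name: spec.speckle_grain_um.get(name, 20.0) / spec.voxel_size_um
        for name in COMPONENT_NAMES
    }
    for lab, name in LABEL_LEGEND.items():
        region = labels == lab
        if not region.any():
            continue
        mean, amp = spec.component_contrast[name]
        if name == "bone":
            tex = _trabecular(spec.shape, grain["bone"], rng)
        elif name == "implant":
            # 0/90° log-pile: layers of struts along x and y, alternating with z
            layer = (zz // strut_vox) % 2
            strut_x = (yy % period) < strut_vox  # struts running along x
            strut_y = (xx % period) < strut_vox  # struts running along y
            is_strut = np.where(layer == 0, strut_x, strut_y)
            pore_mean = spec.component_contrast["void"][0]
            vals = np.where(is_strut, mean, pore_mean) + amp * _speckle(
                spec.shape, 1.0, rng
            )
            vol[region] = vals[region]
            continue
        else:
            tex = _speckle(spec.shape, grain[name], rng)
        vol[region] = mean + amp * tex[region]

    if spec.psf_sigma_um > 0:
        # finite scanner resolution: without it the flat component interfaces
        # are single-voxel sharp, which real reconstructions never are and
        # which destabilises subpixel peak fitting at straddling subvolumes
        vol = ndimage.gaussian_filter(vol, sigma=spec.psf_sigma_um / spec.voxel_size_um)

    if spec.noise_sigma > 0:
        vol = vol + rng.normal(0.0, spec.noise_sigma, size=spec.shape)

    return (
        Volume3D(vol, spec.voxel_size_um),
        ComponentMask(labels, dict(LABEL_LEGEND)),
    )


# ---------------------------------------------------------------------------
# Deformation models


@dataclass
class GroundTruth:
    """Exact displacement and strain of a synthetic deformation.

    ``displacement(pos_um)`` maps (n, 3) physical positions (x, y, z µm) to
    (n, 3) displacement vectors (µm); ``strain(pos_um)`` returns the six
    components (ε_xx, ε_yy, ε_zz, ε_xy, ε_xz, ε_yz) at each position.
    """

    displacement: Callable[[np.ndarray], np.ndarray]
    strain: Callable[[np.ndarray], np.ndarray]


@dataclass
class DeformationModel:
    """An analytic deformation: translation, rigid rotation, uniaxial
    compression, compression plus component-wise rigid micromotion, or a
    custom displacement function.

    ``params`` by kind:

    - ``translation``: ``t_um`` (3-vector, x/y/z µm)
    - ``rigid_rotation``: ``axis`` (3-vector), ``angle_deg``, ``centre_um``
    - ``uniaxial_compression``: ``nominal_strain`` (fraction, >0 compressive),
      ``poisson_ratio``, ``fixed_z_um`` (height of the fixed face; the face at
      ``fixed_z_um`` does not move and material above it moves down)
    - ``rigid_plus_compression``: compression params plus ``offset_um``
      (3-vector applied to implant+new-tissue), ``mask``/``blend_sigma_um``
      are supplied via :func:`micromotion_model`
    - ``custom_analytic``: ``displacement`` and ``strain`` callables
    """

    kind: str
    params: dict

    def __post_init__(self) -> None:
        kinds = (
            "translation",
            "rigid_rotation",
            "uniaxial_compression",
            "rigid_plus_compression",
            "custom_analytic",
        )
        if self.kind not in kinds:
            raise ValueError(f"unknown deformation kind {self.kind!r}")
        if self.kind in ("uniaxial_compression", "rigid_plus_compression"):
            if abs(self.params["nominal_strain"]) >= 0.2:
                raise ValueError("|nominal strain| must be < 0.2")
        if self.kind == "rigid_rotation" and abs(self.params["angle_deg"]) >= 10:
            raise ValueError("rotation angle magnitude must be < 10 degrees")

    def ground_truth(self) -> GroundTruth:
        p = self.params
        if self.kind == "translation":
            t = np.asarray(p["t_um"], dtype=float)

            def u(pos):
                return np.broadcast_to(t, (len(pos), 3)).copy()

            def eps(pos):
                return np.zeros((len(pos), 6))

            return GroundTruth(u, eps)

        if self.kind == "rigid_rotation":
            axis = np.asarray(p["axis"], dtype=float)
            axis = axis / np.linalg.norm(axis)
            ang = np.deg2rad(p["angle_deg"])
            c = np.asarray(p.get("centre_um", (0, 0, 0)), dtype=float)
            K = np.array(
                [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
            )
            R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)

            def u(pos):
                return (np.asarray(pos, float) - c) @ (R.T - np.eye(3))

            def eps(pos):
                # infinitesimal strain of a finite rotation is second order small
                E = 0.5 * (R + R.T) - np.eye(3)
                row = np.array([E[0, 0], E[1, 1], E[2, 2], E[0, 1], E[0, 2], E[1, 2]])
                return np.broadcast_to(row, (len(pos), 6)).copy()

            return GroundTruth(u, eps)

        if self.kind in ("uniaxial_compression", "rigid_plus_compression"):
            e = float(p["nominal_strain"])
            nu = float(p.get("poisson_ratio", 0.0))
            z0 = float(p.get("fixed_z_um", 0.0))
            cx = float(p.get("centre_x_um", 0.0))
            cy = float(p.get("centre_y_um", 0.0))
            base = GroundTruth(
                lambda pos: np.column_stack(
                    [
                        nu * e * (np.asarray(pos, float)[:, 0] - cx),
                        nu * e * (np.asarray(pos, float)[:, 1] - cy),
                        -e * (np.asarray(pos, float)[:, 2] - z0),
                    ]
                ),
                lambda pos: np.broadcast_to(
                    np.array([nu * e, nu * e, -e, 0.0, 0.0, 0.0]), (len(pos), 6)
                ).copy(),
            )
            if self.kind == "uniaxial_compression":
                return base
            # the implant (and its new-tissue cap) rides over an underlying
            # void and moves as a rigid body: inside the blend weight w = 1
            # its displacement is frozen at the anchor's far-field value plus
            # the rigid offset, so its internal strain vanishes
            blend = p["blend"]  # callable pos_um -> weight in [0, 1]
            grad = p["blend_gradient"]  # callable pos_um -> (n, 3) d(weight)/d(x,y,z)
            t = np.asarray(p["offset_um"], dtype=float)
            anchor = np.asarray(p["anchor_um"], dtype=float)

            def u(pos):
                w = blend(pos)[:, None]
                rigid = base.displacement(anchor[None, :])[0] + t
                d = rigid - base.displacement(pos)
                return base.displacement(pos) + w * d

            def eps(pos):
                w = blend(pos)
                g = grad(pos)  # (n, 3)
                rigid = base.displacement(anchor[None, :])[0] + t
                d = rigid - base.displacement(pos)  # (n, 3)
                outer = np.column_stack(
                    [
                        g[:, 0] * d[:, 0],
                        g[:, 1] * d[:, 1],
                        g[:, 2] * d[:, 2],
                        0.5 * (g[:, 0] * d[:, 1] + g[:, 1] * d[:, 0]),
                        0.5 * (g[:, 0] * d[:, 2] + g[:, 2] * d[:, 0]),
                        0.5 * (g[:, 1] * d[:, 2] + g[:, 2] * d[:, 1]),
                    ]
                )
                return (1.0 - w)[:, None] * base.strain(pos) + outer

            return GroundTruth(u, eps)

        return GroundTruth(p["displacement"], p["strain"])


def micromotion_model(
    nominal_strain: float,
    poisson_ratio: float,
    offset_um,
    mask: ComponentMask,
    voxel_size_um: float,
    moving: tuple[str, ...] = ("implant", "new_tissue"),
    blend_sigma_um: float = 15.0,
    fixed_z_um: float = 0.0,
) -> DeformationModel:
    """Far-field uniaxial compression plus rigid micromotion of the implant.

    Inside the blend weight the implant+cap displacement is frozen at its
    anchor (centroid) far-field value plus the rigid ``offset_um``, so the
    moving body carries (next to) no internal strain; the indicator is
    blurred with a Gaussian of ``blend_sigma_um`` so the field stays
    continuous across the surrounding void — the "largely rigid body
    micromotion over an underlying void" scenario.
    """
    moving_labels = [mask.label_of(m) for m in moving]
    ind = np.isin(mask.labels, moving_labels).astype(np.float64)
    zc, yc, xc = ndimage.center_of_mass(ind)
    anchor_um = ((xc + 0.5) * voxel_size_um, (yc + 0.5) * voxel_size_um, (zc + 0.5) * voxel_size_um)
    sigma_vox = blend_sigma_um / voxel_size_um
    w = ndimage.gaussian_filter(ind, sigma=sigma_vox)
    gz, gy, gx = np.gradient(w, voxel_size_um)

    def _sample(grid_arr, pos):
        pos = np.asarray(pos, dtype=float)
        # physical (x, y, z) µm -> fractional voxel (z, y, x)
        coords = np.vstack(
            [
                pos[:, 2] / voxel_size_um - 0.5,
                pos[:, 1] / voxel_size_um - 0.5,
                pos[:, 0] / voxel_size_um - 0.5,
            ]
        )
        return ndimage.map_coordinates(grid_arr, coords, order=1, mode="nearest")

    return DeformationModel(
        "rigid_plus_compression",
        {
            "nominal_strain": nominal_strain,
            "poisson_ratio": poisson_ratio,
            "fixed_z_um": fixed_z_um,
            "offset_um": tuple(offset_um),
            "anchor_um": anchor_um,
            "blend": lambda pos: _sample(w, pos),
            "blend_gradient": lambda pos: np.column_stack(
                [_sample(gx, pos), _sample(gy, pos), _sample(gz, pos)]
            ),
        },
    )


def warp_volume(
    vol: Volume3D,
    model: DeformationModel,
    interpolation_order: int = 3,
    fill_value: float | None = None,
) -> tuple[Volume3D, GroundTruth]:
    """Create the deformed state: ``out(x) = ref(x - u(x))`` (pull-back).

    ``u`` is the analytic displacement of ``model`` evaluated at the voxel
    centre positions of the output grid, so the returned :class:`GroundTruth`
    is exact at every voxel.  Out-of-domain samples take ``fill_value``
    (default: the volume minimum).
    """
    if interpolation_order not in (1, 3):
        raise ValueError("interpolation order must be 1 or 3")
    gt = model.ground_truth()
    nz, ny, nx = vol.shape
    vs = vol.voxel_size_um

    zz, yy, xx = np.meshgrid(
        np.arange(nz, dtype=np.float64),
        np.arange(ny, dtype=np.float64),
        np.arange(nx, dtype=np.float64),
        indexing="ij",
    )
    pos = np.column_stack(
        [(xx.ravel() + 0.5) * vs, (yy.ravel() + 0.5) * vs, (zz.ravel() + 0.5) * vs]
    )
    u = gt.displacement(pos)  # (n, 3) µm, (ux, uy, uz)
    extent = max(nz, ny, nx) * vs
    max_u = np.abs(u).max() if u.size else 0.0
    if max_u > 0.25 * extent:
        raise ValueError(
            f"displacement magnitude {max_u:.1f} µm exceeds 25% of volume extent {extent:.1f} µm"
        )

    coords = np.vstack(
        [
            zz.ravel() - u[:, 2] / vs,
            yy.ravel() - u[:, 1] / vs,
            xx.ravel() - u[:, 0] / vs,
        ]
    )
    fill = float(vol.intensities.min()) if fill_value is None else float(fill_value)
    warped = ndimage.map_coordinates(
        vol.intensities.astype(np.float64),
        coords,
        order=interpolation_order,
        mode="constant",
        cval=fill,
    ).reshape(vol.shape)
    return Volume3D(warped, vs, vol.origin_voxel), gt


def add_noise(vol: Volume3D, sigma: float, seed: int) -> Volume3D:
    """Add independent Gaussian noise (intensity units); seed-reproducible.

    Floating-point volumes are not clipped; integer volumes are clipped to
    the dtype range and the result promoted to float64.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return Volume3D(vol.intensities.copy(), vol.voxel_size_um, vol.origin_voxel)
    rng = np.random.default_rng(seed)
    data = vol.intensities.astype(np.float64)
    noisy = data + rng.normal(0.0, sigma, size=vol.shape)
    if np.issubdtype(vol.intensities.dtype, np.integer):
        info = np.iinfo(vol.intensities.dtype)
        noisy = np.clip(noisy, info.min, info.max)
    return Volume3D(noisy, vol.voxel_size_um, vol.origin_voxel)
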