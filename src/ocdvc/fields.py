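"""Displacement-field post-processing.

Rigid-body movement between scans (specimen settling, stage drift) is fitted
by orthogonal Procrustes and subtracted at the reference positions, restoring
the field to the original orientation before strains are derived.  Strains
are the infinitesimal (small-strain) tensor obtained from a local
least-squares fit of the displacement gradient over a window of grid points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dvc import DisplacementField, SubvolumeGrid

__all__ = [
    "RigidTransform",
    "StrainField",
    "fit_rigid_body",
    "subtract_rigid",
    "compute_strain",
    "principal_strains",
    "total_displacement",
]


@dataclass
class RigidTransform:
    """x -> R (x - c) + c + t with R proper orthonormal (µm coordinates)."""

    rotation: np.ndarray  # (3, 3)
    translation_um: np.ndarray  # (3,)
    centre_um: np.ndarray  # (3,)
    residual_rms_um: float = 0.0

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=np.float64)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det = +1)")
        self.rotation = R
        self.translation_um = np.asarray(self.translation_um, dtype=np.float64)
        self.centre_um = np.asarray(self.centre_um, dtype=np.float64)

    def apply(self, pos_um: np.ndarray) -> np.ndarray:
        p = np.asarray(pos_um, dtype=np.float64)
        return (p - self.centre_um) @ self.rotation.T + self.centre_um + self.translation_um

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), np.zeros(3))


@dataclass
class StrainField:
    """Six small-strain components (ε_xx, ε_yy, ε_zz, ε_xy, ε_xz, ε_yz) per
    grid point, dimensionless."""

    grid: SubvolumeGrid
    components: np.ndarray  # (n, 6)
    valid: np.ndarray  # (n,) bool

    def __post_init__(self) -> None:
        if self.components.shape != (self.grid.n_points, 6):
            raise ValueError("components inconsistent with grid")
        if not np.all(np.isfinite(self.components[self.valid])):
            raise ValueError("components must be finite where valid")


def fit_rigid_body(field: DisplacementField) -> RigidTransform:
    """Least-squares rigid transform (Kabsch/orthogonal Procrustes with
    translation) mapping reference grid positions to displaced positions,
    using valid points only."""
    mask = field.valid & np.isfinite(field.vectors_um).all(axis=1)
    if mask.sum() < 3:
        raise ValueError(f"rigid fit needs >= 3 valid points, got {int(mask.sum())}")
    P = field.grid.positions_um()[mask]  # reference
    Q = P + field.vectors_um[mask]  # displaced
    c = P.mean(axis=0)
    Pc = P - c
    Qc = Q - Q.mean(axis=0)
    if np.linalg.matrix_rank(Pc, tol=1e-6 * max(np.abs(Pc).max(), 1.0)) < 2:
        raise ValueError("rigid fit needs non-collinear points")
    H = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = Q.mean(axis=0) - c
    tf = RigidTransform(R, t, c)
    resid = Q - tf.apply(P)
    tf.residual_rms_um = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return tf


def subtract_rigid(field: DisplacementField, transform: RigidTransform) -> DisplacementField:
    """Subtract the vector of the rigid transform at each reference position:
    residual = (x + u) - T(x).  A pure rigid field maps to zero."""
    P = field.grid.positions_um()
    residual = P + field.vectors_um - transform.apply(P)
    return DisplacementField(
        field.grid, residual, field.correlation.copy(), field.valid.copy()
    )


def compute_strain(field: DisplacementField, window: int = 3) -> StrainField:
    """Displacement-gradient tensor by moving least squares over a
    ``window``³ neighbourhood of grid points; ε = (H + Hᵀ)/2.

    Points whose neighbourhood has fewer than 4 valid, non-degenerate points
    (design matrix rank < 4) are flagged invalid.  Exact for affine fields
    regardless of window size.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    grid = field.grid
    nz, ny, nx = grid.grid_shape
    if grid.n_points < 2:
        raise ValueError("strain undefined on a single-point grid")
    pos = grid.positions_um().reshape((nz, ny, nx, 3))
    vec = field.vectors_um.reshape((nz, ny, nx, 3))
    ok = (field.valid & np.isfinite(field.vectors_um).all(axis=1)).reshape((nz, ny, nx))

    half = window // 2
    comps = np.full((nz, ny, nx, 6), np.nan)
    valid = np.zeros((nz, ny, nx), dtype=bool)
    for k in range(nz):
        zs = slice(max(k - half, 0), min(k + half + 1, nz))
        for j in range(ny):
            ys = slice(max(j - half, 0), min(j + half + 1, ny))
            for i in range(nx):
                xs = slice(max(i - half, 0), min(i + half + 1, nx))
                m = ok[zs, ys, xs].ravel()
                if m.sum() < 4:
                    continue
                p = pos[zs, ys, xs].reshape(-1, 3)[m]
                u = vec[zs, ys, xs].reshape(-1, 3)[m]
                p0 = pos[k, j, i]
                A = np.column_stack([np.ones(len(p)), p - p0])
                if np.linalg.matrix_rank(A) < 4:
                    continue
                coef, *_ = np.linalg.lstsq(A, u, rcond=None)
                H = coef[1:].T  # H[a, b] = d u_a / d x_b
                E = 0.5 * (H + H.T)
                comps[k, j, i] = (
                    E[0, 0], E[1, 1], E[2, 2], E[0, 1], E[0, 2], E[1, 2]
                )
                valid[k, j, i] = True
    return StrainField(grid, comps.reshape(-1, 6), valid.ravel())


def principal_strains(components) -> np.ndarray:
    """Eigenvalues of the symmetric strain tensor, ascending; the first entry
    is the minimum (most compressive) principal strain.

    Accepts one six-vector or an (n, 6) array.
    """
    comp = np.atleast_2d(np.asarray(components, dtype=np.float64))
    if comp.shape[-1] != 6:
        raise ValueError("expected six strain components")
    if not np.all(np.isfinite(comp)):
        raise ValueError("strain components must be finite")
    exx, eyy, ezz, exy, exz, eyz = comp.T
    T = np.empty((len(comp), 3, 3))
    T[:, 0, 0] = exx
    T[:, 1, 1] = eyy
    T[:, 2, 2] = ezz
    T[:, 0, 1] = T[:, 1, 0] = exy
    T[:, 0, 2] = T[:, 2, 0] = exz
    T[:, 1, 2] = T[:, 2, 1] = eyz
    vals = np.linalg.eigvalsh(T)  # ascending
    return vals[0] if np.ndim(components) == 1 else vals


def total_displacement(field: DisplacementField) -> np.ndarray:
    """Euclidean norm of each displacement vector (µm)."""
    return np.linalg.norm(field.vectors_um, axis=1)
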