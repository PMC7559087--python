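"""3D volume containers and I/O.

Volumes are stored with numpy axis order ``(z, y, x)`` — the natural order of
a TIFF slice stack — while every physical quantity written to disk is reported
as ``(x, y, z)`` in micrometres.  The physical position of voxel ``(k, j, i)``
is ``((i + 0.5), (j + 0.5), (k + 0.5)) * voxel_size_um`` (voxel centres).

Only isotropic voxels are supported: the correlation engine assumes a single
scalar voxel size.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np

__all__ = [
    "Volume3D",
    "ComponentMask",
    "VOISpec",
    "COMPONENT_NAMES",
    "read_volume",
    "write_volume",
    "extract_voi",
    "write_field",
    "read_field",
]

#: Canonical component names of the tissue-biomaterial system.
COMPONENT_NAMES = ("background", "bone", "cartilage", "implant", "new_tissue", "void")


@dataclass
class Volume3D:
    """A 3D grayscale image with isotropic voxel size.

    Parameters
    ----------
    intensities : ndarray, shape (nz, ny, nx)
        Scalar intensity grid (arbitrary grayscale units).
    voxel_size_um : float
        Edge length of one (isotropic) voxel in micrometres.
    origin_voxel : tuple of int
        Offset ``(z, y, x)`` of this grid within a parent volume, in voxels.
    """

    intensities: np.ndarray
    voxel_size_um: float
    origin_voxel: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3 or min(self.intensities.shape) < 1:
            raise ValueError("intensities must be a 3D grid with all dimensions >= 1")
        if not np.isfinite(self.voxel_size_um) or self.voxel_size_um <= 0:
            raise ValueError(f"voxel_size_um must be positive, got {self.voxel_size_um}")
        if np.issubdtype(self.intensities.dtype, np.floating) and not np.all(
            np.isfinite(self.intensities)
        ):
            raise ValueError("intensities must be finite")
        self.origin_voxel = tuple(int(v) for v in self.origin_voxel)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]

    def astype_float(self) -> "Volume3D":
        """Return a float64 view-copy (lossless for <= 32-bit integer input)."""
        if self.intensities.dtype == np.float64:
            return self
        return Volume3D(self.intensities.astype(np.float64), self.voxel_size_um, self.origin_voxel)


@dataclass
class ComponentMask:
    """Integer label grid identifying system components.

    ``legend`` maps each label value to a component name from
    :data:`COMPONENT_NAMES`.
    """

    labels: np.ndarray
    legend: Mapping[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer grid")
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"labels {sorted(missing)} not in legend")
        bad = set(self.legend.values()) - set(COMPONENT_NAMES)
        if bad:
            raise ValueError(f"unknown component names in legend: {sorted(bad)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def label_of(self, name: str) -> int:
        for lab, nm in self.legend.items():
            if nm == name:
                return lab
        raise KeyError(f"component {name!r} not in legend")


@dataclass
class VOISpec:
    """A volume-of-interest: ``start`` (z, y, x, 0-based voxels) and ``shape``."""

    start: tuple[int, int, int]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.start = tuple(int(v) for v in self.start)
        self.shape = tuple(int(v) for v in self.shape)
        if any(s < 0 for s in self.start):
            raise ValueError(f"start must be >= 0, got {self.start}")
        if any(s < 1 for s in self.shape):
            raise ValueError(f"shape must be >= 1, got {self.shape}")


def extract_voi(vol: Volume3D, spec: VOISpec) -> Volume3D:
    """Extract a sub-block; ``origin_voxel`` accumulates the start offset."""
    for ax, (st, sh, full) in enumerate(zip(spec.start, spec.shape, vol.shape)):
        if st + sh > full:
            raise IndexError(
                f"VOI out of bounds on axis {ax} ('zyx'[{ax}]): "
                f"start {st} + shape {sh} > volume extent {full}"
            )
    z, y, x = spec.start
    dz, dy, dx = spec.shape
    sub = vol.intensities[z : z + dz, y : y + dy, x : x + dx].copy()
    origin = tuple(o + s for o, s in zip(vol.origin_voxel, spec.start))
    return Volume3D(sub, vol.voxel_size_um, origin)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# Volume I/O


def _read_tiff(path: Path) -> np.ndarray:
    import tifffile

    if path.is_dir():
        slices = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if not slices:
            raise IOError(f"no TIFF slices found in directory {path}")
        arrs = [tifffile.imread(str(p)) for p in slices]
        shapes = {a.shape for a in arrs}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent slice shapes in {path}: {sorted(shapes)}")
        return np.stack(arrs, axis=0)
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 2D/3D TIFF, got ndim={arr.ndim}")
    return arr


def read_volume(path: Union[str, os.PathLike], voxel_size_um: float | None = None) -> Volume3D:
    """Read a TIFF stack (file or directory of slices), MHD or NRRD volume.

    For MHD/NRRD the header spacing is used when ``voxel_size_um`` is not
    given; anisotropic spacing is rejected.  For TIFF the caller must supply
    the voxel size.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read volume: {path} does not exist")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff") or path.is_dir():
        if path.is_file() and path.stat().st_size == 0:
            raise IOError(f"cannot read volume: {path} is empty")
        arr = _read_tiff(path)
        if voxel_size_um is None:
            raise ValueError("voxel_size_um is required for TIFF input (no spacing metadata)")
        return Volume3D(arr, float(voxel_size_um))
    if suffix in (".mhd", ".mha", ".nrrd"):
        if path.stat().st_size == 0:
            raise IOError(f"cannot read volume: {path} is empty")
        import SimpleITK as sitk

        try:
            img = sitk.ReadImage(str(path))
        except RuntimeError as exc:  # sitk wraps I/O failures in RuntimeError
            raise IOError(f"cannot read volume {path}: {exc}") from exc
        spacing = img.GetSpacing()  # (x, y, z)
        arr = sitk.GetArrayFromImage(img)  # (z, y, x)
        if voxel_size_um is None:
            if not np.allclose(spacing, spacing[0], rtol=1e-6):
                raise ValueError(f"anisotropic voxels not supported: spacing {spacing}")
            voxel_size_um = float(spacing[0])
        return Volume3D(arr, float(voxel_size_um))
    raise IOError(f"unrecognised volume format: {path}")


def write_volume(vol: Volume3D, path: Union[str, os.PathLike]) -> None:
    """Write a volume as multipage TIFF, MHD/RAW or NRRD (by extension)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(str(path), vol.intensities)
        return
    if suffix in (".mhd", ".mha", ".nrrd"):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(vol.intensities)
        img.SetSpacing((vol.voxel_size_um,) * 3)
        sitk.WriteImage(img, str(path))
        return
    raise IOError(f"unrecognised volume format for writing: {path}")


# ---------------------------------------------------------------------------
# Field I/O (CSV and VTK STRUCTURED_POINTS)


def _field_table(fld) -> tuple[list[str], np.ndarray]:
    """Columns and data rows for a displacement or strain field."""
    pos = fld.grid.positions_um()  # (n, 3) x, y, z
    if hasattr(fld, "vectors_um"):
        cols = ["x_um", "y_um", "z_um", "u_um", "v_um", "w_um", "correlation"]
        data = np.column_stack([pos, fld.vectors_um, fld.correlation])
    else:
        cols = ["x_um", "y_um", "z_um", "exx", "eyy", "ezz", "exy", "exz", "eyz"]
        data = np.column_stack([pos, fld.components])
    return cols, data


def write_field(fld, path: Union[str, os.PathLike], format: str = "csv") -> None:
    """Write a displacement or strain field as CSV or VTK STRUCTURED_POINTS.

    CSV columns are physical position (x, y, z in µm) followed by the field
    components, plus the correlation value for displacement fields.
    """
    n = len(fld.grid.centres)
    if n == 0:
        raise ValueError("cannot write an empty field")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols, data = _field_table(fld)
    if format == "csv":
        import pandas as pd

        pd.DataFrame(data, columns=cols).to_csv(path, index=False, float_format="%.8g")
        return
    if format == "vtk":
        _write_vtk(fld, path, cols, data)
        return
    raise ValueError(f"unknown field format {format!r} (use 'csv' or 'vtk')")


def _write_vtk(fld, path: Path, cols: Sequence[str], data: np.ndarray) -> None:
    g = fld.grid
    nz, ny, nx = g.grid_shape
    step_um = g.step_vox * g.voxel_size_um
    origin = data[0, :3]
    lines = [
        "# vtk DataFile Version 3.0",
        "ocdvc field",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        f"ORIGIN {origin[0]:.6g} {origin[1]:.6g} {origin[2]:.6g}",
        f"SPACING {step_um:.6g} {step_um:.6g} {step_um:.6g}",
        f"POINT_DATA {nx * ny * nz}",
    ]
    if hasattr(fld, "vectors_um"):
        lines.append("VECTORS displacement_um double")
        for row in data:
            lines.append(f"{row[3]:.8g} {row[4]:.8g} {row[5]:.8g}")
        lines.append("SCALARS correlation double 1")
        lines.append("LOOKUP_TABLE default")
        for row in data:
            lines.append(f"{row[6]:.8g}")
    else:
        for ci, name in enumerate(cols[3:], start=3):
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            for row in data:
                lines.append(f"{row[ci]:.8g}")
    path.write_text("\n".join(lines) + "\n")


def read_field(path: Union[str, os.PathLike]):
    """Read a field CSV back as a pandas DataFrame (positions + components)."""
    import pandas as pd

    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read field: {path} does not exist")
    return pd.read_csv(path)
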