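"""Subvolume digital volume correlation (DVC).

Three processing schemes over a regular grid of cubic subvolumes:

``DC``
    Exhaustive integer-offset search maximising the zero-normalised
    cross-correlation (ZNCC) inside a search radius, then 3-point subpixel
    refinement per axis.
``FFT``
    Cyclic cross-correlation of zero-mean windows computed in the frequency
    domain; integer peak (wrap-limited to half the window) plus subpixel
    refinement; the reported correlation is the ZNCC of the best offset.
``FFT_DC``
    Multi-pass scheme: coarse FFT passes on windows enlarged by a pre-shift
    margin provide an integer predictor (median-smoothed between passes);
    the final pass is DC with subpixel refinement at the target subvolume
    size.

Displacements are stored in physical micrometres with component order
``(u_x, u_y, u_z)``; grids and voxel offsets use storage order ``(z, y, x)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .volume import Volume3D

__all__ = [
    "SubvolumeGrid",
    "DVCConfig",
    "DisplacementField",
    "build_grid",
    "ncc",
    "zncc_search",
    "subpixel_peak",
    "correlate_dc",
    "correlate_fft",
    "correlate_multipass",
    "correlate",
]

_PERFECT = 1.0 - 1e-7  # integer peak this good is exact; skip subpixel fit


@dataclass
class SubvolumeGrid:
    """Regular lattice of cubic interrogation subvolumes.

    ``starts`` are the (z, y, x) corner voxels of each subvolume in z-major
    order; ``centres`` are the integer centre voxels used for mask lookup.
    """

    subvolume_size_vox: int
    overlap_fraction: float
    starts: np.ndarray  # (n, 3) int, (z, y, x)
    grid_shape: tuple[int, int, int]  # (nz, ny, nx) of the lattice
    vol_shape: tuple[int, int, int]
    voxel_size_um: float

    def __post_init__(self) -> None:
        if self.subvolume_size_vox < 8:
            raise ValueError("subvolume_size_vox must be >= 8")
        if not (0 <= self.overlap_fraction < 1):
            raise ValueError("overlap_fraction must be in [0, 1)")

    @property
    def step_vox(self) -> int:
        return max(1, int(round(self.subvolume_size_vox * (1.0 - self.overlap_fraction))))

    @property
    def centres(self) -> np.ndarray:
        return self.starts + self.subvolume_size_vox // 2

    @property
    def n_points(self) -> int:
        return len(self.starts)

    def positions_um(self) -> np.ndarray:
        """Physical (x, y, z) positions of the subvolume centres, in µm."""
        geo = self.starts[:, ::-1].astype(np.float64) + self.subvolume_size_vox / 2.0
        return geo * self.voxel_size_um


def build_grid(
    vol_shape: tuple[int, int, int],
    subvolume_size_vox: int,
    overlap_fraction: float = 0.5,
    voxel_size_um: float = 1.0,
    inset_vox: int | tuple[int, int, int] = 0,
) -> SubvolumeGrid:
    """Lay out subvolume corners with the stated spacing and symmetric margins.

    ``inset_vox`` (scalar or per-axis ``(z, y, x)``) keeps subvolumes that
    far away from each volume face — the interior volume-of-interest
    practice: near-face subvolumes have one-sided search ranges, and under
    load the face adjacent to the moving platen contains material that has
    left the imaged domain.
    """
    size = int(subvolume_size_vox)
    if np.isscalar(inset_vox):
        inset_vox = (int(inset_vox),) * 3
    if any(size + 2 * ins > d for d, ins in zip(vol_shape, inset_vox)):
        raise ValueError(
            f"subvolume size {size} with inset {inset_vox} exceeds volume shape {vol_shape}"
        )
    step = max(1, int(round(size * (1.0 - overlap_fraction))))
    axes = []
    for dim, ins in zip(vol_shape, inset_vox):
        avail = dim - 2 * ins
        n = (avail - size) // step + 1
        margin = ins + (avail - size - (n - 1) * step) // 2
        axes.append(margin + step * np.arange(n))
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    starts = np.column_stack([zz.ravel(), yy.ravel(), xx.ravel()]).astype(np.int64)
    return SubvolumeGrid(
        subvolume_size_vox=size,
        overlap_fraction=float(overlap_fraction),
        starts=starts,
        grid_shape=tuple(len(a) for a in axes),  # type: ignore[arg-type]
        vol_shape=tuple(vol_shape),  # type: ignore[arg-type]
        voxel_size_um=float(voxel_size_um),
    )


@dataclass
class DVCConfig:
    """Correlation-engine settings.

    ``fft_preshift_margin_vox`` enlarges the FFT-pass window on each side,
    giving the coarse passes extra search range before the final DC pass.
    ``dc_search_radius_vox`` is the exhaustive search radius of standalone
    DC; the multipass final DC pass only has to resolve the subvoxel
    residual left by the FFT pre-shift and searches
    ``fft_dc_final_radius_vox``.  ``min_correlation`` is a reporting mask
    applied by downstream summaries (0 keeps every point).
    """

    method: str = "FFT_DC"
    n_passes: int = 3
    fft_preshift_margin_vox: int = 12
    dc_search_radius_vox: int = 4
    fft_dc_final_radius_vox: int = 2
    peak_interpolation: str = "gaussian3"
    min_correlation: float = 0.0

    def __post_init__(self) -> None:
        if self.method not in ("DC", "FFT", "FFT_DC"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.n_passes < 1:
            raise ValueError("n_passes must be >= 1")
        if self.fft_preshift_margin_vox < 0 or self.dc_search_radius_vox < 0:
            raise ValueError("margins/radii must be >= 0")
        if self.peak_interpolation not in ("gaussian3", "parabolic3"):
            raise ValueError(f"unknown peak interpolation {self.peak_interpolation!r}")
        if not (0.0 <= self.min_correlation <= 1.0):
            raise ValueError("min_correlation must be in [0, 1]")


@dataclass
class DisplacementField:
    """Per-grid-point displacement vectors (µm, x/y/z), ZNCC value and validity."""

    grid: SubvolumeGrid
    vectors_um: np.ndarray  # (n, 3) float, (u_x, u_y, u_z)
    correlation: np.ndarray  # (n,)
    valid: np.ndarray  # (n,) bool

    def __post_init__(self) -> None:
        n = self.grid.n_points
        if self.vectors_um.shape != (n, 3) or self.correlation.shape != (n,):
            raise ValueError("field arrays inconsistent with grid")
        if np.any(self.correlation[self.valid] > 1 + 1e-9):
            raise ValueError("correlation exceeds 1")
        if not np.all(np.isfinite(self.vectors_um[self.valid])):
            raise ValueError("vectors must be finite where valid")

    def vectors_on_grid(self) -> np.ndarray:
        """Vectors reshaped to the lattice, (nz, ny, nx, 3)."""
        return self.vectors_um.reshape(self.grid.grid_shape + (3,))


def ncc(sub_ref: np.ndarray, sub_def: np.ndarray) -> float:
    """Zero-normalised cross-correlation coefficient in [-1, 1].

    Returns NaN (the invalid flag) for constant subvolumes so texture-free
    regions degrade gracefully instead of raising.
    """
    a = np.asarray(sub_ref, dtype=np.float64)
    b = np.asarray(sub_def, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    a = a - a.mean()
    b = b - b.mean()
    na = np.linalg.norm(a.ravel())
    nb = np.linalg.norm(b.ravel())
    if na == 0 or nb == 0:
        return float("nan")
    return float(np.clip(np.dot(a.ravel(), b.ravel()) / (na * nb), -1.0, 1.0))


class SubpixelResult(NamedTuple):
    offset: float
    flagged: bool
    estimator: str


def subpixel_peak(profile, method: str = "gaussian3") -> SubpixelResult:
    """Subpixel offset of a 3-point correlation profile (c-, c0, c+).

    The Gaussian estimator fits ``exp`` through the log values (positive
    profiles only; non-positive values fall back to the parabolic fit and
    are flagged).  A symmetric profile yields 0; a plateau ``c- == c0``
    yields the boundary value -0.5, flagged.
    """
    cm, c0, cp = (float(v) for v in profile)
    if not (c0 >= cm and c0 >= cp):
        raise ValueError("middle value must be >= neighbours")
    if cm == c0 == cp:
        return SubpixelResult(0.0, True, "plateau")
    if cm == c0:
        return SubpixelResult(-0.5, True, "plateau")
    if cp == c0:
        return SubpixelResult(0.5, True, "plateau")
    flagged = False
    if method == "gaussian3":
        if cm > 0 and c0 > 0 and cp > 0:
            lm, l0, lp = np.log(cm), np.log(c0), np.log(cp)
            denom = 2 * lm - 4 * l0 + 2 * lp
            if denom != 0:
                delta = (lm - lp) / denom
                return SubpixelResult(float(np.clip(delta, -0.999, 0.999)), False, "gaussian3")
        flagged = True  # fall through to parabolic
    denom = 2 * (cm - 2 * c0 + cp)
    if denom == 0:
        return SubpixelResult(0.0, True, "parabolic3")
    delta = (cm - cp) / denom
    return SubpixelResult(float(np.clip(delta, -0.999, 0.999)), flagged, "parabolic3")


# ---------------------------------------------------------------------------
# helpers


def _texture_threshold(ref: np.ndarray) -> float:
    dyn = float(ref.max() - ref.min())
    return max(1e-12, 1e-6 * dyn)


def _predictor_vox(predictor: Optional[DisplacementField], grid: SubvolumeGrid) -> np.ndarray:
    """Integer predictor offsets (z, y, x voxels) per grid point."""
    n = grid.n_points
    if predictor is None:
        return np.zeros((n, 3), dtype=np.int64)
    vec = predictor.vectors_um.copy()
    bad = ~np.isfinite(vec).all(axis=1) | ~predictor.valid
    if bad.any():
        fill = np.nanmedian(np.where(bad[:, None], np.nan, vec), axis=0)
        fill = np.where(np.isfinite(fill), fill, 0.0)
        vec[bad] = fill
    vox = np.rint(vec[:, ::-1] / grid.voxel_size_um).astype(np.int64)  # (z, y, x)
    return vox


def _best_offset(corr_map: np.ndarray, offsets_origin: np.ndarray) -> tuple[np.ndarray, float]:
    """Deterministic peak pick: max value, ties broken by smallest Euclidean
    offset then lexicographic order."""
    peak_val = float(np.nanmax(corr_map))
    cand = np.argwhere(corr_map >= peak_val - 1e-12)
    offs = cand + offsets_origin  # (m, 3) displacement offsets (z, y, x)
    order = np.lexsort((offs[:, 2], offs[:, 1], offs[:, 0], (offs**2).sum(axis=1)))
    best = cand[order[0]]
    return best, peak_val


def _refine(corr_map: np.ndarray, peak_idx: np.ndarray, peak_val: float, method: str) -> np.ndarray:
    """Per-axis 3-point subpixel refinement; axes with the peak at the map
    border keep their integer offset."""
    delta = np.zeros(3)
    if peak_val >= _PERFECT:
        return delta
    for ax in range(3):
        i = peak_idx[ax]
        if i <= 0 or i >= corr_map.shape[ax] - 1:
            continue
        sel: list = list(peak_idx)
        sel[ax] = slice(i - 1, i + 2)
        prof = corr_map[tuple(sel)]
        if not np.all(np.isfinite(prof)) or not (prof[1] >= prof[0] and prof[1] >= prof[2]):
            continue
        delta[ax] = subpixel_peak(prof, method).offset
    return delta


def _extract_block(vol: np.ndarray, start: np.ndarray, size: int) -> Optional[np.ndarray]:
    """Block of edge ``size`` at ``start`` (z, y, x), or None if out of bounds."""
    if np.any(start < 0) or np.any(start + size > vol.shape):
        return None
    z, y, x = start
    return vol[z : z + size, y : y + size, x : x + size]


def _check_pair(ref: Volume3D, deformed: Volume3D) -> None:
    if ref.shape != deformed.shape:
        raise ValueError(f"volume shapes differ: {ref.shape} vs {deformed.shape}")
    if not np.isclose(ref.voxel_size_um, deformed.voxel_size_um):
        raise ValueError("voxel sizes differ")


def zncc_search(region: np.ndarray, template: np.ndarray) -> np.ndarray:
    """ZNCC of ``template`` against every integer placement inside ``region``.

    Output shape is ``region.shape - template.shape + 1``; placements where
    the region window is constant are NaN.  The numerator is evaluated with
    BLAS over sliding windows (chunked along z to bound memory), the window
    variances with box sums.
    """
    t = template - template.mean()
    tn = np.linalg.norm(t.ravel())
    out_shape = tuple(r - s + 1 for r, s in zip(region.shape, template.shape))
    if tn == 0:
        return np.full(out_shape, np.nan)
    n = template.size
    # box sums of the region windows via sliding windows of ones would cost
    # as much as the numerator; use cumulative sums instead
    win_sum = _box_sum(region, template.shape)
    win_sq = _box_sum(region**2, template.shape)
    var = win_sq - win_sum**2 / n
    np.clip(var, 0.0, None, out=var)
    denom = tn * np.sqrt(var)

    tflat = t.ravel()
    num = np.empty(out_shape)
    windows = sliding_window_view(region, template.shape)  # (oz, oy, ox, sz, sy, sx)
    for z in range(out_shape[0]):  # chunk: one offset plane at a time
        chunk = windows[z].reshape(out_shape[1] * out_shape[2], n)
        num[z] = (chunk @ tflat).reshape(out_shape[1:])
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / denom
    out[denom < 1e-12 * tn] = np.nan
    return np.clip(out, -1.0, 1.0, out=out)


def _box_sum(arr: np.ndarray, box: tuple[int, ...]) -> np.ndarray:
    """Sums over all ``box``-shaped windows of ``arr`` (valid placements)."""
    out = arr
    for ax, b in enumerate(box):
        c = np.cumsum(out, axis=ax)
        lead = np.take(c, [b - 1], axis=ax)
        rest = np.take(c, range(b, out.shape[ax]), axis=ax) - np.take(
            c, range(0, out.shape[ax] - b), axis=ax
        )
        out = np.concatenate([lead, rest], axis=ax)
    return out


# ---------------------------------------------------------------------------
# DC


def correlate_dc(
    ref: Volume3D,
    deformed: Volume3D,
    grid: SubvolumeGrid,
    config: DVCConfig,
    predictor: Optional[DisplacementField] = None,
    search_radius_vox: Optional[int] = None,
    max_recentres: int = 8,
) -> DisplacementField:
    """Exhaustive integer ZNCC search around the predictor, plus subpixel fit.

    When the best integer offset lands on the border of the search window —
    the true peak may lie outside, e.g. because a smoothed predictor was
    biased by neighbours across a displacement discontinuity — the search is
    re-centred on that offset and repeated (up to ``max_recentres`` times),
    walking towards the peak instead of clipping at it.
    """
    _check_pair(ref, deformed)
    rvol = ref.intensities.astype(np.float64, copy=False)
    dvol = deformed.intensities.astype(np.float64, copy=False)
    size = grid.subvolume_size_vox
    radius = config.dc_search_radius_vox if search_radius_vox is None else search_radius_vox
    tex_thresh = _texture_threshold(rvol)
    pred = _predictor_vox(predictor, grid)
    vs = grid.voxel_size_um
    shape = np.array(rvol.shape)

    n = grid.n_points
    vectors = np.full((n, 3), np.nan)
    corr = np.zeros(n)
    valid = np.zeros(n, dtype=bool)

    region_edge = size + 2 * radius
    for i, start in enumerate(grid.starts):
        template = _extract_block(rvol, start, size)
        assert template is not None  # grid guarantees containment
        if template.std() < tex_thresh:
            continue
        centre_off = pred[i].copy()
        result = None
        for _ in range(max_recentres + 1):
            desired = start + centre_off - radius
            lo = np.clip(desired, 0, np.maximum(shape - region_edge, 0))
            hi = np.minimum(shape, lo + region_edge)
            region = dvol[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
            if any(rs < size for rs in region.shape):
                break
            corr_map = zncc_search(region, template)
            if not np.isfinite(corr_map).any():
                break
            origin = lo - start  # displacement offset of map index (0,0,0)
            peak_idx, peak_val = _best_offset(corr_map, origin)
            result = (corr_map, origin, peak_idx, peak_val)
            at_border = any(
                (peak_idx[ax] == 0 and lo[ax] > 0)
                or (peak_idx[ax] == corr_map.shape[ax] - 1 and hi[ax] < shape[ax])
                for ax in range(3)
            )
            if not at_border:
                break
            new_centre = origin + peak_idx
            if np.array_equal(new_centre, centre_off):
                break
            centre_off = new_centre
        if result is None:
            continue
        corr_map, origin, peak_idx, peak_val = result
        delta = _refine(corr_map, peak_idx, peak_val, config.peak_interpolation)
        off = origin + peak_idx + delta  # (z, y, x) voxels
        vectors[i] = off[::-1] * vs
        corr[i] = min(peak_val, 1.0)
        valid[i] = True
    return DisplacementField(grid, vectors, corr, valid)


# ---------------------------------------------------------------------------
# FFT


def correlate_fft(
    ref: Volume3D,
    deformed: Volume3D,
    grid: SubvolumeGrid,
    config: DVCConfig,
    predictor: Optional[DisplacementField] = None,
    window_margin_vox: int = 0,
) -> DisplacementField:
    """Cyclic frequency-domain cross-correlation per (optionally enlarged)
    window; the correlation value is rescaled to the ZNCC of the best offset.

    Peaks at or beyond half the window are wrap-ambiguous and flagged
    invalid.
    """
    _check_pair(ref, deformed)
    rvol = ref.intensities.astype(np.float64, copy=False)
    dvol = deformed.intensities.astype(np.float64, copy=False)
    size = grid.subvolume_size_vox
    win = size + 2 * window_margin_vox
    tex_thresh = _texture_threshold(rvol)
    pred = _predictor_vox(predictor, grid)
    vs = grid.voxel_size_um
    shape = np.array(rvol.shape)
    win_edge = np.minimum(win, shape)  # window clipped to the volume

    n = grid.n_points
    vectors = np.full((n, 3), np.nan)
    corr = np.zeros(n)
    valid = np.zeros(n, dtype=bool)

    for i, start in enumerate(grid.starts):
        wstart = np.clip(start - window_margin_vox, 0, shape - win_edge)
        rw = rvol[
            wstart[0] : wstart[0] + win_edge[0],
            wstart[1] : wstart[1] + win_edge[1],
            wstart[2] : wstart[2] + win_edge[2],
        ]
        dstart = np.clip(wstart + pred[i], 0, shape - win_edge)
        applied_pred = dstart - wstart
        dw = dvol[
            dstart[0] : dstart[0] + win_edge[0],
            dstart[1] : dstart[1] + win_edge[1],
            dstart[2] : dstart[2] + win_edge[2],
        ]
        if rw.std() < tex_thresh or dw.std() == 0:
            continue
        a = rw - rw.mean()
        b = dw - dw.mean()
        fa = np.fft.rfftn(a)
        fb = np.fft.rfftn(b)
        cc = np.fft.irfftn(np.conj(fa) * fb, s=a.shape, axes=(0, 1, 2))
        peak_idx, peak_val = _best_offset(cc, np.zeros(3, dtype=np.int64))
        # cyclic index -> signed offset
        half = np.array(a.shape) // 2
        signed = np.where(peak_idx > half, peak_idx - np.array(a.shape), peak_idx)
        if np.any(np.abs(signed) >= half):
            continue  # wrap-ambiguous peak
        # subpixel on the cyclic map (values are covariances)
        delta = np.zeros(3)
        prof_ok = True
        best_int = applied_pred + signed
        sub_ref = _extract_block(rvol, start, size)
        blk = _extract_block(dvol, start + best_int, size)
        zncc = ncc(sub_ref, blk) if (blk is not None and sub_ref is not None) else np.nan
        if np.isfinite(zncc) and zncc < _PERFECT:
            for ax in range(3):
                sel = [int(peak_idx[0]), int(peak_idx[1]), int(peak_idx[2])]
                m = a.shape[ax]
                prof = [
                    cc[tuple(sel[:ax] + [(peak_idx[ax] - 1) % m] + sel[ax + 1 :])],
                    cc[tuple(sel)],
                    cc[tuple(sel[:ax] + [(peak_idx[ax] + 1) % m] + sel[ax + 1 :])],
                ]
                if prof[1] >= prof[0] and prof[1] >= prof[2]:
                    delta[ax] = subpixel_peak(prof, config.peak_interpolation).offset
        if not np.isfinite(zncc):
            continue
        off = best_int + delta
        vectors[i] = off[::-1] * vs
        corr[i] = zncc
        valid[i] = True
    return DisplacementField(grid, vectors, corr, valid)


# ---------------------------------------------------------------------------
# multi-pass FFT + DC


def _smooth_predictor(fld: DisplacementField) -> DisplacementField:
    """Component-wise 3³ median filter of the vector lattice; invalid points
    are first filled with the global median so isolated outliers cannot
    leak through."""
    grid = fld.grid
    vec = fld.vectors_um.copy()
    bad = ~fld.valid | ~np.isfinite(vec).all(axis=1)
    if bad.all():
        return DisplacementField(grid, np.zeros_like(vec), np.zeros(len(vec)), np.ones(len(vec), bool))
    fill = np.nanmedian(np.where(bad[:, None], np.nan, vec), axis=0)
    vec[bad] = np.where(np.isfinite(fill), fill, 0.0)
    lattice = vec.reshape(grid.grid_shape + (3,))
    for c in range(3):
        lattice[..., c] = ndimage.median_filter(lattice[..., c], size=3, mode="nearest")
    sm = lattice.reshape(-1, 3)
    return DisplacementField(grid, sm, fld.correlation.copy(), np.ones(len(sm), dtype=bool))


def correlate_multipass(
    ref: Volume3D,
    deformed: Volume3D,
    grid: SubvolumeGrid,
    config: DVCConfig,
) -> DisplacementField:
    """FFT pre-shift passes feeding a final DC pass (the combined scheme).

    Passes ``1 .. n_passes-1`` run FFT correlation on windows enlarged by
    ``fft_preshift_margin_vox`` per side; each result is median-smoothed and
    used as the integer predictor of the next pass.  The final pass is DC
    with subpixel refinement at the target subvolume size.
    """
    if config.method != "FFT_DC":
        raise ValueError("correlate_multipass requires method='FFT_DC'")
    predictor: Optional[DisplacementField] = None
    for _ in range(config.n_passes - 1):
        fld = correlate_fft(
            ref,
            deformed,
            grid,
            config,
            predictor=predictor,
            window_margin_vox=config.fft_preshift_margin_vox,
        )
        predictor = _smooth_predictor(fld)
    radius = (
        config.dc_search_radius_vox if predictor is None else config.fft_dc_final_radius_vox
    )
    return correlate_dc(
        ref, deformed, grid, config, predictor=predictor, search_radius_vox=radius
    )


def correlate(
    ref: Volume3D,
    deformed: Volume3D,
    grid: SubvolumeGrid,
    config: DVCConfig,
) -> DisplacementField:
    """Dispatch on ``config.method``."""
    if config.method == "DC":
        return correlate_dc(ref, deformed, grid, config)
    if config.method == "FFT":
        return correlate_fft(ref, deformed, grid, config)
    return correlate_multipass(ref, deformed, grid, config)
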