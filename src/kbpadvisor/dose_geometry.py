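"""Voxel-level geometry and dosimetry engine.

Everything downstream of the treatment planning system is computed on an
axis-aligned voxel lattice in patient coordinates (millimetres): contour
rasterization, ROI volumes, OAR-PTV overlap fractions, cumulative DVHs and
the dose metrics derived from them (mean dose, Dx, Vx, conformity index).

Conventions
-----------
* Patient axes: x right-left, y anterior-posterior (posterior is -y),
  z inferior-superior.  Arrays are indexed ``[ix, iy, iz]`` and ``origin``
  is the centre of voxel (0, 0, 0).
* Doses are in Gy throughout; volumes in cm^3; lengths in mm.
* A voxel belongs to an ROI iff its centre lies inside the even-odd union
  of the slice polygons.
* Metrics are computed on the dose grid's lattice; masks from a different
  lattice are resampled nearest-neighbour, dose trilinearly.
* Metrics on empty masks raise, never return silent zeros.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path as _MplPath
from scipy import ndimage


class EmptyMaskError(ValueError):
    """A dose metric was requested for an ROI with no occupied voxels."""


class EmptyIsodoseError(ValueError):
    """The isodose region of a conformity index is empty."""


class DegeneratePolygonError(ValueError):
    """A contour polygon has fewer than three vertices."""


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned voxel lattice in patient space.

    ``origin`` is the patient-space position (mm) of the centre of the
    first voxel; ``spacing`` the voxel pitch (mm) along x, y, z; ``shape``
    the voxel counts.
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        object.__setattr__(self, "shape", tuple(int(v) for v in self.shape))
        if len(self.origin) != 3 or len(self.spacing) != 3 or len(self.shape) != 3:
            raise ValueError("origin, spacing and shape must be 3-vectors")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if any(n < 1 for n in self.shape):
            raise ValueError(f"shape must be >= 1 along each axis, got {self.shape}")

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-centre coordinates (mm) along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def same_lattice(self, other: "VoxelGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and all(abs(a - b) <= tol for a, b in zip(self.origin, other.origin))
            and all(abs(a - b) <= tol for a, b in zip(self.spacing, other.spacing))
        )


@dataclass(frozen=True)
class ContourSet:
    """Planar closed contours for one ROI: list of (z_mm, (n, 2) vertex array)."""

    roi_name: str
    slices: list[tuple[float, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        cleaned = []
        for z, verts in self.slices:
            verts = np.asarray(verts, dtype=float)
            if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
                raise DegeneratePolygonError(
                    f"contour for {self.roi_name!r} at z={z} needs >= 3 (x, y) vertices"
                )
            cleaned.append((float(z), verts))
        object.__setattr__(self, "slices", cleaned)


@dataclass(frozen=True)
class ROIMask:
    """Boolean occupancy of one ROI on a voxel grid."""

    grid: VoxelGrid
    occupancy: np.ndarray
    roi_name: str = ""

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=bool)
        if occ.shape != self.grid.shape:
            raise ValueError(
                f"occupancy shape {occ.shape} does not match grid shape {self.grid.shape}"
            )
        object.__setattr__(self, "occupancy", occ)

    @property
    def voxel_count(self) -> int:
        return int(self.occupancy.sum())

    def is_empty(self) -> bool:
        return not self.occupancy.any()


@dataclass(frozen=True)
class DoseGrid:
    """Absorbed dose in Gy on a voxel grid."""

    grid: VoxelGrid
    dose: np.ndarray

    def __post_init__(self) -> None:
        dose = np.asarray(self.dose, dtype=float)
        if dose.shape != self.grid.shape:
            raise ValueError(
                f"dose shape {dose.shape} does not match grid shape {self.grid.shape}"
            )
        if np.any(dose < 0):
            raise ValueError("dose values must be non-negative")
        object.__setattr__(self, "dose", dose)


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative dose-volume histogram.

    ``cum_volume[i]`` is the fraction of the ROI receiving at least
    ``bin_edges[i]`` Gy; the curve starts at exactly 1 and is non-increasing.
    """

    bin_edges: np.ndarray
    cum_volume: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        cum = np.asarray(self.cum_volume, dtype=float)
        if edges.ndim != 1 or edges.shape != cum.shape:
            raise ValueError("bin_edges and cum_volume must be 1-D and equal length")
        if edges[0] != 0.0 or np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges must start at 0 and be strictly increasing")
        if cum[0] != 1.0:
            raise ValueError("cum_volume must start at exactly 1")
        if np.any(np.diff(cum) > 1e-12) or cum.min() < -1e-12 or cum.max() > 1 + 1e-12:
            raise ValueError("cum_volume must be non-increasing within [0, 1]")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "cum_volume", cum)


DEFAULT_BIN_WIDTH_GY = 0.1

# relative slack when comparing doses against bin edges, so a voxel at
# exactly 74 Gy counts as receiving >= the 74.0 edge despite float rounding
_EDGE_RTOL = 1e-9


def rasterize(contours: ContourSet, grid: VoxelGrid) -> ROIMask:
    """Rasterize planar contours onto a grid by the voxel-centre rule.

    Each slice polygon is assigned to the nearest grid slice in z; a voxel
    is occupied iff its centre lies inside the even-odd union of the
    polygons on its slice (so a second polygon nested in a first one cuts
    a hole).  Contours entirely outside the grid yield an empty mask with
    a warning rather than an error.
    """
    occ = np.zeros(grid.shape, dtype=bool)
    if not contours.slices:
        return ROIMask(grid=grid, occupancy=occ, roi_name=contours.roi_name)

    xs = grid.axis_coords(0)
    ys = grid.axis_coords(1)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    points = np.column_stack([xx.ravel(), yy.ravel()])

    oz, sz = grid.origin[2], grid.spacing[2]
    nz = grid.shape[2]
    n_used = 0
    for z, verts in contours.slices:
        k = int(round((z - oz) / sz))
        if k < 0 or k >= nz:
            continue
        n_used += 1
        # Path's closed=True treats the final vertex as the close-poly marker,
        # so re-append the first vertex to keep every input vertex in play.
        ring = np.vstack([verts, verts[:1]])
        inside = _MplPath(ring, closed=True).contains_points(points)
        occ[:, :, k] ^= inside.reshape(len(xs), len(ys))

    if n_used == 0:
        warnings.warn(
            f"all contours of {contours.roi_name!r} lie outside the grid; mask is empty",
            stacklevel=2,
        )
    return ROIMask(grid=grid, occupancy=occ, roi_name=contours.roi_name)


def volume(mask: ROIMask) -> float:
    """ROI volume in cm^3 (occupied voxels x voxel volume)."""
    return mask.voxel_count * mask.grid.voxel_volume_mm3 / 1000.0


def resample_mask(mask: ROIMask, grid: VoxelGrid) -> ROIMask:
    """Nearest-neighbour resampling of a mask onto another lattice."""
    if mask.grid.same_lattice(grid):
        return ROIMask(grid=grid, occupancy=mask.occupancy, roi_name=mask.roi_name)
    idx = []
    valid = np.ones(grid.shape, dtype=bool)
    for ax in range(3):
        coords = grid.axis_coords(ax)
        j = np.round((coords - mask.grid.origin[ax]) / mask.grid.spacing[ax]).astype(int)
        ok = (j >= 0) & (j < mask.grid.shape[ax])
        shape = [1, 1, 1]
        shape[ax] = -1
        valid &= ok.reshape(shape)
        idx.append(np.clip(j, 0, mask.grid.shape[ax] - 1))
    ix, iy, iz = np.meshgrid(idx[0], idx[1], idx[2], indexing="ij")
    occ = mask.occupancy[ix, iy, iz] & valid
    return ROIMask(grid=grid, occupancy=occ, roi_name=mask.roi_name)


def resample_dose(dose: DoseGrid, grid: VoxelGrid) -> DoseGrid:
    """Trilinear resampling of a dose grid onto another lattice."""
    if dose.grid.same_lattice(grid):
        return DoseGrid(grid=grid, dose=dose.dose)
    frac = [
        (grid.axis_coords(ax) - dose.grid.origin[ax]) / dose.grid.spacing[ax]
        for ax in range(3)
    ]
    fx, fy, fz = np.meshgrid(*frac, indexing="ij")
    out = ndimage.map_coordinates(dose.dose, [fx, fy, fz], order=1, mode="nearest")
    return DoseGrid(grid=grid, dose=np.clip(out, 0.0, None))


def overlap_fraction(oar: ROIMask, target: ROIMask) -> float:
    """Fraction of the OAR volume lying inside the target: |OAR n T| / |OAR|.

    Asymmetric by construction (the denominator is the OAR); the target is
    resampled to the OAR lattice if the grids differ.
    """
    if oar.is_empty():
        raise EmptyMaskError(
            f"overlap fraction undefined: OAR {oar.roi_name!r} mask is empty"
        )
    target = resample_mask(target, oar.grid)
    inter = int((oar.occupancy & target.occupancy).sum())
    return inter / oar.voxel_count


def cumulative_dvh(
    dose: DoseGrid, mask: ROIMask, bin_width: float = DEFAULT_BIN_WIDTH_GY
) -> DVHCurve:
    """Cumulative DVH of the masked voxels with half-open bins of ``bin_width`` Gy.

    Bin edges run from 0 to just past the maximum masked dose.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if mask.is_empty():
        raise EmptyMaskError(f"DVH undefined for empty mask {mask.roi_name!r}")
    mask = resample_mask(mask, dose.grid)
    if mask.is_empty():
        raise EmptyMaskError(
            f"mask {mask.roi_name!r} is empty after resampling to the dose grid"
        )
    d = np.sort(dose.dose[mask.occupancy])
    dmax = d[-1]
    n_edges = int(np.floor(dmax / bin_width)) + 2
    edges = np.arange(n_edges) * bin_width
    tol = _EDGE_RTOL * max(1.0, dmax)
    below = np.searchsorted(d, edges - tol, side="left")
    cum = (d.size - below) / d.size
    cum[0] = 1.0
    return DVHCurve(bin_edges=edges, cum_volume=cum)


def mean_dose(dose: DoseGrid, mask: ROIMask) -> float:
    """Arithmetic mean dose (Gy) over the occupied voxels."""
    if mask.is_empty():
        raise EmptyMaskError(f"mean dose undefined for empty mask {mask.roi_name!r}")
    mask = resample_mask(mask, dose.grid)
    if mask.is_empty():
        raise EmptyMaskError(
            f"mask {mask.roi_name!r} is empty after resampling to the dose grid"
        )
    return float(dose.dose[mask.occupancy].mean())


def dose_at_volume(dvh: DVHCurve, p: float) -> float:
    """Dp: minimum dose (Gy) received by the hottest ``p`` percent of the ROI.

    Linear interpolation between bin edges; on a flat DVH plateau the
    right-hand (hotter) edge is returned, so D50 of a half-20/half-60 Gy
    field is 60 Gy.
    """
    if not 0 < p < 100:
        raise ValueError(f"p must lie strictly between 0 and 100, got {p}")
    f = p / 100.0
    cum = dvh.cum_volume
    edges = dvh.bin_edges
    idx = int(np.flatnonzero(cum >= f - 1e-12)[-1])
    if idx == len(edges) - 1:
        return float(edges[-1])
    c0, c1 = cum[idx], cum[idx + 1]
    if c0 <= f + 1e-12 or c0 == c1:
        return float(edges[idx])
    w = (c0 - f) / (c0 - c1)
    return float(edges[idx] + w * (edges[idx + 1] - edges[idx]))


def volume_at_dose(dvh: DVHCurve, d: float) -> float:
    """Vd: fraction of the ROI receiving at least ``d`` Gy (interpolated)."""
    if d < 0:
        raise ValueError(f"dose level must be non-negative, got {d}")
    if d >= dvh.bin_edges[-1]:
        return float(dvh.cum_volume[-1]) if d == dvh.bin_edges[-1] else 0.0
    return float(np.interp(d, dvh.bin_edges, dvh.cum_volume))


def conformity_index(dose: DoseGrid, target: ROIMask, iso: float) -> float:
    """CI: |target n {dose >= iso}| / |{dose >= iso}|.

    The ratio of the isodose volume covering the target to the total
    isodose volume; 1 means the isodose conforms exactly to the target.
    """
    region = dose.dose >= iso
    n_iso = int(region.sum())
    if n_iso == 0:
        raise EmptyIsodoseError(f"no voxel receives >= {iso} Gy; CI undefined")
    target = resample_mask(target, dose.grid)
    return int((target.occupancy & region).sum()) / n_iso
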