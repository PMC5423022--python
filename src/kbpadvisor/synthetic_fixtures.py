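"""Synthetic prostate anatomies, dose grids and cohort scatters.

Everything here produces data with known ground truth so that the geometry
engine, the sparing model and the cohort miner can be exercised end-to-end
without clinical data.

The anatomy emulates the trial-protocol geometry used for prostate VMAT:
a prostate sphere with seminal vesicles (SV) superior-posterior, three
concentric planning target volumes grown by anisotropic margins

* PTV3 = prostate + 5 mm isotropic (0 mm posteriorly),
* PTV2 = prostate (+ SV for high-risk patients) + 10 mm (5 mm posteriorly),
* PTV1 = prostate + SV + 10 mm isotropic,

a tubular rectum posterior to the prostate whose anteroposterior position
is solved by bisection so that the rectum-PTV1 overlap fraction hits a
requested target, plus a bladder, small bowel and femoral heads so plan
records are fully populated.  Axes: x right-left, y anterior-posterior
(posterior = -y), z inferior-superior.

The dose emulator is deliberately simple — prescription plateaus inside
the PTVs with exponential lateral falloff — and is then rescaled inside the
rectum so that the mean rectum dose equals (1 + delta_true) times the dose
a reference sparing curve predicts for the achieved overlap.  It is built
to make extraction round-trips exact, not to mimic VMAT physics.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .dose_geometry import DoseGrid, ROIMask, VoxelGrid, overlap_fraction
from .sparing_model import CohortPoint, SparingModel, predict, predict_dose


class InfeasibleSpecError(ValueError):
    """The requested phantom cannot be realised (overlap or dose target)."""


class GridOverflowError(ValueError):
    """A margin expansion would grow a structure beyond the grid."""


def default_grid() -> VoxelGrid:
    """2 mm lattice, 220 x 240 x 160 mm, centred on the prostate."""
    shape = (110, 120, 80)
    spacing = (2.0, 2.0, 2.0)
    origin = tuple(-(n - 1) * s / 2.0 for n, s in zip(shape, spacing))
    return VoxelGrid(origin=origin, spacing=spacing, shape=shape)


@dataclass(frozen=True)
class AnatomySpec:
    """Geometric recipe for one synthetic patient.

    ``target_overlap_frac`` is the requested rectum-PTV1 overlap fraction;
    the rectum's posterior offset is solved to achieve it within +/-0.02.
    ``seed`` drives small per-patient size jitter and is mandatory.
    """

    seed: int
    target_overlap_frac: float = 0.2
    risk_group: str = "HR"
    prostate_radius_mm: float = 20.0
    sv_radius_mm: float = 10.0
    rectum_radius_mm: float = 12.0
    rectum_length_mm: float = 80.0
    size_jitter: float = 0.05
    grid: VoxelGrid = field(default_factory=default_grid)
    overlap_tol: float = 0.02

    def __post_init__(self) -> None:
        if not 0 <= self.target_overlap_frac <= 0.8:
            raise ValueError("target overlap fraction must lie in [0, 0.8]")
        if self.risk_group not in ("HR", "LR"):
            raise ValueError(f"risk_group must be HR or LR, got {self.risk_group!r}")


@dataclass(frozen=True)
class DoseSpec:
    """Dose-emulator recipe: prescription, ground-truth delta, falloff, noise."""

    seed: int
    d_px: float = 74.0
    delta_true: float = 0.0
    falloff_mm: float = 8.0
    noise_sd: float = 0.3
    ptv2_dose: float = 71.0
    ptv1_dose: float = 59.2

    def __post_init__(self) -> None:
        if self.d_px <= 0:
            raise ValueError("prescription dose must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")


@dataclass(frozen=True)
class Anatomy:
    """Generated structure set plus the overlap actually achieved."""

    structures: dict[str, ROIMask]
    grid: VoxelGrid
    achieved_overlap: float
    spec: AnatomySpec


def _coords(grid: VoxelGrid):
    xs = grid.axis_coords(0)[:, None, None]
    ys = grid.axis_coords(1)[None, :, None]
    zs = grid.axis_coords(2)[None, None, :]
    return xs, ys, zs


def _sphere(grid: VoxelGrid, center, radius: float) -> np.ndarray:
    xs, ys, zs = _coords(grid)
    cx, cy, cz = center
    return (xs - cx) ** 2 + (ys - cy) ** 2 + (zs - cz) ** 2 <= radius**2


def _zcylinder(grid: VoxelGrid, center_xy, radius: float, z_half: float) -> np.ndarray:
    xs, ys, zs = _coords(grid)
    cx, cy = center_xy
    return ((xs - cx) ** 2 + (ys - cy) ** 2 <= radius**2) & (np.abs(zs) <= z_half)


def _margin_footprint(
    spacing, margin_mm, posterior_margin_mm: float
) -> np.ndarray:
    """Half-ellipsoid structuring element: the posterior (-y) half-space uses
    ``posterior_margin_mm`` instead of the y margin."""
    mx, my, mz = margin_mm
    radius_vox = [
        int(math.floor(max(mx, 0) / spacing[0])),
        int(math.floor(max(my, posterior_margin_mm, 0) / spacing[1])),
        int(math.floor(max(mz, 0) / spacing[2])),
    ]
    rx, ry, rz = radius_vox
    di = np.arange(-rx, rx + 1)[:, None, None] * spacing[0]
    dj = np.arange(-ry, ry + 1)[None, :, None] * spacing[1]
    dk = np.arange(-rz, rz + 1)[None, None, :] * spacing[2]
    my_eff = np.where(dj < 0, posterior_margin_mm, my)  # -y offsets expand posteriorly
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = (
            np.where(mx > 0, (di / mx) ** 2, np.where(di == 0, 0.0, np.inf))
            + np.where(my_eff > 0, (dj / my_eff) ** 2, np.where(dj == 0, 0.0, np.inf))
            + np.where(mz > 0, (dk / mz) ** 2, np.where(dk == 0, 0.0, np.inf))
        )
    return r2 <= 1.0 + 1e-12


def grow_margin(
    mask: ROIMask,
    margin_mm,
    posterior_margin_mm: float | None = None,
) -> ROIMask:
    """Anisotropic margin expansion (e.g. CTV-to-PTV growth).

    ``margin_mm`` is a scalar or per-axis 3-vector; the posterior half-space
    (offsets toward -y) is expanded by ``posterior_margin_mm`` instead
    (default: same as the y margin).  Raises GridOverflowError when the
    expansion reaches the grid boundary, since the structure would be
    truncated.
    """
    if np.isscalar(margin_mm):
        margin_vec = (float(margin_mm),) * 3
    else:
        margin_vec = tuple(float(v) for v in margin_mm)
    if len(margin_vec) != 3 or any(v < 0 for v in margin_vec):
        raise ValueError(f"margins must be non-negative, got {margin_mm}")
    if posterior_margin_mm is None:
        posterior_margin_mm = margin_vec[1]
    if posterior_margin_mm < 0:
        raise ValueError("posterior margin must be non-negative")

    footprint = _margin_footprint(mask.grid.spacing, margin_vec, posterior_margin_mm)
    if footprint.sum() <= 1 and max(*margin_vec, posterior_margin_mm) == 0:
        return mask
    grown = ndimage.binary_dilation(mask.occupancy, structure=footprint)
    boundary_hit = (
        grown[0, :, :].any()
        or grown[-1, :, :].any()
        or grown[:, 0, :].any()
        or grown[:, -1, :].any()
        or grown[:, :, 0].any()
        or grown[:, :, -1].any()
    )
    if boundary_hit and not _touches_boundary(mask.occupancy):
        raise GridOverflowError(
            f"margin expansion of {mask.roi_name!r} reaches the grid boundary"
        )
    return ROIMask(grid=mask.grid, occupancy=grown, roi_name=mask.roi_name)


def _touches_boundary(occ: np.ndarray) -> bool:
    return bool(
        occ[0].any()
        or occ[-1].any()
        or occ[:, 0, :].any()
        or occ[:, -1, :].any()
        or occ[:, :, 0].any()
        or occ[:, :, -1].any()
    )


def generate_anatomy(spec: AnatomySpec) -> Anatomy:
    """Build the structure set and place the rectum to hit the overlap target.

    The rectum tube's posterior offset from the prostate centre is solved by
    bisection on the measured rectum-PTV1 overlap fraction (tolerance
    ``spec.overlap_tol``, 50 iterations); overlap is monotone decreasing in
    the offset, so bisection is exact up to voxelization steps.
    """
    rng = np.random.default_rng(spec.seed)
    jitter = lambda: 1.0 + spec.size_jitter * rng.uniform(-1.0, 1.0)  # noqa: E731
    r_pro = spec.prostate_radius_mm * jitter()
    r_sv = spec.sv_radius_mm * jitter()
    r_rec = spec.rectum_radius_mm * jitter()
    grid = spec.grid

    prostate = _sphere(grid, (0.0, 0.0, 0.0), r_pro)
    sv = _sphere(grid, (0.0, -0.4 * r_pro, r_pro + 0.6 * r_sv), r_sv)
    pro_mask = ROIMask(grid=grid, occupancy=prostate, roi_name="prostate")
    pro_sv_mask = ROIMask(grid=grid, occupancy=prostate | sv, roi_name="prostate_sv")

    ptv3 = grow_margin(pro_mask, 5.0, posterior_margin_mm=0.0)
    ptv2_base = pro_sv_mask if spec.risk_group == "HR" else pro_mask
    ptv2 = grow_margin(ptv2_base, 10.0, posterior_margin_mm=5.0)
    ptv1 = grow_margin(pro_sv_mask, 10.0, posterior_margin_mm=10.0)

    z_half = spec.rectum_length_mm / 2.0

    def rectum_at(offset: float) -> ROIMask:
        occ = _zcylinder(grid, (0.0, -offset), r_rec, z_half)
        return ROIMask(grid=grid, occupancy=occ, roi_name="rectum")

    def overlap_at(offset: float) -> float:
        return overlap_fraction(rectum_at(offset), ptv1)

    lo, hi = 0.0, 70.0
    if spec.target_overlap_frac <= 0.0:
        offset = hi
        if overlap_at(offset) > 0:
            raise InfeasibleSpecError("cannot place rectum clear of PTV1 on this grid")
    else:
        f_lo = overlap_at(lo)
        if f_lo < spec.target_overlap_frac - spec.overlap_tol:
            raise InfeasibleSpecError(
                f"overlap target {spec.target_overlap_frac} unreachable; "
                f"maximum achievable is about {f_lo:.2f}"
            )
        offset = 0.5 * (lo + hi)
        for _ in range(50):
            f = overlap_at(offset)
            if abs(f - spec.target_overlap_frac) <= spec.overlap_tol:
                break
            if f > spec.target_overlap_frac:
                lo = offset
            else:
                hi = offset
            offset = 0.5 * (lo + hi)
        else:
            f = overlap_at(offset)
            if abs(f - spec.target_overlap_frac) > spec.overlap_tol:
                raise InfeasibleSpecError(
                    f"bisection failed to reach overlap {spec.target_overlap_frac} "
                    f"(best {f:.3f})"
                )
    rectum = rectum_at(offset)
    achieved = overlap_fraction(rectum, ptv1)

    bladder = _sphere(grid, (0.0, 0.9 * r_pro + 25.0, 10.0), 25.0)
    bowel = _sphere(grid, (0.0, 15.0, 55.0), 18.0)
    femhead_l = _sphere(grid, (52.0, 5.0, -5.0), 22.0)
    femhead_r = _sphere(grid, (-52.0, 5.0, -5.0), 22.0)

    structures = {
        "prostate": pro_mask,
        "sv": ROIMask(grid=grid, occupancy=sv, roi_name="sv"),
        "rectum": rectum,
        "ptv1": ptv1,
        "ptv2": ptv2,
        "ptv3": ptv3,
        "bladder": ROIMask(grid=grid, occupancy=bladder, roi_name="bladder"),
        "bowel": ROIMask(grid=grid, occupancy=bowel, roi_name="bowel"),
        "femhead_l": ROIMask(grid=grid, occupancy=femhead_l, roi_name="femhead_l"),
        "femhead_r": ROIMask(grid=grid, occupancy=femhead_r, roi_name="femhead_r"),
    }
    return Anatomy(structures=structures, grid=grid, achieved_overlap=achieved, spec=spec)


def generate_dose(
    anatomy: Anatomy, spec: DoseSpec, reference: SparingModel
) -> DoseGrid:
    """Emulated dose grid with a controlled mean rectum dose.

    Prescription plateaus inside PTV3/PTV2/PTV1 with exponential falloff
    outside each, Gaussian noise added everywhere, then the rectum voxels
    are rescaled so the mean rectum dose equals exactly
    (1 + delta_true) x predict_dose(reference, achieved_overlap, d_px).
    """
    grid = anatomy.grid
    levels = [
        ("ptv3", spec.d_px),
        ("ptv2", spec.ptv2_dose),
        ("ptv1", spec.ptv1_dose),
    ]
    dose = np.zeros(grid.shape, dtype=float)
    for name, level in levels:
        occ = anatomy.structures[name].occupancy
        if not occ.any():
            raise InfeasibleSpecError(f"structure {name!r} is empty")
        dist = ndimage.distance_transform_edt(~occ, sampling=grid.spacing)
        dose = np.maximum(dose, level * np.exp(-dist / spec.falloff_mm))

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        dose = dose + rng.normal(0.0, spec.noise_sd, size=dose.shape)
    dose = np.clip(dose, 0.0, None)

    rect = anatomy.structures["rectum"].occupancy
    target_mean = (1.0 + spec.delta_true) * predict_dose(
        reference, anatomy.achieved_overlap, spec.d_px
    )
    if target_mean <= 0:
        raise InfeasibleSpecError(
            f"delta_true={spec.delta_true} requires a non-positive mean rectum dose"
        )
    current = dose[rect].mean()
    if current <= 0:
        raise InfeasibleSpecError("base dose field is zero inside the rectum")
    dose[rect] *= target_mean / current
    return DoseGrid(grid=grid, dose=dose)


def generate_plan(
    anatomy_spec: AnatomySpec,
    dose_spec: DoseSpec,
    reference: SparingModel,
    patient_id: str = "SYN000",
    fractions: int = 37,
    total_mu: float = 430.0,
) -> tuple[dict[str, ROIMask], DoseGrid, dict]:
    """Convenience wrapper: anatomy + dose + plan metadata for one phantom."""
    anatomy = generate_anatomy(anatomy_spec)
    dose = generate_dose(anatomy, dose_spec, reference)
    plan_meta = {
        "patient_id": patient_id,
        "risk_group": anatomy_spec.risk_group,
        "d_px_gy": dose_spec.d_px,
        "fractions": fractions,
        "total_mu": total_mu,
    }
    return anatomy.structures, dose, plan_meta


def generate_cohort_points(
    n: int,
    model: SparingModel,
    noise_sd: float,
    overlap_range: tuple[float, float] = (0.0, 0.6),
    seed: int = 0,
) -> list[CohortPoint]:
    """Cohort scatter around a sparing curve.

    Overlap fractions are uniform over ``overlap_range``; normalised doses
    are the curve plus Gaussian noise, floored at 0.05; high/low risk labels
    alternate.
    """
    if n < 1:
        raise ValueError("need at least one point")
    lo, hi = overlap_range
    if not 0 <= lo <= hi <= 1:
        raise ValueError(f"overlap range must lie within [0, 1], got {overlap_range}")
    rng = np.random.default_rng(seed)
    v = rng.uniform(lo, hi, size=n)
    y = predict(model, v) + rng.normal(0.0, noise_sd, size=n)
    y = np.maximum(y, 0.05)
    return [
        CohortPoint(
            overlap_frac=float(v[i]),
            norm_dose=float(y[i]),
            patient_id=f"SYN{i:03d}",
            risk_group="HR" if i % 2 == 0 else "LR",
        )
        for i in range(n)
    ]
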