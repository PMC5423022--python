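"""Cohort-level plan-quality mining.

Reimplements the data-mining workflow: extract one row of dose/geometry
metrics per plan (PTV coverage, OAR mean doses, femoral-head D50, rectum Vx
levels, conformity indices, total MU, overlap fraction, relative model
excess delta), collect rows into labelled cohort tables, select validation
patients by delta, and compare cohorts metric-by-metric with Welch t-tests.

delta stored on a record is referenced to the OARD (lower-bound) curve; a
table-level toggle recomputes it against the MARD curve for analyses of the
cohort median.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from . import sparing_model as sm
from .dose_geometry import (
    DoseGrid,
    EmptyMaskError,
    ROIMask,
    conformity_index,
    cumulative_dvh,
    dose_at_volume,
    mean_dose,
    overlap_fraction,
    volume_at_dose,
)

RECTUM_VX_LEVELS_GY: tuple[float, ...] = (30.0, 40.0, 50.0, 60.0, 65.0, 70.0)
CI_LEVELS_GY: tuple[float, float] = (56.2, 40.0)

MANDATORY_ROIS = ("rectum", "bladder", "ptv1", "ptv2", "ptv3")
OPTIONAL_ROIS = ("bowel", "femhead_l", "femhead_r")


class MissingROIError(KeyError):
    """A mandatory structure is absent; ``missing`` lists the names."""

    def __init__(self, missing: list[str]):
        super().__init__(f"missing mandatory structures: {', '.join(missing)}")
        self.missing = missing


class DegenerateTestError(ValueError):
    """A t-test was requested on data with zero variance."""


@dataclass(frozen=True)
class PlanRecord:
    """One mined plan: identifiers, prescription, and plan-quality metrics.

    Optional organs (bowel, femoral heads) are ``None`` when absent from the
    structure set; cohort comparisons drop absent values pairwise.
    """

    patient_id: str
    risk_group: str
    d_px: float
    fractions: int
    overlap_frac: float
    mean_rectum: float
    mean_bladder: float
    ptv3_d99: float
    ptv3_d1: float
    ptv2_d99: float
    ptv1_d99: float
    total_mu: float
    ci_56_2: float
    ci_40_0: float
    rectum_vx: dict[float, float]
    delta: float
    ring1cm_mean: float
    mean_bowel: float | None = None
    femhead_d50_L: float | None = None
    femhead_d50_R: float | None = None

    def __post_init__(self) -> None:
        if self.fractions < 1:
            raise ValueError("fractions must be >= 1")
        levels = sorted(self.rectum_vx)
        vals = [self.rectum_vx[d] for d in levels]
        if np.any(np.diff(vals) > 1e-9):
            raise ValueError("rectum Vx fractions must be non-increasing in dose level")


@dataclass
class CohortTable:
    """A labelled list of plan records with unique patient ids."""

    records: list[PlanRecord] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate patient_id in cohort {self.label!r}")

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                f.name: getattr(r, f.name) for f in fields(PlanRecord) if f.name != "rectum_vx"
            }
            for level in RECTUM_VX_LEVELS_GY:
                row[f"rectum_v{level:g}"] = r.rectum_vx.get(level, np.nan)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, label: str = "") -> "CohortTable":
        df = pd.read_csv(path)
        records = []
        for _, row in df.iterrows():
            vx = {
                level: float(row[f"rectum_v{level:g}"])
                for level in RECTUM_VX_LEVELS_GY
                if f"rectum_v{level:g}" in row
            }
            kwargs = {}
            for f in fields(PlanRecord):
                if f.name == "rectum_vx":
                    continue
                value = row[f.name]
                if f.name in ("mean_bowel", "femhead_d50_L", "femhead_d50_R") and pd.isna(value):
                    value = None
                elif f.name == "fractions":
                    value = int(value)
                elif f.name in ("patient_id", "risk_group"):
                    value = str(value)
                else:
                    value = float(value)
                kwargs[f.name] = value
            records.append(PlanRecord(rectum_vx=vx, **kwargs))
        return cls(records=records, label=label)

    def with_delta_reference(self, pair: sm.ModelPair, reference: str = "mard") -> "CohortTable":
        """Recompute each record's delta against the chosen curve of ``pair``."""
        model = pair.mard if reference == "mard" else pair.oard
        out = []
        for r in self.records:
            pred = sm.predict_dose(model, r.overlap_frac, r.d_px)
            out.append(replace(r, delta=sm.relative_excess(r.mean_rectum, pred)))
        return CohortTable(records=out, label=self.label)


@dataclass(frozen=True)
class ComparisonRow:
    """One metric's pre/post cohort summary with a Welch t-test p-value."""

    metric: str
    mean_pre: float
    sd_pre: float
    mean_post: float
    sd_post: float
    p_value: float

    def __post_init__(self) -> None:
        if self.sd_pre < 0 or self.sd_post < 0:
            raise ValueError("standard deviations must be non-negative")
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value must lie in [0, 1]")


def extract_record(
    structures: dict[str, ROIMask],
    dose: DoseGrid,
    plan_meta: dict,
    pair: sm.ModelPair,
    bin_width: float = 0.1,
) -> PlanRecord:
    """Mine one plan into a PlanRecord using the voxel dosimetry engine.

    ``plan_meta`` must carry patient_id, risk_group, d_px_gy, fractions and
    total_mu.  Mandatory structures: rectum, bladder, ptv1, ptv2, ptv3;
    bowel and femoral heads are optional and left absent when missing.
    """
    missing = [name for name in MANDATORY_ROIS if name not in structures]
    if missing:
        raise MissingROIError(missing)

    d_px = float(plan_meta["d_px_gy"])
    rectum = structures["rectum"]
    v_ovr = overlap_fraction(rectum, structures["ptv1"])
    mean_rect = mean_dose(dose, rectum)
    oard_pred = sm.predict_dose(pair.oard, v_ovr, d_px)

    dvh_rect = cumulative_dvh(dose, rectum, bin_width)
    dvh_ptv3 = cumulative_dvh(dose, structures["ptv3"], bin_width)
    dvh_ptv2 = cumulative_dvh(dose, structures["ptv2"], bin_width)
    dvh_ptv1 = cumulative_dvh(dose, structures["ptv1"], bin_width)

    def optional_mean(name: str) -> float | None:
        if name not in structures or structures[name].is_empty():
            return None
        return mean_dose(dose, structures[name])

    def optional_d50(name: str) -> float | None:
        if name not in structures or structures[name].is_empty():
            return None
        return dose_at_volume(cumulative_dvh(dose, structures[name], bin_width), 50.0)

    return PlanRecord(
        patient_id=str(plan_meta["patient_id"]),
        risk_group=str(plan_meta["risk_group"]),
        d_px=d_px,
        fractions=int(plan_meta["fractions"]),
        overlap_frac=v_ovr,
        mean_rectum=mean_rect,
        mean_bladder=mean_dose(dose, structures["bladder"]),
        mean_bowel=optional_mean("bowel"),
        femhead_d50_L=optional_d50("femhead_l"),
        femhead_d50_R=optional_d50("femhead_r"),
        ptv3_d99=dose_at_volume(dvh_ptv3, 99.0),
        ptv3_d1=dose_at_volume(dvh_ptv3, 1.0),
        ptv2_d99=dose_at_volume(dvh_ptv2, 99.0),
        ptv1_d99=dose_at_volume(dvh_ptv1, 99.0),
        total_mu=float(plan_meta["total_mu"]),
        ci_56_2=conformity_index(dose, structures["ptv1"], CI_LEVELS_GY[0]),
        ci_40_0=conformity_index(dose, structures["ptv1"], CI_LEVELS_GY[1]),
        rectum_vx={level: volume_at_dose(dvh_rect, level) for level in RECTUM_VX_LEVELS_GY},
        delta=sm.relative_excess(mean_rect, oard_pred),
        ring1cm_mean=ring_mean_dose(dose, rectum),
    )


def ring_mean_dose(dose: DoseGrid, rectum: ROIMask, margin_mm: float = 10.0) -> float:
    """Mean dose in the shell within ``margin_mm`` of the organ, outside it.

    The shell is an isotropic Euclidean expansion (distance transform at
    grid resolution, measured from occupied-voxel centres) minus the organ.
    """
    if rectum.is_empty():
        raise EmptyMaskError("ring undefined for an empty organ mask")
    from .dose_geometry import resample_mask

    rectum = resample_mask(rectum, dose.grid)
    if rectum.is_empty():
        raise EmptyMaskError("organ mask empty after resampling to the dose grid")
    dist = ndimage.distance_transform_edt(
        ~rectum.occupancy, sampling=dose.grid.spacing
    )
    ring = (dist <= margin_mm) & ~rectum.occupancy
    if not ring.any():
        raise EmptyMaskError("expansion ring is empty (organ fills the grid)")
    return float(dose.dose[ring].mean())


def select_extremes(
    table: CohortTable, k_high: int, k_low: int
) -> tuple[list[str], list[str]]:
    """Validation-study selection: the ``k_high`` patients with the largest
    delta and, from the remainder, the ``k_low`` with delta closest to zero.

    Deterministic: ties break by ascending patient_id, and overlaps resolve
    in favour of the high set.  Invariant under permutation of the table.
    """
    if len(table) < k_high + k_low:
        raise ValueError(
            f"cohort of {len(table)} cannot supply {k_high}+{k_low} patients"
        )
    by_delta = sorted(table.records, key=lambda r: (-r.delta, r.patient_id))
    high = [r.patient_id for r in by_delta[:k_high]]
    rest = [r for r in table.records if r.patient_id not in set(high)]
    by_abs = sorted(rest, key=lambda r: (abs(r.delta), r.patient_id))
    low = [r.patient_id for r in by_abs[:k_low]]
    return high, low


def paired_test(clinical_deltas, replan_mean_deltas) -> tuple[float, float]:
    """One-tailed paired t-test that replanning reduced delta.

    Alternative hypothesis: replan < clinical.  Returns (t, one-tailed p)
    for the paired differences; zero variance of the differences raises.
    """
    clinical = np.asarray(clinical_deltas, dtype=float)
    replan = np.asarray(replan_mean_deltas, dtype=float)
    if clinical.shape != replan.shape or clinical.ndim != 1 or clinical.size < 2:
        raise ValueError("need two equal-length vectors with at least 2 pairs")
    diff = replan - clinical
    if np.isclose(np.std(diff, ddof=1), 0.0):
        raise DegenerateTestError("paired differences have zero variance")
    res = stats.ttest_rel(replan, clinical, alternative="less")
    return float(res.statistic), float(res.pvalue)


def compare_cohorts(pre: CohortTable, post: CohortTable, metric: str) -> ComparisonRow:
    """Welch two-sample two-tailed t-test on one metric of two cohorts.

    ``metric`` is a flattened column name (e.g. ``mean_rectum`` or
    ``rectum_v30``); absent values are dropped per cohort.
    """
    values = []
    for table in (pre, post):
        df = table.to_dataframe()
        if metric not in df.columns:
            raise KeyError(f"metric {metric!r} not present in cohort {table.label!r}")
        col = df[metric].dropna().to_numpy(dtype=float)
        if col.size == 0:
            raise ValueError(f"metric {metric!r} has no values in cohort {table.label!r}")
        values.append(col)
    a, b = values
    if np.isclose(a.std(ddof=1) if a.size > 1 else 0.0, 0.0) and np.isclose(
        b.std(ddof=1) if b.size > 1 else 0.0, 0.0
    ):
        # degenerate Welch test: identical constants compare equal
        p = 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return ComparisonRow(
        metric=metric,
        mean_pre=float(a.mean()),
        sd_pre=float(a.std(ddof=1)) if a.size > 1 else 0.0,
        mean_post=float(b.mean()),
        sd_post=float(b.std(ddof=1)) if b.size > 1 else 0.0,
        p_value=p,
    )


DEFAULT_COMPARISON_METRICS: tuple[str, ...] = (
    "ptv3_d99",
    "ptv3_d1",
    "ptv2_d99",
    "ptv1_d99",
    "total_mu",
    "mean_bladder",
    "mean_rectum",
    "mean_bowel",
    "femhead_d50_L",
    "femhead_d50_R",
    "ci_56_2",
    "ci_40_0",
    "delta",
    "rectum_v30",
    "rectum_v40",
    "rectum_v50",
    "rectum_v60",
    "rectum_v65",
    "rectum_v70",
)


def compare_all(
    pre: CohortTable, post: CohortTable, metrics=DEFAULT_COMPARISON_METRICS
) -> pd.DataFrame:
    """Population-averaged comparison table: one Welch-test row per metric."""
    rows = [compare_cohorts(pre, post, m) for m in metrics]
    return pd.DataFrame(
        [
            {
                "metric": r.metric,
                "mean_pre": r.mean_pre,
                "sd_pre": r.sd_pre,
                "mean_post": r.mean_post,
                "sd_post": r.sd_post,
                "p_value": r.p_value,
            }
            for r in rows
        ]
    )
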