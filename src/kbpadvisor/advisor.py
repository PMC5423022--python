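"""Plan advisor: the clinical knowledge-based planning workflow.

Given a plan's structure set and dose, the advisor measures the rectum-PTV1
overlap fraction, predicts the achievable (OARD) and median (MARD) mean
rectum doses from the sparing-curve pair, classifies the current mean
rectum dose as OPTIMAL / ACCEPTABLE / NOT_ACCEPTABLE, and evaluates
configured guardrail goals (PTV3 coverage, low-dose conformity, a total-MU
ceiling) that keep the advice from degrading other plan-quality metrics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from . import sparing_model as sm
from .cohort_miner import MissingROIError
from .dose_geometry import (
    DoseGrid,
    ROIMask,
    conformity_index,
    cumulative_dvh,
    dose_at_volume,
    mean_dose,
    overlap_fraction,
)

DEFAULT_MU_CEILING = 600.0


@dataclass(frozen=True)
class Guardrail:
    """One auxiliary clinical goal: name, target, achieved value, pass flag."""

    name: str
    target: float
    achieved: float
    passed: bool


@dataclass(frozen=True)
class AdvisorReport:
    """The advisor's payload: predictions, verdict and guardrail outcomes."""

    prescription: float
    fractions: int
    overlap_frac: float
    current_mean_rectum: float
    oard_dose: float
    mard_dose: float
    verdict: sm.Verdict
    guardrails: tuple[Guardrail, ...] = ()

    def __post_init__(self) -> None:
        if self.mard_dose < self.oard_dose:
            raise ValueError("MARD dose must be >= OARD dose")


def advise(
    structures: dict[str, ROIMask],
    dose: DoseGrid,
    plan_meta: dict,
    pair: sm.ModelPair,
    guardrail_config: dict | None = None,
    bin_width: float = 0.1,
) -> AdvisorReport:
    """Run the knowledge-based planning check on one plan.

    ``guardrail_config`` keys (all optional): ``max_total_mu`` (default
    600 MU), ``min_ptv3_d99_gy`` and ``min_ci_56_2`` / ``min_ci_40_0``
    (checked only when provided — locally routine values, no universal
    default).
    """
    missing = [name for name in ("rectum", "ptv1") if name not in structures]
    if "dose" if dose is None else False:  # pragma: no cover - defensive
        missing.append("dose")
    if missing:
        raise MissingROIError(missing)

    cfg = dict(guardrail_config or {})
    d_px = float(plan_meta["d_px_gy"])
    v_ovr = overlap_fraction(structures["rectum"], structures["ptv1"])
    d_mean = mean_dose(dose, structures["rectum"])
    verdict = sm.classify(d_mean, pair, v_ovr, d_px)

    guardrails: list[Guardrail] = []
    mu_ceiling = float(cfg.pop("max_total_mu", DEFAULT_MU_CEILING))
    total_mu = float(plan_meta.get("total_mu", 0.0))
    guardrails.append(
        Guardrail("total_mu_le", mu_ceiling, total_mu, total_mu <= mu_ceiling)
    )
    if "min_ptv3_d99_gy" in cfg:
        if "ptv3" not in structures:
            raise MissingROIError(["ptv3"])
        target = float(cfg.pop("min_ptv3_d99_gy"))
        achieved = dose_at_volume(cumulative_dvh(dose, structures["ptv3"], bin_width), 99.0)
        guardrails.append(Guardrail("ptv3_d99_ge", target, achieved, achieved >= target))
    for key, iso in (("min_ci_56_2", 56.2), ("min_ci_40_0", 40.0)):
        if key in cfg:
            target = float(cfg.pop(key))
            achieved = conformity_index(dose, structures["ptv1"], iso)
            guardrails.append(
                Guardrail(f"ci_{iso:g}_ge", target, achieved, achieved >= target)
            )
    if cfg:
        raise ValueError(f"unknown guardrail keys: {sorted(cfg)}")

    return AdvisorReport(
        prescription=d_px,
        fractions=int(plan_meta["fractions"]),
        overlap_frac=v_ovr,
        current_mean_rectum=d_mean,
        oard_dose=verdict.oard_dose,
        mard_dose=verdict.mard_dose,
        verdict=verdict,
        guardrails=tuple(guardrails),
    )


def _report_dict(report: AdvisorReport) -> dict:
    return {
        "prescription_gy": report.prescription,
        "fractions": report.fractions,
        "overlap_frac": report.overlap_frac,
        "current_mean_rectum_gy": report.current_mean_rectum,
        "oard_dose_gy": report.oard_dose,
        "mard_dose_gy": report.mard_dose,
        "verdict": {
            "category": report.verdict.category.value,
            "d_mean": report.verdict.d_mean,
            "oard_dose": report.verdict.oard_dose,
            "mard_dose": report.verdict.mard_dose,
            "delta": report.verdict.delta,
        },
        "guardrails": [
            {"name": g.name, "target": g.target, "achieved": g.achieved, "passed": g.passed}
            for g in report.guardrails
        ],
    }


def render_report(report: AdvisorReport, format: str = "text") -> str:
    """Serialize a report deterministically as ``text`` or ``json``."""
    if format == "json":
        return json.dumps(_report_dict(report), indent=1, sort_keys=True)
    if format != "text":
        raise ValueError(f"unknown format {format!r}; use 'text' or 'json'")
    v = report.verdict
    lines = [
        "knowledge-based plan check",
        f"  prescription:        {report.prescription:.1f} Gy in {report.fractions} fractions",
        f"  rectum-PTV1 overlap: {report.overlap_frac:.3f}",
        f"  mean rectum dose:    {report.current_mean_rectum:.2f} Gy",
        f"  OARD prediction:     {report.oard_dose:.2f} Gy",
        f"  MARD prediction:     {report.mard_dose:.2f} Gy",
        f"  relative excess:     {v.delta:+.3f}",
        f"  verdict:             {v.category.value}",
    ]
    if report.guardrails:
        lines.append("  guardrails:")
        for g in report.guardrails:
            status = "pass" if g.passed else "FAIL"
            lines.append(
                f"    {g.name}: target {g.target:g}, achieved {g.achieved:g} [{status}]"
            )
    return "\n".join(lines) + "\n"


def parse_report(serialized: str) -> AdvisorReport:
    """Inverse of ``render_report(..., format='json')``."""
    d = json.loads(serialized)
    verdict = sm.Verdict(
        category=sm.PlanCategory(d["verdict"]["category"]),
        d_mean=d["verdict"]["d_mean"],
        oard_dose=d["verdict"]["oard_dose"],
        mard_dose=d["verdict"]["mard_dose"],
        delta=d["verdict"]["delta"],
    )
    return AdvisorReport(
        prescription=d["prescription_gy"],
        fractions=d["fractions"],
        overlap_frac=d["overlap_frac"],
        current_mean_rectum=d["current_mean_rectum_gy"],
        oard_dose=d["oard_dose_gy"],
        mard_dose=d["mard_dose_gy"],
        verdict=verdict,
        guardrails=tuple(
            Guardrail(g["name"], g["target"], g["achieved"], g["passed"])
            for g in d["guardrails"]
        ),
    )
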