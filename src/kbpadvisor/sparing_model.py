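"""Rectum-sparing prediction model and plan-quality verdicts.

The achievable mean rectum dose of a prostate VMAT plan, normalised to the
primary prescription dose D_Px, is modelled as a saturating exponential in
the fractional rectum-PTV overlap v = V_ovr / V_rec:

    D_mean / D_Px = A + B * (1 - exp(C * v)),        B > 0, C < 0

At zero overlap the prediction is A; as the overlap grows it saturates
towards A + B.  Two curves with shared shape (B, C) but different offsets A
summarise a historical cohort: the lower-bound "optimal average rectum
dose" (OARD) curve and the through-the-middle "median average rectum dose"
(MARD) curve.  A plan's gap to a prediction is the relative model excess

    delta = (D_mean - D_pred) / D_pred

which is dimensionless and insensitive to prescription or absolute overlap
volume.  A plan is OPTIMAL when its mean rectum dose is at or below the
OARD prediction, NOT_ACCEPTABLE when above the MARD prediction, and
ACCEPTABLE in between.

The historical curves were originally adjusted by eye; here the fit is a
reproducible surrogate: quantile (pinball-loss) regression, with the MARD
curve fitted at the median and the OARD curve refitted at a low quantile
with the MARD shape parameters frozen.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize


class PlanCategory(enum.Enum):
    NOT_ACCEPTABLE = "NOT_ACCEPTABLE"
    ACCEPTABLE = "ACCEPTABLE"
    OPTIMAL = "OPTIMAL"


class FitError(RuntimeError):
    """Quantile fit failed to converge; ``best`` carries the last iterate."""

    def __init__(self, message: str, best: "SparingModel | None" = None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class SparingModel:
    """Coefficients (A, B, C) of the exponential sparing curve."""

    A: float
    B: float
    C: float

    def __post_init__(self) -> None:
        if not 0 < self.A < 1:
            raise ValueError(f"A must lie in (0, 1), got {self.A}")
        if self.B <= 0:
            raise ValueError(f"B must be positive, got {self.B}")
        if self.C >= 0:
            raise ValueError(f"C must be negative, got {self.C}")
        if self.A + self.B > 1.5:
            raise ValueError(f"A + B = {self.A + self.B} exceeds the sanity bound 1.5")


def predict(model: SparingModel, overlap_frac):
    """Normalised mean rectum dose A + B*(1 - exp(C*v)) at overlap v in [0, 1]."""
    v = np.asarray(overlap_frac, dtype=float)
    if np.any(v < 0) or np.any(v > 1):
        raise ValueError(f"overlap fraction must lie in [0, 1], got {overlap_frac}")
    out = model.A + model.B * (1.0 - np.exp(model.C * v))
    return float(out) if np.isscalar(overlap_frac) else out


def predict_dose(model: SparingModel, overlap_frac, d_px: float):
    """Predicted mean rectum dose in Gy: predict(v) x prescription dose."""
    if d_px <= 0:
        raise ValueError(f"prescription dose must be positive, got {d_px}")
    return predict(model, overlap_frac) * d_px


def relative_excess(d_mean: float, d_pred: float) -> float:
    """Relative model excess delta = (D_mean - D_pred) / D_pred."""
    if d_pred <= 0:
        raise ValueError(f"predicted dose must be positive, got {d_pred}")
    return (d_mean - d_pred) / d_pred


@dataclass(frozen=True)
class ModelPair:
    """An OARD (lower-bound) and MARD (median) curve sharing B and C."""

    oard: SparingModel
    mard: SparingModel

    def __post_init__(self) -> None:
        grid = np.arange(0.0, 1.0 + 1e-9, 0.01)
        if np.any(predict(self.mard, grid) < predict(self.oard, grid) - 1e-12):
            raise ValueError("MARD curve must dominate the OARD curve on [0, 1]")


@dataclass(frozen=True)
class CohortPoint:
    """One plan of the mined cohort in normalised coordinates."""

    overlap_frac: float
    norm_dose: float
    patient_id: str = ""
    risk_group: str = "HR"

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_frac <= 1:
            raise ValueError(f"overlap_frac must lie in [0, 1], got {self.overlap_frac}")
        if not 0 < self.norm_dose < 1.5:
            raise ValueError(f"norm_dose must lie in (0, 1.5), got {self.norm_dose}")
        if self.risk_group not in ("HR", "LR"):
            raise ValueError(f"risk_group must be HR or LR, got {self.risk_group!r}")


@dataclass(frozen=True)
class Verdict:
    """Three-way plan classification with the doses it was judged against."""

    category: PlanCategory
    d_mean: float
    oard_dose: float
    mard_dose: float
    delta: float


def _pinball(residuals: np.ndarray, q: float) -> float:
    return float(np.mean(np.where(residuals >= 0, q * residuals, (q - 1) * residuals)))


def _points_to_arrays(points) -> tuple[np.ndarray, np.ndarray]:
    v = np.array([p.overlap_frac for p in points], dtype=float)
    y = np.array([p.norm_dose for p in points], dtype=float)
    return v, y


def fit_quantile(
    points,
    q: float,
    init: SparingModel | None = None,
    fix_BC: SparingModel | None = None,
    max_iter: int = 4000,
) -> SparingModel:
    """Fit the sparing curve to the q-th quantile of a cohort scatter.

    Minimises the pinball loss of the residuals norm_dose - predict(v) at
    quantile ``q``, subject to the coefficient constraints.  With ``fix_BC``
    given, B and C are frozen to that model's values and the optimal offset
    A is the q-quantile of the partial residuals (closed form).  The full
    three-parameter fit is a bounded Nelder-Mead search from ``init`` and is
    deterministic for a given init.
    """
    if not 0 < q < 1:
        raise ValueError(f"quantile must lie in (0, 1), got {q}")
    if len(points) < 10:
        raise ValueError(f"need at least 10 cohort points, got {len(points)}")
    v, y = _points_to_arrays(points)

    if fix_BC is not None:
        b, c = fix_BC.B, fix_BC.C
        partial = y - b * (1.0 - np.exp(c * v))
        a = float(np.quantile(partial, q))
        try:
            return SparingModel(A=a, B=b, C=c)
        except ValueError as exc:
            raise FitError(f"closed-form offset fit left the model invalid: {exc}") from exc

    if init is None:
        init = SparingModel(A=0.3, B=0.5, C=-2.0)

    def loss(theta: np.ndarray) -> float:
        a, b, c = theta
        resid = y - (a + b * (1.0 - np.exp(c * v)))
        penalty = 1e3 * max(0.0, a + b - 1.5) ** 2
        return _pinball(resid, q) + penalty

    eps = 1e-6
    res = minimize(
        loss,
        x0=np.array([init.A, init.B, init.C]),
        method="Nelder-Mead",
        bounds=[(eps, 1 - eps), (eps, 1.5), (-10.0, -eps)],
        options={"maxiter": max_iter, "xatol": 1e-6, "fatol": 1e-10},
    )
    a, b, c = res.x
    try:
        model = SparingModel(A=float(a), B=float(b), C=float(c))
    except ValueError as exc:
        raise FitError(f"fit terminated on an invalid model: {exc}") from exc
    if not res.success:
        raise FitError(f"quantile fit did not converge: {res.message}", best=model)
    return model


def fit_pair(
    points,
    q_oard: float = 0.10,
    q_mard: float = 0.50,
    init: SparingModel | None = None,
) -> ModelPair:
    """Fit the MARD/OARD curve pair to a cohort scatter.

    The MARD curve is fitted first with all three coefficients free at
    ``q_mard``; the OARD curve is then refitted at ``q_oard`` with B and C
    frozen to the MARD values, so the pair differs only in the offset A.
    """
    if not 0 < q_oard < q_mard < 1:
        raise ValueError(
            f"need 0 < q_oard < q_mard < 1, got q_oard={q_oard}, q_mard={q_mard}"
        )
    mard = fit_quantile(points, q=q_mard, init=init)
    oard = fit_quantile(points, q=q_oard, fix_BC=mard)
    return ModelPair(oard=oard, mard=mard)


def classify(
    d_mean: float,
    pair: ModelPair,
    overlap_frac: float,
    d_px: float,
    reference: str = "oard",
) -> Verdict:
    """Three-way verdict on a plan's mean rectum dose.

    OPTIMAL iff D_mean <= OARD prediction; NOT_ACCEPTABLE iff D_mean > MARD
    prediction; ACCEPTABLE in between (equality with the MARD prediction is
    still acceptable).  ``delta`` is the relative model excess against the
    OARD prediction by default; ``reference="mard"`` switches it.
    """
    oard_dose = predict_dose(pair.oard, overlap_frac, d_px)
    mard_dose = predict_dose(pair.mard, overlap_frac, d_px)
    # boundary comparisons carry a 1e-9 relative tolerance so that a mean
    # dose physically equal to a prediction classifies deterministically
    # regardless of float rounding in the dose pipeline
    tol = 1e-9
    if d_mean <= oard_dose * (1 + tol):
        category = PlanCategory.OPTIMAL
    elif d_mean <= mard_dose * (1 + tol):
        category = PlanCategory.ACCEPTABLE
    else:
        category = PlanCategory.NOT_ACCEPTABLE
    if reference not in ("oard", "mard"):
        raise ValueError(f"reference must be 'oard' or 'mard', got {reference!r}")
    ref_dose = oard_dose if reference == "oard" else mard_dose
    return Verdict(
        category=category,
        d_mean=float(d_mean),
        oard_dose=oard_dose,
        mard_dose=mard_dose,
        delta=relative_excess(d_mean, ref_dose),
    )


def shift_offset(model: SparingModel, da: float) -> SparingModel:
    """The same curve shape with the offset A shifted by ``da``."""
    return replace(model, A=model.A + da)
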