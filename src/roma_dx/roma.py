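"""ROMA: the Risk of Ovarian Malignancy Algorithm.

ROMA combines serum HE4 (pM) and CA125 (U/ml) with menopausal status into a
logistic risk score for epithelial ovarian cancer. For each subject a
predictive index (PI, a log-odds score) is computed with menopause-specific
coefficients,

    pre-menopausal:   PI = -12.0 + 2.38 * ln(HE4) + 0.0626 * ln(CA125)
    post-menopausal:  PI = -8.09 + 1.04 * ln(HE4) + 0.732  * ln(CA125)

and mapped to a predicted probability on the percent scale,

    PP = 100 * exp(PI) / (1 + exp(PI)).

A subject is classified high risk when PP is at or above the
menopause-specific threshold (12.5% pre-menopausal, 14.4% post-menopausal;
the bound is closed: PP equal to the threshold is high risk). Single-marker
classifiers at fixed cutoffs (CA125 35 U/ml; HE4 70 pM or 150 pM) follow the
same closed-bound convention.

Coefficients, thresholds and cutoffs are configuration, not constants, so
alternative (e.g. cohort-specific best-accuracy) values can be swapped in
for sensitivity analyses. All scalar operations also accept numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import special

from .cohort import Cohort, MenopausalStatus

__all__ = [
    "RomaCoefficients",
    "RomaThresholds",
    "MarkerCutoffs",
    "RiskClass",
    "RomaResult",
    "PRE_COEFFICIENTS",
    "POST_COEFFICIENTS",
    "DEFAULT_THRESHOLDS",
    "DEFAULT_CUTOFFS",
    "compute_pi",
    "compute_pp",
    "classify_roma",
    "classify_marker",
    "score_record",
    "score_cohort",
    "cohort_pp",
]


@dataclass(frozen=True)
class RomaCoefficients:
    """Coefficients of the predictive index: PI = intercept + he4_coef*ln(HE4) + ca125_coef*ln(CA125)."""

    intercept: float
    he4_coef: float
    ca125_coef: float


#: Published pre-menopausal coefficients.
PRE_COEFFICIENTS = RomaCoefficients(intercept=-12.0, he4_coef=2.38, ca125_coef=0.0626)
#: Published post-menopausal coefficients.
POST_COEFFICIENTS = RomaCoefficients(intercept=-8.09, he4_coef=1.04, ca125_coef=0.732)


@dataclass(frozen=True)
class RomaThresholds:
    """High-risk PP thresholds (%, closed lower bound) by menopausal status."""

    pre_pct: float = 12.5
    post_pct: float = 14.4

    def __post_init__(self) -> None:
        for v in (self.pre_pct, self.post_pct):
            if not 0.0 < v < 100.0:
                raise ValueError(f"threshold must lie in (0, 100), got {v}")

    def for_status(self, status: MenopausalStatus) -> float:
        return self.pre_pct if status is MenopausalStatus.PRE else self.post_pct


@dataclass(frozen=True)
class MarkerCutoffs:
    """Fixed single-marker cutoffs: CA125 upper normal limit and the two
    suggested HE4 cutoffs (70 pM and the 150 pM product-insert value)."""

    ca125_u_ml: float = 35.0
    he4_pm_moore: float = 70.0
    he4_pm_insert: float = 150.0

    def __post_init__(self) -> None:
        for v in (self.ca125_u_ml, self.he4_pm_moore, self.he4_pm_insert):
            if v <= 0:
                raise ValueError("marker cutoffs must be strictly positive")


DEFAULT_THRESHOLDS = RomaThresholds()
DEFAULT_CUTOFFS = MarkerCutoffs()


class RiskClass(str, Enum):
    LOW = "low"
    HIGH = "high"


@dataclass(frozen=True)
class RomaResult:
    """ROMA output for one subject: log-odds PI, percent-scale PP, risk class."""

    pi: float
    pp: float
    risk_class: RiskClass


def _coefs_for(
    status: MenopausalStatus,
    coefs: RomaCoefficients | None,
) -> RomaCoefficients:
    if coefs is not None:
        return coefs
    return PRE_COEFFICIENTS if status is MenopausalStatus.PRE else POST_COEFFICIENTS


def compute_pi(he4, ca125, status: MenopausalStatus, coefs: RomaCoefficients | None = None):
    """Predictive index (log-odds) for the given markers and menopausal status.

    ``he4`` (pM) and ``ca125`` (U/ml) must be strictly positive; scalars or
    arrays. ``coefs`` overrides the published status-specific coefficients.
    """
    he4 = np.asarray(he4, dtype=float)
    ca125 = np.asarray(ca125, dtype=float)
    if np.any(he4 <= 0) or np.any(ca125 <= 0):
        raise ValueError("marker values must be strictly positive (ln is taken)")
    c = _coefs_for(status, coefs)
    pi = c.intercept + c.he4_coef * np.log(he4) + c.ca125_coef * np.log(ca125)
    return pi if pi.ndim else float(pi)


def compute_pp(pi):
    """Predicted probability in percent: 100 * exp(PI)/(1 + exp(PI)).

    Computed with the stable logistic (scipy ``expit``): never overflows,
    and stays strictly inside (0, 100) for any PI the markers can produce.
    """
    pi = np.asarray(pi, dtype=float)
    if not np.all(np.isfinite(pi)):
        raise ValueError("predictive index must be finite")
    pp = 100.0 * special.expit(pi)
    return pp if pp.ndim else float(pp)


def classify_roma(
    pp,
    status: MenopausalStatus,
    thresholds: RomaThresholds = DEFAULT_THRESHOLDS,
):
    """Dichotomize PP at the status-specific threshold (high iff PP >= threshold)."""
    t = thresholds.for_status(status)
    pp = np.asarray(pp, dtype=float)
    high = pp >= t
    if high.ndim:
        return np.where(high, RiskClass.HIGH, RiskClass.LOW)
    return RiskClass.HIGH if high else RiskClass.LOW


def classify_marker(value, cutoff: float) -> bool:
    """Single-marker test: positive iff value >= cutoff (closed bound)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be strictly positive")
    value = np.asarray(value, dtype=float)
    if np.any(value <= 0):
        raise ValueError("marker value must be strictly positive")
    pos = value >= cutoff
    return pos if pos.ndim else bool(pos)


def score_record(
    record,
    coefs: RomaCoefficients | None = None,
    thresholds: RomaThresholds = DEFAULT_THRESHOLDS,
) -> RomaResult:
    """Score a single :class:`~roma_dx.cohort.PatientRecord`."""
    try:
        pi = compute_pi(record.he4, record.ca125, record.menopausal_status, coefs)
    except ValueError as exc:
        raise ValueError(f"record {record.id!r}: {exc}") from None
    pp = compute_pp(pi)
    return RomaResult(pi=pi, pp=pp, risk_class=classify_roma(pp, record.menopausal_status, thresholds))


def score_cohort(
    cohort: Cohort,
    coefs: RomaCoefficients | None = None,
    thresholds: RomaThresholds = DEFAULT_THRESHOLDS,
) -> list[RomaResult]:
    """Score every record; order preserved, element-wise equal to the scalar path."""
    return [score_record(r, coefs, thresholds) for r in cohort]


def cohort_pp(cohort: Cohort, thresholds: RomaThresholds = DEFAULT_THRESHOLDS) -> np.ndarray:
    """Vectorized PP (%) for a whole cohort, using each subject's own
    menopause-specific coefficients; one value per record, order preserved."""
    n = len(cohort)
    pp = np.empty(n, dtype=float)
    if n == 0:
        return pp
    he4 = np.array([r.he4 for r in cohort])
    ca125 = np.array([r.ca125 for r in cohort])
    pre = np.array([r.menopausal_status is MenopausalStatus.PRE for r in cohort])
    for status, mask in ((MenopausalStatus.PRE, pre), (MenopausalStatus.POST, ~pre)):
        if mask.any():
            pp[mask] = compute_pp(compute_pi(he4[mask], ca125[mask], status))
    return pp
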