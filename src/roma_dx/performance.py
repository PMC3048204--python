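"""Empirical ROC analysis, AUC estimation and paired comparison, and
best-accuracy cutoff search for diagnostic markers.

Conventions
-----------
* A subject is called test-positive iff its score is **at or above** the
  cutoff (closed bound, matching the ROMA risk classification).
* The AUC is the Mann-Whitney pair-counting estimate: the probability that a
  random diseased subject outscores a random non-diseased subject, ties
  counted half. This equals the trapezoidal area under the empirical ROC.
* Confidence intervals and the paired AUC-difference test use the
  nonparametric placement-value (DeLong-type) variance/covariance with a
  normal approximation. Degenerate cases (zero variance) are flagged rather
  than silently clipped.
* The best-accuracy ("ideal") cutoff is found by exhaustive search over every
  distinct observed score plus a +inf all-negative sentinel; ties in accuracy
  are broken by higher Youden index (sens + spec - 1), then by the smaller
  cutoff, so the result is deterministic.

Labels may be given as booleans (True = diseased), 0/1 integers, or
:class:`~roma_dx.cohort.DiagnosisClass` values (malignant = diseased).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import DiagnosisClass

__all__ = [
    "ConfusionMatrix",
    "RocCurve",
    "AucEstimate",
    "AucComparison",
    "CutoffSearchResult",
    "confusion_at_cutoff",
    "roc_curve",
    "auc_mann_whitney",
    "auc_confidence_interval",
    "compare_paired_aucs",
    "find_ideal_cutoff",
    "sensitivity_specificity_at",
]


def _as_binary(labels) -> np.ndarray:
    """Coerce labels to a boolean array with True = diseased (malignant)."""
    labels = np.asarray(labels)
    if labels.dtype == bool:
        return labels
    if labels.dtype.kind in "iuf":
        return labels.astype(bool)
    out = np.empty(labels.shape, dtype=bool)
    for i, v in enumerate(labels.ravel()):
        if isinstance(v, DiagnosisClass):
            out.ravel()[i] = v is DiagnosisClass.MALIGNANT
        elif v in ("malignant", "benign"):
            out.ravel()[i] = v == "malignant"
        else:
            raise ValueError(f"cannot interpret label {v!r}")
    return out


def _split(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    if scores.shape != y.shape:
        raise ValueError("scores and labels must be aligned")
    cases, controls = scores[y], scores[~y]
    if len(cases) == 0:
        raise ValueError("no diseased (malignant) subjects in input")
    if len(controls) == 0:
        raise ValueError("no non-diseased (benign) subjects in input")
    return cases, controls


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        """True-positive rate among diseased, as a fraction."""
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        """True-negative rate among non-diseased, as a fraction."""
        return self.tn / (self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC: one point per distinct cutoff, plus the (0,0)/(1,1) ends.

    ``thresholds`` are decreasing; ``sens`` and ``one_minus_spec`` are
    non-decreasing, with endpoints (0,0) (cutoff +inf) and (1,1) (cutoff
    below the minimum score).
    """

    thresholds: np.ndarray
    sens: np.ndarray
    one_minus_spec: np.ndarray

    def trapezoidal_auc(self) -> float:
        return float(np.trapezoid(self.sens, self.one_minus_spec))


@dataclass(frozen=True)
class AucEstimate:
    auc: float
    ci_low: float
    ci_high: float
    method: str
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.ci_low <= self.auc <= self.ci_high:
            raise ValueError("CI must bracket the AUC")


@dataclass(frozen=True)
class AucComparison:
    auc_a: float
    auc_b: float
    delta: float
    se_delta: float
    z: float
    p: float
    method: str = "paired placement-value (DeLong-type) covariance, normal approximation"
    degenerate: bool = False


@dataclass(frozen=True)
class CutoffSearchResult:
    """Best-accuracy cutoff with its operating characteristics (percent)."""

    cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float


def confusion_at_cutoff(scores, labels, cutoff: float) -> ConfusionMatrix:
    """Confusion matrix calling positive iff score >= cutoff."""
    cases, controls = _split(scores, labels)
    tp = int(np.count_nonzero(cases >= cutoff))
    fp = int(np.count_nonzero(controls >= cutoff))
    return ConfusionMatrix(tp=tp, fp=fp, tn=len(controls) - fp, fn=len(cases) - tp)


def roc_curve(scores, labels) -> RocCurve:
    """Empirical ROC over all distinct observed cutoffs (>= convention)."""
    cases, controls = _split(scores, labels)
    n1, n0 = len(cases), len(controls)
    cuts = np.unique(np.concatenate([cases, controls]))[::-1]
    # positives at cutoff c: count of scores >= c, via sorted cumulative counts
    sens = np.array([np.count_nonzero(cases >= c) for c in cuts]) / n1
    fpr = np.array([np.count_nonzero(controls >= c) for c in cuts]) / n0
    thresholds = np.concatenate([[np.inf], cuts])
    sens = np.concatenate([[0.0], sens])
    fpr = np.concatenate([[0.0], fpr])
    if sens[-1] != 1.0 or fpr[-1] != 1.0:  # only when min score not shared
        thresholds = np.concatenate([thresholds, [-np.inf]])
        sens = np.concatenate([sens, [1.0]])
        fpr = np.concatenate([fpr, [1.0]])
    return RocCurve(thresholds=thresholds, sens=sens, one_minus_spec=fpr)


def _placements(cases: np.ndarray, controls: np.ndarray):
    """Per-subject placement values and the AUC.

    ``v10[i]`` is the fraction of controls scoring below case i (ties half);
    ``v01[j]`` the fraction of cases scoring above control j. The AUC is the
    mean of either vector.
    """
    m, n = len(cases), len(controls)
    combined = np.concatenate([cases, controls])
    rz = stats.rankdata(combined)
    rx = stats.rankdata(cases)
    ry = stats.rankdata(controls)
    v10 = (rz[:m] - rx) / n
    v01 = 1.0 - (rz[m:] - ry) / m
    auc = float(v10.mean())
    return v10, v01, auc


def auc_mann_whitney(scores, labels) -> AucEstimate:
    """Point-estimate AUC by pair counting (ties counted half)."""
    cases, controls = _split(scores, labels)
    _, _, auc = _placements(cases, controls)
    return AucEstimate(auc=auc, ci_low=auc, ci_high=auc, method="mann-whitney point estimate")


def auc_confidence_interval(scores, labels, level: float = 0.95) -> AucEstimate:
    """AUC with a normal-approximation CI from the placement-value variance.

    The CI is clipped to [0, 1]. When the empirical variance is zero (e.g.
    perfect separation), the point CI is returned with ``degenerate=True``.
    """
    cases, controls = _split(scores, labels)
    m, n = len(cases), len(controls)
    if m < 2 or n < 2:
        raise ValueError("need at least 2 subjects per class for a CI")
    v10, v01, auc = _placements(cases, controls)
    var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    method = "placement-value (DeLong) variance, normal approximation"
    if var <= 0.0:
        return AucEstimate(auc=auc, ci_low=auc, ci_high=auc, method=method, degenerate=True)
    se = float(np.sqrt(var))
    zq = stats.norm.ppf(0.5 + level / 2.0)
    return AucEstimate(
        auc=auc,
        ci_low=max(0.0, auc - zq * se),
        ci_high=min(1.0, auc + zq * se),
        method=method,
    )


def compare_paired_aucs(scores_a, scores_b, labels) -> AucComparison:
    """Two-sided test of AUC_a = AUC_b for two markers on the same subjects.

    Uses the paired placement-value covariance: the variance of the AUC
    difference accounts for the within-subject correlation of the two
    markers. z = (AUC_a - AUC_b)/SE; p from the standard normal. A zero SE
    with a nonzero difference is reported as p = 0 with ``degenerate=True``.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired design: both markers must cover the same subjects")
    y = _as_binary(labels)
    if scores_a.shape != y.shape:
        raise ValueError("scores and labels must be aligned")
    va10, va01, auc_a = _placements(scores_a[y], scores_a[~y])
    vb10, vb01, auc_b = _placements(scores_b[y], scores_b[~y])
    m, n = int(y.sum()), int((~y).sum())
    if m < 2 or n < 2:
        raise ValueError("need at least 2 subjects per class")
    s10 = np.cov(va10, vb10, ddof=1)
    s01 = np.cov(va01, vb01, ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    delta = auc_a - auc_b
    if var <= 0.0:
        if delta == 0.0:
            return AucComparison(auc_a, auc_b, 0.0, 0.0, 0.0, 1.0)
        return AucComparison(
            auc_a, auc_b, delta, 0.0, np.inf if delta > 0 else -np.inf, 0.0, degenerate=True
        )
    se = float(np.sqrt(var))
    z = delta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return AucComparison(auc_a, auc_b, delta, se, float(z), p)


def find_ideal_cutoff(scores, labels) -> CutoffSearchResult:
    """Exhaustive search for the accuracy-maximizing cutoff.

    Candidates are every distinct observed score (positive iff >= cutoff)
    plus +inf (call everything negative). Ties in accuracy are resolved by
    the higher Youden index, then by the smaller cutoff.
    """
    cases, controls = _split(scores, labels)
    n1, n0 = len(cases), len(controls)
    cand = np.concatenate([np.unique(np.concatenate([cases, controls])), [np.inf]])
    # tp(c) = #cases >= c via searchsorted on sorted arrays
    sc = np.sort(cases)
    s0 = np.sort(controls)
    tp = n1 - np.searchsorted(sc, cand, side="left")
    fp = n0 - np.searchsorted(s0, cand, side="left")
    tn = n0 - fp
    acc = (tp + tn) / (n1 + n0)
    sens = tp / n1
    spec = tn / n0
    youden = sens + spec - 1.0
    # lexicographic argmax: accuracy, then Youden, then smaller cutoff
    order = np.lexsort((cand, -youden, -acc))
    best = order[0]
    return CutoffSearchResult(
        cutoff=float(cand[best]),
        sensitivity=100.0 * float(sens[best]),
        specificity=100.0 * float(spec[best]),
        accuracy=float(acc[best]),
    )


def sensitivity_specificity_at(scores, labels, cutoff: float) -> tuple[float, float]:
    """(sensitivity %, specificity %) at a fixed cutoff (>= convention)."""
    cm = confusion_at_cutoff(scores, labels, cutoff)
    return 100.0 * cm.sensitivity, 100.0 * cm.specificity
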