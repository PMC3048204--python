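"""One-command reproduction of the full diagnostic-performance analysis on
any cohort: composition tests, per-group marker summaries, per-stratum
marker performance (AUC with CI, pairwise AUC comparisons, ideal and fixed
cutoffs), and named case-subgroup AUCs.

Strata are ``all`` / ``pre`` / ``post`` menopausal; markers are CA125, HE4
and ROMA (the percent-scale predicted probability). Two conventions
coexist for the pooled stratum, deliberately:

* the pooled ROMA **ROC/AUC** is computed on the pooled PP values (a single
  score axis, each subject scored with its own menopause-specific formula);
* pooled **sensitivity/specificity at the suggested ROMA cutoffs** applies
  each subject's status-specific threshold (12.5% pre / 14.4% post) and then
  pools the confusion matrix.

Every number in the report bundle is traceable to one of the module
operations (``audit`` fields carry the producing operation and filters).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from . import groupstats, performance, roma
from .cohort import (
    Cohort,
    DiagnosisClass,
    FigoStage,
    Grade,
    HistologyGroup,
    MenopausalStatus,
    PathologyLabel,
    stratify,
)
from .performance import AucComparison, AucEstimate, CutoffSearchResult

__all__ = [
    "SubgroupSpec",
    "FixedCutoffRow",
    "PerformanceReport",
    "AnalysisBundle",
    "MARKERS",
    "NAMED_SUBGROUPS",
    "marker_scores",
    "run_full_analysis",
    "evaluate_subgroup",
    "render_reports",
]

MARKERS = ("CA125", "HE4", "ROMA")
STRATA = ("all", "pre", "post")


@dataclass(frozen=True)
class SubgroupSpec:
    """A named case subset: cases are the malignant records passing
    ``case_filter`` (a pure predicate over the pathology label); controls
    are always the full benign class."""

    name: str
    case_filter: Callable[[PathologyLabel], bool]


def _is_eoc(p: PathologyLabel) -> bool:
    return p.histology_group is HistologyGroup.EOC


#: The named case subgroups of the subgroup ROC analysis: all malignant,
#: EOC, invasive EOC (borderline excluded), FIGO stages and stage groups,
#: grade groups, and (pure) serous / mucinous splits (mixed excluded).
NAMED_SUBGROUPS: dict[str, SubgroupSpec] = {
    s.name: s
    for s in [
        SubgroupSpec("all_malignant", lambda p: True),
        SubgroupSpec("eoc", _is_eoc),
        SubgroupSpec("invasive_eoc", lambda p: _is_eoc(p) and p.grade is not Grade.BORDERLINE),
        SubgroupSpec("figo_I", lambda p: p.figo_stage is FigoStage.I),
        SubgroupSpec("figo_II", lambda p: p.figo_stage is FigoStage.II),
        SubgroupSpec("figo_III", lambda p: p.figo_stage is FigoStage.III),
        SubgroupSpec("figo_IV", lambda p: p.figo_stage is FigoStage.IV),
        SubgroupSpec("early_stage", lambda p: p.figo_stage in (FigoStage.I, FigoStage.II)),
        SubgroupSpec("advanced_stage", lambda p: p.figo_stage in (FigoStage.III, FigoStage.IV)),
        SubgroupSpec("borderline", lambda p: p.grade is Grade.BORDERLINE),
        SubgroupSpec("grades_1_3", lambda p: p.grade in (Grade.G1, Grade.G2, Grade.G3)),
        SubgroupSpec("serous_eoc", lambda p: _is_eoc(p) and p.subtype_tag == "serous"),
        SubgroupSpec(
            "non_serous_eoc",
            lambda p: _is_eoc(p) and p.subtype_tag not in ("serous", "mixed"),
        ),
        SubgroupSpec("mucinous_eoc", lambda p: _is_eoc(p) and p.subtype_tag == "mucinous"),
        SubgroupSpec(
            "non_mucinous_eoc",
            lambda p: _is_eoc(p) and p.subtype_tag not in ("mucinous", "mixed"),
        ),
    ]
}


@dataclass(frozen=True)
class FixedCutoffRow:
    """Sensitivity/specificity (%) at one fixed cutoff; ``cutoff_label``
    distinguishes e.g. the composite per-status ROMA thresholds."""

    cutoff_label: str
    cutoff: float | None
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class PerformanceReport:
    stratum: str
    marker: str
    n_cases: int
    n_controls: int
    auc: AucEstimate
    ideal: CutoffSearchResult
    fixed_cutoffs: tuple[FixedCutoffRow, ...]
    audit: str = ""


@dataclass
class AnalysisBundle:
    """Everything the full analysis produces, as plain tables/objects."""

    composition: pd.DataFrame
    summaries: pd.DataFrame
    performance: list[PerformanceReport]
    pairwise: dict[tuple[str, str, str], AucComparison]  # (stratum, marker_a, marker_b)
    subgroup_aucs: dict[tuple[str, str], AucEstimate]  # (subgroup, marker)


def marker_scores(cohort: Cohort, marker: str) -> np.ndarray:
    """Score vector for one marker, order preserved. ROMA is the PP (%)."""
    if marker == "CA125":
        return np.array([r.ca125 for r in cohort])
    if marker == "HE4":
        return np.array([r.he4 for r in cohort])
    if marker == "ROMA":
        return roma.cohort_pp(cohort)
    raise ValueError(f"unknown marker {marker!r}; valid: {MARKERS}")


def _labels(cohort: Cohort) -> np.ndarray:
    return np.array([r.diagnosis is DiagnosisClass.MALIGNANT for r in cohort])


def _roma_suggested_rows(
    cohort: Cohort, stratum: str, thresholds: roma.RomaThresholds
) -> FixedCutoffRow:
    """Suggested-cutoff ROMA row: per-subject status-specific threshold,
    pooled confusion matrix."""
    y = _labels(cohort)
    pp = roma.cohort_pp(cohort)
    thr = np.array([thresholds.for_status(r.menopausal_status) for r in cohort])
    positive = pp >= thr
    tp = int(np.count_nonzero(positive & y))
    fn = int(np.count_nonzero(~positive & y))
    fp = int(np.count_nonzero(positive & ~y))
    tn = int(np.count_nonzero(~positive & ~y))
    label = {
        "all": f"{thresholds.pre_pct}/{thresholds.post_pct} by status",
        "pre": f"{thresholds.pre_pct}",
        "post": f"{thresholds.post_pct}",
    }[stratum]
    cutoff = {"all": None, "pre": thresholds.pre_pct, "post": thresholds.post_pct}[stratum]
    return FixedCutoffRow(
        cutoff_label=label,
        cutoff=cutoff,
        sensitivity=100.0 * tp / (tp + fn),
        specificity=100.0 * tn / (tn + fp),
    )


def _fixed_cutoff_rows(
    sub: Cohort,
    marker: str,
    stratum: str,
    scores: np.ndarray,
    y: np.ndarray,
    cutoffs: roma.MarkerCutoffs,
    thresholds: roma.RomaThresholds,
) -> tuple[FixedCutoffRow, ...]:
    if marker == "CA125":
        fixed = [("35.0", cutoffs.ca125_u_ml)]
    elif marker == "HE4":
        fixed = [("70.0", cutoffs.he4_pm_moore), ("150.0", cutoffs.he4_pm_insert)]
    else:
        return (_roma_suggested_rows(sub, stratum, thresholds),)
    rows = []
    for label, c in fixed:
        sens, spec = performance.sensitivity_specificity_at(scores, y, c)
        rows.append(FixedCutoffRow(cutoff_label=label, cutoff=c, sensitivity=sens, specificity=spec))
    return tuple(rows)


def _composition_table(cohort: Cohort) -> pd.DataFrame:
    """Composition and covariate comparison between benign and malignant
    (counts, age t-test, chi-square tests on the available flags)."""
    by_dx = stratify(cohort, "diagnosis")
    benign = by_dx.get("benign", Cohort([]))
    malignant = by_dx.get("malignant", Cohort([]))
    rows = []
    n_b, n_m = len(benign), len(malignant)
    total = n_b + n_m
    rows.append(
        {
            "variable": "n_cases",
            "benign": n_b,
            "malignant": n_m,
            "benign_pct": round(100 * n_b / total, 1) if total else float("nan"),
            "malignant_pct": round(100 * n_m / total, 1) if total else float("nan"),
            "p": float("nan"),
            "test": "",
        }
    )
    if n_b >= 2 and n_m >= 2:
        ages_b = [r.age for r in benign]
        ages_m = [r.age for r in malignant]
        t = groupstats.students_t(ages_b, ages_m)
        rows.append(
            {
                "variable": "age_years",
                "benign": float(np.mean(ages_b)),
                "malignant": float(np.mean(ages_m)),
                "benign_pct": float("nan"),
                "malignant_pct": float("nan"),
                "p": t.p,
                "test": t.test_name,
            }
        )
    # post-menopausal and boolean covariates: chi-square on 2x2 counts,
    # records with a missing flag excluded pairwise
    def _binary_row(name: str, getter) -> None:
        cb = [getter(r) for r in benign if getter(r) is not None]
        cm = [getter(r) for r in malignant if getter(r) is not None]
        kb, km = sum(cb), sum(cm)
        table = [[kb, len(cb) - kb], [km, len(cm) - km]]
        try:
            res = groupstats.chi_square_2xk(table)
            p, test = res.p, res.test_name
        except ValueError:
            p, test = float("nan"), "not testable (zero marginal)"
        rows.append(
            {
                "variable": name,
                "benign": kb,
                "malignant": km,
                "benign_pct": round(100 * kb / len(cb), 1) if cb else float("nan"),
                "malignant_pct": round(100 * km / len(cm), 1) if cm else float("nan"),
                "p": p,
                "test": test,
            }
        )

    _binary_row("post_menopausal", lambda r: r.menopausal_status is MenopausalStatus.POST)
    _binary_row("smoking", lambda r: r.smoking)
    _binary_row("fh_breast", lambda r: r.family_history_breast)
    _binary_row("fh_ovarian", lambda r: r.family_history_ovarian)
    _binary_row("haemolysis", lambda r: r.haemolysis)
    _binary_row("freeze_delay_gt_4h", lambda r: r.freeze_delay_gt_4h)
    return pd.DataFrame(rows)


def _summary_table(cohort: Cohort) -> pd.DataFrame:
    """Median/IQR of CA125, HE4 and ROMA per pathology group, with the
    benign-vs-malignant rank-sum p per marker on the pooled classes."""
    pp = roma.cohort_pp(cohort)
    values = {
        "CA125": np.array([r.ca125 for r in cohort]),
        "HE4": np.array([r.he4 for r in cohort]),
        "ROMA": pp,
    }
    y = _labels(cohort)

    def _groups() -> list[tuple[str, np.ndarray]]:
        out: list[tuple[str, np.ndarray]] = [("benign (all)", ~y), ("malignant (all)", y)]
        for hg in HistologyGroup:
            mask = np.array([r.pathology.histology_group is hg for r in cohort])
            if mask.any():
                out.append((hg.value, mask))
        for st in (FigoStage.I, FigoStage.II, FigoStage.III, FigoStage.IV):
            mask = np.array([r.pathology.figo_stage is st for r in cohort])
            if mask.any():
                out.append((f"figo_{st.value}", mask))
        for gr in (Grade.BORDERLINE, Grade.G1, Grade.G2, Grade.G3):
            mask = np.array([r.pathology.grade is gr for r in cohort])
            if mask.any():
                out.append((f"grade_{gr.value}", mask))
        return out

    rows = []
    for gname, mask in _groups():
        for marker, vals in values.items():
            s = groupstats.median_iqr(vals[mask], group=gname)
            rows.append(
                {
                    "group": gname,
                    "marker": marker,
                    "n": s.n,
                    "median": s.median,
                    "q1": s.q1,
                    "q3": s.q3,
                }
            )
    frame = pd.DataFrame(rows)
    if y.any() and (~y).any():
        pvals = {
            marker: groupstats.wilcoxon_rank_sum(vals[y], vals[~y]).p
            for marker, vals in values.items()
        }
        frame["benign_vs_malignant_p"] = frame["marker"].map(pvals)
    return frame


def run_full_analysis(
    cohort: Cohort,
    thresholds: roma.RomaThresholds = roma.DEFAULT_THRESHOLDS,
    cutoffs: roma.MarkerCutoffs = roma.DEFAULT_CUTOFFS,
    subgroups: dict[str, SubgroupSpec] | None = None,
) -> AnalysisBundle:
    """Run the complete analysis: composition, summaries, per-stratum
    performance with pairwise AUC comparisons, and subgroup AUCs.

    Deterministic given the cohort. A stratum missing a class is omitted
    with a warning; the run continues.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    subgroups = NAMED_SUBGROUPS if subgroups is None else subgroups

    composition = _composition_table(cohort)
    summaries = _summary_table(cohort)

    by_status = stratify(cohort, "menopausal_status")
    strata: dict[str, Cohort] = {"all": cohort}
    for key in ("pre", "post"):
        if key in by_status:
            strata[key] = by_status[key]
        else:
            warnings.warn(f"stratum {key!r} absent from cohort; omitted", stacklevel=2)

    reports: list[PerformanceReport] = []
    pairwise: dict[tuple[str, str, str], AucComparison] = {}
    for stratum, sub in strata.items():
        y = _labels(sub)
        if not (y.any() and (~y).any()):
            warnings.warn(
                f"stratum {stratum!r} lacks one diagnosis class; omitted", stacklevel=2
            )
            continue
        scores = {m: marker_scores(sub, m) for m in MARKERS}
        for marker in MARKERS:
            auc = performance.auc_confidence_interval(scores[marker], y)
            ideal = performance.find_ideal_cutoff(scores[marker], y)
            fixed = _fixed_cutoff_rows(sub, marker, stratum, scores[marker], y, cutoffs, thresholds)
            reports.append(
                PerformanceReport(
                    stratum=stratum,
                    marker=marker,
                    n_cases=int(y.sum()),
                    n_controls=int((~y).sum()),
                    auc=auc,
                    ideal=ideal,
                    fixed_cutoffs=fixed,
                    audit=f"auc_confidence_interval/find_ideal_cutoff on stratum={stratum}",
                )
            )
        for a, b in (("HE4", "CA125"), ("HE4", "ROMA"), ("CA125", "ROMA")):
            pairwise[(stratum, a, b)] = performance.compare_paired_aucs(
                scores[a], scores[b], y
            )

    subgroup_aucs: dict[tuple[str, str], AucEstimate] = {}
    for name, spec in subgroups.items():
        for marker in MARKERS:
            try:
                subgroup_aucs[(name, marker)] = evaluate_subgroup(cohort, spec, marker)
            except ValueError as exc:
                warnings.warn(f"subgroup {name!r}/{marker}: {exc}; omitted", stacklevel=2)

    return AnalysisBundle(
        composition=composition,
        summaries=summaries,
        performance=reports,
        pairwise=pairwise,
        subgroup_aucs=subgroup_aucs,
    )


def evaluate_subgroup(cohort: Cohort, spec: SubgroupSpec, marker: str) -> AucEstimate:
    """AUC of one marker for the subgroup's cases against all benign controls."""
    cases = [
        r
        for r in cohort
        if r.diagnosis is DiagnosisClass.MALIGNANT and spec.case_filter(r.pathology)
    ]
    controls = [r for r in cohort if r.diagnosis is DiagnosisClass.BENIGN]
    if not cases:
        raise ValueError(f"subgroup filter {spec.name!r} selects no malignant cases")
    if not controls:
        raise ValueError("no benign controls in cohort")
    sub = Cohort(cases + controls)
    y = _labels(sub)
    scores = marker_scores(sub, marker)
    if len(cases) >= 2 and len(controls) >= 2:
        return performance.auc_confidence_interval(scores, y)
    return performance.auc_mann_whitney(scores, y)


# --------------------------------------------------------------------------
# Rendering


def _report_to_dict(r: PerformanceReport) -> dict:
    return {
        "stratum": r.stratum,
        "marker": r.marker,
        "n_cases": r.n_cases,
        "n_controls": r.n_controls,
        "auc": dataclasses.asdict(r.auc),
        "ideal": dataclasses.asdict(r.ideal),
        "fixed_cutoffs": [dataclasses.asdict(f) for f in r.fixed_cutoffs],
        "audit": r.audit,
    }


def _jsonify(obj):
    """Recursively replace non-finite floats (NaN -> None, inf -> string) so
    the JSON is strict and round-trips to an equal dictionary."""
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, float):
        if np.isnan(obj):
            return None
        if np.isinf(obj):
            return "inf" if obj > 0 else "-inf"
    return obj


def bundle_to_dict(bundle: AnalysisBundle) -> dict:
    """JSON-serializable view of the whole bundle (full precision)."""
    return _jsonify({
        "composition": bundle.composition.to_dict(orient="records"),
        "summaries": bundle.summaries.to_dict(orient="records"),
        "performance": [_report_to_dict(r) for r in bundle.performance],
        "pairwise": [
            {"stratum": s, "marker_a": a, "marker_b": b, **dataclasses.asdict(cmp)}
            for (s, a, b), cmp in bundle.pairwise.items()
        ],
        "subgroup_aucs": [
            {"subgroup": name, "marker": marker, **dataclasses.asdict(est)}
            for (name, marker), est in bundle.subgroup_aucs.items()
        ],
    })


def render_reports(bundle: AnalysisBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle as CSV tables plus a full-precision JSON.

    CSV rendering: AUCs to three decimals, percentages to one decimal
    (marker summaries to one decimal), mirroring the conventional precision
    of published diagnostic-performance tables. The JSON is exact and
    re-reads to the same dictionary.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    comp = bundle.composition.copy()
    paths["composition"] = out_dir / "composition.csv"
    comp.to_csv(paths["composition"], index=False, lineterminator="\n")

    summ = bundle.summaries.copy()
    for col in ("median", "q1", "q3"):
        if col in summ:
            summ[col] = summ[col].round(1)
    paths["summaries"] = out_dir / "marker_summaries.csv"
    summ.to_csv(paths["summaries"], index=False, lineterminator="\n")

    perf_rows = []
    for r in bundle.performance:
        base = {
            "stratum": r.stratum,
            "marker": r.marker,
            "n_cases": r.n_cases,
            "n_controls": r.n_controls,
            "auc": round(r.auc.auc, 3),
            "ci_low": round(r.auc.ci_low, 3),
            "ci_high": round(r.auc.ci_high, 3),
            "ideal_cutoff": round(r.ideal.cutoff, 1),
            "ideal_sensitivity_pct": round(r.ideal.sensitivity, 1),
            "ideal_specificity_pct": round(r.ideal.specificity, 1),
        }
        for f in r.fixed_cutoffs:
            perf_rows.append(
                {
                    **base,
                    "fixed_cutoff": f.cutoff_label,
                    "fixed_sensitivity_pct": round(f.sensitivity, 1),
                    "fixed_specificity_pct": round(f.specificity, 1),
                }
            )
    paths["performance"] = out_dir / "performance.csv"
    pd.DataFrame(perf_rows).to_csv(paths["performance"], index=False, lineterminator="\n")

    pair_rows = [
        {
            "stratum": s,
            "comparison": f"{a} vs {b}",
            "auc_a": round(cmp.auc_a, 3),
            "auc_b": round(cmp.auc_b, 3),
            "delta": round(cmp.delta, 3),
            "z": round(cmp.z, 3) if np.isfinite(cmp.z) else cmp.z,
            "p": cmp.p,
        }
        for (s, a, b), cmp in bundle.pairwise.items()
    ]
    paths["pairwise"] = out_dir / "pairwise_auc.csv"
    pd.DataFrame(pair_rows).to_csv(paths["pairwise"], index=False, lineterminator="\n")

    sub_rows = [
        {
            "subgroup": name,
            "marker": marker,
            "auc": round(est.auc, 3),
            "ci_low": round(est.ci_low, 3),
            "ci_high": round(est.ci_high, 3),
        }
        for (name, marker), est in bundle.subgroup_aucs.items()
    ]
    paths["subgroups"] = out_dir / "subgroup_aucs.csv"
    pd.DataFrame(sub_rows).to_csv(paths["subgroups"], index=False, lineterminator="\n")

    paths["json"] = out_dir / "analysis_bundle.json"
    paths["json"].write_text(
        json.dumps(bundle_to_dict(bundle), indent=2, allow_nan=False) + "\n"
    )
    return paths
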