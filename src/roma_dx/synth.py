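"""Synthetic pelvic-mass cohort generator.

No patient-level data are deposited with the validation study this package
evaluates; what is published are cohort summaries: 228 benign / 161
malignant subjects, menopausal mix per class, and per-histology-group
median / interquartile-range levels of CA125 and HE4. This module generates
cohorts with that statistical structure so every downstream stage can be
exercised end to end.

Model
-----
* Within each histology (or FIGO-stage) group, CA125 and HE4 are marginally
  **log-normal**. Markers are positive and heavily right-skewed (group
  medians sit far below the upper quartiles), and the log-normal admits a
  closed-form calibration from the published median and IQR:

      mu = ln(median),   sigma = (ln q3 - ln q1) / (2 * z_0.75)

  with z_0.75 = 0.674490 the 75th standard-normal percentile. The implied
  median is exp(mu) and the implied IQR ratio q3/q1 is exp(2 * z_0.75 * sigma).
* CA125-HE4 dependence within a group is imposed by a Gaussian copula with a
  configurable Spearman rank correlation (default 0.3 benign / 0.5
  malignant; the source study reports no joint statistics, so these are this
  package's assumption).
* Group membership is multinomial with the published composition weights;
  menopausal status is Bernoulli per class; ages are normal per class
  truncated at 18 years; pre-analytic and history flags are independent
  Bernoulli at the published rates (the study found no association between
  flags and marker levels, so none is modelled).

Generation is fully deterministic given the config seed. ROMA levels are
*not* separately calibrated: they emerge from the marker joint distribution
and the menopausal mix.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .cohort import (
    Cohort,
    DiagnosisClass,
    FigoStage,
    Grade,
    HistologyGroup,
    MenopausalStatus,
    PathologyLabel,
    PatientRecord,
)

__all__ = [
    "Z75",
    "LogNormalSpec",
    "GroupSpec",
    "GeneratorConfig",
    "calibrate_lognormal_from_quantiles",
    "default_config",
    "generate_cohort",
    "perturb_config",
    "config_to_json",
    "config_from_json",
    "REFERENCE_BENIGN_HE4",
    "REFERENCE_FIGO_IV_CA125",
]

#: 75th percentile of the standard normal distribution.
Z75 = 0.6744897501960817


@dataclass(frozen=True)
class LogNormalSpec:
    """Log-normal marginal: ``mu`` and ``sigma`` on the natural-log scale.

    The implied median is ``exp(mu)``; the implied quartile ratio q3/q1 is
    ``exp(2 * Z75 * sigma)``. ``source`` records which published cohort row
    the parameters were calibrated from.
    """

    mu: float
    sigma: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    @property
    def median(self) -> float:
        return math.exp(self.mu)

    @property
    def iqr_ratio(self) -> float:
        return math.exp(2.0 * Z75 * self.sigma)


def calibrate_lognormal_from_quantiles(
    median: float, q1: float, q3: float, source: str = ""
) -> LogNormalSpec:
    """Closed-form log-normal calibration from a median and quartiles.

    ``mu = ln(median)``; ``sigma = (ln q3 - ln q1)/(2 * Z75)``. The implied
    median matches the input exactly, and the implied quartile *ratio*
    matches q3/q1 exactly (the individual quartiles match only when the
    published quartiles are symmetric on the log scale around the median).
    """
    if not 0 < q1 <= median <= q3:
        raise ValueError(f"need 0 < q1 <= median <= q3, got ({q1}, {median}, {q3})")
    return LogNormalSpec(
        mu=math.log(median),
        sigma=(math.log(q3) - math.log(q1)) / (2.0 * Z75),
        source=source,
    )


@dataclass(frozen=True)
class GroupSpec:
    """One mixture component: a histology (or EOC FIGO-stage) group.

    ``weight`` is the mixture fraction within the diagnosis class;
    ``rank_corr`` is the Spearman correlation between CA125 and HE4 imposed
    through the Gaussian copula; ``grade_probs``/``subtype_probs`` control
    the pathology labels of EOC records (grade and stage apply to EOC only).
    """

    label: str
    weight: float
    ca125: LogNormalSpec
    he4: LogNormalSpec
    menopause_post_prob: float
    rank_corr: float
    histology_group: HistologyGroup
    figo_stage: FigoStage = FigoStage.NOT_APPLICABLE
    grade_probs: tuple[tuple[Grade, float], ...] = ()
    subtype_probs: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("weight must lie in [0, 1]")
        if not 0.0 <= self.menopause_post_prob <= 1.0:
            raise ValueError("menopause_post_prob must lie in [0, 1]")
        if not -1.0 <= self.rank_corr <= 1.0:
            raise ValueError("rank_corr must lie in [-1, 1]")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full cohort recipe: class sizes, mixture components, ages, flag rates, seed."""

    n_benign: int
    n_malignant: int
    benign_groups: tuple[GroupSpec, ...]
    malignant_groups: tuple[GroupSpec, ...]
    age_benign: tuple[float, float] = (46.3, 16.0)  # mean, sd (years)
    age_malignant: tuple[float, float] = (57.8, 12.6)
    flag_rates_benign: tuple[tuple[str, float], ...] = ()
    flag_rates_malignant: tuple[tuple[str, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for name, groups in (("benign", self.benign_groups), ("malignant", self.malignant_groups)):
            if groups:
                total = sum(g.weight for g in groups)
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(f"{name} group weights must sum to 1, got {total}")


# --------------------------------------------------------------------------
# Default configuration, calibrated to the published reference cohort
# (389 women with a pelvic mass: 228 benign, 161 malignant).

#: Benign-histology HE4 (pM): median and quartiles of the pooled benign class.
REFERENCE_BENIGN_HE4 = (45.4, 35.6, 60.8)
#: FIGO stage IV CA125 (U/ml): median and quartiles.
REFERENCE_FIGO_IV_CA125 = (1260.7, 790.6, 2905.1)

# (label, count, CA125 (median, q1, q3), HE4 (median, q1, q3), histology group)
_BENIGN_ROWS = [
    ("cystadenoma/cystadenofibroma", 78, (11.3, 7.4, 19.5), (53.7, 40.8, 68.0),
     HistologyGroup.CYSTADENOMA_FIBROMA),
    ("endometriosis", 66, (25.5, 10.7, 54.9), (40.0, 34.3, 50.7),
     HistologyGroup.ENDOMETRIOSIS),
    ("mature teratoma", 29, (9.8, 5.7, 15.9), (43.9, 37.5, 52.5),
     HistologyGroup.MATURE_TERATOMA),
    ("fibroma/thecoma", 15, (29.1, 11.6, 45.5), (48.1, 33.9, 73.2),
     HistologyGroup.FIBROMA_THECOMA),
    ("functional cyst", 13, (10.5, 6.8, 20.7), (43.7, 30.8, 54.6),
     HistologyGroup.FUNCTIONAL_CYST),
    # remaining rare/mixed benign histologies: pooled benign marker levels
    ("other benign (pooled benign levels)", 27, (12.8, 8.0, 27.6), REFERENCE_BENIGN_HE4,
     HistologyGroup.OTHER_BENIGN),
]

# EOC by FIGO stage (reference counts out of 131 EOC; the 4 non-epithelial
# cancers are folded into the EOC stage mix — too few to parameterize) plus
# the metastatic group.
_EOC_STAGE_ROWS = [
    ("EOC FIGO I", 43, (38.4, 16.9, 182.6), (73.2, 52.6, 126.5), FigoStage.I),
    ("EOC FIGO II", 8, (60.2, 20.6, 254.8), (69.0, 44.3, 152.6), FigoStage.II),
    ("EOC FIGO III", 66, (757.3, 227.9, 1640.0), (308.0, 135.0, 712.5), FigoStage.III),
    ("EOC FIGO IV", 14, REFERENCE_FIGO_IV_CA125, (578.7, 274.6, 2612.9), FigoStage.IV),
]
_METASTATIC_ROW = ("metastatic", 26, (222.9, 64.9, 913.5), (103.5, 48.9, 302.4))

# Differentiation grade of EOC in the reference cohort: 31 borderline,
# 13 / 14 / 73 grade 1-3 out of 131. Borderline disease is concentrated in
# early stage: all 31 borderline cases are allocated to stages I-II
# (51 cases), which preserves the published grade marginals in expectation.
_GRADE_EARLY = ((Grade.BORDERLINE, 31 / 51),
                (Grade.G1, (20 / 51) * (13 / 100)),
                (Grade.G2, (20 / 51) * (14 / 100)),
                (Grade.G3, (20 / 51) * (73 / 100)))
_GRADE_LATE = ((Grade.G1, 13 / 100), (Grade.G2, 14 / 100), (Grade.G3, 73 / 100))

# Epithelial subtype mix (reference counts; non-epithelial folded into "other").
_EOC_SUBTYPES = (("serous", 84 / 135), ("mucinous", 21 / 135), ("endometrioid", 7 / 135),
                 ("clear_cell", 6 / 135), ("mixed", 6 / 135), ("other", 11 / 135))

_FLAGS_BENIGN = (("haemolysis", 23 / 228), ("freeze_delay_gt_4h", 24 / 228),
                 ("smoking", 53 / 228), ("family_history_breast", 35 / 228),
                 ("family_history_ovarian", 4 / 228))
_FLAGS_MALIGNANT = (("haemolysis", 15 / 161), ("freeze_delay_gt_4h", 16 / 161),
                    ("smoking", 31 / 161), ("family_history_breast", 41 / 161),
                    ("family_history_ovarian", 8 / 161))

#: Post-menopausal fraction per class in the reference cohort.
_POST_PROB_BENIGN = 86 / 228
_POST_PROB_MALIGNANT = 119 / 161

#: Default Gaussian-copula Spearman correlation between CA125 and HE4.
DEFAULT_RANK_CORR_BENIGN = 0.3
DEFAULT_RANK_CORR_MALIGNANT = 0.5


def default_config(seed: int = 0) -> GeneratorConfig:
    """The default recipe: composition, menopausal mix, marker medians/IQRs
    and flag rates of the published 228-benign / 161-malignant reference
    cohort; every embedded constant's ``source`` names its cohort row."""
    benign = tuple(
        GroupSpec(
            label=label,
            weight=count / 228,
            ca125=calibrate_lognormal_from_quantiles(*ca, source=f"{label}: CA125 (U/ml)"),
            he4=calibrate_lognormal_from_quantiles(*he4, source=f"{label}: HE4 (pM)"),
            menopause_post_prob=_POST_PROB_BENIGN,
            rank_corr=DEFAULT_RANK_CORR_BENIGN,
            histology_group=group,
        )
        for label, count, ca, he4, group in _BENIGN_ROWS
    )
    # EOC stage weights within the malignant class: 135/161 of the class,
    # split across stages in the published 43:8:66:14 proportion.
    eoc_scale = (135 / 161) / 131
    malignant = tuple(
        GroupSpec(
            label=label,
            weight=count * eoc_scale,
            ca125=calibrate_lognormal_from_quantiles(*ca, source=f"{label}: CA125 (U/ml)"),
            he4=calibrate_lognormal_from_quantiles(*he4, source=f"{label}: HE4 (pM)"),
            menopause_post_prob=_POST_PROB_MALIGNANT,
            rank_corr=DEFAULT_RANK_CORR_MALIGNANT,
            histology_group=HistologyGroup.EOC,
            figo_stage=stage,
            grade_probs=_GRADE_EARLY if stage in (FigoStage.I, FigoStage.II) else _GRADE_LATE,
            subtype_probs=_EOC_SUBTYPES,
        )
        for label, count, ca, he4, stage in _EOC_STAGE_ROWS
    )
    label, count, ca, he4 = _METASTATIC_ROW
    malignant += (
        GroupSpec(
            label=label,
            weight=count / 161,
            ca125=calibrate_lognormal_from_quantiles(*ca, source=f"{label}: CA125 (U/ml)"),
            he4=calibrate_lognormal_from_quantiles(*he4, source=f"{label}: HE4 (pM)"),
            menopause_post_prob=_POST_PROB_MALIGNANT,
            rank_corr=DEFAULT_RANK_CORR_MALIGNANT,
            histology_group=HistologyGroup.METASTATIC,
        ),
    )
    return GeneratorConfig(
        n_benign=228,
        n_malignant=161,
        benign_groups=benign,
        malignant_groups=malignant,
        flag_rates_benign=_FLAGS_BENIGN,
        flag_rates_malignant=_FLAGS_MALIGNANT,
        seed=seed,
    )


# --------------------------------------------------------------------------
# Generation


def _spearman_to_pearson(rho_s: float) -> float:
    """Gaussian-copula latent correlation giving Spearman correlation rho_s."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def _draw_class(
    rng: np.random.Generator,
    n: int,
    groups: tuple[GroupSpec, ...],
    diagnosis: DiagnosisClass,
    age_mean_sd: tuple[float, float],
    flag_rates: tuple[tuple[str, float], ...],
    id_prefix: str,
    id_offset: int,
) -> list[PatientRecord]:
    if n == 0:
        return []
    if not groups:
        raise ValueError(f"no groups configured for {diagnosis.value} class")
    weights = np.array([g.weight for g in groups])
    membership = rng.choice(len(groups), size=n, p=weights)

    ca125 = np.empty(n)
    he4 = np.empty(n)
    post = np.empty(n, dtype=bool)
    pathologies: list[PathologyLabel | None] = [None] * n
    for gi, g in enumerate(groups):
        idx = np.flatnonzero(membership == gi)
        k = len(idx)
        if k == 0:
            continue
        rho = _spearman_to_pearson(g.rank_corr)
        z1 = rng.standard_normal(k)
        z2 = rho * z1 + math.sqrt(1.0 - rho * rho) * rng.standard_normal(k)
        ca125[idx] = np.exp(g.ca125.mu + g.ca125.sigma * z1)
        he4[idx] = np.exp(g.he4.mu + g.he4.sigma * z2)
        post[idx] = rng.random(k) < g.menopause_post_prob
        if g.grade_probs:
            glabels = [gr for gr, _ in g.grade_probs]
            gp = np.array([p for _, p in g.grade_probs])
            grades = rng.choice(len(glabels), size=k, p=gp / gp.sum())
        else:
            grades = None
        if g.subtype_probs:
            slabels = [s for s, _ in g.subtype_probs]
            sp = np.array([p for _, p in g.subtype_probs])
            subtypes = rng.choice(len(slabels), size=k, p=sp / sp.sum())
        else:
            subtypes = None
        for j, rec_i in enumerate(idx):
            pathologies[rec_i] = PathologyLabel(
                histology_group=g.histology_group,
                figo_stage=g.figo_stage,
                grade=glabels[grades[j]] if grades is not None else Grade.NOT_APPLICABLE,
                subtype_tag=slabels[subtypes[j]] if subtypes is not None else "",
            )

    mean, sd = age_mean_sd
    a, b = (18.0 - mean) / sd, np.inf
    ages = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)

    flags = {name: rng.random(n) < rate for name, rate in flag_rates}

    records = []
    for i in range(n):
        records.append(
            PatientRecord(
                id=f"{id_prefix}{id_offset + i:05d}",
                age=float(ages[i]),
                menopausal_status=MenopausalStatus.POST if post[i] else MenopausalStatus.PRE,
                ca125=float(ca125[i]),
                he4=float(he4[i]),
                diagnosis=diagnosis,
                pathology=pathologies[i],
                haemolysis=bool(flags["haemolysis"][i]) if "haemolysis" in flags else None,
                freeze_delay_gt_4h=(
                    bool(flags["freeze_delay_gt_4h"][i]) if "freeze_delay_gt_4h" in flags else None
                ),
                family_history_breast=(
                    bool(flags["family_history_breast"][i])
                    if "family_history_breast" in flags
                    else None
                ),
                family_history_ovarian=(
                    bool(flags["family_history_ovarian"][i])
                    if "family_history_ovarian" in flags
                    else None
                ),
                smoking=bool(flags["smoking"][i]) if "smoking" in flags else None,
            )
        )
    return records


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Draw a cohort from the configured mixture; deterministic given the seed.

    Benign records come first, then malignant; ids are sequential. A single
    documented generator stream (PCG64 seeded with ``config.seed``) drives
    all draws, in a fixed order (benign class first, groups in configured
    order), so identical configs yield byte-identical cohorts.
    """
    rng = np.random.default_rng(config.seed)
    records = _draw_class(
        rng, config.n_benign, config.benign_groups, DiagnosisClass.BENIGN,
        config.age_benign, config.flag_rates_benign, "B", 0,
    ) if config.n_benign else []
    records += _draw_class(
        rng, config.n_malignant, config.malignant_groups, DiagnosisClass.MALIGNANT,
        config.age_malignant, config.flag_rates_malignant, "M", 0,
    ) if config.n_malignant else []
    return Cohort(records)


def perturb_config(config: GeneratorConfig, overrides: dict) -> GeneratorConfig:
    """Pure update of a config; the original is untouched.

    Keys naming :class:`GeneratorConfig` fields replace those fields; keys
    naming :class:`GroupSpec` fields (e.g. ``rank_corr``) are applied to
    every group in both classes. Unknown keys raise ``ValueError``.
    """
    cfg_fields = {f.name for f in dataclasses.fields(GeneratorConfig)}
    group_fields = {f.name for f in dataclasses.fields(GroupSpec)}
    top: dict = {}
    per_group: dict = {}
    for key, value in overrides.items():
        if key in cfg_fields:
            top[key] = value
        elif key in group_fields:
            per_group[key] = value
        else:
            raise ValueError(f"unknown config field {key!r}")
    new = dataclasses.replace(config, **top) if top else config
    if per_group:
        new = dataclasses.replace(
            new,
            benign_groups=tuple(dataclasses.replace(g, **per_group) for g in new.benign_groups),
            malignant_groups=tuple(
                dataclasses.replace(g, **per_group) for g in new.malignant_groups
            ),
        )
    return new


# --------------------------------------------------------------------------
# Config (de)serialization


def _spec_to_dict(s: LogNormalSpec) -> dict:
    return {"mu": s.mu, "sigma": s.sigma, "source": s.source}


def _group_to_dict(g: GroupSpec) -> dict:
    return {
        "label": g.label,
        "weight": g.weight,
        "ca125": _spec_to_dict(g.ca125),
        "he4": _spec_to_dict(g.he4),
        "menopause_post_prob": g.menopause_post_prob,
        "rank_corr": g.rank_corr,
        "histology_group": g.histology_group.value,
        "figo_stage": g.figo_stage.value,
        "grade_probs": [[gr.value, p] for gr, p in g.grade_probs],
        "subtype_probs": [list(sp) for sp in g.subtype_probs],
    }


def _group_from_dict(d: dict) -> GroupSpec:
    return GroupSpec(
        label=d["label"],
        weight=d["weight"],
        ca125=LogNormalSpec(**d["ca125"]),
        he4=LogNormalSpec(**d["he4"]),
        menopause_post_prob=d["menopause_post_prob"],
        rank_corr=d["rank_corr"],
        histology_group=HistologyGroup(d["histology_group"]),
        figo_stage=FigoStage(d["figo_stage"]),
        grade_probs=tuple((Grade(gr), p) for gr, p in d.get("grade_probs", [])),
        subtype_probs=tuple((s, p) for s, p in d.get("subtype_probs", [])),
    )


def config_to_json(config: GeneratorConfig, path: str | Path | None = None) -> str:
    """Serialize a config to JSON (optionally writing it to ``path``)."""
    d = {
        "schema_version": 1,
        "n_benign": config.n_benign,
        "n_malignant": config.n_malignant,
        "benign_groups": [_group_to_dict(g) for g in config.benign_groups],
        "malignant_groups": [_group_to_dict(g) for g in config.malignant_groups],
        "age_benign": list(config.age_benign),
        "age_malignant": list(config.age_malignant),
        "flag_rates_benign": [list(f) for f in config.flag_rates_benign],
        "flag_rates_malignant": [list(f) for f in config.flag_rates_malignant],
        "seed": config.seed,
    }
    text = json.dumps(d, indent=2)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def config_from_json(source: str | Path) -> GeneratorConfig:
    """Load a config from a JSON string or file path."""
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and source.endswith(".json")):
        d = json.loads(Path(source).read_text())
    else:
        d = json.loads(source)
    return GeneratorConfig(
        n_benign=d["n_benign"],
        n_malignant=d["n_malignant"],
        benign_groups=tuple(_group_from_dict(g) for g in d["benign_groups"]),
        malignant_groups=tuple(_group_from_dict(g) for g in d["malignant_groups"]),
        age_benign=tuple(d["age_benign"]),
        age_malignant=tuple(d["age_malignant"]),
        flag_rates_benign=tuple(tuple(f) for f in d["flag_rates_benign"]),
        flag_rates_malignant=tuple(tuple(f) for f in d["flag_rates_malignant"]),
        seed=d["seed"],
    )
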