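# roma-dx

Diagnostic-performance evaluation of the **Risk of Ovarian Malignancy
Algorithm (ROMA)** and its component serum markers, CA125 and HE4, for
women presenting with a pelvic mass.

Triage of a pelvic mass is a real clinical problem: patients with ovarian
cancer do better when operated on by gynaecological oncologists in tertiary
centres, so community clinicians need a way to flag the masses that are
likely malignant. ROMA combines the two serum tumour markers with menopausal
status into a single predicted probability of epithelial ovarian cancer:

```
pre-menopausal:   PI = -12.0 + 2.38 ln(HE4) + 0.0626 ln(CA125)
post-menopausal:  PI = -8.09 + 1.04 ln(HE4) + 0.732  ln(CA125)
                  PP = 100 · e^PI / (1 + e^PI)     [percent]
```

with HE4 in pM and CA125 in U/ml, and a closed high-risk threshold of
PP ≥ 12.5 % (pre-menopausal) or PP ≥ 14.4 % (post-menopausal).

This package provides, for biostatisticians and clinical-assay evaluators:

* **`roma_dx.cohort`** — a typed patient-level data model (markers,
  menopausal status, surgical-pathology labels, pre-analytic flags) with a
  documented CSV schema, validation and stratification;
* **`roma_dx.roma`** — the ROMA predictive index / predicted probability and
  the threshold classifiers for ROMA, HE4 (70 / 150 pM) and CA125 (35 U/ml);
* **`roma_dx.performance`** — empirical ROC curves, Mann–Whitney AUC, the
  DeLong placement-value variance for confidence intervals and the paired
  AUC-difference test for markers measured on the same subjects, and the
  best-accuracy ("ideal") cutoff search;
* **`roma_dx.groupstats`** — median/IQR summaries, Wilcoxon rank-sum
  (exact for small samples), Kruskal–Wallis, χ² and Student's t;
* **`roma_dx.synth`** — a synthetic cohort generator calibrated to the
  published summary statistics of a 389-patient prospective validation
  cohort (228 benign / 161 malignant), using per-group log-normal marker
  marginals fitted from medians/IQRs and a Gaussian copula for CA125–HE4
  dependence;
* **`roma_dx.pipeline`** — a one-command reproduction of the whole analysis
  (composition tests, marker summaries, per-stratum performance tables,
  subgroup AUCs) on any cohort CSV.

## Worked example

Simulate the default cohort, score it, and run the full analysis:

```bash
roma-dx reproduce --seed 42 --out-dir out/
```

or equivalently in Python:

```python
from roma_dx import synth, pipeline

cohort = synth.generate_cohort(synth.default_config(seed=42))
bundle = pipeline.run_full_analysis(cohort)
for r in bundle.performance:
    if r.stratum == "all":
        print(f"{r.marker:5s} AUC {r.auc.auc:.3f} "
              f"(95% CI {r.auc.ci_low:.3f}-{r.auc.ci_high:.3f})")
```

which prints (seed 42):

```
CA125 AUC 0.868 (95% CI 0.828-0.909)
HE4   AUC 0.850 (95% CI 0.806-0.894)
ROMA  AUC 0.892 (95% CI 0.855-0.930)
```

Each line is one marker's area under the ROC curve for discriminating the
161 malignant from the 228 benign synthetic subjects, with a 95% DeLong
confidence interval: here ROMA separates the classes best, but the paired
AUC comparisons in `bundle.pairwise` show only the HE4-vs-ROMA difference
is significant (p ≈ 0.007), with CA125 vs ROMA at p ≈ 0.08 — the marker
AUCs are statistically indistinguishable from CA125 alone. The rendered
`performance.csv` additionally reports, per stratum (all / pre- /
post-menopausal), the cohort-specific best-accuracy cutoff and the
sensitivity/specificity at the fixed cutoffs (CA125 35 U/ml, HE4 70 and
150 pM, ROMA 12.5/14.4 % by status); `subgroup_aucs.csv` covers the named
case subgroups (EOC only, invasive EOC, FIGO stages, grades, serous /
mucinous subtypes) against all benign controls.

Because the cohort is synthetic — drawn from log-normal marginals
calibrated to published group medians and IQRs, not from the original
patient records — these numbers emulate, not reproduce, the published
analysis; see `docs/methods.md` for exactly what is and is not calibrated.

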