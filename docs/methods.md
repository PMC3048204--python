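# Methods

## The ROMA score

ROMA is a fixed-coefficient logistic score. For each subject a predictive
index (log-odds) is computed from the natural logs of serum HE4 (pM) and
CA125 (U/ml) with menopause-specific coefficients — pre-menopausal
(−12.0, 2.38, 0.0626), post-menopausal (−8.09, 1.04, 0.732) — and mapped to
a predicted probability PP = 100·logistic(PI) on the percent scale. The
published post-menopausal formula contains an obvious bracket typo around
the CA125 term; it is implemented as +0.732·ln(CA125). The coefficients are
*validated*, not re-estimated: this package deliberately contains no
coefficient-fitting code.

Classification is dichotomous with a **closed lower bound**: PP equal to
the threshold (12.5 % pre-, 14.4 % post-menopausal) is high risk. The same
≥ convention is applied to the single-marker cutoffs (CA125 35 U/ml, HE4
70 pM and 150 pM) and to every ROC threshold sweep, so all confusion
matrices in the package are mutually consistent. The source material never
states the single-marker boundary convention; aligning it with ROMA's
printed "≥ = high risk" is this package's choice.

Coefficients, thresholds and cutoffs are configuration objects
(`RomaCoefficients`, `RomaThresholds`, `MarkerCutoffs`), so post-hoc
cohort-specific cutoffs (e.g. best-accuracy values such as ROMA 22.2 % or
HE4 72.2 pM) can be swapped in for sensitivity analyses.

### Numerical behaviour of PP

PP is computed with the numerically stable logistic (`scipy.special.expit`);
it never overflows and stays strictly inside (0, 100) for every PI that
positive finite markers can produce (clinically, |PI| stays below ~10).
Inverting the *stored* PP back to PI via logit(PP/100) is exact to ≤1e-9
relative error for |PI| ≲ 17. Beyond that the float64 quantization of PP
near 100 (spacing ≈ 1.4e-14) dominates: any inverse of the stored percent
value carries absolute error of order 1.4e-14·e^|PI|/100, reaching ~7e-4 at
PI = 30. This is a representation limit of percent-scale double-precision
probabilities, not an implementation defect; the unit tests assert the
1e-9 round-trip in the attainable regime and the quantization bound above it.

## ROC analysis and the AUC machinery

The AUC is the Mann–Whitney pair-counting estimate (ties counted half),
which equals the trapezoidal area under the empirical ROC constructed over
all distinct observed cutoffs — an identity the test suite checks to 1e-12
on random tied data. Variances come from the placement-value (DeLong)
decomposition: for each diseased subject the fraction of non-diseased
subjects it outscores, and vice versa; the AUC variance is the sum of the
two between-subject variances scaled by the class sizes. Confidence
intervals use the normal approximation, clipped to [0, 1], with no
finite-sample correction; a zero empirical variance (e.g. perfect
separation) returns the point interval flagged `degenerate=True` rather
than a silently clipped band.

The paired AUC-difference test for two markers measured on the same
subjects uses the paired placement-value covariance, z = ΔAUC/SE(Δ), with a
two-sided normal p. The historical method cited for such comparisons is a
correlation-lookup approximation; the placement-value covariance is the
fully specified, asymptotically equivalent modern form and is recorded in
`AucComparison.method`. Monte-Carlo tests verify the operating
characteristics at desk scale: type-I error of the paired test within
5 % ± 1.5 % under a correlated-markers null (2,000 replicates, 50 + 50
subjects), and 95 % CI coverage within ± 2 % under a binormal model with
true AUC 0.8 (2,000 replicates, 50 + 50). These sizes give Monte-Carlo
standard errors (~0.5 %) comfortably inside the asserted bands.

The "ideal" cutoff is the accuracy maximizer ("minimal false-negative and
false-positive results") over every distinct observed score plus a +inf
all-negative sentinel — with the ≥ convention this candidate set spans all
achievable confusion matrices, so the search is exhaustive, not heuristic.
Equal-accuracy ties are broken by the higher Youden index (sens+spec−1),
then by the smaller cutoff, making the result deterministic; the source
material is silent on ties.

## Group statistics

Summaries are median and quartiles by linear interpolation between order
statistics (`numpy.quantile` default). Published tables never state their
quartile convention, so last-decimal differences against printed IQRs are
expected. Hypothesis tests delegate to scipy with fixed conventions:

* **Wilcoxon rank-sum**: exact enumeration when the combined n ≤ 10 with no
  ties (exactness is cheap there), otherwise the tie- and
  continuity-corrected normal approximation.
* **Kruskal–Wallis**: tie-corrected H, p from χ²(k−1); the all-identical
  degenerate case is defined as H = 0, p = 1. Post-hoc pairwise rank-sum
  comparisons are unadjusted by default (matching how such tables are
  usually reported), with Bonferroni/Holm available by flag.
* **χ²**: Pearson, *without* Yates continuity correction by default, with a
  flag to enable it. Note: the published family-history p-values (0.009
  breast, 0.028 ovarian) are not reproduced by a standard Pearson χ² on the
  printed 2×2 counts (which give ≈0.013 and ≈0.071); the original
  procedure/denominators are unknown, and this discrepancy is documented
  rather than chased.
* **Student's t**: pooled variance by default, Welch by flag; zero-variance
  degeneracies resolved explicitly (equal means → p = 1, unequal → p = 0,
  noted). A summary-statistic variant supports testing printed
  mean/sd/n rows.

## The synthetic cohort

No patient-level data accompany the validation study, so the generator
emulates its *published summaries*:

* **Composition**: 228 benign / 161 malignant; benign histology mix
  (cystadenoma/cystadenofibroma 78, endometriosis 66, mature teratoma 29,
  fibroma/thecoma 15, functional cyst 13, other 27); malignant mass split
  into EOC by FIGO stage (43 : 8 : 66 : 14 out of 131, scaled to 135/161 of
  the class after folding in the 4 non-epithelial cancers, too few to
  parameterize) plus a 26/161 metastatic group.
* **Markers**: within each group CA125 and HE4 are log-normal, calibrated
  in closed form from the published median and IQR: mu = ln(median),
  sigma = (ln q3 − ln q1)/(2·z₀.₇₅) with z₀.₇₅ = 0.674490. The log-normal is
  an assumption of this package — markers are positive and strongly
  right-skewed — and the calibration reproduces the median exactly and the
  quartile *ratio* exactly (individual quartiles exactly only when they are
  log-symmetric around the median). The rarer benign histologies share the
  pooled benign-class marker levels.
* **Dependence**: a Gaussian copula imposes a Spearman correlation between
  CA125 and HE4 within each group (latent Pearson ρ = 2·sin(π·ρ_s/6)),
  defaulting to 0.3 (benign) / 0.5 (malignant). No joint marker statistics
  were published; these defaults are invented, configurable, and are a
  within-group property — measuring the pooled cohort mixes group means and
  attenuates the rank correlation, which is expected behaviour, not error.
* **Menopause, age, flags**: post-menopausal probability 86/228 (benign) and
  119/161 (malignant); ages normal (46.3 ± 16.0 / 57.8 ± 12.6 years)
  truncated at 18; haemolysis, freeze-delay, smoking and family-history
  flags are independent Bernoulli at the published rates — the study found
  no association between pre-analytic flags and marker levels, so none is
  modelled.
* **Grades**: the 31 borderline EOC are allocated entirely to FIGO I–II
  (probability 31/51 there), with grades 1–3 in 13 : 14 : 73 proportion
  elsewhere; this preserves the published grade marginals in expectation
  and concentrates borderline disease in early stage, where the published
  marker levels place it. No stage-by-grade cross-table was published.
* **Seeding**: one PCG64 stream seeded with the config seed, consumed in a
  fixed documented order (benign class first, groups in configured order),
  so identical configs produce byte-identical cohorts. Per-subject stream
  splitting was considered and rejected: the single-stream contract is
  simpler, fully vectorized, and record order is part of the cohort
  contract anyway.

**What passing tests show — and don't.** ROMA-level distributions are *not*
separately calibrated: they emerge from the marker joint distribution and
menopausal mix, and on the default cohort they land close to the published
medians (benign ≈ 7.7 % vs 6.8 printed; malignant ≈ 79 % vs 76.1). The
generator reproduces marginal group structure, not the true joint
dependence of markers, menopause, age and histology in real patients, so
AUC-level agreement with the published 0.898/0.877/0.857 (typically within
~0.01–0.03 on simulated cohorts) is an emergent plausibility check, not a
validation claim; the test suite therefore asserts only directional
end-to-end properties (ROMA AUC > 0.75; excluding borderline tumours raises
the AUC in expectation).

## Pipeline conventions

The full analysis evaluates three markers (CA125, HE4, ROMA-PP) in three
strata (all, pre-, post-menopausal). Two conventions coexist for the pooled
stratum, on purpose: the pooled ROMA *ROC/AUC* is computed on pooled PP
values (one score axis, each subject scored with its own menopause-specific
formula), while pooled *sensitivity/specificity at the suggested cutoffs*
applies each subject's status-specific threshold and then pools the
confusion matrix — the only reading consistent with reporting both a pooled
AUC and stratum-specific suggested cutoffs in one table. The pooled
operating point consequently always lies between the two stratum values
(verified as an invariant). A stratum missing a diagnosis class is omitted
with a warning and the run continues. Rendered CSV tables round AUCs to
three decimals and percentages to one, mirroring conventional reporting;
the JSON bundle is full precision and round-trips exactly.

Subgroup ROCs compare a filtered malignant case set (EOC only, invasive
EOC, FIGO stage sets, grade sets, pure serous/mucinous splits with mixed
subtypes excluded) against the full benign control class. For disjoint case
subsets sharing the controls, the pooled pair-count AUC is exactly the
case-weighted mean of the subgroup AUCs — an algebraic identity the tests
verify numerically.

## Problem sizes

Default simulated cohorts match the published 389-subject composition.
Calibration-recovery checks draw 200,000 samples per marker (sample-median
standard error ≈ 0.3 % of the median, well inside the 1 % acceptance band).
Monte-Carlo calibration of the DeLong inference uses 2,000 replicates of
100-subject datasets. The full test suite runs in well under a minute on a
single CPU.

## Known limitations

* Marker marginals are log-normal by assumption; real marker distributions
  may have heavier tails, and menopausal status does not shift marker
  levels within a group (the published summaries do not stratify markers by
  menopause within histology).
* The copula correlations are invented defaults; subgroup AUC contrasts that
  depend on the CA125–HE4 joint structure (e.g. endometriosis-driven
  pre/post differences) are only qualitatively represented.
* The paired AUC test and CIs are asymptotic; very small strata (a handful
  of cases) return degenerate-flagged results rather than exact inference.
* The CSV schema stores raw booleans for oral-contraception/HRT-style
  covariates only via the generic flag mechanism; published subgroup
  denominators for such rows were internally inconsistent and are not
  reproduced.
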