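# qsmradiomics

Radiomic analysis of the nigrosome-1-containing substantia nigra on
quantitative susceptibility maps (QSM), for differentiating idiopathic
Parkinson's disease (IPD) from healthy controls (HC).

Loss of nigrosome-1 — the "swallow-tail sign" (STS) on iron-sensitive MRI —
is an established imaging biomarker of Parkinson's disease, but its visual
reading is inconsistent across readers and protocols. This package
implements the alternative: extract a standard set of radiomic features
from a susceptibility volume restricted to a nigrosome-1-containing volume
of interest (VOI), select a robust feature subset with an ensemble ranker,
classify subjects with an RBF-kernel SVM under repeated cross-validation,
and report the group-level statistics that characterize the discriminative
features. Because no imaging data from the original cohort are public,
the package ships a calibrated synthetic cohort generator that reproduces
the reported class differences, so the entire pipeline runs and is tested
end to end without any external data.

## What it computes

**Features (105 per subject).** 18 first-order intensity statistics, 13
shape descriptors, and 74 texture features built on five gray-level
matrices: co-occurrence (GLCM, 23), dependence (GLDM, 14), run length
(GLRLM, 16), size zone (GLSZM, 16), and neighbouring gray-tone difference
(NGTDM, 5). GLCM and GLRLM are evaluated along the 13 unique lattice axes
of the 3D 26-neighbourhood at distance δ = 1 and averaged across
directions; for example the run-length feature

    LongRunLowGrayLevelEmphasis = Σᵢ Σⱼ P(i,j) · j² / i²  / N_r

weights long runs (j) of low gray levels (i) among the N_r runs.

**Feature selection.** Three rankers — the one-way ANOVA F statistic,
impurity-based importance of a 10-tree random forest, and recursive
feature elimination (RFE) with a linear SVM — each produce a permutation
of ranks 1..105; the ensemble rank is their arithmetic mean and the top
N = 40 features are kept. RFE also emits the training-accuracy versus
feature-count curve.

**Classification.** Per training fold: standardize to zero mean/unit
variance, rotate into the full PCA basis, then fit an SVM with RBF kernel
K(xᵢ,xⱼ) = exp(−γ‖xᵢ−xⱼ‖²), C = 30, γ = 0.001. The protocol is
stratified 3-fold cross-validation repeated 10 times; AUC (rank-based),
accuracy, sensitivity and specificity are pooled as mean ± SD over the 30
fold records, with IPD the positive class.

**Group statistics.** Unpaired two-tailed t-tests with Bonferroni
threshold 0.05/40 = 0.00125, per-feature ROC AUC (reported on the ≥ 0.5
side), Pearson correlation of features with a motor score (UPDRS-III-like),
and contingency arithmetic for the radiologist's STS reading.

## Worked example

```python
from qsmradiomics import (
    CohortSpec, StudyConfig, generate_cohort, cohort_feature_table,
    ensemble_select, cross_validate, feature_ttests,
    ContingencyTable, contingency_metrics,
)

cohort = generate_cohort(CohortSpec(seed=0))        # 87 IPD + 77 HC images
table = cohort_feature_table(cohort)                # 164 x 105 features
ranks, reduced = ensemble_select(table, n_select=40, seed=0)
report = cross_validate(reduced, StudyConfig(seed=0))
for metric, (mean, sd) in report.pooled().items():
    print(f"{metric:12s} {mean:.2f} +/- {sd:.2f}")

selected = [c for c in reduced.columns if c in table.columns[3:]]
stats = feature_ttests(reduced, selected, family_n=40)
print("significant at 0.05/40:", sum(s.significant for s in stats), "of 40")

sts = contingency_metrics(ContingencyTable(52, 77, 8, 87))
print("STS reading: acc {accuracy:.2%} sens {sensitivity:.2%} "
      "spec {specificity:.2%}".format(**sts))
```

prints

```
auc          0.92 +/- 0.04
accuracy     0.82 +/- 0.06
sensitivity  0.85 +/- 0.09
specificity  0.78 +/- 0.11
significant at 0.05/40: 27 of 40
STS reading: acc 79.88% sens 67.53% spec 90.80%
```

The classifier separates the synthetic cohort well (pooled AUC 0.92 here),
27 of the 40 selected features differ significantly between groups after
Bonferroni correction, and the sign-reading metrics follow exactly from
the 52/77 and 8/87 reading counts.

The same pipeline is available from the shell:

```bash
qsmradiomics run-all --seed 0 --out results/run0
qsmradiomics simulate --seed 1 --out cohort/ --write-images
qsmradiomics extract --cohort-dir cohort/ --out features.csv
qsmradiomics select --features features.csv \
    --out-ranks ranks.json --out-reduced reduced.csv
qsmradiomics classify --features reduced.csv --out cv.json
qsmradiomics stats --features reduced.csv --family-n 40 --out stats.json
```

## Layout

- `src/qsmradiomics/features.py` — discretization, gray-level matrices,
  the 105-feature roster and extraction
- `src/qsmradiomics/synthetic.py` — image-level cohort generator and the
  direct Gaussian feature-table generator
- `src/qsmradiomics/selection.py` — ANOVA / random-forest / RFE ranking
  and ensemble selection
- `src/qsmradiomics/classify.py` — standardize → PCA → RBF-SVM repeated CV
- `src/qsmradiomics/stats.py` — t-tests, per-feature AUC, correlation,
  contingency metrics
- `src/qsmradiomics/io.py`, `config.py`, `cli.py` — NIfTI/CSV/JSON I/O,
  study configuration, command-line interface
- `docs/methods.md` — model assumptions, parameter choices, limitations
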