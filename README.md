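# texnac

Texture and kinetic analysis of dynamic contrast-enhanced (DCE) breast MRI
for predicting **non-response to neoadjuvant chemotherapy (NAC)**.

## The problem

A substantial fraction of breast-cancer patients scheduled for NAC do not
benefit from it. Identifying likely non-responders (NR) *before* treatment
— as opposed to partial or complete responders (PR/CR) — from the baseline
MRI would allow alternative therapy to be considered early. `texnac`
implements a desk-scale version of this radiomics workflow for a cohort
modelled on a 69-patient study population (19 NR / 36 PR / 14 CR):

1. **Synthetic data** — dynamic-series phantoms (1 pre-contrast + 5
   post-contrast frames, Δt = 60 s) with ground-truth lesion masks, and
   labelled cohorts whose biomarker frequencies and class-conditional
   texture/kinetic differences have the structure the analysis assumes.
2. **Kinetics** — subtraction images (post − pre), ROI signal–time curves,
   and the three semi-quantitative curve parameters:
   *amplitude* = max enhancement over the post-contrast points,
   *wash-in* = slope between the peak and the preceding point,
   *wash-out* = OLS slope over the last three points.
3. **Segmentation** — per-pixel (amplitude, wash-in) maps inside a
   rectangular search box, 2-means clustering (lesion = higher-amplitude
   cluster), morphological opening, largest 4-connected component;
   validated by Dice overlap against the manual mask.
4. **Texture** — grey-level co-occurrence matrix (GLCM) and run-length
   matrix (RLM) at pixel distance 1, pooled over the four main directions,
   on 5-bit min–max quantized masked images; 9 GLCM features (energy,
   entropy, contrast, homogeneity, correlation, inverse difference moment,
   sum average, sum variance, difference variance) and 11 RLM features
   (SRE, LRE, GLN, RLN, RP, LGRE, HGRE, SRLGE, SRHGE, LRLGE, LRHGE);
   sliding-window feature maps scaled to 0–255.
5. **Statistics** — Wilcoxon rank-sum, D'Agostino–Pearson normality,
   two-sided **mid-P Fisher** exact tests on 2×2 biomarker-by-response
   tables, empirical ROC with trapezoidal AUC (= Mann–Whitney U/n₁n₂) and
   Youden-index cut-offs, DeLong-style paired AUC comparison.
6. **Prediction** — multi-parametric classification of NR vs PR+CR with
   leave-one-out cross-validation (LOOCV): logistic regression, and a
   2-means / L1 nearest-centroid classifier (2 random observations as
   initial centroids, 30 replicates); exhaustive feature-subset search over
   the 26 parameters (20 texture + 3 kinetic + mass/non-mass + Ki67 > 14 %
   + HR−/HER2+).

## Worked example

Run the full pipeline on the default synthetic cohort (69 patients):

```bash
$ texnac run --out demo --seed 1
done: Se=95% Sp=92% accuracy=93% (demo)
```

This simulates the cohort, validates the automatic segmentation against
the manual masks (`demo/segmentation.csv`), measures the 26 parameters per
patient (`demo/features.csv`), performs per-feature ROC analysis
(`demo/roc.csv`) and mid-P Fisher tests for the binary markers
(`demo/fisher.csv`), and evaluates the 4-parameter k-means model
(inverse difference moment, GLN, LRHGE, wash-in) by LOOCV
(`demo/model.json`):

```json
{"subset": ["inv_diff_moment", "gln", "lrhge", "wash_in"],
 "classifier": "kmeans",
 "se": 94.7, "sp": 92.0, "accuracy": 92.8,
 "confusion": {"tp": 18, "fn": 1, "tn": 46, "fp": 4}}
```

Se is the percentage of non-responders classified correctly over the
LOOCV folds (here 18/19), Sp the percentage of responders (46/50).  The
per-feature ROC table shows the planted class differences, e.g.
inverse difference moment AUC 0.94 (higher in NR — smoother texture) and
wash-in AUC 0.94 (lower in NR — slower uptake).  Synthetic cohorts are
calibrated to make the planted effect clearly detectable; the numbers
quantify the pipeline's machinery, not clinical performance.

A single statistic from the command line:

```bash
$ texnac fisher --table 8,5,11,45
mid-P two-sided p = 0.00534274
```

— the association between Luminal-A subtype and non-response for the
study's printed counts (8 of 13 Luminal-A patients were NR vs 11 of 56
others), p ≈ 0.005.

Other subcommands: `simulate`, `kinetics`, `segment`, `features`, `roc`,
`predict`, `search` (see `texnac --help`).

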