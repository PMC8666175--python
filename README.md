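# srmquant

A targeted-proteomics (SRM/MRM) quantification pipeline for multiplexed
protein panels measured with stable-isotope-labeled (SIL) internal
standards. The package implements the full computational arc of a
CPTAC-style assay: in-silico tryptic digestion and proteotypic-peptide
selection, transition-level light/heavy ratio quantification with
interference exclusion, assay characterization (LLOD, LLOQ, linearity, CV
components), normalization and peptide-to-protein rollup, differential
abundance with FDR control, PCA and Ward clustering, and biomarker-panel
classification under leave-one-out cross-validation (LOOCV).

The motivating application is a 13-enzyme one-carbon-metabolism (1CM)
panel (GNMT, AHCY, CBS, CGL, DHFR, MAT1A, MAT2A, MAT2B, MTAP, BHMT,
SHMT1, SHMT2, METH) measured in human liver across three clinical
classes — control, cirrhosis, and hepatocellular carcinoma (HCC) — where
the pathway's reconfiguration acts as a *functional* biomarker. Because
the processed study data are not redistributable, a first-class
synthetic-data generator reproduces each experiment class (dilution
series with blanks, a days x replicates repeatability design, and the
clinical cohort) with known ground truth, making every downstream stage
testable.

## Core quantities

- **Peptide ratio.** For peptide *p* in run *r*, with usable transition
  set *T* (interference-excluded):
  `R_pr = sum_{t in T} light_t / sum_{t in T} heavy_t`
  (orientation flips to heavy/light in calibration experiments, where the
  SIL standard is the titrated analyte).
- **LLOD.** Signal threshold `mean(blank) + 3*SD(blank)` over >= 3 blank
  matrix runs (fallback `3*SD(lowest spike)` when blanks show no signal),
  inverted through the 1/x^2-weighted calibration line to fmol.
- **LLOQ.** The lowest spiked level with replicate CV < 20%, all higher
  levels also qualifying.
- **CV components** from the days x replicates design:
  `intra = mean_d CV(replicates in day d)`,
  `inter = mean_j CV(injection j across days)`,
  `CV_t = sqrt(intra^2 + inter^2)`; peptides are accepted when all three
  are < 20% at every level.
- **Rollup.** Protein estimator per sample
  `y = sum_p w_p x_p`, `sum w_p = 1`, with `w_p ∝ 1/Var(x_p)`
  (minimum-variance combination) or equal weights.
- **Cohort statistics.** Per-protein linear model of log2 abundance on
  condition with F tests and Benjamini–Hochberg q-values per contrast
  family; PCA and Ward clustering on centered/scaled estimators.
- **Classification.** Proteins ranked by ANOVA p-value; nested panels of
  1..13 proteins evaluated with LDA, QDA, multinomial logistic regression
  and random forests under LOOCV; the selected model is reported with its
  confusion matrix and per-class one-vs-rest ROC/AUC.

## Worked example

Run the five numbered analyses (each a thin driver over the library), or
equivalently `srmquant run-all --seed 1 --out-dir results/pipeline`:

```sh
python analysis/01_simulate.py     --seed 1 --out-dir results/pipeline
python analysis/02_assay_qc.py     --seed 1 --out-dir results/pipeline
python analysis/03_quantify.py     --seed 1 --out-dir results/pipeline
python analysis/04_cohort_stats.py --seed 1 --out-dir results/pipeline
python analysis/05_classify.py     --seed 1 --out-dir results/pipeline
```

prints

```
wrote 6480 calibration rows, 10800 replicate-design rows, and a 62-sample cohort to results/pipeline
accepted 40/40 peptides; LLOD 0.49-2.82 fmol, LLOQ 0.5-1 fmol, 21 transitions excluded for interference
rolled 40 peptides up into 13 protein estimators -> results/pipeline/protein_matrix.csv
39 significant (q < 0.05) pairwise contrasts; PC1 explains 71.1% of variance; protein clusters of sizes [7, 6]
best model: LDA with a 6-protein panel (CGL, AHCY, MAT1A, BHMT, MTAP, CBS); LOOCV accuracy 100.00%, in-sample 100.00%; one-vs-rest AUC: control 1.0000, cirrhosis 1.0000, HCC 1.0000
```

Reading the output: the 40-peptide panel is characterized from the
dilution series (detection limits around 0.5–3 fmol, quantifiable from
the lowest levels) and the repeatability design (all peptides under the
20% CV acceptance bound). The cohort analysis recovers the two
generator-defined protein clusters (7 liver-enriched proteins down in
HCC, 6 ubiquitous proteins up), separates the conditions along PC1 with
cirrhosis intermediate, and — at the default, well-separated effect size
of 1 log2 unit — classifies the 62 samples perfectly from a 6-protein
panel. Shrink `hcc_effect`/raise `cohort_noise_sd` in the config for
harder, more realistic regimes.

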