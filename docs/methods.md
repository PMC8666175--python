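# Methods

## Scope and model

The package models a multiplexed SRM/MRM assay in which each protein is
represented by a few proteotypic peptides, each peptide by a few
precursor→fragment transitions, and each transition by one chromatographic
peak area per run. Quantification is relative: the endogenous/unlabeled
("light") signal is referenced to a stable-isotope-labeled ("heavy")
synthetic peptide spiked at known amount, so run-level technical variation
that scales both labels cancels in the ratio.

Assumptions worth making explicit:

- areas are non-negative and already integrated (peak picking and
  integration are upstream, Skyline-style; this package never touches raw
  chromatograms);
- a peptide's transitions measure the same molecule, so their light/heavy
  ratios agree up to noise — disagreement beyond a fold tolerance is
  treated as interference;
- peptides are pure surrogates of their protein: condition effects act at
  the protein level and peptides inherit them.

## Synthetic data generator

The generator emulates the three experiment classes that characterize and
then apply the assay. Defaults are the study design sizes: a
0.5–1000 fmol dilution series (8 levels, 3 replicate runs per level,
3 blank matrix runs, light counterpart fixed at 100 fmol), a repeatability
design of 3 injections x 5 days at 5/50/500 fmol heavy with 30 fmol fixed
light, and a clinical cohort of 28 control / 15 cirrhosis / 19 HCC
samples over the 13-protein, 40-peptide panel (4 peptides for one protein,
3 for the rest; 3 transitions each).

Noise model: spiked peak areas are multiplicative-lognormal around
`slope x amount` with a concentration-dependent CV (defaults fall from 10%
at 0.5 fmol to 3% at 1000 fmol, reproducing the CV inflation toward the
detection limit), plus a small zero-mean additive residual (default SD 50
area units). Blank-run signal draws from a Normal(1000, 900) truncated at
zero. The two are deliberately decoupled: integrated peak areas in spiked
runs are effectively background-subtracted, so the blank distribution
enters blank runs only. This is what lets the generator reproduce the
empirically observed regime in which the blank-derived LLOD (≈0.5–4 fmol)
sits at or above the CV-derived LLOQ (≈0.5–1 fmol) — the two limits use
different arithmetic and need not be ordered. A generator that added the
full blank distribution to every spiked area would force LLOQ far above
LLOD and could not reproduce that regime.

The lognormal noise draw is shared across a peptide's transitions within a
run (injection/ionization noise acts at the precursor level); the additive
residual is per transition. The lognormal's log-SD is
`sqrt(log(1+CV^2))` so the requested CV is exact, and the distributional
form itself is a stand-in — the experiments emulated here do not identify
it.

Repeatability runs decompose the heavy area as
`expected x exp(day) x exp(rep)` with `day ~ N(0, sigma(inter_cv))` per
(peptide, level, day) and `rep ~ N(0, sigma(intra_cv))` per injection
(defaults 5% intra, 8% inter). Light areas in this design are noise-free
so the ratio carries exactly the two configured components.

Cohort samples are generated directly on the normalized log2 scale:
protein baseline + condition effect + per-peptide offset
(SD 0.3) + N(0, 0.5) residual. Condition effects follow the two-cluster
structure: the seven liver-enriched proteins (GNMT, CBS, CGL, MAT1A, BHMT,
SHMT1, SHMT2) move down in HCC and the six ubiquitous ones (AHCY, DHFR,
MAT2A, MAT2B, MTAP, METH) up, by ±1 log2 unit at default, with cirrhosis
at half the HCC effect (an intermediate, pre-tumoral state). All
generators take explicit seeds; there is no global random state.

What the generator does *not* emulate: retention-time drift, peak-shape
pathology, missingness mechanisms (censoring must be injected explicitly),
batch structure in the cohort, and correlated biological variation between
proteins beyond the condition effects. Passing tests therefore demonstrate
correctness of the estimators under the stated noise model, not robustness
to every failure mode of real chromatography.

## Assay characterization

- **Calibration fit.** The response curve (summed heavy area vs nominal
  fmol) is fitted with 1/x^2-weighted least squares, the standard choice
  when noise is proportional to signal; an unweighted fit lets the top
  levels swing the intercept by thousands of area units, which dominates
  the back-calculated LLOD. Ratio-scale linearity (the reported R^2) is
  unweighted; protein-level linearity averages the protein's peptide
  ratios per level before fitting, and R^2 is reported against a
  configurable lower acceptance bound (default 0.9).
- **LLOD** = inverse of the calibration line at `mean+3SD` of >= 3 blank
  runs, floored at zero; when no blank shows signal the threshold is
  `3*SD` of the lowest spiked level (no mean term — the fallback estimates
  spread only). LLOD is monotone in the blank SD by construction.
- **LLOQ** is the lowest level with replicate CV < 20% *and* every higher
  level also below 20%; the monotonicity requirement prevents a noise dip
  at one low level from defining a spurious LLOQ. LLOQ may legitimately
  fall below LLOD (different arithmetic); the report carries a
  `lloq_below_llod` flag rather than reconciling them.
- **CV components.** All CVs are sample SD/mean (ddof = 1) on the ratio
  scale, in percent. Intra-assay = mean over days of the within-day
  replicate CV; inter-assay = mean over injection index of that
  injection's across-day CV; total = quadrature sum. Note these
  averaged-CV estimators carry small-sample bias (E[S] = c4(n)·σ,
  c4(3) ≈ 0.886), so with 3 replicates the intra estimate sits ~11% below
  the generating σ; tests therefore validate against a Monte-Carlo oracle
  of the same estimand, not against σ itself. Missing cells are tolerated
  while >= 2 values remain per retained slice and >= 2 slices per axis.
- **Acceptance**: a peptide passes when intra, inter, and total CV are all
  under the threshold (default 20%) at every level; protein-level total CV
  averages the accepted peptides' totals.

## Quantification

- **Interference exclusion** automates what is manual peak curation in
  practice: within each (run, peptide), a transition whose light/heavy
  ratio deviates from the within-peptide median by more than the fold
  tolerance (default 2) in either direction is excluded; at least one
  transition is always retained, and single-transition peptides are
  returned unflagged with a warning. The median rule assumes interference
  hits a minority of transitions; with only 3 transitions a contaminated
  *pair* captures the median and the rule flags the clean one instead.
- **Ratios** are summed-transition (area-weighted) rather than averaged
  per-transition: strong transitions dominate, damping weak-transition
  noise. Zero or absent denominators yield missing ratios with reason
  codes, never fabricated values.
- **Normalization**: the per-run technical factor is the median over
  peptides of (log2 heavy area − that peptide's across-run mean), i.e. a
  median-polish-style run effect estimated from the spiked-constant heavy
  standards; subtracting it levels the standards across runs. The median
  is robust at the panel's small size (<= 40 peptides); a config switch
  substitutes the least-squares two-way (run + peptide) fit, whose run
  coefficients are the mean of the same residuals. Runs with < 3 heavy
  observations keep factor 0 and are flagged.
- **Rollup**: protein estimator = weighted sum of the protein's
  non-missing peptides with weights renormalized per sample, so adding a
  constant to all peptides shifts the protein by the same constant.
  Default weights ∝ 1/variance of the peptide across samples — the
  minimum-variance combination when peptide errors are independent.
  When shared biological variation dominates, the variances converge and
  the weights approach equality, which is the conservative limit; an
  equal-weight scheme is available. Whether the original weighted sums
  used inverse-variance weights is not established; the default is this
  package's choice.

## Cohort statistics

Per protein, a one-way fixed-effects linear model of log2 abundance on
condition (row-wise deletion of missing cells): overall condition F test
plus the three pairwise contrasts with effects in log2 units and
F = t^2 statistics from the pooled residual variance. Implemented with
direct linear algebra for speed under simulation; an optional
subject-blocking path (two-way OLS via statsmodels) serves repeated-
measures designs — in the default cohort each subject contributes one
sample, so no subject term is fitted. Degenerate inputs return p = 1 with
a zero-variance flag rather than erroring. FDR control is
Benjamini–Hochberg, applied within each contrast family across the 13
proteins (matching per-contrast q < 0.05 reporting); the step-up q-values
are order-preserving and capped at 1.

PCA and clustering operate on the centered, unit-variance protein
columns; missing cells are first imputed with the protein's half-minimum
observed value (a left-censored, below-detection-limit mechanism).
Zero-variance proteins are excluded with a warning before scaling. PCA is
the exact SVD; variance fractions sum to 1 over the retained components.
Protein clustering is Ward's method on the Euclidean distance matrix
between protein profiles, cut at a user-chosen k (default 2 — the cluster
count is an inspection choice, not estimated).

## Classification

Proteins are ranked by one-way ANOVA p-value (ties and zero-variance
proteins break deterministically on the name) and nested panels of the
top 1..13 feed four fixed-default algorithms: LDA, QDA, multinomial
logistic regression (unregularized), and a 100-tree seeded random forest.
No hyperparameter tuning anywhere — model complexity is controlled by
panel size. Out-of-sample error is LOOCV; by default the ANOVA ranking is
recomputed inside every training fold so feature selection cannot leak
the held-out sample, with a `rank_once` switch reproducing the simpler
rank-on-everything protocol (the two coincide in well-separated regimes).
QDA is skipped with a recorded warning in folds where a class has fewer
training samples than panel size + 1 (singular class covariance), and any
residual rank failure is likewise caught and recorded.

The final report pools LOOCV held-out class probabilities into the
confusion matrix (trace/n is exactly the out-of-sample accuracy),
per-class one-vs-rest ROC curves, and trapezoidal AUC; accuracies are
reported in percent to two decimals. Two LOOCV artifacts are worth
knowing: under null (permuted) labels the pooled held-out probabilities
are *pessimistically* biased — the held-out sample's class is always
under-represented in its training fold — so null AUC sits near 0.36
rather than 0.50 at n = 62, and a single model's null accuracy falls
between sum(p_c^2) and the largest-class rate. The grid's *selected* best
cell, by contrast, averages near the largest-class rate (45.2% here)
under the null because model selection inflates the maximum; tests check
both behaviors in their respective forms.

## Numerical and engineering choices

- Seeds are explicit everywhere; stage seeds derive from the master seed
  by fixed offsets, and identical configurations produce byte-identical
  outputs (retention times and panel identities come from stable hashes,
  not Python's salted `hash`).
- Missing areas are empty CSV fields, never 0 (0 is a legal blank area);
  readers reject negative areas, invalid residues, and duplicate keys
  with line numbers, and never silently drop rows.
- Degenerate inputs follow explicit contracts: insufficient blanks or
  levels raise typed errors; a CV threshold of 0 accepts no peptides and
  downstream stages skip with warnings instead of failing.
- Default problem sizes (8-level/3-replicate calibration, 5x3 design,
  62-sample cohort, 13x4 LOOCV grid) run the full pipeline in about two
  minutes on one CPU; simulation-based tests size their replication
  (100–1000 draws) to keep statistical power while staying fast.

## Known limitations

- The interference rule needs >= 3 transitions to isolate a single
  contaminated transition reliably, and >= 5 to survive contaminated
  pairs.
- Inverse-variance rollup weights are estimated from the same samples
  they weight; with few samples the weights are noisy (the equal-weight
  scheme is safer below ~10 samples).
- The differential model assumes homoscedastic residuals across
  conditions; the F tests are exact under normality and only
  asymptotically calibrated otherwise.
- With 62 samples, LOOCV accuracy has high variance and the selected
  best grid cell is optimistically biased; the final model's reported
  LOOCV accuracy is conditional on that selection, as in the emulated
  protocol.
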