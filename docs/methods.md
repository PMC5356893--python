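# Methods

## Data model and conventions

Expression matrices are genes × samples (the qPCR array export
convention). Non-detects are carried as an explicit boolean mask with NaN
in the value cell; a "plausible" sentinel Ct never appears in memory — the
Ct-40 substitution exists only as the explicit `substitute_ceiling`
preprocessing arm. The positive class is *recurrent* throughout. Staging
comparisons are component-wise: "T2bN0M0 or below" means T ≤ T2b **and**
N = N0 **and** M = M0, not a lexicographic order on the combined string
("< T2c" and "≤ T2b" are the same cut on the T axis). Follow-up times are
stored in months; week-denominated inputs are converted at ingestion
(weeks × 12/52).

## ΔCt normalization

`expr[g,s] = Ct[ref,s] − Ct[g,s]`, so higher values mean more transcript
and the unit is log2 fold over the reference gene (BECN1 by default). The
reference must be detected in every sample (it is a highly expressed
housekeeping gene; a failed reference reaction indicates a failed sample,
and the error names it). Normalization is exactly invariant to a constant
Ct shift applied to a whole sample, which is the plate-level nuisance it
exists to remove. The reference row is dropped from the output: its
normalized value is identically zero.

## EM imputation of non-detects

Model: for gene g in group k, log2 expression y ~ N(μ_gk, σ_g²) with the
variance pooled across groups within a gene; detection failure follows a
logistic law shared by all genes, Pr(ND | y) = expit(β₀ + β₁·y). This is
the minimal model that honors a *non-random* missing-data mechanism: a
single (β₀, β₁) pair links missingness to expression, and β₁ < 0 encodes
"low expression amplifies less reliably".

The E-step computes, for each non-detect cell, the posterior mean and
second moment of y under density ∝ N(y; μ, σ²)·expit(β₀+β₁y), by 64-point
Gauss–Hermite quadrature — deterministic given the parameters (the seed
only jitters the initial β). The M-step updates μ and σ² from observed
values and posterior moments, then maximizes the expected logistic
log-likelihood over (β₀, β₁) with a weak L2 penalty (10⁻⁶) that keeps the
optimum finite when the data contain no non-detects at all. The observed
log-likelihood is monotone non-decreasing across iterations (asserted to
1e-9 in tests); convergence is declared when it changes by < `tol`
(default 1e-6), and hitting `max_iter` sets `converged=False` on the
returned model rather than raising. Note the default tolerance stops at
roughly 0.1-accurate β estimates on small single-gene problems; parameter-
recovery comparisons in the tests tighten `tol` to 1e-9.

**Grouping and calibration.** The group structure of μ_gk is chosen by the
caller. Passing outcome labels reproduces the within-outcome-group means
the original analysis used, but it is anticonservative for downstream
differential expression: imputing each group's non-detects toward that
group's own mean manufactures separation for null genes, and on a
1000-gene null cohort it inflates the nominal 0.05 t-test rate to ≈ 0.084.
The label-free default (one group per gene) is calibrated (≈ 0.059, within
3 binomial SE) and is what blinded cohorts get, since their labels are
unknown by construction. The training pipeline passes labels for fidelity
to the original procedure; users who prefer calibrated selection can
withhold them.

Imputation in `run_train` is fit once on the whole training cohort before
the LOOCV grid, mirroring the original cohort-wide preprocessing; the
`impute_nondetects` API accepts arbitrary sample subsets, so a per-fold
refit is a caller-side loop if full leakage avoidance is wanted. The
dominant leakage channel inside LOOCV is signature selection, which *is*
switchable (below).

## t-test variants and signatures

Welch is the default (the sensible reading of an unqualified "two-tailed
t-test" with no variance-homogeneity claim); pooled is available, and a
censored variant maximizes a Gaussian likelihood with left-censored terms
Φ((bound−μ)/σ) at the detection bound and compares null vs split-mean
fits by a 1-df likelihood ratio. The censored variant is an approximation
to censored-ML group comparison, not a replica of any particular package's
internals. Signatures take genes with p **strictly** below the cutoff,
ordered by ascending p; an empty signature raises `EmptySignatureError`
because classification in zero dimensions is undefined. No
multiple-testing correction is applied anywhere: the cutoff is a
classifier tuning parameter swept by cross-validation, not an inference
claim, and the signature report header says so.

Signed fold changes are computed on normalized log2 means:
r = 2^(μ_rec − μ_non), reported as r if r ≥ 1 else −1/r, so |fold| ≥ 1 and
the sign tracks direction in the recurrent group (+1 at exact equality).
Folds are computed on imputed data by the training pipeline.

## Scorers and the decision rule

All three scorers work on unstandardized log2 ΔCt values (already a
common scale; no per-gene standardization is applied). The distance
scorer averages within-group distances by default: a raw sum grows with
group size, which silently biases the decision toward the smaller group
in unbalanced cohorts (invisible in a 16/16 design); `raw_sum` restores
the summed convention. Prediction takes the lower score; the margin is
(non-recurrence − recurrence score) and a sample is called recurrent iff
margin + modifier ≥ 0. Ties at the boundary go to recurrent — the design
consistently prioritizes sensitivity, since a false negative withholds
adjuvant therapy from a patient who needs it. The modifier convention is
chosen so that +10 calls every sample recurrent and −10 none, and 0
reproduces the base rule exactly; ROC curves evaluate every modifier at
which some prediction flips (the negated margins) plus sentinels beyond
both ends, giving curves that always contain (0,0) and (1,1), with AUC by
trapezoid.

## LOOCV and model selection

`full_set` mode selects the signature once on the full training set
and reuses it in every fold; this lets the held-out sample influence gene
selection and inflates LOOCV estimates, so a warning is logged whenever
it runs. `nested` re-selects inside each fold and is the recommended
mode; nested folds with an empty signature fall back to the tie-rule
label (recurrent) and are flagged on the grid cell. The default p-cutoff
grid is {0.01, 0.02, 0.05, 0.10, 0.20} (configurable). Marginal summary
curves (mean accuracy over algorithms per data handling, and vice versa)
carry a trapezoidal area over the cutoff axis for comparison purposes;
winner selection uses only per-cell accuracy with the deterministic tie
cascade (sensitivity, signature size, centroid < distance < nearest
neighbor, imputed < unimputed).

## Clinical strategies

The surgical rule requires negative margins by default; a flag drops the
margin clause for the staging-only variant. "Gleason grade 2–6" in the
CRG+Gleason strategy is read as the Gleason *sum* 2–6, and the 7–8 band
defers to the expression classifier. Strategy composition is purely
deterministic given the classifier's per-sample labels, and the
strategies that never need the classifier (2, 3, 4, 7, 8) never touch it.
The staging fields consumed are whichever staging the clinical table
carries (the table schema has one TNM triplet per patient).

## Survival analysis

Kaplan–Meier estimation and the two-group log-rank test are delegated to
`lifelines` (product-limit estimator; hypergeometric variance at each
distinct event time, 1-df chi-square, two-sided p). Tests cross-check the
KM curve against a direct product-limit computation and the log-rank
statistic against an independent O−E/variance implementation plus an
exhaustive permutation oracle on 6-subject fixtures.

## Synthetic cohorts

The generator draws, per gene, a baseline log2 expression (N(0, 2)),
shifts signature genes by log2|fold|·sign(fold) in recurrent samples
(defaults: HBEGF −2.2, HOXC13 +6.7, IGFBP2 −1.4, SATB1 −3.1), and adds
per-cell Gaussian noise (default sd 1.0 log2 units; the package's
scaled-down reproductions use 0.5 to reflect a low-noise assay).
Expression maps to cycles via ct = ref_ct − expr with a per-sample
reference Ct ~ N(25, 0.5), so ΔCt normalization has a real plate quantity
to remove. Non-detects are drawn from expit(β₀ + β₁·y) with defaults
(−4, −1): ≈ 2% failure at the reference level, 50% at 16-fold below. The
reference gene itself is always detected. Default cohort shape is 16/16
training and 13/10 validation on a 96-gene panel.

Clinical covariates mix a baseline profile with an aggressive-disease
profile at weight `clinical_association` (default 0.75). The aggressive
profile concentrates mass at ≥ T2c, nodal/metastatic involvement,
positive margins and high Gleason, reflecting that biochemical recurrence
after prostatectomy nearly always implies capsular escape; under the
defaults, P(organ-confined with negative margins | recurrent) ≈ 0.08, so
the surgical rule finds true negatives without erasing sensitivity.
Recurrence times are Weibull (shape 1.5, scale 51.4 months ⇒ median
≈ 40 months); censoring times for non-recurrent patients are uniform on
36–120 months (everyone has ≥ 3 years of follow-up). The null generator
keeps the cohort shape but zeroes all expression shifts and sets the
clinical association to 0.

**What the generator does not emulate:** stromal-content confounding,
plate/batch effects, amplification-efficiency differences, replicate
wells, or correlated noise between genes. Passing tests therefore show
the pipeline's operations are correct and calibrated under the assumed
model, not that the four-gene signature would validate on new tissue.

## Problem sizes and numerical choices

Test and reproduction problem sizes are chosen to keep the full suite
fast while leaving no operation untested at realistic scale: study-shaped
cohorts (96 × 55) for pipeline tests, 1000 genes for type-I calibration,
200/class for fold-change recovery, 500 events for Weibull recovery, and
200 random instances for scorer-oracle equivalence. Quadrature is fixed
at 64 Gauss–Hermite nodes; EM tolerance 1e-6 (1e-9 where parameter
agreement with an oracle is asserted); grid/oracle comparisons use the
oracle's own grid resolution as tolerance.

## Known limitations

- A borderline effect (|fold| 1.4 at noise sd 0.5, n = 16/16) sits at the
  p < 0.01 detection boundary: its expected |t| ≈ 2.75 equals the
  critical value, so a 4/4 signature recovery at that cutoff is a coin
  flip for any given seed. The suite asserts recovery of the three
  high-power genes unconditionally and documents the fourth's borderline
  status here.
- The censored-likelihood t-test is a 1-df LRT approximation and is
  slightly anticonservative at very small n.
- `full_set` LOOCV estimates are optimistic by construction; use
  `nested` when the estimate itself matters.
- The distance scorer's `raw_sum` convention is only meaningful for
  balanced training groups.
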