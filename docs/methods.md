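# Methods

This note documents the statistical model behind `drugtarget_mr`, the
defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical decisions that were genuinely open.

## Model

The package treats a drug target pharmacologically: variants in a
cis-window around the target gene that alter its expression and move a
downstream biomarker are treated as lifelong, randomly assorted analogues
of taking the drug. Weighting those variants by their biomarker effects
and *negating* the betas expresses estimates per unit of biomarker-lowering
(inhibition), so an odds ratio below 1 means the drug-like exposure is
protective.

All estimation is two-sample summary-data MR. For instruments j = 1..k
with exposure effects βXⱼ (se σXⱼ) and outcome effects βYⱼ (se σYⱼ) aligned
to a shared effect allele, the Wald ratio is βYⱼ/βXⱼ with first-order se
σYⱼ/|βXⱼ|; IVW pools ratios with weights βXⱼ²/σYⱼ², equivalent to weighted
regression through the origin. Cochran's Q = Σwⱼ(βYⱼ/βXⱼ − β̂)² is referred
to chi-square on k−1 df (k−2 for the Egger residual). MR-Egger re-runs the
weighted regression with an intercept after orienting every pair so
βXⱼ ≥ 0; the weighted median interpolates the weighted ratio distribution
at 50%; MR-PRESSO compares observed leave-one-out residual sums of squares
to a parametric no-pleiotropy null.

Mediation uses the product method on the summary scale. β2′, the mediator
effect conditional on the exposure, comes from multivariable IVW: weighted
regression (weights σYⱼ⁻², no intercept) of outcome betas on the k×2 matrix
of exposure and mediator betas over the union of both instrument sets, with
exposure betas for mediator instruments looked up in the full exposure
GWAS. The proportion mediated β1·β2′/β3 is reported signed and unclamped;
values outside [0, 1] (inconsistent mediation, i.e. indirect and total
effects of opposite sign) raise a warning rather than an error because the
quantity remains interpretable as a signed ratio.

## Key parameters

| parameter | default | rationale |
|---|---|---|
| biomarker association p | 1e-4 | drug-target candidate filter |
| expression association p | 1e-4 | not separately specified by convention; configurable, echoed in the run report |
| drug-target clumping | r² < 0.8, 1,000 kb | deliberately lenient cis profile; residual correlation triggers a warning because the estimators assume independent instruments |
| metabolite profiles | relaxed p<1e-5, r²<0.1, 500 kb; strict p<5e-8, r²<0.001, 10 Mb | relaxed keeps power for small metabolite GWASs; strict guards against weak-instrument bias |
| coloc priors p1, p2, p12 | 1e-4, 1e-4, 1e-5 | canonical single-causal-variant priors |
| coloc prior sd | 0.15 (quantitative) | canonical effect-size prior; the decision rule is PP.H4 > 0.70 alone, no H3/H4 ratio |
| IVW mode | multiplicative random effects | dominant two-sample convention; inflation floored at 1, fixed mode available and recorded |
| weak-instrument F | 10 | conventional threshold |
| CI multiplier | 1.96 | 95% intervals throughout; p-values two-sided normal, not t |
| MR-PRESSO n_sim | 1000 | add-one p-value floor 1/(n_sim+1); outlier alpha 0.05 Bonferroni over k; removal is single-pass |
| weighted-median n_boot | 1000 | parametric bootstrap; the seed is a mandatory argument — no hidden global randomness |

## Synthetic data: what it emulates

Generators draw summary statistics directly at summary level: marginal
betas are LD-propagated true joint effects plus multivariate normal noise
with covariance LD/n, standard errors 1/√n on the standardized scale. This
is sufficient (and fast) for every estimator here; individual-level
genotypes are generated only to test LD-matrix computation. Default sample
sizes mirror the study design the package targets: a 344k-individual
biomarker GWAS, an 8.3k metabolite panel with an equally sized independent
replicate, a 140k case-control outcome and 219k-scale screening outcomes.
Default instrument strength (0.012 sd per allele against se ≈ 0.0017)
puts per-SNP F statistics in the 20–95 band typical of cis drug-target
instruments.

Horizontal pleiotropy is simulated as direct instrument→outcome effects
expressed **relative to the exposure-increasing allele**: "directional"
pleiotropy means directional after orienting instruments by their exposure
effect, which is the quantity the Egger intercept actually tests (an
orientation-agnostic constant shift would cancel under allele flips and be
indistinguishable from balanced pleiotropy). Because the Egger covariance
carries multiplicative overdispersion, intercept power requires the
directional mean to dominate the pleiotropy spread; the property tests use
mean 0.05 with spread 0.01 for power checks and spread 0.02 elsewhere.

Not modeled: realistic allele-frequency spectra, imputation noise, and
sample overlap between the exposure and outcome GWASs (the generators
assume non-overlapping samples). Passing tests therefore demonstrate
estimator correctness and calibration under the stated DAG, not robustness
to overlap-induced bias or frequency-dependent LD structure.

## Numerical choices

- Colocalization sums are normalized with log-sum-exp; H3 uses a stable
  log-difference (cross-product sum minus same-variant diagonal), so
  |z| > 30 does not overflow. With p12 = 0, PP.H4 is exactly 0. Note the
  posteriors are invariant to a change of units (scaling betas, ses *and*
  the prior sd together); scaling betas and ses alone changes V relative
  to the fixed effect-size prior and thus the Bayes factors slightly.
- Duplicate variant ids on read keep the lowest-p row, ties broken by file
  order. Palindromic (A/T, C/G) variants are excluded when either dataset's
  allele frequency is missing or within 0.08 of 0.5, and otherwise strand-
  inferred by comparing which side of 0.5 the two frequencies fall on.
- Clumping sorts by (p, position, id) so output is deterministic and
  invariant to input order; r² ≥ threshold prunes (strict inequality
  retains), matching "exclude r² ≥ 0.001" conventions.
- MVMR rank checks use matrix rank plus a condition-number bound (1e8);
  the covariance uses a pseudo-inverse so a deliberately degenerate design
  (guard relaxed in tests) still reduces to univariable IVW.
- CI→se conversion for literature-style inputs is (upper−lower)/(2·1.96)
  exactly, used only when ingesting quoted intervals.
- Every stochastic routine takes an explicit seed; the pipeline report is
  serialized with sorted keys and no timestamps, so a rerun with the same
  config is byte-identical.

## Open design choices made here

- **MVMR instrument union.** The design matrix uses the union of exposure
  and mediator instruments (configurable to exposure-only by omitting the
  full exposure GWAS), since the union is the common default and maximizes
  conditional-effect identification.
- **Proportion-mediated uncertainty.** A first-order delta-method se
  (treating the three coefficient estimates as independent across GWAS
  samples) is available as `proportion_mediated_se` but off by default in
  reports; it is an extension, not part of the core decomposition.
- **Screen multiplicity.** Outcomes that fail harmonization still count
  toward the Bonferroni denominator, so failures can never make the
  surviving tests easier to pass.
- **Simulation scale in the validation suites.** The acceptance script and
  test suite use 100–500 seeded replicates per property (about one minute
  total on one CPU), sizes at which the Monte-Carlo error of each checked
  rate is a small fraction of its tolerance band.

## Known limitations

- Estimators assume independent instruments; the lenient r² < 0.8
  drug-target profile can leave residual LD, which is warned about but not
  modeled (no correlation-aware IVW).
- No Steiger directionality filtering, MR-RAPS, mode-based or
  contamination-mixture estimators; no SuSiE-style multi-causal
  colocalization; no genome-build liftover or GWAS-VCF parsing.
- Binary outcomes are handled on the log-odds scale throughout; no
  liability-scale conversion.
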