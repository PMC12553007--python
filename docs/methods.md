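# Methods

This note documents the statistical model behind `mrtriangle`, the
parameters that matter, what the synthetic-data generators do and do not
emulate, and the numerical and design choices made where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. The estimation problem

The pipeline asks whether a plasma protein is a plausible intervention
target for coronary heart disease (CHD) by requiring three genetically
estimated effects to form a consistent causal chain:

1. **metabolite → CHD** (genome-wide MR): does a urinary metabolite's
   level affect disease risk?
2. **protein → metabolite** (cis-MR): does the protein regulate that
   metabolite?
3. **protein → CHD** (cis-MR): does the protein affect disease risk, in
   the direction the first two effects predict?

Each layer is a two-sample summary-statistic MR: variant-level effect
estimates on the exposure (`bx`, `se_x`) and the outcome (`by`, `se_y`)
come from separate GWAS and are combined into a causal slope. Because
clumping at r² ≤ 0.30 deliberately keeps partially correlated
instruments (to retain information at cis loci), the estimators are
generalised least squares rather than the independent-instrument forms.

## 2. GLS-IVW and GLS-MR-Egger

With `S = diag(se_y)` and `C` the LD correlation among the retained
instruments, the error covariance is `Ω = S C S` and

* **IVW** fits `by = θ bx` (no intercept),
* **Egger** fits `by = α + θ bx` after re-orienting every variant so
  `bx ≥ 0`; the intercept `α` estimates the average directional
  pleiotropic effect.

Coefficients are `(XᵀΩ⁻¹X)⁻¹XᵀΩ⁻¹by`; heterogeneity is the generalised
`Q = eᵀΩ⁻¹e`. Two details are easy to get wrong and are covered by
tests:

* **Orientation transforms the LD matrix too.** Flipping a variant's
  effect allele flips the sign of its correlation with every other
  variant, so the Egger orientation applies `C → D C D` with
  `D = diag(sign(bx))`. Omitting this breaks the nesting of IVW inside
  Egger (Q_Egger can then exceed Q_IVW, which is impossible for nested
  least-squares fits on the same data).
* **Weights are first-order.** `Ω` uses outcome-side standard errors
  only. This is the standard first-order IVW weighting; its cost is a
  mild narrowing of confidence intervals when instruments are close to
  the strength floor (see §7).

Reported standard errors are inflated by `sqrt(max(1, Q/Q_df))`
(multiplicative random effects); the plain fixed-effect SE is stored
alongside. `ci95 = slope ± 1.96·se`. Disease-outcome slopes are
log-odds per 1 SD exposure; `odds_ratio` exponentiates them.

**Diagnostics and pruning.** Leverage is the diagonal of
`X(XᵀΩ⁻¹X)⁻¹XᵀΩ⁻¹`; the per-variant outlier statistic is the squared
whitened residual `z_i² = (L⁻¹e)_i²` with `Ω = LLᵀ` (these sum to Q and
reduce to the familiar `(e_i/se_i)²` under independence). Variants with
leverage above 3× the mean or `z² > 10.83` — the 1-df χ² critical value
at p = 0.001 — are excluded in a single pass and the model refitted
once. Iterating the pass is configurable but off by default: a single
pass matches the described procedure and avoids over-pruning.

**Model selection.** Egger's extra parameter is accepted only if it
earns its degree of freedom: Egger is selected iff
`Q_IVW − Q_Egger > χ²₁(0.95) = 3.841`, otherwise the parsimonious IVW
is kept. The decision statistic is recorded on the returned fit.
Analyses with fewer than six variants at any fitting stage are
discarded with a reason, never reported.

**Near-singular LD.** If the condition number of `C` exceeds a bound
(default 1e8), off-diagonals are shrunk toward zero by the smallest
mixing weight that restores it; the shrinkage is recorded on the fit.

## 3. Instrument selection

Applied in order, each removal logged with stage and reason:

| step | rule | default |
|---|---|---|
| cis window (proteins) | keep `pos ∈ [start − w, end + w]`, closed | w = 200 kb |
| MAF | `min(eaf, 1 − eaf) ≥ maf_min` | 0.01 |
| strength | `F = (β/se)² ≥ f_min`, closed bound | 24 |
| clumping | greedy by ascending p; drop `r² > r2_max` vs retained | 0.30 |
| harmonisation | align outcome to exposure's effect allele | — |

Ties in clumping break by ascending variant id, making the output
invariant to input order. Palindromic (A/T, C/G) variants are retained
and aligned by allele labels only — no frequency-based strand
inference — and each such alignment is logged so it can be audited.
Harmonisation negates the outcome beta and reflects eaf when the allele
pair is swapped; incompatible pairs are dropped.

## 4. Screening and triangulation

Each layer has a Bonferroni plan `threshold = α / n_effective` with
strict `p < threshold` retention. For the correlated metabolite family,
`n_effective` is the smallest number of principal components of the
trait correlation matrix explaining ≥ 90% of total variance
(`effective_tests_pca`); for the protein layers it is a test count
(the protein–metabolite layer uses the full proteins × surviving
metabolites product even if fewer pairs were actually fit). With the
reference counts these thresholds evaluate to 0.05/365 = 1.37×10⁻⁴ and
0.05/(1562×29) = 1.10×10⁻⁶. (For the protein–CHD layer, alpha over a
count of 682 is 7.33×10⁻⁵; the implementation always computes `α/n`
and does not attempt to reproduce any differently printed exponent.)

A triangle is emitted for every protein–metabolite pair surviving
layer 2 whose metabolite survived layer 1 and whose protein survived
layer 3; it is **concordant** iff
`sign(θ_pm)·sign(θ_mc) = sign(θ_pc)`, with any zero effect treated as
indeterminate and excluded. Unique proteins are counted once even when
concordant through several metabolites. Replication against a second
GWAS is flagged at nominal (p ≤ 0.05, same sign) and strict
(p ≤ 0.05/n_overlap, same sign) levels, with `n_overlap` supplied by
the caller; when a protein appears in several studies the largest
sample size wins, ties broken lexicographically.

## 5. Tissue validation

**Plaque.** Expression (response) is regressed on the plaque
vulnerability index (PVI, predictor) by OLS; the slope is the mean
difference in normalised count per unit PVI. No covariate adjustment in
the primary model (none is part of the described design); covariates
are carried in the table and can be added behind a flag. The
residual-vs-fitted correlation is stored as a linearity diagnostic.
BH adjustment at FDR 0.1 is applied separately to the protein- and
mRNA-expression families, which are measured on different cohorts.
Subgroup analyses stratify by sex, age (<65 vs ≥65, strict), and
diabetes; the interaction p comes from the PVI × group coefficient of a
pooled model with main effects and interaction.

**Single cell.** One-vs-rest Wilcoxon rank-sum tests per gene × cell
type, and again at the level of three broad clusters (structural,
innate immune, adaptive immune); the 13-type → 3-cluster mapping ships
as an editable table (`simulate.CLUSTER_MAP`). Tests are two-sided at
nominal 0.05 with the direction recorded.

## 6. Enrichment and druggability

Over-representation is the upper-tail hypergeometric probability
`P(X ≥ k)` with universe N, set size K (after intersection with the
universe), hit count n and overlap k — no mid-p correction — followed
by BH at FDR 0.05 across sets. The same machinery serves protein
pathway collections and metabolite set collections; the background
universe is always an explicit input. Druggability is a static-table
join: `drugged` (approved drug), `druggable` (developmental compound),
`not_yet_druggable` (default for absent proteins); duplicate rows merge
with the union of drugs and the most advanced status.

## 7. Synthetic data: what it emulates, and what not

All generation is at the summary level — no individual-level genotypes.
Observed effects are true marginal effects plus correlated noise
`ε ~ N(0, S C S)` with `se = 1/sqrt(2·maf·(1−maf)·n)` for unit-variance
traits, which reproduces the F/sample-size relationship the filters
depend on.

Defaults (the study conditions; chosen once):

* cis loci of 25 variants in blocks of 5, within-block r = 0.3 (so
  clumping at r² ≤ 0.30 retains correlated instruments and the GLS
  correction matters);
* exposure GWAS n = 35 000 (the order of the largest protein study);
  outcome effective n = 180 000 (the CHD case-count scale); metabolite
  GWAS n = 3 000 in the multi-locus study generator (the order of the
  urinary-metabolite study);
* true cis effect magnitudes uniform on 0.1–0.4 SD per allele with
  random sign: a lead-plus-secondary spread. Instruments sit well above
  the F = 24 floor, and the order-of-magnitude spread in instrument
  strength is what makes the Egger intercept statistically separable
  from the slope — with near-constant `bx` the two are collinear and
  the model-selection branch is unreachable;
* pleiotropy: `balanced` draws zero-mean per-variant direct effects;
  `directional` draws effects with mean `pleiotropy_sd` (default 0.03)
  and spread `pleiotropy_sd/2`, oriented to the exposure-increasing
  allele. The orientation matters: a direct effect whose sign is tied
  to an arbitrary allele labelling averages out under Egger's `bx ≥ 0`
  convention and is undetectable in principle. The default magnitude is
  deliberately modest — a pervasive shift of ~10% of the median cis
  effect — because much larger direct effects are flagged variant by
  variant as outliers (z² > 10.83) and removed before model selection,
  which masks the systematic pattern Egger is meant to absorb;
* the multi-locus study generator gives each chain a cis locus and a
  separate trans locus for its metabolite. Cis-locus metabolite
  associations (attenuated by θ_pm) fall below F = 24 at n = 3 000,
  so the genome-wide metabolite → disease layer instruments itself from
  the metabolite's own architecture — which is precisely what allows a
  planted chain to be genuinely discordant;
* plaque PVI is standard normal (its real construction is a composite
  histology score and is consumed, not derived); covariates mimic an
  endarterectomy cohort (75% male, age ≈ N(69, 9²), 22% diabetic);
* single-cell counts are Poisson with a fold-change planted in the
  target type; 13 plaque cell types in realistic proportions.

Not emulated: realistic allele-frequency spectra, fine-scale LD decay,
sample overlap between GWAS, binary-trait liability scale (the disease
layer uses an effective-n Gaussian approximation), metabolite–metabolite
correlation (the synthetic metabolite correlation matrix is identity),
single-cell depth variation and dropout. Passing tests therefore
demonstrate internal statistical correctness and calibration under
these idealised conditions, not robustness to the full messiness of
real summary statistics.

## 8. Numerical choices

* Wilcoxon asymptotic p: two-sided normal approximation with mid-rank
  ties, tie-corrected variance, 0.5 continuity correction, and an
  Edgeworth fourth-moment term using the closed-form excess kurtosis of
  the tie-free rank-sum null,
  `γ₂ = −(6/5)(n₁² + n₂² + n₁n₂ + N) / (n₁n₂(N+1))`.
  The plain continuity-corrected approximation deviates from the exact
  enumeration by up to ~0.04 for groups of three; the corrected form
  stays within 0.02 down to the minimum group size of three and decays
  to the textbook approximation as groups grow. An exact-enumeration
  mode (scipy) is kept for validation.
* Degenerate inputs: constant features are `not_detected`; all-tied
  Wilcoxon returns p = 1 with undefined direction; empty instrument
  sets are allowed and become discards downstream; an empty p-value
  vector BH-adjusts to empty.
* Block-constant LD matrices are PSD by construction for
  `r > −1/(m−1)`; the generator still checks eigenvalues and applies
  recorded minimal diagonal inflation if round-off bites.
* All simulations are driven by `numpy.random.default_rng` with
  explicit seeds; identical config + seed reproduces byte-identical
  pipeline outputs (verified in the suite).

## 9. Known limitations

* **Post-selection coverage.** Under a correctly specified null
  (no pleiotropy), the IVW-vs-Egger selection picks Egger in a small
  fraction of replicates precisely when the data spuriously favour an
  intercept; the Egger CI in those replicates covers the truth far
  below nominal. The pruned GLS-IVW interval is well calibrated;
  the selected-model interval is slightly anticonservative overall.
  `scripts/acceptance.py` reports both coverages.
* First-order weights ignore exposure-side error; with instruments near
  the F floor this narrows CIs by a few percent of their width.
* Single-pass pruning can leave residual outliers in principle
  (configurable passes, default 1).
* The replication module assumes the overlap list is externally
  supplied; it does not infer which proteins were assayed twice.
* Problem sizes in the test suite and acceptance script (25-variant
  loci, 500-replicate calibration runs, 2 000-cell matrices) are the
  package's chosen synthetic scale: large enough for stable Monte-Carlo
  bands, small enough to iterate on quickly.
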