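# Methods

This note documents the statistical model behind `targetmr`, the synthetic
cohort generator used to validate it, the numerical choices, and what the
validation results do and do not establish.

## Causal model and estimator

The estimand is the effect θ of a 1 SD change in an exposure (a lipoprotein
lipid trait), achieved through a specific gene product, on an outcome
(disease log-odds, or a metabolite in SD units). Instruments are cis
variants for the encoding gene; the identifying assumptions are the usual
instrumental-variable ones (relevance, no confounding of the
variant–outcome relationship, exclusion restriction), with the cis window
serving to reduce the risk that an instrument acts through a neighbouring
gene (horizontal pleiotropy).

Estimation is two-sample: instrument–exposure effects β_X come from a
discovery sample, instrument–outcome effects β_Y from a non-overlapping
outcome sample, and instrument correlations ρ from a third reference panel.
Because cis instruments are deliberately allowed to be correlated (pruning
keeps pairs up to r² < 0.1), the IVW estimator is the generalised
least-squares solution with outcome-side covariance Ω_jk = σ_Yj σ_Yk ρ_jk:

    θ̂  = (β_Xᵀ Ω⁻¹ β_X)⁻¹ β_Xᵀ Ω⁻¹ β_Y
    se² = (β_Xᵀ Ω⁻¹ β_X)⁻¹

Properties relied on in tests: with ρ = I this is algebraically the
standard fixed-effect IVW (weights β_Xj²/σ_Yj²); with one instrument it is
the Wald ratio with delta-method SE. Exposure-side uncertainty σ_X is
ignored in the estimator (standard two-sample practice; the simulations
confirm the resulting CI coverage is nominal at the instrument strengths
involved) and enters only the weak-instrument summary F = k⁻¹ Σ (β_Xj/σ_Xj)²,
the mean per-instrument squared z-score. A multiplicative random-effects
variance inflation is available behind a flag (default off; it never
shrinks the SE below the fixed-effect value).

Ill-conditioned Ω (smallest eigenvalue < 1e-10 × largest) is a hard error
naming the most correlated instrument pair rather than a silent
regularisation: conditioning is the job of LD pruning, and a near-singular
Ω means pruning was bypassed.

### Orientation and comparison conventions

Raw estimates are per 1 SD *higher* exposure. Reported estimates are
oriented to mimic therapy: multiplied by the target's therapeutic direction
(−1 for LDL- and TG-lowering targets, +1 for HDL-raising), with CI bounds
negated and swapped; SE and P are unchanged. Binary-outcome estimates
exponentiate to odds ratios with 95% bounds exp(θ ± 1.96·se).

For cross-target comparison, each target's metabolite signature is divided
by the absolute value of its oriented CAD log-odds effect, putting all
targets on the scale "trait-SD change per unit CAD log-odds reduction".
The absolute value is used so that every target points toward risk
reduction regardless of sign. Concordance between two scaled signatures is
the coefficient of determination of an intercept-included least-squares
regression of the comparator on the baseline (r² = var(fitted)/var(observed));
the regression direction matters for the slope but hardly for r², so the
convention (comparator on baseline) is fixed and recorded in the output.

## Selection rules

* **cis window**: closed interval [gene_start − w, gene_end + w] in 1-based
  coordinates, w = 100 kb by default with a 50-kb sensitivity setting. A
  variant exactly on the boundary is included.
* **P threshold**: candidates require exposure P < 1×10⁻⁶.
* **LD pruning**: candidates are visited in ascending-P order (ties broken
  by position then variant ID) and kept iff their squared correlation with
  every already-kept variant is below 0.1. The best-P candidate is always
  kept. Signed r (aligned to stated effect alleles) is retained for Ω; the
  pruning rule uses r².
* **Minimum instruments**: targets retaining fewer than 2 instruments are
  rejected — single-instrument cis scores are vulnerable to confounding by
  neighbouring genes in gene-dense regions.
* **Harmonisation**: outcome records whose effect/other alleles are swapped
  relative to the exposure have β negated and frequency complemented;
  irreconcilable allele pairs and instruments absent from the outcome are
  dropped with a logged reason (dropping all is an error). Palindromic
  (A/T, C/G) variants are kept by default, appropriate when both samples
  share one genotyping pipeline; `drop_palindromic` is available for
  cross-consortium use where strand cannot be trusted.

## Association scans

Quantitative traits are rank-based inverse-normal transformed before the
scan (Blom offset c = 3/8, i.e. Φ⁻¹((r − 3/8)/(n + 1/4)); ties get the mean
of their tied ranks; missing values pass through), so effects are in
trait-SD units and comparable across traits. The per-variant coefficient is
from a joint regression of the trait on dosage plus covariates (age, sex,
fasting time, genotyping chip by default); computationally this is done by
the Frisch–Waugh identity — residualise trait and dosage on the covariates
once, then take simple slopes — which makes a 200-trait metabolome scan
cost little more than one trait, and is verified against a direct
`statsmodels` OLS fit in the tests. P-values use the normal approximation,
matching large-sample GWAS convention. Binary traits use per-variant
logistic regression (log-odds per effect allele); non-converged or
separated fits and monomorphic variants are emitted with an unusable SE and
excluded downstream rather than silently dropped.

Hit counting at the conventional genome-wide threshold (P < 5×10⁻⁸) defines
loci by greedy clumping: the smallest-P remaining hit seeds a locus and
absorbs hits within ±500 kb on the same chromosome (window configurable).

## FDR control

Benjamini–Hochberg step-up q-values are computed **within one target's
family of traits** — never pooled across targets — and discoveries are
q < 0.05. Disease analyses apply the same rule over the set of targets,
separately per disease. Screen cells where harmonisation retains under half
of a target's instruments are flagged missing and excluded from the FDR
family rather than imputed.

## The synthetic cohort generator

What it emulates, and the defaults that define the study conditions:

* **Genotypes**: each locus carries 30 biallelic variants (MAF uniform in
  [0.1, 0.5]) over ~60 kb. Per haplotype a latent standard-normal AR(1)
  field with decay ρ = 0.6 is thresholded at the MAF quantile; dosage is
  the sum of two independent haplotypes, so Hardy–Weinberg proportions hold
  by construction and the latent correlation between variants i, j is
  exactly ρ^|i−j| — a single interpretable decay parameter with a closed
  form the tests can check. This is a surrogate for real haplotype
  structure, not a reconstruction of it (no recombination maps, no
  population structure).
* **Exposures**: E = (Σ γ_j (G_j − 2p_j) + ε)/s with three causal variants
  per locus (γ = 0.14, −0.12, 0.10 raw-SD per allele, ~2% of exposure
  variance — the scale of a strong lipid locus). The divisor s is the
  *analytic* model-implied SD, computed from γ, the allele frequencies and
  the latent LD via the bivariate normal orthant probability, so exposures
  have unit variance in expectation and downstream true effects are exactly
  per 1 SD (an empirical divisor would blur the ground truth).
* **Metabolites**: linear in the exposures with loadings drawn i.i.d.
  N(0, 0.5²) per (trait, exposure) — pathway-shared signal — plus unit
  noise; optional direct variant→metabolite effects provide a pleiotropy
  switch, and zero loadings provide a global-null panel for FDR
  calibration.
* **Disease**: Bernoulli from a logistic model in the exposures;
  single-locus studies use θ = −0.25 log-odds/SD with intercept −1.5
  (≈19% prevalence), the three-target design uses harmful effects
  (+0.35, +0.25) per SD of higher LDL-like/TG-like exposure with intercept
  −2.0 (≈12% prevalence).
* **Covariates**: age (40–71), sex, fasting time, chip and 10 PCs,
  independent of genotypes by default; a confounding switch adds a shared
  latent factor to exposures and age for negative-control experiments.
* **Partitions**: 45% discovery / 45% outcome / 10% reference by
  largest-remainder apportionment of a seeded permutation — disjoint and
  exhaustive, emulating the two-sample design with a separate LD panel.

Default cohort size is n = 50,000. What passing tests on these cohorts
does **not** show: robustness to real LD complexity (allelic heterogeneity,
long-range LD), population stratification, assortative mating, selection
effects in biobank recruitment, or horizontal pleiotropy beyond the
explicit switch — the generator is deliberately faithful to the *assumed*
causal chain so that estimator properties can be isolated.

## Validation design and problem sizes

The replicated experiments (in `targetmr.validation`, driven by both the
test suite and `scripts/acceptance.py`) use: 100 replicates at n = 50,000
for parameter recovery and CI coverage; 200 replicates for type-I error
with the causal path severed; 100 replicates of a 200-trait global-null
metabolome at n = 50,000 for FDR calibration (the mean false-discovery
proportion, counting no-discovery replicates as 0, should sit at or below
the nominal 5% plus Monte-Carlo slack); single n = 50,000 cohorts for the
concordance contrast and the GRS-vs-IVW cross-method check. Estimator
exactness (GLS oracle, degenerate reductions) uses random synthetic inputs
with random positive-definite correlation matrices, k ≤ 10.

Smaller fixtures in the unit tests use n = 16,000–20,000; below roughly
n = 16,000 the P < 1×10⁻⁶ cis filter can leave fewer than two instruments
for a locus of this architecture, which the minimum-instrument rule then
correctly rejects.

## Numerical choices and degenerate inputs

* 95% CIs use the normal 1.96 quantile throughout (symmetric on the log
  scale for binary outcomes).
* Ω is solved with a dense linear solve after an eigenvalue conditioning
  check; no pseudo-inverse, no ridge.
* `rank_inverse_normal` refuses all-identical input (< 3 non-missing values
  likewise) — the transform is undefined there.
* Monomorphic variants: flagged in scans (β = 0, SE = NaN), an error with
  the offending ID in LD computation.
* GRS construction mean-imputes sparse missing dosages and refuses scoring
  when more than 10% of weight variants are absent; scores are standardised
  to unit SD within each analysis stratum so slopes are per score-SD, and
  the two-stratum comparison is formalised as a two-sample z-test on the
  slope difference.
* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence` spawning; identical configs give bitwise
  identical outputs.

## Known limitations

* The F-statistic is a summary-level approximation (mean squared z); it is
  not the first-stage regression F of individual-level data, and different
  published analyses compute it differently.
* The fixed-effect Ω assumes no residual heterogeneity among instruments;
  the random-effects flag inflates the SE multiplicatively but no formal
  heterogeneity test is exposed.
* Logistic outcome effects are marginal log-odds; non-collapsibility
  attenuates them slightly relative to the conditional effect (at the
  simulated effect sizes this bias is ≪ 1 SE, visible as mean recovery of
  ≈ −0.21 for a true −0.25 with SE ≈ 0.13, well inside the 3-SE recovery
  band), and winner's-curse selection of instruments in the discovery
  sample contributes a further small attenuation.
* MR-Egger, weighted-median/mode, multivariable MR and Steiger filtering
  are out of scope; the package estimates the plain correlated-instrument
  IVW and its sensitivity analyses (50-kb window, age strata) only.
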