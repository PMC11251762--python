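# Methods

## Statistical model

### Random-effects meta-analysis

Per variant, study effects β_s with standard errors se_s are pooled by the
DerSimonian–Laird moment estimator: with fixed-effect weights w_s = se_s⁻²,

- β_FE = Σwβ/Σw, Q = Σw(β − β_FE)², df = S − 1,
- τ² = max(0, (Q − df) / (Σw − Σw²/Σw)),
- random-effects weights w*_s = 1/(se_s² + τ²), pooled β = Σw*β/Σw*,
  pooled se = √(1/Σw*), I² = max(0, (Q − df)/Q).

A single study passes through unchanged.  Variants present in only a subset
of studies are pooled over the available studies with the study count
recorded, matching standard GWAS meta-analysis practice.  All studies are
harmonized to the first study's effect-allele orientation before pooling;
the reported allele frequency is taken from the largest contributing study,
with a logged warning when studies disagree by more than 0.05.

### Correlated-instrument GLS estimators

For k harmonized instruments with exposure effects b_X, outcome effects b_Y,
outcome standard errors σ_Y, and signed LD correlation matrix R from a
reference panel, the working model is b_Y ~ N(Xθ, Ω) with
Ω = diag(σ_Y) R diag(σ_Y) and design X = [b_X] (IVW) or [1, b_X]
(MR-Egger).  The GLS solution, heterogeneity statistic and covariance are

    θ̂ = (XᵀΩ⁻¹X)⁻¹XᵀΩ⁻¹b_Y,
    Q  = (b_Y − Xθ̂)ᵀΩ⁻¹(b_Y − Xθ̂),
    cov(θ̂) = (XᵀΩ⁻¹X)⁻¹ · φ,   φ = max(1, Q/(k − p)).

φ is a multiplicative random-effects (overdispersion) factor: residual
heterogeneity beyond the LD-aware sampling covariance widens the interval,
but the covariance is never deflated below its nominal value.  Exposure
standard errors do not enter Ω (the usual no-measurement-error convention of
summary-data MR); the consequence is quantified below.

Whitening by the Cholesky factor Ω = LLᵀ yields residuals e = L⁻¹(b_Y − Xθ̂)
whose squares are χ²₁-scale outlier statistics under the model, and a
whitened hat matrix whose diagonal gives leverages.  Instruments with
e_j² > 10.83 (χ²₁ at 0.001) or leverage above 3× the mean are pruned one at
a time — worst squared residual first, ties broken by leverage — with a full
refit after each removal, stopping when nothing is flagged, the method's
minimum k is reached, or 20 rounds have run.  One-at-a-time pruning is used
because both statistics change after every removal.

MR-Egger requires a sign convention for its intercept: instruments are
oriented so all exposure effects are non-negative by flipping b_X, b_Y and
the corresponding rows/columns of R.  This is a pure reparameterization
(IVW is invariant to it; the oriented Egger fit is invariant to the
original per-variant orientation).

Model selection between IVW and Egger uses the heterogeneity difference:
Egger is reported iff Q_IVW − Q_Egger > 3.84, i.e. the intercept must
reduce heterogeneity by more than a χ²₁ critical value at 0.05 to justify
its variance cost.  Both the outlier threshold and the selection critical
value are configuration, not constants.  Pruning runs in the IVW
parameterization before the selection step (a configurable choice; the
alternative ordering is not exposed because the pruned set must be common
to the two candidate models for their Q statistics to be comparable).

p-values are two-sided normal on α̂/se(α̂): k is small but Ω is treated as
known, the standard convention for summary-data MR.  For binary outcomes
the estimate is also reported as an odds ratio exp(α̂) with an
exp-transformed interval.

### Multivariable MR

For two co-located genes, the design becomes X = [b_X1, b_X2] (optionally
with an intercept after orienting on exposure 1's signs), with the same Ω,
φ, pruning and Q-difference selection.  The two slopes are mutually
adjusted: when gene 2 has no causal effect on the outcome but its
instruments tag gene 1's causal variants through LD, the univariable
estimate for gene 2 is biased away from zero while the multivariable one is
centred on zero — the property the module exists for, and the one the test
suite verifies by Monte Carlo.  Joint instruments are drawn from the union
of the two gene windows, clumped on the smaller of the two exposure
p-values, and retained when F ≥ 15 for at least one exposure (conditional
instrument strength for co-located genes has no agreed definition; the
permissive rule plus reported per-exposure F statistics keeps the analysis
auditable).  Estimation refuses collinear exposure columns, reporting the
design condition number.

### Instrument selection defaults

| parameter | default | meaning |
|---|---|---|
| flank_bp | 1,000,000 | cis window around the gene body (closed interval) |
| maf_min | 0.01 | minor-allele-frequency floor |
| clump_r2 | 0.40 | greedy clumping threshold; residual correlation kept in R |
| f_min | 15 | per-variant instrument strength (β/se)² |
| leverage_multiplier | 3 | pruning: multiples of mean leverage |
| outlier_chi2 | 10.83 | pruning: squared whitened residual cut (χ²₁ at 0.001) |
| q_select_crit | 3.84 | IVW→Egger switch on Q difference (χ²₁ at 0.05) |
| ld ridge | 0.001 | shrinkage (1−λ)R + λI guaranteeing an invertible Ω |

The filter order is window → MAF → clump → F → outcome intersection; the
set is not re-clumped when the outcome intersection removes a lead (a
config flag enables re-clumping).  Selection is a pure function of its
inputs: reruns are identical.

### Harmonization

Variants are matched on (chromosome, position, unordered allele pair);
rsids are carried but never joined on.  Where the effect allele disagrees
with the reference, β flips sign and the frequency becomes 1 − eaf.
Palindromic variants (A/T, C/G) are aligned by allele frequency and dropped
when either table's minor-allele frequency exceeds 0.42.  These are
conventional two-sample MR defaults, configurable because upstream sources
differ.

## Synthetic data-generating process

The generator emulates the statistical structure the estimators assume, at
desk scale:

- **Reference panel.**  400 variants in LD blocks of 20; within a block,
  latent Gaussians with AR(1) correlation ρ^|i−j| (ρ = 0.7) are thresholded
  at per-variant MAF quantiles (MAF ~ U(0.05, 0.5)) to give two haplotypes
  per individual; dosage is their sum; 5000 individuals, mirroring the
  scale of a biobank LD reference subset.  The dosage correlation is the
  dichotomized-Gaussian attenuation of the latent ρ, which the test suite
  checks against the bivariate-normal closed form.
- **Exposure GWAS.**  Joint causal effects γ on the standardized protein
  live at a handful of variants inside the gene; summary statistics report
  *marginal* effects, so the expected estimate vector is Rγ and estimates
  are drawn MVN(Rγ_study, R/n) on the standardized scale, then rescaled to
  per-allele units by 1/√(2f(1−f)).  Three studies of n = 3301, 5368 and
  35559 echo a realistic multi-cohort proteomics design; between-study
  heterogeneity enters as a Normal(0, 0.02²) shift of each causal effect
  per study, giving the meta-analysis genuine τ² > 0 to estimate.
- **Outcome GWAS.**  b_Y = Σ_e α_e·(Rγ_e) + Rδ, sampled MVN(b_Y, R/n) with
  n = 50,000.  Directional pleiotropy δ ~ Normal(μ, σ²) is placed on every
  variant of the causal gene's body by default — the classical setting an
  Egger intercept absorbs.  Restricting δ to the causal variants themselves
  (scope "causal") is also supported, but then Rδ is nearly collinear with
  Rγ and *no* intercept can separate pleiotropy from the causal slope; the
  default scope is the one under which the Egger estimator's advertised
  robustness is a testable property.  Binary outcomes are simulated
  directly on the log-odds summary-statistic scale: two-sample MR consumes
  only summary statistics, and individual-level logistic sampling would add
  cost without changing what the estimators see.
- **Two-gene geometry.**  Gene 1 (variants 120–159) and gene 2 (240–279)
  sit ~200 kb apart.  Gene 2's four causal variants split between its own
  locus and gene 1's LD block — a shared regulatory region — so that gene
  2's marginal signal is partially confounded with gene 1's, the situation
  multivariable MR is meant to resolve.  With purely gene-body causal sets
  and disjoint 20-variant LD blocks there would be no cross-locus LD and
  nothing for MVMR to correct.

All randomness flows from explicit seeds (identical config + seed gives
byte-identical output); study-level seeds are spawned from the scenario
seed.  What the generator does **not** emulate: realistic human LD maps and
allele-frequency spectra, imputation uncertainty, sample overlap between
exposure and outcome studies, INDELs/multi-allelic sites, and assay
artefacts.  Passing tests therefore demonstrate the statistical machinery
under its stated assumptions, not robustness to everything real data do.

## Monte-Carlo behaviour and known limitations

The acceptance suite measures the full pipeline's operating
characteristics under the generator's default conditions, and two of them
deserve explicit framing:

- **Attenuation toward the null.**  The mean recovered effect sits ~2–4%
  below the simulated truth.  This is weak-instrument regression dilution
  (F ≥ 15 still admits instruments with up to ~6% attenuation, and exposure
  measurement error is outside Ω by construction) compounded by
  between-study heterogeneity and by leverage pruning, which preferentially
  removes the strongest, least-diluted instruments.  It is the conservative
  "bias toward the null" inherent to non-overlapping two-sample designs:
  confidence-interval coverage stays in range while the point estimate is
  slightly shrunk.
- **Mild type-I inflation.**  The selected-model rejection rate under the
  null runs slightly above nominal (roughly 0.06 against 0.05 across seed
  streams).  Outlier pruning and Q-difference model selection both condition
  on the data before the final p-value is computed; neither step's
  selection event is accounted for in the reported standard error.  Users
  applying stringent corrected thresholds (as the orchestrator does by
  default) are little affected, but nominal-level inference should be read
  with this in mind.

Other numerical choices: Cholesky-based solves throughout (a singular Ω
raises an error advising a larger LD ridge rather than silently
pseudo-inverting); clumping ties broken by position then allele; duplicate
variant records resolved to the smallest p-value with a logged count;
p-values floored at the smallest positive double to stay in (0, 1].

## Orchestration

`run_study` composes the module operations over many outcomes: exposure
meta-analysis, genome-wide leads with cis/trans labels, per-outcome
instrument selection and estimation, MVMR for outcomes nominally associated
(p < 0.05) with both exposures, and Bonferroni flags at fwer/n_traits with
the trait count explicit in config so scaled-down runs can mirror a larger
design.  Failures are isolated per outcome and reported in a failure table;
every intermediate artifact is serialized as TSV so any number in the
results table can be reproduced by re-running the corresponding operation
alone; the run log records config, seed and per-stage counts.
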