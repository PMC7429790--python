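# Methods

## Scope and shape

The package implements a single-step genomic-prediction study end to end
on synthetic data: data generation (`simdata`), relationship matrices
(`relmat`), Bayesian SNP weights (`weights`), mixed-model solving and
variance-component estimation (`mme`), validation statistics
(`validate`), SNP-panel assembly and QC (`panels`), and an orchestration
layer (`pipeline`). The fit-shaped components are scikit-learn-style
estimators (`weights.BayesN0`, `mme.MixedModelBLUP`) with constructor
parameters, `fit`, and trailing-underscore fitted attributes; the
module-level functions named after the operations are thin wrappers.

## The generator

`simdata` emulates a dairy evaluation's data structure, not any real
herd.

* **Pedigree**: discrete generations; each generation has a fixed number
  of females and a small number of males, parents drawn uniformly from
  the previous generation. Validation uses the last generation; because
  generations do not overlap, no validation animal has a sib or daughter
  among the reference animals — the structural analogue of a birth-year
  cutoff with a kinship exclusion.
* **Genotypes**: gene dropping over the pedigree with Mendelian
  transmission and Haldane crossovers at 1 Morgan per chromosome. Allele
  frequencies at the *historical founding* are Uniform(0.05, 0.5); a
  burn-in of 100 generations of random mating in a population of 80
  builds linkage disequilibrium (expected r² ≈ 1 / (1 + 4Nc)) before the
  recorded founders are sampled. Without the burn-in markers carry no
  population-level information about QTL and a chip cannot tag anything;
  the burn-in length and size are chosen to give chip-like LD at the
  few-cM scale. Drift during burn-in fixes a fraction of loci; monomorphic
  SNPs are removed by the MAF filter downstream.
* **Trait architecture**: `n_qtl` QTL (default 100) drawn among
  segregating loci, allele effects from a signed gamma(0.4) — a
  heavy-tailed, moderately polygenic architecture; effects are rescaled
  so the population TBV variance equals h² exactly, and each animal's TBV
  is exactly its QTL dosages times the effects.
* **Panels**: the base chip is every SNP except the QTL themselves; the
  two add-on panels (sizes defaulting to 0.6·n_qtl and 1.0·n_qtl, ~5%
  overlap, the ratio of a small association-selected and a larger
  bioinformatics-selected list) draw causal loci first and immediate
  flanks as filler. Flanking SNPs not picked into an add-on stay on the
  chip, so the chip tags QTL through LD as a real 54K panel does.
* **Phenotypes**: y = µ + age + parity + TBV + pe + hys + e, with
  var(y − fixed) normalised to 1 and split σ²_a = h², σ²_pe =
  repeatability − h², σ²_hys = var_hys, σ²_e = 1 − repeatability −
  var_hys. Calving ages get an interval jitter so age classes overlap
  across parities (otherwise age would alias parity and the fixed part
  would be singular). Setting repeatability + var_hys = 1 legally
  produces zero residual variance for degenerate checks.
* Two traits on one population (`pipeline.run_study_replicate`) share the
  pedigree and genotypes but have independent QTL sets; the panels are
  assigned from the high-h² trait's QTL, mirroring selected-SNP lists
  that target production traits rather than fertility.

What the generator does **not** emulate: overlapping generations,
selection, genotyping-by-cohort bias, real chip ascertainment, imputation
errors beyond deliberate masking, genetic groups, multi-trait
covariances. Passing tests therefore demonstrate internal correctness
and qualitative transferability of the model comparisons, not
quantitative reliabilities of any real population.

## Matrices

A is built by the tabular method (numba) and its inverse directly by
Henderson's rules with Mendelian-sampling variances 0.5 − 0.25(F_s +
F_d); inbreeding comes from the tabular diagonal, an O(n²) choice that is
fine at the few-thousand-animal scale this package targets. G follows
VanRaden with frequencies always recomputed from the supplied genotypes,
missing dosages mean-imputed to 2p before centering, one code path for
weighted and unweighted matrices (so unit weights reproduce the
unweighted G bit for bit), the two-point scale adjustment matching
Avg(diag) and Avg to A22, and blending with ω_a = 0.2 (exposed, since
the literature default has no sensitivity analysis behind it). H⁻¹ adds
the dense genotyped-block correction G⁻¹ − A22⁻¹ to the sparse A⁻¹;
a singular G raises an error pointing at ω and SNP QC.

## BayesN0

Single-site Gibbs in numba: SNP effects from their normal full
conditionals under residual weights 1/d, region variances from
scaled-inverse-χ² with df v_α + n_i, the mean from its weighted-normal
conditional, and σ²_e from a flat scaled-inverse-χ² (df −2). Priors:
v_α = 4.2 and S²_α chosen ("auto") so the prior mean SNP variance equals
h²_prior · var(y)/Σ2pq with h²_prior = 0.5 — weakly informative, quickly
dominated by data. Update order is map order, then region variances, then
µ, then σ²_e. Chains are deterministic given the seed. The production
chain is 50,000 / 10,000 burn-in / thin 20 (2,000 saved samples); the
package default (5,000 / 1,000 / 10) is the desk-scale setting used
throughout the tests. Reliabilities r² = 1 are clipped to 1 − 1e−6 so
residual weights stay finite. Weights are posterior SNP variances divided
by their mean; a whole-genome region hence gives unit weights and the
model collapses to GBLUP.

## Mixed models and REML

The solver assembles Henderson's equations sparsely (drop-first fixed
effects; pe restricted to animals with records) and solves either densely
(≤ 2,000 equations) or by Jacobi-preconditioned conjugate gradients
(rtol 1e−10); the two agree to 1e−6 on every test system. The featured
model simply carries two genetic components against the same incidence
matrix; reported EBV is their per-animal sum.

Variance components: EM-REML with the classical updates
σ²_u = (û'K⁻¹û + tr(K⁻¹C^uu))/q and σ²_e = (y'y − θ̂'W'y)/(n − p),
converged at 1e−6 relative change. Plain EM needs hundreds of dense
inversions at this tolerance, so after the third round, once the EM step
is inside the basin, a Newton step on the average-information matrix is
taken when it keeps all components positive (same fixed point, about an
order of magnitude fewer rounds); standard errors come from the inverse
AI matrix. The two-component genomic split (`split_variance_fgblup`) uses
the same EM with guarded geometric extrapolation, warns when the two
matrices coincide (non-identifiable), and returns proportions that sum
to 1. Variance floors at 1e−8·var(y) keep boundary cases finite.

Yield deviations are EBV + residual per record (the phenotype adjusted
for everything except the genetic term), averaged per animal; their
reliability uses the repeatability-model formula n h²/(1 + (n−1)t) with
h² and t computed *excluding* the hys variance, since YD is adjusted for
the contemporary group. The study pipeline derives YD from the full-data
PBLUP fit and then fits all prediction models on reference phenotypes
only.

## Validation

Reliability and bias are unweighted by design. The paired bootstrap
resamples validation animals with replacement, uses a two-sided
percentile p-value 2·min(P(d≤0), P(d≥0)) with continuity correction
1/(n_boot + 1) and Bonferroni adjustment, refuses n_boot < 100, and is
deterministic given the seed. Its empirical size at α = 0.05 over 500
null meta-replicates sits inside [0.03, 0.07].

## Problem sizes used by the tests and the acceptance script

Chosen as the package's own desk-scale study conditions: H⁻¹ oracle on
20 pedigrees of ≤ 200 animals with ≤ 50 genotyped and 500 SNPs; BayesN0
recovery on 20 seeds of 500 animals × 1,000 SNPs with a planted region
carrying 30% of the genetic variance (the QTL region attains the maximum
posterior variance in ≥ 18/20 seeds); EM-REML recovery on ~1,250 cows ×
3 records per trait architecture; directional model comparisons on 20
paired replicates of 945-animal pedigrees (150 founders + 3 × 265
offspring, 60% genotyped, 5 chromosomes × 200 SNPs); bootstrap
calibration on 500 meta-replicates of 250 animals with 400 resamples.

## Known limitations

* The weighting-gain comparison between SNP sets is reference-size
  dependent: with a few hundred genotyped reference animals, the
  region-weighted model keeps a real advantage even when causal loci are
  genotyped, because the basic model is far from its information ceiling.
  Growing the genotyped reference from ~450 to ~1,100 moves the basic
  combined-panel reliability from 0.79 to 0.87 and visibly narrows that
  gap; the regime where the gap closes entirely needs reference
  populations orders of magnitude larger than desk scale.
* PEV-based individual reliabilities are not computed from the MME
  inverse; validation reliabilities are population-level.
* A single trait at a time; no genetic groups or metafounders; imputation
  itself is out of scope (`panels` scores supplied imputed matrices).
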