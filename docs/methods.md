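# Methods

`respoly` implements a complete resource-polymorphism analysis for a
lake-dwelling crayfish sampled in two habitats (littoral vs. pelagic), plus a
synthetic-data generator that emulates the whole study design so every stage
can be exercised, calibrated, and checked for parameter recovery without any
field data.

## The analysis pipeline

### Habitat use across lakes

Pelagic abundance (CPUE, individuals·trap⁻¹·hr⁻¹) is modeled with a linear
model on littoral CPUE, predator biomass (BPUE), % littoral habitat, and
invasion year, with all two-way interactions. The response is
square-root-transformed. Interactions are backward-eliminated: the least
significant interaction (type-II F) is removed until all remaining ones clear
the retention threshold. Retention is a selection over a family of six tests,
so the default threshold is Bonferroni-corrected (`alpha/6`); with a plain
per-test 0.05 rule a spurious interaction survives in roughly 30% of null
datasets at n = 16 lakes and inflates the main-effect type-I error to ~0.085
(measured), violating nominal calibration. The per-test rule remains
available (`family_correct=False`). Main effects are always retained; VIF is
computed on the main-effects design and flagged at ≥ 5.

### Geometric morphometrics

Landmarks (19 body, 7 chela per specimen, 2-D, TPS files) are superimposed by
generalized Procrustes analysis: center, scale to unit centroid size
(CS = √Σ‖xⱼ − x̄‖²), rotate each configuration to the running consensus with
the closed-form 2-D rotation (reflections disallowed — specimens are
digitized consistently in dorsal view), re-estimate the consensus, iterate to
convergence (max coordinate change < 1e-10, cap 100 iterations; these are
ordinary GPA defaults). Shape variables are Procrustes tangent coordinates
(orthogonal projection at the consensus). Partial warps + uniform components
are *not* computed: a two-group discriminant is invariant under any
invertible linear change of shape basis, so tangent coordinates give
identical scores; this equivalence is itself a test
(`test_dfa_invariant_to_linear_reparameterization`).

Allometry is removed by pooled within-habitat regression of the tangent
coordinates on centroid size: the common slope is estimated from
group-centered predictor and response, residuals are `shape − slope·CS`,
grand-centered — habitat mean differences are retained because habitat never
enters as a regressor. Raw centroid size is the default regressor with log
size as an option.

Habitat divergence per structure is a two-group linear discriminant after PCA
reduction (retain eigenvalues > 1e-12 × max; shape space has rank ≤ 2k − 4).
Scores are centered to grand mean 0 and scaled to unit pooled within-group
variance; the axis is oriented so the pelagic mean is positive. Hotelling T²
is reported with a seeded label-permutation p-value (default 10,000
permutations) rather than the parametric distribution, which is invalid when
n is not large relative to the retained dimension. Classification accuracy is
leave-one-out. Extreme shapes are rendered at consensus ± 10× the axis.

### Stable-isotope trophic metrics

Per-lake baselines are means over the 3 replicate collection locations.
Trophic position uses the nitrogen fractionation of 3.4‰ per level over the
periphyton/litter baseline mix (baseline TP = 1); littoral reliance is the
two-source linear carbon mixing proportion between periphyton (littoral
endmember) and zooplankton (pelagic endmember). Baselines are shared per lake
between habitats (per-habitat baselines are an option). No lipid or
discrimination correction is applied to δ13C. Raw LR values outside [0, 1]
are expected under isotopic noise; they are counted and reported, and a copy
clamped to [0.001, 0.999] feeds the beta-family models, which need
open-interval support.

Trophic position is tested with a lake-random-intercept LMM; littoral
reliance with a beta GLMM (logit link, habitat fixed, lake random intercept).
No Python package fits a beta GLMM, so it is fit in-package by maximizing the
Gauss-Hermite-quadrature marginal likelihood (20 nodes) over the fixed
effects, log precision, and log random-intercept SD. Gradient-based
optimizers stall on the log-scale nuisance parameters (measured null type-I
error 0.21 via inflated LR statistics), so optimization is Nelder-Mead with
tight tolerances, and the null and alternative fits warm-start each other so
the likelihood ratio compares converged optima (restores type-I error to
0.05). Its σ_lake → 0 limit is cross-checked against `statsmodels`
`BetaModel` (plain beta regression) in the tests, and the
morphology-diet association (LR on body and chela DFA scores) uses
`BetaModel` directly.

### Mixed-model inference details

LMMs are REML fits (`statsmodels` MixedLM) with sum-coded factors so per-term
Wald F tests are type-III-like. The denominator df is the residual
approximation N − rank(X) − (n_lakes − 1); a Satterthwaite approximation is
not exposed by `statsmodels`, and at this design's sizes (n ≈ 280, 7 lakes,
within-lake treatment structure) the two are practically identical. When the
habitat × sex interaction is significant, habitat contrasts within each sex
are reported from the estimated marginal means. The carapace-length model is
the same operation without the interaction.

### Population genetics

Diversity per population × locus: allele count, observed heterozygosity,
Nei's unbiased expected heterozygosity `(2n/(2n−1))(1 − Σp²)`,
F_IS = 1 − Ho/He (undefined at He = 0), and allelic richness rarefied to
g = 2 × (global minimum per-cell sample size) via
`Σₐ [1 − C(2N − Nₐ, g)/C(2N, g)]`. Missing genotypes are handled by per-locus
complete cases.

HWE is tested by permuting the 2n allele copies among individuals (the
statistic reduces to Ho since He is permutation-invariant); because Ho is
heavily tied (multiples of 1/n) the p-value uses mid-p tie handling — a plain
≥ rule is measurably conservative (~0.02–0.03 null rejection vs. the nominal
0.05). The deficit-direction p is Bonferroni-flagged across cells and doubles
as the null-allele screen (a dedicated null-allele algorithm is out of
scope). LD uses a G statistic on the two-locus genotype table with one
locus's genotypes permuted among individuals.

F_ST is the Weir–Cockerham (1984) θ from the per-allele a/b/c variance
components, multilocus as a ratio of sums. The headline littoral–pelagic
estimate treats each lake × habitat as a sample and contrasts habitats within
lakes, summing components over alleles, loci, and lakes ("habitat_paired");
pooled two-group, among-lake and raw-population groupings are options.
Negative θ is reported raw in JSON and truncated to 0.000 in human-readable
output. The 95% CI is a percentile bootstrap over loci; for a ratio-of-sums
estimator the point estimate can fall outside the CI, and no code asserts
otherwise. The test oracle re-derives θ through the nested
indicator-variable ANOVA (mean squares for alleles within individuals within
samples), an independent computational path that agrees to 1e-10.

### P_ST vs. F_ST

For each trait (body DFA score, chela DFA score, trophic position, and
square-root-transformed littoral reliance) the between- and within-habitat
variance components give

    P_ST = σ²_b / (σ²_b + 2 h² σ²_w),   h² = 0.5 by default,

with a mandatory sensitivity table over h² ∈ {0.1, …, 1.0} because the
plug-in dominates the estimate. Components come from a one-way
random-intercept REML fit with a method-of-moments (expected-mean-squares)
fallback; with only two habitat levels REML is fragile and both estimators
share the r−1 divisor convention, whose two-group estimand for a fixed mean
difference Δ is Δ²/2 (this convention matters for simulation truth values
and is used consistently in the tests). The 95% CI is a stratified
nonparametric bootstrap (resampling individuals within habitat, default
10,000 replicates) recomputing the MoM components each replicate — the
bootstrap uses the MoM path because ten thousand REML fits on a 2-level
random effect are both slow and unstable; replicates with zero within-group
variance are dropped and counted. Lake structure is ignored in this variance
model (habitat is the only grouping), matching the headline analysis; a
lake-adjusted variant is available but off by default.

Classification compares CIs: P_ST CI entirely above the F_ST CI ⇒ adaptive
divergence; entirely below ⇒ homogenizing selection; overlap ⇒ drift cannot
be excluded.

## The synthetic-data generator

The generator emulates the study design: 7 lakes × 20 crayfish per habitat
(landmarks, isotopes, genotypes all on the same individuals), 3 replicate
baseline samples per resource per lake, and a separate 16-lake environment
survey. All outputs are deterministic functions of the scenario seed, with
independent substreams per dataset.

* **Landmarks.** A specimen's pre-noise shape is the structure's mean shape
  plus habitat, sex, and allometric deformations (each a unit-norm pattern ×
  magnitude in Procrustes units, orthogonalized against the similarity
  directions of the mean shape so a Procrustes fit cannot silently absorb
  part of the nominal effect), then randomly rotated (U(0, 2π)), scaled to
  the specimen's lognormal centroid size, translated, and perturbed with
  isotropic Gaussian landmark noise proportional to size. Default habitat
  magnitudes (0.0081 body, 0.0046 chela at landmark noise 0.010) are solved
  so the realized DFA-score P_ST matches the study's reported effect sizes
  (≈ 0.36 body, ≈ 0.15 chela): the study reports outcomes, not generative
  inputs, so effect sizes are backed out of the reported statistics.
* **Isotopes.** Crayfish δ15N/δ13C are drawn so the TP and LR equations
  invert to the generating habitat means (TP 3.00/3.05, LR 0.35/0.33 —
  the study's observed means) in expectation; noise SDs (2.0‰ N, 2.4‰ C) are
  backed out of the reported standard errors at n ≈ 140/habitat. Baseline
  replicate scatter is a free parameter (0.5‰ default) since among-location
  variability is not reported.
* **Genotypes.** Balding–Nichols divergence: lake allele frequencies are
  Dirichlet draws `p(1−θ)/θ` around ancestral frequencies (θ_lake = 0.05),
  habitat samples share lake frequencies at θ_habitat = 0 (the study's null);
  genotypes are HWE draws. 14 loci spanning 2–11 alleles. The θ ↔ F_ST
  correspondence gives direct estimator-recovery tests. Loci are strictly
  neutral.
* **Environment.** `√(pelagic CPUE) = 1.0 + 0.5·littoral CPUE + N(0, 0.45)`,
  other covariates independent. The intercept keeps the null model
  uncensored at zero so the LM's calibration is testable.

What the generator does **not** emulate: spatial structure within habitats,
temporal dynamics of invasion, selection at loci, non-Gaussian landmark
digitization error, diet—morphology coupling (littoral reliance and shape are
generated independently, so the shape-diet beta regression has a true null
under defaults), and lake-level covariance between phenotype and environment.
Passing recovery tests therefore demonstrates the estimators and the
pipeline wiring, not robustness to these real-data features.

## Numerical choices and degenerate inputs

* GPA: convergence 1e-10 / 100 iterations; degenerate all-coincident
  configurations give CS = 0 with a warning; landmark-count mismatches are
  rejected naming the offending specimen.
* DFA: PCA rank tolerance 1e-12 (relative); singular pooled covariance or
  n ≤ dim + 2 raise with advice to collect more specimens; permutation count
  and seed are explicit arguments.
* Beta models: boundary LR values instruct clamping; the clamp interval
  [0.001, 0.999] is fixed.
* Rarefaction at g = 2N returns the observed allele number exactly; g > 2N
  is rejected; monomorphic loci yield He = 0 and undefined F_IS, and are
  carried (flagged), never dropped.
* Bootstrap replicates with degenerate variance are dropped and counted;
  seeded generators make every permutation/bootstrap reproducible.

## Problem sizes in the shipped analyses

The numbered scripts and the acceptance script run the full study scale
(280 specimens, 14 loci, 16 environment lakes) with 9,999 permutations and
10,000 bootstrap replicates. The test suite's calibration studies use 400
replicates per procedure with 199 permutations each, coverage studies 300
replicates × 2,000 bootstraps, and pattern-recovery 20 generated studies —
sizes chosen to keep Monte-Carlo error well inside the asserted bands.

## Known limitations

* With two habitat levels, σ²_b has large sampling variance under any
  estimator; the bootstrap CI reflects but cannot remove this.
* The h² plug-in is a modeling assumption; the sensitivity table is the
  honest statement of its influence.
* The residual-df approximation for LMM F tests is slightly anticonservative
  in tiny designs (irrelevant at this study's n).
* The GENEPOP reader handles the 2-/3-digit diploid dialect used here, not
  haploid or extended variants; the TPS reader handles LM/ID/IMAGE/SCALE
  records only.
* Morphometrics packages differ in their (often undocumented) pre-DFA
  dimension-reduction rules; tolerance-based rank retention is this package's
  choice, and score scale (unit pooled within-group variance) is a
  convention — P_ST and all tests are invariant to both.
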