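# Methods

## The model

For a quantitative trait measured on N individuals from a family cohort,
famvar fits the linear mixed model

    y = Xβ + g + k + f + s + c + ε

where X carries the fixed effects (intercept, age, sex and four MDS
ancestry axes in the full pipeline) and each random term is a zero-mean
Gaussian vector with covariance proportional to one of five N×N
structure matrices:

| term | matrix | construction | variance fraction |
|------|--------|--------------|-------------------|
| g | **G** | genomic relationship matrix, `G_jk = (1/m) Σ_i (x_ij − 2p_i)(x_ik − 2p_i) / (2p_i(1−p_i))` with in-sample allele frequencies, missing dosages mean-imputed per SNP | h²g |
| k | **K** | G with off-diagonals below 0.05 set to 0, diagonal kept | h²p |
| f | **F** | 1 iff the pair belongs to the same nuclear-family unit (a couple plus their common offspring; childless couples form a two-member unit; an individual who is offspring in one unit and parent in another links to both) | e²f |
| s | **S** | 1 iff the pair shares both parents | e²s |
| c | **C** | 1 iff the pair are mutual spouses | e²c |
| ε | I | residual | 1 − Σ |

G tags variance spread over common SNPs in related *and* unrelated
pairs; K is nonzero only among close relatives (expected relatedness
≥ 0.05), so fitted jointly with G it absorbs additive genetic variance
that common SNPs do not tag. Narrow-sense heritability is reported as
h²n = h²g + h²p. F, S and C distinguish early shared environment
(family, sibling) from recent shared environment (couple).

Because the K threshold splits one estimator into two collinear
components, and F overlaps S and C by construction, the five-component
fit spreads variance across correlated components. The package therefore
also implements backward stepwise selection: starting from the full
GKFSC model, every component is tested with a drop-one likelihood-ratio
test; while any p ≥ α (default 0.05) the component with the largest p is
removed (ties broken toward the smaller estimated fraction — an
arbitrary but deterministic rule) and the procedure repeats.

## Estimation

Variance components are estimated by restricted maximum likelihood with
the average-information (AI) algorithm. The covariance matrix is linear
in the parameter vector θ, V(θ) = Σ θ_i D_i, which covers both the
univariate model (D_i = structure matrices plus I) and the bivariate
model (block designs, below) with one engine:

- restricted log-likelihood
  `lR = −½ [ log|V| + log|X'V⁻¹X| + y'Py + (n−p) log 2π ]`,
  with P the REML projection matrix;
- score `½ (y'P D_i P y − tr(P D_i))` and average information
  `AI_ij = ½ y'P D_i P D_j P y`, both computed from matrix–vector
  products once V⁻¹ and P are formed (one Cholesky factorization and a
  LAPACK `dpotri` per iteration — the only O(N³) work);
- the first iteration takes an EM-REML step (monotone, parameter-space
  preserving); subsequent iterations take active-set AI steps: variance
  parameters pinned at the floor with a downhill score are frozen so
  they do not contaminate the Newton direction of the free parameters.
  Each proposed step is backtracked (halved) until the likelihood does
  not decrease and V stays positive definite; if the AI system is
  singular (as it is for degenerate inputs such as duplicated traits) a
  ridge-regularized solve and finally a scaled gradient step are tried.
- convergence: |Δ logL| < 1e-6 (configurable), max 100 iterations.
  Exiting because no uphill direction exists at a constrained point also
  counts as converged; exhausting the iteration budget flags the fit.

Negative variance estimates are constrained to a floor of 1e-6 × the
phenotypic variance and reported as 0.00, so a boundary component shows
as `0.00 (SE)`. Variance fractions are θ_i / Σθ with delta-method
standard errors from the inverse AI matrix; a fit whose AI matrix is
numerically singular (or that includes an identity-like structure
matrix, indistinguishable from the residual) is flagged
`identifiable=False`.

With no structure matrices the model reduces to OLS and the residual
variance RSS/(n−p) with its restricted likelihood is returned in closed
form.

### Boundary likelihood-ratio tests

A variance component's null value lies on the boundary of the parameter
space, so 2ΔlogL is referred to a 50:50 mixture of a point mass at zero
and χ²₁: p = ½ P(χ²₁ > stat), one-tailed, and p = 0.5 exactly when the
statistic is zero. The same convention is used for the genetic
correlations (tested against zero covariance by a constrained refit);
for a covariance the null is interior, so the half-χ² reference is a
conservative convention rather than the asymptotic law, kept for
consistency with how such tests are conventionally reported in this
design.

### Bivariate model

Two traits are stacked into a 2N-vector with block covariance
`Σ_comp [[v₁ M, c M],[c M, v₂ M]]` over components G, K (optional) and
the residual (cross-trait residual covariance only for individuals
observed for both traits; individuals missing one trait are retained for
the other rather than intersected). Fixed effects are estimated per
trait (block-diagonal design). Correlations are recovered as
r = c/√(v₁v₂) with delta-method SEs; if either variance sits at the
floor the correlation is reported as undefined (flagged, not NaN), and
an unconstrained optimum outside [−1, 1] is clamped with a flag. When a
trait is an exact duplicate of the other the restricted likelihood is
unbounded at the singular boundary; the optimizer stops at a constrained
point rather than diverging, and any independent noise in the second
trait restores a finite optimum at r = 1.

## Quality control and covariates

SNP/individual filters use the standard array thresholds: SNP call rate
≥ 0.98, per-individual missingness ≤ 0.02, Hardy-Weinberg exact p
> 1e-6, MAF > 0.01. The HWE test is the conditional exact test
(enumeration of the heterozygote count given allele counts, two-sided by
probability-mass inclusion). Filter order is fixed: SNP call rate →
individual missingness → per-SNP statistics recomputed on the retained
individuals → HWE → MAF. The order matters only through the recompute
step and is stated rather than configurable.

MDS ancestry covariates are classical principal coordinates of the
within-cohort identity-by-state distance matrix (pairwise-complete over
missing calls), ordered by eigenvalue and scaled by √eigenvalue. No
external reference panel is used: the projection-onto-1000-Genomes
variant of this procedure needs an external download, and the covariate
role — absorbing ancestry gradients in the fixed effects — is preserved
by the within-cohort axes. A `founders` mask can restrict the
computation when family structure would otherwise dominate the axes.

## The synthetic cohort

The generator exists so that every stage can be tested against known
truth; its defaults describe a family-based adult cohort.

- **Pedigree**: `n_families` founder couples each draw a number of
  offspring (fixed or k + Poisson(λ)); with more than one generation, a
  fraction of each non-final offspring generation is paired into new
  couples across founding families (opposite sexes, no within-family
  pairing). Ages are Uniform(18, 90) — an adult cohort; sex is coded
  0/1.
- **Genotypes**: founders are drawn in Hardy-Weinberg equilibrium at
  MAF ~ Uniform(maf_low, maf_high) (default 0.05–0.5, i.e. common
  variants); offspring inherit one allele from each parent
  (gene-dropping), so emitted trios are Mendelian-consistent by
  construction. Missingness is masked after transmission.
- **Phenotypes**: y = β_age·age + β_sex·sex + g + k + f + s + c + ε.
  g is a weighted sum of `n_causal` standardized SNP dosages with
  standard-normal weights (standardization matching the GRM estimator);
  k is multivariate normal with covariance proportional to the expected
  pedigree relationship matrix A (the quantity K is meant to tag) rather
  than simulated rare variants — equivalent for the estimand and far
  cheaper; f, s, c are one shared draw per nuclear unit / sibship /
  couple (unpaired individuals draw independently; an individual in two
  nuclear units takes the draw of the unit where they are offspring, the
  early environment F represents). Every component vector is rescaled so
  its realized sample variance equals its specified share exactly, which
  removes one layer of Monte-Carlo noise from recovery experiments; the
  realized fractions are recorded in `attrs`.
- **Bivariate traits** share causal SNPs with effect sizes drawn from a
  2×2 normal at correlation r_G; the pedigree-genetic and residual
  white-noise draws are correlated at r_K and r_E; shared-environment
  draws are independent between traits.
- **Items**: Likert responses are `clip(round(3 + a·z ± noise), 1, 5)`
  with loading a = 1.1 and noise SD 0.9, calibrated once so the scored
  6-item scale's Cronbach's alpha lands in the mid-0.8s after
  discretization (the band reported for the instrument this emulates).
  Even-numbered resilience items are reverse-keyed. The 48 coping items
  fall in three fixed 16-item blocks; the genuine instrument's
  item-to-subscale map is proprietary, so the package ships the
  consecutive-block placeholder as a configurable default.

What the generator does *not* emulate: linkage disequilibrium, ancestry
stratification (the cohort it mirrors removed population outliers),
assortative mating, selection, dominance/epistasis, and non-Gaussian
trait distributions. Passing recovery tests therefore demonstrate the
estimator's correctness under its own model assumptions, not robustness
to these real-data features.

## Validation experiments and problem sizes

The test suite validates the estimator against independent oracles and
then measures its statistical behavior at desk scale (all sizes chosen
so the whole suite runs on one CPU in a few minutes):

- **Grid-search oracle**: on N = 60 instances with ≤ 2 components, the
  AI-REML optimum is compared with a dense direct evaluation of the
  restricted likelihood over fraction space (step 0.01), with the
  overall scale profiled in closed form; estimates must agree within
  grid resolution.
- **Closed form**: balanced full-sib designs (500 sibships of 2)
  reproduce the one-way ANOVA method-of-moments components to 1e-6.
- **Recovery**: the four selected-model regimes — (h²g, e²f) =
  (0.06, 0.05); (h²g, e²s, e²c) = (0.14, 0.10, 0.18); (h²g, e²f, e²c) =
  (0.15, 0.05, 0.14); (h²g, e²s, e²c) = (0.15, 0.07, 0.18) — are
  re-estimated over 8 replicate cohorts of 150 four-offspring families
  (N = 900, ~1500 post-QC SNPs), the cohort resimulated each replicate
  so the Monte-Carlo SE reflects all sampling variation; mean bias must
  be under 2 Monte-Carlo SEs per component. A companion check verifies
  that the mean reported (average-information) SE of each fraction is
  within a factor of two of the empirical SD across replicates, and
  that the estimated total variance stays within 10% of the adjusted
  sample variance.
- **Type-I error**: 300 pure-noise replicates on a 150-family cohort
  (N = 600); the boundary LRT's rejection rate at α = 0.05 must fall in
  the exact binomial 95% interval.
- **Selection consistency**: 5 cohorts of 350 four-offspring families
  (N = 2100) at the (0.14, 0.10, 0.18) regime; backward selection must
  return exactly {G, S, C} in ≥ 80% of runs. The design was fixed from
  a power calculation: with e²s = 0.10 the sibling component needs
  roughly 2000 informative sib pairs for decisive (z > 3.5) detection,
  couples need N/6 ≈ 350 couple pairs for e²c = 0.18, and four-offspring
  families maximize informative pairs per genotyped individual; at
  smaller N the sibling effect is regularly absorbed by the collinear
  family or pedigree-genetic component and exact recovery drops toward
  75%.
- **Bivariate recovery**: 8 cohorts (N = 1200) at r_G = −0.8,
  h²g = 0.3 per trait; the mean estimate must sit within 2 Monte-Carlo
  SEs of the truth, and 8 null cohorts (r_G = 0) must not reject above
  chance.

`scripts/acceptance.py` re-runs the same experiments end to end at
slightly reduced replicate counts and writes the measured quantities to
JSON (see the README).

## Known limitations

- Dense linear algebra throughout: O(N³) per REML iteration, practical
  to N of a few thousand on one core. The original analyses at N ≈ 8700
  used the same algorithm in optimized C++; nothing in the method
  changes, only the constant factor.
- The G/K split is weakly identified in small cohorts (K is G among
  relatives), which is exactly why backward selection usually removes K
  when no pedigree-specific variance was generated; full-model
  estimates of h²g and h²p individually carry large SEs while their sum
  is stable.
- Standard errors come from the inverse average information
  (asymptotic); near boundaries they are approximate, and the reported
  SEs of clamped correlations should be read as descriptive.
- The item generator produces a single-factor scale per instrument
  block; it does not emulate cross-loadings or item-specific
  difficulty.
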