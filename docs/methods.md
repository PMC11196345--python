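# Methods

## Model

A biallelic locus with reference-allele frequency `p` acts on a quantitative
trait through a family-level environment `f` with mixture weight `ω_f`. The
crossover norm of reaction assigns genotype values `(a, d, −a)` to
`(BB, Bb, bb)` in Scheme I environments and `(−a, d, a)` in Scheme II.
Phenotypes are `y = G + e` with `e ~ N(0, σ²_e)` and the trait kept on the
unit-variance scale: `σ²_e = 1 − σ²_a − σ²_d`, where
`σ²_a = 2pq[a − (p−q)d]²` and `σ²_d = 4p²q²d²`. Requesting a target
heritability calibrates `a` (positive root when `d ≠ 0`); an infeasible
variance budget raises an error rather than silently rescaling.

HE regression fits `Y_ij = μ + β x_ij + ε` by ordinary least squares with
intercept, where `Y_ij = (y_i − y_j)²` and `x` is, per design:

| design          | pairs                | x                         | Var(x)    |
|-----------------|----------------------|---------------------------|-----------|
| linkage-single  | K sib pairs          | single-locus IBD π        | 1/8       |
| linkage-genome  | n sib pairs          | genome-wide IBD π̃         | 1/(16 𝓛) |
| assoc-single    | all n(n−1)/2 pairs   | z_i z_j                   | 1         |
| assoc-genome    | all n(n−1)/2 pairs   | s_ij = (1/m) Σ z_il z_jl  | ρ̄²_mm    |

The slope expectation is `−2h²` in every design (the recombination factor
`(1−2c)²` is set to 1: the marker is treated as causal/saturated), so fits
report the implied heritability `−slope/2`, unclamped. For sib pairs the
crossover sign flip is invisible within families, so the linkage designs
estimate `𝒽² = Σ_f ω_f 2p_f q_f a²_f` including GxE; the association
designs estimate only the marginal (environment-averaged) component.

Analytic t statistics follow `t = −2h² / SE(β̂)` with
`SE² = [Var(Y)/Var(x) − 4h⁴] / df`, `Var(Y) = 8(1−θ)²h⁴ + 8(1−h²)`
(`θ = 1/2` for sib pairs), `df = n−2` for sib designs and `n(n−1)/2 − 2`
for the all-pairs association designs. Squared statistics are referred to a
1-df noncentral χ²; power uses the exact noncentral distribution, with a
normal approximation retained as a cross-check. The symmetry tests contrast
the two designs' slopes Welch-style and refer `t²` to central χ²₁ — the
intended sample sizes (tens of thousands and up) make a Satterthwaite df
pointless.

## Key parameters and defaults

- `θ = 1/2` — sib-pair "recombination-like" constant in Var(Y).
- `𝓛 = 32` Morgan — genetic length of the 22 human autosomes; sets
  Var(π̃) = 1/(16𝓛) = 1/512.
- `ρ̄²_mm` — mean squared pairwise marker correlation; 1 for a single
  marker, `1/m` for independent markers, `10⁻⁵` as the genome-wide default
  in the Symmetry-II power layout.
- `α = 0.05/10⁶` — per-test rate after a million-SNP scan; target power
  0.85; sample-size grid 500,000…10,000,000 step 500,000. On this grid the
  single-locus linkage design needs 3,000,000 pairs at `𝒽² = 0.015` and
  7,000,000 at `𝒽² = 0.01`; `𝒽² = 0.005` is not reachable (sentinel).
- Experiment defaults (200 replicates; `K ∈ {200, 500}`;
  `h² ∈ {0.1, 0.25, 0.5}`; MAF ~ Uniform(0.01, 0.5) per replicate;
  symmetry layout `n_linkage ∈ {50k, 150k, 300k}`,
  `n_assoc ∈ {10k, 100k}`, GxE grid 0…0.2 step 0.02, baselines
  `h² ∈ {0.25, 0.6}`) match the validation and power experiments the
  analytics were designed around, so headline tables regenerate with no
  flags.

## What the generators emulate — and what they do not

`simulate_sibpairs` draws HWE parents, transmits alleles with explicit
Mendelian segregation (so `π` has the exact (¼, ½, ¼) masses and
Var(π) = 1/8), assigns environments deterministically by family order, and
supports dominance and a continuous per-family effect
`a_fam ~ N(a, E²)` (linkage-visible variance `2pq(a² + E²)`).
`simulate_unrelated` draws independent HWE markers (optionally correlated
through the symmetric square root of a user correlation matrix on the
latent gamete scale — approximate on the genotype scale), splits a total
heritability equally over causal markers, and applies the crossover sign
per individual environment. `simulate_genomewide_ibd_pairs` draws
π̃ ~ N(½, 1/(16𝓛)) truncated to [0,1] (truncation is negligible at
𝓛 = 32 and is counted in the output) with bivariate-normal phenotypes at
correlation `π̃h̃²`, rather than simulating recombination explicitly: only
Var(π̃) enters the analytics, and an explicit map would add unvalidated
structure.

Not emulated: ascertainment or selection, multi-generation pedigrees,
sibling-specific environments, missing genotypes, non-normal residuals,
and realistic LD. Passing tests therefore certify the estimators and the
analytic calculus under the model's own assumptions, not robustness to
real-data violations of them.

## Numerical and design choices

- **OLS paths.** All fits go through one closed-form normal-equations
  routine. The single-marker association fit additionally has an exact
  O(n) pair-moment path (every pair sum reduces to per-individual power
  sums), used for cohorts where enumerating n(n−1)/2 pairs is infeasible;
  it is bit-compatible with the explicit path.
- **Genotype standardization.** Two modes: exact sample z-scoring
  (default; satisfies the mean-0/variance-1 contract of
  `relatedness_scores`) and generating-frequency ("population")
  standardization. The tabulated association sampling variances assume the
  population mode: exact sample centering pins each column sum and
  deflates the null slope SD from `4/n` to about `√8/n`. Replicate-level
  variance checks therefore use the population mode.
- **Null-convention SEs.** The tabulated association SE
  `σ²_b ≈ 16/(n(n−1)) · 1/ρ̄²_mm` is the null sampling variance. At
  `h² > 0` the all-pairs design acquires an extra between-replicate
  variance `≈ 16h²(1−h²)/n` from pairs sharing individuals, which the
  Wald denominator does not track; consequently `E[t²] ≈ NCP + 1 + nh²`
  for association designs at the alternative. The linkage designs, whose
  pairs are independent families, satisfy `E[t²] = NCP + 1` to within a
  few percent and are calibrated at any `h²`.
- **Var(Y) accuracy.** `Var(Y) = 8(1−θ)²h⁴ + 8(1−h²)` is a normal-theory
  value. The explicit genotype model's Y has heavier tails, noticeably at
  large `h²` with rare alleles (empirically 4.62 at `p = 0.5` up to 6.78
  at `p = 0.05` against the analytic 4.50 at `h² = 0.5`), so the analytic
  single-locus linkage t overstates |t| by ≈ 6% at `h² = 0.5` averaged
  over MAF ~ U(0.01, 0.5); at `h² ≤ 0.25` the agreement is within
  Monte-Carlo noise. Validation comparisons use the signed mean t — the
  mean *magnitude* of a noisy t is upward-biased at small noncentrality
  (folded-normal effect) and would miscompare even a perfect simulator.
- **Exact vs tabulated forms.** The single-locus linkage denominator uses
  `16(1−h²)/h⁴` (the tabulated form consistent with the `−(h²/4)√n`
  approximation; the running-text variant with `/h²` is a typo). Both the
  exact `(n−2)` statistics and the large-n NCP table are exposed; exact is
  the default everywhere, including the sample-size solver, whose grid
  answers match the tabulated approximations on the headline grid.
- **Validation sample composition.** Scheme-I and Scheme-II validation
  samples each contain K families; the pooled sample concatenates both
  (2K families), so the pooled linkage gain reflects the doubled cohort
  while pooled GWAS cancels. Each comparison uses its own sample's n.
- **Symmetry power layout.** The Fig-style grid defaults to baselines
  `h² ∈ {0.25, 0.6}`. At genome-scan α the 50,000-pair linkage arm never
  reaches power 0.5 anywhere on the GxE grid; the 300,000-pair arm crosses
  0.5 only for the higher baseline.
- **RNG.** Every generator accepts an integer seed or a Generator;
  experiment runners derive independent per-replicate streams from
  (seed, scenario, replicate). Identical seeds give bit-identical tables.

## Problem sizes used in the checks

Replicate counts and cohort sizes in the test suite are chosen to keep each
statistical check's Monte-Carlo error several times smaller than the
quantity it bounds: transmission moments at 10⁵ families; slope-SD
agreement at 200 replicates of (5,000 sib pairs / 1,000 unrelated /
20,000 genome-IBD pairs / 1,000×50-marker cohorts); validation at the
standard 200 replicates; symmetry null calibration at 2,000 summary-level
replicates and the noncentrality recovery at 500 individual-level
replicates of 300,000 sib pairs plus 100,000 unrelateds (via the O(n)
association path).

## Known limitations

- The analytic association machinery is a null-variance calculus; its
  power predictions at strong alternatives are optimistic (see above).
- `ρ̄²_mm` from a finite sample is upward-biased by `≈ (m−1)/(mn)`; a
  correction is available but off by default since the analytics use
  population values.
- The LD-inducing generator controls latent-scale, not genotype-scale,
  correlation.
- Binary traits, ascertainment, GLS/REML variants, and overlapping
  linkage/association cohorts are out of scope.
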