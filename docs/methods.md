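# Methods

## Synthetic data: what it emulates and what it does not

The generator (`menvgp.sim`) reproduces the data regime of a diversity
panel of fully inbred lines evaluated in a few location-year environments:

* **Genotypes** are independent biallelic SNPs with allele frequencies
  drawn uniformly from a configurable MAF range (default 0.05–0.5, a free
  choice since the post-QC frequency spectrum of real panels varies);
  dosages are strictly {0, 2} because an inbred panel carries no
  heterozygotes. No linkage disequilibrium is simulated.
* **Breeding values** follow `vec(U) ~ N(0, E ⊗ K)` with `K` computed from
  the simulated markers and `E` a configurable environment covariance
  (default: equicorrelated, correlation 0.8, matching the high positive
  between-environment correlations typical of geographically close
  trials). Sampling uses `U = L_K Z L_E′`, which has exactly this
  Kronecker covariance.
* **Field trials** place `n_lines × n_reps` plots per environment on a
  near-square row-column grid (randomized complete blocks: each replicate
  is a contiguous permutation of all lines). The phenotype adds the
  environment mean, the breeding value, a smooth surface (low-frequency
  sinusoids plus a bilinear row×column term, rescaled to a target SD and
  deliberately inside the function space the PS-ANOVA basis spans, so
  spatial recovery is a fair test), an i.i.d. replicate effect (default SD
  0.25, modest block differences), and Gaussian noise. The residual
  variance is set from the per-environment heritability target `h²` so
  that `var(g) / (var(g) + var(ε)/n_reps) = h²` at the level of line
  means; the spatial surface sits on top and is removable by adjustment.
  Default heritabilities (0.25, 0.40, 0.50, 0.35) span the moderate-to-low
  range reported for stalk-lodging-related traits.
* **Unbalancedness** drops a configurable fraction of line × environment
  cells (default 10%) uniformly at random, by default never leaving a line
  unobserved in two or more environments — the same guard the exclusion
  rule applies to real data.

Passing tests on these data demonstrates correct algebra and parameter
recovery under a correctly specified model; they do not speak to LD
structure, population stratification, non-Gaussian residuals, or
covariate-driven G×E beyond what the kernels encode.

## Spatial model

Per environment: `y = 1μ + X_s β_s + Z_s s + Z_u u + Z_g g + ε` with fixed
surface part {1, r, c, rc} (coordinates scaled to [0, 1] and centered),
five penalized blocks — row smooth `f₁(r)`, column smooth `f₂(c)`, two
linear-by-smooth interactions `h₃(r)c` and `h₄(c)r`, and the tensor
`f₅(r, c)` — random row and column factors `u`, and fixed genotype effects
under sum-to-zero contrasts (BLUE = intercept + effect, so columns are
comparable across environments). Smooth blocks are cubic B-splines on
equally spaced knots (one segment per two plot positions, clipped to
[5, 20]) with second-order difference penalties, eigen-reparameterized to
i.i.d. random-effect form; the penalty null space (constants and linear
trends) lives in the fixed part. Replicates are not given a separate block
term: discontinuous field variation is carried by the row/column factors.

REML maximizes the restricted likelihood by fixed-point iteration on
effective dimensions: solve the mixed-model equations at the current
ratios `λ_k = σ²_ε/σ²_k`, update `σ²_k = û_k′û_k / ED_k` with
`ED_k = q_k − λ_k tr(C⁻¹_kk)`, update `σ²_ε` from the residual sum of
squares, and stop when successive restricted log-likelihoods differ by
less than 1e-6 (maximum 200 iterations). Variances are floored at
1e-10 × var(y); when `σ²_ε` hits the floor (noise-free data) the fit stops
with genotype estimates equal to least-squares means. The monotonicity of
the objective is checked by a test rather than guaranteed by the scheme.

## Prediction models and priors

All scalar-variance models run on one Gibbs engine
(`gibbs_multikernel`): each random term's effect vector is updated jointly
in the eigenbasis of its kernel (where the full conditional is diagonal),
scalar variances get scaled-inverse-χ² updates with prior df 5 and scales
chosen so the prior *mode* splits the sample phenotypic variance equally
across terms and residual (BGLR-like); fixed effects are flat; records
with missing phenotypes are handled by data augmentation, which leaves
them without influence on the posterior and yields predictions as a
by-product. Multi-environment records are stacked environment-major, so
every covariance is a Kronecker product of a small environment-side matrix
and a line-side matrix; the engine exploits this for fast projections and
shares eigendecompositions across cross-validation replicates.

Model-specific notes:

* **G×C**: five terms — genetic main (`K` in every environment pair),
  environment main, EC kernel `Ω` (environment-level; the alternative
  cell-level reading of the EC effect is not used), and the two Hadamard
  interactions (block-diagonal `K`, and `Ω ⊗ K`). The environment main
  effect has only J levels and is weakly identified; it is kept random
  with its own variance, as the model family specifies.
* **M×E**: GBLUP parameterization with a shared main term (`K` across all
  environment pairs) and one specific term per environment, plus
  per-environment intercepts. The ridge parameterization on marker effects
  is implemented in closed form; the two match exactly at
  `σ²_u = p · σ²_b` (verified to 1e-6 in a test), which resolves the
  scaling between the marker-effect and kernel variances under
  standardized markers.
* **MTM1/2**: a dedicated matrix-normal sampler in the eigenbasis of the
  ridge-stabilized `K` (+1e-6 on the diagonal), with per-line J×J
  conditionals, inverse-Wishart updates for the unstructured `E` (and `F`
  for MTM2) with df J+2, and a homogeneous residual. The IW *scale* uses
  the prior-mean convention: `S₀ = share × (ν − J − 1)` so the prior mean
  of `E` is an equal share of the per-environment phenotypic variance.
  With a mode-matched scale (as for the scalar variances) the prior mean
  is an order of magnitude above the phenotypic variance, and because a
  panel genotyped at many independent markers has a genomic kernel with a
  near-identity spectrum — leaving `E` and `σ²_ε` only weakly separated by
  the likelihood — that prior visibly inflated genetic variances and
  diluted genetic correlations. Posterior summaries use means; a crude
  effective sample size of the residual-variance chain is logged, and no
  convergence diagnostic gates results.

Heritability is `σ²_g/(σ²_g + σ²_ε)` per environment, computed per
posterior sample then averaged; genetic correlations are
`E_jk/√(E_jj E_kk)` per sample (non-positive-definite draws would be
excluded with a logged count; inverse-Wishart draws are PD by
construction); variance proportions divide each component's posterior-mean
variance by the total including residual.

### Identifiability caveat

With `p` independent markers ≫ `n` lines, `K = WW′/p` concentrates around
the identity, so kernels that differ from `I` only through `K` (the
block-diagonal G×E term, the M×E specific terms, `E ⊗ K` at J = 1) are
weakly separated from the residual; posteriors for those contrasts then
lean on the prior. Tests of null behavior (noise-free heritability near 1,
residual dominance under pure noise, interaction proportions near zero
without G×E) therefore use instances with markers < lines, where `K` is
rank-deficient and its null space pins the residual variance. Parameter
recovery at the stated study scale (300 lines, 2000 markers) is unaffected
within its tolerances. Real resequence data are less afflicted: LD and
structure give `K` a strongly non-uniform spectrum.

## Cross-validation

Test fraction 0.2 of lines; 100 replicates by default for all three
schemes (single-environment 80/20, CV1, CV2 — the replicate count for the
multi-environment schemes follows the same convention). CV2 hides each
test line in a uniformly chosen nonempty proper subset of its observed
environments. Predictive ability is Pearson r per environment over that
environment's masked cells (matching per-environment reporting), recorded
as missing below three test pairs. Masking is leak-free by construction
(masked cells enter the samplers as missing data) and verified by a
sentinel-poisoning test. Wilcoxon signed-rank comparisons use the exact
null for ≤ 25 pairs and the continuity-corrected normal approximation
otherwise, dropping zero differences; the paired t test reports a flagged
degenerate p-value when differences have zero variance.

## Problem sizes used in the shipped runs

The test suite and `scripts/acceptance.py` use simulations of 100–300
lines, 250–2000 markers, and chains of 600–14,000 iterations depending on
what each check needs (closed-form comparisons need long chains on tiny
instances; recovery checks need realistic n with moderate chains; CV
contrasts need many replicates with short chains). The acceptance study
(300 lines × 1200 markers × 4 environments, 10 CV replicates per scheme,
800-iteration chains) was chosen to make the full run complete in a few
minutes on a single CPU while leaving every qualitative contrast stable
across seeds; default chain settings for production use remain
20,000/8,000/5.

## Known limitations

* No LD or population-structure simulation; no dominance or epistatic
  kernels; no Gaussian (nonlinear) kernels; no hybrid prediction.
* Residual variance is homogeneous across environments in every model.
* Correlation pruning in QC is a greedy left-to-right scan on mean-imputed
  dosages (the later marker of a correlated pair is dropped); windowed,
  position-aware LD pruning is out of scope.
* The environment-level terms (E, w) in G×C rest on very few levels and
  should be read as weakly identified descriptive splits, not precise
  estimates.
* BLUE standard errors are reported from the prediction-error covariance
  of the final REML solve and ignore variance-component uncertainty.
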