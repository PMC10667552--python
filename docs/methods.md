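# Methods

This note documents the models, the synthetic-data generator, and the
numerical choices behind `clonalmate`, in enough detail to judge what a
passing test suite does and does not demonstrate.

## 1. Genomic models

Genotypes are pseudo-diploid SNP dosages of the major allele
(2/1/0 = homozygous major / heterozygous / homozygous minor). All
relationship matrices, heterozygosity ratios, and inbreeding
coefficients are defined relative to a fixed vector of allele
frequencies `p`, computed from the training population and frozen
thereafter — simulated progeny are measured against the same base
population as their parents, and both mate-allocation strategies see
identical matrices. (Combined-population frequencies can be passed
explicitly where wanted.)

**Additive GRM.** Off-diagonal
`G_A[j,k] = (1/n) Σ_i (x_ij − 2p_i)(x_ik − 2p_i) / (2p_i q_i)`;
diagonal
`G_A[j,j] = 1 + (1/n) Σ_i (x_ij² − (1+2p_i)x_ij + 2p_i²) / (2p_i q_i)`,
the unbiased self-relationship whose mean is `1 + mean F`. The diagonal
therefore does *not* equal the cross-product form `Σ(x−2p)²/(2pq)/n`
except at `p = 1/2` or under exact Hardy–Weinberg dosages; in an
excess-heterozygosity population (mean `F < 0`) the matrix is mildly
indefinite. This has two numerical consequences handled below (§4).

**Dominance GRM.** `G_D = HH'/n` with
`h_ij = (x_D,ij − 2p_i²)/(2p_i q_i)` and `x_D ∈ {0, 2p, 4p−2}`. This
coding makes the per-marker dominance covariate orthogonal to the
additive covariate at HWE genotype frequencies, so adding the dominance
term does not bias the additive solutions there (asserted on exact-HWE
fixtures in the tests; real and synthetic populations deviate from HWE
and the orthogonality is then only approximate).

**Epistatic GRM.** `G_AA = (G_A ⊙ G_A)/(tr(G_A ⊙ G_A)/m)`; the
normaliser makes `mean(diag) = 1` exactly so all variance components sit
on the trait scale. For progeny blocks the *training* normaliser is
reused.

**Heterozygosity.** `Het_k = (# heterozygous loci of k) / Σ_i 2p_i q_i`,
an observed/expected ratio with mean ≈ 1 in an HWE population. An
alternative reading that sums the `H`-matrix elements instead of the
0/1 heterozygosity indicator is available via
`genomewide_heterozygosity(..., numerator="h_element")`; the indicator
reading is the default because it is the one with a direct biological
interpretation, but both are kept since the literature is ambiguous
about which enters the regression.

**Inbreeding.** `F_k = G_A[k,k] − 1`; negative values mean more
heterozygous than the base population.

**REML.** Variance components are estimated by average-information REML
on `V = Σ_i σ²_i G_i + σ²_ε I`:

* scores `∂logL/∂σ²_i = −½(tr(P G_i) − y'P G_i P y)` and AI matrix
  `AI_ij = ½ y'P G_i P G_j P y`, with `P` the REML projection;
* Newton step, halved up to 8 times while it leaves the parameter
  space; a component still below the floor is pinned at
  `1e−6 · var(y)` and flagged (reported as a boundary estimate, the
  `~ 0` of variance-component tables) and excluded from later updates;
* EM fallback step if the AI system is singular;
* convergence when `|Δ logL| < 1e−6` (config key), start values an
  equal split of `var(y)`;
* standard errors from the inverse AI matrix over free components
  (undefined for pinned ones).

The heterozygosity ratio enters the extended model as a fixed covariate,
mean-centred for conditioning; the reported slope `b̂` is unchanged by
centring and the centring constant is stored with the fit so that
predicted heterozygosity terms are deviations from the training mean.
The likelihood-ratio test compares the two nested fits against χ²(1) by
default, mirroring common practice even though the extended model adds
three parameters; a caller can pass the true df, and boundary-aware
mixtures are deliberately left out of the default path.

**Mixed-model equations.** With one record per clone (`Z = I`) the MME
solutions are computed through the variance matrix:
`β̂` by GLS and `â_i = σ²_i G_i V⁻¹(y − Xβ̂)`. These are algebraically
the unique MME solutions whenever the `G_i` are invertible, and remain
defined when a matrix is singular or slightly indefinite (§4). The
explicit coefficient system (with `G⁻¹` after a `1e−8` ridge) is kept as
`solve_mme(..., method="mme")` and the two routes are asserted equal on
positive-definite fixtures.

**Progeny prediction.** For unphenotyped progeny each random component
is the conditional expectation `G_pt G_tt⁻¹ â_train`, computed as
`G_pt · (σ²_i V⁻¹ r)` through the stored fit weights — identical by
algebra, and exact also for the epistatic term (no marker-effect
backsolve exists for `G_AA`, and the GCTA-style diagonal breaks the
exact additive backsolve identity as well, so the relationship path is
the only path). The clonal value is `ĝ = û + d̂ + t̂ + b̂(Het − H̄)`;
the GEBV is `û` alone. Cross blocks are computed in progeny chunks
(default 2,048) to bound memory at full factorial scale.

## 2. Meiosis

Strictly diploid, interference-free count-location meiosis: per
chromosome, crossover count ~ Poisson(length in Morgans), positions
i.i.d. uniform, starting haplotype a fair coin. Two samplers:

* a literal positional sampler (`sample_gamete`), which also reports
  realized crossover counts (used to verify the Poisson property);
* a vectorised marker-interval sampler (`sample_gametes`) that switches
  source haplotype between adjacent markers `d` apart with probability
  `(1 − e^(−2d))/2`. A Poisson process puts an odd number of points in
  disjoint intervals independently with exactly these probabilities, so
  the two samplers are distributionally identical at the markers;
  crossovers between markers with no marker in between are unobservable
  either way. Tests check both samplers against the Haldane map
  function at `d ∈ {0.05, 0.2, 0.5, 1.0}` M.

Phase is not observed in dosage data: heterozygous loci are phased
uniformly at random, once per parent per run, from a seeded stream.
Each cross draws from its own substream (derived from the root seed and
the cross's position in the deterministic female-major cross list), so
families are reproducible independently of execution order.

## 3. Synthetic data

The generator emulates the statistical shape of an elite clonal
breeding panel; no real data ships with the package.

* **Map**: uniform marker positions on equal-length chromosomes
  (defaults: 10 chromosomes × 1.5 M).
* **Marker-wise founders**: major-allele frequency ~ Uniform(0.5,
  1 − maf_min) per marker; genotype frequencies inflate HWE
  heterozygosity by `(1 + h)` with `h = 0.2` by default (clonal hybrids
  are more heterozygous than random mating would give), capped at
  feasibility; markers whose sample MAF falls below the floor (default
  0.01) are resampled, then dropped. The inflation default is a
  modelling choice — the heterozygosity distribution of real panels is
  program-specific.
* **Training population**: the experiment pipeline mates a small
  ancestor pool (default 24) at random for one generation (family size
  4) and applies the MAF filter to the result. The resulting
  full-/half-sib network supplies the off-diagonal relationship
  structure that makes dominance and epistatic variance separable from
  residual noise — with mutually unrelated clones, `G_AA ≈ I` and
  `σ²_AA` is confounded with `σ²_ε`. It also keeps `G_A` numerically
  near-PSD. This is the single most consequential design decision in
  the generator.
* **Trait architecture**: additive and dominance effects are N(0,1)
  draws per marker; epistasis is a finite set of marker-pair
  interactions (default 200 pairs) on centred additive covariates, so
  that the truth is heritable through meiosis (an infinitesimal
  `G_AA`-truth would not be attached to marker states a progeny can
  inherit). Each component's effects are rescaled so its realized
  variance over the training clones equals the target exactly;
  component targets default to the cane-yield-like decomposition
  (σ²_A, σ²_D, σ²_AA, σ²_ε) = (15.82, 3.08, 22.94, 46.10) with
  heterozygosity slope 92.84 per unit Het ratio ("tch" preset); the
  "ccs"/"fibre" presets have near-zero dominance and small slopes.
* **Phenotypes**: one record per clone, total genetic value plus
  N(0, σ²_ε) noise — the single-stage stand-in for spatially adjusted
  trial BLUPs. No trial, plot, ratoon, or G×E structure is simulated.
* **`mvn_phenotypes`**: draws from the *exact* relationship-matrix
  model (matrix-root sampling per component) and exists solely for
  REML parameter-recovery tests, where the fitted model is true by
  construction.

What passing tests therefore show: the estimators and the allocation
machinery are correct for data whose generative process matches the
model (exactly, for `mvn_phenotypes`; approximately, for the
finite-loci truth). What they do not show: performance under real-world
complications — polyploid meiosis, preferential pairing, genotype
calling error, G×E, LD patterns of a long-bred elite panel — none of
which are simulated.

## 4. Numerical choices

* **Indefinite `G_A`**: the unbiased diagonal `1 + F` of an
  excess-heterozygosity population sits below the cross-product
  diagonal, so `G_A` can have small negative eigenvalues. REML and the
  GLS-route MME never invert `G` (only `V`, which is PD for
  `σ²_ε > 0`), so they are unaffected. `mvn_phenotypes` needs a matrix
  root and projects onto the nearest PSD matrix by clipping negative
  eigenvalues (default; disable to get a hard error instead).
* **Ridges**: `1e−8` on any explicitly factorised relationship matrix;
  never applied to reported matrix values.
* **Floors and tolerances** (config keys with these defaults):
  REML logL tolerance `1e−6`, component floor `1e−6 · var(y)`, MME
  residual check `1e−8` relative.
* **ILP tie-breaking**: merits are perturbed by `rank × 1e−12` in the
  deterministic female-major cross order before solving, so the
  selected set is reproducible across solver backends; the reported
  objective is unperturbed. The number of selected crosses is an
  equality constraint by default (`exact_count=False` relaxes it to
  ≤). Top-decile counts use the ceiling (50 progeny → best 5).
* **Seeding**: one root seed; map/founders/architecture/phenotypes,
  each iteration, and each cross use children of a `SeedSequence`
  spawned from it. Identical configuration and seed reproduce every
  number bit-for-bit (timings aside).

## 5. The experiment pipeline

`run_experiment` mirrors the two-strategy comparison: fit both models
once on the training clones, rank clones by GEBV and keep the top
`2 × n_per_sex` as parents, then per iteration re-randomise the sex
split (to remove male/female assignment bias; the parent pool itself is
fixed), simulate the full factorial with `n_progeny_per_cross` progeny,
predict `û` and `ĝ` for every progeny, score each cross by its
top-decile progeny, and solve one ILP per strategy on the same progeny.
Reported per iteration: each strategy's average expected progeny value
(EPV) on its own objective, mean progeny inbreeding of the selected
crosses (PIB), `Δu` and `Δg` (selected-set mean minus all-cross mean),
cross overlap, and — since simulation knows the truth — the mean true
clonal value of the selected families. Aggregates are mean (SD) over
iterations. Training fits are reused across iterations (a per-iteration
refit flag exists); whether `Δu` of the GPCP plan should be computed
from the `û` merits of its crosses is not uniquely defined, so both
plans report both `Δu` and `Δg`.

Desk-scale defaults (400 clones × ~2,000 markers, 12 parents per sex,
20 progeny per cross, 2 iterations) run in seconds and are the test
configuration; `ExperimentConfig.full_scale()` gives the full-scale
profile (2,909 clones, ~10,000 mapped markers, 35 × 35 factorial, 50
progeny per cross, 10 iterations), which is supported but takes far
longer and is not exercised by the tests.

## 6. Known limitations

* Diploid meiosis only — no polyploid or preferential-pairing modes,
  although clonal polyploids are the motivating crops; dosage markers
  are treated as pseudo-diploid.
* The LRT default df of 1 understates the parameter difference of the
  nested pair; it is a convention, not a recommendation.
* Cross merit uses the mean of top-decile *predicted* progeny; no
  usefulness-criterion variance term, optimal-contribution control, or
  multi-trait index is implemented.
* At desk scale the non-additive variance components are weakly
  identified (large SEs; boundary pins are common on finite-loci
  phenotypes); the strategy comparison remains well behaved because it
  depends on the fitted predictions, not on an accurate variance
  decomposition.
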