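# Methods

## Models

Both samplers work in the marker-effect (SNP-BLUP) parameterization of
GBLUP. For a single trait on the training animals,

    y = X b + W d + M α + e

- `X`: intercept plus treatment-coded dummies for lactation order
  (levels 1–3) and farm (levels 1–12); only levels observed in the training
  set receive columns, so `X` is always full rank.
- `W`: incidence of days-in-milk (DIM) classes. DIM is continuous; it enters
  as a random *factor*, binned into 30-day classes (`class = ⌊DIM/30⌋ + 1`,
  configurable bin width). The 30-day default mirrors monthly milk
  recording, where test days are roughly 28–33 days apart. Class effects are
  i.i.d. `N(0, σ²_d)`.
- `M`: dosage matrix centered by twice the observed ALT-allele frequency.
  Marker effects are i.i.d. `N(0, σ²_α)`, so the genetic values `g = Mα`
  have covariance `(MM') σ²_α` — exactly GBLUP with the VanRaden-1
  relationship matrix `K = MM'/c`, `c = 2 Σ_j p_j(1−p_j)`, and
  `σ²_a = c σ²_α`. The marker parameterization is used because the
  genetic-parameter summaries consume per-iteration marker effects directly;
  no backsolving is needed.

The multi-trait model gives each marker a `t`-variate effect
`a_j ~ N(0, Σ_α)` (unstructured) and each animal a residual row
`~ N(0, R)` (unstructured), inducing `Σ ⊗ K` on stacked genetic values and
`R ⊗ I` on residuals. DIM effects stay diagonal across traits: with ~11
classes an unstructured DIM covariance is not identifiable at this scale.
Training uses complete cases (animals missing any trait are dropped); there
is no missing-phenotype machinery.

## Sampler

Single-site (coordinate) Gibbs, compiled with numba:

1. fixed effects jointly from their multivariate-normal full conditional
   (flat prior);
2. each DIM class effect (scalar or `t`-vector);
3. each marker effect from its normal / `t`-variate-normal full conditional,
   maintaining a running residual so one sweep costs `O(n p)` single-trait
   and `O(n p t + p t³)` multi-trait;
4. variance components: scaled-inverse-chi-square full conditionals for
   scalar variances, inverse-Wishart for `Σ_α` and `R` (Bartlett
   factorization; a failed Cholesky triggers one jitter-and-retry on the
   posterior scale matrix before aborting with the iteration number).

All randomness flows through one RNG seeded at kernel entry, so chains are
bit-reproducible. The single-trait sampler was validated against an exact
two-dimensional grid integration of the marginalized posterior (effects and
fixed effects integrated analytically): posterior means of `σ²_α` and `σ²_e`
agree to three decimals. The multi-trait sampler is cross-checked in the
tests against closed-form solves at fixed variances and against the
single-trait chain at `t = 1`.

## Priors and defaults

- Chain: 100,000 iterations, 20,000 burn-in (production protocol);
  desk-scale work and the bundled tests use 3,000/1,000. Thinning keeps
  every 10th draw by default (configurable to 1); draws are stored, so
  thinning only bounds memory.
- Scalar variances: scaled-inverse-chi-square, ν = 5, scale set so the prior
  *mode* splits the training-phenotype variance 30% genetic / 5% DIM / 65%
  residual. This is the weakly-informative empirical split customary for
  Bayesian ridge fits of dairy traits.
- `Σ_α`, `R`: inverse-Wishart with ν = t + 3 and diagonal scale matrices
  implying the same 30/65 modal split.
- Heritability denominator includes the DIM variance
  (`h² = σ²_g/(σ²_g + σ²_d + σ²_e)`): DIM is a model term, and dropping it
  would inflate h². A flag excludes it for comparison with analyses that
  treat DIM as purely environmental noise.
- Genetic correlations are computed per retained draw as
  `σ_g,12/√(σ_g,11 σ_g,22)` and averaged; draws with a non-positive genetic
  variance are skipped and counted.
- Phenotypic correlations are Pearson correlations of raw trait values
  (pairwise complete); whether to adjust for fixed effects first is an open
  choice, and raw values are the default with an `--adjusted` option on the
  validation command.
- Validation: one random hold-out split (default 400 train / 97 test),
  accuracy = Pearson r of observed phenotype vs GEBV, bias = slope of
  phenotype on GEBV. Regressing phenotype on GEBV (not the reverse) is the
  direction in which `b > 1` means the GEBVs are under-dispersed. Marker
  rank correlations default to squared posterior-mean effects (the scale on
  which per-marker influence is usually displayed), with absolute/raw
  available.

## Synthetic population

The generator emulates a ~500-cow genotyped Holstein population recorded
for MY, MF, MP, ML, MDM across 12 farms and 3 lactations:

- markers: independent biallelic loci, `p_j ~ U(0.05, 0.5)`, dosages
  `Binomial(2, p_j)` i.i.d. across animals, per-cell missingness 1%;
- effects: per-marker `t`-vectors `N(0, Σ*_α)` with
  `Σ*_α = Σ_g,target / Σ_i var(SNP_i)`, so the aggregate genetic covariance
  matches the target heritabilities (defaults 0.24, 0.22, 0.30, 0.22, 0.24)
  and genetic-correlation matrix (defaults in the weakly-negative-with-MY,
  MF–MDM ≈ 0.5 regime typical of milk components) in expectation;
- phenotypes: mean + lactation + farm + DIM-class + genetic + residual;
  farm and lactation effects are drawn `N(0, (0.15 sd)²)` and
  `N(0, (0.10 sd)²)`, DIM classes carry 5% of variance, and the residual
  covariance is diagonal by default (no residual cross-trait correlation);
  trait means/SDs default to field-typical values (MY 6500 ± 1100 kg,
  MF 4.1 ± 0.45%, MP 3.3 ± 0.25%, ML 4.8 ± 0.20%, MDM 12.9 ± 0.70%);
- every dataset ships with a truth record (effects, genetic values,
  realized h² and genetic correlations) for parameter-recovery tests.

What the generator does **not** emulate: linkage disequilibrium (an optional
Gaussian-copula block mode exists but is off by default — the inference
model nowhere uses LD, and independent loci make the realized-parameter
oracles exact in expectation), pedigree/family structure, selection, and
chip ascertainment. The family-structure omission matters most: simulated
animals are mutually unrelated, so the genomic relationship matrix has
near-zero off-diagonals.

## What passing tests do and do not show

Because simulated animals are unrelated, variance components are weakly
identified at n ≈ 400: exact ML/REML on the same data has a per-replicate
sampling SD of roughly 0.16 for h² and ≥ 0.3 for a genetic correlation (we
verified this with an eigen-decomposition REML oracle). The Bayesian
posterior — which the tests verify is sampled exactly — trades that
variance for shrinkage toward the prior's 30% genetic mode, so posterior
mean h² typically lands 0.05–0.12 above a truth of 0.22–0.30, and a true
genetic correlation of 0.5 is attenuated to ≈ 0.2. Hold-out GEBV accuracies
are similarly modest (≈ 0.1–0.3) because test animals share no family ties
with training animals. Real dairy data behave differently on all three
counts: dense half-sib structure concentrates relatedness, which is what
makes h² estimates tight and accuracies of 0.77–0.88 reachable. Passing
recovery tests here therefore demonstrate correctness of the machinery and
honest behavior in a hard, unstructured regime — not field-level accuracy.

## Numerical choices

- MAF filter is strict (`MAF > threshold`), matching "greater than 5%";
  monomorphic markers always fail it. Animal missing-rate filter is also
  strict (`rate > 10%` removed). Animals are filtered before MAF is
  computed, then residual missing dosages are mean-imputed (preserves
  allele frequency).
- `K` gets an optional `ε·I` jitter (default off; 1e-8 recommended for
  factorization) — never applied silently.
- `var(SNP_i)` in the genetic-covariance summary is the empirical dosage
  variance (population denominator), not `2p(1−p)`; the two agree in
  expectation under Hardy–Weinberg.
- Ties in rank correlations use average ranks (scipy); p-values use the
  t approximation.
- Degenerate inputs raise: empty animal intersection, all-filtered panels,
  fully-missing markers, zero-variance GEBV vectors (flagged NaN with a
  warning rather than an exception when a single trait degenerates inside a
  batch run).

## Known limitations

- Genotyped-animals-only: no pedigree relationship matrix and no blending
  of pedigree with genomic relationships (nothing in scope defines a
  pedigree).
- Bayesian ridge only (all markers share one variance); no variable
  selection priors, no REML backend.
- Complete-case multi-trait training.
- Exact draw-level equality under trait permutation is not guaranteed
  (single RNG stream); posterior summaries are permutation-consistent and
  tested as such.
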