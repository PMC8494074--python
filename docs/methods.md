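# Methods

## Null polygenic model

The trait is modelled as Gaussian, `Y ~ N(Z beta, Sigma0)` with
`Sigma0 = sigma_e^2 I + sigma_a^2 A`.  Count-valued indices (DMFT-like) are
treated as continuous; no count-model alternative is provided.

**Relatedness convention.**  `A = 2 Phi` (the additive genetic relationship
matrix) by default, so the diagonal is ~1 for outbred samples and
`sigma_a^2 / (sigma_a^2 + sigma_e^2)` is interpretable as narrow-sense
heritability.  A strict-kinship switch (`relatedness="phi"`) puts `Phi`
itself inside `Sigma0`; the two conventions are *not* equivalent up to
rescaling once both variance components are free, and the switch also
changes the `V'AV` denominator of the test statistics, so it must match
between fit and test (the Results object enforces this by carrying its own
`A`).

**Fitting.**  Maximum likelihood (not REML).  Writing
`sigma^2 = sigma_a^2 + sigma_e^2` and `h = sigma_a^2 / sigma^2`,
`Sigma0 = sigma^2 [(1-h) I + h A]`.  One eigendecomposition `A = U W U'`
rotates the data; given `h`, GLS `beta` and the ML `sigma^2 = RSS_w / n`
are closed-form, and the profile likelihood is maximized over
`h in [1e-6, 1 - 1e-6]` by bounded Brent search (xatol 1e-8).  When the
profile is flat to within 1e-6 log-likelihood units of the `h -> 0` endpoint
(exactly what happens when `A = I` and the split is unidentifiable) the fit
reports `h = 0`; a boundary optimum at `h = 0` is reported, not an error.
Wald standard errors for `beta` come from `(Z' Sigma0^-1 Z)^-1` with
two-sided normal p-values.  The fit exposes `V = Sigma0^-1 (Y - Z beta)` and
`P = Sigma0^-1 - Sigma0^-1 Z (Z'Sigma0^-1 Z)^-1 Z'Sigma0^-1`, which satisfy
`V = P Y`, `P Z = 0`, and `P Sigma0 P = P` (asserted in tests).

## Gene test

`S_ABT = V'G (DRD)^-1 G'V / V'AV` with `DRD` the sample covariance
(ddof = 1) of the gene's cleaned, mean-imputed dosage columns.  The null law
is the mixture `sum_k lambda_k chi^2_1` with `lambda_k` the eigenvalues of
`W G'PG W`, `W = (V'AV)^(-1/2) (DRD)^(-1/2)` (symmetric inverse square
root).  Numerical choices:

- **Spectrum hygiene:** eigenvalues below `-1e-8 * max|lambda|` trigger a
  warning; all negative round-off is clipped to 0, and components below
  `1e-12 * max` are dropped before tail computation.
- **Near-singular LD:** after monomorphic/duplicate-column cleaning the gene
  covariance is almost always well-conditioned; if its condition number
  still reaches 1e12 (LD just short of exact duplication), `R` is
  ridge-shrunk `(1-eps) R + eps I` with `eps` escalating tenfold from 1e-6,
  and the applied `eps` is recorded on the result.
- **Tail probability cascade:** exact chi-square survival when all nonzero
  eigenvalues coincide; Ruben's certified chi-square series when the
  statistic is below the mixture mean (where it converges fast and the
  inversion integral is awkward); otherwise Imhof characteristic-function
  inversion, implemented as adaptive quadrature on an initial segment plus
  integration between phase zeros with Euler (repeated-averaging)
  acceleration of the alternating series — absolute accuracy ~1e-9.  Tails
  below the inversion's noise floor (p < 1e-10) and any failed inversion
  fall back to four-moment (Liu-type) matching; every p-value is floored at
  1e-30.  The method actually used is recorded per gene.
- No extra MAF-based weights are layered on top of `D`; the adaptive weight
  is entirely the `(DRD)^(-1/2)` factor.

The single-SNP test is the m = 1 specialization referred to chi-square(1)
("MASTOR-style": score numerator `(g'V)^2`, retrospective variance from the
genotype dispersion times `V'AV`); its genotype variance uses the same
ddof = 1 convention so the two code paths agree exactly at m = 1 (tested).
Gene-level SNP-based calls use the within-gene Bonferroni rule
`min_j p_j < alpha / m`.

## QC and partitioning

Samples first, then SNPs.  Samples are dropped for completeness < 96% or
empirical self-kinship > 0.525, i.e. genomic inbreeding >= 0.05, using the
frequency-standardized estimator
`h_i = mean_j [g^2 - (1+2p)g + 2p^2] / (2pq)` (the paper-level source does
not pin down its estimator; this standard one is used).  SNPs are dropped
for call rate < 96% or MAF < 1% computed on retained samples, then recoded
so dosages count the minor allele.  Boundary values are retained on the
completeness/call-rate/MAF side and excluded only strictly above the
self-kinship cut, matching the stated inequalities literally.  Missing
dosages are mean-imputed per SNP within each gene before testing (this
preserves the first moments of `G'V`); duplicate detection is exact
post-imputation column equality, keeping the first column in position
order.  A SNP inside two overlapping genes is tested in both.  Coordinates:
1-based from BIM/VCF sources, 0-based half-open internally and in BED.

Pedigree kinship uses the recursive tabular method (founders 0.5 on the
diagonal; `phi_ij = (phi_fj + phi_mj)/2`, `phi_ii = 0.5 + phi_fm/2`),
validated against Monte Carlo gene dropping in the tests.  Cyclic pedigrees
and single-named-parent records are rejected.

## Reporting

The 2x2 comparison of gene-significance calls uses Pearson's chi-square
with 1 df and no continuity correction (a corrected variant is a switch);
tables with an empty margin are flagged degenerate rather than crashed.
The gene-based side of the comparison uses nominal p < 0.05 — the
analysis-level threshold on that side is a documented assumption.  The
genomic inflation factor is the GWAS-standard
`median(qchisq(1-p, 1)) / 0.4549364`.  QQ/Manhattan data are always written
as TSV so checks operate on numbers, not rendered pixels.

## Synthetic-data generator

The generator reproduces the statistical structure the analysis assumes,
with defaults frozen to the motivating family caries study:

- **Pedigree:** 201 families + 81 unrelated singletons = 652 samples with
  571 family members.  Since 571 < 3 x 201, not every family can be a trio;
  the default mix is 169 trios and 32 childless founder couples, the
  simplest structure in which every named parent is a sampled individual.
  Offspring counts can be overridden per family.  Unrelated singletons are
  unrelated to everyone.
- **Genotypes:** genes are LD blocks.  All SNPs of a gene share one MAF
  drawn from `maf_range` (default (0.01, 0.5]); founder haplotypes come
  from a one-factor thresholded latent Gaussian whose loading is calibrated
  through the equal-threshold bivariate-normal orthant (Owen's T) so the
  *allelic* haplotype correlation equals `ld_block_rho` (default 0.5)
  exactly — an uncalibrated latent correlation would undershoot the target
  on the allele scale.  The shared within-block MAF is what makes a single
  latent parameter able to hit the target for every SNP pair.  Offspring
  inherit one whole-block haplotype per parent per gene: no recombination
  within a gene, free recombination between genes — adequate at gene scale
  and exactly Mendelian.  Dosages count the minor allele.
- **Covariates:** eight covariates with the reference sample's marginals
  (sex 281/371 male/female, age N(25.4, 13.3^2), water source
  492/147/13 expanded to two indicators, brushing-frequency codes 2–5 with
  72.39% above once daily, saliva flow N(0.2, 0.4^2), fluoride
  N(0.7, 0.4^2), education 452/115/85, S. mutans 74.1%).  Continuous
  covariates are plain Gaussians — they can stray outside physical ranges
  (negative flow rates, very low ages); truncating would shift the means
  away from the published marginals and the linear model is indifferent.
  The covariate "sex" is drawn independently of the pedigree's male/female
  transmission roles so its marginal matches the sample's 43% male rather
  than the ~50% forced by founder couples; genotypes are autosomal, so
  pedigree sex carries no genetic information.  No genotype–covariate
  confounding is simulated.
- **Trait:** `Y = Z beta + g + a + e` with `a ~ N(0, sigma_a^2 2Phi)` drawn
  by Cholesky factorization and i.i.d. `e`.  Defaults: total variance
  33.211 split as heritability 0.4437, and the ten fixed effects of the
  reference analysis (age 0.225, S. mutans 2.134, ...).  Optional causal
  genes add a constant per-minor-allele effect to every SNP of a randomly
  chosen gene subset; the truth record keeps the causal genes, per-SNP
  effects, and each variance component's realized contribution so recovery
  can be scored without hidden state.
- **Randomness:** one integer seed feeds per-operation substreams keyed by
  CRC32 of the operation name, so each component is individually
  reproducible and independent of the others.

**What passing tests do and do not show.**  The generator has block-
exchangeable LD with equal within-gene MAFs, no genotyping error, no
missingness (tests inject it), no population stratification, no
ascertainment, and covariates independent of genotype.  Calibration and
recovery results under it therefore demonstrate correctness of the
statistical machinery under the model's own assumptions — not robustness to
stratification, differential missingness, or LD structure unlike the
one-factor block model.  X-linked inheritance is out of scope.

## Simulation studies (experiments module)

Problem sizes were chosen to give tight Monte Carlo error at desk scale:
type-I error pools 25 replicate studies x 200 genes = 5,000 effect-free
gene tests (binomial SE at alpha = 0.05 is ~0.003); heritability recovery
refits 500 trait replicates on one fixed 652-sample pedigree (reusing its
eigendecomposition), with Wald-interval coverage scored on the first 200.

## Known limitations

- ML (not REML) variance components are slightly biased downward with
  p = 10 fixed effects; at n = 652 the effect on heritability is well below
  the recovery tolerance.
- The mixture null treats the fitted `Sigma0` as known; uncertainty in the
  variance components is ignored, as is standard for score-type tests at
  these sample sizes.
- The single-SNP test uses the genotype-dispersion (retrospective) variance
  form; it is "MASTOR-style", not a re-implementation of the MASTOR
  software (e.g. its partially-missing-data machinery is not reproduced).
- `P` is a dense n x n matrix; the implementation targets cohort sizes in
  the hundreds to low thousands, not biobank scale.
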