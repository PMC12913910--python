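# Methods

This note documents the statistical models, the synthetic-cohort generator,
the numerical choices, and the limitations of the `wildgwas` pipeline.

## The analysis problem

A small natural cohort (n ≈ 52 diploid individuals from 3 sites × 3 plots)
is genotyped at a few thousand biallelic ddRAD SNPs and phenotyped for a
single quantitative trait: lamina elongation rate, measured by the
hole-punch method as (hole distance − 5 cm) / elapsed days, in cm/day.
Rates are right-skewed and analysed on the log₁₀ scale, z-scored over the
cohort. At this sample size single-method discoveries are unreliable; the
pipeline therefore classifies loci by how many of three independently
implemented engines flag them, calibrates expectations with a
phenotype-randomization null, and summarizes the aggregate signal with a
polygenic score.

## Genotype representation and filtering

Genotypes are minor-allele dosages: 0 (homozygous major), 0.5
(heterozygote), 1 (homozygous minor), with NaN for missing calls. The
minor allele is the empirically less frequent allele among non-missing
calls; an exact 0.5 tie breaks toward ALT and the orientation is recorded.

The filter cascade runs in a fixed order (the order matters for the
missingness/MAF interplay, so it is logged):

1. drop indels and sites with more than two alleles;
2. mask genotypes with depth < 5× or > 2× the mean depth (mean over all
   unmasked genotype depths before masking) — masking at the genotype
   level rather than dropping sites is the conservative reading of
   per-genotype depth filters;
3. drop sites with > 10% missing calls;
4. drop sites with MAF < 0.03 (so with n = 52, a minor-allele count of 3
   of 104 chromosomes = 0.0288 is removed).

Residual missingness is mean-imputed per locus before any matrix-based
method (relatedness, LFMM, RDA, polygenic score). With n ≈ 52, weak
structure and ≤10% missingness, richer imputation (EM, haplotype-based)
would add model risk for negligible gain.

## Phenotype checks

* Shapiro–Wilk W and p are reported for raw and log₁₀ rates; the log
  transform is a fixed analysis choice, never switched automatically.
* One-way ANOVA of log growth across sites, and across plot-in-site
  labels (nested labels as groups; no mixed model — it would be
  over-parameterized at 3–10 individuals per plot).
* Genomic relatedness is the VanRaden method-1 matrix
  A = WWᵀ / (2Σpₗ(1−pₗ)), W = d − 2p with allele dosage d ∈ [0, 2];
  monomorphic loci are skipped.
* The Mantel test correlates pairwise growth distance |yᵢ − yⱼ| (log
  scale) with genomic distance max(A) − A over off-diagonal pairs;
  significance is two-sided from seeded permutations of individual labels.
  max(A) − A was chosen because it is monotone decreasing in relatedness
  and keeps the sign of r interpretable; 1 − A or Euclidean row distance
  are equally defensible transforms.

## The three association engines

**GWAS.** Vectorized per-locus OLS with complete-case arithmetic when given
an unimputed matrix (imputed input is the pipeline default for consistency
across engines). Tests are two-sided; no kinship adjustment by design —
residual structure is the LFMM's job, and the naive scan doubles as the
inflation reference.

**Multiple testing.** Storey q-values with the cubic-polynomial smoother
for π₀ over λ ∈ {0.05, …, 0.95}, clipped to ≤ 1; Benjamini–Hochberg is the
automatic fallback when m < 100 or the π₀ estimate is non-positive, and can
be selected outright. Working thresholds: FDR < 0.05 (strict) and < 0.10
(relaxed; the GWAS contribution to concordance).

**Ridge LFMM.** Genotypes are the response, the trait the explanatory
variable: min ‖G꜀ − xBᵀ − UVᵀ‖²_F + λ‖B‖²_F with K latent factors.
Default λ = 1e−5 (the conventional ridge-LFMM default; at λ ≪ ‖x‖² the
penalty mostly disambiguates the factor/effect split rather than shrinking
B materially). Two solvers:

* *analytic* (default): shrink the component of G꜀ along x by
  √(λ/(λ+‖x‖²)), truncated rank-K SVD, re-expand, then ridge-solve B.
* *ALS*: alternate exact solves (truncated SVD for (U,V) given B; per-locus
  ridge for B given (U,V)). The objective is asserted non-increasing at
  every iteration. Because ALS converges linearly with rate ≈ ‖x‖²/(‖x‖²+λ)
  — very slowly for small λ — stopping on the per-iteration decrement would
  halt far from the optimum; the solver instead stops on an Aitken
  geometric-tail estimate of the remaining gap (`tol` bounds the estimated
  relative suboptimality, default 1e−8). The two routes agree to < 1e−6 in
  relative objective on random instances.

Per-locus significance: each genotype column is regressed on [x, Û]; the t
statistic of the x coefficient (df = n − K − 2, one df for centering) is
converted to an exact normal z-score via the probability integral
transform — at df ≈ 50 the raw t would inflate median(z²) by ~1.6% and bias
the inflation factor. Calibration divides z² by
GIF = median(z²)/0.4549364 (the χ²₁ median) and takes the upper χ²₁ tail;
with K = 0 and λ → 0 the raw p-values reproduce the GWAS exactly.

**Choosing K.** Horn's parallel analysis: eigenvalues of the standardized
genotype covariance are compared against the 95th percentile of eigenvalues
from 20 column-wise permutations, requiring a 10% margin (marginal
exceedances arise from row-norm variation under missingness and
imputation; genuine planted factors sit 4–10× above the null edge). When
nothing exceeds the threshold the recommendation falls back to K = 1.
K is always overridable in configuration: the appropriate K is the main
reproducibility lever of this method and the chosen value is surfaced in
every report.

**RDA.** With one predictor the fitted matrix P_x G꜀ has rank 1, so the
constrained-axis loadings are computed directly as the normalized vector of
per-locus covariances with x (the full projection + SVD construction is
kept as the test oracle). Loci are centered but not scaled by default
(the convention of the classic constrained-ordination implementation);
scaling is a flag. Candidates are loci whose loading deviates > 2.5 SD
from the mean loading — under pure noise this flags ≈ 2Φ(−2.5) ≈ 1.24% of
loci, which is the built-in false-positive cost of the screen.

## Integration

* **Concordance**: GWAS at q < 0.10, LFMM at q < 0.05, RDA candidates;
  loci classified none/single/double/triple; flagged loci sharing the tag
  part of a `tag:pos` ID are collapsed into one ddRADtag region (SNPs on
  one assembled contig are linked markers, not independent evidence).
* **Randomization null**: log growth permuted across individuals, the
  GWAS + FDR scan rerun per iteration (same FDR method as the observed
  scan — mixing methods is refused), discovery counts at q < 0.05
  collected over (default) 1000 iterations; reported as the fractions of
  iterations with ≤1 and 0 discoveries and with ≥ the observed count.
* **Per-locus R²**: squared Pearson correlation of dosage with log growth
  (equals simple-regression R²).
* **ANCOVA**: per locus, log growth ~ site + dosage + site:dosage with the
  type-II interaction F test; a locus is flagged inestimable when a site
  carries a single genotype class.
* **Polygenic score**: ridge-LFMM refit restricted to the selected loci;
  the per-locus coefficients weight a dosage sum that is z-scaled per
  individual, and the model is judged by the R² (with F-test p) of
  observed scaled growth on the score. Default K = 0 for the refit: with a
  panel of ~5–20 selected loci a latent factor would absorb the very
  signal being scored. A plain ridge regression of growth on the selected
  dosages is available behind a flag; with a single selected locus both
  reduce to that locus's per-locus R².

## Synthetic cohorts

The generator emulates the study conditions end to end and emits
VCF 4.2 (+ FORMAT/DP), a phenotype CSV of raw field measurements
(`id,site,plot,distance_cm,days`), and a ground-truth JSON.

* **Neutral loci**: ancestral MAF ~ U(0.05, 0.5); dosage
  Bin(2, p_il)/2 with logit(p_il) = logit(pₗ) + w·uᵢ·fₗ, u and f standard
  normal — a logistic-scale low-rank perturbation that is valid at any
  weight. The default weight 0.25 encodes weak, PCA-visible-but-small
  structure with K = 1. Loci are rejection-sampled so every emitted locus
  passes the MAF and missingness filters.
* **Missingness**: MCAR per entry at rate 0.05, truncated so no locus
  exceeds the 10% filter ceiling.
* **Depth**: negative-binomial (dispersion 10) around mean 27.5×, clipped
  into the depth-filter window for observed calls; depths for missing
  calls are written below the 5× floor. The emitted VCF therefore
  round-trips the default filter cascade bit-exactly (GT is exact; DP is
  realistic but not bit-guaranteed).
* **Causal architecture**: m causal loci are drawn conditional on a shared
  standard-normal liability h with per-locus correlation ρ calibrated by
  Gauss–Hermite quadrature and root-finding, where
  ρ² = (r²_locus/R²_joint − 1/m)/(1 − 1/m). The genetic score S is the
  standardized, sign-aligned sum of standardized causal dosages, and
  log growth is √R²_joint·S plus noise orthogonalized against the causal
  dosages (and the leading latent factor), so the realized joint R² is
  exact up to range clipping and the marginal per-locus R² matches its
  target in expectation. The mutual correlation is the point: five loci
  can each explain ~25% of variation while jointly explaining ~50%, which
  is infeasible for independent loci. Configurations with
  r²_locus < R²_joint/m or r²_locus > R²_joint are rejected with the
  feasible range in the message; r²_locus = 0 or m = 0 means a global
  null. An optional `latent_pheno_r2` loads the phenotype on the leading
  latent factor to create genuine confounding for stress tests (the
  calibration battery uses w = 1.0 and latent share 0.3, which produces
  naive-scan inflation factors of 4–15 while the matched-K LFMM stays
  near 1).
* **Growth mapping**: the standardized trait maps to
  log₁₀ rate = μ + σz with μ, σ chosen so ±3 SD spans the configured
  0.12–0.46 cm/day range, then clips to that range; distances are
  5 + rate × days (79 days). Sites and plots are assigned round-robin
  with zero site effect.
* IDs follow the `tag:pos` ddRADtag convention, with ~2% of SNPs sharing
  a tag (at least one guaranteed pair) to exercise region collapsing.

What the generator does *not* emulate: read-level errors and genotype
likelihood uncertainty, restriction-site dropout (missingness is MCAR, not
allele-biased), linkage beyond same-tag clustering, selection or
demographic history, site-environment effects on growth, and measurement
error in the hole-punch distances. Passing tests therefore demonstrate the
statistical machinery under the designed architecture, not robustness to
these real-data pathologies.

## Numerical choices and degenerate inputs

* All randomness flows through `numpy.random.default_rng`; the pipeline
  fans a single global seed into per-stage child seeds via
  `SeedSequence([seed, stage_counter])`, so stages rerun independently yet
  reproducibly and full reruns are bit-identical.
* Zero-variance loci: flagged and skipped by the GWAS (NaN statistics);
  refused by RDA scaling; contribute nothing to relatedness.
* Constant phenotype: z-scoring, LFMM, RDA and the randomization null all
  raise explicit errors rather than emitting NaNs.
* p-values are floored at 1e−300 before q-value computation; q-values are
  monotonized by the usual step-up cumulative minimum.
* Exact threshold semantics: MAF < 0.03 removed (0.03 kept), missingness
  > 10% removed (10% kept), |loading z| > 2.5 flagged, q < threshold
  significant.
* The ANCOVA uses type-II sums of squares; for the interaction term in
  this two-factor design it coincides with the sequential test.

## Problem sizes used in validation

The validation battery runs the generator at the study scale (52 × 5000)
where the property under test depends on it (parallel-analysis K choice,
inflation control, permutation-null calibration, planted-architecture
recovery — 20–50 replicates each) and at reduced locus counts (400–1000)
where it does not (realized-R² calibration depends only on the causal
construction; IO round-trips and orchestration are scale-free). The
randomization-null calibration uses 200 permutations per cohort, the
pipeline default being 1000.

## Known limitations

* The q-value arithmetic at n ≈ 52 and m ≈ 5000 makes single-method FDR
  gates severe: a locus explaining 25% of trait variation has p ≈ 1.6e−4,
  which is near — not past — the FDR < 0.10 boundary. Cross-method
  concordance recovers effect loci far more reliably than any single gate,
  and the RDA screen (not FDR-controlled) is the most sensitive of the
  three; this asymmetry is intrinsic to the design, and on default
  synthetic cohorts most concordant discoveries are double, not triple.
* The LFMM K is a genuine researcher degree of freedom; results are
  reported with the K used, and the automatic choice is a recommendation,
  not a guarantee.
* In-sample polygenic R² on loci selected by the same data is optimistic
  (winner's curse); the package reports it as a descriptive summary, as is
  conventional, and the randomization null is the guard against
  over-interpretation.
* The Mantel test has known low power against structured alternatives;
  it is used as a coarse cohort-level check only.
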