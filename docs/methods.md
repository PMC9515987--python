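# Methods

## The mapping problem

Expression QTL mapping in an inbred diversity panel associates each
SNP with each transcript's expression. Strains are fully inbred, so
genotypes are homozygous 0/1 codes and each strain contributes one
phenotype value (a strain mean). The difficulty is relatedness:
recombinant-inbred (RI) strains derived from one founder pair share
half their genome in expectation, while divergent classic inbreds
share much less, so phenotypes are correlated across strains and a
per-SNP ordinary regression grossly overstates evidence.

## Kinship

Kinship between two strains is the proportion of shared alleles over
the SNPs non-missing in both (pairwise-complete). The diagonal is 1 by
definition. This matrix is used as-is (no centering or trace
normalization) as the covariance structure of the mixed model's random
effect; a Gower-centering variant was considered and rejected because
the sharing matrix is itself the method's definition. Pairwise-complete
estimation can make the matrix slightly indefinite, so eigenvalues are
floored at `1e-8` before eigendecomposition. The leave-one-chromosome-
out (LOCO) variant recomputes sharing without the tested SNP's
chromosome, removing the correlation between the fixed-effect SNP and
the random effect.

## The mixed model

`y = Xb + u + e` with `u ~ N(0, σ²_g K)`, `e ~ N(0, σ²_e I)`.
Writing `λ = σ²_g/σ²_e` and `K = U diag(d) U'`, rotation by `U'`
diagonalizes the covariance, so for fixed `λ` the ML estimates of `b`
and `σ²_e` are weighted least squares with weights `1/(λ d_i + 1)`.
The profiled likelihood is maximized over a 50-point log-uniform grid
on `λ ∈ [1e-5, 1e5]` followed by bounded Brent refinement of `log₁₀ λ`
(tolerance 1e-6), with `λ = 0` always a boundary candidate. ML (not
REML) is used throughout because p-values are 1-df likelihood-ratio
statistics against the intercept-only null, with `λ` re-optimized
under the alternative; REML is available for variance-component
sensitivity checks. PVE, the SNP-based heritability estimate, is
`λ̂/(λ̂+1)` (valid because the kinship diagonal is exactly 1).

Missing genotype calls at a tested SNP are mean-imputed by default,
matching the behaviour of standard exact mixed-model association
software; a `drop` policy (remove those strains, refit the null on the
identical subset so the LRT stays nested) is available per test.

Two finite-sample facts shape everything downstream and are verified
by the test suite rather than assumed away:

* **PVE is weakly identified on sharing matrices.** With ~0.5 mean
  off-diagonal sharing and three subpanel blocks, one near-constant
  eigenvector carries most of `K`'s trace and is absorbed by the
  intercept; the remaining spectrum is flat and small, so at 43–92
  strains `λ̂` is noisy, piles up at 0, and the mean PVE is biased
  toward 0 at low-to-moderate heritability. The estimator is unbiased
  (bias < 0.05) on smooth-spectrum relationship matrices, and its
  likelihood agrees with a direct multivariate-normal evaluation to
  1e-10, so this is a property of the design, not of the code.
* **Null inflation comes from `λ` estimation noise.** On structured
  null phenotypes the pooled genomic inflation factor of the mixed
  model sits around 1.3–1.6 (versus ≥ 2 for OLS); fixing `λ` at its
  generative value restores GIF ≈ 1.06. Real mixed-model analyses of
  such panels likewise report median GIFs above 1.

## Synthetic panel generator

The generator reproduces the *structure* of a hybrid rat diversity
panel, not any particular strain set.

* **Genome**: 20 autosomes × 130 Mb × 75 cM with 900 uniformly placed
  SNPs each — 18,000 SNPs at ~7 SNPs/Mb over ~1,500 cM, the dimensions
  of the real array marker set. The cM–bp relation is linear by
  default and configurable. Chromosome count matters: the residual
  false-positive rate of the LOCO model scales with the fraction of
  causal trans-SNPs sharing the tested chromosome, so a 5-chromosome
  toy genome inflates it four-fold relative to a 20-autosome genome.
* **Haplotype pool**: ancestral haplotypes draw per-SNP allele
  frequencies from Uniform(0.1, 0.9) and carry along-chromosome
  persistence — alleles are resampled at rate 0.03/cM moving along the
  map, otherwise copied. Inbred genomes consist of long shared
  segments, so neighbouring array SNPs are strongly correlated;
  i.i.d.-per-SNP pools would make classic-inbred cis windows LD-free,
  an artifact with direct consequences for the Bonferroni calibration
  below.
* **RI subpanels**: each strain chromosome starts from either founder
  with probability 1/2 and accumulates breakpoints as a Poisson
  process at 4 per Morgan (the classical sib-mating RI map expansion),
  alternating founders at each breakpoint.
* **Classic inbreds**: Li–Stephens-style mosaics over the pool
  (switch rate 0.02/cM, pool size 8), carried across chromosome
  boundaries so that a zero switch rate reproduces a single ancestor
  genome-wide.
* **Missingness**: entries are masked independently at rate 0.02
  (the real mechanism is unpublished; uniform masking is the neutral
  choice).

Resulting pairwise kinship on the 92-strain design spans roughly
0.33–0.88 — inside the range reported for real panels — with high
within-RI and lower RI–classic sharing. What the generator does *not*
reproduce: real allele-frequency spectra and ascertainment, substrain
near-duplicates (kinship ≈ 0.9997), local recombination-rate
variation, and any specific real LD pattern. Conclusions that depend
on those features (e.g. exact counts of QC-surviving SNPs) are outside
what passing tests demonstrate.

## Phenotype simulation

SNP effects follow a point-normal law under three architectures:
`no_cis` (every SNP causal with probability 0.10, one shared normal),
`one_cis` (exactly one causal cis-SNP), and `multi_cis` (zero-truncated
Poisson count of causal cis-SNPs with conditional mean 2, truncated at
`q_cis`; rate solved by root-finding). cis-SNPs are SNPs within 1 Mb
of the gene body; trans-SNPs are causal with probability 0.10 in the
cis architectures.

Component scaling is empirical, which makes heritability control
exact: the cis genetic value is centered and scaled to variance
`h² × c` (cis fraction `c ~ Uniform(0.7, 0.9)` per gene), the trans
value is residualized against the cis value and scaled so total
genetic variance is `h²`, and the error is residualized against both
and scaled to `1 − h²`. Realized heritability therefore equals its
target exactly for every gene, at the cost of slightly perturbing
trans effects (the residualization mixes them); the raw normal
variances of the point-normal components are immaterial after this
rescaling. Degenerate draws (zero-variance components, e.g. a
monomorphic causal cis-SNP) are resampled, and gene placement can
require a polymorphic cis-SNP so a cis effect is always simulatable.

Heritability targets come in four modes. `fixed_grid`
({0.05, 0.1, …, 0.9}, cycled) populates every cis-heritability stratum
and is used for the power studies. `pve_like` reproduces the study
anchoring "simulated heritability = estimated PVE of the matching real
trait": latent kinship-structured traits are drawn, their PVE is
estimated with the package's own mixed model, and the *estimates*
become targets. Because of the weak identifiability above, ~3/4 of
those estimates are exactly 0 at 43 strains — the type-I study
inherits this realistic, low-heritability-heavy mix. `uniform` and
`beta` are available for custom designs.

## Scans, QC and evaluation

SNPs enter a scan with minor allele frequency > 0.10 and missingness
< 0.05 among analyzed strains (the 0.1%-MAF reading of the threshold
is available via config but is inconsistent with panel sizes of 43–92).
The map-level filter for improbable recombination removes SNPs whose
adjacent same-chromosome gaps are both ≥ 20 cM (single gap for
terminal SNPs), unioned over RI populations. The subpopulation
meta-analysis requires QC to pass in both groups separately, fits each
group against its own sharing matrix, and combines direction-signed
z-scores without weights (two groups of comparable size).

A SNP call is significant when `p < 0.05/q_cis`, where `q_cis` counts
*all* map SNPs in the gene's cis window, including those QC removed —
the divisor is deliberately not the number of tests actually run,
adding conservativeness. A gene is called when any cis-SNP is
significant; a called gene with any truly nonzero cis effect is a true
positive regardless of which SNP fired (no fine mapping). Type-I error
is measured only on global-null genes (no causal cis-SNP), the one
configuration where cis LD cannot blur the truth labels. Power is
reported overall and within realized cis-heritability strata (default
edges 0, 0.1, 0.25, 0.4, 0.6, 0.8, 1.0). The genomic inflation factor
is `median(χ²)/0.4549` over a result set's p-values; per-gene GIFs are
noisy because cis LD leaves few effectively independent tests, so
cross-gene comparisons pool p-values.

## Study recipes and problem sizes

Three seeded end-to-end studies summarize the methods; all randomness
descends from a master seed via spawned seed sequences, so every run
is bit-reproducible.

* **Null false-positive study (43 strains)**: 1,500 `no_cis` genes
  with `pve_like` targets, of which ~350 are global-null and enter the
  evaluation; all three mixed-model strategies are scanned cis-only.
  Measured rates sit near 0.011 (standard), 0.017 (LOCO) and below
  0.01 (meta). The residual excess over the nominal conservative level
  traces to the χ²₁ approximation of the LRT at n = 43 (the exact-F
  tail is ~25–30% lighter at these thresholds) plus, for LOCO, leakage
  of same-chromosome trans effects into the cis window.
* **Power study (43 strains)**: 450 `one_cis` genes on the grid;
  power within the cis-h² > 0.4 stratum (~200 genes) is ~0.82 for both
  the standard and LOCO mixed models; overall one-cis power is ~0.62
  (standard/LOCO) versus ~0.28 for the meta-analysis — the meta-method
  is distinctly underpowered, mainly through its stricter two-group QC.
* **Power study (92 strains)**: 300 `one_cis` genes on the
  subpopulation design (33 + 30 RI, 29 classic); LOCO power above
  cis-h² 0.25 is ~0.96, and each subpanel alone is substantially less
  powerful than the pooled panel, the RI subpanels most of all (their
  high internal relatedness shrinks the effective sample size).

These sizes put each study at a few minutes on one core while keeping
binomial standard errors on the reported rates below ~0.01.

## Trait characterization

Broad-sense heritability of replicated expression values is the
one-way ANOVA R² with strain as the factor; its null distribution
comes from permuting strain labels. Modality of strain-level
expression is selected among k = 1, 2, 3 equal-variance normal
mixtures by minimal BIC (`−2ℓ + 2k log n`; the k = 1 fit is the
closed-form MLE). The EM uses a quantile-split initialization with 10
random restarts, tolerance 1e-8, at most 500 iterations; runs that
empty a component are discarded, and a k whose restarts all fail is
excluded with a warning. The association between modality class and
PVE is assessed with a one-way ANOVA plus Welch pairwise contrasts.

## Numerical conventions

P-values are floored at 1e-300; LRT statistics are clamped at 0 (so a
tied fit gives p = 1); zero p-values entering the GIF are floored at
the smallest positive float with a warning. Eigenvalue floor 1e-8
throughout. File formats are plain TSV with `NA` for missing, 1-based
inclusive bp coordinates, and `%.17g` floats so write/read round-trips
are bit-exact.

## Known limitations

* PVE point estimates on sharing-matrix kinship at panel scale are
  noisy and biased toward 0 (see above); rank comparisons across genes
  remain meaningful, absolute values should be interpreted with care.
* The mixed model's null calibration inherits `λ̂` noise; gene-level
  error control relies on the cis-Bonferroni margin, not on perfectly
  calibrated per-SNP p-values.
* Trans-eQTL detection is out of scope (trans effects are simulated as
  individually undetectable background), as are fine mapping,
  FDR-based multiplicity, and replicate-level simulation of the eQTL
  scan itself.
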