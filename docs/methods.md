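# Methods

## Data model

Populations are inbred and effectively haploid: a genotype column takes
values 0 (major-allele homozygote), 1 (minor-allele homozygote) or missing.
Genotype frequencies therefore equal allele frequencies and all LD
arithmetic treats columns as haplotypes. Positions are 1-based bp (as in
VCF); marker maps are kept sorted by (chromosome label, position).
Heterozygous VCF calls — residual in inbred material — default to no-calls
(`het_policy="missing"`), preserving sample size; `drop_marker` and `error`
are available. MAF filters are strict ("MAF > t"): a marker exactly at the
threshold is dropped.

## Second-order LD

For predictors M₁, M₂ and target Q, the four one-vs-rest pseudomarkers
P₁={AB}, P₂={Ab}, P₃={aB}, P₄={ab} (A, B the major alleles) partition the
triplet-complete individuals. The second-order LD is the maximum defined
pseudomarker-to-target r². Numerical choices:

* **Exact integer arithmetic.** Every r² is evaluated as
  (n·n₁₁ − n₁·n₂)² / (n₁(n−n₁)n₂(n−n₂)) from integer 2×2 counts, so scalar,
  matrix and batch kernels agree bitwise with a brute-force contingency
  computation. Counts accumulated through float32 matmuls are exact integers
  for n < 2²⁴.
* **Monomorphic pseudomarkers are excluded from the max**, not scored 0: r²
  is undefined for a monomorphic locus, and exclusion never changes a
  defined maximum. If all four are monomorphic (or the target is), the
  statistic is undefined (nan), never an exception.
* **Ties break to the lowest pseudomarker index** for deterministic
  regression tests.
* **Missing data**: pairwise-complete individuals for r², triplet-complete
  for second-order LD. The vectorized kernels require complete data; a
  scalar path handles panels with no-calls.

The 0.3 retention threshold is applied by the scan layer (`keep_r2`), not
inside the kernel, keeping the statistic pure.

## Triplet scans, classification, extrapolation

A predictor is *cis* to a target iff same chromosome and |Δpos| ≤ 1 Mb
(inclusive boundary; the window is configurable). Classes: cis-cis /
cis-trans / trans-trans by the number of cis predictors (2/1/0).

`scan_triplets` first drops targets already tagged by a single predictor
(max individual r² ≥ 0.6 by default), then evaluates every unordered
predictor pair against each remaining target in blocks, materializing only
records above `keep_r2` (default 0.3) and flagging records above
`strong_r2` (default 0.6). Per-class denominators count evaluated
(pair, target) *triplets*; the total pair count C(P,2) and target counts
are also reported so per-pair rates can be recovered. The exhaustive scan is
meant for window-sized panels; for genome-scale panels
`sample_triplet_proportions` estimates the same per-class proportions by
seeded uniform Monte Carlo sampling of triplets (unbiased; the standard
error is governed by the per-class sample count).

`count_possible_pairs` computes per-class genome totals per target with
c cis predictors of P: C(c,2), c(P−c), C(P−c,2) — summed in Python integers
(genome-scale totals overflow int64). `extrapolate_genome` multiplies the
**pooled** proportion (Σ observed / Σ evaluated across windows) by the
genome total; the estimation error is the sample SD (ddof = 1) of the
per-window genome estimates, nan when only one window contributes and the
whole estimate is undefined for a class never evaluated. Pooling (rather
than averaging window proportions) weights windows by the evidence they
carry.

## Two-locus model and scans

Model: y = μ + a₁β₁ + a₂β₂ + a₁a₂β₁₂ + e with a = +1 for the major
homozygote and −1 for the minor (the a₁a₂ code is +1 for AABB/aabb, −1 for
AAbb/aaBB). Single fits go through statsmodels OLS; the exhaustive pair scan
solves the same normal equations from precomputed cross-product matrices
(A'A, A'y, (A∘y)'A), in batches, which is algebraically identical (verified
to ~1e-15 in the tests). p-values are two-sided t with n − 4 df. A pair with
an empty two-locus class has a collinear interaction code; such fits carry
an `aliased` flag with undefined SE/p rather than being silently dropped.
Bonferroni thresholds default to all C(m,2) pairs; an explicit effective
test count can be supplied for LD-block-based corrections (estimating that
block count is out of scope).

**Kinship.** Genomic kinship is the cross-product of column-standardized
genotypes divided by the marker count, with per-column mean imputation of
missing entries for this computation only; it is symmetric PSD by
construction and duplicated individuals share their diagonal entry.

**Mixed-model refit.** Pairs passing the scan threshold are refitted with a
random polygenic effect u, cov(u) = σ²g·K. Rotating by the eigenvectors of
K leaves independent observations with variances σ²e(λdᵢ + 1),
λ = σ²g/σ²e. REML profiles over λ by bounded scalar minimization on
log λ ∈ [−12, 12] (tolerance 1e-8), with λ = 0 evaluated explicitly so the
no-structure boundary is exact (then the refit reproduces OLS to machine
precision). Wald t-tests (n − 4 df) on the GLS estimates; Wald rather than
likelihood-ratio because it is the common default of this software family.
K must be symmetric PSD up to a 1e-6 relative tolerance (negative
eigenvalues beyond that are rejected, smaller ones clipped to zero).

## Synthetic data: what it emulates, what it does not

All generators are deterministic given their seed.

* **`sample_population`** draws whole haplotypes i.i.d. — inbred accessions
  carry one haplotype and no heterozygosity.
* **`make_fig1_scenario`** builds the minimal phantom-epistasis case: equal
  two-locus classes AB/Ab/aB/ab and a hidden locus Q carried exactly by ab.
  At equal class sizes r²(M₁,Q) = r²(M₂,Q) = 1/3 while pseudomarker P₄ tags
  Q perfectly, and the zero-noise OLS fit gives β₁ = β₂ = −0.25,
  β₁₂ = +0.25 exactly — the package's central, literally assertable
  property: a fitted interaction with no interaction in the truth.
* **`simulate_mosaic_genome`** produces a background genome: founder
  haplotypes (default 20) with per-site allele frequencies from a U-shaped
  Beta(0.5, 0.5) spectrum, each individual an independent recombination
  mosaic per chromosome with crossover counts Poisson in distance (default
  10⁻⁶ per bp, so LD decays on the ~1 Mb scale over which the cis window is
  defined; defaults 5 chromosomes × 30 Mb echo a small plant genome).
  Within-chromosome LD decays from the founder-drift level (~1/K) to the
  finite-sample level (~1/n); chromosomes are mutually independent, so
  cross-chromosome associations arise from sampling drift alone — the small-n
  mechanism under study. The generator does **not** reproduce real
  population structure (shared ancestry across chromosomes), selection,
  migration, or a realistic site-frequency spectrum, so passing tests speak
  to the drift mechanism, not to any particular species' LD landscape.
* **`make_complex_locus_scenario`** encodes a hidden linkage block of four
  effect loci (three trait-increasing, one decreasing; effects ±1, noise SD
  0.5 — magnitudes chosen for clear but noisy group separation) in
  incomplete mutual LD, arranged so the four genotype classes of one
  cis + one trans predictor order low / intermediate / intermediate / high
  in expected phenotype, with the extreme classes separated only by the
  *pair*. The hidden-locus haplotype frequencies reproduce this ordering
  structure, not any measured frequencies. The panel adds (default 100)
  neutral background markers independent of the block; causal loci are never
  in the panel.
* **`simulate_phenotype`** adds per-minor-allele effects (trait units) and
  Gaussian noise; `true_epistasis` mode adds an interaction effect on the
  ±1 product code of the first two causal loci, so the two-locus fit
  recovers it as β₁₂ directly.

## Problem sizes

The test suite and `scripts/acceptance.py` run the sample-size experiment on
mosaic genomes of ~7,000 markers (≈2,000 predictors / ≈5,000 targets after
MAF > 0.05) and 500 individuals, with per-class strong-triplet proportions
estimated from 400,000 sampled triplets per genome at n = 50 and 100,000 at
n = 500 (pooled over 10 genomes in the tests, 5 in the script) — enough to
resolve proportions of order 10⁻⁵ while keeping the runs at minutes on one
CPU. The three-window extrapolation demonstration uses a 3,000-marker
genome at n = 100 with 4 Mb window pairs.

## Known limitations

* Diploid outbred genotypes, phasing, imputation, multi-allelic records and
  structural variants are out of scope; VCF records that are not bi-allelic
  SNPs are skipped (and counted).
* Third-or-higher-order predictor sets and LD measures other than r² are not
  implemented.
* The exhaustive triplet scan materializes per-target P×P work and is meant
  for window panels, not whole genomes; use the Monte Carlo estimator there.
* The integer r² identity relies on int64 headroom and is valid for
  n ≲ 50,000 individuals — far beyond the intended panel sizes.
* The mixed model fits a single variance ratio; multiple variance components
  or permutation-based thresholds are not supported.
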