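# Methods

This note documents the statistical models, the numerical choices, and the
synthetic-data generator behind `coabnet`, in enough detail to reproduce or
critique every stage.

## Count model

Spectral counts are treated as draws from the Poisson–Tweedie (PT) family in
its moment parametrization: mean μ > 0, dispersion φ = Var/E ≥ 1, and shape
index *a*.  The package implements the family through its three named special
cases, which span the dispersion behaviours the pipeline must handle:

| a   | distribution              | sampler                                   |
|-----|---------------------------|-------------------------------------------|
| 1   | Poisson                   | direct (requires φ = 1)                   |
| 0   | negative binomial         | gamma–Poisson mixture, Λ ~ Gamma(μ/(φ−1), φ−1) |
| 0.5 | Poisson–inverse-Gaussian  | IG–Poisson mixture, Λ ~ IG(μ, μ²/(φ−1))   |

Both mixtures give E[X] = μ and Var[X] = φμ exactly; φ = 1 degenerates to
Poisson for every shape.  Underdispersion (φ < 1) is rejected, as is the
inconsistent combination a = 1 with φ > 1.  A full continuous-*a* PT sampler
is deliberately out of scope: the downstream test depends only on
mean–variance handling, not on fine shape resolution.

## Quantification

Two tracks are kept separate because they serve different consumers:

**Protein track (NSAF).**  NSAF_ij = (SpC_ij/L_i) / Σ_k (SpC_kj/L_k), the
length-normalized spectral abundance factor; each nonzero sample column sums
to 1.  Values are log2-transformed, and zeros — interpreted as
below-detection-limit missingness rather than true absence — are imputed per
sample from a downshifted Gaussian with mean m − 1.8·s and SD 0.3·s, where
(m, s) are that sample's observed log2 moments.  The (1.8, 0.3) defaults are
the convention established by mainstream proteomics software for mimicking
the left tail of intensity distributions; a sample with fewer than 3 observed
values cannot provide the moments and is rejected.  No pseudocount is used:
zeros are imputed, not offset.  This track feeds clustering/heatmaps.

**Taxon track (counts).**  Raw counts are summed per taxon at each protein's
lowest confidently-assigned rank; a protein known only to genus level
aggregates into a genus-level taxon that remains distinct from any
species-level taxon of that genus.  Taxa without ≥ 5 counts in ≥ 2 samples
are removed — equivalently, a taxon with fewer than five counts in all
samples but one is dropped, the reading under which one aberrant sample
cannot rescue a taxon.  This track feeds testing and networks.

**TMM normalization.**  Between-sample factors follow the trimmed mean of
M-values algorithm with its published defaults: reference = sample whose
75th-percentile count fraction is closest to the mean; per sample, log-ratios
M_g and log-averages A_g over taxa positive in both sample and reference;
double trimming (30% of each M tail, 5% of each A tail); inverse
delta-method-variance weighted mean of the surviving M_g.  The implementation
is verified against edgeR's `calcNormFactors` to 1e-8 in the test suite.
Two factor sets are returned:

* `tmm` — the pure composition correction (geometric mean 1; a sample that
  is an exact scalar multiple of another gets 1);
* `factors` — effective per-sample scale, library size × tmm, rescaled to
  geometric mean 1.  Dividing counts by `factors` puts samples on a common
  scale; all downstream testing and network inference uses counts rescaled
  this way (the normalized counts are rescaled directly rather than passed
  as model offsets).

## Differential abundance

Per taxon and per pair of phenotype groups, the test statistic is the
moment-based z on rescaled group means with PT variance plug-ins,
z = (μ̂_A − μ̂_B)/√(φ̂_A μ̂_A/n_A + φ̂_B μ̂_B/n_B), where φ̂μ̂ is the ddof=1
sample variance of the rescaled counts (the PT moment identity).  Degenerate
cases: all-zero in both groups → (z, p) = (0, 1); a zero-variance group
contributes a floor of one count to its variance term.

**Small-sample calibration.**  With n = 4 per group the plug-in variances
are noisy and the asymptotic standard-normal tail is anti-conservative
(empirical size ≈ 0.08 at nominal 0.05 in negative-binomial null
simulations).  The p-value therefore uses a Student-t reference with
n_A + n_B − 2 degrees of freedom, which converges to the normal tail as n
grows.  Null simulations (2000 replicates, n = 4 vs 4) put the empirical
size at 0.040–0.055 for negative-binomial counts (μ = 20, φ = 3) and
0.043–0.056 for Poisson counts across seeds — both at the nominal level.
This calibration is exercised by the test suite and the acceptance script.

All six pairwise comparisons of the four phenotypes are tested;
Benjamini–Hochberg correction is applied within each comparison separately
(six families), and a taxon is differentially abundant if q < 0.05 in at
least one comparison.  The union of such taxa is the network node set.
Reported log2 fold changes are log2((μ̂_A + 0.5)/(μ̂_B + 0.5)); the
0.5-count pseudocount only guards all-zero groups.

The per-group PT fit also estimates the shape *a* by a likelihood grid over
{Poisson, NB, PIG} on rounded rescaled counts (PIG log-pmf by numerical
integration of the IG–Poisson mixture; ties go to NB; a = 1 only when φ
clamps to 1).  The two-sample test itself depends only on (μ, φ), so the
grid is skipped inside the testing loop.

Auxiliary procedures: one-sided hypergeometric (Fisher) enrichment of
annotation terms in the DA set, flagged at raw p < 0.01 without multiplicity
correction and with empty-background terms skipped; Welch two-sample t-tests
of hub abundances per comparison; agglomerative clustering of z-scaled
profiles (Euclidean distance, complete linkage, items processed in sorted
label order so ties break deterministically; constant rows are dropped with
a warning).

## Co-abundance network

Inference runs on log2(rescaled counts + 1) of the union-DA taxa.

**MI estimator.**  Each profile is discretized into ⌈√n⌉ equal-frequency
bins (4 bins at the study's n = 16); mutual information is the plug-in
estimate with Miller–Madow bias correction, in bits, clamped at 0.  The
correction removes the discretization bias only when the joint histogram is
well sampled (n ≫ bins²); this holds in the pipeline's regime, and any
residual bias cancels in the permutation-null significance step below.
Constant profiles get MI = 0 with a warning.

**C3NET.**  Pair significance is assessed against a pooled permutation null
(random profile pairs with one profile permuted; 1000 draws by default);
per-pair empirical p-values are BH-corrected and pairs with q < 0.05 are
significant.  Each node then contributes the edge to its maximum-MI
significant partner (ties to the smaller label); the network is the
deduplicated union, so |E| ≤ |V|.  The implementation is tested against
exhaustive brute-force application of the rule on random instances.

**BC3NET.**  B = 100 bootstrap resamples of the sample columns; C3NET on
each; an edge's support count is tested against Binomial(B, p0) with
p0 = 1/#pairs (the expected null edge rate), BH-corrected at 0.05; surviving
edges carry their support fraction as weight.  The whole procedure is
deterministic under a seed, and with bootstrapping disabled and B = 1 it
reduces exactly to C3NET.

**MST2.**  Edge distance is d = w_max − w (bounded, unlike 1/w, as w → 0).
Per connected component, MST1 is the minimum spanning tree under d and the
second tree is the minimum spanning forest after removing MST1's edges;
MST2 is their union, so each component contributes at most 2(n_c − 1) edges.
Kruskal tie-breaks are lexicographic on the sorted node pair, making the
reduction deterministic.

**Topology and hubs.**  Mean degree is 2|E|/|V| over the giant component
(largest component; ties broken by smallest node label); betweenness is
unnormalized shortest-path betweenness with unweighted paths and endpoints
excluded, averaged over giant-component nodes; nodes outside the giant
component are reported as unconnected.  The hub threshold is the
linear-interpolation percentile (default 95th) of the degree sequence over
all nodes including isolated ones — hence possibly non-integer — and hubs
are nodes with degree strictly above it, so an all-equal degree sequence
yields no hubs.

## Synthetic generator

The generator emulates a 4-group (CKD, CKDRS, HRS, H), n = 4-per-group
cecal metaproteome:

* **Layout.**  60 taxa by default, each with 1–20 proteins of 80–1500
  residues; per-protein baseline mean spectral count log-uniform in [1, 30];
  per-protein dispersion uniform in [1, 10] (the empirical dispersion range
  of real spectral counts is not well established; this range covers
  near-Poisson through strongly overdispersed behaviour); NB counts by
  default.
* **Planted effects.**  A quarter of taxa receive a signed log2 fold change
  uniform in [2, 5] in one randomly chosen group, applied multiplicatively
  to all of the taxon's proteins.  Effects of this magnitude are
  disease-scale: gut-microbiome shifts between severe-disease and healthy
  phenotypes are frequently order-of-magnitude to presence/absence.  Under
  the default conditions the pipeline detects roughly a quarter of taxa as
  DA at FDR < 0.05 — the same fraction the motivating study design reports
  — so the defaults constitute a realistic end-to-end exercise of every
  stage including the network.
* **Biological variability and modules.**  Every taxon's per-sample mean is
  multiplied by a mean-preserving log-normal factor exp(σ·ε − σ²/2) with
  σ = 0.35 (between-animal CV ≈ 36%).  For taxa inside a co-abundance
  module, ε = ρ·z_module + √(1−ρ²)·z_private with ρ = 0.9, so module
  membership controls the *correlation* of the biological wobble without
  changing its marginal scale; non-members get independent ε.  Module
  members are drawn preferentially from the planted-DA taxa so modules
  survive the DA filter that feeds the network stage.
* **Taxonomic ambiguity and missingness.**  10% of proteins are assigned
  only at genus (2/3) or family (1/3) rank; cells are zeroed independently
  at rate 2% with below-median-abundance proteins twice as likely to drop
  out (a light approximation of detection-limit missingness, matching what
  the downshifted-Gaussian imputation presumes).

What the generator does **not** emulate: peptide-level identification and
its FDR, shared peptides between proteins, protein-inference ambiguity,
compositionality constraints of the instrument's sampling depth, or
phylogenetic correlation between taxa.  Passing recovery tests therefore
demonstrates that the inference chain is correct under its own model
assumptions, not that those assumptions hold for any particular real
dataset.

## Problem sizes and determinism

Recovery experiments use the sizes at which they are run in the test suite
and acceptance script: 2000 null replicates for calibration; 20 replicate
simulations for planted-effect power (50 taxa, 10 planted, μ = 50, φ = 2,
log2FC = 2) and for module recovery (30 taxa, 3 modules of 5, ρ = 0.9,
B = 100).  All randomness flows from `numpy.random.default_rng` seeds; the
pipeline fans one global seed out to per-stage seeds by a fixed counter
scheme, and identical configuration + seed reproduces every TSV artifact
byte for byte (verified by manifest SHA-256 digests in the test suite).

## Known limitations

* The moment-based test does not share dispersion information across taxa;
  with n = 4 per group its power against modest (< 4-fold) effects is
  limited, which is a property of the design, not the implementation.
* MI at n = 16 with 4 bins is coarse; the permutation-null filter keeps the
  false-edge rate controlled, but weak dependencies are undetectable.
* BC3NET's binomial ensemble test with p0 = 1/#pairs is permissive on small
  node sets, so small networks can be dense and may contain no strict-
  percentile hubs.
* Genus/family-level aggregation treats rank-truncated proteins as separate
  taxa rather than distributing them over candidate species; planted-truth
  bookkeeping is exact only for species-level taxa.
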