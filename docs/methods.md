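# Methods

`conjfdr` implements a cross-trait pleiotropy screen for GWAS summary
statistics: two traits' per-variant p-values are combined through
conditional and conjunctional false discovery rates to nominate loci
associated with both traits, with LD-aware control of genomic inflation and
of the correlation structure that distorts empirical p-value distributions.
A gene-level SKAT burden test complements the screen on genotype-level
case-control data.  This note records the model, the defaults and why they
are what they are, the numerical choices, and the limitations a user should
know about.

## Harmonization

The two input tables are joined on (chromosome, position) in GRCh37
coordinates, 1-based inclusive; variant ids are carried along but never used
as a join key, because id dialects differ across GWAS releases.  Where the
second trait reports the effect/other alleles in the reverse orientation,
its z-score is sign-flipped.  Strand-ambiguous variants (A/T and C/G) are
dropped: without strand information their orientation between two studies
cannot be resolved, and the safe default for a meta-style merge is removal.
Duplicate positions keep the record with the smaller primary p-value.
p-values are stored as given; internal computations work in −log10 space
with p floored at 1e-300 to avoid underflow.

Two extended-LD regions are excluded from every statistical analysis by
default — chr6:25,119,106–33,854,733 (HLA) and chr17:40,000,000–47,000,000
(MAPT), 1-based inclusive — because their long-range LD would let a single
association signal dominate the empirical distributions that all FDR
estimates are built from.

## Random-pruning weights

LD makes dense summary statistics over-count each association signal.  The
de-correlation device used throughout is random pruning: in one iteration,
variants are visited in a random order and a variant is retained iff no
already-retained variant has r² above the threshold with it (a greedy
maximal independent set, matching PLINK-style pruning semantics; one
retained SNP per LD clump).  Averaging the retention indicator over
iterations gives a per-SNP weight in [0, 1] that multiplies the SNP's
contribution to every empirical distribution.  Defaults: r² threshold 0.1,
100 iterations, r² estimated within a ±20 Mb window.  A SNP with no
neighbor above the threshold has weight exactly 1; a fully linked clump of
size k gives each member expected weight 1/k, and clump weights sum to 1.

Each iteration draws its visit order from an RNG stream keyed by
(seed, iteration), so iterations are order-independent and the whole
computation is reproducible bit for bit.  Pairs with r² < 0.05 are not
stored (the storage floor must stay at or below any threshold used).  A
note on a tempting but false monotonicity: raising the r² threshold does
not necessarily raise every SNP's expected weight — removing an edge
elsewhere in a chain can make a neighbor compete more often.  It does hold
when the change disconnects a SNP or dissolves a clique, which is what the
tests assert.

## Genomic inflation control

The inflation factor is λ = (weighted median of the observed χ²₁
quantiles) / 0.4549364, where the constant is the χ²₁ median (hardcoded to
full precision so the computation is bit-reproducible) and the weights are
the pruning weights, so that each LD clump contributes to the median
roughly once.  The weighted median is the value at cumulative weight
fraction 0.5.  When λ > 1, every statistic is divided by λ and p-values are
recomputed from the χ²₁ upper tail; λ < 1 is reported but never applied —
the correction may only be conservative.  Correction preserves p-value
ranks, and re-estimating λ on corrected statistics returns exactly 1
(the weighted median is one of the data values, so the fixed point is
exact).  λ is estimated on all non-excluded SNPs.

A single 10,000-SNP estimate has Monte-Carlo standard deviation ≈ 0.04
under the default block-LD simulation, so recovery checks average λ̂ over
12 replicates.

## Conditional Q-Q curves and the deflection statistic

Conditional Q-Q curves plot observed −log10 p quantiles of the primary
trait within strata of conditional-trait significance (all SNPs, p2 < 0.1,
< 0.01, < 0.001 by default) against uniform expectations.  Weighted Hazen
plotting positions (cumw − w/2)/W are used.  Strata with total weight below
50 are omitted — with default weights that is roughly ten LD-independent
SNPs, below which a quantile curve is noise.

Enrichment is summarized by a deflection statistic: the weighted mean of
observed −log10 p minus its null expectation log10 e ≈ 0.4343.  Under the
null −log10 p is exponential with mean and standard deviation log10 e, so
the 95% null band for the deflection is ±1.96·log10 e/√n_eff, with n_eff
taken as the stratum's total pruning weight.  Total weight — not Kish's
(Σw)²/Σw², which ignores correlation between distinct retained SNPs — is
the right effective count here and is, if anything, slightly conservative
(measured null coverage ≈ 100% at nominal 95%).

## Conditional and conjunctional FDR

The conditional FDR uses the conservative empirical-Bayes construction
with the null proportion fixed at 1:

    cFDR(p1 | p2 ≤ c) = min(1, p1 / F̂(p1 | p2 ≤ c)),

with F̂ the weighted empirical cdf (ties counted by ≤) of primary p-values
in the conditioning stratum.  The conjunctional FDR is the maximum of the
two conditional FDRs with trait roles swapped, evaluated for each SNP at
its own (p1, p2); it upper-bounds the FDR for joint association.

Values are tabulated on a grid — 200 log-spaced p1 nodes spanning
[1e-12, 1] augmented with the observed p1 values, and 40 log-spaced
conditioning cuts spanning [1e-8, 1] (augmented with the observed p2 values
when there are at most 256 distinct ones) — and queried by bilinear
interpolation of log10 cFDR in (log10 p1, log10 p2), clamped at the grid
boundary.  Because log cFDR is linear in log p1 wherever F̂ is constant,
interpolation is exact at data points.

Monotonization happens in two passes.  Along p1, the per-data-point
estimates are made non-decreasing by a running maximum anchored at the
stratum's data points (the conservative direction: a dip below an earlier
estimate is raised, never the reverse), and each grid node takes the value
of the first data point at or above it; anchoring at data points keeps node
values at the data exactly equal to direct counting whenever the raw
sequence is already monotone, which a node-level running max on a dense
grid would destroy.  Below the smallest data point the estimate is
extrapolated linearly through the first ecdf jump; at p1 = 1 the value is
1.  Across cuts, a running minimum toward stricter conditioning enforces
that tightening the conditioning never raises the estimate.  Empty strata
columns are filled from the nearest populated (looser) cut.  A q-value
style right-to-left running minimum was evaluated as the alternative
p1-monotonization and measured statistically indistinguishable on null
calibration; the conservative direction was kept.

Calibration behaves as the construction predicts.  With the primary trait
fully null, per-SNP false-flag rates at conjFDR < 0.05 are of order 1e-5,
but the genome-wide probability that *some* SNP is flagged in a 10k-SNP
scan is ≈ 0.14 when the full pipeline (inflation control before FDR) is
run — the nested conditioning strata act like a union of stratum-level BH
procedures, so the all-or-nothing realized FDP under a complete null
exceeds the nominal per-SNP level.  This is a property of the standard
conservative cFDR construction, not of this implementation; the acceptance
test measures it on the full pipeline path.

No correction for sample overlap between the two GWAS is implemented (by
design); when the two studies share controls, conjFDR values are
optimistic, and the pipeline surfaces this only as documentation, not as a
statistical adjustment.

## Locus definition and gene annotation

Among SNPs below the conjFDR threshold (0.05), the smallest-conjFDR SNP
seeds a locus (ties broken by smaller p1, then position, so output is
independent of input order); every significant SNP with r² > 0.1 with the
lead joins and is removed, and the process repeats.  Reported members are
those with r² > 0.6 with the lead — the display threshold governs reporting
only, while 0.1 (the pruning threshold) governs locus independence.  Genes
are attached when their interval intersects the lead ± 100 kb (inclusive at
the boundary); the closest gene (distance 0 if the lead is inside) sets the
relation, classified at gene-interval level as inside / upstream /
downstream with upstream meaning the 5′ side of the closest gene's strand.
Exon/intron resolution would require transcript models and is out of scope.

## SKAT

For a gene with dosage matrix G (n samples × m variants), binary phenotype
y, covariates X (intercept always included) and variant weights
W = diag(w_v), the statistic is Q = (y−μ̂)ᵀ G W² Gᵀ (y−μ̂) with μ̂ from the
null logistic fit.  Its null law is Σ ξ_k χ²₁ with ξ_k the nonzero
eigenvalues of W Gᵀ P₀ G W, P₀ = V − V X (XᵀVX)⁻¹ XᵀV, V = diag(μ̂(1−μ̂)).
The tail probability is computed by numerical inversion of the
characteristic function (Imhof's integral): the integrand's envelope decays
like u^(−1−m/2), so the integral is truncated where the analytic tail bound
drops below tolerance, and the quadrature error plus truncation bound must
stay below 1e-4 or the moment-matched noncentral-χ² approximation
(Liu–Tang–Zhang) is used instead.  With a single eigenvalue the mixture is
a scaled χ²₁ and the exact tail is returned, which also realizes the
classical reduction of single-variant SKAT to the score test.

Defaults: weights w_v = Beta(1, 25) density at the minor allele frequency
(the canonical choice that up-weights rare variants), with a flat-weights
option; missing dosages mean-imputed per variant; monomorphic variants
dropped (zero information) but no MAF threshold otherwise; large-sample
null (no small-sample moment correction), with a permutation p-value
available for verification.  Note that when simulated effects are
MAF-independent — as in this package's generator — flat weights are the
matched analysis and have materially higher power than the rare-variant
weighting; the test suite's power check uses flat weights for that reason,
while type-I error and the permutation cross-check run under the default.
Bonferroni correction is min(1, p × n_genes).

## Synthetic data generator

The generator defines the study conditions under which everything above is
validated.  Each SNP is null, trait-1-causal, trait-2-causal, or shared,
with fractions (pi1, pi2, pi12) = (0.01, 0.01, 0.01) by default; shared
effects are bivariate normal with correlation 0.5.  LD is
blockwise-exchangeable: 10,000 SNPs in 2,000 blocks (sizes random around
5), one within-block r² = 0.5.  Exchangeable blocks keep the relation
between pruning weights and block size analytically checkable (expected
weight ≈ 1/size for a fully linked block) at the cost of realism — no LD
decay with distance, no inter-block LD.  Marginal z-scores per block are
z = √N·(Rβ) + ε with ε ~ MVN(0, R) and R exchangeable with off-diagonal
√(block_r2), since test-statistic correlation equals dosage correlation r,
not r².  Sample sizes default to N1 = N2 = 20,000 and effect variances to
1.25e-3 per causal SNP, so a causal variant carries |z| of typical size
√(Nσ²) = 5 — detectable but not trivial, the regime in which conditional
enrichment is visible in the Q-Q strata.  An inflation factor λ can be
injected by scaling z by √λ, making the null mean χ² equal λ so the
genomic-control module can be validated end to end.  Two-sided p-values
come from the normal tail; an effect-size column is emitted as z/√N for
schema completeness.  Everything is seeded; identical seeds give
byte-identical files.

The genotype-panel emitter uses a copy/fresh binomial construction (a
sample's dosage copies a block-shared draw with probability block_r2^(1/4))
whose pairwise dosage correlation is √block_r2 in expectation, so the
empirical r² converges to block_r2 as the panel grows.

What passing these tests does not show: robustness to real LD decay,
allele-frequency-dependent architectures, sample overlap between traits,
population stratification beyond a scalar inflation factor, or the
behavior of the FDR estimates at genome scale (8M variants).  The worked
10-SNP fixture and the brute-force oracles verify the arithmetic of the
estimators, and the simulations verify their statistical behavior under
the stated generative model only.

## Problem sizes

The test suite and the reproduction script run everything at desk scale on
one CPU: 10,000-SNP simulated genomes; 100 replicates (60 in the script)
for null calibration; 50 seeds (30 in the script) for the enrichment
pattern; 12 replicates for λ recovery; 10,000 pruning iterations for the
weight expectations; 500 replicates (300 in the script) of n = 200 SKAT
null fixtures and 20,000 phenotype permutations for the SKAT oracle.
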