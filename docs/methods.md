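# Methods

`sweepstack` implements four complementary within-population selection
scans for dense diploid SNP-array data, the quality-control chain that
precedes them, a multi-method consensus step, QTL-class enrichment, and a
Wright–Fisher simulator that generates the synthetic datasets used to
validate the whole stack. This note documents the models, the parameter
choices, and the numerical decisions, and states what the simulation-based
checks do and do not demonstrate about real data.

## Data model and quality control

Genotypes are held as allele-b dosages in {0, 1, 2, missing}; phased data
additionally as binary haplotypes with 1 = derived where polarity is known
(VCF `AA` tag, or the simulator's truth). Coordinates are 1-based
inclusive bp; BED export converts to 0-based half-open.

QC applies four filters in a fixed, logged order — individual call rate
(default ≥ 0.90), SNP call rate (≥ 0.95), minor allele frequency (≥ 0.01),
and a Hardy–Weinberg exact test (P ≥ 1e-4) — followed by relatedness
pruning. The HWE test is the two-sided exact test on genotype counts:
conditional on the allele counts, the probability of every admissible
heterozygote count is computed and all configurations no more probable
than the observed one are summed. Relatedness uses method-of-moments
estimates of P(IBD = 0/1/2) from identity-by-state counts with sample
allele frequencies; PI_HAT = P(IBD=2) + P(IBD=1)/2, and a greedy pruner
removes the individual with most partners above the threshold (default
0.18, i.e. between second- and third-degree relatives) until no pair
remains. The finite-sample bias corrections some tools add to the IBS
expectations are omitted; at hundreds of SNPs and moderate sample sizes
their effect is far below the 0.18 decision boundary. Pairs with fewer
than 50 jointly called SNPs are flagged unreliable rather than estimated.

LD decay is summarized as mean composite genotype-correlation r² in
physical-distance bins over all intra-chromosome pairs within a maximum
distance; for independent loci the estimator has a known positive floor of
about 1/(n−1), visible in the neutral-simulation tests.

## ROH detection and eROHi islands

Runs of homozygosity are found per individual by the consecutive-runs
("windowless") method: a run is a maximal interval of SNPs whose endpoints
are homozygous calls, containing at most `max_het` heterozygotes (default
1, accommodating genotyping error in long runs) and at most
`max_missing_in_run` missing calls (default 0), with no inter-SNP gap
larger than `max_gap_bp`. Retained runs must satisfy a minimum length
(default 1 Mb), a minimum number of homozygous SNPs (15) and a minimum SNP
density (1 per 100 kb) — the standard configuration for HD-array data.
Maximality is computed with a two-pointer sweep and is tested against an
exhaustive interval enumerator. Length classes are left-closed,
right-open: [1–2), [2–4), [4–8), [8–16), ≥16 Mb.

The eROHi statistic is the per-SNP count of individuals covered by a run,
z-scored within each chromosome (mean and SD across that chromosome's
SNPs, guarding against chromosome-size artefacts) and transformed to
−log10 of the right Gaussian tail. SNPs with −log10 P ≥ 4 are outliers;
only stretches of at least two consecutive outlier SNPs are called
islands, extended by 100 kb on each side. A chromosome with zero
incidence variance yields no outliers by convention.

## EHH, iHS and nSL

EHH at distance x from a focal SNP is the probability that two random
haplotypes carrying the same core allele are identical at every SNP
between the focal SNP and x. It is computed by partition refinement —
haplotype group labels are refined one SNP at a time outward — which the
tests verify against an all-pairs oracle exactly.

iHS integrates the ancestral- and derived-allele EHH curves over physical
distance by the trapezoid rule, truncating a curve after its first value
below the EHH cutoff (default 0.05) or before any inter-SNP gap larger
than 200 kb, and takes ln(iHH_A / iHH_D). nSL measures the same contrast
in units of segregating sites: the mean over same-allele haplotype pairs
of the number of sites in the maximal interval containing the focal SNP
over which the pair is identical. This mean is computed through the
identity "mean pair extent = Σ EHH over sites", which makes it exactly the
all-pairs quantity at a fraction of the cost; steps across gaps larger
than the 20 kb gap scale are down-weighted by gap_scale/gap, extension
stops at gaps over 200 kb or after 100 sites per direction (the reference
scan defaults for array data). SNPs with derived frequency outside
[0.05, 0.95] are skipped. A compiled (numba) kernel reproduces the pure
reference implementation bit-for-bit; the test suite asserts the two
routes agree to 1e-10 on random fixtures.

Raw scores are standardized in 100 equal-width derived-allele-frequency
bins pooled genome-wide (bins with fewer than two finite scores or zero
spread yield missing values) and mapped to two-tailed Gaussian
−log10(2Φ(−|z|)). Windows of 0.5 Mb, sliding by 10 kb, are significant
when they contain at least three SNPs with −log10 P ≥ 4; overlapping
significant windows merge into candidate regions. The window step is a
configurable reading of a 0.5 Mb window "overlapping adjacent windows";
both a 10 kb and a 490 kb step are reachable through `--window-step`.
Polarization uses the ancestral-allele annotation when present; otherwise
the major allele is treated as ancestral and the SNP flagged. Unphased
input is rejected — both statistics are defined on haplotypes and phasing
is out of scope.

## Composite likelihood ratio (CLR) scan

The null model is the genome-wide empirical site frequency spectrum. The
sweep model at distance d and strength α lets each of the n sampled
lineages escape the sweep independently with probability
p_e = 1 − exp(−α d); conditional on k escapees, the k escaped lineages
plus the single ancestor of the swept cluster form a hypergeometric
subsample of size k+1 from the background spectrum, the non-escapees
inherit the cluster ancestor's allele, and the resulting derived-count
distribution is renormalized over segregating outcomes (monomorphic sites
are not modelled: array data). The implementation is verified against
exhaustive enumeration over all escape configurations at n = 4 and n = 6.
With unknown polarity, the folded (minor-count) spectrum is used: the
folded background is unfolded symmetrically, pushed through the model and
refolded.

For each position of an evenly spaced per-chromosome grid (default
10,000 positions), the composite log likelihood is maximized over a grid
of 40 log-spaced α values plus a full-escape sentinel that nests the null;
Λ = 2(ℓ̂₁ − ℓ₀), clamped at zero. The likelihood-ratio factor 2 is
configurable. Spectra are precomputed on a 400-point log-spaced lattice of
x = αd; the lattice is fine where the near-sweep regime changes quickly.
The α range spans footprints from roughly 35 kb to 10 Mb. The upper α
bound is deliberately conservative: stronger α values let the model fit a
chance cluster of two or three extreme-frequency SNPs at essentially zero
distance, producing sub-grid spikes of spurious likelihood; footprints
below the local SNP spacing are not resolvable on array-density data, so
they are excluded from the default grid rather than guarded by ad hoc
penalties. Once the grid resolves the SNP spacing, doubling the grid size
changes the per-chromosome maximum by well under 5%.

Significance is empirical: the genome-wide threshold is the
(1 − top_fraction) quantile (higher interpolation) of all grid values,
default top 0.1%; contiguous strictly-above-threshold grid runs merge into
regions, padded by half a grid step.

## Consensus and annotation

Regions from the four methods (closed intervals, shared endpoints
overlap) are merged by connected components of the overlap graph;
components supported by at least two distinct methods are emitted with
union bounds, sorted, and reported with lengths in Mb (half-up, three
decimals — the convention that reproduces the published candidate-region
table exactly). Union bounds rather than intersections are used because
the published lengths can exceed any single method's window.

Gene and QTL annotation intersects candidate regions with user-supplied
GFF3/BED/TSV intervals. QTL-class enrichment counts each QTL once even
when it spans several regions; expected counts follow the proportional
model (class total × overall overlap fraction within the scope, genome or
chromosome), the richness factor is observed/expected, P values are
hypergeometric upper tails, and Benjamini–Hochberg controls the FDR
across classes. A proportional-to-bp expected-count convention is not
implemented; the proportional-to-scope model matches the bubble-plot
quantities the enrichment output is designed to feed.

## The simulator

Synthetic datasets emulate one diploid population genotyped on a dense
array: biallelic SNPs with known ancestral allele, ~26 autosome-style
chromosome labels available through concatenation of independent
per-chromosome simulations, realistic site-frequency spectra,
configurable missingness, and planted duplicate and parent–child
individuals for exercising QC.

Neutral standing variation is drawn from the discrete-time Wright–Fisher
model (msprime, `model="dtwf"`, binary mutations at discrete sites), which
samples the same process a forward simulation with long burn-in would at a
fraction of the cost. Hard sweeps are simulated forward from that
standing variation: the whole population of N diploids is evolved with
fitness-weighted multinomial parent sampling (additive fitness 1, 1+s,
1+2s), Poisson recombination (single-crossover fast path, multi-crossover
exact path), and Poisson mutation influx; the beneficial mutation is
introduced on one haplotype and trajectories losing it are restarted from
the same standing variation, against a retry budget of 10,000 (an
explicit conditioning failure reports the attempts used). The run stops
when the population frequency reaches the target; individuals are then
sampled without replacement and the sample is re-drawn (and, if needed,
the trajectory re-run) until the sampled sweep-allele frequency is within
0.05 of the target. Sites fixed or lost in the population are purged
during the run; sample-monomorphic sites are dropped at output, so a
target frequency of 1 leaves the focal site recorded only in the truth
sidecar.

### Desk-scale study conditions

The validation experiments run on a standard scaled genome: four 2 Mb
chromosomes, 50 diploids sampled from N = 800, μ = 1e-7 and r = 2.5e-7
per bp per generation, and one complete hard sweep (s = 0.1, per-copy)
in the middle of chromosome 1. The scaled rates preserve per-bp diversity
(4Nμ ≈ 3.2e-4, SNP spacing ≈ 1.2 kb) and linkage at a tractable
population size; under these rates a complete s = 0.1 sweep leaves a
footprint of roughly s/(r ln 2Ns) ≈ 100 kb, resolvable against 2 Mb of
flanking variation, and the three neutral chromosomes keep the empirical
background spectrum predominantly neutral, as a genome-wide scan's
background is. ROH thresholds scale with the ~10–20× map compression
(minimum run 50 kb, gap 100 kb, density 1 SNP/10 kb, 15 SNPs); the purely
statistical thresholds (outlier −log10 P ≥ 4, 0.5 Mb windows, ≥3 hits,
CLR top fraction) stay at their standard values except that the CLR top
fraction is 0.5% because a 250-point-per-chromosome grid leaves too few
grid values for a meaningful 0.1% cut.

What these experiments show: the detectors agree exactly with brute-force
oracles; standardized iHS/nSL are close to standard normal on neutral
data (KS distance ≪ 0.05 at ~10,000 SNPs); the CLR null is quiet and the
scan localizes complete sweeps to within tens of kb in the large majority
of replicates; and ≥2-method consensus regions coincide with the true
sweep far more often than on matched neutral data. What they do not show:
robustness to demography (bottlenecks, admixture), soft sweeps, array
ascertainment bias, genotyping-intensity artefacts, or phasing error —
none of which the generator emulates.

### A known calibration gap

On neutral simulations at these conditions the fraction of SNPs passing
the eROHi outlier threshold is about 5–10 × 10⁻⁴ rather than the ~10⁻⁴
Gaussian tail mass. The per-SNP ROH incidence is strongly clumped: at
N = 800 many sampled individuals share recent ancestry, so chromosome
segments where several haplotypes coalesce recently produce island-like
stacks of coverage, and each such island contributes tens of adjacent
outlier SNPs at once. The z → Gaussian-tail transform is therefore
anti-conservative on clumped incidence, which is precisely why island
calls additionally require consecutive outliers and why the consensus
step demands confirmation by a second method. Configurations that damp
the clumping (much longer minimum runs) also destroy the detector's power
for footprint-scale islands, so the default keeps the scaled thresholds
and documents the inflation instead.

## Numerical choices

- HWE enumeration works in log space with a stable max-subtraction; ties
  with the observed configuration's probability are included with a
  relative tolerance of 1e-12.
- Empirical quantiles for the CLR threshold use "higher" interpolation so
  the threshold is an attained grid value.
- Half-up decimal rounding (not banker's) for Mb lengths.
- Gaussian tail probabilities are floored at 1e-300 before log10.
- All randomness flows through explicit integer seeds; identical seeds
  give byte-identical simulator output and bit-identical pipeline runs.
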