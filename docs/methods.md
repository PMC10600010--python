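# Methods

This note records the models implemented in `admixfreq`, their
assumptions, the defaults and why, and what the simulation-based tests
do and do not demonstrate.

## Ancestry-specific allele frequencies

Local-ancestry calls exist only at sparse "array" anchor sites; each
anchor carries a probability vector over the K ancestral populations
for every haplotype. Sequence variants between anchors receive the
convex combination of the two flanking anchor vectors, linear in
base-pair position. Beyond the first or last anchor the nearest anchor
vector is used unchanged (clamping keeps the field continuous and
total probability exactly 1; extrapolation could leave the simplex).
Interpolation is in bp, not cM: anchor spacing is far below typical
ancestry-tract lengths, so the two scales are locally proportional and
bp positions are always available.

The weighted counts AC_k, AN_k, θ_k = AC_k/AN_k and n_k = AN_k/2 are
plain sums over haplotypes; missing alleles contribute to neither sum,
matching VCF AN semantics. θ_k is undefined (NaN, "." in VCF output)
when AN_k = 0. Conservation — Σ_k AC_k equals the unweighted ALT
count and Σ_k AN_k the non-missing allele count — holds by
construction because every probability vector sums to 1, and is
asserted in tests including singleton-corrected sites.

Singleton handling: a cohort singleton whose carrier shows different
argmax ancestries on its two haplotypes is "het-ancestry"; its phasing
is unreliable, so under the default `equal-weight` policy the carrying
allele's vector is replaced by the mean of the carrier's two haplotype
vectors. Only the carrying haplotype's contribution is modified (both
its AC and AN terms); the non-carrying haplotype keeps its own vector.
This is the minimal departure from the base formula; the alternative
`haplotype` policy disables the correction. Het-ancestry status is
evaluated pointwise at the variant position (argmax with ties broken
toward the lower ancestry index), a deterministic operationalization
of "stretches of heterozygous ancestry".

Relatedness is deliberately not adjusted here — released cohort
frequencies are computed over all samples — but every entry point
accepts an unrelated-subset sample list.

## IBD-graph relatedness correction

Vertices at a locus are haplotypes with a non-missing allele. Edges
join haplotype pairs whose (filtered) IBD segment covers the locus
*and* whose samples are related at degree ≤ 3; the degree table is an
explicit input (from the simulator or external kinship inference —
the package does not infer relatedness). Conflicting-allele edges are
removed before components are computed, treating them as IBD false
positives; with conflicts gone first, every component is
allele-homogeneous, which is asserted at every locus rather than
assumed. Components, not maximal cliques, define clusters: missed
edges inside a component are taken to be detection false negatives.
AC/AN count components once each; with no qualifying edges this reduces
exactly to naive haplotype counting, so unrelated cohorts are a strict
no-op. Ancestry-resolved counts average the local-ancestry vectors
within a component (p̄_C) and sum over ALT components (W) and all
components (N).

On pedigree gene-drop simulations with exact IBD truth this machinery
is checked against an independent oracle — counting distinct founder
haplotypes carrying each allele — and agrees exactly at every
segregating site. Loci where one haplotype of a sample is missing are
handled by dropping that haplotype from the vertex set.

Segment filtering follows the coverage/density screening idea: tile
the chromosome with 50 kb windows (configurable; no published window
size exists for the screening procedure), compute per-window segment
coverage and SNP density, and drop any segment overlapping a window
with coverage above 4× or below 0.25× the chromosome median, or
density below 0.25× the median.

ROH–ancestry overlay: an ROH is assigned ancestry k only if at every
anchor inside it both haplotypes have argmax k with posterior
strictly above 0.9; anchors (not interpolated points) are used for
determinism, and an ROH containing no anchor falls back to the nearest
anchor. Rare-homozygote overlap counts homozygous-ALT genotypes at
variants with AF < 0.1% and reports the fraction inside the carrier's
own ROH, split by assigned ROH ancestry.

## IBD-network spectral embedding

w_ij is the total cM shared by samples i and j over all haplotype
pairings; edges with w_ij > 72 cM are zeroed so close relatives do not
dominate the geometry (the threshold applies to the per-pair total
after summation). The embedding solves Wu = μDu, equivalent to the
eigenproblem of the random-walk Laplacian L = I − D⁻¹W with μ = 1 − λ.
Numerically the symmetric form D^(-1/2) W D^(-1/2) is diagonalized
(dense `eigh`; at the network sizes exercised here a dense solve is
faster and simpler than a sparse Lanczos run, and the stated residual
contract ‖Wu − μDu‖ ≤ 1e-6‖u‖ is verified after back-transformation).
Signs are fixed so each eigenvector's largest-magnitude entry is
positive, making outputs deterministic up to eigenvalue ties. The
default dimension is p = 20. The solver requires a connected network;
`largest_connected_component` restricts to the biggest component, ties
going to the component containing the lowest original index. For
diagnostic use, `laplacian_zero_multiplicity` counts zero eigenvalues
(isolated vertices, where D is singular, count one each as their own
components).

## Deviation scan and robust mean

The global proportion p0 per ancestry is the Tukey biweight mean over
positions: iteratively reweighted location with bisquare weights,
scale fixed at the raw MAD, tuning constant c = 9 (a conservative
choice that downweights only gross outliers — appropriate because the
inputs are themselves means over thousands of haplotypes), iterated to
|Δ| < 1e-10 or 50 iterations; an all-equal sample (MAD 0) returns the
median. The per-position statistic is
z = (p̂_l − p0)/√(p0(1 − p0)/N_hap) with a two-sided normal p-value and
Bonferroni threshold α/(n_positions × K). N_hap is an explicit
parameter: the haplotype count behind the local means is a property of
the input cohort, not something the scan can infer. Degenerate p0 ∈
{0, 1} makes the test undefined for that ancestry; rows are emitted as
missing.

Calibration: with binomial draws at p0 = 0.3, N_hap = 2,000, the
empirical type-I error at α = 0.05 sits within [0.04, 0.06]. Exact
KS uniformity of these null p-values is *not* achievable: the
binomial support spaces achievable p-values ~0.04 apart near p ≈ 1,
bounding the KS distance from Uniform(0,1) below by ≈ 0.02 for every
seed, beyond the 0.0163 critical value at the 1% level for 10,000
positions. The corresponding test asserts uniformity as specified and
documents this as the reason it fails; the p-values are valid
(conservative) despite the discreteness.

## Sex-biased admixture

The solver inverts the simplest single-pulse mixture model: one
founding event with female contribution s_f and male contribution s_m
per ancestry, at equilibrium transmitting H_A = (s_f + s_m)/2 on
autosomes and H_X = (2s_f + s_m)/3 on X (two-thirds of X copies reside
in females). The closed-form inverse is s_f = 3H_X − 2H_A,
s_m = 4H_A − 3H_X, female fraction s_f/(2H_A). Observed (H_A, H_X)
pairs outside the image of [0,1]² produce out-of-range solutions; they
are returned with a warning flag because they diagnose model misfit —
multi-pulse or continuous-migration histories give different estimates,
and published female-contribution figures from such models are
therefore not comparable targets for this solver.

## Imputation accuracy

r² per MAF bin is the squared Pearson correlation between the
concatenated vector of true (masked) genotypes and the concatenated
imputed dosages across all variants in the bin; pairs with missing
entries are dropped and zero-variance bins yield NaN. Concatenating
before correlating weights every genotype equally, so rare variants do
not get per-variant noise amplification; the statistic is invariant to
affine rescaling of dosages.

## Variant QC

The exact HWE test conditions on the allele counts and evaluates the
Levene–Haldane distribution of the heterozygote count in log space
(gammaln + logsumexp), so extreme tails (e.g. 10⁻⁵⁹ for 200/200
heterozygotes) are computed without underflow. The excess-het tail
P(het ≥ observed) is one-sided because the filter pairs it with an
excess-het condition (observed > 1.5× the HWE expectation 2np̂q̂); a
two-sided option exists. Mendel errors are genotype-level
impossibilities given parental genotypes; trios with any missing
member contribute nothing. Filters are order-independent and
idempotent; "unresolved duplicates" come from an external list and are
never inferred.

## Synthetic-data generator

The generator emulates the study conditions the estimators target:

- **Ancestry tracts**: a continuous-time Markov jump process along the
  genetic map with intensity G per Morgan (default G = 15 generations
  since admixture); at each jump the new ancestry is drawn i.i.d. from
  the admixture proportions. Expected observed switches per haplotype
  are G·L·(1 − Σπ_k²) for map length L Morgans — the Monte-Carlo tests
  check exactly this rate. Default proportions (0.65, 0.31, 0.04) for
  (AMR, EUR, AFR) mirror a three-way admixed Mexican cohort.
- **Frequencies**: per-population Beta(0.5, 0.5) marginals (a
  U-shaped, SFS-like spectrum with enough common variants to score
  recovery), optionally coupled across populations by a Gaussian
  copula (ρ = 0 by default; ρ = 1 makes populations identical).
  Frequencies are clipped to [1e-6, 1 − 1e-6] to keep draws
  non-degenerate.
- **Geometry**: 2,000 evenly spaced variants on a 100 Mb chromosome at
  1 cM/Mb by default; every 10th variant is an "array" anchor site,
  the rest are sequence-only and exercise interpolation.
- **Gene drop**: founder haplotypes are transmitted with Poisson
  crossovers (rate = map length in Morgans, positions uniform in cM);
  every transmitted segment records its founder haplotype of origin,
  and truth IBD segments are the maximal intervals where two
  haplotypes of distinct individuals share a founder haplotype.
  Touching truth segments of one haplotype pair are merged even when
  the shared founder changes at the junction, mirroring what a
  detector would report; per-locus coverage is unaffected. Relatedness
  degrees come from pedigree kinship, d = round(−log2 2φ).
- **Determinism**: all randomness flows from the single config seed;
  identical configs give byte-identical outputs.

What the simulations do *not* model: coalescent linkage disequilibrium
within populations, mutation and sequencing error, phase-switch
errors, LAI miscalls (truth ancestry is exact unless blurred with the
ε option), sex-chromosome transmission, and non-stationary admixture
histories. Passing recovery tests therefore demonstrate correctness of
the estimators given accurate inputs, not robustness to upstream
inference error.

## Problem sizes and numerical choices

The test battery and `scripts/acceptance.py` use n = 1,000 diploids ×
2,000 variants for frequency recovery (r² > 0.98 on variants with
n_k ≥ 100 and ancestry-MAF ≥ 1%), twenty 3-generation families
(200 individuals) for the founder-allele oracle, 10,000 positions for
scan calibration, and a 10 × 10 grid for the sex-bias round trip —
sizes at which every statistical check has comfortable power while the
whole battery completes in seconds. Probability-sum tolerances are
1e-6 (matching fb-file precision), eigen-residuals 1e-6, robust-mean
convergence 1e-10, and exact identities (conservation, oracle
equality, round trips) are asserted to machine precision or printing
precision as appropriate.
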