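# admixfreq

Ancestry-resolved and relatedness-corrected allele frequencies for
admixed cohorts.

Large admixed cohorts — for example Mexican-ancestry cohorts carrying
Indigenous American, European and African segments — need allele
frequencies *per ancestral population*, not just cohort-wide averages:
without them, rare ancestry-specific variants are indistinguishable
from potentially pathogenic ones. `admixfreq` implements the
population-genetic machinery for this setting, for methodologists and
cohort analysts who already have phased genotypes, local-ancestry calls
(RFMix v2) and IBD/ROH segments (hap-IBD), and want tested, reusable
building blocks rather than one-off scripts.

## What it computes

**Ancestry-specific allele frequencies.** Local ancestry is called at
sparse array sites; probabilities are linearly interpolated (in bp) to
every sequence variant. With `p_ijk` the probability that haplotype `j`
of individual `i` derives from population `k` and `G_ij` the 0/1 ALT
indicator,

    AC_k = Σ_i Σ_j p_ijk G_ij      (weighted allele count)
    AN_k = Σ_i Σ_j p_ijk           (weighted allele number)
    θ_k  = AC_k / AN_k             (ancestry-specific frequency)
    n_k  = AN_k / 2                (effective diploid sample size)

Singletons falling in heterozygous-ancestry stretches (the carrier's
two haplotypes have different most-probable ancestries) are phased
unreliably; the carrying allele then receives the average of the two
haplotype vectors ("equal weight to the two ancestries").

**IBD-relatedness-corrected frequencies.** At each locus a graph joins
haplotypes that share an IBD segment covering the locus, restricted to
pairs related at third degree or closer, with allele-conflicting edges
removed. Connected components stand in for distinct ancestral alleles:
`AC = |C_ALT|`, `AN = |C_ALT| + |C_REF|`, `AF = AC/AN`; per-ancestry
counts sum component-averaged local-ancestry vectors.

**IBD-network embedding.** Pairwise shared cM are summed into a weight
matrix `W` (edges > 72 cM removed to suppress extended families); the
coordinates are the bottom eigenvectors of the normalized random-walk
Laplacian `L = I − D⁻¹W`, solved as `Wu = μDu` with `μ = 1 − λ`.

**Ancestry deviation scan.** Local mean ancestry dosage vs a robust
(Tukey biweight) genome-wide proportion, z-tested under binomial
sampling with Bonferroni correction `α / (n_positions × K)`.

**Sex-biased admixture.** Inverts the single-pulse model
`H_A = (s_f + s_m)/2`, `H_X = (2s_f + s_m)/3` to estimate female and
male founding contributions per ancestry from autosomal vs
X-chromosome ancestry proportions.

**Variant QC.** Hard filters: monomorphic, >10% missingness, ≥3 Mendel
errors, exact Hardy–Weinberg excess heterozygosity (one-sided
P < 1e-30 with observed het > 1.5× expected).

**Simulator.** A truth-tracking generator produces admixed haplotypes
(Markov ancestry tracts at G switches per Morgan), ancestral allele
frequencies, pedigree gene drops with exact IBD truth segments, and
relatedness-degree tables — so every estimator above is testable
against known truth with no external data.

## Worked example

```sh
$ admixfreq demo --seed 1
admixfreq demo (seed=1)
========================================
cohort: 300 samples, 600 variants, K=3, G=15.0, proportions=[0.65, 0.31, 0.04]
conservation check (sum_k AC_k = AC, sum_k AN_k = AN at all sites): passed
theta_hat vs truth, AMR: r^2 = 0.9958 over 534 variants
theta_hat vs truth, EUR: r^2 = 0.9859 over 524 variants
IBD correction at 20 loci: mean corrected AN 32.0 vs naive 80.0
embedding: largest component 10 samples, lambda_1 = 0.5104
deviation scan: p0 = [0.655, 0.305, 0.04], threshold = 2.78e-05, significant = 0
hard filters: 600/600 variants pass
```

Reading the report: the simulated cohort's ancestry-specific frequency
estimates `θ̂_k` track the true per-population frequencies with
r² ≈ 0.99 on well-covered common variants, and the per-ancestry counts
sum exactly to the overall counts at every site. In the pedigree
segment, relatedness correction shrinks the allele number from 80
haplotypes to 32 distinct founder alleles. The deviation scan finds no
significant departures — correct, since the simulated admixture is
homogeneous along the chromosome.

The same stages are exposed as `admixfreq simulate / convert / validate /
afreq / ibd-afreq / roh-ancestry / embed / scan / sexbias / impacc / qc`;
run any subcommand with `--help`.

A library-level sketch of the main path:

```python
import admixfreq as af

cfg = af.SimulationConfig(n_samples=1000, n_variants=2000, seed=1)
truth = af.gen_ancestral_frequencies(cfg.n_variants, cfg.K, cfg.sfs_params, seed=1)
haps, lai = af.gen_admixed_haplotypes(cfg, truth)
anchors = af.thin_to_anchors(lai, cfg.anchor_indices())   # sparse array sites
table = af.ancestry_frequency_pipeline(haps, anchors)      # interpolate + count
table.theta        # (variants, K) ancestry-specific frequencies
table.n_k          # effective diploid sample sizes
```

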