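"""Synthetic admixed cohorts with full truth.

Two generators cover the downstream needs:

* :func:`gen_admixed_haplotypes` draws phased haplotypes whose ancestry
  along the chromosome follows a continuous-time Markov jump process on
  the genetic-map (cM) axis with intensity ``G`` per Morgan — ``G``
  generations since a single admixture pulse — restarting ancestry
  i.i.d. from the admixture proportions.  Alleles are Bernoulli draws
  from ancestry-specific frequencies, so ancestry-resolved frequency
  estimators can be scored against exact truth.

* :func:`gene_drop_pedigree` transmits founder haplotypes down a
  pedigree with Poisson crossovers, recording the founder-haplotype
  origin of every transmitted segment.  IBD truth segments are the
  maximal intervals where two haplotypes descend from the same founder
  haplotype, and the relatedness-degree table follows from pedigree
  kinship.

All randomness flows from the seed in the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    IBD_COLUMNS,
    GeneticMap,
    IBDSegmentSet,
    LocalAncestryField,
    PedigreeSpec,
    PhasedHaplotypeSet,
)

DEFAULT_PROPORTIONS = (0.65, 0.31, 0.04)  # Indigenous American, European, African
DEFAULT_ANCESTRIES = ("AMR", "EUR", "AFR")


@dataclass
class BetaSFS:
    """Per-population allele-frequency distribution: Beta(a, b) marginals.

    ``rho`` couples populations through a Gaussian copula; ``rho = 0``
    draws frequencies independently per population and ``rho = 1`` makes
    all populations identical.
    """

    a: float = 0.5
    b: float = 0.5
    rho: float = 0.0

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("Beta parameters must be positive")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("correlation rho must be in [0, 1]")


@dataclass
class SimulationConfig:
    """Study conditions for one simulated admixed chromosome."""

    K: int = 3
    n_samples: int = 1000
    n_variants: int = 2000
    chromosome_length_bp: int = 100_000_000
    genetic_map: GeneticMap | None = None  # default: uniform 1 cM/Mb
    admixture_proportions: np.ndarray = field(
        default_factory=lambda: np.array(DEFAULT_PROPORTIONS)
    )
    generations_G: float = 15.0
    sfs_params: BetaSFS = field(default_factory=BetaSFS)
    anchor_spacing: int = 10
    lai_blur_eps: float = 0.0
    ancestries: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        self.admixture_proportions = np.atleast_1d(
            np.asarray(self.admixture_proportions, dtype=np.float64)
        )
        props = self.admixture_proportions
        if props.ndim == 1:
            if props.size != self.K:
                raise ValueError("admixture proportions must have K entries")
            total = props.sum()
        else:
            if props.shape != (self.n_samples, self.K):
                raise ValueError("per-individual proportions must be (n_samples, K)")
            total = props.sum(axis=1)
        if not np.allclose(total, 1.0, atol=1e-9):
            raise ValueError("admixture proportions must sum to 1")
        if self.generations_G < 1:
            raise ValueError("generations_G must be >= 1")
        if self.genetic_map is None:
            self.genetic_map = GeneticMap.uniform(self.chromosome_length_bp)
        if self.ancestries is None:
            if self.K == len(DEFAULT_ANCESTRIES):
                self.ancestries = DEFAULT_ANCESTRIES
            else:
                self.ancestries = tuple(f"POP{k}" for k in range(self.K))

    def variant_positions(self) -> np.ndarray:
        """Evenly spaced 1-based positions spanning the chromosome."""
        return np.linspace(1, self.chromosome_length_bp, self.n_variants).astype(np.int64)

    def anchor_indices(self) -> np.ndarray:
        """Indices of "array" anchor variants (every anchor_spacing-th)."""
        return np.arange(0, self.n_variants, self.anchor_spacing)


def gen_ancestral_frequencies(
    n_variants: int, K: int, sfs_params: BetaSFS | None = None, seed: int = 0
) -> np.ndarray:
    """True allele frequencies f[m, k] per variant m and population k.

    Marginals are Beta(a, b); a Gaussian copula with correlation ``rho``
    couples the K populations at each variant.
    """
    if n_variants < 1 or K < 2:
        raise ValueError("need n_variants >= 1 and K >= 2")
    sfs = sfs_params or BetaSFS()
    rng = np.random.default_rng(seed)
    if sfs.rho == 0.0:
        f = rng.beta(sfs.a, sfs.b, size=(n_variants, K))
    else:
        shared = rng.standard_normal((n_variants, 1))
        own = rng.standard_normal((n_variants, K))
        z = np.sqrt(sfs.rho) * shared + np.sqrt(1.0 - sfs.rho) * own
        u = stats.norm.cdf(z)
        f = stats.beta.ppf(u, sfs.a, sfs.b)
    # keep frequencies interior so Bernoulli draws are non-degenerate
    return np.clip(f, 1e-6, 1.0 - 1e-6)


def _simulate_tracts(
    rng: np.random.Generator,
    length_cm: float,
    G: float,
    proportions: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """One haplotype's tract boundaries (cM, ascending) and tract ancestries."""
    n_jumps = rng.poisson(G * length_cm / 100.0)
    cuts = np.sort(rng.uniform(0.0, length_cm, size=n_jumps))
    anc = rng.choice(proportions.size, size=n_jumps + 1, p=proportions)
    return cuts, anc


def gen_admixed_haplotypes(
    config: SimulationConfig, truth_freqs: np.ndarray
) -> tuple[PhasedHaplotypeSet, LocalAncestryField]:
    """Draw a phased admixed cohort plus its one-hot local-ancestry truth.

    Returns the haplotype set and a :class:`LocalAncestryField` anchored
    at *every* variant position (use :func:`thin_to_anchors` for the
    sparse array-site field).
    """
    truth_freqs = np.asarray(truth_freqs, dtype=np.float64)
    if truth_freqs.shape != (config.n_variants, config.K):
        raise ValueError("truth frequency matrix does not match config dimensions")
    gmap = config.genetic_map
    if gmap.length_cm <= 0:
        raise ValueError("genetic map has zero genetic length")
    rng = np.random.default_rng(config.seed)
    n, m, K = config.n_samples, config.n_variants, config.K
    positions = config.variant_positions()
    pos_cm = gmap.bp_to_cm(positions) - gmap.cm[0]

    props = config.admixture_proportions
    per_individual = props.ndim == 2

    ancestry = np.empty((n, 2, m), dtype=np.int8)
    for i in range(n):
        p = props[i] if per_individual else props
        for j in range(2):
            cuts, anc = _simulate_tracts(rng, gmap.length_cm, config.generations_G, p)
            ancestry[i, j] = anc[np.searchsorted(cuts, pos_cm, side="right")]

    u = rng.random((n, 2, m))
    alleles = (u < truth_freqs[np.arange(m)[None, None, :], ancestry]).astype(np.int8)

    probs = np.zeros((n, 2, m, K))
    np.put_along_axis(probs, ancestry[..., None].astype(np.int64), 1.0, axis=-1)
    eps = config.lai_blur_eps
    if eps > 0:
        probs = (1.0 - eps) * probs + eps / K

    haps = PhasedHaplotypeSet(
        samples=[f"S{i:05d}" for i in range(n)],
        chrom="1",
        positions=positions,
        ref=["A"] * m,
        alt=["G"] * m,
        alleles=alleles,
    )
    lai = LocalAncestryField(list(config.ancestries), positions, probs)
    return haps, lai


def thin_to_anchors(lai: LocalAncestryField, anchor_idx: np.ndarray) -> LocalAncestryField:
    """Restrict a dense ancestry field to sparse "array" anchor sites."""
    return LocalAncestryField(
        list(lai.ancestries), lai.anchors[anchor_idx], lai.probs[:, :, anchor_idx, :]
    )


# ---------------------------------------------------------------------------
# pedigree gene dropping


def three_generation_pedigree(
    n_families: int, children_per_couple: int = 2, prefix: str = "F"
) -> PedigreeSpec:
    """Stock pedigree: a grandparental couple, two brothers, their children.

    Each family holds one grandparental couple, their two sons, two
    married-in spouses and ``children_per_couple`` grandchildren per
    couple.  The grandchildren across the two couples are first cousins,
    so every within-family relationship is third degree or closer.
    """
    individuals, sex, father, mother = [], {}, {}, {}

    def add(ind, s, f=None, m=None):
        individuals.append(ind)
        sex[ind] = s
        father[ind], mother[ind] = f, m

    for fam in range(n_families):
        p = f"{prefix}{fam:03d}"
        add(f"{p}_gpa", "M"); add(f"{p}_gma", "F")
        add(f"{p}_dad", "M", f"{p}_gpa", f"{p}_gma")
        add(f"{p}_unc", "M", f"{p}_gpa", f"{p}_gma")
        add(f"{p}_mom", "F")   # married-in founder
        add(f"{p}_ant", "F")   # married-in founder
        for c in range(children_per_couple):
            add(f"{p}_kidA{c}", "M" if c % 2 else "F", f"{p}_dad", f"{p}_mom")
            add(f"{p}_kidB{c}", "M" if c % 2 else "F", f"{p}_unc", f"{p}_ant")
    return PedigreeSpec(individuals, sex, father, mother)


class _Hap:
    """A haplotype: allele vector + piecewise founder-origin map."""

    __slots__ = ("alleles", "breaks", "labels")

    def __init__(self, alleles: np.ndarray, breaks: np.ndarray, labels: np.ndarray):
        self.alleles = alleles
        self.breaks = breaks  # (s+1,) bp boundaries, half-open intervals
        self.labels = labels  # (s,) founder-haplotype ids


def _meiosis(
    rng: np.random.Generator,
    hap_a: _Hap,
    hap_b: _Hap,
    gmap: GeneticMap,
    positions: np.ndarray,
    chrom_end: int,
) -> _Hap:
    """Recombine two parental haplotypes into one gamete."""
    n_x = rng.poisson(gmap.length_cm / 100.0)
    cuts_cm = np.sort(rng.uniform(gmap.cm[0], gmap.cm[-1], size=n_x))
    cuts_bp = np.unique(np.round(gmap.cm_to_bp(cuts_cm)).astype(np.int64))
    cuts_bp = cuts_bp[(cuts_bp > 1) & (cuts_bp < chrom_end)]
    start = int(rng.integers(2))

    # alleles: phase of each variant = number of cuts before it, mod 2
    phase = (np.searchsorted(cuts_bp, positions, side="right") + start) % 2
    alleles = np.where(phase == 0, hap_a.alleles, hap_b.alleles)

    # origin map: stitch parental origin maps at the crossover boundaries
    bounds = np.concatenate(([1], cuts_bp, [chrom_end + 1]))
    breaks, labels = [1], []
    for seg in range(len(bounds) - 1):
        lo, hi = int(bounds[seg]), int(bounds[seg + 1])
        src = hap_a if (seg + start) % 2 == 0 else hap_b
        i0 = np.searchsorted(src.breaks, lo, side="right") - 1
        i1 = np.searchsorted(src.breaks, hi, side="left")
        for t in range(i0, i1):
            s = max(lo, int(src.breaks[t]))
            e = min(hi, int(src.breaks[t + 1]))
            if s >= e:
                continue
            lab = int(src.labels[t])
            # pieces tile the chromosome contiguously, so each piece starts
            # where the previous one ended; merge same-origin neighbours
            if labels and labels[-1] == lab:
                breaks[-1] = e
            else:
                breaks.append(e)
                labels.append(lab)
    return _Hap(alleles, np.asarray(breaks, dtype=np.int64), np.asarray(labels, dtype=np.int64))


def gene_drop_pedigree(
    founders: PhasedHaplotypeSet,
    pedigree: PedigreeSpec,
    genetic_map: GeneticMap | None = None,
    seed: int = 0,
    min_ibd_cm: float = 0.0,
    return_origins: bool = False,
    founder_assignment: dict[str, int] | None = None,
):
    """Drop founder haplotypes through a pedigree, with exact IBD truth.

    Founders are matched to ``founders.samples`` in pedigree order
    unless ``founder_assignment`` maps founder ids to sample indices
    explicitly (mapping two ids to one sample models a duplicated
    individual: the pair then shares both haplotypes genome-wide).
    Returns the full cohort (founders + descendants), truth IBD segments
    between all haplotype pairs of distinct individuals that share a
    founder haplotype over >= ``min_ibd_cm``, and the degree <= 3
    relatedness table derived from pedigree kinship.
    """
    gmap = genetic_map or GeneticMap.uniform(int(founders.positions[-1]))
    founder_ids = pedigree.founders
    if founder_assignment is None:
        founder_assignment = {ind: fi for fi, ind in enumerate(founder_ids)}
    missing = [f for f in founder_ids if f not in founder_assignment]
    if missing or max(founder_assignment.values(), default=-1) >= founders.n_samples:
        raise ValueError(
            f"pedigree founders not covered by founder samples "
            f"({len(founder_ids)} founders, {founders.n_samples} samples)"
        )
    rng = np.random.default_rng(seed)
    positions = founders.positions
    chrom_end = int(positions[-1])

    haps: dict[str, tuple[_Hap, _Hap]] = {}
    whole = np.array([1, chrom_end + 1], dtype=np.int64)
    for ind in founder_ids:
        fi = founder_assignment[ind]
        haps[ind] = tuple(
            _Hap(founders.alleles[fi, j].copy(), whole.copy(), np.array([2 * fi + j]))
            for j in range(2)
        )
    for ind in pedigree.nonfounders:
        fa, mo = pedigree.father[ind], pedigree.mother[ind]
        pat = _meiosis(rng, *haps[fa], gmap, positions, chrom_end)
        mat = _meiosis(rng, *haps[mo], gmap, positions, chrom_end)
        haps[ind] = (pat, mat)

    cohort_ids = list(pedigree.individuals)
    alleles = np.stack(
        [np.stack([haps[i][0].alleles, haps[i][1].alleles]) for i in cohort_ids]
    ).astype(np.int8)
    cohort = PhasedHaplotypeSet(
        samples=cohort_ids,
        chrom=founders.chrom,
        positions=positions,
        ref=list(founders.ref),
        alt=list(founders.alt),
        alleles=alleles,
    )
    ibd = _truth_ibd(haps, cohort_ids, gmap, min_ibd_cm)
    degrees = pedigree.relatedness_degrees(max_degree=3)
    if return_origins:
        origins = {
            ind: tuple((haps[ind][j].breaks.copy(), haps[ind][j].labels.copy()) for j in (0, 1))
            for ind in cohort_ids
        }
        return cohort, ibd, degrees, origins
    return cohort, ibd, degrees


def _truth_ibd(
    haps: dict[str, tuple[_Hap, _Hap]],
    cohort_ids: list[str],
    gmap: GeneticMap,
    min_cm: float,
) -> IBDSegmentSet:
    """Maximal same-founder-origin intervals between haplotypes of distinct samples."""
    # index: founder label -> [(sample, hap12, start, end)]
    by_label: dict[int, list[tuple[str, int, int, int]]] = {}
    for ind in cohort_ids:
        for j in (0, 1):
            h = haps[ind][j]
            for t in range(len(h.labels)):
                by_label.setdefault(int(h.labels[t]), []).append(
                    (ind, j + 1, int(h.breaks[t]), int(h.breaks[t + 1]))
                )
    rows = []
    for carriers in by_label.values():
        for a in range(len(carriers)):
            s1, h1, st1, en1 = carriers[a]
            for b in range(a + 1, len(carriers)):
                s2, h2, st2, en2 = carriers[b]
                if s1 == s2:
                    continue
                st, en = max(st1, st2), min(en1, en2)
                if st >= en:
                    continue
                cm = float(gmap.bp_to_cm(en) - gmap.bp_to_cm(st))
                if cm <= 0:
                    continue  # min_cm is applied after merging touching segments
                rows.append((s1, h1, s2, h2, "1", st, en, cm))
    # maximal intervals: a pair of haplotypes may share several founder labels
    # back-to-back; merge touching segments between the same haplotype pair
    df = pd.DataFrame(rows, columns=IBD_COLUMNS)
    if len(df):
        df = df.sort_values(["sample1", "hap1", "sample2", "hap2", "start"])
        merged = []
        for _, grp in df.groupby(["sample1", "hap1", "sample2", "hap2"], sort=False):
            cur = None
            for r in grp.itertuples(index=False):
                if cur is not None and r.start <= cur[5]:
                    cur[5] = max(cur[5], r.end)
                else:
                    if cur is not None:
                        merged.append(cur)
                    cur = [r.sample1, r.hap1, r.sample2, r.hap2, r.chrom, r.start, r.end]
            if cur is not None:
                merged.append(cur)
        df = pd.DataFrame(
            [(a, b, c, d, ch, st, en, float(gmap.bp_to_cm(en) - gmap.bp_to_cm(st)))
             for a, b, c, d, ch, st, en in merged],
            columns=IBD_COLUMNS,
        )
        df = df[df["length_cm"] >= min_cm] if min_cm > 0 else df
        df = df[df["length_cm"] > 0]
    return IBDSegmentSet(df)
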