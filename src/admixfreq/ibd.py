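"""Relatedness-corrected allele frequencies from per-locus IBD graphs,
plus segment filtering and ROH–ancestry overlays.

At a locus, haplotypes that descend IBD from a common ancestor carry
redundant copies of one ancestral allele.  The correction builds a
graph whose vertices are haplotypes with a non-missing allele and whose
edges join haplotype pairs that (a) share a filtered IBD segment
covering the locus, (b) belong to samples related at third degree or
closer, and (c) agree on the observed allele (conflicting edges are
treated as IBD false positives and removed).  Connected components —
not maximal cliques, since IBD detection misses edges — stand in for
distinct ancestral alleles:

    AC = |C_ALT|,  AN = |C_ALT| + |C_REF|,  AF = AC / AN

Ancestry-resolved corrected counts average the local-ancestry vectors
within each component and sum the averages over ALT (W) and all (N)
components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .types import MISSING, IBDSegmentSet, LocalAncestryField, PhasedHaplotypeSet


# ---------------------------------------------------------------------------
# segment filtering (IBDkin-style coverage / marker-density screens)


def filter_ibd_segments(
    segs: IBDSegmentSet,
    variant_positions: np.ndarray,
    window_bp: int = 50_000,
    chrom_end: int | None = None,
) -> IBDSegmentSet:
    """Drop segments overlapping windows of aberrant coverage or SNP density.

    The chromosome is tiled with ``window_bp`` windows; a window is bad
    when its segment coverage exceeds 4x or falls below 0.25x the
    chromosome-median coverage, or its marker density falls below 0.25x
    the median density.  Any segment overlapping a bad window is removed.
    """
    df = segs.df
    if not len(df):
        import warnings

        warnings.warn("empty IBD segment set; nothing to filter")
        return segs
    variant_positions = np.asarray(variant_positions)
    end = int(chrom_end or max(int(df["end"].max()), int(variant_positions.max())))
    n_win = max(1, -(-end // window_bp))

    w0 = ((df["start"].to_numpy() - 1) // window_bp).clip(0, n_win - 1)
    w1 = ((df["end"].to_numpy() - 2) // window_bp).clip(0, n_win - 1)  # end exclusive
    delta = np.zeros(n_win + 1, dtype=np.int64)
    np.add.at(delta, w0, 1)
    np.add.at(delta, w1 + 1, -1)
    coverage = np.cumsum(delta[:-1])

    density = np.bincount((variant_positions - 1) // window_bp, minlength=n_win)[:n_win]

    med_cov = np.median(coverage)
    med_den = np.median(density)
    bad = (coverage > 4.0 * med_cov) | (coverage < 0.25 * med_cov) | (density < 0.25 * med_den)

    keep = np.ones(len(df), dtype=bool)
    bad_idx = np.flatnonzero(bad)
    if len(bad_idx):
        for s in range(len(df)):
            lo, hi = w0[s], w1[s]
            if bad[lo : hi + 1].any():
                keep[s] = False
    return IBDSegmentSet(df[keep].reset_index(drop=True))


# ---------------------------------------------------------------------------
# per-locus IBD graphs


@dataclass
class LocusIBDGraph:
    """IBD graph at one variant: haplotype vertices, alleles, components."""

    chrom: str
    pos: int
    vertices: list[tuple[int, int]]  # (sample index, hap index 0/1)
    alleles: dict[tuple[int, int], int]
    graph: nx.Graph
    components: list[set[tuple[int, int]]] = field(default_factory=list)

    def component_alleles(self) -> list[int]:
        return [self.alleles[next(iter(c))] for c in self.components]


def build_locus_ibd_graph(
    haps: PhasedHaplotypeSet,
    segs: IBDSegmentSet,
    degrees: pd.DataFrame,
    pos: int,
    max_degree: int = 3,
) -> LocusIBDGraph:
    """IBD graph at ``pos`` after degree thresholding and conflict removal.

    ``degrees`` has columns (sample1, sample2, degree); pairs absent
    from it are treated as unrelated and get no edge.  After removing
    edges whose endpoint alleles conflict, every connected component is
    allele-homogeneous (asserted).
    """
    hit = np.flatnonzero(haps.positions == pos)
    if hit.size == 0:
        raise ValueError(f"locus {pos} not in variant set")
    v = int(hit[0])
    sample_idx = {s: i for i, s in enumerate(haps.samples)}

    alleles: dict[tuple[int, int], int] = {}
    for i in range(haps.n_samples):
        for j in (0, 1):
            a = int(haps.alleles[i, j, v])
            if a != MISSING:
                alleles[(i, j)] = a
    g = nx.Graph()
    g.add_nodes_from(alleles.keys())

    close = {
        frozenset((r.sample1, r.sample2))
        for r in degrees.itertuples(index=False)
        if r.degree <= max_degree
    }
    for r in segs.segments_covering(pos).itertuples(index=False):
        if frozenset((r.sample1, r.sample2)) not in close:
            continue
        u = (sample_idx.get(r.sample1), int(r.hap1) - 1)
        w = (sample_idx.get(r.sample2), int(r.hap2) - 1)
        if u[0] is None or w[0] is None:
            continue
        if u not in alleles or w not in alleles:
            continue  # missing alleles leave the vertex set
        if alleles[u] != alleles[w]:
            continue  # conflicting alleles: edge removed as a false positive
        g.add_edge(u, w)

    comps = [set(c) for c in nx.connected_components(g)]
    for c in comps:
        vals = {alleles[x] for x in c}
        assert len(vals) == 1, "component mixes alleles after conflict removal"
    return LocusIBDGraph(haps.chrom, pos, list(alleles.keys()), alleles, g, comps)


def ibd_corrected_counts(graph: LocusIBDGraph) -> tuple[int, int, float]:
    """(AC, AN, AF) counting connected components once each."""
    comp_alleles = graph.component_alleles()
    ac = sum(1 for a in comp_alleles if a == 1)
    an = len(comp_alleles)
    af = ac / an if an else float("nan")
    return ac, an, af


@dataclass
class ComponentAncestrySummary:
    """Per-component ancestry averages and the locus totals W, N."""

    sizes: list[int]
    comp_alleles: list[int]
    p_bar: np.ndarray  # (n_components, K)
    W: np.ndarray  # (K,) weighted ALT counts
    N: np.ndarray  # (K,) weighted totals

    @property
    def frequencies(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            f = self.W / self.N
        return np.where(self.N > 0, f, np.nan)


def ibd_corrected_ancestry_counts(
    graph: LocusIBDGraph, probs_at_locus: np.ndarray
) -> ComponentAncestrySummary:
    """Ancestry-weighted component counts from (n, 2, K) locus probabilities."""
    K = probs_at_locus.shape[-1]
    p_bar = np.zeros((len(graph.components), K))
    sizes, comp_alleles = [], []
    for c_i, comp in enumerate(graph.components):
        vecs = np.stack([probs_at_locus[i, j] for (i, j) in comp])
        p_bar[c_i] = vecs.mean(axis=0)
        sizes.append(len(comp))
        comp_alleles.append(graph.alleles[next(iter(comp))])
    alt = np.array(comp_alleles) == 1
    W = p_bar[alt].sum(axis=0) if alt.any() else np.zeros(K)
    N = p_bar.sum(axis=0)
    return ComponentAncestrySummary(sizes, comp_alleles, p_bar, W, N)


def corrected_frequency_table(
    haps: PhasedHaplotypeSet,
    segs: IBDSegmentSet,
    degrees: pd.DataFrame,
    lai_probs: np.ndarray | None = None,
    positions: np.ndarray | None = None,
) -> pd.DataFrame:
    """Corrected (AC, AN, AF) — and W/N per ancestry when LAI given — per locus."""
    positions = haps.positions if positions is None else positions
    rows = []
    for pos in positions:
        g = build_locus_ibd_graph(haps, segs, degrees, int(pos))
        ac, an, af = ibd_corrected_counts(g)
        row = {"pos": int(pos), "AC": ac, "AN": an, "AF": af}
        if lai_probs is not None:
            v = int(np.flatnonzero(haps.positions == pos)[0])
            summ = ibd_corrected_ancestry_counts(g, lai_probs[:, :, v, :])
            for k in range(summ.W.size):
                row[f"W{k}"] = summ.W[k]
                row[f"N{k}"] = summ.N[k]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ROH overlays


@dataclass
class ROHSegment:
    """A run of homozygosity, optionally assigned a single ancestry."""

    individual: str
    chrom: str
    start: int
    end: int
    length_cm: float
    assigned_ancestry: str | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("ROH requires start < end")


def assign_roh_ancestry(
    roh: list[ROHSegment],
    lai: LocalAncestryField,
    sample_index: dict[str, int],
    min_posterior: float = 0.9,
) -> list[ROHSegment]:
    """Assign each ROH the ancestry supported by both haplotypes throughout.

    An ROH gets ancestry k iff at every anchor inside it both haplotype
    vectors have argmax k with probability > ``min_posterior``; ROHs
    with no interior anchor use the nearest anchor.  Everything else is
    left unassigned.
    """
    out = []
    anchors = lai.anchors
    for seg in roh:
        i = sample_index[seg.individual]
        inside = np.flatnonzero((anchors >= seg.start) & (anchors < seg.end))
        if inside.size == 0:
            mid = (seg.start + seg.end) // 2
            inside = np.array([np.argmin(np.abs(anchors - mid))])
        assigned: str | None = None
        p = lai.probs[i, :, inside, :]  # (n_anchor, 2, K) after fancy index
        calls = p.argmax(axis=-1)
        post = p.max(axis=-1)
        first = calls.flat[0]
        if (calls == first).all() and (post > min_posterior).all():
            assigned = lai.ancestries[int(first)]
        out.append(
            ROHSegment(seg.individual, seg.chrom, seg.start, seg.end, seg.length_cm, assigned)
        )
    return out


def rhlof_roh_overlap(
    haps: PhasedHaplotypeSet,
    af: np.ndarray,
    roh: list[ROHSegment],
    af_threshold: float = 0.001,
) -> pd.DataFrame:
    """Rare homozygous-ALT genotypes and their overlap with the carrier's ROH.

    Variants with AF < ``af_threshold`` (default 0.1%) are screened for
    homozygous-ALT genotypes; each is annotated with whether it lies in
    an ROH of the same individual and, if so, the ROH's assigned
    ancestry.  Half-open interval convention: pos in [start, end).
    """
    af = np.asarray(af, dtype=float)
    rare = np.flatnonzero(af < af_threshold)
    by_ind: dict[str, list[ROHSegment]] = {}
    for seg in roh:
        by_ind.setdefault(seg.individual, []).append(seg)
    rows = []
    for v in rare:
        hom = np.flatnonzero((haps.alleles[:, 0, v] == 1) & (haps.alleles[:, 1, v] == 1))
        pos = int(haps.positions[v])
        for i in hom:
            sample = haps.samples[int(i)]
            in_roh, anc = False, None
            for seg in by_ind.get(sample, []):
                if seg.start <= pos < seg.end:
                    in_roh, anc = True, seg.assigned_ancestry
                    break
            rows.append(
                {"sample": sample, "pos": pos, "af": af[v], "in_roh": in_roh, "roh_ancestry": anc}
            )
    return pd.DataFrame(rows, columns=["sample", "pos", "af", "in_roh", "roh_ancestry"])
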