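"""Core in-memory containers shared across the pipeline.

Conventions
-----------
* Genomic positions are 1-based inclusive in every file that is read or
  written; internal interval arithmetic is half-open ``[start, end)``.
* Haplotypes are indexed ``j in {0, 1}`` internally and ``{1, 2}`` in
  emitted tables (matching hap-IBD).
* Missing alleles are encoded as ``-1`` in allele matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

IBD_COLUMNS = ["sample1", "hap1", "sample2", "hap2", "chrom", "start", "end", "length_cm"]


class GeneticMap:
    """Monotone piecewise-linear bp -> cM map for one chromosome."""

    def __init__(self, bp: np.ndarray, cm: np.ndarray):
        bp = np.asarray(bp, dtype=np.float64)
        cm = np.asarray(cm, dtype=np.float64)
        if bp.ndim != 1 or bp.shape != cm.shape or bp.size < 2:
            raise ValueError("genetic map needs >= 2 (bp, cM) points of equal length")
        if np.any(np.diff(bp) <= 0):
            raise ValueError("genetic map bp positions must be strictly increasing")
        if np.any(np.diff(cm) < 0):
            raise ValueError("genetic map cM values must be non-decreasing")
        self.bp = bp
        self.cm = cm

    @classmethod
    def uniform(cls, length_bp: int, cm_per_mb: float = 1.0) -> "GeneticMap":
        """Constant-rate map over ``[1, length_bp]``."""
        ends = np.array([1.0, float(length_bp)])
        return cls(ends, (ends - 1.0) * cm_per_mb / 1e6)

    @property
    def length_cm(self) -> float:
        return float(self.cm[-1] - self.cm[0])

    def bp_to_cm(self, bp) -> np.ndarray:
        return np.interp(np.asarray(bp, dtype=np.float64), self.bp, self.cm)

    def cm_to_bp(self, cm) -> np.ndarray:
        return np.interp(np.asarray(cm, dtype=np.float64), self.cm, self.bp)


@dataclass
class PhasedHaplotypeSet:
    """Phased biallelic genotypes: allele matrix indexed (sample, haplotype, variant)."""

    samples: list[str]
    chrom: str
    positions: np.ndarray  # (m,) int64, strictly increasing, 1-based
    ref: list[str]
    alt: list[str]
    alleles: np.ndarray  # (n, 2, m) int8 in {0, 1, MISSING}

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        n, two, m = self.alleles.shape
        if two != 2:
            raise ValueError("allele matrix must have haplotype axis of size 2")
        if n != len(self.samples) or m != self.positions.size:
            raise ValueError("allele matrix shape inconsistent with samples/positions")
        if self.positions.size > 1 and np.any(np.diff(self.positions) <= 0):
            raise ValueError("variant positions must be strictly increasing")
        bad = ~np.isin(self.alleles, [0, 1, MISSING])
        if bad.any():
            raise ValueError("alleles must be 0, 1 or missing (-1)")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return int(self.positions.size)

    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Naive per-variant (AC, AN) over non-missing haplotype alleles."""
        obs = self.alleles != MISSING
        ac = np.where(obs, self.alleles, 0).sum(axis=(0, 1))
        an = obs.sum(axis=(0, 1))
        return ac.astype(np.int64), an.astype(np.int64)

    def subset_samples(self, keep: list[str]) -> "PhasedHaplotypeSet":
        idx = [self.samples.index(s) for s in keep]
        return PhasedHaplotypeSet(
            samples=list(keep), chrom=self.chrom, positions=self.positions.copy(),
            ref=list(self.ref), alt=list(self.alt), alleles=self.alleles[idx].copy(),
        )


@dataclass
class LocalAncestryField:
    """Per-haplotype ancestry probability vectors at sorted anchor positions."""

    ancestries: list[str]
    anchors: np.ndarray  # (A,) int64 bp, sorted ascending
    probs: np.ndarray  # (n, 2, A, K) float64, rows sum to 1

    def __post_init__(self):
        self.anchors = np.asarray(self.anchors, dtype=np.int64)
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if len(self.ancestries) < 2:
            raise ValueError("need at least two ancestries")
        if self.probs.shape[-1] != len(self.ancestries):
            raise ValueError("probability vectors do not match ancestry count")
        if self.probs.shape[2] != self.anchors.size:
            raise ValueError("probability array does not match anchor count")
        if self.anchors.size > 1 and np.any(np.diff(self.anchors) < 0):
            raise ValueError("anchors must be sorted")
        sums = self.probs.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("ancestry probabilities must sum to 1 at every anchor")

    @property
    def K(self) -> int:
        return len(self.ancestries)

    @property
    def n_samples(self) -> int:
        return self.probs.shape[0]


class IBDSegmentSet:
    """Haplotype-pair shared segments with bp and cM extents.

    Stored as a DataFrame with columns ``sample1 hap1 sample2 hap2 chrom
    start end length_cm``; the unordered pair key is canonicalized so
    ``(sample1, hap1) <= (sample2, hap2)`` lexicographically.
    """

    def __init__(self, df: pd.DataFrame):
        missing = set(IBD_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"IBD table missing columns: {sorted(missing)}")
        df = df[IBD_COLUMNS].copy()
        if len(df):
            if (df["start"] >= df["end"]).any():
                raise ValueError("IBD segments require start < end")
            if (df["length_cm"] <= 0).any():
                raise ValueError("IBD segments require positive cM length")
            flip = (df["sample1"].astype(str) > df["sample2"].astype(str)) | (
                (df["sample1"].astype(str) == df["sample2"].astype(str))
                & (df["hap1"] > df["hap2"])
            )
            for a, b in (("sample1", "sample2"), ("hap1", "hap2")):
                av, bv = df.loc[flip, a].copy(), df.loc[flip, b].copy()
                df.loc[flip, a], df.loc[flip, b] = bv, av
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def segments_covering(self, pos: int) -> pd.DataFrame:
        """Segments whose half-open [start, end) interval contains pos."""
        d = self.df
        return d[(d["start"] <= pos) & (pos < d["end"])]

    def pair_totals(self) -> pd.DataFrame:
        """Total cM shared per unordered *sample* pair (haplotype pairs pooled)."""
        d = self.df.copy()
        s1 = d[["sample1", "sample2"]].min(axis=1)
        s2 = d[["sample1", "sample2"]].max(axis=1)
        tot = (
            pd.DataFrame({"sample1": s1, "sample2": s2, "length_cm": d["length_cm"]})
            .groupby(["sample1", "sample2"], as_index=False)["length_cm"].sum()
        )
        return tot


@dataclass
class AncestryFrequencyTable:
    """Per-variant overall and per-ancestry weighted allele counts.

    ``theta`` is NaN where the corresponding AN_k is zero (frequency
    undefined in an ancestry with no probability mass at the site).
    """

    ancestries: list[str]
    ac: np.ndarray  # (m,) overall ALT allele count
    an: np.ndarray  # (m,) overall non-missing allele number
    ac_k: np.ndarray  # (m, K) weighted ALT counts
    an_k: np.ndarray  # (m, K) weighted allele numbers

    def __post_init__(self):
        self.ac = np.asarray(self.ac, dtype=np.float64)
        self.an = np.asarray(self.an, dtype=np.float64)
        self.ac_k = np.asarray(self.ac_k, dtype=np.float64)
        self.an_k = np.asarray(self.an_k, dtype=np.float64)
        if self.ac_k.shape != self.an_k.shape or self.ac_k.shape[1] != len(self.ancestries):
            raise ValueError("per-ancestry count arrays inconsistent")

    @property
    def theta(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = self.ac_k / self.an_k
        return np.where(self.an_k > 0, t, np.nan)

    @property
    def n_k(self) -> np.ndarray:
        """Effective diploid sample size per ancestry, AN_k / 2."""
        return self.an_k / 2.0

    @property
    def af(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            f = self.ac / self.an
        return np.where(self.an > 0, f, np.nan)

    def validate_conservation(self, atol: float = 1e-6) -> None:
        """Sum of per-ancestry counts must reproduce overall counts."""
        if not np.allclose(self.ac_k.sum(axis=1), self.ac, atol=atol):
            raise AssertionError("sum_k AC_k != AC")
        if not np.allclose(self.an_k.sum(axis=1), self.an, atol=atol):
            raise AssertionError("sum_k AN_k != AN")


@dataclass
class PedigreeSpec:
    """Pedigree as a table of (id, sex, father, mother); founders have no parents.

    ``sex`` is "M"/"F"; father/mother are ``None`` for founders.  The
    individual list must be topologically ordered (parents precede
    children) and acyclic.
    """

    individuals: list[str]
    sex: dict[str, str] = field(default_factory=dict)
    father: dict[str, str | None] = field(default_factory=dict)
    mother: dict[str, str | None] = field(default_factory=dict)

    def __post_init__(self):
        seen: set[str] = set()
        for ind in self.individuals:
            f, m = self.father.get(ind), self.mother.get(ind)
            if (f is None) != (m is None):
                raise ValueError(f"{ind}: must have both parents or neither")
            for p in (f, m):
                if p is not None and p not in seen:
                    raise ValueError(f"{ind}: parent {p} not defined before child")
            if f is not None:
                if self.sex.get(f) == "F" or self.sex.get(m) == "M":
                    raise ValueError(f"{ind}: parental sexes inconsistent")
            seen.add(ind)

    @property
    def founders(self) -> list[str]:
        return [i for i in self.individuals if self.father.get(i) is None]

    @property
    def nonfounders(self) -> list[str]:
        return [i for i in self.individuals if self.father.get(i) is not None]

    def kinship_matrix(self) -> pd.DataFrame:
        """Recursive kinship coefficients phi for all pairs."""
        ids = self.individuals
        idx = {s: i for i, s in enumerate(ids)}
        n = len(ids)
        phi = np.zeros((n, n))
        for a_i, a in enumerate(ids):
            f, m = self.father.get(a), self.mother.get(a)
            if f is None:
                phi[a_i, a_i] = 0.5
            else:
                phi[a_i, a_i] = 0.5 * (1 + phi[idx[f], idx[m]])
            for b_i in range(a_i):
                if f is None:
                    # a is a founder: unrelated to everyone defined before it
                    val = 0.0
                else:
                    val = 0.5 * (phi[idx[f], b_i] + phi[idx[m], b_i])
                phi[a_i, b_i] = phi[b_i, a_i] = val
        return pd.DataFrame(phi, index=ids, columns=ids)

    def relatedness_degrees(self, max_degree: int = 3) -> pd.DataFrame:
        """Pairs with relationship degree <= max_degree.

        Degree d corresponds to kinship ~ 2^-(d+1); pairs are binned by
        rounding -log2(2*phi) to the nearest integer (0 = duplicates/MZ).
        """
        phi = self.kinship_matrix().to_numpy()
        ids = self.individuals
        rows = []
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if phi[i, j] <= 0:
                    continue
                degree = int(round(-np.log2(2.0 * phi[i, j])))
                if degree <= max_degree:
                    rows.append((ids[i], ids[j], degree))
        return pd.DataFrame(rows, columns=["sample1", "sample2", "degree"])
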