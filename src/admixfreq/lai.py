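"""Ancestry-specific allele frequencies from interpolated local ancestry.

Local ancestry is called at sparse "array" anchor sites; sequence
variants between anchors receive probability vectors by linear
interpolation in base-pair position.  With ``p_ijk`` the probability
that haplotype ``j`` of individual ``i`` carries ancestry ``k`` at a
site and ``G_ij`` the 0/1 ALT indicator, the ancestry-resolved counts
are

    AC_k = sum_ij p_ijk G_ij,   AN_k = sum_ij p_ijk,   theta_k = AC_k / AN_k

and the effective diploid sample size is ``n_k = AN_k / 2``.  Singleton
alleles that sit in a stretch of heterozygous ancestry (the carrier's
two haplotypes have different most-probable ancestries) are phased
unreliably; under the default "equal-weight" policy the carrying
allele's vector is replaced by the average of the carrier's two
haplotype vectors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import MISSING, AncestryFrequencyTable, LocalAncestryField, PhasedHaplotypeSet


def interpolate_field(lai: LocalAncestryField, positions: np.ndarray) -> np.ndarray:
    """Ancestry probabilities linearly interpolated (in bp) at query positions.

    Returns an array of shape (n, 2, M, K).  Queries at an anchor return
    the anchor vector; queries beyond the first/last anchor are clamped
    to the nearest anchor vector.  Each output vector is a convex
    combination of the two flanking anchor vectors, hence sums to 1.
    """
    anchors = lai.anchors
    if anchors.size == 0:
        raise ValueError("no anchors available for interpolation")
    q = np.asarray(positions, dtype=np.float64)
    right = np.searchsorted(anchors, q, side="left")
    left = np.clip(right - 1, 0, anchors.size - 1)
    right = np.clip(right, 0, anchors.size - 1)
    at_anchor = (right < anchors.size) & (anchors[right] == q)
    left = np.where(at_anchor, right, left)
    span = (anchors[right] - anchors[left]).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(span > 0, (q - anchors[left]) / np.where(span > 0, span, 1.0), 0.0)
    w = np.clip(w, 0.0, 1.0)
    pl = lai.probs[:, :, left, :]
    pr = lai.probs[:, :, right, :]
    return (1.0 - w[None, None, :, None]) * pl + w[None, None, :, None] * pr


def interpolate_ancestry(
    lai: LocalAncestryField, position: int, individual: int, haplotype: int
) -> np.ndarray:
    """Single-query convenience wrapper around :func:`interpolate_field`."""
    return interpolate_field(lai, np.array([position]))[individual, haplotype, 0]


def flag_het_ancestry_singletons(
    haps: PhasedHaplotypeSet, probs: np.ndarray
) -> pd.DataFrame:
    """Identify cohort singletons and whether they lie in heterozygous ancestry.

    ``probs`` is the (n, 2, M, K) interpolated field.  A singleton is a
    variant with exactly one ALT allele cohort-wide; it is het-ancestry
    when the argmax ancestries of the carrier's two haplotype vectors
    differ (argmax ties resolve to the lower ancestry index).
    """
    ac, _ = haps.allele_counts()
    is_singleton = ac == 1
    m = haps.n_variants
    carrier = np.full(m, -1, dtype=np.int64)
    carrier_hap = np.full(m, -1, dtype=np.int64)
    het_anc = np.zeros(m, dtype=bool)
    for v in np.flatnonzero(is_singleton):
        i, j = [int(x[0]) for x in np.nonzero(haps.alleles[:, :, v] == 1)]
        carrier[v], carrier_hap[v] = i, j
        a0 = int(np.argmax(probs[i, 0, v]))
        a1 = int(np.argmax(probs[i, 1, v]))
        het_anc[v] = a0 != a1
    return pd.DataFrame(
        {
            "variant": np.arange(m),
            "is_singleton": is_singleton,
            "carrier": carrier,
            "carrier_hap": carrier_hap,
            "het_ancestry": het_anc,
        }
    )


def compute_ancestry_frequencies(
    haps: PhasedHaplotypeSet,
    probs: np.ndarray,
    ancestries: list[str],
    singleton_policy: str = "equal-weight",
    flags: pd.DataFrame | None = None,
) -> AncestryFrequencyTable:
    """Weighted allele counts AC_k, AN_k and frequencies theta_k per variant.

    Missing alleles contribute to neither AC_k nor AN_k.  Under the
    "equal-weight" singleton policy, a het-ancestry singleton's carrying
    haplotype uses the average of the carrier's two haplotype vectors;
    "haplotype" keeps every haplotype's own vector.
    """
    if singleton_policy not in ("equal-weight", "haplotype"):
        raise ValueError("singleton_policy must be 'equal-weight' or 'haplotype'")
    n, _, m = haps.alleles.shape
    if probs.shape[:3] != (n, 2, m):
        raise ValueError("interpolated probabilities do not match haplotype set")
    obs = haps.alleles != MISSING
    weights = np.where(obs[..., None], probs, 0.0)

    if singleton_policy == "equal-weight":
        if flags is None:
            flags = flag_het_ancestry_singletons(haps, probs)
        sel = flags[flags["is_singleton"] & flags["het_ancestry"]]
        if len(sel):
            weights = weights.copy()
            for r in sel.itertuples(index=False):
                i, j, v = int(r.carrier), int(r.carrier_hap), int(r.variant)
                if obs[i, 0, v] and obs[i, 1, v]:
                    weights[i, j, v] = 0.5 * (probs[i, 0, v] + probs[i, 1, v])

    alt = (haps.alleles == 1)[..., None]
    ac_k = np.where(alt, weights, 0.0).sum(axis=(0, 1))
    an_k = weights.sum(axis=(0, 1))
    ac, an = haps.allele_counts()
    return AncestryFrequencyTable(list(ancestries), ac.astype(float), an.astype(float), ac_k, an_k)


def ancestry_frequency_pipeline(
    haps: PhasedHaplotypeSet,
    lai: LocalAncestryField,
    singleton_policy: str = "equal-weight",
    subset: list[str] | None = None,
) -> AncestryFrequencyTable:
    """Interpolate anchors to variant positions and compute the table."""
    if subset is not None:
        idx = [haps.samples.index(s) for s in subset]
        lai = LocalAncestryField(list(lai.ancestries), lai.anchors, lai.probs[idx])
        haps = haps.subset_samples(subset)
    probs = interpolate_field(lai, haps.positions)
    return compute_ancestry_frequencies(haps, probs, list(lai.ancestries), singleton_policy)
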