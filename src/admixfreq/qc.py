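"""Hard variant filters: missingness, Mendel errors, HWE excess heterozygosity.

A variant fails when it is monomorphic, has genotype missingness above
10%, shows >= 3 Mendel errors across trios, or fails the exact
Hardy-Weinberg test in the excess-heterozygosity direction (one-sided
P < 1e-30 together with an observed het count above 1.5x the HWE
expectation).  An externally supplied duplicate list can also be
flagged.  Filters are order-independent and idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .types import MISSING, PhasedHaplotypeSet

DEFAULT_THRESHOLDS = {
    "missingness": 0.10,
    "mendel": 3,
    "hwe_p": 1e-30,
    "het_ratio": 1.5,
}


@dataclass
class GenotypeCounts:
    """Diploid genotype counts at one variant."""

    n_homref: int
    n_het: int
    n_homalt: int
    n_missing: int = 0

    @property
    def n_called(self) -> int:
        return self.n_homref + self.n_het + self.n_homalt

    @property
    def ac(self) -> int:
        return self.n_het + 2 * self.n_homalt


def genotype_counts(haps: PhasedHaplotypeSet) -> list[GenotypeCounts]:
    """Per-variant genotype counts; genotypes with any missing allele count as missing."""
    a = haps.alleles
    missing = (a == MISSING).any(axis=1)  # (n, m)
    gt = a.sum(axis=1)  # (n, m) in {0,1,2} where called
    out = []
    for v in range(haps.n_variants):
        called = ~missing[:, v]
        g = gt[called, v]
        out.append(
            GenotypeCounts(
                int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum()),
                int(missing[:, v].sum()),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Mendel errors

# genotype -> set of transmissible alleles
_TRANSMIT = {0: (0,), 1: (0, 1), 2: (1,)}


def count_mendel_errors(
    gt: np.ndarray, trios: list[tuple[int, int, int]]
) -> np.ndarray:
    """Per-variant count of Mendelian-impossible child genotypes.

    ``gt`` is (n_samples, m) with values {0, 1, 2} and negative for
    missing; ``trios`` holds (father, mother, child) sample indices.
    Trios with any missing member at a variant contribute no error.
    """
    gt = np.asarray(gt)
    m = gt.shape[1]
    errors = np.zeros(m, dtype=np.int64)
    for fa, mo, ch in trios:
        gf, gm, gc = gt[fa], gt[mo], gt[ch]
        ok = (gf >= 0) & (gm >= 0) & (gc >= 0)
        for v in np.flatnonzero(ok):
            possible = {
                a + b for a in _TRANSMIT[int(gf[v])] for b in _TRANSMIT[int(gm[v])]
            }
            if int(gc[v]) not in possible:
                errors[v] += 1
    return errors


# ---------------------------------------------------------------------------
# exact HWE


def hwe_excess_het_test(
    counts: GenotypeCounts, het_ratio: float = 1.5, two_sided: bool = False
) -> tuple[float, bool]:
    """Exact HWE heterozygote-count test, excess-het tail.

    Returns ``(p, excess_flag)`` where ``p`` is the one-sided
    P(het >= observed) under the exact conditional distribution of the
    heterozygote count given the allele counts (Levene/Haldane), and the
    flag marks observed het > ``het_ratio`` x the HWE-expected het
    count.  ``two_sided`` instead sums all outcomes no more probable
    than the observed one.  Monomorphic input returns p = 1.
    """
    n = counts.n_called
    if n < 1:
        raise ValueError("need at least one called genotype")
    ac = counts.ac
    na = min(ac, 2 * n - ac)  # minor allele count
    if na == 0:
        return 1.0, False
    # support: het counts with the parity of na
    hets = np.arange(na % 2, na + 1, 2)
    hom_rare = (na - hets) // 2
    hom_common = n - hets - hom_rare
    valid = hom_common >= 0
    hets, hom_rare, hom_common = hets[valid], hom_rare[valid], hom_common[valid]
    logp = (
        hets * np.log(2.0)
        - gammaln(hom_rare + 1)
        - gammaln(hom_common + 1)
        - gammaln(hets + 1)
    )
    logp -= logsumexp(logp)
    obs = counts.n_het
    if two_sided:
        p = float(np.exp(logsumexp(logp[logp <= logp[hets == obs][0] + 1e-12])))
    else:
        p = float(np.exp(logsumexp(logp[hets >= obs])))
    p = min(1.0, p)
    p_hat = ac / (2.0 * n)
    expected_het = 2.0 * n * p_hat * (1.0 - p_hat)
    excess = obs > het_ratio * expected_het
    return p, excess


# ---------------------------------------------------------------------------
# verdicts


def apply_hard_filters(
    counts: list[GenotypeCounts],
    mendel_errors: np.ndarray | None = None,
    duplicates: set[int] | None = None,
    thresholds: dict | None = None,
) -> pd.DataFrame:
    """Per-variant pass/fail verdicts with all triggered reasons.

    Reasons: ``monomorphic``, ``missingness`` (> 10%), ``mendel``
    (>= 3 errors), ``hwe_excess_het`` (exact P < 1e-30 and observed het
    > 1.5x expected), ``duplicate`` (external list).
    """
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    rows = []
    for v, c in enumerate(counts):
        reasons = []
        total = c.n_called + c.n_missing
        if c.ac == 0 or c.ac == 2 * c.n_called:
            reasons.append("monomorphic")
        if total and c.n_missing / total > th["missingness"]:
            reasons.append("missingness")
        if mendel_errors is not None and mendel_errors[v] >= th["mendel"]:
            reasons.append("mendel")
        if c.n_called:
            p, excess = hwe_excess_het_test(c, het_ratio=th["het_ratio"])
            if p < th["hwe_p"] and excess:
                reasons.append("hwe_excess_het")
        if duplicates and v in duplicates:
            reasons.append("duplicate")
        rows.append({"variant": v, "pass": not reasons, "reasons": reasons})
    return pd.DataFrame(rows)
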