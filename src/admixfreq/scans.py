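"""Genome-wide local-ancestry deviation scan, sex-biased admixture
solver and the imputation-accuracy metric.

The deviation scan compares the local mean ancestry dosage at each
position with a robust genome-wide proportion (Tukey's biweight mean
over positions), under binomial sampling of ``N_hap`` haplotypes and a
normal approximation for the sample mean; significance is assessed at
a Bonferroni threshold alpha / (n_positions x K).

The sex-bias solver inverts a single-pulse admixture model relating
autosomal and X-chromosome ancestry proportions to female and male
founding contributions ``s_f, s_m``: autosomes carry ``(s_f + s_m)/2``
and the X (two-thirds of copies spent in females) carries
``(2 s_f + s_m)/3``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def tukey_biweight_mean(
    values, c: float = 9.0, tol: float = 1e-10, max_iter: int = 50
) -> float:
    """Tukey biweight (bisquare) robust location with MAD scale.

    Observations farther than ``c`` MAD-scaled units from the current
    center get zero weight.  Degenerate samples with MAD 0 return the
    median directly.
    """
    x = np.asarray(values, dtype=np.float64)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("need at least one finite value")
    center = float(np.median(x))
    scale = float(stats.median_abs_deviation(x))
    if scale == 0.0:
        return center
    for _ in range(max_iter):
        u = (x - center) / (c * scale)
        w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        if w.sum() == 0:
            break
        new = float(np.sum(w * x) / np.sum(w))
        if abs(new - center) < tol:
            center = new
            break
        center = new
    return center


@dataclass
class ScanResult:
    """Per-(position, ancestry) deviation test results."""

    table: pd.DataFrame  # columns: position, ancestry, local_mean, global_mean, z, p, significant
    p0: np.ndarray  # (K,) robust global proportions
    threshold: float


def ancestry_deviation_scan(
    local_means: np.ndarray,
    n_haplotypes: int,
    alpha: float = 0.05,
    ancestries: list[str] | None = None,
    positions: np.ndarray | None = None,
) -> ScanResult:
    """Two-sided z test of local vs robust global ancestry proportion.

    ``local_means`` is (n_positions, K) mean ancestry dosages over
    unrelated haplotypes.  For each ancestry the global proportion p0 is
    the Tukey biweight mean over positions, the statistic is

        z = (p_l - p0) / sqrt(p0 (1 - p0) / N_hap)

    and the Bonferroni threshold is alpha / (n_positions x K).
    Ancestries with degenerate p0 in {0, 1} are emitted as missing.
    """
    local_means = np.atleast_2d(np.asarray(local_means, dtype=np.float64))
    n_pos, K = local_means.shape
    if ancestries is None:
        ancestries = [f"POP{k}" for k in range(K)]
    if positions is None:
        positions = np.arange(n_pos)
    threshold = alpha / (n_pos * K)
    p0 = np.array([tukey_biweight_mean(local_means[:, k]) for k in range(K)])
    rows = []
    for k in range(K):
        if p0[k] <= 0.0 or p0[k] >= 1.0:
            z = np.full(n_pos, np.nan)
            p = np.full(n_pos, np.nan)
        else:
            se = np.sqrt(p0[k] * (1.0 - p0[k]) / n_haplotypes)
            z = (local_means[:, k] - p0[k]) / se
            p = 2.0 * stats.norm.sf(np.abs(z))
            p = np.clip(p, np.finfo(float).tiny, 1.0)
        rows.append(
            pd.DataFrame(
                {
                    "position": positions,
                    "ancestry": ancestries[k],
                    "local_mean": local_means[:, k],
                    "global_mean": p0[k],
                    "z": z,
                    "p": p,
                    "significant": p <= threshold,
                }
            )
        )
    return ScanResult(pd.concat(rows, ignore_index=True), p0, threshold)


def bonferroni_threshold(alpha: float, n_positions: int, K: int) -> float:
    """alpha / (n_positions x K)."""
    return alpha / (n_positions * K)


# ---------------------------------------------------------------------------
# sex-biased admixture


@dataclass
class SexBiasEstimate:
    """Founding female/male contributions for one ancestry."""

    ancestry: str
    h_autosome: float
    h_x: float
    s_f: float
    s_m: float
    female_fraction: float
    out_of_range: bool


def sex_bias_forward(s_f: float, s_m: float) -> tuple[float, float]:
    """Autosomal and X ancestry proportions implied by (s_f, s_m)."""
    return (s_f + s_m) / 2.0, (2.0 * s_f + s_m) / 3.0


def solve_sex_biased_contributions(
    h_autosome, h_x, ancestries: list[str] | None = None
) -> list[SexBiasEstimate]:
    """Invert the single-pulse model: s_f = 3 H_X - 2 H_A, s_m = 4 H_A - 3 H_X.

    The female fraction of an ancestry's total contribution is
    s_f / (s_f + s_m) = s_f / (2 H_A), undefined when H_A = 0.
    Solutions outside [0, 1] are returned with a warning flag — they
    indicate the single-pulse model cannot represent the inputs.
    """
    h_a = np.atleast_1d(np.asarray(h_autosome, dtype=np.float64))
    h_xv = np.atleast_1d(np.asarray(h_x, dtype=np.float64))
    if h_a.shape != h_xv.shape:
        raise ValueError("H_A and H_X must have matching shapes")
    if ancestries is None:
        ancestries = [f"POP{k}" for k in range(h_a.size)]
    out = []
    for k in range(h_a.size):
        s_f = 3.0 * h_xv[k] - 2.0 * h_a[k]
        s_m = 4.0 * h_a[k] - 3.0 * h_xv[k]
        frac = s_f / (2.0 * h_a[k]) if h_a[k] > 0 else float("nan")
        flag = not (0.0 <= s_f <= 1.0 and 0.0 <= s_m <= 1.0)
        out.append(
            SexBiasEstimate(ancestries[k], float(h_a[k]), float(h_xv[k]),
                            float(s_f), float(s_m), float(frac), flag)
        )
    return out


# ---------------------------------------------------------------------------
# imputation accuracy


def imputation_r2_by_maf(
    true_genotypes: np.ndarray,
    imputed_dosages: np.ndarray,
    maf: np.ndarray,
    bin_edges,
) -> pd.DataFrame:
    """Squared correlation between concatenated truth and dosages per MAF bin.

    ``true_genotypes`` and ``imputed_dosages`` are (n_samples,
    n_variants); ``maf`` assigns each variant to a bin (computed in a
    designated reference sample set).  Entries where either value is NaN
    are dropped; bins with a zero-variance concatenated vector yield NaN.
    """
    g = np.asarray(true_genotypes, dtype=np.float64)
    d = np.asarray(imputed_dosages, dtype=np.float64)
    if g.shape != d.shape:
        raise ValueError("genotype and dosage matrices must align")
    maf = np.asarray(maf, dtype=np.float64)
    edges = np.asarray(list(bin_edges), dtype=np.float64)
    rows = []
    for b in range(edges.size - 1):
        lo, hi = edges[b], edges[b + 1]
        sel = np.flatnonzero((maf >= lo) & (maf < hi))
        r2 = np.nan
        n_pairs = 0
        if sel.size:
            gv = g[:, sel].ravel()
            dv = d[:, sel].ravel()
            ok = np.isfinite(gv) & np.isfinite(dv)
            gv, dv = gv[ok], dv[ok]
            n_pairs = int(gv.size)
            if gv.size >= 2 and np.std(gv) > 0 and np.std(dv) > 0:
                r2 = float(np.corrcoef(gv, dv)[0, 1] ** 2)
        rows.append({"maf_lo": lo, "maf_hi": hi, "n_variants": int(sel.size),
                     "n_pairs": n_pairs, "r2": r2})
    return pd.DataFrame(rows)
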