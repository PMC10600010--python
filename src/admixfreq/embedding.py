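"""Low-dimensional embedding of the IBD-sharing network.

Pairwise IBD segment lengths are summed into a symmetric weight matrix
``W`` (``w_ij`` = total cM shared by samples i and j).  Edges heavier
than 72 cM are removed so that extended families do not dominate the
picture, the largest connected component is extracted, and coordinates
come from the bottom eigenvectors of the normalized (random-walk) graph
Laplacian ``L = I - D^{-1} W`` — equivalently from the generalized
eigenproblem ``W u = mu D u`` with ``mu = 1 - lambda``.

For numerical stability the solver works on the symmetric form
``D^{-1/2} W D^{-1/2}`` and back-transforms the eigenvectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csgraph

from .types import IBDSegmentSet

DEFAULT_MAX_EDGE_CM = 72.0


@dataclass
class IBDNetwork:
    """Symmetric nonnegative IBD weight matrix with sample labels."""

    samples: list[str]
    W: np.ndarray  # (n, n) float, zero diagonal

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=np.float64)
        n = len(self.samples)
        if self.W.shape != (n, n):
            raise ValueError("weight matrix shape does not match sample count")
        if not np.allclose(self.W, self.W.T):
            raise ValueError("weight matrix must be symmetric")
        if (self.W < 0).any():
            raise ValueError("weights must be nonnegative")
        if np.any(np.diagonal(self.W) != 0):
            raise ValueError("diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def degrees(self) -> np.ndarray:
        return self.W.sum(axis=1)


@dataclass
class EmbeddingResult:
    """Eigenvalues of L (ascending), generalized eigenvalues and coordinates."""

    samples: list[str]
    eigenvalues: np.ndarray  # (p + 1,) lambda_0 <= ... <= lambda_p
    coords: np.ndarray  # (n, p) columns u_1..u_p (constant u_0 excluded)

    @property
    def generalized_eigenvalues(self) -> np.ndarray:
        """mu = 1 - lambda, eigenvalues of W u = mu D u."""
        return 1.0 - self.eigenvalues


def build_ibd_weight_matrix(
    segs: IBDSegmentSet,
    samples: list[str] | None = None,
    max_edge_cm: float = DEFAULT_MAX_EDGE_CM,
) -> IBDNetwork:
    """Sum per-pair segment cM into W; zero out edges heavier than the cap.

    Both haplotype combinations of a sample pair pool into one weight.
    ``samples`` fixes vertex order (default: sorted union of samples in
    the segment table).
    """
    totals = segs.pair_totals()
    if samples is None:
        samples = sorted(set(totals["sample1"]) | set(totals["sample2"]))
    idx = {s: i for i, s in enumerate(samples)}
    n = len(samples)
    W = np.zeros((n, n))
    for r in totals.itertuples(index=False):
        i, j = idx.get(r.sample1), idx.get(r.sample2)
        if i is None or j is None or i == j:
            continue
        w = float(r.length_cm)
        if w > max_edge_cm:
            continue  # heavy edges (close relatives) are removed entirely
        W[i, j] = W[j, i] = w
    return IBDNetwork(list(samples), W)


def connected_components(net: IBDNetwork) -> np.ndarray:
    """Component label per vertex (scipy connected-components on W > 0)."""
    n_comp, labels = csgraph.connected_components((net.W > 0).astype(np.int8), directed=False)
    return labels


def largest_connected_component(net: IBDNetwork) -> tuple[IBDNetwork, np.ndarray]:
    """Restrict to the largest component; ties go to the lowest-index vertex.

    Returns the restricted network and the original indices retained.
    """
    if net.n == 0:
        raise ValueError("empty network")
    labels = connected_components(net)
    sizes = np.bincount(labels)
    best = sizes.max()
    # among equally large components, pick the one containing the smallest index
    winner = next(lab for lab in labels if sizes[lab] == best)
    keep = np.flatnonzero(labels == winner)
    sub = IBDNetwork([net.samples[i] for i in keep], net.W[np.ix_(keep, keep)])
    return sub, keep


def spectral_embed(net: IBDNetwork, p: int = 20) -> EmbeddingResult:
    """Bottom-``p`` nontrivial eigenvectors of the normalized Laplacian.

    Requires a connected network with positive degrees and ``p < n``.
    Eigenvector signs are fixed so each vector's largest-magnitude entry
    is positive; the solution satisfies ``W u = (1 - lambda) D u`` to
    1e-6 relative residual.
    """
    n = net.n
    if p < 1 or p >= n:
        raise ValueError("need 1 <= p < n")
    d = net.degrees
    if (d <= 0).any():
        raise ValueError("isolated vertex (zero degree) in network")
    labels = connected_components(net)
    if labels.max() > 0:
        raise ValueError("network is disconnected; embed the largest component")

    d_isqrt = 1.0 / np.sqrt(d)
    S = net.W * d_isqrt[:, None] * d_isqrt[None, :]
    # dense symmetric solve: we only need the top p+1 eigenpairs of S
    mu, V = np.linalg.eigh(S)
    mu, V = mu[::-1][: p + 1], V[:, ::-1][:, : p + 1]  # mu descending = lambda ascending
    lam = 1.0 - mu
    U = d_isqrt[:, None] * V
    # normalize and fix signs deterministically
    U = U / np.linalg.norm(U, axis=0, keepdims=True)
    flip = U[np.abs(U).argmax(axis=0), np.arange(U.shape[1])] < 0
    U[:, flip] *= -1.0

    D = np.diag(d)
    for c in range(p + 1):
        resid = np.linalg.norm(net.W @ U[:, c] - mu[c] * (D @ U[:, c]))
        if resid > 1e-6 * np.linalg.norm(U[:, c]) * max(1.0, d.max()):
            raise ArithmeticError("generalized eigenproblem residual too large")
    return EmbeddingResult(list(net.samples), lam, U[:, 1:])


def laplacian_zero_multiplicity(net: IBDNetwork, tol: float = 1e-8) -> int:
    """Multiplicity of eigenvalue 0 of L = I - D^{-1}W (isolated vertices count)."""
    d = net.degrees
    iso = int((d == 0).sum())
    keep = np.flatnonzero(d > 0)
    if keep.size == 0:
        return iso
    W = net.W[np.ix_(keep, keep)]
    d_isqrt = 1.0 / np.sqrt(d[keep])
    S = W * d_isqrt[:, None] * d_isqrt[None, :]
    lam = 1.0 - np.linalg.eigvalsh(S)
    return iso + int((np.abs(lam) < tol).sum())
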