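"""Nonlinear embeddings of epoch matrices and epoch-count decimation.

Three manifold-learning methods operate on the raw per-epoch sample
vectors: locally linear embedding (LLE), diffusion maps (DM) and
Laplacian eigenmaps (LE).  Before embedding, the pipeline thins the
epoch population roughly twenty-fold (every 20th epoch is kept), which
is the bookkeeping that takes e.g. 43333 VT epochs down to 2167.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import eigsh
from sklearn.neighbors import NearestNeighbors

from ecgdetect.epochs import EpochMatrix

DECIMATION_BLOCK = 20


@dataclass
class LLEParams:
    k_neighbors: int = 12
    target_dim: int = 10
    regularizer: float = 1e-3

    def __post_init__(self) -> None:
        if self.k_neighbors < self.target_dim + 1:
            raise ValueError(
                f"k_neighbors={self.k_neighbors} must be >= target_dim+1="
                f"{self.target_dim + 1}"
            )


@dataclass
class DMParams:
    sigma: float | None = None  # None = median pairwise distance
    t: int = 1
    h: int = 10

    def __post_init__(self) -> None:
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.t < 1:
            raise ValueError("diffusion time t must be >= 1")
        if self.h < 1:
            raise ValueError("h must be >= 1")


@dataclass
class LEParams:
    m_neighbors: int = 12
    sigma: float | None = None  # None = median pairwise distance
    target_dim: int = 10

    def __post_init__(self) -> None:
        if self.m_neighbors < 1:
            raise ValueError("m_neighbors must be >= 1")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class EmbeddingResult:
    """Low-dimensional coordinates per retained epoch.

    coords: (n, target_dim); method: LLE | DM | LE; params: the method
    parameter object actually used (kernel widths resolved); labels and
    source_epoch_ids index back into the input EpochMatrix.
    """

    coords: np.ndarray
    method: str
    params: object
    labels: np.ndarray
    source_epoch_ids: np.ndarray
    extras: dict = field(default_factory=dict)


def decimate_epoch_count(n_epochs: int) -> int:
    """Epoch count after the ~20x thinning: ceil(n / 20)."""
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    return -(-n_epochs // DECIMATION_BLOCK)


def decimate_epochs(epochs: EpochMatrix) -> EpochMatrix:
    """Keep the first epoch of every block of 20, per class.

    The retained count per class equals ``decimate_epoch_count`` of the
    class's epoch count.
    """
    keep = np.zeros(epochs.n_epochs, dtype=bool)
    for lab in dict.fromkeys(epochs.labels):
        idx = np.flatnonzero(epochs.labels == lab)
        keep[idx[::DECIMATION_BLOCK]] = True
    return epochs.subset(np.flatnonzero(keep), note="decimated 1-in-20")


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Make the first nonzero entry of each column positive (reproducibility)."""
    v = vectors.copy()
    for j in range(v.shape[1]):
        col = v[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if len(nz) and col[nz[0]] < 0:
            v[:, j] = -col
    return v


def _median_pairwise(x: np.ndarray) -> float:
    from scipy.spatial.distance import pdist

    d = pdist(x)
    med = float(np.median(d))
    if med == 0:
        med = float(d[d > 0].mean()) if np.any(d > 0) else 1.0
    return med


def lle_reconstruction_weights(
    x: np.ndarray, k: int, regularizer: float
) -> sparse.csr_matrix:
    """Barycentric reconstruction weights of every point from its k
    nearest neighbours; each row sums to exactly 1."""
    n = x.shape[0]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
    _, idx = nn.kneighbors(x)
    idx = idx[:, 1:]  # drop self
    rows, cols, vals = [], [], []
    for i in range(n):
        z = x[idx[i]] - x[i]          # k x d local differences
        g = z @ z.T                    # local Gram matrix
        trace = np.trace(g)
        if trace > 0:
            g = g + np.eye(k) * regularizer * trace / k
        elif regularizer > 0:
            g = g + np.eye(k) * regularizer
        try:
            w = np.linalg.solve(g, np.ones(k))
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                f"singular local Gram matrix at point {i}; increase the "
                "regularizer (points may be duplicated)"
            )
        w = w / w.sum()
        rows.extend([i] * k)
        cols.extend(idx[i])
        vals.extend(w)
    return sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))


def lle_embed(epochs: EpochMatrix, params: LLEParams | None = None) -> EmbeddingResult:
    """Locally linear embedding of the epoch sample vectors.

    Minimizes the reconstruction cost of each point from its neighbours,
    then embeds via the bottom nonconstant eigenvectors of
    (I-W)^T (I-W); the embedding second-moment matrix is the identity.
    """
    params = params or LLEParams()
    x = epochs.data
    n = x.shape[0]
    if n <= params.k_neighbors:
        raise ValueError(
            f"need more epochs ({n}) than k_neighbors ({params.k_neighbors})"
        )
    w = lle_reconstruction_weights(x, params.k_neighbors, params.regularizer)
    m = (sparse.identity(n) - w).T @ (sparse.identity(n) - w)
    d = params.target_dim
    if d + 2 < n:
        vals, vecs = eigsh(m.tocsc(), k=d + 1, sigma=0.0, which="LM")
    else:
        vals, vecs = np.linalg.eigh(m.toarray())
    order = np.argsort(vals)
    vecs = vecs[:, order[1: d + 1]]  # drop the constant eigenvector
    coords = _fix_signs(vecs * np.sqrt(n))  # sample second moment = identity
    cost = np.asarray(m @ coords).T @ coords
    return EmbeddingResult(
        coords=coords,
        method="LLE",
        params=params,
        labels=epochs.labels.copy(),
        source_epoch_ids=np.arange(n),
        extras={"weights": w, "eigenvalues": vals[order[1: d + 1]],
                "embedding_cost": float(np.trace(cost))},
    )


def diffusion_map_embed(epochs: EpochMatrix, params: DMParams | None = None) -> EmbeddingResult:
    """Diffusion-map embedding.

    Gaussian kernel a_kl = exp(-||y_k-y_l||^2 / (2 sigma^2)) row-normalized
    to a Markov transition matrix; coordinates are the top nontrivial
    eigenvectors scaled by lambda^t (the trivial lambda=1 eigenvector is
    dropped).
    """
    params = params or DMParams()
    x = epochs.data
    n = x.shape[0]
    if n < params.h + 1:
        raise ValueError(f"need at least h+1={params.h + 1} epochs, got {n}")
    sigma = params.sigma if params.sigma is not None else _median_pairwise(x)
    sq = np.sum(x ** 2, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * x @ x.T, 0.0)
    a = np.exp(-d2 / (2.0 * sigma ** 2))
    off = a[~np.eye(n, dtype=bool)]
    if off.size and off.max() < 1e-300:
        warnings.warn(
            "diffusion kernel underflows to the identity; sigma is too small",
            RuntimeWarning,
        )
    rowsum = a.sum(axis=1)
    b = a / rowsum[:, None]
    # symmetric conjugate of b shares its eigenvalues; d^(1/2) v maps back
    dhalf = np.sqrt(rowsum)
    a_sym = a / np.outer(dhalf, dhalf)
    vals, vecs = eigh(a_sym)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    psi = vecs / dhalf[:, None]            # right eigenvectors of b
    psi = psi / np.abs(psi[:, 0:1])        # trivial eigenvector == 1
    h = params.h
    lam = vals[1: h + 1]
    coords = _fix_signs(psi[:, 1: h + 1] * (lam ** params.t)[None, :])
    resolved = DMParams(sigma=sigma, t=params.t, h=params.h)
    return EmbeddingResult(
        coords=coords,
        method="DM",
        params=resolved,
        labels=epochs.labels.copy(),
        source_epoch_ids=np.arange(n),
        extras={"transition_matrix": b, "eigenvalues": vals},
    )


def graph_laplacian(x: np.ndarray, m_neighbors: int, sigma: float):
    """Symmetrized kNN graph with Gaussian edge weights; returns (A, P, E)
    with degree matrix P and unnormalized Laplacian E = P - A."""
    n = x.shape[0]
    nn = NearestNeighbors(n_neighbors=min(m_neighbors + 1, n)).fit(x)
    dist, idx = nn.kneighbors(x)
    a = np.zeros((n, n))
    for i in range(n):
        for d, j in zip(dist[i, 1:], idx[i, 1:]):
            w = np.exp(-(d ** 2) / (2.0 * sigma ** 2))
            a[i, j] = max(a[i, j], w)
            a[j, i] = a[i, j]
    p = np.diag(a.sum(axis=1))
    return a, p, p - a


def laplacian_eigenmap_embed(epochs: EpochMatrix, params: LEParams | None = None) -> EmbeddingResult:
    """Laplacian-eigenmap embedding via the generalized eigenproblem
    E x = lambda P x, keeping the eigenvectors of the smallest nonzero
    eigenvalues (the constant null vector is excluded)."""
    params = params or LEParams()
    x = epochs.data
    n = x.shape[0]
    sigma = params.sigma if params.sigma is not None else _median_pairwise(x)
    a, p, e = graph_laplacian(x, params.m_neighbors, sigma)
    n_comp, comp = connected_components(sparse.csr_matrix(a > 0), directed=False)
    if n_comp > 1:
        sizes = np.bincount(comp).tolist()
        raise ValueError(
            f"neighbourhood graph is disconnected ({n_comp} components of "
            f"sizes {sizes}); the embedding is ill-defined across components"
        )
    vals, vecs = eigh(e, p)
    order = np.argsort(vals)
    vals, vecs = vals[order], vecs[:, order]
    coords = _fix_signs(vecs[:, 1: params.target_dim + 1])
    resolved = LEParams(m_neighbors=params.m_neighbors, sigma=sigma,
                        target_dim=params.target_dim)
    return EmbeddingResult(
        coords=coords,
        method="LE",
        params=resolved,
        labels=epochs.labels.copy(),
        source_epoch_ids=np.arange(n),
        extras={"adjacency": a, "degree": p, "laplacian": e,
                "eigenvalues": vals},
    )


def le_cost(e: np.ndarray, f: np.ndarray) -> float:
    """Graph-Laplacian embedding cost sum_nt (f_n - f_t)^2 a_nt = 2 tr(F' E F)."""
    return float(2.0 * np.trace(f.T @ e @ f))


def embed(epochs: EpochMatrix, method: str, params=None) -> EmbeddingResult:
    """Dispatch on method name: 'lle', 'dm' or 'le'."""
    key = method.lower()
    if key == "lle":
        return lle_embed(epochs, params)
    if key == "dm":
        return diffusion_map_embed(epochs, params)
    if key == "le":
        return laplacian_eigenmap_embed(epochs, params)
    raise ValueError(f"unknown embedding method {method!r}")
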