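"""Structured precision matrix of the multivariate Laplace prior.

Each regression coefficient beta_i carries a pair of latent Gaussian scale
variables (u_i, v_i); u and v are each N(0, J^{-1}) with a sparse precision
matrix J that couples the prior scales of neighbouring features.  J is built
as lambda*I + c*L, where L is the graph Laplacian of the declared neighbour
pairs, then symmetrically scaled to unit diagonal, so c = 0 reduces exactly
to independent unit-variance auxiliaries (and hence an iid Laplace(0,1)
marginal prior on the coefficients).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .datasets import FeatureIndex

__all__ = [
    "CouplingSpec",
    "PrecisionModel",
    "build_precision",
    "temporal_pairs",
    "spatial_pairs",
    "cross_dataset_pairs",
]


def temporal_pairs(index: FeatureIndex) -> np.ndarray:
    """Consecutive-time neighbour pairs within each channel (channel-major order)."""
    n_t = index.n_times
    pairs = []
    for ch in range(index.n_channels):
        base = ch * n_t
        for t in range(n_t - 1):
            pairs.append((base + t, base + t + 1))
    return np.asarray(pairs, dtype=int).reshape(-1, 2)


def spatial_pairs(index: FeatureIndex) -> np.ndarray:
    """Same-time neighbour pairs between index-adjacent channels."""
    n_t = index.n_times
    pairs = []
    for ch in range(index.n_channels - 1):
        for t in range(n_t):
            pairs.append((ch * n_t + t, (ch + 1) * n_t + t))
    return np.asarray(pairs, dtype=int).reshape(-1, 2)


def cross_dataset_pairs(n_features: int, n_datasets: int) -> np.ndarray:
    """Twin pairs linking the same feature across stacked datasets."""
    pairs = []
    for d in range(n_datasets - 1):
        for e in range(d + 1, n_datasets):
            for i in range(n_features):
                pairs.append((d * n_features + i, e * n_features + i))
    return np.asarray(pairs, dtype=int).reshape(-1, 2)


@dataclass
class CouplingSpec:
    """Neighbourhood graph and hyperparameters of the auxiliary-variable prior.

    ``coupling_strength`` (c) weighs the graph-Laplacian smoothing term;
    ``regularization`` (lambda) is the ridge on the diagonal.  Defaults c=100,
    lambda=1 (temporal-neighbour coupling).
    """

    n_features: int
    neighbor_pairs: np.ndarray = field(default_factory=lambda: np.empty((0, 2), int))
    coupling_strength: float = 100.0
    regularization: float = 1.0

    def __post_init__(self) -> None:
        self.neighbor_pairs = np.asarray(self.neighbor_pairs, dtype=int).reshape(-1, 2)
        if self.n_features <= 0:
            raise ValueError("n_features must be positive")
        if self.coupling_strength < 0:
            raise ValueError("coupling strength must be >= 0")
        if self.regularization <= 0:
            raise ValueError("regularization must be > 0")
        p = self.neighbor_pairs
        if p.size:
            if (p < 0).any() or (p >= self.n_features).any():
                raise ValueError("neighbor pair index out of range")
            if (p[:, 0] == p[:, 1]).any():
                raise ValueError("self-pairs are not allowed")


@dataclass
class PrecisionModel:
    """Sparse SPD precision matrix J with its connected-component structure.

    ``components`` lists the feature-index arrays of the connected components
    of the coupling graph; all linear algebra on J is done densely per
    component (components are small: temporal chains within a channel, or a
    few chains linked across datasets).
    """

    J: sparse.csr_matrix
    components: list[np.ndarray]
    spec: CouplingSpec

    @property
    def n_features(self) -> int:
        return self.J.shape[0]

    def _blocks(self) -> list[np.ndarray]:
        if not hasattr(self, "_block_cache"):
            self._block_cache = [
                np.asarray(self.J[np.ix_(idx, idx)].todense()) for idx in self.components
            ]
        return self._block_cache

    @property
    def is_diagonal(self) -> bool:
        return len(self.components) == self.n_features

    def posterior_variances(self, omega: np.ndarray) -> np.ndarray:
        """diag((J + diag(omega))^{-1}); omega >= 0 per feature."""
        if self.is_diagonal:
            return 1.0 / (self.J.diagonal() + omega)
        out = np.empty(self.n_features)
        for idx, block in zip(self.components, self._blocks()):
            M = block + np.diag(omega[idx])
            out[idx] = np.diag(np.linalg.inv(M))
        return out

    def prior_variances(self) -> np.ndarray:
        """Marginal prior variance of each auxiliary variable, diag(J^{-1})."""
        return self.posterior_variances(np.zeros(self.n_features))

    def sample_aux(self, n_draws: int, rng: np.random.Generator) -> np.ndarray:
        """Draws from N(0, J^{-1}), shape (n_draws, n_features)."""
        if self.is_diagonal:
            sd = 1.0 / np.sqrt(self.J.diagonal())
            return rng.standard_normal((n_draws, self.n_features)) * sd
        out = np.empty((n_draws, self.n_features))
        for idx, block in zip(self.components, self._blocks()):
            L = np.linalg.cholesky(block)  # J = L L^T  =>  u = L^{-T} z
            z = rng.standard_normal((len(idx), n_draws))
            out[:, idx] = np.linalg.solve(L.T, z).T
        return out


def build_precision(spec: CouplingSpec) -> PrecisionModel:
    """Assemble J = lambda*I + c*Laplacian(pairs), scaled to unit diagonal."""
    p = spec.n_features
    pairs = spec.neighbor_pairs
    if pairs.size:
        i, j = pairs[:, 0], pairs[:, 1]
        data = np.ones(len(pairs))
        A = sparse.coo_matrix((data, (i, j)), shape=(p, p))
        A = A + A.T
        A.data[:] = np.minimum(A.data, 1.0)  # tolerate duplicated pairs
        deg = np.asarray(A.sum(axis=1)).ravel()
        L = sparse.diags(deg) - A
    else:
        L = sparse.csr_matrix((p, p))
    J0 = sparse.diags(np.full(p, spec.regularization)) + spec.coupling_strength * L
    d = np.sqrt(J0.diagonal())
    Dinv = sparse.diags(1.0 / d)
    J = (Dinv @ J0 @ Dinv).tocsr()
    # exact unit diagonal (guard against round-off)
    J.setdiag(1.0)

    if pairs.size and spec.coupling_strength > 0:
        graph = sparse.coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(p, p)
        )
        n_comp, labels = connected_components(graph, directed=False)
        components = [np.flatnonzero(labels == k) for k in range(n_comp)]
    else:
        components = [np.array([i]) for i in range(p)]
    return PrecisionModel(J=J, components=components, spec=spec)
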