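"""Ground-truth spatial adjacency matrices from spot coordinates.

Each kernel turns pairwise Euclidean distances into non-negative weights and
then divides every row by its sum, so row i of the result is spot i's
normalized proximity distribution over all spots. This row-stochastic matrix
is the supervision target for the encoder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from .data_model import SpatialCoords

GAUSSIAN = "gaussian"
EXPONENTIAL = "exponential"
KNN = "knn"


@dataclass
class SpatialAdjacency:
    """Row-stochastic N x N proximity matrix with its kernel provenance."""

    weights: np.ndarray
    kernel: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.all(np.isfinite(w)):
            raise ValueError("adjacency must be finite")
        if (w < 0).any():
            raise ValueError("adjacency weights must be non-negative")
        if np.max(np.abs(w.sum(axis=1) - 1.0)) > 1e-8:
            raise ValueError("adjacency rows must sum to 1")

    @property
    def n(self) -> int:
        return self.weights.shape[0]


def _distances(y: SpatialCoords) -> np.ndarray:
    return cdist(y.coords, y.coords)


def default_sigma(y: SpatialCoords) -> float:
    """Half of the mean nearest-neighbor distance between spots.

    This is the default Gaussian bandwidth; it adapts to the coordinate units
    of the slide.
    """
    if y.n < 2:
        raise ValueError("need at least 2 spots to compute a default sigma")
    d = _distances(y)
    np.fill_diagonal(d, np.inf)
    sigma = 0.5 * float(d.min(axis=1).mean())
    if sigma <= 0:
        raise ValueError(
            "duplicate coordinates make the default sigma zero; set sigma manually"
        )
    return sigma


def _row_normalize(phi: np.ndarray, kernel: str, params: dict) -> SpatialAdjacency:
    sums = phi.sum(axis=1, keepdims=True)
    return SpatialAdjacency(phi / sums, kernel, params)


def gaussian_adjacency(y: SpatialCoords, sigma: float | None = None) -> SpatialAdjacency:
    """Gaussian-kernel adjacency: phi_ij = N(0, sigma) density at d(i, j).

    The self-pair is included (it carries the row maximum); rows are then
    normalized to sum to 1. `sigma` defaults to :func:`default_sigma`.
    """
    if sigma is None:
        sigma = default_sigma(y)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    d = _distances(y)
    phi = np.exp(-(d**2) / (2 * sigma**2)) / (np.sqrt(2 * np.pi) * sigma)
    return _row_normalize(phi, GAUSSIAN, {"sigma": float(sigma)})


def exponential_adjacency(y: SpatialCoords, scale: float) -> SpatialAdjacency:
    """Exponential-kernel adjacency: phi_ij = exp(-d(i, j) / scale), row-normalized."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    phi = np.exp(-_distances(y) / scale)
    return _row_normalize(phi, EXPONENTIAL, {"scale": float(scale)})


def knn_adjacency(y: SpatialCoords, k: int) -> SpatialAdjacency:
    """K-nearest-neighbor adjacency: 1/k on each of a spot's k neighbors.

    Self is excluded; ties at the k-th distance are broken by spot index.
    """
    n = y.n
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    d = _distances(y)
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")  # stable sort: index tie-break
    phi = np.zeros_like(d)
    rows = np.repeat(np.arange(n), k)
    phi[rows, order[:, :k].ravel()] = 1.0
    return _row_normalize(phi, KNN, {"k": int(k)})


def build_adjacency(y: SpatialCoords, kernel: str = GAUSSIAN, **params) -> SpatialAdjacency:
    """Dispatch to the requested kernel; parameters as keyword arguments."""
    if kernel == GAUSSIAN:
        return gaussian_adjacency(y, params.get("sigma"))
    if kernel == EXPONENTIAL:
        return exponential_adjacency(y, params["scale"])
    if kernel == KNN:
        return knn_adjacency(y, params["k"])
    raise ValueError(f"unknown kernel {kernel!r}")
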