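"""Post-training products derived from the mapping matrices and embeddings.

With the trained encoder in hand, everything downstream is linear algebra on
the row-stochastic mapping matrices: spot deconvolution ``T_hat = C_hat @ T``,
pseudo-coordinates ``Y_hat = C @ Y``, annotation transfer ``v_hat = C @ v``,
and the SC-SC adjacency as the Gram matrix of SC embeddings (consumed only
through per-row rankings).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .data_model import CellTypeAnnotation, SpatialCoords
from .model import Embeddings


@dataclass
class DeconvolutionResult:
    """Per-spot cell-type proportions (rows sum to 1)."""

    proportions: np.ndarray
    cell_types: list[str]

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if (p < -1e-12).any():
            raise ValueError("proportions must be non-negative")
        if np.max(np.abs(p.sum(axis=1) - 1.0)) > 1e-8:
            raise ValueError("proportion rows must sum to 1")
        self.proportions = p


def _check_row_stochastic(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if np.max(np.abs(m.sum(axis=1) - 1.0)) > 1e-8 or (m < 0).any():
        raise ValueError(f"{name} must be row-stochastic")
    return m


def deconvolve(c_hat: np.ndarray, t_sc: CellTypeAnnotation) -> DeconvolutionResult:
    """Spot cell-type proportions: ``T_hat = C_hat @ T_sc``.

    A row-stochastic spot-over-cells matrix times a one-hot indicator yields
    valid proportions by construction.
    """
    c_hat = _check_row_stochastic(c_hat, "C_hat")
    if c_hat.shape[1] != t_sc.indicator.shape[0]:
        raise ValueError(
            f"C_hat has {c_hat.shape[1]} cells, annotation has "
            f"{t_sc.indicator.shape[0]}"
        )
    return DeconvolutionResult(c_hat @ t_sc.indicator, list(t_sc.categories))


def pseudo_coordinates(c: np.ndarray, y_st: SpatialCoords) -> SpatialCoords:
    """Per-cell pseudo-coordinates: ``Y_hat_sc = C @ Y_st``.

    Each cell lands at the C-weighted mean of spot coordinates, hence inside
    the convex hull of the spots.
    """
    c = _check_row_stochastic(c, "C")
    if c.shape[1] != y_st.n:
        raise ValueError(f"C has {c.shape[1]} spots, coordinates have {y_st.n}")
    coords = c @ y_st.coords
    return SpatialCoords(coords, [f"cell_{i}" for i in range(c.shape[0])])


def sc_adjacency(z_sc: Embeddings | np.ndarray) -> np.ndarray:
    """Reconstructed SC-SC adjacency: the raw Gram matrix of SC embeddings.

    Left unnormalized on purpose — downstream evaluation (hit number) is
    rank-based within rows, so any monotone rescaling is irrelevant.
    """
    z = z_sc.vectors if isinstance(z_sc, Embeddings) else np.asarray(z_sc)
    if z.shape[0] < 2:
        raise ValueError("need at least 2 cells")
    return z @ z.T


def transfer_spot_annotation(c: np.ndarray, v_st: np.ndarray) -> np.ndarray:
    """Transfer a per-spot scalar (e.g. a zonation score) to cells: ``C @ v``."""
    c = _check_row_stochastic(c, "C")
    v = np.asarray(v_st, dtype=float)
    if v.ndim != 1 or v.size != c.shape[1]:
        raise ValueError(f"annotation length {v.size} != {c.shape[1]} spots")
    return c @ v


@dataclass
class UnifiedMapping:
    """Unified view of any method's non-negative cell-to-spot weight matrix.

    ``neighbor_ranks[i, j]`` is the rank of cell j among cell i's neighbors
    by pseudo-coordinate distance (1 = closest, self and unmapped cells get
    0). ``unmapped`` flags cells whose weight row summed to zero.
    """

    coords: SpatialCoords
    neighbor_ranks: np.ndarray
    unmapped: np.ndarray


def unify_mapping(c_any: np.ndarray, y_st: SpatialCoords) -> UnifiedMapping:
    """Convert an arbitrary non-negative mapping matrix into coordinates + ranks.

    Rows are renormalized to sum to 1; zero rows mark the cell unmapped (its
    coordinates are NaN and it is excluded from ranking). Distance ties are
    broken by smaller cell index.
    """
    c_any = np.asarray(c_any, dtype=float)
    if (c_any < 0).any():
        raise ValueError("mapping weights must be non-negative")
    if c_any.shape[1] != y_st.n:
        raise ValueError("mapping matrix columns do not match spot count")
    sums = c_any.sum(axis=1)
    unmapped = sums == 0
    m = c_any.shape[0]
    coords = np.full((m, 2), np.nan)
    mapped = ~unmapped
    coords[mapped] = (c_any[mapped] / sums[mapped, None]) @ y_st.coords
    ranks = np.zeros((m, m), dtype=int)
    idx = np.flatnonzero(mapped)
    if idx.size >= 2:
        d = cdist(coords[idx], coords[idx])
        np.fill_diagonal(d, np.inf)
        order = np.argsort(d, axis=1, kind="stable")  # stable: index tie-break
        sub = np.empty_like(order)
        rows = np.arange(idx.size)[:, None]
        sub[rows, order] = np.arange(1, idx.size + 1)[None, :]
        # self got the largest rank via inf distance; zero it out
        np.fill_diagonal(sub, 0)
        ranks[np.ix_(idx, idx)] = sub
    return UnifiedMapping(_coords_allow_nan(coords, m), ranks, unmapped)


def _coords_allow_nan(coords: np.ndarray, m: int) -> SpatialCoords:
    # unmapped rows keep NaN coordinates, which the SpatialCoords validator
    # would reject; construct directly and let `unmapped` carry the flag
    obj = SpatialCoords.__new__(SpatialCoords)
    obj.coords = coords
    obj.row_ids = [f"cell_{i}" for i in range(m)]
    return obj
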