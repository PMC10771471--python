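"""Integrated-gradient gene attribution, spatial trajectories, and SDG calling.

For each cell the model assigns a most likely spot (the argmax of its row of
the SC->ST mapping matrix C). Integrated gradients along the straight path
from the all-zero baseline to the cell's expression vector decompose that
mapped probability into per-gene contributions; genes whose contributions
are significantly elevated within a segment of a fitted spatial trajectory
are called spatially dominant genes (SDGs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from numpy.polynomial import Polynomial
from scipy import stats
from scipy.integrate import cumulative_trapezoid
from statsmodels.stats.multitest import multipletests

from .data_model import ExpressionMatrix, LOGNORM, SpatialCoords
from .model import Embeddings, MLPEncoder, _row_softmax


# ---------------------------------------------------------------------------
# Integrated gradients
# ---------------------------------------------------------------------------

def integrated_gradients(
    x: np.ndarray,
    f: Callable[[np.ndarray], float],
    grad_f: Callable[[np.ndarray], np.ndarray],
    steps: int = 50,
) -> np.ndarray:
    """Midpoint-rule integrated gradients from the zero baseline to `x`.

    ``W_j = x_j * (1/steps) * sum_t df(a_t * x)/dx_j`` with midpoints
    ``a_t = (t - 0.5)/steps``. For differentiable f the completeness axiom
    ``sum_j W_j -> f(x) - f(0)`` holds as steps grows.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    x = np.asarray(x, dtype=float)
    total = np.zeros_like(x)
    for t in range(1, steps + 1):
        a = (t - 0.5) / steps
        g = np.asarray(grad_f(a * x), dtype=float)
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(f"non-finite gradient at step {t}")
        total += g
    return x * total / steps


@dataclass
class AttributionProfile:
    """Per-cell, per-gene attribution of the mapped-spot probability.

    ``convergence_gap[i]`` is ``|sum_j scores[i, j] - (f(x_i) - f(0))|``, the
    residual of the completeness axiom at the used step count — reported, not
    hidden.
    """

    scores: np.ndarray
    target_spot: np.ndarray
    convergence_gap: np.ndarray
    gene_ids: list[str]


def _mapped_probability_and_grad(
    x: np.ndarray, encoder: MLPEncoder, z_st: np.ndarray, targets: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """f(x) = softmax(encode(x) @ Z_st.T)[target] per row, with d f / d x."""
    z, cache = encoder.forward(x)
    p = _row_softmax(z @ z_st.T)
    rows = np.arange(x.shape[0])
    f = p[rows, targets]
    # df/dz = f * (z_st[target] - sum_j p_j z_st[j])
    d_z = f[:, None] * (z_st[targets] - p @ z_st)
    grads = encoder.backward(cache, d_z)
    return f, grads["input"]


def attribution_profile(
    sc: ExpressionMatrix,
    encoder: MLPEncoder,
    z_st: Embeddings | np.ndarray,
    steps: int = 50,
) -> AttributionProfile:
    """Attribute each cell's mapped-spot probability to its genes.

    The target of cell i is the argmax spot of its row in the SC->ST mapping
    matrix, computed with the ST embeddings frozen; gradients flow through
    the shared encoder and the softmax over spots.
    """
    if sc.layer != LOGNORM:
        raise ValueError("attribution expects log-normalized expression")
    zt = z_st.vectors if isinstance(z_st, Embeddings) else np.asarray(z_st)
    x = sc.values
    z_sc, _ = encoder.forward(x)
    c = _row_softmax(z_sc @ zt.T)
    targets = np.argmax(c, axis=1)

    total = np.zeros_like(x)
    for t in range(1, steps + 1):
        a = (t - 0.5) / steps
        _, g = _mapped_probability_and_grad(a * x, encoder, zt, targets)
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(f"non-finite gradient at step {t}")
        total += g
    scores = x * total / steps
    f_x, _ = _mapped_probability_and_grad(x, encoder, zt, targets)
    f_0, _ = _mapped_probability_and_grad(np.zeros_like(x), encoder, zt, targets)
    gap = np.abs(scores.sum(axis=1) - (f_x - f_0))
    return AttributionProfile(scores, targets, gap, list(sc.gene_ids))


# ---------------------------------------------------------------------------
# Spatial trajectory
# ---------------------------------------------------------------------------

@dataclass
class SpatialTrajectory:
    """A 1-D trajectory through tissue: polynomial fit + arc-length pseudotime."""

    coefficients: np.ndarray  # ascending-power polynomial coefficients
    start_cell: int
    pseudotime: np.ndarray
    residual: float


def _arc_length_table(
    coef: np.ndarray, x_lo: float, x_hi: float, n_grid: int = 20001
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative arc length of y = p(x) on a dense grid (trapezoid rule)."""
    p = Polynomial(coef)
    dp = p.deriv()
    xs = np.linspace(x_lo, x_hi, n_grid)
    integrand = np.sqrt(1.0 + dp(xs) ** 2)
    lengths = cumulative_trapezoid(integrand, xs, initial=0.0)
    return xs, lengths


def fit_trajectory(
    coords: SpatialCoords | np.ndarray,
    degree: int = 5,
    start_rule: str = "top_right",
) -> SpatialTrajectory:
    """Least-squares polynomial trajectory y = p(x) with arc-length pseudotime.

    The start cell (pseudotime 0) defaults to the top-right corner: maximal
    x, ties by maximal y. Each cell is mapped onto the curve at its own
    x-coordinate; pseudotime is the unsigned arc length along the curve
    between the start cell's x and the cell's x.
    """
    xy = coords.coords if isinstance(coords, SpatialCoords) else np.asarray(coords)
    x, y = xy[:, 0], xy[:, 1]
    n = x.size
    if n < degree + 1:
        raise ValueError(
            f"{n} cells cannot support degree {degree}; lower the degree"
        )
    if np.ptp(x) == 0:
        raise ValueError("x-coordinates are all equal; the fit is rank-deficient")
    poly = Polynomial.fit(x, y, deg=degree)
    coef = poly.convert().coef
    residual = float(((poly(x) - y) ** 2).sum())

    if start_rule == "top_right":
        cand = np.flatnonzero(x == x.max())
        start = int(cand[np.argmax(y[cand])])
    elif start_rule == "top_left":
        cand = np.flatnonzero(x == x.min())
        start = int(cand[np.argmax(y[cand])])
    else:
        raise ValueError(f"unknown start rule {start_rule!r}")

    xs, lengths = _arc_length_table(coef, float(x.min()), float(x.max()))
    cum = np.interp(x, xs, lengths)
    pseudotime = np.abs(cum - cum[start])
    return SpatialTrajectory(coef, start, pseudotime, residual)


def segment_cells(
    traj: SpatialTrajectory, n_segments: int = 11, method: str = "width"
) -> np.ndarray:
    """Partition cells into trajectory segments by pseudotime.

    ``method="width"`` uses equal-width pseudotime bins (default);
    ``"count"`` uses equal-count quantile bins.
    """
    if n_segments < 2:
        raise ValueError("n_segments must be >= 2")
    t = traj.pseudotime
    span = np.ptp(t)
    if span == 0:
        warnings.warn("all cells share one pseudotime; single segment")
        return np.zeros(t.size, dtype=int)
    if method == "width":
        seg = np.floor((t - t.min()) / span * n_segments).astype(int)
        return np.minimum(seg, n_segments - 1)
    if method == "count":
        q = np.quantile(t, np.linspace(0, 1, n_segments + 1)[1:-1])
        return np.searchsorted(q, t, side="right").astype(int)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Spatially dominant genes
# ---------------------------------------------------------------------------

def _segment_ranksum(
    matrix: np.ndarray,
    segments: np.ndarray,
    gene_ids: list[str],
    fdr: float,
) -> pd.DataFrame:
    """One-sided rank-sum of each gene in each segment vs the union of the rest.

    Benjamini-Hochberg correction is applied across all gene x segment tests.
    Returns the rows with adjusted p below `fdr`.
    """
    segments = np.asarray(segments)
    seg_ids = np.unique(segments)
    rows = []
    for seg in seg_ids:
        mask = segments == seg
        if mask.sum() < 2 or (~mask).sum() < 2:
            warnings.warn(f"segment {seg} has too few cells; excluded")
            continue
        res = stats.mannwhitneyu(
            matrix[mask], matrix[~mask], alternative="greater", axis=0
        )
        for j, g in enumerate(gene_ids):
            rows.append((g, int(seg), float(res.statistic[j]), float(res.pvalue[j])))
    table = pd.DataFrame(rows, columns=["gene", "segment", "statistic", "p"])
    if table.empty:
        return table.assign(p_adj=pd.Series(dtype=float))
    table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
    hits = table[table["p_adj"] < fdr].reset_index(drop=True)
    return hits


def identify_sdgs(
    profile: AttributionProfile | np.ndarray,
    segments: np.ndarray,
    fdr: float = 0.05,
    gene_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Call spatially dominant genes from attribution scores.

    A gene is an SDG if its attribution in at least one trajectory segment is
    significantly above the pooled remaining segments (one-sided Wilcoxon
    rank-sum, BH-adjusted p < `fdr`). Returns a table (gene, segment,
    statistic, p, p_adj) of significant gene-segment pairs.
    """
    if isinstance(profile, AttributionProfile):
        matrix, genes = profile.scores, profile.gene_ids
    else:
        matrix = np.asarray(profile, dtype=float)
        genes = gene_ids or [f"gene_{j}" for j in range(matrix.shape[1])]
    return _segment_ranksum(matrix, segments, genes, fdr)


def identify_degs(
    expr: ExpressionMatrix, segments: np.ndarray, fdr: float = 0.05
) -> pd.DataFrame:
    """Expression-based analog of :func:`identify_sdgs` on the same segments."""
    return _segment_ranksum(expr.values, segments, list(expr.gene_ids), fdr)
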