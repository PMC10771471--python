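"""Metrics for reconstructed spatial information.

Three headline metrics: coordinate MAE (mean Euclidean distance between
predicted and true cell positions), hit number (mean overlap between true
and predicted k-nearest-neighbor sets), and per-cell-type Pearson
correlation between deconvolved and true spatial distributions. The hollow
profile quantifies embedding-space geometry via sphere-inclusion fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .data_model import CellTypeAnnotation, SpatialCoords
from .model import Embeddings


def _coords(y) -> np.ndarray:
    return y.coords if isinstance(y, SpatialCoords) else np.asarray(y, dtype=float)


def coordinate_mae(y_true, y_pred, mask: np.ndarray | None = None) -> float:
    """Mean Euclidean distance between paired true and predicted coordinates.

    `mask` restricts the mean to a subset of cells (e.g. the cells covered by
    pseudo-spots, or the mapped cells of a method that discards some).
    """
    a, b = _coords(y_true), _coords(y_pred)
    if a.shape != b.shape:
        raise ValueError(f"coordinate shapes differ: {a.shape} vs {b.shape}")
    d = np.linalg.norm(a - b, axis=1)
    if mask is not None:
        d = d[np.asarray(mask, dtype=bool)]
    return float(d.mean())


def _true_neighbor_sets(y_true: np.ndarray, k: int) -> np.ndarray:
    d = cdist(y_true, y_true)
    np.fill_diagonal(d, np.inf)
    return np.argsort(d, axis=1, kind="stable")[:, :k]


def hit_number(
    y_true,
    pred_adjacency: np.ndarray,
    k: int,
    mask: np.ndarray | None = None,
) -> float:
    """Mean size of the overlap between true and predicted k-NN sets.

    The true set of cell i holds its k nearest cells by coordinates; the
    predicted set holds the k largest entries of row i of `pred_adjacency`
    (self excluded; ties broken by index). Perfect ranking gives k.
    """
    y = _coords(y_true)
    a = np.asarray(pred_adjacency, dtype=float).copy()
    m = y.shape[0]
    if a.shape != (m, m):
        raise ValueError("adjacency shape does not match coordinates")
    if not 1 <= k <= m - 1:
        raise ValueError(f"k must be in [1, {m - 1}]")
    truth = _true_neighbor_sets(y, k)
    np.fill_diagonal(a, -np.inf)
    pred = np.argsort(-a, axis=1, kind="stable")[:, :k]
    hits = np.empty(m)
    for i in range(m):
        hits[i] = np.intersect1d(truth[i], pred[i]).size
    if mask is not None:
        hits = hits[np.asarray(mask, dtype=bool)]
    return float(hits.mean())


def hit_curve(y_true, pred_adjacency: np.ndarray, ks: list[int]) -> dict[int, float]:
    """Hit number at each k (non-decreasing in k)."""
    return {k: hit_number(y_true, pred_adjacency, k) for k in ks}


def celltype_pcc(
    c: np.ndarray,
    labels: CellTypeAnnotation,
    p_true: np.ndarray,
    cell_types: list[str] | None = None,
) -> dict[str, float]:
    """Pearson correlation of mapped vs true spatial distribution per type.

    For type t the estimated distribution is the column-sum of the rows of C
    belonging to its cells; the true one is the corresponding column of the
    pseudo-ST proportion matrix. Zero-variance vectors yield a correlation
    of 0 with a warning.
    """
    c = np.asarray(c, dtype=float)
    p_true = np.asarray(p_true, dtype=float)
    cols = cell_types or list(labels.categories)
    col_of = {t: j for j, t in enumerate(cols)}
    unknown = [t for t in labels.categories if t not in col_of]
    if unknown:
        raise ValueError(f"labels contain unknown types: {unknown}")
    out: dict[str, float] = {}
    lab = np.asarray(labels.labels)
    for t in labels.categories:
        est = c[lab == t].sum(axis=0)
        truth = p_true[:, col_of[t]]
        if est.std() == 0 or truth.std() == 0:
            warnings.warn(f"zero-variance distribution for type {t}; PCC set to 0")
            out[t] = 0.0
        else:
            out[t] = float(np.corrcoef(est, truth)[0, 1])
    return out


def hollow_profile(
    z: Embeddings | np.ndarray, radii: list[float] | np.ndarray
) -> dict[float, float]:
    """Sphere-inclusion fractions around the mean embedding.

    The unit is D, the distance from the centroid to its nearest point: for
    each normalized radius r the value is the fraction of points within
    ``r * D`` of the centroid. A hollow embedding keeps this fraction low at
    small r.
    """
    v = z.vectors if isinstance(z, Embeddings) else np.asarray(z, dtype=float)
    if v.shape[0] < 2:
        raise ValueError("need at least 2 points")
    center = v.mean(axis=0)
    dist = np.linalg.norm(v - center, axis=1)
    d_unit = dist.min()
    if d_unit == 0:
        raise ValueError(
            "a point coincides with the centroid; the normalized radius is undefined"
        )
    radii = np.asarray(radii, dtype=float)
    if np.any(np.diff(radii) < 0):
        raise ValueError("radii must be sorted ascending")
    return {float(r): float((dist <= r * d_unit).mean()) for r in radii}


@dataclass
class EvaluationReport:
    """Bundle of the three metrics plus input provenance notes."""

    mae: float
    hit_curve: dict[int, float]
    per_type_pcc: dict[str, float]
    notes: dict

    def to_dict(self) -> dict:
        return {
            "mae": self.mae,
            "hit_curve": {str(k): v for k, v in self.hit_curve.items()},
            "per_type_pcc": self.per_type_pcc,
            "notes": self.notes,
        }


def evaluate_mapping(
    y_true,
    y_pred,
    pred_adjacency: np.ndarray,
    c: np.ndarray,
    labels: CellTypeAnnotation,
    p_true: np.ndarray,
    ks: list[int] = (10, 20, 50),
    mask: np.ndarray | None = None,
    cell_types: list[str] | None = None,
    notes: dict | None = None,
) -> EvaluationReport:
    """Compute the full metric bundle for one mapping result."""
    return EvaluationReport(
        mae=coordinate_mae(y_true, y_pred, mask=mask),
        hit_curve={k: hit_number(y_true, pred_adjacency, k, mask=mask) for k in ks},
        per_type_pcc=celltype_pcc(c, labels, p_true, cell_types=cell_types),
        notes=notes or {},
    )
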