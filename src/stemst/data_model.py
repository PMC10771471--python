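"""Core data containers, expression normalization, gene alignment, and I/O.

Expression values travel through the pipeline in one of two layers:

``raw``
    Unique-molecular-identifier counts (non-negative, usually integer).
``lognorm``
    Depth-normalized values, ``log(1 + 1e4 * x / row_total)`` — counts per
    ten thousand, log-transformed. This is the layer the encoder consumes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("stemst")

RAW = "raw"
LOGNORM = "lognorm"
NORM_SCALE = 1e4


@dataclass
class ExpressionMatrix:
    """A rows-by-genes expression matrix with identifiers and a layer tag.

    Parameters
    ----------
    values
        Dense ``(n_rows, n_genes)`` float array. Raw counts must be
        non-negative; all values must be finite.
    gene_ids
        Ordered, unique gene symbols (one per column).
    row_ids
        Ordered cell or spot identifiers (one per row).
    layer
        ``"raw"`` or ``"lognorm"``.
    """

    values: np.ndarray
    gene_ids: list[str]
    row_ids: list[str]
    layer: str = RAW

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.row_ids = [str(r) for r in self.row_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.layer not in (RAW, LOGNORM):
            raise ValueError(f"unknown layer {self.layer!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if self.layer == RAW and (self.values < 0).any():
            raise ValueError("raw counts must be non-negative")
        n_rows, n_genes = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} columns"
            )
        if len(self.row_ids) != n_rows:
            raise ValueError(f"{len(self.row_ids)} row ids for {n_rows} rows")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene ids must be unique")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Return a copy restricted to `genes`, in the given order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes not present: {missing[:5]}")
        cols = [index[g] for g in genes]
        return ExpressionMatrix(
            self.values[:, cols].copy(), list(genes), list(self.row_ids), self.layer
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.gene_ids)


@dataclass
class SpatialCoords:
    """2-D coordinates aligned row-for-row with an :class:`ExpressionMatrix`."""

    coords: np.ndarray
    row_ids: list[str]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.row_ids = [str(r) for r in self.row_ids]
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coordinates must be an (n, 2) matrix")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if len(self.row_ids) != self.coords.shape[0]:
            raise ValueError("row ids do not match coordinate rows")

    @property
    def n(self) -> int:
        return self.coords.shape[0]


@dataclass
class CellTypeAnnotation:
    """Per-cell categorical labels with a one-hot indicator matrix.

    ``indicator`` is the M x D matrix whose row i is the one-hot encoding of
    cell i's type; column order follows ``categories`` (sorted unique labels).
    """

    labels: list[str]
    categories: list[str]
    indicator: np.ndarray

    @property
    def n_types(self) -> int:
        return len(self.categories)

    def argmax_labels(self) -> list[str]:
        """Recover labels from the indicator (round-trip check)."""
        return [self.categories[j] for j in np.argmax(self.indicator, axis=1)]


def one_hot_annotation(labels: Sequence[str]) -> CellTypeAnnotation:
    """Build a one-hot cell-type indicator from per-row labels.

    Column order is the sorted set of unique labels. Empty or missing labels
    are rejected.
    """
    labels = list(labels)
    if len(labels) == 0:
        raise ValueError("labels must be non-empty")
    clean: list[str] = []
    for i, lab in enumerate(labels):
        if lab is None or (isinstance(lab, float) and np.isnan(lab)) or str(lab) == "":
            raise ValueError(f"missing or empty label at row {i}")
        clean.append(str(lab))
    categories = sorted(set(clean))
    col = {c: j for j, c in enumerate(categories)}
    indicator = np.zeros((len(clean), len(categories)))
    for i, lab in enumerate(clean):
        indicator[i, col[lab]] = 1.0
    return CellTypeAnnotation(clean, categories, indicator)


def normalize_expression(
    x: ExpressionMatrix, drop_zero_rows: bool = True
) -> ExpressionMatrix:
    """Depth-normalize raw counts and log-transform.

    Each row is scaled to a total of ``1e4`` and transformed as
    ``log(1 + scaled)``. Rows with zero total counts are dropped (with a
    warning naming them) when `drop_zero_rows` is true, otherwise they raise.
    """
    if x.layer != RAW:
        raise ValueError(f"expected raw layer, got {x.layer!r}")
    totals = x.values.sum(axis=1)
    zero = totals == 0
    values, row_ids = x.values, list(x.row_ids)
    if zero.any():
        bad = [row_ids[i] for i in np.flatnonzero(zero)]
        if not drop_zero_rows:
            raise ValueError(f"rows with zero total counts: {bad[:10]}")
        warnings.warn(f"dropping {len(bad)} zero-count rows: {bad[:10]}")
        keep = ~zero
        values, totals = values[keep], totals[keep]
        row_ids = [r for r, k in zip(row_ids, keep) if k]
    out = np.log1p(NORM_SCALE * values / totals[:, None])
    return ExpressionMatrix(out, list(x.gene_ids), row_ids, LOGNORM)


def align_genes(
    sc: ExpressionMatrix,
    st: ExpressionMatrix,
    gene_set: Sequence[str] | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict two matrices to a shared gene set in identical order.

    With `gene_set` given, its order is respected (after intersecting with
    both matrices); otherwise the intersection keeps the SC matrix's gene
    order. Matching is exact and case-sensitive.
    """
    st_genes = set(st.gene_ids)
    sc_genes = set(sc.gene_ids)
    if gene_set is not None:
        shared = [g for g in gene_set if g in sc_genes and g in st_genes]
    else:
        shared = [g for g in sc.gene_ids if g in st_genes]
    if not shared:
        raise ValueError("no shared genes between the two matrices")
    return sc.subset_genes(shared), st.subset_genes(shared)


def select_variable_genes(
    x: ExpressionMatrix, n_genes: int, n_bins: int = 20
) -> list[str]:
    """Rank genes by mean-binned normalized dispersion and return the top set.

    Dispersion is variance/mean of the log-normalized values; genes are
    grouped into `n_bins` equal-frequency mean bins and dispersions are
    z-scored within each bin, which removes the mean-dispersion trend before
    ranking. Ties are broken by column order, making the selection
    deterministic.
    """
    if x.layer != LOGNORM:
        raise ValueError("variable-gene selection expects log-normalized values")
    if n_genes > x.n_genes:
        raise ValueError(f"n_genes={n_genes} exceeds gene count {x.n_genes}")
    means = x.values.mean(axis=0)
    var = x.values.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(means > 0, var / np.maximum(means, 1e-12), 0.0)
    # equal-frequency bins on the mean keep bins populated even for skewed
    # means; cap the count so every bin holds enough genes to z-score
    n_bins = max(1, min(n_bins, x.n_genes // 3))
    order = np.argsort(means, kind="stable")
    bins = np.empty(x.n_genes, dtype=int)
    bins[order] = np.minimum(
        (np.arange(x.n_genes) * n_bins) // max(x.n_genes, 1), n_bins - 1
    )
    normed = np.zeros_like(dispersion)
    for b in range(n_bins):
        mask = bins == b
        if not mask.any():
            continue
        d = dispersion[mask]
        sd = d.std()
        normed[mask] = (d - d.mean()) / sd if sd > 0 else 0.0
    ranked = np.argsort(-normed, kind="stable")  # stable: ties keep column order
    return [x.gene_ids[i] for i in ranked[:n_genes]]


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_expression_csv(path: str | Path, layer: str = RAW) -> ExpressionMatrix:
    """Read a comma-separated table: header row of genes, first column row ids."""
    df = pd.read_csv(path, index_col=0)
    return ExpressionMatrix(
        df.to_numpy(dtype=float), list(df.columns), list(df.index), layer
    )


def write_expression_csv(x: ExpressionMatrix, path: str | Path) -> None:
    x.to_frame().to_csv(path)


def read_expression_mtx(
    mtx_path: str | Path,
    gene_path: str | Path,
    row_path: str | Path,
    layer: str = RAW,
) -> ExpressionMatrix:
    """Read a matrix-market triplet file with sidecar gene/row id lists.

    The id files hold one identifier per line; the matrix is rows x genes.
    """
    from scipy.io import mmread
    from scipy import sparse

    m = mmread(str(mtx_path))
    values = np.asarray(m.toarray() if sparse.issparse(m) else m, dtype=float)
    genes = Path(gene_path).read_text().split()
    rows = Path(row_path).read_text().split()
    return ExpressionMatrix(values, genes, rows, layer)


def read_coords_csv(path: str | Path) -> SpatialCoords:
    """Read coordinates: first column row id, next two columns x and y."""
    df = pd.read_csv(path, index_col=0)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two coordinate columns")
    return SpatialCoords(df.iloc[:, :2].to_numpy(dtype=float), list(df.index))


def write_coords_csv(y: SpatialCoords, path: str | Path) -> None:
    pd.DataFrame(y.coords, index=y.row_ids, columns=["x", "y"]).to_csv(path)


def read_anndata(
    path: str | Path,
    layer: str = RAW,
    label_key: str | None = None,
    spatial_key: str = "spatial",
):
    """Load an .h5ad file into package containers.

    Returns ``(ExpressionMatrix, SpatialCoords | None, labels | None)``.
    Coordinates are looked up under ``obsm[spatial_key]`` and labels under
    ``obs[label_key]``.
    """
    import anndata as ad
    from scipy import sparse

    adata = ad.read_h5ad(str(path))
    values = adata.X
    if sparse.issparse(values):
        values = values.toarray()
    expr = ExpressionMatrix(
        np.asarray(values, dtype=float),
        list(adata.var_names),
        list(adata.obs_names),
        layer,
    )
    coords = None
    if spatial_key in adata.obsm:
        coords = SpatialCoords(
            np.asarray(adata.obsm[spatial_key])[:, :2], list(adata.obs_names)
        )
    labels = None
    if label_key is not None and label_key in adata.obs:
        labels = [str(v) for v in adata.obs[label_key]]
    return expr, coords, labels


def write_anndata(
    path: str | Path,
    expr: ExpressionMatrix,
    coords: SpatialCoords | None = None,
    labels: Sequence[str] | None = None,
    label_key: str = "cell_type",
) -> None:
    import anndata as ad

    adata = ad.AnnData(
        X=expr.values,
        obs=pd.DataFrame(index=expr.row_ids),
        var=pd.DataFrame(index=expr.gene_ids),
    )
    if coords is not None:
        adata.obsm["spatial"] = coords.coords
    if labels is not None:
        adata.obs[label_key] = pd.Categorical([str(v) for v in labels])
    adata.write_h5ad(str(path))
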