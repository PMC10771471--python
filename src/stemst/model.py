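"""Shared MLP encoder, adjacency/mapping predictors, and loss terms.

The model embeds single-cell (SC) and spatial-transcriptomics (ST) expression
vectors with one shared encoder. Three losses shape the latent space:

* ``L_extract`` — row cross-entropy between the ST-ST adjacency predicted
  from ST embeddings (row-softmax of the Gram matrix) and the ground-truth
  kernel adjacency, so ST embeddings encode spatial proximity.
* ``L_mmd`` — maximum mean discrepancy between SC and ST embedding batches,
  pulling the two domains onto a common distribution.
* ``L_trans`` — row cross-entropy between the two-step adjacency
  ``S_hat = C_hat @ C`` (spot -> cell -> spot round trip through the
  cross-domain mapping matrices) and the ground truth, forcing the
  cross-domain inner products themselves to carry spatial structure.

Everything here is plain NumPy; gradients for all three losses are analytic
and verified against finite differences in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .adjacency import SpatialAdjacency
from .data_model import ExpressionMatrix, LOGNORM, RAW

SC = "SC"
ST = "ST"


@dataclass
class EncoderConfig:
    """Architecture and regularization settings for the shared encoder.

    ``st_dropout_rate`` is the probability of zeroing an ST input entry
    before the first layer, used to match the sparsity of the (sparser) SC
    profiles; see :func:`sparsity_dropout_rate`.
    """

    n_genes: int
    hidden_sizes: tuple[int, ...] = (512,)
    latent_dim: int = 128
    st_dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if not 0.0 <= self.st_dropout_rate < 1.0:
            raise ValueError("st_dropout_rate must be in [0, 1)")


@dataclass
class Embeddings:
    """An (n, h) block of latent vectors tagged with its domain."""

    vectors: np.ndarray
    domain: str

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2:
            raise ValueError("embeddings must be 2-D")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embeddings must be finite")
        if self.domain not in (SC, ST):
            raise ValueError(f"unknown domain {self.domain!r}")


@dataclass
class LossRecord:
    """One optimization step's (or epoch's) loss decomposition."""

    l_extract: float
    l_mmd: float
    l_trans: float
    alpha: float
    beta: float
    total: float = field(init=False)

    def __post_init__(self) -> None:
        self.total = self.l_extract + self.alpha * self.l_mmd + self.beta * self.l_trans


def total_loss(
    l_extract: float, l_mmd: float, l_trans: float, alpha: float = 0.5, beta: float = 1.0
) -> LossRecord:
    """Combine the three loss terms: ``L = L_extract + alpha*L_mmd + beta*L_trans``."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must be in [0, 1]")
    return LossRecord(l_extract, l_mmd, l_trans, alpha, beta)


def sparsity_dropout_rate(sc: ExpressionMatrix, st: ExpressionMatrix) -> float:
    """Dropout rate equalizing SC and ST sparsity.

    ``d = 1 - median(genes detected per cell) / median(genes detected per
    spot)``, clamped to [0, 0.95]. Spots aggregate several cells and detect
    more genes, so dropping a fraction d of ST inputs puts both domains at a
    comparable detection level before the shared encoder.
    """
    for m, name in ((sc, "SC"), (st, "ST")):
        if m.values.size == 0 or not np.any(m.values > 0):
            raise ValueError(f"{name} matrix has no nonzero entries")
    med_sc = float(np.median((sc.values > 0).sum(axis=1)))
    med_st = float(np.median((st.values > 0).sum(axis=1)))
    d = 1.0 - med_sc / med_st
    if d < 0:
        warnings.warn(
            "SC data is denser than ST data; clamping sparsity dropout to 0"
        )
        return 0.0
    return min(d, 0.95)


# ---------------------------------------------------------------------------
# Encoder
# ---------------------------------------------------------------------------

class MLPEncoder:
    """Fully connected encoder: n_genes -> hidden ... -> latent_dim.

    ReLU after each hidden layer, linear output. Parameters are He-initialized
    from ``cfg.seed``. Forward passes cache activations for the analytic
    backward pass.
    """

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator | None = None):
        self.cfg = cfg
        rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        sizes = [cfg.n_genes, *cfg.hidden_sizes, cfg.latent_dim]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        n_maps = len(sizes) - 1
        for layer, (fan_in, fan_out) in enumerate(zip(sizes[:-1], sizes[1:])):
            scale = np.sqrt(2.0 / fan_in)
            if layer == n_maps - 1:
                # keep initial embeddings small so the Gram-matrix softmaxes
                # start near-uniform instead of saturated
                scale = 0.1 * np.sqrt(1.0 / fan_in)
            self.weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def parameters(self) -> list[np.ndarray]:
        return [*self.weights, *self.biases]

    def forward(
        self,
        x: np.ndarray,
        dropout_rate: float = 0.0,
        dropout_rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, dict]:
        """Return (embeddings, cache). Dropout uses inverted scaling 1/(1-d)."""
        x = np.asarray(x, dtype=float)
        if x.shape[1] != self.cfg.n_genes:
            raise ValueError(
                f"input has {x.shape[1]} genes, encoder expects {self.cfg.n_genes}"
            )
        cache: dict = {"inputs": [], "relu_masks": [], "dropout_mask": None}
        h = x
        if dropout_rate > 0.0:
            if dropout_rng is None:
                raise ValueError("dropout requires a random generator")
            mask = dropout_rng.random(x.shape) >= dropout_rate
            h = x * mask / (1.0 - dropout_rate)
            cache["dropout_mask"] = mask
            cache["dropout_rate"] = dropout_rate
        for layer in range(self.n_layers):
            cache["inputs"].append(h)
            a = h @ self.weights[layer] + self.biases[layer]
            if layer < self.n_layers - 1:
                mask = a > 0
                cache["relu_masks"].append(mask)
                h = a * mask
            else:
                h = a
        return h, cache

    def encode(self, x: ExpressionMatrix | np.ndarray, domain: str = SC) -> Embeddings:
        """Deterministic (no-dropout) embedding of an expression matrix."""
        values = x.values if isinstance(x, ExpressionMatrix) else np.asarray(x)
        z, _ = self.forward(values)
        return Embeddings(z, domain)

    def backward(
        self, cache: dict, d_z: np.ndarray, accumulate: dict | None = None
    ) -> dict:
        """Backpropagate d(loss)/d(embeddings) to parameter and input grads.

        Returns ``{"weights": [...], "biases": [...], "input": dX}``; pass a
        previous result as `accumulate` to sum gradients over several forward
        passes through the shared encoder.
        """
        grads = accumulate or {
            "weights": [np.zeros_like(w) for w in self.weights],
            "biases": [np.zeros_like(b) for b in self.biases],
            "input": None,
        }
        delta = d_z
        for layer in range(self.n_layers - 1, -1, -1):
            h_in = cache["inputs"][layer]
            grads["weights"][layer] += h_in.T @ delta
            grads["biases"][layer] += delta.sum(axis=0)
            delta = delta @ self.weights[layer].T
            if layer > 0:
                delta = delta * cache["relu_masks"][layer - 1]
        if cache["dropout_mask"] is not None:
            delta = delta * cache["dropout_mask"] / (1.0 - cache["dropout_rate"])
        # parameter grads accumulate across shared-encoder passes; the input
        # grad belongs to this pass's batch only
        grads["input"] = delta
        return grads

    def state_dict(self) -> dict:
        return {
            **{f"w{i}": w for i, w in enumerate(self.weights)},
            **{f"b{i}": b for i, b in enumerate(self.biases)},
        }

    def load_state_dict(self, state: dict) -> None:
        for i in range(self.n_layers):
            self.weights[i] = np.asarray(state[f"w{i}"], dtype=float)
            self.biases[i] = np.asarray(state[f"b{i}"], dtype=float)

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    @classmethod
    def load(cls, path, cfg: EncoderConfig) -> "MLPEncoder":
        enc = cls(cfg)
        with np.load(path) as state:
            enc.load_state_dict({k: state[k] for k in state.files})
        return enc


def encode(
    x: ExpressionMatrix,
    encoder: MLPEncoder,
    training: bool = False,
    dropout_rng: np.random.Generator | None = None,
    domain: str = SC,
) -> Embeddings:
    """Embed log-normalized expression; dropout only when `training`."""
    if x.layer != LOGNORM:
        raise ValueError("encoder expects log-normalized expression")
    rate = encoder.cfg.st_dropout_rate if (training and domain == ST) else 0.0
    z, _ = encoder.forward(x.values, dropout_rate=rate, dropout_rng=dropout_rng)
    return Embeddings(z, domain)


# ---------------------------------------------------------------------------
# Predictors (all row-stochastic by construction)
# ---------------------------------------------------------------------------

def _row_softmax(scores: np.ndarray) -> np.ndarray:
    shifted = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def _row_log_softmax(scores: np.ndarray) -> np.ndarray:
    shifted = scores - scores.max(axis=1, keepdims=True)
    return shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))


def _masked_cross_entropy(truth: np.ndarray, log_pred: np.ndarray) -> float:
    """Mean row cross-entropy treating 0 * log(0) as 0.

    Kernel truths underflow to exact zeros at long range; those positions
    contribute nothing regardless of the prediction there.
    """
    terms = np.where(truth > 0, truth * log_pred, 0.0)
    return float(-terms.sum(axis=1).mean())


def intra_adjacency(z_st: Embeddings | np.ndarray) -> np.ndarray:
    """Predicted ST-ST adjacency: row-softmax of the embedding Gram matrix."""
    z = z_st.vectors if isinstance(z_st, Embeddings) else np.asarray(z_st)
    if z.shape[0] < 2:
        raise ValueError("need at least 2 spots")
    return _row_softmax(z @ z.T)


def cross_mapping(
    z_sc: Embeddings | np.ndarray, z_st: Embeddings | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """SC->ST and ST->SC mapping matrices from cross-domain inner products.

    ``C[i]`` is cell i's probability distribution over spots (row-softmax of
    B = Z_sc @ Z_st.T); ``C_hat[j]`` is spot j's distribution over cells
    (row-softmax of B.T).
    """
    zc = z_sc.vectors if isinstance(z_sc, Embeddings) else np.asarray(z_sc)
    zt = z_st.vectors if isinstance(z_st, Embeddings) else np.asarray(z_st)
    if zc.shape[1] != zt.shape[1]:
        raise ValueError("latent dimensions differ between domains")
    b = zc @ zt.T
    return _row_softmax(b), _row_softmax(b.T)


def two_step_adjacency(c: np.ndarray, c_hat: np.ndarray) -> np.ndarray:
    """Two-step ST-ST adjacency ``S_hat = C_hat @ C`` (spot -> cell -> spot)."""
    c = np.asarray(c, dtype=float)
    c_hat = np.asarray(c_hat, dtype=float)
    if c_hat.shape[1] != c.shape[0]:
        raise ValueError(
            f"shapes not conformable: C_hat {c_hat.shape}, C {c.shape}"
        )
    return c_hat @ c


def row_cross_entropy(pred: np.ndarray, truth: SpatialAdjacency | np.ndarray) -> float:
    """Mean over rows of ``-sum_j truth_ij * log(pred_ij)``."""
    t = truth.weights if isinstance(truth, SpatialAdjacency) else np.asarray(truth)
    pred = np.asarray(pred, dtype=float)
    if pred.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape}, truth {t.shape}")
    if (pred <= 0).any():
        raise ValueError("prediction entries must be strictly positive")
    return float(-(t * np.log(pred)).sum(axis=1).mean())


# ---------------------------------------------------------------------------
# Maximum mean discrepancy
# ---------------------------------------------------------------------------

DEFAULT_BANDWIDTH_FACTORS = (0.5, 1.0, 2.0)


def _sq_dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    aa = (a * a).sum(axis=1)[:, None]
    bb = (b * b).sum(axis=1)[None, :]
    return np.maximum(aa + bb - 2.0 * (a @ b.T), 0.0)


def _median_heuristic(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.vstack([a, b])
    d2 = _sq_dists(pooled, pooled)
    off = d2[np.triu_indices_from(d2, k=1)]
    med = float(np.sqrt(np.median(off))) if off.size else 1.0
    return med if med > 0 else 1.0


def _mmd_coefficients(m: int, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Coefficient matrices (U_aa, U_bb, U_ab) for the unbiased estimator.

    For equal batch sizes the paired U-statistic (diagonal excluded from the
    cross term too) is used, which is exactly zero when both batches are
    identical; otherwise the standard three-term unbiased estimator.
    """
    u_aa = np.full((m, m), 1.0 / (m * (m - 1)))
    np.fill_diagonal(u_aa, 0.0)
    u_bb = np.full((n, n), 1.0 / (n * (n - 1)))
    np.fill_diagonal(u_bb, 0.0)
    if m == n:
        u_ab = np.full((m, n), -2.0 / (m * (m - 1)))
        np.fill_diagonal(u_ab, 0.0)
    else:
        u_ab = np.full((m, n), -2.0 / (m * n))
    return u_aa, u_bb, u_ab


def mmd(
    z_a: Embeddings | np.ndarray,
    z_b: Embeddings | np.ndarray,
    kernel: str = "rbf",
    bandwidth_factors: tuple[float, ...] = DEFAULT_BANDWIDTH_FACTORS,
) -> float:
    """Unbiased squared maximum mean discrepancy between two batches.

    The default kernel is a sum of Gaussian RBFs at bandwidths
    ``{0.5, 1, 2} x`` the median pairwise distance of the pooled batch.
    ``kernel="linear"`` computes the biased linear-kernel statistic, whose
    closed form is ``||mean(z_a) - mean(z_b)||^2`` (useful as a hand check).
    """
    a = z_a.vectors if isinstance(z_a, Embeddings) else np.asarray(z_a, dtype=float)
    b = z_b.vectors if isinstance(z_b, Embeddings) else np.asarray(z_b, dtype=float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each batch needs at least 2 rows")
    if kernel == "linear":
        diff = a.mean(axis=0) - b.mean(axis=0)
        return float(diff @ diff)
    if kernel != "rbf":
        raise ValueError(f"unknown kernel {kernel!r}")
    value, _, _ = _mmd_with_grad(a, b, bandwidth_factors, want_grad=False)
    return value


def _mmd_with_grad(
    a: np.ndarray,
    b: np.ndarray,
    bandwidth_factors: tuple[float, ...] = DEFAULT_BANDWIDTH_FACTORS,
    want_grad: bool = True,
) -> tuple[float, np.ndarray | None, np.ndarray | None]:
    """RBF-kernel unbiased MMD^2 and its gradients w.r.t. both batches.

    Bandwidths (median heuristic) are treated as constants in the gradient.
    """
    m, n = a.shape[0], b.shape[0]
    u_aa, u_bb, u_ab = _mmd_coefficients(m, n)
    med = _median_heuristic(a, b)
    sigmas = [f * med for f in bandwidth_factors]
    d2_aa, d2_bb, d2_ab = _sq_dists(a, a), _sq_dists(b, b), _sq_dists(a, b)
    value = 0.0
    g_aa = np.zeros_like(d2_aa)
    g_bb = np.zeros_like(d2_bb)
    g_ab = np.zeros_like(d2_ab)
    for s in sigmas:
        two_s2 = 2.0 * s * s
        k_aa = np.exp(-d2_aa / two_s2)
        k_bb = np.exp(-d2_bb / two_s2)
        k_ab = np.exp(-d2_ab / two_s2)
        value += float((u_aa * k_aa).sum() + (u_bb * k_bb).sum() + (u_ab * k_ab).sum())
        if want_grad:
            g_aa += u_aa * k_aa / (s * s)
            g_bb += u_bb * k_bb / (s * s)
            g_ab += u_ab * k_ab / (s * s)
    if not want_grad:
        return value, None, None
    # d/dx exp(-|x-y|^2 / 2s^2) = -(x-y)/s^2 * k; U_aa and U_bb are symmetric,
    # so same-set points receive their row and column contributions (factor 2).
    d_a = -2.0 * (g_aa.sum(axis=1)[:, None] * a - g_aa @ a)
    d_b = -2.0 * (g_bb.sum(axis=1)[:, None] * b - g_bb @ b)
    d_a += -(g_ab.sum(axis=1)[:, None] * a - g_ab @ b)
    d_b += -(g_ab.sum(axis=0)[:, None] * b - g_ab.T @ a)
    return value, d_a, d_b


# ---------------------------------------------------------------------------
# Loss gradients with respect to embeddings (used by the training loop)
# ---------------------------------------------------------------------------

def _softmax_row_backward(p: np.ndarray, d_p: np.ndarray) -> np.ndarray:
    """Backprop through a row-softmax: dL/dscores from dL/dprobabilities."""
    inner = (d_p * p).sum(axis=1, keepdims=True)
    return p * (d_p - inner)


def extract_loss_and_grad(
    z_st: np.ndarray, s_truth: np.ndarray
) -> tuple[float, np.ndarray]:
    """``L_extract`` and its gradient w.r.t. the ST embeddings."""
    n = z_st.shape[0]
    scores = z_st @ z_st.T
    loss = _masked_cross_entropy(s_truth, _row_log_softmax(scores))
    d_scores = (_row_softmax(scores) - s_truth) / n  # softmax + CE shortcut
    d_z = (d_scores + d_scores.T) @ z_st
    return loss, d_z


def trans_loss_and_grad(
    z_sc: np.ndarray, z_st: np.ndarray, s_truth: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """``L_trans`` with gradients w.r.t. both embedding blocks.

    Returns ``(loss, d_z_sc, d_z_st, C, C_hat)`` so the training loop can
    reuse the mapping matrices without recomputing them.
    """
    n = z_st.shape[0]
    b = z_sc @ z_st.T
    c = _row_softmax(b)
    c_hat = _row_softmax(b.T)
    s_hat = c_hat @ c
    # entries are positive in exact arithmetic; guard against float underflow
    s_safe = np.maximum(s_hat, 1e-300)
    loss = _masked_cross_entropy(s_truth, np.log(s_safe))
    d_s_hat = -np.where(s_truth > 0, s_truth / s_safe, 0.0) / n
    d_c_hat = d_s_hat @ c.T
    d_c = c_hat.T @ d_s_hat
    d_b = _softmax_row_backward(c, d_c) + _softmax_row_backward(c_hat, d_c_hat).T
    return loss, d_b @ z_st, d_b.T @ z_sc, c, c_hat
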