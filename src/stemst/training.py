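"""Optimization loop: mini-batching, the dynamic beta schedule, and logging.

Training alternates nothing — every step optimizes the full objective
``L = L_extract + alpha * L_mmd + beta(t) * L_trans`` on one SC batch and one
ST batch, with beta ramping linearly from 0 to 1 over the run so the model
first learns to reconstruct spatial adjacency within ST and only then the
cross-domain mapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adjacency import SpatialAdjacency
from .data_model import ExpressionMatrix, LOGNORM
from .model import (
    Embeddings,
    EncoderConfig,
    LossRecord,
    MLPEncoder,
    SC,
    ST,
    _mmd_with_grad,
    extract_loss_and_grad,
    trans_loss_and_grad,
)

logger = logging.getLogger("stemst")


@dataclass
class TrainConfig:
    """Optimization hyperparameters.

    Batch sizes of ``None`` resolve to ``min(1024, M)`` cells and
    ``min(512, N)`` spots. The run is bit-reproducible for a fixed seed on
    one machine.
    """

    alpha: float = 0.5
    epochs: int = 400
    batch_size_sc: int | None = None
    batch_size_st: int | None = None
    learning_rate: float = 1e-3
    seed: int = 0
    beta_schedule: str = "linear"

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.beta_schedule not in ("linear", "constant"):
            raise ValueError(f"unknown beta schedule {self.beta_schedule!r}")


def beta_schedule(epoch: int, total_epochs: int, kind: str = "linear") -> float:
    """Weight of the transition loss at a given epoch.

    Linear: 0 at the first epoch, 1 at the last, interpolated in between.
    A single-epoch linear schedule degenerates to 1.
    """
    if not 0 <= epoch < total_epochs:
        raise ValueError(f"epoch {epoch} outside [0, {total_epochs})")
    if kind == "constant":
        return 1.0
    if kind != "linear":
        raise ValueError(f"unknown beta schedule {kind!r}")
    if total_epochs < 2:
        return 1.0
    return epoch / (total_epochs - 1)


class Adam:
    """Adam optimizer over a flat list of parameter arrays (in-place updates)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


@dataclass
class TrainResult:
    encoder: MLPEncoder
    z_sc: Embeddings
    z_st: Embeddings
    history: pd.DataFrame


def _batches(n: int, batch_size: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [perm[i : i + batch_size] for i in range(0, n, batch_size)]


def train_stem(
    sc: ExpressionMatrix,
    st: ExpressionMatrix,
    s_truth: SpatialAdjacency,
    enc_cfg: EncoderConfig | None = None,
    cfg: TrainConfig | None = None,
) -> TrainResult:
    """Train the shared encoder on aligned SC and ST expression.

    Per step, ``L_extract`` and ``L_trans`` are evaluated on the sub-matrix
    of the ground-truth adjacency restricted to the ST batch, with rows
    renormalized so each target row stays a distribution; when the ST batch
    is the full dataset this equals the full-data loss. Inputs are never
    mutated. Returns final no-dropout embeddings and a per-epoch loss table.
    """
    cfg = cfg or TrainConfig()
    if sc.layer != LOGNORM or st.layer != LOGNORM:
        raise ValueError("training expects log-normalized SC and ST matrices")
    if sc.gene_ids != st.gene_ids:
        raise ValueError("SC and ST gene sets are not aligned")
    n_spots, m_cells = st.n_rows, sc.n_rows
    if s_truth.n != n_spots:
        raise ValueError("ground-truth adjacency does not match ST rows")
    enc_cfg = enc_cfg or EncoderConfig(n_genes=sc.n_genes, seed=cfg.seed)
    bs_sc = cfg.batch_size_sc or min(1024, m_cells)
    bs_st = cfg.batch_size_st or min(512, n_spots)
    if bs_sc < 2 or bs_st < 2:
        raise ValueError("batch sizes must be >= 2")

    root = np.random.default_rng(cfg.seed)
    init_rng, dropout_rng, batch_rng = root.spawn(3)
    encoder = MLPEncoder(enc_cfg, rng=init_rng)
    optimizer = Adam(encoder.parameters(), lr=cfg.learning_rate)

    x_sc, x_st = sc.values, st.values
    s_full = s_truth.weights
    records: list[LossRecord] = []
    for epoch in range(cfg.epochs):
        beta = beta_schedule(epoch, cfg.epochs, cfg.beta_schedule)
        sc_batches = _batches(m_cells, bs_sc, batch_rng)
        st_batches = _batches(n_spots, bs_st, batch_rng)
        n_steps = max(len(sc_batches), len(st_batches))
        epoch_terms = np.zeros(3)
        for step in range(n_steps):
            idx_sc = sc_batches[step % len(sc_batches)]
            idx_st = st_batches[step % len(st_batches)]
            s_batch = s_full[np.ix_(idx_st, idx_st)]
            s_batch = s_batch / s_batch.sum(axis=1, keepdims=True)

            z_st, cache_st = encoder.forward(
                x_st[idx_st],
                dropout_rate=enc_cfg.st_dropout_rate,
                dropout_rng=dropout_rng,
            )
            z_sc, cache_sc = encoder.forward(x_sc[idx_sc])

            l_ext, d_st_ext = extract_loss_and_grad(z_st, s_batch)
            l_mmd, d_sc_mmd, d_st_mmd = _mmd_with_grad(z_sc, z_st)
            l_trans, d_sc_tr, d_st_tr, _, _ = trans_loss_and_grad(z_sc, z_st, s_batch)
            for name, value in (
                ("L_extract", l_ext), ("L_MMD", l_mmd), ("L_trans", l_trans)
            ):
                if not np.isfinite(value):
                    raise FloatingPointError(
                        f"non-finite loss term {name} at epoch {epoch}, step {step}"
                    )

            d_z_st = d_st_ext + cfg.alpha * d_st_mmd + beta * d_st_tr
            d_z_sc = cfg.alpha * d_sc_mmd + beta * d_sc_tr
            grads = encoder.backward(cache_st, d_z_st)
            grads = encoder.backward(cache_sc, d_z_sc, accumulate=grads)
            optimizer.step([*grads["weights"], *grads["biases"]])
            epoch_terms += (l_ext, l_mmd, l_trans)

        mean_terms = epoch_terms / n_steps
        records.append(LossRecord(*mean_terms, alpha=cfg.alpha, beta=beta))
        if epoch % max(1, cfg.epochs // 10) == 0 or epoch == cfg.epochs - 1:
            logger.info(
                "epoch %d/%d: extract=%.4f mmd=%.4f trans=%.4f beta=%.2f",
                epoch, cfg.epochs, *mean_terms, beta,
            )

    z_sc_final, _ = encoder.forward(x_sc)
    z_st_final, _ = encoder.forward(x_st)
    history = pd.DataFrame(
        {
            "epoch": np.arange(cfg.epochs),
            "l_extract": [r.l_extract for r in records],
            "l_mmd": [r.l_mmd for r in records],
            "l_trans": [r.l_trans for r in records],
            "alpha": [r.alpha for r in records],
            "beta": [r.beta for r in records],
            "total": [r.total for r in records],
        }
    )
    return TrainResult(
        encoder, Embeddings(z_sc_final, SC), Embeddings(z_st_final, ST), history
    )
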