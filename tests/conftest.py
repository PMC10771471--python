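"""Shared fixtures: small random inputs and session-scoped trained models."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from stemst import (
    EncoderConfig,
    TrainConfig,
    gaussian_adjacency,
    generate_pseudo_st,
    normalize_expression,
    synthetic_tissue,
    train_stem,
)
from stemst.model import sparsity_dropout_rate


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def _train_on_tissue(noise_r: float = 0.0, epochs: int = 100):
    """Train on the standard synthetic benchmark tissue.

    2000 cells x 200 genes, 5 spatially contiguous types, 20 x 20 pseudo-spot
    grid; optional gene-variance-scaled Gaussian noise on the SC counts.
    """
    from stemst import add_expression_noise

    tissue = synthetic_tissue(2000, 200, 5, seed=0)
    pseudo = generate_pseudo_st(
        tissue.sc_expr, tissue.sc_coords, tissue.labels, grid=(20, 20), seed=0
    )
    sc_raw = (
        add_expression_noise(tissue.sc_expr, noise_r, seed=0)
        if noise_r > 0
        else tissue.sc_expr
    )
    dropout = sparsity_dropout_rate(sc_raw, pseudo.st_expr)
    sc_norm = normalize_expression(sc_raw)
    st_norm = normalize_expression(pseudo.st_expr)
    s_truth = gaussian_adjacency(pseudo.st_coords)
    result = train_stem(
        sc_norm,
        st_norm,
        s_truth,
        EncoderConfig(n_genes=200, st_dropout_rate=dropout, seed=0),
        TrainConfig(epochs=epochs, seed=0),
    )
    return tissue, pseudo, result


@pytest.fixture(scope="session")
def trained_benchmark():
    """Model trained on the clean benchmark tissue (shared across tests)."""
    return _train_on_tissue(noise_r=0.0)


@pytest.fixture(scope="session")
def trained_toy():
    """A tiny trained model for attribution tests: 150 cells, 30 genes."""
    tissue = synthetic_tissue(150, 30, 2, n_spatial_genes=10, seed=3)
    pseudo = generate_pseudo_st(
        tissue.sc_expr, tissue.sc_coords, tissue.labels, grid=(5, 5),
        capture_radius=18.0, seed=3,
    )
    sc_norm = normalize_expression(tissue.sc_expr)
    st_norm = normalize_expression(pseudo.st_expr)
    s_truth = gaussian_adjacency(pseudo.st_coords)
    result = train_stem(
        sc_norm,
        st_norm,
        s_truth,
        EncoderConfig(n_genes=30, hidden_sizes=(32,), latent_dim=8, seed=3),
        TrainConfig(epochs=60, batch_size_sc=150, batch_size_st=None, seed=3),
    )
    return tissue, pseudo, sc_norm, result
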