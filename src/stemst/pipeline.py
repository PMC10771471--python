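"""End-to-end pipeline runner: normalize -> align -> adjacency -> train ->
map -> (attribute) -> evaluate, with a resolved config and a file manifest
written into the run directory."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import adjacency as adj
from .attribution import attribution_profile, fit_trajectory, identify_sdgs, segment_cells
from .data_model import (
    CellTypeAnnotation,
    ExpressionMatrix,
    SpatialCoords,
    align_genes,
    normalize_expression,
    one_hot_annotation,
    select_variable_genes,
    write_coords_csv,
    write_expression_csv,
)
from .evaluation import evaluate_mapping
from .mapping import deconvolve, pseudo_coordinates, sc_adjacency
from .model import EncoderConfig, cross_mapping, sparsity_dropout_rate
from .simulation import PseudoSTDataset, SyntheticTissue, generate_pseudo_st, synthetic_tissue
from .training import TrainConfig, train_stem

logger = logging.getLogger("stemst")


@dataclass
class RunConfig:
    """Resolved configuration of one end-to-end run (YAML round-trippable)."""

    out_dir: str = "stem_run"
    kernel: str = "gaussian"
    kernel_params: dict = field(default_factory=dict)
    n_hvg: int | None = None
    latent_dim: int = 128
    hidden_sizes: tuple[int, ...] = (512,)
    alpha: float = 0.5
    epochs: int = 400
    batch_size_sc: int | None = None
    batch_size_st: int | None = None
    learning_rate: float = 1e-3
    seed: int = 0
    attribution_steps: int | None = None
    n_segments: int = 11
    fdr: float = 0.05
    eval_ks: tuple[int, ...] = (10, 20, 50)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("hidden_sizes", "eval_ks"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)


def run_pipeline(
    cfg: RunConfig,
    sc_raw: ExpressionMatrix,
    sc_coords: SpatialCoords | None,
    labels: CellTypeAnnotation | list[str],
    pseudo: PseudoSTDataset,
) -> Path:
    """Run the full method on prepared inputs and write artifacts + manifest.

    `sc_coords` is optional ground truth: when present the evaluation stage
    runs and an ``evaluation.json`` report is produced.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    if not isinstance(labels, CellTypeAnnotation):
        labels = one_hot_annotation(labels)
    manifest: dict[str, str] = {"config": "config.yaml"}

    def stage(name):
        logger.info("stage %s starting", name)
        return time.perf_counter()

    t0 = stage("normalize")
    dropout = sparsity_dropout_rate(sc_raw, pseudo.st_expr)
    sc_norm = normalize_expression(sc_raw)
    st_norm = normalize_expression(pseudo.st_expr)
    if sc_norm.n_rows != sc_raw.n_rows:  # zero-count cells were dropped
        keep = [i for i, r in enumerate(sc_raw.row_ids) if r in set(sc_norm.row_ids)]
        labels = one_hot_annotation([labels.labels[i] for i in keep])
        if sc_coords is not None:
            sc_coords = SpatialCoords(
                sc_coords.coords[keep], [sc_coords.row_ids[i] for i in keep]
            )
    if st_norm.n_rows != pseudo.st_expr.n_rows:
        raise RuntimeError("pseudo-spots with zero counts; regenerate with more cells")
    sc_norm, st_norm = align_genes(sc_norm, st_norm)
    if cfg.n_hvg is not None and cfg.n_hvg < sc_norm.n_genes:
        hvg = sorted(
            set(select_variable_genes(sc_norm, cfg.n_hvg))
            | set(select_variable_genes(st_norm, cfg.n_hvg))
        )
        sc_norm, st_norm = align_genes(sc_norm, st_norm, gene_set=hvg)
    logger.info("normalize done in %.1fs (%d genes)", time.perf_counter() - t0,
                sc_norm.n_genes)

    t0 = stage("adjacency")
    s_truth = adj.build_adjacency(pseudo.st_coords, cfg.kernel, **cfg.kernel_params)
    t0 = stage("train")
    enc_cfg = EncoderConfig(
        n_genes=sc_norm.n_genes,
        hidden_sizes=tuple(cfg.hidden_sizes),
        latent_dim=cfg.latent_dim,
        st_dropout_rate=dropout,
        seed=cfg.seed,
    )
    train_cfg = TrainConfig(
        alpha=cfg.alpha,
        epochs=cfg.epochs,
        batch_size_sc=cfg.batch_size_sc,
        batch_size_st=cfg.batch_size_st,
        learning_rate=cfg.learning_rate,
        seed=cfg.seed,
    )
    result = train_stem(sc_norm, st_norm, s_truth, enc_cfg, train_cfg)
    result.history.to_csv(out / "loss_history.csv", index=False)
    result.encoder.save(out / "checkpoint.npz")
    manifest["loss_history"] = "loss_history.csv"
    manifest["checkpoint"] = "checkpoint.npz"
    logger.info("train done in %.1fs", time.perf_counter() - t0)

    t0 = stage("map")
    c, c_hat = cross_mapping(result.z_sc, result.z_st)
    coords_pred = pseudo_coordinates(c, pseudo.st_coords)
    coords_pred.row_ids = list(sc_norm.row_ids)
    decon = deconvolve(c_hat, labels)
    adj_sc = sc_adjacency(result.z_sc)
    pd.DataFrame(c, index=sc_norm.row_ids, columns=st_norm.row_ids).to_csv(
        out / "C.csv"
    )
    pd.DataFrame(c_hat, index=st_norm.row_ids, columns=sc_norm.row_ids).to_csv(
        out / "Chat.csv"
    )
    write_coords_csv(coords_pred, out / "pseudo_coords.csv")
    pd.DataFrame(
        decon.proportions, index=st_norm.row_ids, columns=decon.cell_types
    ).to_csv(out / "proportions.csv")
    manifest.update(
        C="C.csv", Chat="Chat.csv", pseudo_coords="pseudo_coords.csv",
        proportions="proportions.csv",
    )
    logger.info("map done in %.1fs", time.perf_counter() - t0)

    if cfg.attribution_steps:
        t0 = stage("attribute")
        profile = attribution_profile(
            sc_norm, result.encoder, result.z_st, steps=cfg.attribution_steps
        )
        pd.DataFrame(
            profile.scores, index=sc_norm.row_ids, columns=sc_norm.gene_ids
        ).to_csv(out / "attribution_scores.csv")
        manifest["attribution_scores"] = "attribution_scores.csv"
        if sc_coords is not None:
            traj = fit_trajectory(sc_coords)
            segments = segment_cells(traj, cfg.n_segments)
            sdgs = identify_sdgs(profile, segments, fdr=cfg.fdr)
            sdgs.to_csv(out / "sdgs.csv", index=False)
            manifest["sdgs"] = "sdgs.csv"
        logger.info("attribute done in %.1fs", time.perf_counter() - t0)

    if sc_coords is not None:
        t0 = stage("evaluate")
        report = evaluate_mapping(
            sc_coords,
            coords_pred,
            adj_sc,
            c,
            labels,
            pseudo.true_proportions,
            ks=list(cfg.eval_ks),
            cell_types=pseudo.cell_types,
            notes={"seed": cfg.seed, "n_cells": sc_norm.n_rows,
                   "n_spots": st_norm.n_rows, "n_genes": sc_norm.n_genes},
        )
        (out / "evaluation.json").write_text(json.dumps(report.to_dict(), indent=2))
        manifest["evaluation"] = "evaluation.json"
        logger.info("evaluate done in %.1fs", time.perf_counter() - t0)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    for rel in manifest.values():
        p = out / rel
        if not p.exists() or p.stat().st_size == 0:
            raise RuntimeError(f"manifest entry missing or empty: {p}")
    return out


def run_synthetic_pipeline(
    cfg: RunConfig,
    n_cells: int = 2000,
    n_genes: int = 200,
    n_types: int = 5,
    grid: tuple[int, int] = (20, 20),
) -> Path:
    """Convenience wrapper: synthesize a tissue, derive pseudo-ST, run everything."""
    tissue = synthetic_tissue(n_cells, n_genes, n_types, seed=cfg.seed)
    pseudo = generate_pseudo_st(
        tissue.sc_expr, tissue.sc_coords, tissue.labels, grid=grid, seed=cfg.seed
    )
    return run_pipeline(cfg, tissue.sc_expr, tissue.sc_coords, tissue.labels, pseudo)
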