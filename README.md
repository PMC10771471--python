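# stemst

Spatially aware embedding of single-cell and spatial transcriptomics.

Spot-based spatial transcriptomics (ST) measures gene expression at known
tissue positions, but each spot mixes several cells; single-cell RNA-seq (SC)
resolves individual cells but loses their positions. `stemst` integrates the
two: a shared encoder embeds both data types into one latent space in which
inner products carry spatial information, yielding for every cell a
probabilistic tissue location, for every spot a cell-type composition, and
for every gene a quantitative contribution to each cell's placement.

## Model

Let `X_ST ∈ R^{N×H}` and `X_SC ∈ R^{M×H}` be log-normalized expression over
the same `H` genes, and `Y_ST ∈ R^{N×2}` the spot coordinates. Coordinates
are converted to a row-stochastic ground-truth adjacency `S` with a Gaussian
kernel (σ defaults to half the mean nearest-neighbor spot distance;
exponential and KNN kernels are available):

    φ(Y_i, Y_j) = exp(−‖Y_i − Y_j‖² / 2σ²) / (√(2π) σ),   S_ij = φ_ij / Σ_k φ_ik

A shared MLP encoder `f_θ` (H → 512 → 128; ST inputs pass a sparsity-matching
dropout layer with rate `d = 1 − median(n_SC)/median(n_ST)`) produces
embeddings `Z_ST`, `Z_SC`. Three losses are minimized jointly:

    S̃_ij = softmax_j ⟨Z_i^ST, Z_j^ST⟩          L_extract = H(S̃, S)
    C    = softmax_rows(Z_SC Z_ST^T)            (cell → spot mapping)
    Ĉ    = softmax_rows(Z_ST Z_SC^T)            (spot → cell mapping)
    Ŝ    = Ĉ C                                  L_trans = H(Ŝ, S)
    L    = L_extract + α·MMD(Z_SC, Z_ST) + β·L_trans

with `H` the mean row cross-entropy, `α = 0.5`, and `β` ramping linearly from
0 to 1 over training so the encoder first learns spatial structure within ST
and then the cross-domain mapping. The MMD term (unbiased multi-bandwidth
RBF estimator) aligns the two embedding distributions.

After training:

* pseudo-coordinates `Ŷ_SC = C · Y_ST`,
* spot deconvolution `T̂_ST = Ĉ · T_SC` (one-hot cell-type indicator `T_SC`),
* SC–SC adjacency `⟨Z_i^SC, Z_j^SC⟩` (evaluated by neighbor-rank overlap),
* per-spot scalar annotations (e.g. zonation scores) transfer to cells as `C·v`,
* integrated gradients of each cell's mapped-spot probability attribute the
  placement to genes; genes significantly elevated within segments of a
  fitted spatial trajectory (one-sided rank-sum, Benjamini–Hochberg) are
  called spatially dominant genes (SDGs).

Everything is plain NumPy, including the encoder, backpropagation, Adam, and
the analytic integrated-gradient computation; gradients are verified against
finite differences in the test suite.

## Worked example

```python
from stemst import (synthetic_tissue, generate_pseudo_st, normalize_expression,
                    gaussian_adjacency, train_stem, cross_mapping,
                    pseudo_coordinates, hit_number, coordinate_mae,
                    EncoderConfig, TrainConfig)
from stemst.model import sparsity_dropout_rate
from stemst.mapping import sc_adjacency

tissue = synthetic_tissue(2000, 200, 5, seed=0)          # cells with true positions
pseudo = generate_pseudo_st(tissue.sc_expr, tissue.sc_coords,
                            tissue.labels, grid=(20, 20), seed=0)
d = sparsity_dropout_rate(tissue.sc_expr, pseudo.st_expr)
sc = normalize_expression(tissue.sc_expr)
st = normalize_expression(pseudo.st_expr)
S = gaussian_adjacency(pseudo.st_coords)
fit = train_stem(sc, st, S,
                 EncoderConfig(n_genes=200, st_dropout_rate=d, seed=0),
                 TrainConfig(epochs=200, seed=0))
C, Chat = cross_mapping(fit.z_sc, fit.z_st)
print("MAE:", coordinate_mae(tissue.sc_coords,
                             pseudo_coordinates(C, pseudo.st_coords).coords))
print("hit@20:", hit_number(tissue.sc_coords, sc_adjacency(fit.z_sc), 20))
```

prints (tissue spans a 100 × 100 unit square; chance-level 20-NN overlap for
2,000 cells is 0.20):

```
MAE: 22.9
hit@20: 1.31
```

i.e. predicted positions land ~23 units from the truth (uniform-random
placement gives ~52) and true nearest neighbors are recovered ~6.5× more
often than chance.

The same pipeline is scriptable from the shell:

```bash
stem synth --cells 2000 --genes 200 --types 5 --seed 0 --out tissue.h5ad
stem simulate --sc tissue.h5ad --grid 20x20 --out pseudo.h5ad
stem run --seed 0 --out run_dir/
```

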