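# Methods

## The integration problem

Spot-based spatial transcriptomics (ST) reports expression at known tissue
coordinates, but each spot aggregates several cells; single-cell RNA-seq
(SC) resolves cells but not positions. The package learns one latent space
in which both data types live and in which inner products reproduce spatial
proximity, so that cross-domain inner products define a probabilistic
SC↔ST mapping.

## Preprocessing

Raw counts are depth-normalized per row to 10,000 and transformed as
`log(1 + x)`. Rows with zero totals are dropped with a warning by default
(pseudo-spot generation can create empty rows at tissue edges) or rejected
with an error on request. Genes are matched by exact, case-sensitive string
comparison — silent case-folding hides species or annotation mismatches.
Highly variable genes are ranked by mean-binned normalized dispersion of the
log values: dispersions (variance/mean) are z-scored within 20 equal-
frequency mean bins (capped so every bin holds at least three genes), which
removes the mean–dispersion trend; ties resolve by column order, making the
selection deterministic. When both datasets are reduced, the default gene
set is the union of the per-dataset selections, so genes variable in either
domain survive alignment.

## Ground-truth spatial adjacency

Spot coordinates become a row-stochastic adjacency matrix `S`. The Gaussian
kernel (default) includes the self-pair — the printed density at distance 0
is the row maximum, which supervises identity preservation — and its
bandwidth σ defaults to half the mean nearest-neighbor spot distance, which
adapts to the slide's units; duplicate coordinates drive that default to
zero, which is reported as an error asking for an explicit σ. The
exponential kernel `exp(−d/l)` and a KNN indicator kernel (self excluded,
1/k per neighbor, ties at the k-th distance broken by spot index) are
drop-in alternatives; every kernel's rows are normalized to sum to exactly 1.
Distances are Euclidean in input units with no rescaling.

## Encoder and objective

A single MLP (inputs → 512 → 128, ReLU on the hidden layer, linear output,
biases on) embeds both domains. The architecture is intentionally the
smallest consistent with a latent dimension of 128; depth, width and
activation are exposed in `EncoderConfig`. Because a spot detects more genes
than a cell, ST inputs pass an inverted-dropout layer with rate
`d = 1 − median(genes per cell)/median(genes per spot)` (clamped to
[0, 0.95]) during training, putting both domains at comparable sparsity
before the shared weights.

Three losses act on the embeddings:

* **Extraction** — mean row cross-entropy between the row-softmax of the ST
  Gram matrix and the ground-truth adjacency.
* **Alignment** — unbiased MMD² between SC and ST batches under a sum of
  Gaussian RBF kernels at bandwidths {0.5, 1, 2} × the median pairwise
  distance of the pooled batch (a standard bandwidth-robust choice; the
  median is treated as a constant in the gradient). For equal batch sizes
  the paired U-statistic is used, which is exactly zero on identical
  batches; otherwise the three-term unbiased estimator. A linear-kernel
  variant (closed form ‖μ_a − μ_b‖²) exists for hand checks.
* **Transition** — cross-entropy between `Ŝ = Ĉ·C` and the truth, where `C`
  and `Ĉ` are the row-softmaxed cross-domain inner products. This is the
  term that makes the mapping matrices themselves spatially meaningful.

The total is `L_extract + α·L_MMD + β·L_trans` with α = 0.5 throughout and β
ramping linearly from 0 (first epoch) to 1 (last): the encoder first learns
spatial structure within ST, then the cross-domain transfer. A constant-β
schedule is available; a single-epoch linear schedule degenerates to β = 1.

All softmaxes subtract the per-row maximum. Cross-entropies treat
`0 · log 0` as 0 — kernel truths underflow to exact zeros at long range — and
the transition loss clips `Ŝ` at 1e−300 before the logarithm, since its
entries are positive in exact arithmetic but can underflow. The output
layer is initialized at a deliberately small scale (0.1/√fan_in) so the Gram
softmaxes start near-uniform rather than saturated.

## Optimization

Adam (learning rate 1e−3, default 400 epochs, no weight decay), mini-batches
of min(1024, M) cells and min(512, N) spots drawn without replacement per
epoch. The extraction and transition targets use the ground-truth adjacency
restricted to the ST batch with rows renormalized, so each target row stays
a distribution; with a full-data ST batch this equals the full-data loss
exactly. One config seed spawns independent streams for parameter
initialization, dropout masks, and batching, making runs bit-reproducible on
a machine. A non-finite loss aborts immediately, naming the offending term.
No early stopping by default, to keep runs reproducible.

The implementation is pure NumPy — forward passes, analytic gradients of all
three losses, backpropagation through the shared encoder (parameter
gradients accumulate over the SC and ST passes), and Adam. Every gradient is
verified against central finite differences in the test suite.

## Mapping products

`C` rows are cells' distributions over spots; `Ĉ` rows are spots'
distributions over cells. Products: pseudo-coordinates `C·Y_ST` (always
inside the spot hull), deconvolution `Ĉ·T_SC` (valid proportions by
construction, columns in sorted label order), per-spot scalar transfer
`C·v`, and the SC–SC adjacency as the raw embedding Gram matrix —
deliberately unnormalized because downstream evaluation is rank-based within
rows, so any monotone rescaling is irrelevant. `unify_mapping` accepts any
non-negative cell×spot weight matrix (e.g. exported by other tools),
renormalizes rows, flags zero rows as unmapped (NaN coordinates, excluded
from ranking) and produces neighbor ranks with ties broken by smaller index.

## Attribution and spatially dominant genes

For cell i the scalar of interest is `C_{i,m}`, its probability at its
argmax spot m, recomputed with the ST embeddings frozen; gradients flow
through the encoder and the softmax over spots. Integrated gradients use the
straight path from the all-zero baseline with a midpoint Riemann sum
(default 50 steps); the per-cell completeness residual
`|Σ_j W_ij − (f(x) − f(0))|` is reported, not hidden. Genes absent from a
cell get exactly zero attribution (the `x_j` factor).

Spatial trajectories fit `y = p(x)` by least squares (degree 5 by default;
the fit regresses y on x, so a vertical cloud is rejected with advice to
lower the degree or rotate). Pseudotime is unsigned arc length along the
curve between the cell's x and the start cell's x (top-right corner: max x,
ties by max y), computed by trapezoid quadrature of `√(1 + p′(x)²)` on a
20,001-point grid and interpolation — accurate to ~1e−8 on the tested
curves. Cells are divided into equal-width pseudotime segments (11 by
default; equal-count bins behind a flag). Each gene × segment combination is
tested one-sided (greater) by Wilcoxon rank-sum against the pooled remaining
segments; Benjamini–Hochberg runs across all tests and hits below the FDR
threshold (0.05 default) define SDGs. Segments with fewer than two cells are
excluded with a warning. The same machinery applied to expression instead of
attribution (`identify_degs`) gives the expression-based comparison.

## Semi-simulation

Pseudo-ST spots sit at the crossings of a regular grid (default 30 × 40)
over the coordinate bounding box. A cell joins at most one spot — its
nearest node — and only within a capture radius, mimicking the partial
tissue coverage of real capture arrays; the radius is calibrated on a
400-point lattice to the smallest value reaching a target captured fraction
(default 2/3, ±0.05 band). Spots with fewer than three member cells are
discarded. Spot expression is the exact integer sum of member counts (total
counts over spots equal total counts over covered cells), proportions come
from member labels, and membership plus the covered-cell set are kept for
stratified evaluation. Alternative spot resolutions are expressed as grid
densities, not physical units, because synthetic coordinates are unitless.
Expression noise is zero-mean Gaussian with per-gene variance `R × Var(g)`
(population variance of the raw values), clipped at zero; `R = 0` is an
exact identity, and graded sweeps such as R ∈ {0.2, 0.4, 0.6, 0.8} are plain
arguments.

## Synthetic tissue generator

The generator emulates single-cell-resolution spatial data: cells uniform on
a 100 × 100 square; cell types are the Voronoi regions of well-separated
centers (greedy max-min selection from random candidates), so each type is a
contiguous domain; counts are negative binomial (dispersion 3) around
log-normal baseline means with 6-fold markers (8 per type) on non-spatial
genes; one-fifth of genes carry type-independent spatial programs
alternating linear gradients (the first gene is a canonical left-to-right
gradient) and Gaussian bumps, multiplying means over a [0.2, ~2.7] range
with a 4× baseline boost so the patterns are well expressed. All generation
parameters are recorded in `archetype_params`, and a given seed reproduces
the dataset bit-for-bit.

What the generator does *not* emulate: sequencing-depth variation between
cells, ambient RNA, doublets, batch effects, irregular tissue boundaries, or
non-convex/interleaved cell-type territories. Passing tests therefore show
the method recovers smooth, region-structured spatial signal through the
spot-aggregation bottleneck — not that it is robust to every artifact of
real assays.

## Evaluation

* **Coordinate MAE** — mean Euclidean distance between paired predicted and
  true positions; optional masks restrict to covered/mapped cells (the
  alternative convention of zero-filling discarded cells is available to
  callers by substituting coordinates before the call).
* **Hit number** — mean overlap between each cell's true k-NN set (by
  coordinates) and predicted k-NN set (k largest row entries of the
  predicted adjacency, self excluded, ties by index). Chance level is
  k²/(M−1); perfect ranking gives k. Invariant to monotone row transforms.
* **Per-type PCC** — Pearson correlation between each type's mapped mass per
  spot (column sums of its C rows) and the true proportion column;
  zero-variance vectors yield 0 with a warning.
* **Hollow profile** — fraction of points within `r · D` of the mean
  embedding, D being the centroid-to-nearest-point distance. By this
  normalization the fraction is 0 for all r < 1 on any dataset; curves are
  informative for r ≥ 1 and comparisons across embeddings are meaningful
  when their D values are commensurate.

## Problem sizes used by the shipped checks

The test suite and the acceptance script run the method on the synthetic
benchmark (2,000 cells, 200 genes, 5 types, 20 × 20 grid → ~250–260
surviving spots) with 100 training epochs in tests and 200 in the acceptance
script — enough for the loss plateau on this problem while keeping a full
run in the minutes range on one CPU. Attribution checks use a 150-cell,
30-gene tissue. These sizes are package choices recorded here so results are
interpreted at the scale that produced them.

## Known limitations

* The trajectory model is a single-valued function y = p(x); looping or
  vertical trajectories need a coordinate rotation first.
* Hit numbers are bounded by the spot pitch: cells sharing a nearest spot
  are not distinguishable by mapping-derived adjacency, so absolute hit
  values on spot-aggregated data are small even for good mappings; ratios
  against chance are the interpretable quantity.
* MMD bandwidths follow the pooled median heuristic per batch; extremely
  imbalanced batch sizes make the estimator noisy.
* The encoder is a plain MLP; no graph structure or spatial priors beyond
  the adjacency supervision.
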