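# Methods

## Problem setting and model

`histoexpr` treats nucleus-level expression prediction as weighted
multi-output regression from histology features. The supervision signal is
nuclear RNA: 2×2-μm bins of a sequencing-based spatial assay, assigned to
segmented nuclei by bin-center-in-polygon containment (boundary inclusive;
a bin feeds at most one cell, first polygon in input order on overlap, so
no UMI is counted twice). Labels are per-cell counts scaled to a common
library size (`target_sum` = 10⁴, the dominant single-cell convention) and
log1p-transformed; predictions live in that space and are exported as
`expm1` of the clipped output. No per-cell library rescaling is applied on
export, because a predicted cell has no observed library size — the choice
is recorded in the h5ad metadata.

Nuclear counts are extremely sparse, and the failure mode of plain least
squares is to blur "silent" into "low". The model therefore couples two
objectives through one shared d-gene linear output: the raw output is the
regression estimate, and the same output through a sigmoid is the
probability the gene is expressed at all. Per-gene class weights
(ω_p = 5 on expressed entries, ω_n = 1 on silent ones) and loss mixing
λ₁ = 1, λ₂ = 20 are treated as constants of the method. A two-head variant
(separate linear classification head) exists behind
`ModelConfig(two_head=True)`; the shared head is the default because it is
the only realization consistent with the stated architecture and its
≈4.0M-parameter budget (exactly 4,004,636 at input 576, hidden
512/512/1024/1024 with batch norm, 1,820 outputs).

### Network and training engine

Hidden blocks are linear → leaky-ReLU (slope 0.01) → batch norm → dropout
(0.1); the output layer is linear. Forward, backward and the AdamW update
(decoupled weight decay applied uniformly to all parameters, including
batch-norm scale/shift) are implemented directly on numpy arrays — the
model is small enough that a single CPU core trains it in seconds at desk
scale. Initialization is the uniform fan-in scheme (±1/√fan_in) from a
generator seeded by `ModelConfig.seed`; the same seed drives the
validation split (10%), epoch shuffling and dropout masks, so training is
bit-reproducible on one thread.

Numerical choices worth knowing:

* **Batch-norm running statistics** use a cumulative moving average over
  all training batches rather than a fixed-momentum EMA. At desk scale an
  epoch may contain only one or two batches; a 0.1-momentum estimate then
  takes tens of epochs to approach the activation statistics, which
  corrupts eval-mode validation losses and with them early stopping. The
  cumulative average is unbiased from the first batch. Eval mode uses the
  running statistics, so inference is batch-size invariant.
* **Early stopping** keeps the weights of the best validation epoch
  (patience 10, max 100 epochs) and records `best_epoch`/`best_val_loss`.
* Fewer cells than two batches triggers a warning and full-batch training.

## Histology features

Tiles are 256×256 px at the 0.5 μm/px working scale (origin =
round-half-up of the nucleus centroid minus 128; out-of-slide regions are
padded with white, the H&E background). The tile is partitioned into 256
half-open 16×16-px blocks, indexed row-major; a block belongs to the
nucleus if the rasterized mask (pixel-center-in-polygon, boundary
inclusive) has at least one true pixel there, with a fallback to the
central block so the local feature is always defined. C1 averages the
selected patch tokens (indices sorted first, making the mean exactly
permutation-invariant); C2 is the backbone's whole-tile summary; the model
input is their concatenation.

The backbone is pluggable: anything exposing `d_local`, `d_global` and
`run(raster) -> BackboneOutput` works, e.g. an adapter around a
self-supervised vision transformer whose 16×16 patch tokens are linearly
projected to `d_local`. The bundled `ToyBackbone` computes per-patch and
per-tile statistics (channel means, variances, gradient energies, dark-
pixel fractions) and projects them with fixed seed-reproducible Gaussian
matrices to 192/384 dims. It is deterministic, mask-free and
patch-permutation-equivariant — sufficient for every property the test
suite checks, and honest about what it is: a statistics-based stand-in,
not a pretrained representation.

## Preprocessing defaults

* QC keeps a cell iff area < 2,000 px (500 μm² at 0.5 μm/px) **and**
  UMI > 20 **and** mitochondrial fraction < 0.15 — all three strict. The
  area threshold is interpreted in pixels at the working scale (the unit
  is configurable); mitochondrial genes are matched by the case-insensitive
  prefix `mt-` (regex configurable for human `MT-` data).
* Percentile normalization before segmentation stretches each channel from
  its 1.0 to its 99.8 percentile — common nuclear-segmentation practice;
  both bounds configurable.
* HVG selection is dispersion-based (20 mean bins, z-scored dispersion
  within bin) on the log-normalized matrix; clustering is Leiden
  (resolution 0.6 by default; 1.8 is the convention for ground-truth
  annotation granularity) on a 15-NN graph over the top 50 PCs of the
  gene-centered data, with a seed that fixes the partition. Marker
  statistics are one-vs-rest Wilcoxon rank-sum with tie correction and
  normal approximation, BH-adjusted within cluster; log₂FC compares
  expm1-recovered group means with a 10⁻⁹ floor. The panel takes genes
  with adjusted P < 0.01 (strict) and |log₂FC| ≥ 1 in any cluster.

## The synthetic-slide generator

The generator exists so that every stage — geometry, aggregation, QC,
panel selection, training, evaluation — runs and is testable at desk
scale. It emulates the *statistical* structure the pipeline assumes, not
histology appearance:

* Non-touching elliptical nuclei (32 vertices) on a pink background;
  hematoxylin darkness varies per cell. The 2-μm bin grid is registered to
  image pixels with bin (i, j) centered at ((j+0.5)·4, (i+0.5)·4) px.
* Each cell belongs to one of `n_programs` latent programs. Programs
  differ in expression profiles (each gene is elevated ~13× in one home
  program) **and** in observable morphology (base radius and stain
  darkness increase with program index) — cell identity is readable from
  the image, as it is for real tissue.
* Expected expression is the program profile modulated multiplicatively by
  `exp(morphology_effect · ⟨loadings, standardized (area, stain,
  density)⟩)`, clipped at e±3. Area loadings are non-negative (bigger
  nuclei capture more transcripts), so total expression grows with nucleus
  size. `feature_loadings` can silence individual channels — e.g.
  `(0, 0, 1)` with `n_programs=1` yields a slide whose expression varies
  only with neighborhood density, the contrast fixture for the local/global
  ablation.
* Counts are zero-inflated Poisson: each (cell, gene) is silenced with
  probability `zero_rate`, otherwise Poisson with mean
  `count_mean × expected`. Counts are scattered uniformly (multinomially)
  over the bins inside the nucleus. A single seeded generator drives
  everything; outputs are byte-identical across runs, including after
  serialization.

**Choice of `zero_rate`.** The silencing draw is irreducible noise: no
predictor, however good, can see it in the image. The correlation between
the *true* expected expression and the realized normalized counts —
the ceiling for any model — is ≈0.39 at `zero_rate` 0.5 and drops below
0.3 by 0.7 under the default depth (`count_mean` 4). The default is
therefore 0.5: sparse enough that the dual-loss design is exercised
(roughly 60–70% zeros per cell after Poisson sampling), with enough
headroom that a working model demonstrably recovers the morphology signal
(the suite requires held-out mean per-gene PCC ≥ 0.3 over 3 seeds, against
a label-permuted control).

**What passing tests do not show.** The generator has no stain-batch
variation, no texture, no touching or mis-segmented nuclei, no spatial
autocorrelation beyond the density feature, and its morphology→expression
link is exactly the model family's multiplicative form. Success here
validates the machinery (geometry, bookkeeping, optimization, metrics),
not performance on real slides, which depends on a pretrained backbone and
a real segmentation engine.

## Evaluation conventions

Metrics are computed in log1p space. Per-gene RMSE is the Euclidean
distance over cells divided by √n_cells, aggregated by the mean over
genes (a whole-matrix variant is exposed as `matrix_rmse`). Per-gene PCC
excludes genes whose truth or prediction vector is numerically constant
(tolerance 10⁻¹² relative to scale); excluded genes are listed in the
report, and means are over defined genes only. Binary accuracy counts
p ≥ 0.5 as "expressed", boundary included. The ablation harness trains
full / local-only / global-only variants under identical seeds and
configuration, with input widths 576/192/384.

## Problem sizes used by the test suite

Synthetic slides of 50–400 cells, 30–100 genes on 640–1024 px images; the
recovery check uses 400 cells × 100 genes × 3 seeds with a 25% held-out
split and a label-permuted control per seed, and the ablation contrast
uses two 300-cell single-program density slides. These sizes give stable
statistics while keeping the full suite in the low minutes on one core.

## Known limitations

* The Wilcoxon p-values are normal-approximation values (with tie
  correction); at very small group sizes they differ from the exact
  permutation p by a few percent.
* The asymmetric feature widths (C1 = 192, C2 = 384) are reconciled with a
  same-width token backbone by a declared linear projection inside the
  adapter; a pretrained adapter must persist its projection with the
  checkpoint.
* Denormalized exports assume the log1p/total-count transform recorded in
  the panel metadata; gating predictions by the expression probability is
  off by default and available via `gate=true`.
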