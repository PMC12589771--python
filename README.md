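# histoexpr

Predict **single-cell-resolution spatial gene expression from plain H&E
histology**. Sequencing-based spatial transcriptomics at 2-μm bin
resolution (Visium HD-style) is expensive and scarce; routine H&E slides
are everywhere. `histoexpr` learns the mapping from what a nucleus and its
neighborhood *look like* to what the cell *expresses*, using a binned
spatial transcriptomics slide as supervision, and then predicts a
cell-by-gene expression matrix for new stained sections.

The pipeline:

1. **Label construction** — nucleus polygons (from any segmentation engine
   behind a thin adapter, or from fixtures) are overlaid on the 2-μm bin
   grid; each bin whose center falls inside a nucleus contributes its UMIs
   to that cell. Cells are QC-filtered (nucleus area < 2,000 px at
   0.5 μm/px, UMI count > 20, mitochondrial fraction < 15%), total-count
   normalized to 10⁴ and log1p-transformed.
2. **Gene panel** — highly variable genes → PCA → Leiden clustering
   (resolution 0.6) → one-vs-rest Wilcoxon markers; genes with
   adjusted *P* < 0.01 and |log₂FC| ≥ 1 in any cluster form the trainable
   panel.
3. **Histology features** — each cell gets a 256×256-px tile at 0.5 μm/px
   centered on its nucleus, split into 16×16-px patches (8×8 μm, about one
   cell). A backbone embeds the tile; the **local feature C1** (192-d)
   averages the patch tokens overlapping the nucleus, the **global feature
   C2** (384-d) summarizes the whole tile, and the fused input is
   z = [C1 | C2] ∈ ℝ⁵⁷⁶.
4. **Model** — a feed-forward network (hidden layers 512, 512, 1024, 1024;
   leaky-ReLU → batch-norm → dropout 0.1; ≈4.0M parameters) with a dual
   objective on one shared d-gene output. With per-gene class weights
   wᵢ = ω_p if yᵢ > 0 else ω_n (ω_p = 5, ω_n = 1):

   L_reg = Σᵢ wᵢ (ŷᵢ − yᵢ)²,  L_bin = weighted BCE(σ(ŷᵢ), [yᵢ > 0]),
   Loss = λ₁ L_reg + λ₂ L_bin  (λ₁ = 1, λ₂ = 20)

   trained with AdamW (lr 0.01, weight decay 0.05), batch 256, early
   stopping on a 10% validation split. The classification term teaches the
   model to separate *silent* from *lowly expressed* — the central
   difficulty of sparse nuclear counts.
5. **Evaluation** — per-gene Pearson correlation and RMSE in log1p space,
   binary expressed/silent accuracy, and a C1/C2 ablation harness.

A seeded **synthetic-slide generator** (H&E-like rendering, non-overlapping
elliptical nuclei whose size/stain/density drive zero-inflated Poisson
counts on the 2-μm grid) makes every stage testable without downloads.

## Worked example

```sh
histoexpr simulate --out fx --seed 11 --n-cells 80 --n-genes 40 --image-size 768
histoexpr prepare  --fixture fx --out prep.h5ad --seed 11
histoexpr train    --prepared prep.h5ad --out model.npz --seed 11 --max-epochs 40
histoexpr predict  --model model.npz --prepared prep.h5ad --out pred.h5ad
histoexpr evaluate --pred pred.h5ad --truth prep.h5ad --out report
```

prints, step by step:

```
prepared 48 cells x 4 panel genes -> prep.h5ad
trained 39 epochs (final val loss 938.1525) -> model.npz
predicted 48 cells x 4 genes -> pred.h5ad
mean PCC 0.432, mean RMSE 3.278, binary accuracy 0.740 -> report/summary.json
```

Reading: of 80 simulated cells, 48 pass QC; clustering finds marker genes
and keeps a 4-gene panel at this tiny scale; training early-stops after 39
epochs; predictions correlate with the measured normalized expression at a
mean per-gene Pearson r of 0.432 (training-set predictions on a toy
backbone — held-out performance on larger slides is what the test suite
measures), and the expressed/silent call is right for 74% of
(cell, gene) entries. `pred.h5ad` holds the denormalized expm1 matrix with
normalized predictions and expression probabilities as layers.

The same steps are available as library calls (`histoexpr.simulate_slide`,
`prepare_cells`, `fit`, `predict_cells`, `evaluate_predictions`,
`run_ablation`); `histoexpr ablate` trains full / local-only / global-only
variants (input widths 576 / 192 / 384) and tabulates both metrics.

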