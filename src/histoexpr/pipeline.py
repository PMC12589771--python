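"""End-to-end orchestration: fixture/slide -> per-cell training table.

`prepare_cells` runs the full preprocessing chain -- rescale to the 0.5
um/px working frame, aggregate 2-um bins into nuclei, QC-filter, normalize,
select the marker gene panel, and extract fused histology features -- and
returns one AnnData holding everything the trainer and evaluator need:

* ``X``: log1p-normalized expression over the panel genes (the labels)
* ``obs``: cell id, centroid x/y, area, total UMI, mito fraction, cluster
* ``obsm``: ``X_histology`` (fused z), ``X_c1`` / ``X_c2`` (the split kept
  for the ablation harness)
* ``uns``: normalization metadata, panel thresholds, seed and config hash
"""

from __future__ import annotations

import hashlib
import json

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import expression as ex
from . import features as ft
from . import geometry as geo


def config_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def prepare_cells(
    image: geo.SlideImage,
    polygons: list[geo.NucleusPolygon],
    bins: ex.BinTable,
    *,
    backbone=None,
    max_area: float = 2000.0,
    min_umi: int = 20,
    max_mito: float = 0.15,
    n_hvg: int = 2000,
    n_pcs: int = 50,
    resolution: float = 0.6,
    min_cluster_size: int = 0,
    p_adj_max: float = 0.01,
    min_abs_log2fc: float = 1.0,
    target_sum: float = 1e4,
    seed: int = 0,
) -> ad.AnnData:
    """Run preprocessing and panel selection on one slide."""
    backbone = backbone or ft.ToyBackbone(seed=seed)
    if image.um_per_px != geo.TARGET_UM_PER_PX:
        factor = image.um_per_px / geo.TARGET_UM_PER_PX
        polygons = [p.scaled(factor) for p in polygons]
        bins = ex.BinTable(barcodes=bins.barcodes, genes=bins.genes,
                           counts=bins.counts, bin_centers=bins.bin_centers * factor)
        image = geo.rescale_to_target(image)

    cells = ex.aggregate_bins_to_cells(bins, polygons)
    by_id = {p.cell_id: p for p in polygons}
    cells = ex.qc_filter(cells, max_area=max_area, min_umi=min_umi,
                         max_mito=max_mito)
    if not cells.cell_ids:
        raise ValueError("no cell passed QC; check thresholds and input frames")
    kept_polys = [by_id[cid] for cid in cells.cell_ids]

    norm, norm_meta = ex.normalize_log1p(cells, target_sum=target_sum)
    hvg = ex.select_hvg(norm, cells.genes, n_top=n_hvg)
    hvg_idx = [cells.genes.index(g) for g in hvg]
    labels = ex.cluster_cells(norm[:, hvg_idx], n_pcs=n_pcs,
                              resolution=resolution,
                              min_cluster_size=min_cluster_size, seed=seed)
    stats = ex.rank_genes_wilcoxon(norm, labels, cells.genes)
    panel = ex.build_panel(stats, p_adj_max=p_adj_max,
                           min_abs_log2fc=min_abs_log2fc,
                           target_sum=target_sum)

    panel_idx = [cells.genes.index(g) for g in panel.genes]
    y = np.asarray(norm[:, panel_idx].todense())

    feats = ft.extract_features(image, kept_polys, backbone)
    z = ft.feature_matrix(feats)
    c1, c2 = ft.split_feature_matrix(feats)

    cfg_payload = {
        "max_area": max_area, "min_umi": min_umi, "max_mito": max_mito,
        "n_hvg": n_hvg, "n_pcs": n_pcs, "resolution": resolution,
        "min_cluster_size": min_cluster_size, "p_adj_max": p_adj_max,
        "min_abs_log2fc": min_abs_log2fc, "target_sum": target_sum,
        "seed": seed, "backbone": type(backbone).__name__,
    }
    adata = ad.AnnData(
        X=sp.csr_matrix(y),
        obs=pd.DataFrame({
            "x": [p.centroid[0] for p in kept_polys],
            "y": [p.centroid[1] for p in kept_polys],
            "area_px": cells.area_px,
            "total_umi": cells.total_umi,
            "mito_frac": cells.mito_frac,
            "cluster": pd.Categorical(labels),
        }, index=pd.Index(cells.cell_ids, name="cell_id")),
        var=panel.stats.set_index("gene").loc[panel.genes],
        obsm={"X_histology": z, "X_c1": c1, "X_c2": c2},
    )
    adata.uns["normalization"] = norm_meta
    adata.uns["panel"] = {"p_adj_max": p_adj_max,
                          "min_abs_log2fc": min_abs_log2fc,
                          "genes": panel.genes}
    adata.uns["seed"] = seed
    adata.uns["config_hash"] = config_hash(cfg_payload)
    return adata


def panel_from_prepared(adata: ad.AnnData) -> ex.ExpressionPanel:
    stats = adata.var.reset_index().rename(columns={"index": "gene"})
    if "gene" not in stats.columns:
        stats = stats.rename(columns={stats.columns[0]: "gene"})
    return ex.ExpressionPanel(
        genes=list(adata.var_names),
        stats=stats,
        p_adj_max=float(adata.uns["panel"]["p_adj_max"]),
        min_abs_log2fc=float(adata.uns["panel"]["min_abs_log2fc"]),
        target_sum=float(adata.uns["normalization"]["target_sum"]),
    )
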