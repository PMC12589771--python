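"""From 2-um bins to a trainable per-cell gene panel.

The sequencing side of the pipeline: assign each 2x2-um bin to the nucleus
polygon containing its center, sum assigned bin counts into per-cell UMI
counts, filter cells on nucleus area / UMI depth / mitochondrial fraction,
normalize (per-cell total-count scaling to ``target_sum`` then log1p), and
select the gene panel the regressor is trained on (highly variable genes ->
PCA -> Leiden clusters -> one-vs-rest Wilcoxon markers).

Clustering, HVG selection and marker ranking are delegated to scanpy; the
thin wrappers here fix the parameter choices and return plain arrays/frames.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp
import shapely
from shapely.strtree import STRtree

from .geometry import NucleusPolygon

MITO_REGEX = r"^mt-"  # case-insensitive by default; human data uses "MT-"


@dataclass
class BinTable:
    """Sparse bins x genes counts with bin-center pixel coordinates."""

    barcodes: list[str]
    genes: list[str]
    counts: sp.csr_matrix  # bins x genes, non-negative integers
    bin_centers: np.ndarray  # (n_bins, 2) float, columns (x, y) in pixels

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        if self.counts.shape != (len(self.barcodes), len(self.genes)):
            raise ValueError("counts shape does not match barcodes x genes")
        if self.bin_centers.shape != (len(self.barcodes), 2):
            raise ValueError("need one (x, y) center per barcode")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene names must be unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total_umi(self) -> int:
        return int(self.counts.sum())


@dataclass
class CellCounts:
    """Per-nucleus aggregated counts plus the QC covariates."""

    cell_ids: list[str]
    genes: list[str]
    counts: sp.csr_matrix  # cells x genes
    area_px: np.ndarray  # per-cell nucleus area in pixels at 0.5 um/px
    mito_regex: str = MITO_REGEX
    total_umi: np.ndarray = field(default=None)  # type: ignore[assignment]
    mito_frac: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.area_px = np.asarray(self.area_px, dtype=float)
        if self.counts.shape != (len(self.cell_ids), len(self.genes)):
            raise ValueError("counts shape does not match cells x genes")
        if self.total_umi is None:
            self.total_umi = np.asarray(self.counts.sum(axis=1)).ravel().astype(int)
        mito = np.array([bool(re.match(self.mito_regex, g, re.IGNORECASE))
                         for g in self.genes])
        if self.mito_frac is None:
            mito_counts = (np.asarray(self.counts[:, mito].sum(axis=1)).ravel()
                           if mito.any() else np.zeros(len(self.cell_ids)))
            self.mito_frac = mito_counts / np.maximum(self.total_umi, 1)

    def subset(self, keep: np.ndarray) -> "CellCounts":
        keep = np.asarray(keep)
        return CellCounts(
            cell_ids=[self.cell_ids[i] for i in np.flatnonzero(keep)] if keep.dtype == bool
            else [self.cell_ids[i] for i in keep],
            genes=list(self.genes),
            counts=self.counts[keep],
            area_px=self.area_px[keep],
            mito_regex=self.mito_regex,
        )


@dataclass
class ExpressionPanel:
    """The trainable gene panel with the selection evidence and the
    normalization metadata needed to reproduce / invert the label transform."""

    genes: list[str]
    stats: pd.DataFrame  # one row per panel gene: p_adj, log2fc, cluster
    p_adj_max: float
    min_abs_log2fc: float
    target_sum: float = 1e4
    log1p: bool = True

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("panel genes must be unique")


def aggregate_bins_to_cells(bins: BinTable, polygons: list[NucleusPolygon],
                            mito_regex: str = MITO_REGEX) -> CellCounts:
    """Sum each nucleus's overlapping bins into one UMI row per cell.

    A bin belongs to a cell iff its center lies inside the nucleus polygon
    (boundary counts as inside). Each bin goes to at most one cell; when
    polygons overlap the first polygon in input order wins, so no UMI is
    counted twice.
    """
    n_bins = len(bins.barcodes)
    points = shapely.points(bins.bin_centers)
    tree = STRtree(points)
    assigned = np.zeros(n_bins, dtype=bool)
    rows, datas = [], []
    for poly in polygons:
        cand = tree.query(poly.shapely, predicate="intersects")
        cand = cand[~assigned[cand]]
        cand = np.sort(cand)
        assigned[cand] = True
        if cand.size:
            rows.append(np.asarray(bins.counts[cand].sum(axis=0)).ravel())
        else:
            rows.append(np.zeros(len(bins.genes)))
    if polygons and n_bins and assigned.sum() < 0.01 * n_bins and bins.total_umi > 0:
        warnings.warn(
            "over 99% of bins fall outside every polygon; the bin table and the "
            "polygons may be in different coordinate frames", stacklevel=2)
    counts = sp.csr_matrix(np.rint(np.vstack(rows)).astype(np.int64)) if polygons \
        else sp.csr_matrix((0, len(bins.genes)), dtype=np.int64)
    return CellCounts(
        cell_ids=[p.cell_id for p in polygons],
        genes=list(bins.genes),
        counts=counts,
        area_px=np.array([p.area_px for p in polygons]),
        mito_regex=mito_regex,
    )


def qc_filter(cells: CellCounts, max_area: float = 2000.0, min_umi: int = 20,
              max_mito: float = 0.15) -> CellCounts:
    """Keep cells with nucleus area strictly below ``max_area`` px (500 um^2 at
    0.5 um/px), UMI count strictly above ``min_umi``, and mitochondrial
    fraction strictly below ``max_mito``. All three comparisons are strict;
    order is preserved."""
    if max_area <= 0 or min_umi <= 0 or max_mito <= 0:
        raise ValueError("thresholds must be positive")
    keep = ((cells.area_px < max_area)
            & (cells.total_umi > min_umi)
            & (cells.mito_frac < max_mito))
    return cells.subset(keep)


def normalize_log1p(cells: CellCounts, target_sum: float = 1e4):
    """Per-cell total-count normalization to ``target_sum`` followed by
    log1p: ``value = log(1 + count * target_sum / total_umi)``.

    Returns ``(matrix, metadata)`` where the matrix is sparse float (zeros map
    to zeros) and the metadata records the transform for later inversion.
    Cells with zero total are an error: run :func:`qc_filter` first.
    """
    zero = np.flatnonzero(cells.total_umi == 0)
    if zero.size:
        raise ValueError(
            f"cell '{cells.cell_ids[zero[0]]}' has zero total UMI; "
            "normalize after QC filtering")
    scale = target_sum / cells.total_umi
    norm = cells.counts.astype(float).multiply(scale[:, None]).tocsr()
    norm.data = np.log1p(norm.data)
    meta = {"target_sum": float(target_sum), "log1p": True}
    return norm, meta


def _to_adata(norm_matrix, genes: list[str]) -> ad.AnnData:
    X = sp.csr_matrix(norm_matrix, dtype=np.float32)
    adata = ad.AnnData(X=X, var=pd.DataFrame(index=pd.Index(genes, name="gene")))
    adata.obs_names = [f"c{i}" for i in range(X.shape[0])]
    return adata


def select_hvg(norm_matrix, genes: list[str], n_top: int = 2000) -> list[str]:
    """Top ``n_top`` highly variable genes by binned normalized dispersion
    (20 mean-expression bins, z-scored dispersion within bin), computed on the
    log-normalized matrix. Returned in original gene order."""
    X = sp.csr_matrix(norm_matrix)
    mean = np.asarray(X.mean(axis=0)).ravel()
    sq = X.copy()
    sq.data **= 2
    var = np.asarray(sq.mean(axis=0)).ravel() - mean ** 2
    usable = [g for g, v in zip(genes, var) if v > 0]
    if len(usable) <= n_top:
        if len(usable) < n_top:
            warnings.warn(
                f"only {len(usable)} genes have nonzero variance; returning all",
                stacklevel=2)
        return usable
    adata = _to_adata(norm_matrix, genes)
    sc.pp.highly_variable_genes(adata, flavor="seurat", n_top_genes=n_top, n_bins=20)
    chosen = set(adata.var_names[adata.var["highly_variable"]])
    return [g for g in genes if g in chosen]


FILTERED_LABEL = "filtered"


def cluster_cells(norm_matrix, n_pcs: int = 50, resolution: float = 0.6,
                  min_cluster_size: int = 0, neighbors_k: int = 15,
                  seed: int = 0) -> np.ndarray:
    """Leiden clustering on a k-nearest-neighbor graph in PCA space.

    Gene-centered normalized data are projected onto the top ``n_pcs``
    principal components; clusters smaller than ``min_cluster_size`` are
    relabeled ``"filtered"``. Deterministic for a fixed seed.
    """
    X = sp.csr_matrix(norm_matrix)
    n_cells, n_genes = X.shape
    if n_cells < neighbors_k + 1:
        raise ValueError(f"need at least neighbors_k+1 = {neighbors_k + 1} cells")
    cap = min(n_cells, n_genes) - 1
    if n_pcs > cap:
        warnings.warn(f"n_pcs={n_pcs} capped to {cap}", stacklevel=2)
        n_pcs = cap
    adata = _to_adata(X, [f"g{i}" for i in range(n_genes)])
    sc.pp.pca(adata, n_comps=n_pcs, zero_center=True, random_state=seed)
    sc.pp.neighbors(adata, n_neighbors=neighbors_k, random_state=seed)
    sc.tl.leiden(adata, resolution=resolution, random_state=seed,
                 flavor="leidenalg")
    labels = adata.obs["leiden"].astype(str).to_numpy()
    if min_cluster_size > 0:
        sizes = pd.Series(labels).value_counts()
        small = set(sizes.index[sizes < min_cluster_size])
        labels = np.array([FILTERED_LABEL if l in small else l for l in labels])
    return labels


def rank_genes_wilcoxon(norm_matrix, labels, genes: list[str]) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum marker statistics per cluster.

    Normal approximation with tie correction; Benjamini-Hochberg adjustment
    across genes within each cluster; log2FC computed on expm1-recovered
    means with a 1e-9 floor. Cells labeled "filtered" are excluded. Genes
    constant within a comparison get p = 1 and log2FC = 0.
    """
    labels = np.asarray(labels, dtype=str)
    keep = labels != FILTERED_LABEL
    X = sp.csr_matrix(norm_matrix)[keep]
    labels = labels[keep]
    groups = [g for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need at least 2 clusters")
    counts = pd.Series(labels).value_counts()
    if (counts < 2).any():
        raise ValueError("every cluster needs at least 2 cells")
    adata = _to_adata(X, genes)
    adata.obs["cluster"] = pd.Categorical(labels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.tl.rank_genes_groups(adata, "cluster", method="wilcoxon",
                                tie_correct=True, n_genes=len(genes))
    frames = []
    for grp in adata.obs["cluster"].cat.categories:
        df = sc.get.rank_genes_groups_df(adata, group=str(grp))
        df = df.rename(columns={"names": "gene", "pvals": "p",
                                "pvals_adj": "p_adj", "logfoldchanges": "log2fc"})
        df["cluster"] = str(grp)
        frames.append(df[["cluster", "gene", "p", "p_adj", "log2fc"]])
    out = pd.concat(frames, ignore_index=True)
    out["p"] = out["p"].fillna(1.0)
    out["p_adj"] = out["p_adj"].fillna(1.0)
    out["log2fc"] = out["log2fc"].fillna(0.0).replace([np.inf, -np.inf], 0.0)
    return out


def build_panel(stats: pd.DataFrame, p_adj_max: float = 0.01,
                min_abs_log2fc: float = 1.0, target_sum: float = 1e4) -> ExpressionPanel:
    """Genes passing ``p_adj < p_adj_max`` (strict) and ``|log2FC| >=
    min_abs_log2fc`` in at least one cluster, deduplicated in order of first
    qualifying appearance."""
    ok = stats[(stats["p_adj"] < p_adj_max)
               & (stats["log2fc"].abs() >= min_abs_log2fc)]
    if ok.empty:
        raise ValueError(
            "no gene passes the marker thresholds; relax p_adj_max or "
            "min_abs_log2fc, or check that clustering found real structure")
    first = ok.drop_duplicates(subset="gene", keep="first")
    return ExpressionPanel(
        genes=first["gene"].tolist(),
        stats=first.reset_index(drop=True),
        p_adj_max=p_adj_max,
        min_abs_log2fc=min_abs_log2fc,
        target_sum=target_sum,
    )


def binary_labels(y) -> np.ndarray:
    """Expressed/silent indicator: true exactly where the normalized value is
    positive (log1p preserves positivity, so this matches raw count > 0)."""
    y = np.asarray(y.todense() if sp.issparse(y) else y)
    if y.size and y.min() < 0:
        raise ValueError("normalized expression must be non-negative")
    return y > 0


def qc_metrics(matrix) -> pd.DataFrame:
    """Per-cell total counts and number of detected features (nonzero genes),
    the two QC maps drawn over the tissue."""
    X = sp.csr_matrix(matrix)
    return pd.DataFrame({
        "total_counts": np.asarray(X.sum(axis=1)).ravel(),
        "n_features": X.getnnz(axis=1),
    })


def clip_percentile(values, p: float = 99.0) -> tuple[float, float]:
    """Display range (0, p-th percentile) used to keep outliers from
    saturating spatial QC maps."""
    values = np.asarray(values, dtype=float)
    return 0.0, float(np.percentile(values, p))
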