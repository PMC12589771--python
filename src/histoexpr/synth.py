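"""Seeded synthetic slides: an H&E-like rendering, non-overlapping nucleus
polygons, a 2-um bin count table, and the generating ground truth.

The generator reproduces the statistical structure the pipeline assumes
rather than realistic histology texture: cells belong to latent expression
programs; programs differ both in their gene profiles and in observable
nuclear morphology (size and hematoxylin intensity), and per-cell expression
is further modulated by standardized nucleus features (area, mean stain,
local density), so that a model reading the image has real signal to find.
Counts are zero-inflated Poisson draws scattered uniformly over the 2-um
bins whose centers fall inside each nucleus.

Geometry contract: the bin grid is registered to image pixels at 0.5 um/px,
bin (i, j) having its center at ``x = (j + 0.5) * 4``, ``y = (i + 0.5) * 4``
pixels (2 um = 4 px).

All randomness flows from one ``numpy`` generator seeded by
``SynthConfig.seed``; same config means byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
import shapely
from skimage.draw import polygon as draw_polygon

from . import io as hio
from .expression import BinTable
from .geometry import NucleusPolygon, SlideImage

BIN_PX = 4  # 2-um bin side at 0.5 um/px
_BACKGROUND = np.array([238.0, 205.0, 218.0])  # eosin-like pink
_NUCLEUS = np.array([78.0, 52.0, 130.0])  # hematoxylin-like dark purple
_ELLIPSE_VERTICES = 32
_DENSITY_RADIUS_PX = 128.0  # neighborhood used for the local-density feature


@dataclass
class SynthConfig:
    """Study conditions for one synthetic slide.

    Defaults describe a sparse nuclear-RNA regime: half of the (cell, gene)
    entries silenced outright, a handful of UMIs per expressed gene, and
    four morphologically distinct programs. The silencing rate is capped at
    the point where the irreducible zero-inflation noise still leaves the
    morphology signal recoverable (see docs/methods.md).
    """

    image_size_px: tuple[int, int] = (1024, 1024)  # (rows, cols)
    um_per_px: float = 0.5
    n_cells: int = 200
    n_genes: int = 100
    n_programs: int = 4
    zero_rate: float = 0.5  # per-(cell, gene) silencing probability
    count_mean: float = 4.0  # mean nonzero UMIs per expressed gene
    morphology_effect: float = 1.0  # strength of the nucleus-feature -> expression link
    feature_loadings: tuple[float, float, float] = (1.0, 1.0, 1.0)  # area, stain, density
    n_mito_genes: int = 3
    polygon_jitter: float = 0.0  # optional vertex jitter (px) to mimic segmentation error
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.image_size_px[0] > 256 and self.image_size_px[1] > 256):
            raise ValueError("image_size_px must both exceed 256")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        if not (0 <= self.zero_rate < 1):
            raise ValueError("zero_rate must be in [0, 1)")
        if self.n_programs < 1:
            raise ValueError("n_programs must be >= 1")
        if self.morphology_effect < 0:
            raise ValueError("morphology_effect must be >= 0")


@dataclass
class GroundTruth:
    """What the generator actually drew, kept for oracle-style tests."""

    cell_ids: list[str]
    expression: np.ndarray  # cells x genes expected counts (non-negative)
    programs: np.ndarray  # per-cell program label (int)
    nucleus_features: np.ndarray  # cells x 3: area_px, mean_stain, local_density
    sampled_counts: np.ndarray  # cells x genes realized integer counts
    genes: list[str] = field(default_factory=list)


def _gene_names(cfg: SynthConfig) -> list[str]:
    mito = [f"mt-Sg{i + 1}" for i in range(min(cfg.n_mito_genes, cfg.n_genes - 1))]
    rest = [f"Gene{i + 1:04d}" for i in range(cfg.n_genes - len(mito))]
    return mito + rest


def _place_nuclei(cfg: SynthConfig, rng: np.random.Generator):
    """Rejection-sample non-touching ellipse centers and shapes.

    Programs get distinct morphology: base radius and stain darkness increase
    with the program index, which is what makes programs image-predictable.
    """
    rows, cols = cfg.image_size_px
    programs = rng.integers(cfg.n_programs, size=cfg.n_cells)
    base_radius = np.linspace(7.0, 13.0, cfg.n_programs)
    base_stain = np.linspace(0.55, 0.95, cfg.n_programs)
    ax_a = base_radius[programs] * rng.uniform(0.85, 1.15, cfg.n_cells)
    ax_b = base_radius[programs] * rng.uniform(0.70, 1.00, cfg.n_cells)
    angle = rng.uniform(0, np.pi, cfg.n_cells)
    stain = np.clip(base_stain[programs] + rng.normal(0, 0.04, cfg.n_cells), 0.3, 1.0)
    margin = float(np.maximum(ax_a, ax_b).max()) + 2.0
    radius = np.maximum(ax_a, ax_b)

    centers = np.empty((cfg.n_cells, 2))
    placed = 0
    attempts = 0
    max_attempts = 500 * cfg.n_cells
    while placed < cfg.n_cells:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {cfg.n_cells} non-overlapping nuclei in a "
                f"{rows}x{cols} image after {max_attempts} attempts; enlarge the "
                "image or reduce n_cells")
        attempts += 1
        cand = np.array([rng.uniform(margin, cols - margin),
                         rng.uniform(margin, rows - margin)])
        if placed:
            d = np.hypot(*(centers[:placed] - cand).T)
            if (d < radius[:placed] + radius[placed] + 3.0).any():
                continue
        centers[placed] = cand
        placed += 1
    return programs, centers, ax_a, ax_b, angle, stain


def _ellipse_vertices(cx, cy, a, b, angle, jitter, rng) -> np.ndarray:
    t = np.linspace(0, 2 * np.pi, _ELLIPSE_VERTICES, endpoint=False)
    x = a * np.cos(t)
    y = b * np.sin(t)
    xr = cx + x * np.cos(angle) - y * np.sin(angle)
    yr = cy + x * np.sin(angle) + y * np.cos(angle)
    verts = np.column_stack([xr, yr])
    if jitter > 0:
        verts = verts + rng.normal(0, jitter, verts.shape)
    return verts


def _program_profiles(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Programs x genes expected-expression profiles.

    Each non-mitochondrial gene is a marker of one "home" program (elevated
    ~13x over the off-program baseline, with lognormal jitter); mitochondrial
    fixture genes are housekeeping-flat so the QC fraction is well defined.
    """
    n_mito = min(cfg.n_mito_genes, cfg.n_genes - 1)
    profiles = np.full((cfg.n_programs, cfg.n_genes), 0.15)
    home = np.arange(cfg.n_genes) % cfg.n_programs
    profiles[home, np.arange(cfg.n_genes)] = 2.0
    profiles *= rng.lognormal(0.0, 0.2, size=profiles.shape)
    profiles[:, :n_mito] = 0.8 * rng.lognormal(0.0, 0.05, size=(cfg.n_programs, n_mito))
    return profiles


def simulate_slide(cfg: SynthConfig):
    """Draw one synthetic slide.

    Returns ``(SlideImage, list[NucleusPolygon], BinTable, GroundTruth)``.
    Raises ``RuntimeError`` if nuclei cannot be placed without overlap.
    """
    rng = np.random.default_rng(cfg.seed)
    rows, cols = cfg.image_size_px
    genes = _gene_names(cfg)

    programs, centers, ax_a, ax_b, angle, stain = _place_nuclei(cfg, rng)
    polygons = [
        NucleusPolygon(
            cell_id=f"cell_{i:05d}",
            vertices=_ellipse_vertices(centers[i, 0], centers[i, 1], ax_a[i],
                                       ax_b[i], angle[i], cfg.polygon_jitter, rng),
        )
        for i in range(cfg.n_cells)
    ]

    # observable nucleus features: polygon area, rendered stain darkness,
    # number of neighboring nuclei within the tile-scale radius
    area = np.array([p.area_px for p in polygons])
    if cfg.n_cells > 1:
        d = np.hypot(centers[:, None, 0] - centers[None, :, 0],
                     centers[:, None, 1] - centers[None, :, 1])
        density = ((d < _DENSITY_RADIUS_PX).sum(axis=1) - 1).astype(float)
    else:
        density = np.zeros(1)
    features = np.column_stack([area, stain, density])

    # expected expression: program profile, multiplicatively modulated by
    # standardized features through per-gene loadings
    profiles = _program_profiles(cfg, rng)
    std = features.std(axis=0)
    std[std == 0] = 1.0
    f_std = (features - features.mean(axis=0)) / std
    loadings = rng.normal(0, 1, size=(cfg.n_genes, 3))
    # larger nuclei capture more transcripts: the area loading is kept
    # non-negative so total expression grows with nucleus size
    loadings[:, 0] = np.abs(loadings[:, 0])
    loadings /= np.linalg.norm(loadings, axis=1, keepdims=True)
    loadings *= np.asarray(cfg.feature_loadings)
    modulation = np.clip(cfg.morphology_effect * (f_std @ loadings.T), -3.0, 3.0)
    lam = profiles[programs] * np.exp(modulation)  # cells x genes

    expressed = rng.random((cfg.n_cells, cfg.n_genes)) < (1.0 - cfg.zero_rate)
    sampled = rng.poisson(cfg.count_mean * lam) * expressed
    expected = (1.0 - cfg.zero_rate) * cfg.count_mean * lam

    # scatter each cell's counts uniformly over the bins inside its nucleus
    n_bin_rows, n_bin_cols = rows // BIN_PX, cols // BIN_PX
    jj, ii = np.meshgrid(np.arange(n_bin_cols), np.arange(n_bin_rows))
    bin_x = (jj.ravel() + 0.5) * BIN_PX
    bin_y = (ii.ravel() + 0.5) * BIN_PX
    barcodes = [f"bin_{i:04d}_{j:04d}" for i, j in zip(ii.ravel(), jj.ravel())]
    coo_r, coo_c, coo_v = [], [], []
    for ci, poly in enumerate(polygons):
        minx, miny, maxx, maxy = poly.shapely.bounds
        j_lo = max(0, int(minx / BIN_PX - 1))
        j_hi = min(n_bin_cols - 1, int(maxx / BIN_PX + 1))
        i_lo = max(0, int(miny / BIN_PX - 1))
        i_hi = min(n_bin_rows - 1, int(maxy / BIN_PX + 1))
        jj_c, ii_c = np.meshgrid(np.arange(j_lo, j_hi + 1), np.arange(i_lo, i_hi + 1))
        xs = (jj_c.ravel() + 0.5) * BIN_PX
        ys = (ii_c.ravel() + 0.5) * BIN_PX
        inside = shapely.intersects_xy(poly.shapely, xs, ys)
        bin_idx = (ii_c.ravel()[inside] * n_bin_cols + jj_c.ravel()[inside])
        if bin_idx.size == 0:
            # tiny nucleus straddling no bin center: use the nearest bin
            ci_row = min(n_bin_rows - 1, max(0, int(poly.centroid[1] / BIN_PX)))
            ci_col = min(n_bin_cols - 1, max(0, int(poly.centroid[0] / BIN_PX)))
            bin_idx = np.array([ci_row * n_bin_cols + ci_col])
        probs = np.full(bin_idx.size, 1.0 / bin_idx.size)
        for gi in np.flatnonzero(sampled[ci]):
            alloc = rng.multinomial(sampled[ci, gi], probs)
            nz = np.flatnonzero(alloc)
            coo_r.extend(bin_idx[nz])
            coo_c.extend([gi] * nz.size)
            coo_v.extend(alloc[nz])
    counts = sp.coo_matrix(
        (coo_v, (coo_r, coo_c)),
        shape=(n_bin_rows * n_bin_cols, cfg.n_genes), dtype=np.int64).tocsr()
    bins = BinTable(barcodes=barcodes, genes=genes, counts=counts,
                    bin_centers=np.column_stack([bin_x, bin_y]))

    image = _render(cfg, polygons, stain, rng)
    truth = GroundTruth(
        cell_ids=[p.cell_id for p in polygons],
        expression=expected,
        programs=programs,
        nucleus_features=features,
        sampled_counts=sampled,
        genes=genes,
    )
    return image, polygons, bins, truth


def _render(cfg: SynthConfig, polygons, stain, rng) -> SlideImage:
    """H&E-like rendering: pink background with mild noise, each nucleus
    filled with purple whose darkness tracks its stain feature."""
    rows, cols = cfg.image_size_px
    img = np.empty((rows, cols, 3))
    img[:] = _BACKGROUND
    img += rng.normal(0, 3.0, size=(rows, cols, 1))
    for poly, s in zip(polygons, stain):
        rr, cc = draw_polygon(poly.vertices[:, 1], poly.vertices[:, 0],
                              shape=(rows, cols))
        color = (1.0 - s) * 255.0 + s * _NUCLEUS
        img[rr, cc] = color + rng.normal(0, 2.0, size=(rr.size, 3))
    return SlideImage(pixels=np.clip(np.rint(img), 0, 255).astype(np.uint8),
                      um_per_px=cfg.um_per_px, name=f"synthetic_seed{cfg.seed}")


def write_fixture(package, directory) -> dict[str, Path]:
    """Serialize a simulated slide to disk in the pipeline's input formats.

    ``package`` is the 4-tuple from :func:`simulate_slide`. Writes the TIFF
    image, GeoJSON polygons, MTX counts triplet + parquet bin positions, and
    the ground truth as h5ad; everything round-trips through the readers in
    :mod:`histoexpr.io`.
    """
    image, polygons, bins, truth = package
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {"image": hio.write_slide_tiff(image, directory / "slide.tif"),
             "polygons": hio.write_polygons_geojson(polygons,
                                                    directory / "nuclei.geojson")}
    paths.update(hio.write_bin_table(bins, directory / "binned"))
    truth_ad = ad.AnnData(
        X=truth.expression.astype(np.float64),
        obs=pd.DataFrame({
            "program": truth.programs,
            "area_px": truth.nucleus_features[:, 0],
            "mean_stain": truth.nucleus_features[:, 1],
            "local_density": truth.nucleus_features[:, 2],
        }, index=pd.Index(truth.cell_ids, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(truth.genes, name="gene")),
        layers={"sampled_counts": truth.sampled_counts.astype(np.int64)},
    )
    truth_path = directory / "ground_truth.h5ad"
    truth_ad.write_h5ad(truth_path)
    paths["ground_truth"] = truth_path
    return paths


def read_ground_truth(path) -> GroundTruth:
    adata = ad.read_h5ad(path)
    return GroundTruth(
        cell_ids=list(adata.obs_names),
        expression=np.asarray(adata.X),
        programs=adata.obs["program"].to_numpy(),
        nucleus_features=adata.obs[["area_px", "mean_stain",
                                    "local_density"]].to_numpy(),
        sampled_counts=np.asarray(adata.layers["sampled_counts"]),
        genes=list(adata.var_names),
    )
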