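"""Slide geometry: rescaling, stain normalization, segmentation adapter,
and the tile/patch layout that links each nucleus to histology context.

Conventions (fixed throughout the package):

* Coordinates are 0-based with ``x`` = column and ``y`` = row; pixel centers
  sit at integer coordinates.
* The working scale for all tile geometry is 0.5 um/px, so a 16-px patch
  spans 8 um per side -- roughly one cell.
* Tiles are ``TILE_PX`` x ``TILE_PX`` (default 256) and are divided into a
  ``PATCH_GRID`` x ``PATCH_GRID`` grid of 16-px patches, indexed row-major
  ``k = 16*r + c`` over half-open pixel blocks ``[16r, 16r+16) x [16c, 16c+16)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon
from skimage.transform import resize

TILE_PX = 256
PATCH_PX = 16
PATCH_GRID = TILE_PX // PATCH_PX  # 16 -> 256 patches per tile
TARGET_UM_PER_PX = 0.5
WHITE = 255


def patch_span_um(patch_px: int = PATCH_PX, um_per_px: float = TARGET_UM_PER_PX) -> float:
    """Physical side length, in micrometers, of a square patch of ``patch_px``
    pixels at the given scale."""
    if patch_px <= 0 or um_per_px <= 0:
        raise ValueError("patch_px and um_per_px must be positive")
    return patch_px * um_per_px


@dataclass
class SlideImage:
    """RGB histology raster with a known physical scale."""

    pixels: np.ndarray  # rows x cols x 3, uint8
    um_per_px: float
    name: str = "slide"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be rows x cols x 3")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must have at least one row and column")
        if not self.um_per_px > 0:
            raise ValueError("um_per_px must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class NucleusPolygon:
    """One segmented nucleus as a simple polygon in slide pixel coordinates."""

    cell_id: str
    vertices: np.ndarray  # (n, 2) float, columns (x, y)
    centroid: tuple[float, float] = field(default=None)  # type: ignore[assignment]
    area_px: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array of (x, y)")
        if self.vertices.shape[0] < 3:
            raise ValueError("polygon needs at least 3 vertices")
        if self.centroid is None or self.area_px is None:
            poly = self.shapely
            if self.area_px is None:
                self.area_px = float(poly.area)
            if self.centroid is None:
                c = poly.centroid
                self.centroid = (float(c.x), float(c.y))
        if not self.area_px > 0:
            raise ValueError("polygon area must be positive")

    @property
    def shapely(self) -> Polygon:
        return Polygon(self.vertices)

    def scaled(self, factor: float) -> "NucleusPolygon":
        """Polygon with all coordinates multiplied by ``factor`` (used when the
        slide is rescaled to the working resolution)."""
        return NucleusPolygon(cell_id=self.cell_id, vertices=self.vertices * factor)


@dataclass
class CellTile:
    """A 256x256 histology tile centered on one nucleus, with the rasterized
    nucleus mask and the indices of the 16x16 patches the nucleus touches."""

    cell_id: str
    tile: np.ndarray  # 256 x 256 x 3 uint8
    mask: np.ndarray  # 256 x 256 bool
    origin: tuple[int, int]  # (x0, y0) of the tile's top-left corner, slide frame
    nucleus_patch_indices: list[int]

    def __post_init__(self) -> None:
        if self.tile.shape != (TILE_PX, TILE_PX, 3):
            raise ValueError(f"tile must be {TILE_PX}x{TILE_PX}x3")
        if self.mask.shape != (TILE_PX, TILE_PX):
            raise ValueError(f"mask must be {TILE_PX}x{TILE_PX}")
        if not self.nucleus_patch_indices:
            raise ValueError("nucleus_patch_indices must be non-empty")


def rescale_to_target(image: SlideImage, target_um_per_px: float = TARGET_UM_PER_PX) -> SlideImage:
    """Bilinearly resample ``image`` to ``target_um_per_px``.

    Output dimensions are ``round(dim * image.um_per_px / target)``. An image
    already at the target scale is returned unchanged. Polygons segmented at
    the source scale must be rescaled with :func:`rescale_polygons` by the
    same factor.
    """
    if not target_um_per_px > 0:
        raise ValueError("target_um_per_px must be positive")
    if image.um_per_px == target_um_per_px:
        return image
    factor = image.um_per_px / target_um_per_px
    rows, cols = image.shape
    out_shape = (max(1, round(rows * factor)), max(1, round(cols * factor)))
    out = resize(
        image.pixels.astype(float),
        out_shape + (3,),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return SlideImage(
        pixels=np.clip(np.rint(out), 0, 255).astype(np.uint8),
        um_per_px=target_um_per_px,
        name=image.name,
    )


def rescale_polygons(polygons: list[NucleusPolygon], source_um_per_px: float,
                     target_um_per_px: float = TARGET_UM_PER_PX) -> list[NucleusPolygon]:
    """Companion to :func:`rescale_to_target` for polygons given at source scale."""
    factor = source_um_per_px / target_um_per_px
    if factor == 1.0:
        return list(polygons)
    return [p.scaled(factor) for p in polygons]


def percentile_normalize(image: SlideImage, p_low: float = 1.0, p_high: float = 99.8) -> SlideImage:
    """Per-channel linear stretch mapping the ``p_low`` percentile to 0 and the
    ``p_high`` percentile to 255, clipped to [0, 255].

    A constant channel is left unchanged with a warning. Applied before
    nuclear segmentation so the engine sees a standardized intensity range.
    """
    if not (0 <= p_low < p_high <= 100):
        raise ValueError("need 0 <= p_low < p_high <= 100")
    out = image.pixels.astype(float).copy()
    for ch in range(3):
        lo, hi = np.percentile(image.pixels[:, :, ch], [p_low, p_high])
        if hi <= lo:
            warnings.warn(
                f"channel {ch} is constant over the [{p_low}, {p_high}] percentile "
                "range; left unchanged", stacklevel=2)
            continue
        out[:, :, ch] = np.clip((out[:, :, ch] - lo) / (hi - lo) * 255.0, 0, 255)
    return SlideImage(pixels=np.rint(out).astype(np.uint8), um_per_px=image.um_per_px,
                      name=image.name)


class GroundTruthEngine:
    """Segmentation adapter that replays known polygons (fixtures / external
    segmentations loaded from GeoJSON). Satisfies the engine contract:
    ``run(raster) -> list of (n, 2) vertex arrays``."""

    def __init__(self, polygons: list[NucleusPolygon]):
        self._polygons = polygons

    def run(self, raster: np.ndarray) -> list[np.ndarray]:
        return [p.vertices for p in self._polygons]


def segment_nuclei(image: SlideImage, engine) -> list[NucleusPolygon]:
    """Run a segmentation engine and wrap its polygons.

    ``engine`` is any object with ``run(raster) -> list of vertex lists``
    (a StarDist-style tool behind a thin adapter, or :class:`GroundTruthEngine`
    for fixtures). Degenerate outputs (< 3 vertices, zero area) are dropped.
    """
    try:
        raw = engine.run(image.pixels)
    except Exception as exc:  # pragma: no cover - pass-through context
        raise RuntimeError(f"segmentation engine failed on '{image.name}'") from exc
    polygons: list[NucleusPolygon] = []
    for k, verts in enumerate(raw):
        verts = np.asarray(verts, dtype=float)
        if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
            continue
        if abs(Polygon(verts).area) <= 0:
            continue
        polygons.append(NucleusPolygon(cell_id=f"cell_{k:05d}", vertices=verts))
    return polygons


def rasterize_polygon_mask(polygon: NucleusPolygon, origin: tuple[int, int],
                           shape: tuple[int, int] = (TILE_PX, TILE_PX)) -> np.ndarray:
    """Boolean mask over a pixel window: true where the pixel center lies
    inside the polygon (boundary included)."""
    x0, y0 = origin
    rows, cols = shape
    minx, miny, maxx, maxy = polygon.shapely.bounds
    c_lo = max(0, int(np.floor(minx - x0)))
    c_hi = min(cols - 1, int(np.ceil(maxx - x0)))
    r_lo = max(0, int(np.floor(miny - y0)))
    r_hi = min(rows - 1, int(np.ceil(maxy - y0)))
    mask = np.zeros(shape, dtype=bool)
    if c_hi < c_lo or r_hi < r_lo:
        return mask
    cs = np.arange(c_lo, c_hi + 1)
    rs = np.arange(r_lo, r_hi + 1)
    cc, rr = np.meshgrid(cs, rs)
    inside = shapely.intersects_xy(polygon.shapely, (cc + x0).ravel(), (rr + y0).ravel())
    mask[rr.ravel()[inside], cc.ravel()[inside]] = True
    return mask


def nucleus_patch_indices(mask: np.ndarray) -> list[int]:
    """Indices of the 16x16-px patches containing at least one nucleus pixel.

    Patch ``k`` is row ``k // 16``, column ``k % 16`` of the patch grid. If the
    mask is empty the single central patch is returned so that the local
    feature is always defined.
    """
    if mask.shape != (TILE_PX, TILE_PX):
        raise ValueError(f"mask must be {TILE_PX}x{TILE_PX}")
    blocks = mask.reshape(PATCH_GRID, PATCH_PX, PATCH_GRID, PATCH_PX)
    hit = blocks.any(axis=(1, 3))
    rr, cc = np.nonzero(hit)
    if rr.size == 0:
        center = PATCH_GRID // 2
        return [center * PATCH_GRID + center]
    return sorted(int(r) * PATCH_GRID + int(c) for r, c in zip(rr, cc))


def extract_cell_tile(image: SlideImage, polygon: NucleusPolygon,
                      tile_px: int = TILE_PX) -> CellTile:
    """Cut the 256x256 tile centered on the nucleus centroid.

    The origin is ``round(centroid) - tile_px/2`` per axis (round half up);
    regions falling outside the slide are padded with white, the H&E
    background color. The mask rasterizes the polygon into the tile frame.
    """
    if tile_px != TILE_PX:
        raise ValueError("tile side is fixed at 256 px (the patch grid depends on it)")
    cx, cy = polygon.centroid
    rows, cols = image.shape
    if not (0 <= cx < cols and 0 <= cy < rows):
        raise ValueError(
            f"centroid ({cx:.1f}, {cy:.1f}) of {polygon.cell_id} is outside the image")
    half = tile_px // 2
    x0 = int(np.floor(cx + 0.5)) - half  # round half up
    y0 = int(np.floor(cy + 0.5)) - half
    tile = np.full((tile_px, tile_px, 3), WHITE, dtype=np.uint8)
    src_x0, src_x1 = max(x0, 0), min(x0 + tile_px, cols)
    src_y0, src_y1 = max(y0, 0), min(y0 + tile_px, rows)
    if src_x1 > src_x0 and src_y1 > src_y0:
        tile[src_y0 - y0:src_y1 - y0, src_x0 - x0:src_x1 - x0] = \
            image.pixels[src_y0:src_y1, src_x0:src_x1]
    mask = rasterize_polygon_mask(polygon, (x0, y0), (tile_px, tile_px))
    return CellTile(
        cell_id=polygon.cell_id,
        tile=tile,
        mask=mask,
        origin=(x0, y0),
        nucleus_patch_indices=nucleus_patch_indices(mask),
    )
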