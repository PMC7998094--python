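"""Geometric primitives for stratified-epithelium image analysis.

The ectocervical epithelium is delimited in a tissue section by three
operator-drawn polylines: the basal membrane, the apical end of the
E-cadherin-expressing layer, and the last (most superficial) epithelial
cell layer.  This module represents those annotations together with the
channel images they refer to, rasterizes them onto the pixel grid, and
derives distance maps and layer thicknesses from them.

Coordinate convention
---------------------
Pixel indices are 0-based.  A coordinate pair is ``(x, y)`` =
``(column, row)`` with the origin at the top-left corner of the image.
The center of pixel ``(x, y)`` sits at the continuous coordinate
``(x, y)``; the pixel therefore spans ``[x - 0.5, x + 0.5) x
[y - 0.5, y + 0.5)``.  A pixel whose center lies exactly on a reference
polyline has depth 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.ndimage import distance_transform_edt
from scipy.spatial import cKDTree
from skimage.draw import line as _bresenham_line

__all__ = [
    "BoundaryError",
    "InvalidROIError",
    "ChannelImage",
    "BoundarySet",
    "EpitheliumMask",
    "DepthMap",
    "ThicknessResult",
    "rasterize_polyline",
    "build_epithelium_mask",
    "distance_from_boundary",
    "measure_thickness",
]

logger = logging.getLogger(__name__)


class BoundaryError(ValueError):
    """A polyline/polygon annotation is malformed or out of bounds."""


class InvalidROIError(ValueError):
    """A region-of-interest polygon is degenerate or non-simple."""


def _as_vertex_array(line, name: str = "polyline") -> np.ndarray:
    arr = np.asarray(line, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise BoundaryError(f"{name} must be an (N, 2) array of (x, y) vertices")
    if not np.all(np.isfinite(arr)):
        raise BoundaryError(f"{name} contains non-finite vertices")
    return arr


@dataclass
class ChannelImage:
    """One grayscale fluorescence plane with its physical pixel size.

    Parameters
    ----------
    pixels
        2D array of non-negative intensities.
    channel_name
        Stain label, e.g. ``"DAPI"``, ``"E-cadherin"``, ``"CD4"``,
        ``"CCR5"``, ``"Langerin"``.
    pixel_size_um
        Physical side length of one pixel in micrometres.
    """

    pixels: np.ndarray
    channel_name: str
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("ChannelImage.pixels must be 2D")
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise ValueError("intensities must be finite and >= 0")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class BoundarySet:
    """The operator annotations for one image.

    ``roi_polygon`` is a closed simple polygon outlining the epithelium;
    ``basal_line`` traces the basal membrane, ``ecad_boundary_line`` the
    apical end of the E-cadherin-positive layer, and ``apical_line`` the
    last epithelial cell layer.  All in pixel coordinates (x, y).
    """

    roi_polygon: np.ndarray
    basal_line: np.ndarray
    ecad_boundary_line: np.ndarray
    apical_line: np.ndarray

    def __post_init__(self) -> None:
        self.roi_polygon = _as_vertex_array(self.roi_polygon, "roi_polygon")
        self.basal_line = _as_vertex_array(self.basal_line, "basal_line")
        self.ecad_boundary_line = _as_vertex_array(
            self.ecad_boundary_line, "ecad_boundary_line"
        )
        self.apical_line = _as_vertex_array(self.apical_line, "apical_line")
        for name in ("roi_polygon", "basal_line", "ecad_boundary_line", "apical_line"):
            if len(getattr(self, name)) < 2:
                raise BoundaryError(f"{name} needs at least 2 vertices")


@dataclass
class EpitheliumMask:
    """Boolean tissue mask with physical pixel size; area derived."""

    mask: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def area_mm2(self) -> float:
        return float(self.mask.sum()) * (self.pixel_size_um / 1000.0) ** 2

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape  # type: ignore[return-value]


@dataclass
class DepthMap:
    """Per-pixel distance (µm) from a reference boundary.

    ``depth_um`` is NaN outside the epithelium mask.  ``reference`` names
    the boundary the distances are anchored at ("apical" or "basal").
    """

    depth_um: np.ndarray
    reference: str
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.depth_um = np.asarray(self.depth_um, dtype=float)
        if self.reference not in ("apical", "basal", "ecad"):
            raise ValueError(f"unknown reference {self.reference!r}")

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.depth_um)


@dataclass
class ThicknessResult:
    """Layer thickness summaries for one image, in µm.

    ``total_um`` is the apical-to-basal distance summary, ``ecad_pos_um``
    the basal-to-E-cadherin-boundary summary, ``ecad_neg_um`` the
    apical-to-E-cadherin-boundary summary.  Per-point lists hold the raw
    nearest-neighbour distances the summaries were taken over.
    """

    total_um: float
    ecad_pos_um: float
    ecad_neg_um: float
    per_point_total: np.ndarray
    per_point_ecad_pos: np.ndarray
    per_point_ecad_neg: np.ndarray
    summary_statistic: str = "median"
    pixel_size_um: float = 1.0

    @property
    def n_points(self) -> int:
        return len(self.per_point_total)


def rasterize_polyline(line, image_shape: tuple[int, int]) -> np.ndarray:
    """Rasterize an open polyline onto a boolean grid.

    Each consecutive vertex pair is traversed with Bresenham's line
    algorithm, giving an 8-connected pixel path; endpoints are marked.

    Parameters
    ----------
    line
        (N, 2) array of (x, y) vertices, N >= 2.
    image_shape
        (rows, cols) of the target grid.

    Raises
    ------
    BoundaryError
        If a vertex falls outside the image, naming its index.
    """
    arr = _as_vertex_array(line)
    if len(arr) < 2:
        raise BoundaryError("polyline needs at least 2 vertices")
    nrows, ncols = image_shape
    cols = np.rint(arr[:, 0]).astype(int)
    rows = np.rint(arr[:, 1]).astype(int)
    for i, (c, r) in enumerate(zip(cols, rows)):
        if not (0 <= c < ncols and 0 <= r < nrows):
            raise BoundaryError(
                f"vertex {i} at (x={arr[i, 0]:g}, y={arr[i, 1]:g}) is outside "
                f"the {nrows}x{ncols} image"
            )
    grid = np.zeros(image_shape, dtype=bool)
    for i in range(len(arr) - 1):
        rr, cc = _bresenham_line(rows[i], cols[i], rows[i + 1], cols[i + 1])
        grid[rr, cc] = True
    return grid


def build_epithelium_mask(
    boundaries, image_shape: tuple[int, int], pixel_size_um: float
) -> EpitheliumMask:
    """Rasterize the ROI polygon into an epithelium mask.

    A pixel belongs to the mask when its center lies strictly inside the
    polygon (even-odd rule; for the simple polygons required here this
    coincides with ordinary point-in-polygon containment).

    ``boundaries`` may be a :class:`BoundarySet` or a bare (N, 2) vertex
    array of the ROI polygon.
    """
    polygon = boundaries.roi_polygon if isinstance(boundaries, BoundarySet) else boundaries
    arr = _as_vertex_array(polygon, "roi_polygon")
    if len(arr) < 3:
        raise InvalidROIError("ROI polygon needs at least 3 vertices")
    poly = shapely.Polygon(arr)
    if poly.area == 0 or not np.isfinite(poly.area):
        raise InvalidROIError("ROI polygon has zero area")
    nrows, ncols = image_shape
    xs, ys = np.meshgrid(np.arange(ncols, dtype=float), np.arange(nrows, dtype=float))
    inside = shapely.contains_xy(poly, xs.ravel(), ys.ravel()).reshape(nrows, ncols)
    return EpitheliumMask(mask=inside, pixel_size_um=pixel_size_um)


def distance_from_boundary(mask: EpitheliumMask, line, reference: str) -> DepthMap:
    """Exact Euclidean distance (µm) of every epithelium pixel to a polyline.

    The polyline is rasterized first; distances are taken to the nearest
    rasterized line pixel via an exact Euclidean distance transform and
    scaled by the physical pixel size.  Pixels outside the epithelium
    mask are NaN.
    """
    ras = rasterize_polyline(line, mask.shape)
    if not ras.any():
        raise BoundaryError("reference line rasterizes to no pixels inside the image")
    # EDT of the complement: distance of every pixel to the nearest line pixel.
    dist_px = distance_transform_edt(~ras)
    depth = np.where(mask.mask, dist_px * mask.pixel_size_um, np.nan)
    return DepthMap(depth_um=depth, reference=reference, pixel_size_um=mask.pixel_size_um)


def _line_pixel_coords(line, shape) -> np.ndarray:
    ras = rasterize_polyline(line, shape)
    pts = np.argwhere(ras)  # (row, col)
    if len(pts) == 0:
        raise BoundaryError("polyline rasterizes to no pixels")
    return pts.astype(float)


def _nearest_distances(from_pts: np.ndarray, to_pts: np.ndarray) -> np.ndarray:
    tree = cKDTree(to_pts)
    d, _ = tree.query(from_pts, k=1)
    return np.asarray(d, dtype=float)


def measure_thickness(
    boundaries: BoundarySet,
    mask: EpitheliumMask,
    summary_statistic: str = "median",
) -> ThicknessResult:
    """Measure total, E-cadherin-positive and -negative layer thickness.

    For every rasterized apical-line pixel the nearest distance to the
    rasterized basal line gives the per-point total thickness, and the
    nearest distance to the E-cadherin boundary line gives the
    E-cadherin-negative (superficial) layer thickness.  For every
    E-cadherin-boundary pixel the nearest distance to the basal line
    gives the E-cadherin-positive layer thickness.  Each list is reduced
    to one number per image by the summary statistic (median by default).

    The three summaries are measured independently, so exact additivity
    ``total = pos + neg`` is not guaranteed; on near-parallel boundaries
    the gap stays within about two pixel widths.
    """
    if summary_statistic not in ("median", "mean"):
        raise ValueError("summary_statistic must be 'median' or 'mean'")
    shape = mask.shape
    apical = _line_pixel_coords(boundaries.apical_line, shape)
    basal = _line_pixel_coords(boundaries.basal_line, shape)
    ecad = _line_pixel_coords(boundaries.ecad_boundary_line, shape)

    px = mask.pixel_size_um
    per_total = _nearest_distances(apical, basal) * px
    per_neg = _nearest_distances(apical, ecad) * px
    per_pos = _nearest_distances(ecad, basal) * px

    reduce = np.median if summary_statistic == "median" else np.mean
    return ThicknessResult(
        total_um=float(reduce(per_total)),
        ecad_pos_um=float(reduce(per_pos)),
        ecad_neg_um=float(reduce(per_neg)),
        per_point_total=per_total,
        per_point_ecad_pos=per_pos,
        per_point_ecad_neg=per_neg,
        summary_statistic=summary_statistic,
        pixel_size_um=px,
    )
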