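"""Cell segmentation, polygonization and jamming shape descriptors.

The jamming state of an epithelial monolayer is read out from cell shape: the
apical shape index q_a = p_a / sqrt(A_a) (perimeter over square root of area;
lower and more uniform in jammed tissue), the aspect ratio AR of the best-fit
ellipse together with its standard deviation across the monolayer, and the
cell density sigma in cells per mm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon
from skimage.measure import (
    approximate_polygon,
    find_contours,
    label as cc_label,
    perimeter,
    regionprops,
)

from .graph import JunctionGraph, Skeleton

__all__ = [
    "CellRecord",
    "MonolayerSummary",
    "segment_cells",
    "link_cells",
    "polygonize",
    "shape_index",
    "aspect_ratio",
    "summarize",
    "region_perimeter",
    "polygon_shape_index",
]

ISOPERIMETRIC_MIN = 2.0 * np.sqrt(np.pi)  # q_a of a disk, ~3.5449


@dataclass
class CellRecord:
    id: int
    pixel_coords: np.ndarray  # (n, 2) int
    centroid: tuple[float, float]
    border_flag: bool
    polygon: list[int] = field(default_factory=list)  # ordered vertex ids
    polygon_coords: np.ndarray | None = None  # (k, 2) float (row, col)
    area_px: float = float("nan")
    perimeter_px: float = float("nan")
    q_a: float = float("nan")
    AR: float = float("nan")
    flags: set[str] = field(default_factory=set)

    def area_um2(self, pixel_size: float) -> float:
        return self.area_px * pixel_size**2

    def perimeter_um(self, pixel_size: float) -> float:
        return self.perimeter_px * pixel_size


@dataclass
class MonolayerSummary:
    n_cells: int
    sigma: float  # cells per mm^2
    mean_q_a: float
    mean_AR: float
    sd_AR: float


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_cells(skel: Skeleton | np.ndarray) -> list[CellRecord]:
    """Cells as 4-connected components of the skeleton's complement.

    Components touching the image border are flagged ``border`` (they are
    clipped by the field of view and excluded from monolayer summaries).
    """
    mask = skel.mask if isinstance(skel, Skeleton) else np.asarray(skel, bool)
    labels = cc_label(~mask, connectivity=1)
    h, w = labels.shape
    border_labels = set(
        np.unique(
            np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
        )
    ) - {0}
    cells: list[CellRecord] = []
    for prop in regionprops(labels):
        coords = prop.coords
        cells.append(
            CellRecord(
                id=prop.label,
                pixel_coords=coords,
                centroid=tuple(prop.centroid),
                border_flag=prop.label in border_labels,
                area_px=float(prop.area),
            )
        )
    if not any(not c.border_flag for c in cells):
        raise ValueError("no interior cell found; is the junction network closed?")
    return cells


def link_cells(graph: JunctionGraph, cells: list[CellRecord], label_image=None) -> None:
    """Attach incident-cell ids to the graph's edges and vertices in place.

    A cell is incident to an edge when its pixels touch the edge path
    (8-neighborhood); a vertex inherits the union of its edges' cells.
    """
    if label_image is None:
        h, w = graph.shape
        label_image = np.zeros((h, w), dtype=np.int32)
        for c in cells:
            label_image[c.pixel_coords[:, 0], c.pixel_coords[:, 1]] = c.id
    h, w = label_image.shape
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for e in graph.edges.values():
        found: set[int] = set()
        for r, c in e.pixel_path:
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and label_image[rr, cc] > 0:
                    found.add(int(label_image[rr, cc]))
        e.incident_cell_ids = sorted(found)
    for v in graph.vertices.values():
        cells_v: set[int] = set()
        for eid in v.incident_edge_ids:
            cells_v.update(graph.edges[eid].incident_cell_ids)
        # keep only cells actually adjacent to the vertex neighborhood
        near: set[int] = set()
        r0, c0 = v.skeleton_coords
        rad = 3
        rr0, rr1 = max(0, r0 - rad), min(h, r0 + rad + 1)
        cc0, cc1 = max(0, c0 - rad), min(w, c0 + rad + 1)
        near.update(int(x) for x in np.unique(label_image[rr0:rr1, cc0:cc1]) if x > 0)
        v.incident_cell_ids = sorted(cells_v & near) if cells_v & near else sorted(near)


# ---------------------------------------------------------------------------
# polygons and descriptors
# ---------------------------------------------------------------------------

def polygonize(cell: CellRecord, graph: JunctionGraph) -> CellRecord:
    """Build the cell's polygon from its incident vertices ordered by angle.

    Auxiliary points added by edit scripts are included.  If fewer than three
    vertices are incident, or the angular ordering self-intersects, the cell is
    flagged ``non_polygonal`` and keeps its pixel-region measures.
    """
    vids = [
        vid for vid, v in graph.vertices.items() if cell.id in v.incident_cell_ids
    ]
    pts = [(graph.vertices[vid].relocated_coords, vid) for vid in vids]
    pts += [
        ((p["coords"][0], p["coords"][1]), -1)
        for p in graph.aux_points
        if p["cell_id"] == cell.id
    ]
    if len(pts) < 3:
        cell.flags.add("non_polygonal")
        return cell
    cr, cc = cell.centroid
    ang = [np.arctan2(p[0][0] - cr, p[0][1] - cc) for p in pts]
    order = np.argsort(ang)
    coords = np.array([pts[i][0] for i in order], dtype=float)
    poly = Polygon([(c, r) for r, c in coords])  # shapely is (x, y)
    if not poly.is_valid or poly.area <= 0:
        cell.flags.add("non_polygonal")
        return cell
    cell.polygon = [pts[i][1] for i in order]
    cell.polygon_coords = coords
    cell.area_px = float(poly.area)
    cell.perimeter_px = float(poly.length)
    return cell


def polygon_shape_index(coords) -> float:
    """q_a of an explicit polygon: exact Euclidean perimeter over sqrt(area)."""
    poly = Polygon([(c, r) for r, c in np.asarray(coords, dtype=float)])
    if poly.area <= 0:
        raise ValueError("polygon has zero area")
    return float(poly.length / np.sqrt(poly.area))


def region_perimeter(mask: np.ndarray, method: str = "contour") -> float:
    """Perimeter of a pixel region.

    ``contour`` (default): subpixel marching-squares boundary simplified by
    Douglas-Peucker (1 px tolerance), accurate to ~1% for convex cells at
    >= 40 px diameter regardless of edge orientation.  ``weighted``: classic
    boundary-step count (1 straight, sqrt(2) diagonal), which biases diagonal
    edges by a few percent.
    """
    m = np.asarray(mask, bool)
    if method == "weighted":
        return float(perimeter(m, neighborhood=4))
    padded = np.pad(m.astype(float), 1)
    contours = find_contours(padded, 0.5)
    if not contours:
        return 0.0
    total = 0.0
    for c in contours:
        c = approximate_polygon(c, tolerance=1.0)
        total += float(np.sum(np.hypot(*np.diff(c, axis=0).T)))
    return total


def _region_measures(cell: CellRecord, shape) -> tuple[float, float]:
    coords = cell.pixel_coords
    r0, c0 = coords.min(axis=0)
    r1, c1 = coords.max(axis=0)
    mask = np.zeros((r1 - r0 + 3, c1 - c0 + 3), dtype=bool)
    mask[coords[:, 0] - r0 + 1, coords[:, 1] - c0 + 1] = True
    return float(mask.sum()), region_perimeter(mask)


def shape_index(cell: CellRecord, image_shape=None) -> float:
    """Apical shape index q_a = p_a / sqrt(A_a).

    Computed on the polygon when one is available, otherwise on the pixel
    region with the Crofton perimeter estimator.  Scale-invariant; bounded
    below by 2*sqrt(pi) for smooth shapes.
    """
    if cell.polygon_coords is not None and "non_polygonal" not in cell.flags:
        a, p = cell.area_px, cell.perimeter_px
    else:
        a, p = _region_measures(cell, image_shape)
        cell.area_px, cell.perimeter_px = a, p
    if not (a > 0):
        raise ValueError(f"cell {cell.id} has zero area")
    cell.q_a = float(p / np.sqrt(a))
    return cell.q_a


def aspect_ratio(cell: CellRecord, method: str = "moments") -> float:
    """Aspect ratio of the cell region, >= 1.

    ``moments``: major/minor axis of the best-fit ellipse from second central
    moments.  ``bbox``: side ratio of the minimum-area bounding box (requires a
    polygon).  Degenerate (collinear) regions give ``inf`` with a flag.
    """
    if method == "bbox" and cell.polygon_coords is not None:
        poly = Polygon([(c, r) for r, c in cell.polygon_coords])
        rect = poly.minimum_rotated_rectangle
        xs, ys = rect.exterior.coords.xy
        s1 = float(np.hypot(xs[1] - xs[0], ys[1] - ys[0]))
        s2 = float(np.hypot(xs[2] - xs[1], ys[2] - ys[1]))
        lo, hi = sorted([s1, s2])
        cell.AR = float("inf") if lo == 0 else hi / lo
        return cell.AR
    coords = cell.pixel_coords.astype(float)
    if len(coords) < 2:
        raise ValueError("aspect ratio needs a region of at least 2 pixels")
    cov = np.cov(coords.T)
    evals = np.sort(np.linalg.eigvalsh(cov))
    if evals[0] <= 0:
        cell.flags.add("degenerate")
        cell.AR = float("inf")
        return cell.AR
    cell.AR = float(np.sqrt(evals[1] / evals[0]))
    return cell.AR


def summarize(
    cells: list[CellRecord],
    pixel_size: float,
    image_shape: tuple[int, int],
    include_border: bool = False,
) -> MonolayerSummary:
    """Monolayer summary over non-border cells.

    ``sigma`` is cells per mm^2 with border-cell pixels excluded from the area
    denominator, so it reflects interior packing.
    """
    kept = [c for c in cells if include_border or not c.border_flag]
    if not kept:
        raise ValueError("no cells to summarize")
    h, w = image_shape
    border_px = sum(
        len(c.pixel_coords) for c in cells if c.border_flag and not include_border
    )
    area_mm2 = (h * w - border_px) * (pixel_size**2) / 1e6
    ars = np.array([c.AR for c in kept if np.isfinite(c.AR)])
    qas = np.array([c.q_a for c in kept if np.isfinite(c.q_a)])
    return MonolayerSummary(
        n_cells=len(kept),
        sigma=len(kept) / area_mm2,
        mean_q_a=float(qas.mean()) if len(qas) else float("nan"),
        mean_AR=float(ars.mean()) if len(ars) else float("nan"),
        sd_AR=float(ars.std(ddof=1)) if len(ars) > 1 else 0.0,
    )
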