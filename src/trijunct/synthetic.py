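"""Synthetic epithelial-monolayer image generator with exact ground truth.

Renders multichannel fluorescence-like images of a confluent monolayer — a
junctional channel (thin bright cell-boundary lines, ZO-1-like), a
tricellular-marker channel (same boundaries with controllable enrichment or
depletion at the three-cell vertices, tricellulin-like) and a nuclear channel
(one disk per cell) — from a centroidal-relaxed random Voronoi tessellation,
so every downstream stage of the pipeline can be tested against known
geometry.

Vertex enrichment is controlled by the ratio ``rho`` of the tricellular-marker
intensity at a vertex puncta center to the bicellular boundary intensity:
boundary pixels near a vertex are modulated by ``1 + (rho - 1) * g`` where
``g`` is a unit-peak Gaussian profile, so the puncta center sits at
``rho * boundary_intensity`` while boundary lines away from vertices stay at
``boundary_intensity``.  ``rho = 0`` disables punctae entirely (the
tricellular channel then matches the junctional channel up to noise).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial import Voronoi
from scipy import ndimage
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.morphology import dilation as binary_dilation, disk as disk_footprint

from .graph import BoundaryMap, Edge, JunctionGraph, Vertex

__all__ = [
    "TessellationSpec",
    "GroundTruth",
    "generate_tessellation",
    "generate_wound_front",
    "generate_zstack",
    "write_channels",
]


@dataclass
class TessellationSpec:
    """Parameters of a synthetic monolayer rendering.

    ``enrichment_ratio`` is the tricellular-marker peak at a vertex divided by
    the bicellular boundary intensity; values above 1 emulate mature
    tricellular junctions, below 1 depleted (immature) ones.
    """

    n_cells: int = 25
    image_size: tuple[int, int] = (512, 512)
    boundary_width: int = 3
    boundary_intensity: float = 200.0
    enrichment_ratio: float = 2.0
    puncta_sigma: float = 2.0
    noise_sd: float = 0.0
    nuclear_radius: float = 8.0
    rng_seed: int = 0
    pixel_size: float = 0.5  # micrometres per pixel
    background_level: float | None = None  # cytoplasmic background; default 2% of boundary
    nuclear_intensity: float | None = None
    relax_iterations: int = 2  # Lloyd iterations; 0 keeps elongated (unjammed-looking) cells

    def __post_init__(self) -> None:
        if self.n_cells < 4:
            raise ValueError("n_cells must be >= 4")
        if self.boundary_width < 1:
            raise ValueError("boundary_width must be >= 1")
        if self.enrichment_ratio < 0:
            raise ValueError("enrichment_ratio must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        h, w = self.image_size
        diameter = float(np.sqrt(h * w / self.n_cells))
        if diameter < 4 * self.boundary_width:
            raise ValueError(
                f"image too small to host {self.n_cells} cells: expected cell "
                f"diameter {diameter:.1f} px < 4 x boundary_width "
                f"({4 * self.boundary_width} px); enlarge the image or reduce "
                "n_cells/boundary_width"
            )
        if self.background_level is None:
            self.background_level = 0.02 * self.boundary_intensity
        if self.nuclear_intensity is None:
            self.nuclear_intensity = self.boundary_intensity


@dataclass
class GroundTruth:
    """Exact tessellation geometry plus the rendered-image scoring oracle."""

    vertex_coords: list[tuple[float, float]]  # (row, col)
    vertex_interior: list[bool]
    cell_polygons: list[list[int]]  # vertex-index lists, ordered
    cell_adjacency: list[tuple[int, int]]
    cell_centroids: list[tuple[float, float]]  # (row, col)
    cell_border: list[bool]
    per_vertex_expected_TL: list[float] = field(default_factory=list)
    per_cell_phase_label: list[str] | None = None
    leader_cell: int | None = None
    cell_rows: list[int] | None = None
    per_vertex_rho: list[float] | None = None

    @property
    def n_cells(self) -> int:
        return len(self.cell_polygons)

    def interior_vertex_ids(self) -> list[int]:
        return [i for i, ok in enumerate(self.vertex_interior) if ok]

    def to_json(self, path=None) -> str:
        doc = asdict(self)
        text = json.dumps(
            doc, indent=1, sort_keys=True,
            default=lambda o: o.item() if hasattr(o, "item") else str(o),
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# ---------------------------------------------------------------------------
# tessellation geometry (mirrored-point Voronoi clipped to a rectangle)
# ---------------------------------------------------------------------------

def _box_voronoi_polygons(points: np.ndarray, x0, x1, y0, y1):
    """Voronoi polygons of ``points`` clipped exactly to the box.

    Points are mirrored across all four box edges so every original region is
    finite and bounded by the box.  Returns (polygons as (k, 2) xy arrays,
    adjacency pairs).
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    mirrors = [
        pts,
        np.column_stack([2 * x0 - pts[:, 0], pts[:, 1]]),
        np.column_stack([2 * x1 - pts[:, 0], pts[:, 1]]),
        np.column_stack([pts[:, 0], 2 * y0 - pts[:, 1]]),
        np.column_stack([pts[:, 0], 2 * y1 - pts[:, 1]]),
    ]
    vor = Voronoi(np.vstack(mirrors))
    polys = []
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        verts = vor.vertices[region]
        # angular order around the seed (regions of a Voronoi cell are convex)
        ang = np.arctan2(verts[:, 1] - pts[i, 1], verts[:, 0] - pts[i, 0])
        order = np.argsort(ang)
        polys.append(verts[order])
    adjacency = set()
    for (a, b) in vor.ridge_points:
        if a < n and b < n:
            adjacency.add((min(a, b), max(a, b)))
    return polys, sorted(adjacency)


def _poly_centroid(poly: np.ndarray) -> np.ndarray:
    x, y = poly[:, 0], poly[:, 1]
    xs, ys = np.roll(x, -1), np.roll(y, -1)
    cross = x * ys - xs * y
    a = cross.sum() / 2.0
    if abs(a) < 1e-12:
        return poly.mean(axis=0)
    cx = ((x + xs) * cross).sum() / (6.0 * a)
    cy = ((y + ys) * cross).sum() / (6.0 * a)
    return np.array([cx, cy])


def _merge_close_vertices(coords, cell_polygons, tol: float):
    """Collapse vertices closer than ``tol`` px into one (four-fold) nodal point.

    Two tessellation vertices separated by less than the boundary-line width
    render as a single nodal point, so ground truth reports them as one.
    """
    n = len(coords)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    arr = np.asarray(coords, dtype=float)
    from scipy.spatial import cKDTree

    pairs = cKDTree(arr).query_pairs(tol)
    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    new_id = {}
    new_coords = []
    for root in sorted(groups):
        members = groups[root]
        c = arr[members].mean(axis=0)
        for m in members:
            new_id[m] = len(new_coords)
        new_coords.append((float(c[0]), float(c[1])))
    new_polys = []
    for ids in cell_polygons:
        out = []
        for vid in ids:
            nv = new_id[vid]
            if not out or out[-1] != nv:
                out.append(nv)
        if len(out) > 1 and out[0] == out[-1]:
            out.pop()
        new_polys.append(out)
    return new_coords, new_polys


def _tessellate(spec: TessellationSpec, y0: float = 0.0):
    """Relaxed Voronoi geometry in the box [0, W] x [y0, H] (xy coords)."""
    h, w = spec.image_size
    rng = np.random.default_rng(spec.rng_seed)
    pts = np.column_stack(
        [rng.uniform(0, w, spec.n_cells), rng.uniform(y0, h, spec.n_cells)]
    )
    for _ in range(spec.relax_iterations):
        polys, _ = _box_voronoi_polygons(pts, 0, w, y0, h)
        pts = np.array([_poly_centroid(p) for p in polys])
    polys, adjacency = _box_voronoi_polygons(pts, 0, w, y0, h)

    # canonical vertex list: merge coincident polygon corners
    key_to_id: dict[tuple[int, int], int] = {}
    coords: list[tuple[float, float]] = []
    cell_polygons: list[list[int]] = []
    for poly in polys:
        ids = []
        for x, y in poly:
            key = (round(x * 1e6), round(y * 1e6))
            if key not in key_to_id:
                key_to_id[key] = len(coords)
                coords.append((float(y), float(x)))  # store as (row, col)
            vid = key_to_id[key]
            if not ids or ids[-1] != vid:
                ids.append(vid)
        if len(ids) > 1 and ids[0] == ids[-1]:
            ids.pop()
        cell_polygons.append(ids)

    coords, cell_polygons = _merge_close_vertices(
        coords, cell_polygons, tol=max(3.0, float(spec.boundary_width))
    )

    # a vertex merged with a border vertex can sit up to tol/2 off the frame
    eps = 2.0
    on_border = [
        (c <= eps or c >= w - eps or r <= y0 + eps or r >= h - eps)
        for r, c in coords
    ]
    incident: dict[int, set[int]] = {i: set() for i in range(len(coords))}
    for ci, ids in enumerate(cell_polygons):
        for vid in ids:
            incident[vid].add(ci)
    interior = [
        (not on_border[i]) and len(incident[i]) >= 3 for i in range(len(coords))
    ]
    centroids = [
        (float(_poly_centroid(p)[1]), float(_poly_centroid(p)[0])) for p in polys
    ]
    border_cell = [
        any(on_border[vid] for vid in ids) for ids in cell_polygons
    ]
    gt = GroundTruth(
        vertex_coords=coords,
        vertex_interior=interior,
        cell_polygons=cell_polygons,
        cell_adjacency=[tuple(p) for p in adjacency],
        cell_centroids=centroids,
        cell_border=border_cell,
    )
    return gt


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _boundary_mask(gt: GroundTruth, shape, width: int) -> np.ndarray:
    h, w = shape
    mask = np.zeros((h, w), dtype=bool)
    drawn = set()
    for ids in gt.cell_polygons:
        for a, b in zip(ids, ids[1:] + ids[:1]):
            key = (min(a, b), max(a, b))
            if key in drawn:
                continue
            drawn.add(key)
            r0, c0 = gt.vertex_coords[a]
            r1, c1 = gt.vertex_coords[b]
            rr, cc = draw_line(
                int(np.clip(round(r0), 0, h - 1)),
                int(np.clip(round(c0), 0, w - 1)),
                int(np.clip(round(r1), 0, h - 1)),
                int(np.clip(round(c1), 0, w - 1)),
            )
            mask[rr, cc] = True
    radius = (width - 1) // 2
    if radius > 0:
        mask = binary_dilation(mask, disk_footprint(radius))
    return mask


def _puncta_factor(
    gt: GroundTruth, shape, sigma: float, rho_per_vertex: np.ndarray
) -> np.ndarray:
    """Multiplicative modulation field: 1 away from vertices, rho at centers."""
    h, w = shape
    delta = np.zeros((h, w), dtype=float)
    for vid in gt.interior_vertex_ids():
        r, c = gt.vertex_coords[vid]
        ri = int(np.clip(round(r), 0, h - 1))
        ci = int(np.clip(round(c), 0, w - 1))
        delta[ri, ci] += rho_per_vertex[vid] - 1.0
    if not np.any(delta):
        return np.ones((h, w), dtype=float)
    blurred = ndimage.gaussian_filter(delta, sigma)
    # normalize so a unit impulse has peak exactly 1
    size = 2 * int(4 * sigma) + 9
    probe = np.zeros((size, size))
    probe[probe.shape[0] // 2, probe.shape[1] // 2] = 1.0
    peak = ndimage.gaussian_filter(probe, sigma).max()
    return np.clip(1.0 + blurred / peak, 0.0, None)


def _render_channels(spec: TessellationSpec, gt: GroundTruth, rho_per_vertex: np.ndarray):
    shape = spec.image_size
    b = spec.boundary_intensity
    bg = spec.background_level
    bmask = _boundary_mask(gt, shape, spec.boundary_width)

    zo1 = np.full(shape, bg, dtype=float)
    zo1[bmask] = b

    tric = np.full(shape, bg, dtype=float)
    if np.all(rho_per_vertex == 0.0):
        tric[bmask] = b  # rho = 0: no punctae at all
    else:
        factor = _puncta_factor(gt, shape, spec.puncta_sigma, rho_per_vertex)
        tric[bmask] = b * factor[bmask]

    nuclei = np.zeros(shape, dtype=float)
    for (r, c), is_border in zip(gt.cell_centroids, gt.cell_border):
        rr, cc = draw_disk((r, c), spec.nuclear_radius, shape=shape)
        nuclei[rr, cc] = spec.nuclear_intensity
    return bmask, zo1, tric, nuclei


def _add_noise(spec: TessellationSpec, *channels: np.ndarray):
    rng = np.random.default_rng(spec.rng_seed + 1)
    out = []
    for ch in channels:
        if spec.noise_sd > 0:
            ch = ch + rng.normal(0.0, spec.noise_sd, size=ch.shape)
        out.append(np.clip(ch, 0.0, None))
    return out


def ground_truth_graph(gt: GroundTruth, shape) -> JunctionGraph:
    """A :class:`JunctionGraph` built directly from ground-truth geometry.

    Edges carry straight pixel paths between vertex coordinates; used to score
    the rendered noiseless image with exactly the masks the pipeline's scorer
    uses, which makes ``per_vertex_expected_TL`` an exact oracle.
    """
    h, w = shape
    g = JunctionGraph(vertices={}, edges={}, shape=(h, w))
    for vid, (r, c) in enumerate(gt.vertex_coords):
        ri = int(np.clip(round(r), 0, h - 1))
        ci = int(np.clip(round(c), 0, w - 1))
        g.vertices[vid] = Vertex(
            id=vid,
            skeleton_coords=(ri, ci),
            relocated_coords=(float(ri), float(ci)),
        )
    drawn = {}
    eid = 0
    for ci_, ids in enumerate(gt.cell_polygons):
        for a, b_ in zip(ids, ids[1:] + ids[:1]):
            key = (min(a, b_), max(a, b_))
            if key in drawn:
                g.edges[drawn[key]].incident_cell_ids.append(ci_)
                continue
            ra, ca = g.vertices[a].skeleton_coords
            rb, cb = g.vertices[b_].skeleton_coords
            rr, cc = draw_line(ra, ca, rb, cb)
            g.edges[eid] = Edge(
                id=eid,
                pixel_path=np.column_stack([rr, cc]),
                endpoint_vertex_ids=(a, b_),
                incident_cell_ids=[ci_],
            )
            drawn[key] = eid
            eid += 1
    for e in g.edges.values():
        for vid in e.endpoint_vertex_ids:
            g.vertices[vid].incident_edge_ids.append(e.id)
    for v in g.vertices.values():
        v.degree = len(v.incident_edge_ids)
        cells = set()
        for e_id in v.incident_edge_ids:
            cells.update(g.edges[e_id].incident_cell_ids)
        v.incident_cell_ids = sorted(cells)
    return g


def _expected_tl(
    spec: TessellationSpec, gt: GroundTruth, bmask, tric_noiseless, r_tri=4.0, w_bi=2
):
    from .scoring import compute_masks, score_vertex

    g = ground_truth_graph(gt, spec.image_size)
    masks = compute_masks(g, BoundaryMap(mask=bmask), r_tri=r_tri, w_bi=w_bi)
    out = [float("nan")] * len(gt.vertex_coords)
    for vid in gt.interior_vertex_ids():
        tri, bi = masks.get(vid, (None, None))
        if tri is None or len(tri) == 0 or bi is None or len(bi) == 0:
            continue
        rec = score_vertex(tric_noiseless, tri, bi, vertex_id=vid)
        out[vid] = rec.T_L
    return out


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------

def generate_tessellation(spec: TessellationSpec):
    """Render a confluent-monolayer field with exact ground truth.

    Returns ``(ground_truth, zo1, tric, nuclei)`` where the channels are 2D
    float arrays.  Rendering is bit-reproducible for a fixed ``rng_seed``.
    """
    gt = _tessellate(spec)
    rho = np.full(len(gt.vertex_coords), spec.enrichment_ratio, dtype=float)
    gt.per_vertex_rho = rho.tolist()
    bmask, zo1, tric, nuclei = _render_channels(spec, gt, rho)
    gt.per_vertex_expected_TL = _expected_tl(spec, gt, bmask, tric)
    zo1, tric, nuclei = _add_noise(spec, zo1, tric, nuclei)
    return gt, zo1, tric, nuclei


def generate_wound_front(
    spec: TessellationSpec,
    n_rows: int,
    rho_by_row: list[float],
):
    """Render a monolayer with a free wound edge and row-graded enrichment.

    The wound occupies a strip at the top of the field; the cell touching the
    free edge closest to the field midline is flagged as the leader (row 1) and
    rows are breadth-first adjacency distance from it.  Each vertex takes the
    enrichment of the *youngest* (lowest-row) incident cell:
    ``rho_by_row[min(row) - 1]``, with rows beyond the list length clamped to
    its last entry.  Rows beyond ``n_rows`` are reported as ``n_rows``
    (interior).
    """
    if len(rho_by_row) < 1:
        raise ValueError("rho_by_row must have at least one entry")
    h, w = spec.image_size
    y0 = 0.12 * h  # wound strip height
    gt = _tessellate(spec, y0=y0)

    # leader: free-edge cell nearest the field midline
    eps = 2.0
    front_cells = [
        ci
        for ci, ids in enumerate(gt.cell_polygons)
        if any(gt.vertex_coords[v][0] <= y0 + eps for v in ids)
    ]
    if not front_cells:
        raise ValueError("no cells touch the wound edge; check image size")
    leader = min(front_cells, key=lambda ci: abs(gt.cell_centroids[ci][1] - w / 2))
    gt.leader_cell = int(leader)

    import networkx as nx

    adj = nx.Graph(gt.cell_adjacency)
    adj.add_nodes_from(range(gt.n_cells))
    dist = nx.single_source_shortest_path_length(adj, leader)
    rows = [min(dist.get(ci, n_rows) + 1, n_rows) for ci in range(gt.n_cells)]
    gt.cell_rows = rows

    incident: dict[int, set[int]] = {i: set() for i in range(len(gt.vertex_coords))}
    for ci, ids in enumerate(gt.cell_polygons):
        for vid in ids:
            incident[vid].add(ci)
    rho = np.empty(len(gt.vertex_coords), dtype=float)
    for vid in range(len(gt.vertex_coords)):
        if incident[vid]:
            youngest = min(rows[ci] for ci in incident[vid])
        else:
            youngest = n_rows
        rho[vid] = rho_by_row[min(youngest, len(rho_by_row)) - 1]
    gt.per_vertex_rho = rho.tolist()

    bmask, zo1, tric, nuclei = _render_channels(spec, gt, rho)
    gt.per_vertex_expected_TL = _expected_tl(spec, gt, bmask, tric)
    zo1, tric, nuclei = _add_noise(spec, zo1, tric, nuclei)
    return gt, zo1, tric, nuclei


def generate_zstack(
    spec: TessellationSpec,
    n_slices: int,
    focus_profile: np.ndarray,
    block_size: int = 20,
    defocus_sigma: float = 2.0,
    attenuation: float = 0.7,
):
    """Build per-channel z-stacks whose in-focus slice varies per block.

    ``focus_profile`` maps each ``block_size`` block to its in-focus slice
    index.  Out-of-focus slices are Gaussian-blurred, intensity-attenuated
    copies (attenuation ``attenuation ** |dz|``), so the junctional block sum
    is strictly maximal at the in-focus slice.  With ``defocus_sigma = 0`` and
    ``attenuation = 1`` all slices are identical (tie case).
    """
    from .projection import ZStack

    if n_slices < 2:
        raise ValueError("n_slices must be >= 2")
    h, w = spec.image_size
    nbr, nbc = -(-h // block_size), -(-w // block_size)
    profile = np.asarray(focus_profile, dtype=int)
    if profile.shape != (nbr, nbc):
        raise ValueError(
            f"focus_profile shape {profile.shape} does not match the "
            f"{(nbr, nbc)} block grid of a {spec.image_size} image"
        )
    if profile.min() < 0 or profile.max() >= n_slices:
        raise ValueError("focus_profile entries must be valid slice indices")

    gt = _tessellate(spec)
    rho = np.full(len(gt.vertex_coords), spec.enrichment_ratio, dtype=float)
    gt.per_vertex_rho = rho.tolist()
    bmask, zo1, tric, nuclei = _render_channels(spec, gt, rho)
    gt.per_vertex_expected_TL = _expected_tl(spec, gt, bmask, tric)

    tags = {"zo1": "junction", "tric": "tricellular", "nuclei": "nuclear"}
    stacks = {}
    rng = np.random.default_rng(spec.rng_seed + 1)
    for name, base in (("zo1", zo1), ("tric", tric), ("nuclei", nuclei)):
        stack = np.empty((n_slices, h, w), dtype=float)
        for bi in range(nbr):
            r0, r1 = bi * block_size, min((bi + 1) * block_size, h)
            for bj in range(nbc):
                c0, c1 = bj * block_size, min((bj + 1) * block_size, w)
                block = base[r0:r1, c0:c1]
                # defocus per block (reflect boundary): attenuation then
                # strictly orders block sums, in-focus slice on top
                for s in range(n_slices):
                    dz = abs(s - int(profile[bi, bj]))
                    if dz == 0:
                        out = block
                    else:
                        out = block * (attenuation ** dz)
                        if defocus_sigma > 0:
                            out = ndimage.gaussian_filter(
                                out, defocus_sigma * dz, mode="reflect"
                            )
                    stack[s, r0:r1, c0:c1] = out
        if spec.noise_sd > 0:
            stack = stack + rng.normal(0.0, spec.noise_sd, size=stack.shape)
        stacks[name] = ZStack(voxels=np.clip(stack, 0.0, None), channel_tag=tags[name])
    return gt, stacks


def write_channels(out_dir, channels: dict, ground_truth: GroundTruth | None = None):
    """Write each channel as TIFF (stacks as multi-page) plus ground-truth JSON."""
    import os

    import tifffile

    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name, ch in channels.items():
        arr = ch.voxels if hasattr(ch, "voxels") else np.asarray(ch)
        path = os.path.join(out_dir, f"{name}.tif")
        tifffile.imwrite(path, arr.astype(np.float32))
        paths[name] = path
    if ground_truth is not None:
        gt_path = os.path.join(out_dir, "ground_truth.json")
        ground_truth.to_json(gt_path)
        paths["ground_truth"] = gt_path
    return paths
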