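"""Tricellulin localization score T_L and the downstream group analyses.

A mature tricellular tight junction concentrates tricellulin at the vertex
where three cells meet; an immature one leaves it spread along (or excluded
from) the bicellular junctions.  For every vertex, a small tricellular disk
mask and a bicellular ribbon mask along the incident edges are carved out of
the junction network, and the localization score is the normalized intensity
contrast

    T_L = I_tri / (I_tri + I_bi)

where I_tri and I_bi are the mean contrast-adjusted tricellular-marker
intensities over the two masks.  T_L is bounded in [0, 1]: 0.5 when the marker
is uniform along junctions, towards 1 under pure vertex enrichment and towards
0 under vertex exclusion.  It is invariant under any positive rescaling of the
image.  A raw-ratio variant ``min(I_tri / I_bi, 1)`` is available for
sensitivity analysis.

Group analyses: per-cell aggregation, breadth-first row assignment behind a
wound-front leader cell, row-resolved profiles, cell-cycle triplet
classification, two-sample Kolmogorov-Smirnov comparisons, and normalization
to a control group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .graph import BoundaryMap, JunctionGraph

__all__ = [
    "TLRecord",
    "CellTL",
    "GroupResult",
    "compute_masks",
    "vertex_masks",
    "score_vertex",
    "score_graph",
    "score_cells",
    "assign_rows",
    "rowwise_profile",
    "vertex_rows",
    "triplet_by_label",
    "compare_groups",
    "normalize_to_control",
]

_DISK_CACHE: dict[float, np.ndarray] = {}


def _disk_offsets(radius: float) -> np.ndarray:
    if radius not in _DISK_CACHE:
        r = int(np.ceil(radius))
        dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
        keep = dr**2 + dc**2 <= radius**2
        _DISK_CACHE[radius] = np.column_stack([dr[keep], dc[keep]])
    return _DISK_CACHE[radius]


@dataclass
class TLRecord:
    vertex_id: int
    I_tri: float
    I_bi: float
    T_L: float
    tri_area: int
    bi_area: int
    flags: set[str] = field(default_factory=set)


@dataclass
class CellTL:
    cell_id: int
    T_L_cell: float
    n_vertices_scored: int


@dataclass
class GroupResult:
    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values)) if len(self.values) else float("nan")

    @property
    def sem(self) -> float:
        if len(self.values) < 2:
            return float("nan")
        return float(stats.sem(self.values))


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def compute_masks(
    graph: JunctionGraph,
    boundary: BoundaryMap,
    r_tri: float = 4.0,
    w_bi: int = 2,
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Tricellular / bicellular mask pixel coordinates for every vertex.

    tri mask: disk of radius ``r_tri`` at the vertex's relocated coordinates,
    intersected with a ``w_bi``-dilation of the junction network; pixels inside
    several disks go to the nearest vertex.  bi mask: the vertex's incident
    edge paths dilated by ``w_bi``, intersected with the binarized junctional
    foreground, minus every tri mask.  Returns ``{vertex_id: (tri, bi)}`` with
    ``(n, 2)`` coordinate arrays; tri/bi masks of one vertex are disjoint, and
    tri masks of different vertices are disjoint.
    """
    h, w = graph.shape
    bmask = boundary.mask

    # dilated junction network from the edge pixel paths
    net = graph.rasterize()
    from skimage.morphology import dilation as binary_dilation, disk as disk_fp

    net_dil = binary_dilation(net, disk_fp(w_bi)) if w_bi > 0 else net

    vids = sorted(graph.vertices)
    centers = np.array(
        [graph.vertices[v].relocated_coords for v in vids], dtype=float
    )

    # tri ownership: nearest vertex wins contested disk pixels
    offsets = _disk_offsets(r_tri)
    owner: dict[tuple[int, int], tuple[float, int]] = {}
    for v, (cr, cc) in zip(vids, centers):
        ri, ci = int(round(cr)), int(round(cc))
        for dr, dc in offsets:
            r, c = ri + dr, ci + dc
            if not (0 <= r < h and 0 <= c < w) or not net_dil[r, c]:
                continue
            d = (r - cr) ** 2 + (c - cc) ** 2
            if d > r_tri**2:
                continue
            cur = owner.get((r, c))
            if cur is None or d < cur[0] or (d == cur[0] and v < cur[1]):
                owner[(r, c)] = (d, v)

    tri_coords: dict[int, list] = {v: [] for v in vids}
    all_tri = np.zeros((h, w), dtype=bool)
    for (r, c), (_, v) in owner.items():
        tri_coords[v].append((r, c))
        all_tri[r, c] = True

    ribbon_offsets = _disk_offsets(float(w_bi)) if w_bi > 0 else np.zeros((1, 2), int)
    masks: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for v in vids:
        vert = graph.vertices[v]
        bi_set: set[tuple[int, int]] = set()
        for eid in vert.incident_edge_ids:
            path = graph.edges[eid].pixel_path
            if len(path) == 0:
                continue
            pts = (path[:, None, :] + ribbon_offsets[None, :, :]).reshape(-1, 2)
            for r, c in pts:
                if 0 <= r < h and 0 <= c < w and bmask[r, c] and not all_tri[r, c]:
                    bi_set.add((int(r), int(c)))
        tri = np.asarray(sorted(tri_coords[v]), dtype=int).reshape(-1, 2)
        bi = np.asarray(sorted(bi_set), dtype=int).reshape(-1, 2)
        masks[v] = (tri, bi)
    return masks


def vertex_masks(
    graph: JunctionGraph,
    vertex_id: int,
    boundary: BoundaryMap,
    r_tri: float = 4.0,
    w_bi: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Masks for a single vertex (computed in the context of the whole graph)."""
    return compute_masks(graph, boundary, r_tri=r_tri, w_bi=w_bi)[vertex_id]


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def score_vertex(
    tric_adjusted: np.ndarray,
    tri: np.ndarray,
    bi: np.ndarray,
    vertex_id: int = -1,
    tl_form: str = "normalized",
) -> TLRecord:
    """Score one vertex from its masks on the adjusted tricellular image."""
    img = np.asarray(
        tric_adjusted.pixels if hasattr(tric_adjusted, "pixels") else tric_adjusted,
        dtype=float,
    )
    if len(tri) == 0 or len(bi) == 0:
        return TLRecord(
            vertex_id=vertex_id, I_tri=float("nan"), I_bi=float("nan"),
            T_L=float("nan"), tri_area=len(tri), bi_area=len(bi),
            flags={"unscorable"},
        )
    i_tri = float(img[tri[:, 0], tri[:, 1]].mean())
    i_bi = float(img[bi[:, 0], bi[:, 1]].mean())
    if tl_form == "normalized":
        tl = 0.0 if (i_tri + i_bi) == 0 else i_tri / (i_tri + i_bi)
    elif tl_form == "raw-clipped":
        tl = 1.0 if i_bi == 0 and i_tri > 0 else (
            0.0 if i_bi == 0 else min(i_tri / i_bi, 1.0)
        )
    else:
        raise ValueError(f"unknown tl_form {tl_form!r}")
    return TLRecord(
        vertex_id=vertex_id, I_tri=i_tri, I_bi=i_bi, T_L=tl,
        tri_area=len(tri), bi_area=len(bi),
    )


def score_graph(
    graph: JunctionGraph,
    tric_adjusted: np.ndarray,
    boundary: BoundaryMap,
    r_tri: float = 4.0,
    w_bi: int = 2,
    tl_form: str = "normalized",
    min_degree: int = 3,
) -> list[TLRecord]:
    """Score every vertex of degree >= ``min_degree``.

    Unscorable vertices (empty masks) are kept in the output with NaN score
    and an ``unscorable`` flag, never silently dropped.
    """
    masks = compute_masks(graph, boundary, r_tri=r_tri, w_bi=w_bi)
    out = []
    for vid in sorted(graph.vertices):
        if graph.vertices[vid].degree < min_degree:
            continue
        tri, bi = masks[vid]
        out.append(score_vertex(tric_adjusted, tri, bi, vertex_id=vid, tl_form=tl_form))
    return out


def score_cells(graph: JunctionGraph, records: list[TLRecord]) -> list[CellTL]:
    """Per-cell T_L: unweighted mean over the cell's scored incident vertices."""
    by_vertex = {r.vertex_id: r for r in records}
    cells: dict[int, list[float]] = {}
    for vid, v in graph.vertices.items():
        rec = by_vertex.get(vid)
        if rec is None or not np.isfinite(rec.T_L):
            continue
        for cid in v.incident_cell_ids:
            cells.setdefault(cid, []).append(rec.T_L)
    return [
        CellTL(cell_id=cid, T_L_cell=float(np.mean(vals)), n_vertices_scored=len(vals))
        for cid, vals in sorted(cells.items())
    ]


# ---------------------------------------------------------------------------
# wound-front rows
# ---------------------------------------------------------------------------

def assign_rows(cell_adjacency, leader_cell_id: int) -> dict[int, int]:
    """Row labels by adjacency distance from the leader cell.

    The leader is row 1, its immediate followers row 2, and so on
    (breadth-first shortest-path distance on the cell-adjacency graph).
    Unreachable cells get no assignment.
    """
    g = cell_adjacency if isinstance(cell_adjacency, nx.Graph) else nx.Graph(cell_adjacency)
    if leader_cell_id not in g:
        raise ValueError(f"leader cell {leader_cell_id} not in adjacency graph")
    dist = nx.single_source_shortest_path_length(g, leader_cell_id)
    return {cid: d + 1 for cid, d in dist.items()}


def vertex_rows(graph: JunctionGraph, rows: dict[int, int]) -> dict[int, int]:
    """Row label per vertex: the row of the youngest (lowest-row) incident cell."""
    out = {}
    for vid, v in graph.vertices.items():
        rs = [rows[c] for c in v.incident_cell_ids if c in rows]
        if rs:
            out[vid] = min(rs)
    return out


def rowwise_profile(
    rows: dict[int, int],
    cell_tl: dict[int, float],
    cell_areas: dict[int, float],
    interior_reference_row: int = 15,
) -> pd.DataFrame:
    """Mean cell area and T_L per row, with SEM and an interior reference.

    The reference line is the mean over cells at least
    ``interior_reference_row`` rows behind the leader.  SEM is NaN for
    single-cell rows.
    """
    recs = []
    for cid, row in rows.items():
        recs.append(
            {
                "cell_id": cid,
                "row": row,
                "T_L": cell_tl.get(cid, np.nan),
                "area": cell_areas.get(cid, np.nan),
            }
        )
    df = pd.DataFrame(recs)
    if df.empty:
        return df
    grouped = df.groupby("row").agg(
        n=("cell_id", "count"),
        mean_area=("area", "mean"),
        sem_area=("area", lambda x: stats.sem(x) if len(x) > 1 else np.nan),
        mean_TL=("T_L", "mean"),
        sem_TL=("T_L", lambda x: stats.sem(x) if len(x) > 1 else np.nan),
    ).reset_index()
    interior = df[df["row"] >= interior_reference_row]
    grouped.attrs["reference_TL"] = float(interior["T_L"].mean()) if len(interior) else float("nan")
    grouped.attrs["reference_area"] = float(interior["area"].mean()) if len(interior) else float("nan")
    return grouped


# ---------------------------------------------------------------------------
# cell-cycle triplets
# ---------------------------------------------------------------------------

def triplet_by_label(
    graph: JunctionGraph, cell_labels: dict[int, str]
) -> dict[int, str]:
    """Classify vertices by the cell-cycle labels of their incident cells.

    A vertex is label-homogeneous (value = the label) iff *all* incident cells
    carry the same label — for a degree-4 vertex all four must agree —
    otherwise it is ``"mixed"`` (non-synchronized).  Vertices with any
    unlabeled incident cell, or fewer than three incident cells, are excluded.
    """
    out = {}
    for vid, v in graph.vertices.items():
        cells = v.incident_cell_ids
        if len(cells) < 3 or any(c not in cell_labels for c in cells):
            continue
        labels = {cell_labels[c] for c in cells}
        out[vid] = labels.pop() if len(labels) == 1 else "mixed"
    return out


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def compare_groups(a, b) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov-Smirnov comparison of T_L samples.

    Uses the exact p-value when ``n_a * n_b <= 10**4``, the asymptotic
    approximation otherwise.
    """
    av = np.asarray(a.values if isinstance(a, GroupResult) else a, dtype=float)
    bv = np.asarray(b.values if isinstance(b, GroupResult) else b, dtype=float)
    if len(av) < 2 or len(bv) < 2:
        raise ValueError("both groups need at least 2 observations for a KS test")
    method = "exact" if len(av) * len(bv) <= 10_000 else "asymp"
    res = stats.ks_2samp(av, bv, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def normalize_to_control(
    groups: dict[str, GroupResult] | dict[str, np.ndarray],
    control_label: str,
) -> dict[str, GroupResult]:
    """Divide every group's values by the control group's mean."""
    if control_label not in groups:
        raise ValueError(f"control group {control_label!r} not found")
    ctrl = groups[control_label]
    cv = np.asarray(ctrl.values if isinstance(ctrl, GroupResult) else ctrl, float)
    if len(cv) == 0 or cv.mean() <= 0:
        raise ValueError("control group must be nonempty with a positive mean")
    scale = 1.0 / cv.mean()
    out = {}
    for label, g in groups.items():
        vals = np.asarray(g.values if isinstance(g, GroupResult) else g, float)
        out[label] = GroupResult(label=label, values=vals * scale)
    return out
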