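"""Binarization, thinning, vertex detection, graph building, edits."""

import numpy as np
import pytest

from trijunct import TessellationSpec, generate_tessellation
from trijunct import graph as jg

from conftest import interior_vertex_f1


def _y_skeleton(size=41):
    """A perfect Y: three straight arms meeting at the center."""
    m = np.zeros((size, size), bool)
    c = size // 2
    m[c, : c + 1] = True  # west arm
    for i in range(1, c):
        m[c - i, c + i] = True  # north-east arm
        m[c + i, c + i] = True  # south-east arm
    return m


def test_binarize_recall_on_noiseless_boundaries(tess25):
    gt, zo1 = tess25["gt"], tess25["zo1"]
    spec = tess25["spec"]
    fg = tess25["boundary"].mask
    truth = zo1 > spec.background_level
    recall = fg[truth].mean()
    assert recall >= 0.99


def test_binarize_empty_image_raises():
    with pytest.raises(ValueError):
        jg.binarize_junctions(np.zeros((64, 64)))


def test_binarize_noisy_network_stays_connected():
    from skimage.measure import label

    spec = TessellationSpec(
        n_cells=25, image_size=(512, 512), noise_sd=20.0, rng_seed=8
    )  # noise 10% of boundary intensity
    _, zo1, _, _ = generate_tessellation(spec)
    fg = jg.binarize_junctions(zo1).mask
    labels = label(fg, connectivity=2)
    sizes = np.bincount(labels.ravel())[1:]
    assert sizes.max() / sizes.sum() > 0.99


def test_skeleton_is_thin_and_idempotent():
    bar = np.zeros((20, 60), bool)
    bar[8:13, 5:55] = True
    sk = jg.skeletonize(jg.BoundaryMap(mask=bar))
    # no fully-foreground 2x2 block
    quad = sk.mask[:-1, :-1] & sk.mask[1:, :-1] & sk.mask[:-1, 1:] & sk.mask[1:, 1:]
    assert not quad.any()
    again = jg.skeletonize(sk)
    np.testing.assert_array_equal(sk.mask, again.mask)


def test_skeleton_preserves_euler_number(tess25):
    from skimage.measure import euler_number

    fg = tess25["boundary"].mask
    sk = tess25["skel"].mask
    assert euler_number(fg, connectivity=2) == euler_number(sk, connectivity=2)


def test_y_skeleton_yields_one_degree3_vertex():
    sk = jg.Skeleton(mask=_y_skeleton())
    verts = jg.detect_vertices(sk)
    assert len(verts) == 1
    g = jg.build_graph(sk, verts, min_branch_len=5)
    assert len(g.vertices) == 1
    (v,) = g.vertices.values()
    assert v.degree == 3


def test_straight_line_has_no_vertices():
    m = np.zeros((10, 40), bool)
    m[5, 2:38] = True
    assert jg.detect_vertices(jg.Skeleton(mask=m)) == []


def test_short_spur_is_pruned():
    m = _y_skeleton(41)
    # add a 4-px spur hanging off the west arm
    for i in range(1, 5):
        m[20 - i, 10] = True
    sk = jg.Skeleton(mask=m)
    g = jg.build_graph(sk, jg.detect_vertices(sk), min_branch_len=10)
    assert len(g.vertices) == 1
    assert next(iter(g.vertices.values())).degree == 3


def test_vertex_f1_on_synthetic_tessellation(tess25):
    assert interior_vertex_f1(tess25["gt"], tess25["graph"]) >= 0.95


def test_euler_relation_on_extracted_graph(tess25):
    assert jg.euler_residual(tess25["graph"], tess25["skel"]) == 0


def test_relocation_identity_when_puncta_at_vertex():
    img = np.full((41, 41), 10.0)
    img[18:23, 20] = 100.0
    img[20, 10:31] = 100.0
    sk_mask = np.zeros((41, 41), bool)
    sk_mask[20, 10:31] = True
    sk_mask[18:23, 20] = True
    g = jg.build_graph(jg.Skeleton(mask=sk_mask), jg.detect_vertices(jg.Skeleton(mask=sk_mask)), min_branch_len=3)
    if not g.vertices:
        pytest.skip("degenerate cross skeleton")
    img2 = img.copy()
    v = next(iter(g.vertices.values()))
    img2[v.skeleton_coords] = 500.0  # bright puncta exactly at the vertex
    jg.relocate_vertices(g, img2, search_radius=5)
    assert v.relocated_coords == tuple(map(float, v.skeleton_coords))
    assert "unrelocated" not in v.flags


def test_relocation_never_exceeds_search_radius(tess25):
    g = tess25["graph"]
    for v in g.vertices.values():
        d = np.hypot(
            v.relocated_coords[0] - v.skeleton_coords[0],
            v.relocated_coords[1] - v.skeleton_coords[1],
        )
        assert d <= 5.0 + 1e-9


def test_relocation_accuracy_against_true_vertices(tess25):
    from scipy.spatial import cKDTree

    gt, g = tess25["gt"], tess25["graph"]
    gtc = np.array([gt.vertex_coords[i] for i in gt.interior_vertex_ids()])
    h, w = g.shape
    det = np.array(
        [v.relocated_coords for v in g.vertices.values()
         if "unrelocated" not in v.flags], float
    )
    det = det[(det[:, 0] > 8) & (det[:, 0] < h - 8) & (det[:, 1] > 8) & (det[:, 1] < w - 8)]
    d, _ = cKDTree(gtc).query(det)
    assert np.mean(d) <= 1.5


def test_rho_zero_leaves_interior_vertices_unrelocated():
    spec = TessellationSpec(
        n_cells=25, image_size=(512, 512), enrichment_ratio=0.0, rng_seed=3
    )
    gt, zo1, tric, _ = generate_tessellation(spec)
    boundary = jg.binarize_junctions(zo1)
    sk = jg.skeletonize(boundary)
    g = jg.build_graph(sk, jg.detect_vertices(sk))
    jg.relocate_vertices(g, tric)
    h, w = g.shape
    interior = [
        v for v in g.vertices.values()
        if 8 <= v.skeleton_coords[0] < h - 8 and 8 <= v.skeleton_coords[1] < w - 8
    ]
    assert interior
    for v in interior:
        assert "unrelocated" in v.flags
        assert v.relocated_coords == tuple(map(float, v.skeleton_coords))


# ---- edit scripts ---------------------------------------------------------

def test_empty_edit_script_is_identity(tess25):
    import copy

    g = copy.deepcopy(tess25["graph"])
    out = jg.apply_edits(g, [])
    assert out.edit_log == []
    assert len(out.vertices) == len(tess25["graph"].vertices)
    assert len(out.edges) == len(tess25["graph"].edges)


def test_delete_vertex_drops_or_joins_edges(tess25):
    import copy

    g = copy.deepcopy(tess25["graph"])
    vid = next(v.id for v in g.vertices.values() if v.degree == 3)
    n_edges = len(g.edges)
    jg.apply_edits(g, [{"op": "delete_vertex", "id": vid}])
    assert vid not in g.vertices
    assert len(g.edges) == n_edges - 3  # three dangling edges dropped
    assert len(g.edit_log) == 1


def test_move_vertex_and_aux_point(tess25):
    import copy

    g = copy.deepcopy(tess25["graph"])
    vid = next(iter(g.vertices))
    jg.apply_edits(
        g,
        [
            {"op": "move_vertex", "id": vid, "coords": [100.0, 200.0]},
            {"op": "add_auxiliary_point", "coords": [50.0, 60.0], "cell_id": 1},
        ],
    )
    assert g.vertices[vid].relocated_coords == (100.0, 200.0)
    assert g.aux_points == [{"coords": [50.0, 60.0], "cell_id": 1}]


def test_merge_vertices_combines_incidence(tess25):
    import copy

    g = copy.deepcopy(tess25["graph"])
    e = next(e for e in g.edges.values() if None not in e.endpoint_vertex_ids)
    a, b = e.endpoint_vertex_ids
    jg.apply_edits(g, [{"op": "merge_vertices", "id_a": a, "id_b": b}])
    assert b not in g.vertices
    assert e.id not in g.edges  # the connecting edge collapsed


def test_edit_referencing_missing_id_reports_command_index(tess25):
    import copy

    g = copy.deepcopy(tess25["graph"])
    with pytest.raises(ValueError, match="command 0"):
        jg.apply_edits(g, [{"op": "move_vertex", "id": 10**9, "coords": [0, 0]}])


def test_graph_json_roundtrip(tess25):
    g = tess25["graph"]
    text = g.to_json()
    g2 = jg.JunctionGraph.from_json(text)
    assert set(g2.vertices) == set(g.vertices)
    assert set(g2.edges) == set(g.edges)
    for eid in g.edges:
        np.testing.assert_array_equal(g2.edges[eid].pixel_path, g.edges[eid].pixel_path)
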