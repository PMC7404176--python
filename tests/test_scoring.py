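"""T_L scoring, masks, rows, triplets, KS comparisons, normalization."""

import numpy as np
import pytest

from trijunct import scoring as sc
from trijunct.scoring import GroupResult


@pytest.fixture(scope="module")
def scored(tess25):
    g = tess25["graph"]
    masks = sc.compute_masks(g, tess25["boundary"])
    records = sc.score_graph(g, tess25["tric"], tess25["boundary"])
    return {"graph": g, "masks": masks, "records": records}


def test_masks_are_pairwise_disjoint(scored):
    masks = scored["masks"]
    tri_sets = {}
    for vid, (tri, bi) in masks.items():
        tri_set = set(map(tuple, tri))
        bi_set = set(map(tuple, bi))
        assert not tri_set & bi_set  # tri vs own bi
        tri_sets[vid] = tri_set
    vids = sorted(tri_sets)
    all_tri = set().union(*tri_sets.values())
    for vid, (tri, bi) in masks.items():
        assert not set(map(tuple, bi)) & all_tri  # bi excludes every tri disk
    # tri disks of different vertices are disjoint
    total = sum(len(s) for s in tri_sets.values())
    assert total == len(all_tri)


def test_tl_bounded_and_mostly_scorable(scored):
    finite = [r for r in scored["records"] if np.isfinite(r.T_L)]
    assert len(finite) >= 0.9 * len(scored["records"])
    for r in finite:
        assert 0.0 <= r.T_L <= 1.0


def test_tl_symmetric_and_boundary_cases():
    img = np.zeros((10, 10))
    tri = np.array([[1, 1], [1, 2]])
    bi = np.array([[5, 5], [5, 6]])
    img[1, 1] = img[1, 2] = 4.0
    img[5, 5] = img[5, 6] = 4.0
    assert sc.score_vertex(img, tri, bi).T_L == pytest.approx(0.5)
    img[5, 5] = img[5, 6] = 0.0
    assert sc.score_vertex(img, tri, bi).T_L == pytest.approx(1.0)
    img[1, 1] = img[1, 2] = 0.0
    assert sc.score_vertex(img, tri, bi).T_L == 0.0


def test_tl_invariant_under_intensity_scaling(scored, tess25):
    """T_L is a ratio: multiplying the image by any constant changes nothing."""
    tric = tess25["tric"]
    checked = 0
    for vid, (tri, bi) in scored["masks"].items():
        if len(tri) == 0 or len(bi) == 0:
            continue
        t1 = sc.score_vertex(tric, tri, bi).T_L
        t10 = sc.score_vertex(tric * 10.0, tri, bi).T_L
        assert t10 == pytest.approx(t1, abs=1e-12)
        checked += 1
    assert checked >= 10


def test_unscorable_vertex_reported_not_dropped():
    img = np.ones((5, 5))
    rec = sc.score_vertex(img, np.zeros((0, 2), int), np.array([[1, 1]]))
    assert "unscorable" in rec.flags
    assert np.isnan(rec.T_L)


def test_cell_score_is_mean_of_incident_vertices():
    from trijunct.graph import JunctionGraph, Vertex
    from trijunct.scoring import TLRecord

    g = JunctionGraph(vertices={}, edges={}, shape=(10, 10))
    g.vertices[0] = Vertex(0, (1, 1), (1.0, 1.0), incident_cell_ids=[7])
    g.vertices[1] = Vertex(1, (2, 2), (2.0, 2.0), incident_cell_ids=[7])
    recs = [
        TLRecord(0, 1, 1, 0.2, 4, 4),
        TLRecord(1, 1, 1, 0.4, 4, 4),
    ]
    cells = sc.score_cells(g, recs)
    assert len(cells) == 1
    assert cells[0].T_L_cell == pytest.approx(0.3)


def test_assign_rows_on_path_graph():
    adj = [(0, 1), (1, 2), (2, 3)]
    rows = sc.assign_rows(adj, 0)
    assert rows == {0: 1, 1: 2, 2: 3, 3: 4}


def test_assign_rows_leader_and_followers():
    adj = [(0, 1), (0, 2), (1, 2), (2, 3)]
    rows = sc.assign_rows(adj, 0)
    assert rows[0] == 1
    assert rows[1] == rows[2] == 2
    assert rows[3] == 3
    for a, b in adj:
        assert abs(rows[a] - rows[b]) <= 1


def test_rowwise_profile_sem_missing_for_single_cell_rows():
    rows = {1: 1, 2: 2, 3: 2}
    tl = {1: 0.1, 2: 0.4, 3: 0.6}
    areas = {1: 100.0, 2: 90.0, 3: 80.0}
    prof = sc.rowwise_profile(rows, tl, areas, interior_reference_row=2)
    r1 = prof[prof["row"] == 1].iloc[0]
    assert np.isnan(r1["sem_TL"])
    r2 = prof[prof["row"] == 2].iloc[0]
    assert r2["mean_TL"] == pytest.approx(0.5)
    assert prof.attrs["reference_TL"] == pytest.approx(0.5)


def test_triplet_classification():
    from trijunct.graph import JunctionGraph, Vertex

    g = JunctionGraph(vertices={}, edges={}, shape=(5, 5))
    g.vertices[0] = Vertex(0, (1, 1), (1, 1), incident_cell_ids=[1, 2, 3])
    g.vertices[1] = Vertex(1, (2, 2), (2, 2), incident_cell_ids=[1, 2, 4])
    g.vertices[2] = Vertex(2, (3, 3), (3, 3), incident_cell_ids=[1, 2, 3, 4])
    g.vertices[3] = Vertex(3, (4, 4), (4, 4), incident_cell_ids=[1, 2, 5])
    labels = {1: "G1", 2: "G1", 3: "G1", 4: "S-G2"}
    out = sc.triplet_by_label(g, labels)
    assert out[0] == "G1"
    assert out[1] == "mixed"
    assert out[2] == "mixed"  # degree-4: all four must agree
    assert 3 not in out  # cell 5 unlabeled -> excluded


def test_ks_statistic_matches_brute_force_ecdf():
    a = [0.1, 0.2, 0.3]
    b = [0.2, 0.3, 0.4]

    def brute_D(x, y):
        pts = sorted(set(x) | set(y))
        best = 0.0
        for t in pts:
            fx = sum(v <= t for v in x) / len(x)
            fy = sum(v <= t for v in y) / len(y)
            best = max(best, abs(fx - fy))
        return best

    D, p = sc.compare_groups(a, b)
    assert brute_D(a, b) == pytest.approx(1 / 3)
    assert D == pytest.approx(1 / 3)


def test_ks_identical_samples():
    a = [0.1, 0.5, 0.9, 0.3]
    D, p = sc.compare_groups(a, a)
    assert D == 0.0
    assert p == pytest.approx(1.0)


def test_ks_disjoint_supports():
    rng = np.random.default_rng(5)
    a = rng.uniform(0, 0.5, 100)
    b = rng.uniform(0.5, 1.0, 100)
    D, _ = sc.compare_groups(a, b)
    assert D == pytest.approx(1.0)


def test_ks_requires_two_observations():
    with pytest.raises(ValueError):
        sc.compare_groups([0.1], [0.2, 0.3])


def test_normalize_to_control():
    groups = {
        "ctrl": GroupResult("ctrl", np.array([0.2, 0.4])),
        "treated": GroupResult("treated", np.array([0.6, 0.6])),
    }
    out = sc.normalize_to_control(groups, "ctrl")
    assert out["ctrl"].mean == pytest.approx(1.0)
    assert out["treated"].mean == pytest.approx(2.0)


def test_normalization_does_not_change_ks():
    rng = np.random.default_rng(9)
    groups = {
        "ctrl": GroupResult("ctrl", rng.uniform(0.2, 0.6, 50)),
        "t": GroupResult("t", rng.uniform(0.3, 0.9, 50)),
    }
    D0, _ = sc.compare_groups(groups["ctrl"], groups["t"])
    out = sc.normalize_to_control(groups, "ctrl")
    D1, _ = sc.compare_groups(out["ctrl"], out["t"])
    assert D0 == pytest.approx(D1)


def test_zero_control_mean_raises():
    groups = {"ctrl": GroupResult("ctrl", np.zeros(3))}
    with pytest.raises(ValueError):
        sc.normalize_to_control(groups, "ctrl")
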