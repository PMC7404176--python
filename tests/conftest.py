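import numpy as np
import pytest

from trijunct import TessellationSpec, generate_tessellation
from trijunct import graph as jg


@pytest.fixture(scope="session")
def tess25():
    """Noiseless 25-cell field with enriched vertices, plus its extracted graph."""
    spec = TessellationSpec(
        n_cells=25, image_size=(512, 512), enrichment_ratio=3.0, rng_seed=1
    )
    gt, zo1, tric, nuclei = generate_tessellation(spec)
    boundary = jg.binarize_junctions(zo1)
    skel = jg.skeletonize(boundary)
    graph = jg.build_graph(skel, jg.detect_vertices(skel))
    jg.relocate_vertices(graph, tric)
    return {
        "spec": spec, "gt": gt, "zo1": zo1, "tric": tric, "nuclei": nuclei,
        "boundary": boundary, "skel": skel, "graph": graph,
    }


@pytest.fixture(scope="session")
def small_noisy():
    """Small noisy field for fast end-to-end checks."""
    spec = TessellationSpec(
        n_cells=40, image_size=(300, 300), enrichment_ratio=2.0,
        noise_sd=8.0, rng_seed=7,
    )
    gt, zo1, tric, nuclei = generate_tessellation(spec)
    return {"spec": spec, "gt": gt, "zo1": zo1, "tric": tric, "nuclei": nuclei}


def interior_vertex_f1(gt, graph, tol=3.0, margin=4):
    """F1 of relocated vertex positions against interior ground-truth vertices."""
    from scipy.spatial import cKDTree

    h, w = graph.shape
    gtc = np.array([gt.vertex_coords[i] for i in gt.interior_vertex_ids()])
    det = np.array([v.relocated_coords for v in graph.vertices.values()], float)
    det = det[
        (det[:, 0] >= margin) & (det[:, 0] < h - margin)
        & (det[:, 1] >= margin) & (det[:, 1] < w - margin)
    ]
    if len(det) == 0 or len(gtc) == 0:
        return 0.0
    d, _ = cKDTree(det).query(gtc)
    recall = float((d <= tol).mean())
    d2, _ = cKDTree(gtc).query(det)
    precision = float((d2 <= tol).mean())
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)
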