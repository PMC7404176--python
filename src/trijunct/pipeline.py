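"""End-to-end orchestration: project, segment, edit, measure, score, report.

A run is driven by a :class:`RunConfig` holding either channel file paths or a
simulation spec plus every stage parameter.  The config is serialized verbatim
into the output directory together with per-stage counts, so any run is
reproducible from its output bundle alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geometry, graph as jgraph, projection, scoring, synthetic

logger = logging.getLogger("trijunct")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "render_maps"]


@dataclass
class RunConfig:
    # inputs: either file paths ...
    zo1_path: str | None = None
    tric_path: str | None = None
    nuclei_path: str | None = None
    # ... or a simulation spec
    simulate: synthetic.TessellationSpec | None = None
    edits_path: str | None = None
    # stage parameters
    block_size: int = 20
    max_projection_junction: bool = False
    binarize_sensitivity: float = 1.0
    min_object_area: int = 64
    min_branch_len: float = 10.0
    search_radius: float = 5.0
    r_tri: float = 4.0
    w_bi: int = 2
    tl_form: str = "normalized"
    pixel_size: float = 0.5
    rng_seed: int = 0
    leader_cell: int | None = None
    write_map: bool = True
    out_dir: str = "trijunct_out"

    def to_json(self) -> str:
        doc = dataclasses.asdict(self)
        return json.dumps(doc, indent=1, sort_keys=True, default=str)


@dataclass
class PipelineResult:
    graph: jgraph.JunctionGraph
    cells: list
    vertex_records: list
    cell_tl: list
    summary: geometry.MonolayerSummary | None
    log: dict = field(default_factory=dict)


def _load_channel(path: str) -> np.ndarray:
    import tifffile

    return np.asarray(tifffile.imread(path), dtype=float)


def _as_image(arr: np.ndarray, guide: np.ndarray | None, cfg: RunConfig, tag: str):
    """Project a stack with the guide, or pass a 2D image through."""
    if arr.ndim == 2:
        return projection.ProjectedImage(pixels=arr)
    stack = projection.ZStack(voxels=arr, channel_tag=tag)
    if guide is None:
        guide_stack = stack
    else:
        guide_stack = projection.ZStack(voxels=guide, channel_tag="junction")
    if tag == "junction" and cfg.max_projection_junction:
        return projection.ProjectedImage(pixels=arr.max(axis=0))
    return projection.guided_block_projection(guide_stack, stack, cfg.block_size)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full pipeline and write the output bundle.

    Stages: load/simulate -> guided projection -> noise estimation and
    contrast adjustment -> binarize/skeletonize/vertex detection/graph ->
    optional edit script -> cell segmentation and shape descriptors -> vertex
    relocation and T_L scoring -> CSV/JSON/log outputs.  Missing tricellular
    channel degrades to geometry-only mode with an explicit notice.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    log: dict = {"stages": {}}

    stage = "input"
    try:
        if config.simulate is not None:
            gt, zo1, tric, nuclei = synthetic.generate_tessellation(config.simulate)
            zo1_img = projection.ProjectedImage(pixels=zo1)
            tric_img = projection.ProjectedImage(pixels=tric)
            nuc_img = projection.ProjectedImage(pixels=nuclei)
            log["stages"]["input"] = {"mode": "simulate", "gt_cells": gt.n_cells}
        else:
            if config.zo1_path is None:
                raise ValueError("either a junction channel path or a simulation spec is required")
            zo1_raw = _load_channel(config.zo1_path)
            guide = zo1_raw if zo1_raw.ndim == 3 else None
            zo1_img = _as_image(zo1_raw, None, config, "junction")
            tric_img = None
            if config.tric_path is not None:
                tric_img = _as_image(_load_channel(config.tric_path), guide, config, "tricellular")
            nuc_img = None
            if config.nuclei_path is not None:
                nuc_img = _as_image(_load_channel(config.nuclei_path), guide, config, "nuclear")
            log["stages"]["input"] = {"mode": "files"}

        stage = "contrast"
        tric_adj = None
        if tric_img is not None:
            if nuc_img is not None:
                nmask = projection.nuclear_mask(nuc_img)
                model = projection.estimate_noise(tric_img, nmask)
                tric_adj = projection.adjust_contrast(tric_img, model)
                log["stages"]["contrast"] = {
                    "noise": model.noise, "max_intensity": model.max_intensity,
                    "snr": model.snr,
                }
            else:
                tric_adj = tric_img
                log["stages"]["contrast"] = {"note": "no nuclei channel; adjustment skipped"}
        else:
            logger.warning("no tricellular channel: geometry-only mode, T_L not computed")
            log["stages"]["contrast"] = {"note": "geometry-only mode (no tricellular channel)"}

        stage = "segment"
        boundary = jgraph.binarize_junctions(
            zo1_img.pixels,
            sensitivity=config.binarize_sensitivity,
            min_object_area=config.min_object_area,
        )
        skel = jgraph.skeletonize(boundary)
        vertices = jgraph.detect_vertices(skel)
        g = jgraph.build_graph(skel, vertices, min_branch_len=config.min_branch_len)
        log["stages"]["segment"] = {"vertices": len(g.vertices), "edges": len(g.edges)}

        stage = "edits"
        if config.edits_path:
            with open(config.edits_path) as fh:
                edits = json.load(fh)
            jgraph.apply_edits(g, edits)
            log["stages"]["edits"] = {"applied": len(g.edit_log)}

        stage = "geometry"
        cells = geometry.segment_cells(skel)
        geometry.link_cells(g, cells)
        for cell in cells:
            geometry.polygonize(cell, g)
            geometry.shape_index(cell)
            geometry.aspect_ratio(cell)
        summary = geometry.summarize(cells, config.pixel_size, g.shape)
        log["stages"]["geometry"] = {
            "cells": len(cells),
            "interior_cells": sum(1 for c in cells if not c.border_flag),
            "sigma_cells_per_mm2": summary.sigma,
            "mean_q_a": summary.mean_q_a,
        }

        stage = "score"
        vertex_records: list = []
        cell_tl: list = []
        if tric_adj is not None:
            jgraph.relocate_vertices(g, tric_adj.pixels, search_radius=config.search_radius)
            vertex_records = scoring.score_graph(
                g, tric_adj.pixels, boundary,
                r_tri=config.r_tri, w_bi=config.w_bi, tl_form=config.tl_form,
            )
            cell_tl = scoring.score_cells(g, vertex_records)
            n_unscorable = sum(1 for r in vertex_records if "unscorable" in r.flags)
            log["stages"]["score"] = {
                "scored": len(vertex_records) - n_unscorable,
                "unscorable": n_unscorable,
            }

        stage = "write"
        _write_outputs(config, g, cells, vertex_records, cell_tl, summary, log)
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed at stage {stage!r}: {exc}; check the stage inputs "
            "and the parameters in the run config"
        ) from exc
    return PipelineResult(
        graph=g, cells=cells, vertex_records=vertex_records,
        cell_tl=cell_tl, summary=summary, log=log,
    )


def _write_outputs(config, g, cells, vertex_records, cell_tl, summary, log) -> None:
    out = config.out_dir
    with open(os.path.join(out, "config.json"), "w") as fh:
        fh.write(config.to_json())
    g.to_json(os.path.join(out, "graph.json"), parameters={"seed": config.rng_seed})

    cell_rows = []
    tl_by_cell = {c.cell_id: c for c in cell_tl}
    for c in sorted(cells, key=lambda c: c.id):
        rec = tl_by_cell.get(c.id)
        cell_rows.append(
            {
                "cell_id": c.id,
                "centroid_row": round(c.centroid[0], 3),
                "centroid_col": round(c.centroid[1], 3),
                "area_um2": round(c.area_um2(config.pixel_size), 4),
                "perimeter_um": round(c.perimeter_um(config.pixel_size), 4),
                "q_a": round(c.q_a, 6) if np.isfinite(c.q_a) else "",
                "AR": round(c.AR, 6) if np.isfinite(c.AR) else "",
                "T_L_cell": round(rec.T_L_cell, 6) if rec else "",
                "border_flag": int(c.border_flag),
                "polygon_vertex_ids": ";".join(str(v) for v in c.polygon),
            }
        )
    pd.DataFrame(cell_rows).to_csv(os.path.join(out, "cells.csv"), index=False)

    vrows = []
    for r in sorted(vertex_records, key=lambda r: r.vertex_id):
        v = g.vertices.get(r.vertex_id)
        vrows.append(
            {
                "vertex_id": r.vertex_id,
                "row": round(v.relocated_coords[0], 2) if v else "",
                "col": round(v.relocated_coords[1], 2) if v else "",
                "I_tri": round(r.I_tri, 6) if np.isfinite(r.I_tri) else "",
                "I_bi": round(r.I_bi, 6) if np.isfinite(r.I_bi) else "",
                "T_L": round(r.T_L, 6) if np.isfinite(r.T_L) else "",
                "flags": ";".join(sorted(r.flags)),
            }
        )
    pd.DataFrame(vrows).to_csv(os.path.join(out, "vertices.csv"), index=False)

    if config.write_map and cell_tl:
        values = {c.cell_id: c.T_L_cell for c in cell_tl}
        try:
            render_maps(
                cells, values, os.path.join(out, "tl_map.png"),
                image_shape=g.shape, vmin=0.0, vmax=1.0, label="T_L",
            )
        except Exception as exc:  # map rendering must never sink a run
            logger.warning("map rendering failed: %s", exc)

    if summary is not None:
        log["summary"] = dataclasses.asdict(summary)
    with open(os.path.join(out, "run_log.json"), "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True)


def render_maps(
    cells,
    values: dict[int, float],
    path: str,
    image_shape: tuple[int, int] | None = None,
    cmap: str = "viridis",
    vmin: float | None = None,
    vmax: float | None = None,
    label: str = "value",
):
    """Render cells as filled polygons colored by a per-cell value.

    Cells without a value (or without a polygon) are hatched grey.  The figure
    extent equals the image extent so maps overlay the source channels.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Polygon as MplPolygon

    if image_shape is None:
        image_shape = (
            int(max(c.pixel_coords[:, 0].max() for c in cells)) + 1,
            int(max(c.pixel_coords[:, 1].max() for c in cells)) + 1,
        )
    finite = [v for v in values.values() if v is not None and np.isfinite(v)]
    lo = vmin if vmin is not None else (min(finite) if finite else 0.0)
    hi = vmax if vmax is not None else (max(finite) if finite else 1.0)
    norm = matplotlib.colors.Normalize(vmin=lo, vmax=hi)
    cm = matplotlib.colormaps[cmap]

    fig, ax = plt.subplots(figsize=(6, 6 * image_shape[0] / image_shape[1]))
    for c in cells:
        if c.polygon_coords is None or len(c.polygon_coords) < 3:
            continue
        xy = np.column_stack([c.polygon_coords[:, 1], c.polygon_coords[:, 0]])
        v = values.get(c.id)
        if v is not None and np.isfinite(v):
            ax.add_patch(MplPolygon(xy, closed=True, facecolor=cm(norm(v)), edgecolor="k", lw=0.4))
        else:
            ax.add_patch(
                MplPolygon(xy, closed=True, facecolor="0.85", edgecolor="k", lw=0.4, hatch="///")
            )
    ax.set_xlim(0, image_shape[1])
    ax.set_ylim(image_shape[0], 0)
    ax.set_aspect("equal")
    ax.set_xticks([])
    ax.set_yticks([])
    sm = matplotlib.cm.ScalarMappable(norm=norm, cmap=cm)
    fig.colorbar(sm, ax=ax, label=label, shrink=0.8)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path
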