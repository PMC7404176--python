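"""Render a synthetic epithelial monolayer with known ground truth.

Generates the three fluorescence-like channels (junctional ZO-1-like lines,
tricellular marker with vertex punctae, nuclei) and prints what the generator
knows to be true about the field, which downstream stages are tested against.
"""

import numpy as np

from trijunct import TessellationSpec, generate_tessellation
from trijunct.synthetic import write_channels

spec = TessellationSpec(
    n_cells=25,
    image_size=(512, 512),
    enrichment_ratio=3.0,  # vertex puncta peak = 3x the boundary-line intensity
    noise_sd=8.0,
    rng_seed=1,
)
gt, zo1, tric, nuclei = generate_tessellation(spec)
paths = write_channels(
    "scratch/example_sim", {"zo1": zo1, "tric": tric, "nuclei": nuclei}, gt
)

interior = gt.interior_vertex_ids()
oracle = np.array([gt.per_vertex_expected_TL[i] for i in interior])
print(f"cells: {gt.n_cells}, vertices: {len(gt.vertex_coords)} "
      f"({len(interior)} interior tricellular)")
print(f"expected T_L at interior vertices (median): {np.nanmedian(oracle):.3f}")
print("  -> with 3x vertex enrichment the localization score sits above 0.5,")
print("     i.e. the tricellular mask is brighter than the bicellular ribbons")
print("channels written to:", ", ".join(sorted(paths.values())))
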