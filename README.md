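# trijunct

Spatially resolved quantification of **tricellular tight-junction (tTJ)
maturity** in epithelial monolayers, from multichannel fluorescence images to
per-vertex and per-cell scores.

## The problem

In a confluent epithelium, bicellular tight junctions (outlined by ZO-1) form
a polygonal network whose nodes — the vertices where three cells meet — host a
specialized complex, the tricellular tight junction. Tricellulin (MARVELD2)
concentrates at mature tTJs and is excluded from them in immature or actively
remodeling tissue (e.g. leader cells at a healing wound). The degree of this
concentration is a readout of junctional maturity that complements the
classical jamming descriptors of cell shape.

`trijunct` implements the full analysis:

1. **Projection** — for z-stacks, the junctional channel selects the
   best-focus slice per 20×20-pixel block and the tricellular channel is
   composed from the same slices; background is estimated from the nuclear
   mask (tricellulin is absent from nuclei) and the image adjusted as
   `(I − noise) / SNR` with `SNR = max / (2·noise)`.
2. **Junction graph** — the junctional channel is binarized, thinned to a
   single-pixel skeleton, vertices are found by counting skeleton neighbors
   (≥3), bicellular edges are traced between them, and each vertex is
   relocated onto the nearest tricellular point source. Manual corrections are
   replayed from declarative JSON edit scripts.
3. **Cell geometry** — cells are the connected components of the skeleton's
   complement; each gets a vertex polygon, the apical shape index
   `q_a = p_a / √A_a`, the aspect ratio AR of its moment ellipse, and the
   monolayer gets `q̄_a`, `ĀR`, SD(AR) and the density σ (cells mm⁻²).
4. **Maturity score** — per vertex, a small tricellular disk mask and
   bicellular ribbon masks along the incident edges are carved from the
   junction network, and

   ```
   T_L = I_tri / (I_tri + I_bi)      ∈ [0, 1]
   ```

   where `I_tri`, `I_bi` are mean adjusted tricellular-marker intensities over
   the two masks: 0.5 for a uniform marker, → 1 under vertex enrichment,
   → 0 under exclusion. Group analyses cover wound-front rows (adjacency
   distance from a leader cell), cell-cycle triplets, two-sample two-sided
   Kolmogorov–Smirnov comparisons, and normalization to a control group.

A first-class synthetic-epithelium generator (centroidal-relaxed Voronoi
tessellations rendered as fluorescence-like channels with controllable vertex
enrichment, noise, and per-block defocus) provides exact ground truth for
every stage.

## Worked example

```sh
python examples/03_segment_and_score.py
```

prints (exactly reproducible, seed 7):

```
cells segmented: 51 (40 interior)
monolayer: density sigma = 1790 cells/mm^2, mean q_a = 4.100, mean AR = 1.368 (SD 0.252)
  -> q_a near 3.8-4.1 with low SD(AR) is the jammed, solid-like regime
vertices scored: 74, median T_L = 0.508
  -> T_L > 0.5 means tricellulin is concentrated at vertices (mature tTJs)
per-cell T_L map written to: scratch/example_run/tl_map.png
```

The other examples cover simulation (`01`), guided z-projection and contrast
adjustment (`02`), wound-front row profiles (`04`), and condition comparisons
with KS tests and control normalization (`05`). A thin CLI wraps the same
library calls:

```sh
trijunct simulate --n-cells 25 --size 512 --rho 3 --seed 1 --out sim/
trijunct run --zo1 sim/zo1.tif --tric sim/tric.tif --nuclei sim/nuclei.tif --out out/
```

Every run writes its config, the serialized junction graph, per-cell and
per-vertex CSVs, and a stage log sufficient to reproduce it.

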