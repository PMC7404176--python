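"""Wound-front analysis: T_L versus adjacency distance from the leader cell.

A healing wound destabilizes into migration fingers led by a mesenchymal-like
leader cell whose tricellular junctions are immature.  Cells are ranked by
breadth-first adjacency distance behind the leader (leader = row 1) and vertex
scores are grouped by the youngest incident row.
"""

import numpy as np

from trijunct import scoring as sc
from trijunct.evaluation import wound_row_tl

tl_by_row, violations = wound_row_tl(
    rho_by_row=(0.5, 2.0, 2.0, 2.0, 2.0), n_seeds=4, seed=0
)
print(f"row adjacency violations (must be 0): {violations}")
for row in sorted(tl_by_row)[:6]:
    vals = tl_by_row[row]
    print(f"row {row}: n={len(vals):3d}  mean T_L = {np.mean(vals):.3f}")
D, p = sc.compare_groups(tl_by_row[1], tl_by_row[2])
print(f"KS row 1 vs row 2: D = {D:.3f}, p = {p:.2e}")
print("  -> the leader row scores well below its followers: tricellular")
print("     junctions are disassembled where migration is active")
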