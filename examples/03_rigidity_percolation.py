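"""Tension-network percolation and the wrapping criterion.

Marks junctions of a random periodic Voronoi tiling as rigid with
increasing probability and reports when the rigid sub-network wraps the
periodic box in both directions, then calibrates the wrapping threshold
f_c over a few tilings (literature value for Voronoi graphs: ~0.66).
"""

import numpy as np

import vertexclosure as vc

box = vc.Box(12.0, 12.0)
state = vc.build_voronoi_tissue(144, box, seed=3)
m = state.n_junctions
rng = np.random.default_rng(0)
marks = rng.uniform(size=m)
for f in (0.4, 0.6, 0.7, 0.9):
    wx, wy = vc.wrapping_percolation(state, marks < f)
    print(f"f = {f:.1f}: wraps_x={wx!s:5}  wraps_y={wy!s:5}")

est = vc.calibrate_fc_voronoi(n_cells=144, n_trials=25, seed=7)
print(f"\ncalibrated threshold f_c = {est.mean:.3f} +/- {est.stderr:.3f} "
      f"({est.n_trials} tilings)")
print("A tissue is classified solid when its tension-bearing junctions "
      "wrap in both periodic directions (fraction above ~f_c).")
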