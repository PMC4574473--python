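"""Decompose the shear of a synthetic tracked tissue into cellular parts.

Builds a ~550-cell hexagonal tissue sheared along the PD axis with one T1
exchange, one division and one extrusion, runs the triangle-method
decomposition and compares each cumulative contribution with the
generator's ground-truth budget.
"""

import numpy as np

from epishear import SynthScript, generate, run_decomposition

probe = SynthScript(rows=12, cols=12, n_frames=2, seed=2)
tissue0, _ = generate(probe)
grid = {v: k for k, v in tissue0.grid.items()}          # (row, col) -> cell id
center = grid[(6, 6)]
neighbor = tissue0.frames[0].neighbors[center][0]

script = SynthScript(
    rows=12, cols=12, disorder=0.05, n_frames=16, shear_xx=0.1, seed=2,
    events=[
        ("t1", 6, center, neighbor),
        ("division", 8, grid[(4, 4)], 0.3),
        ("extrusion", 10, grid[(8, 8)]),
    ],
)
tissue, budget = generate(script)
series = run_decomposition(tissue, roi="bulk", detect=False)

print("cumulative PD shear (xx component), pipeline vs scripted budget:")
for term, bud in [
    ("total", budget.total), ("cell_shape", budget.cell_shape),
    ("t1", budget.t1), ("division", budget.division),
    ("extrusion", budget.extrusion),
]:
    print(f"  {term:<11s} {series.final(term):+0.5f}   budget {bud[0]:+0.5f}")
print(f"closure residual (max |total - sum of parts|): "
      f"{series.max_abs_residual:.2e} /h")
print("Positive values are elongation along the PD (x) axis; the residual "
      "shows the decomposition is exact up to round-off.")
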