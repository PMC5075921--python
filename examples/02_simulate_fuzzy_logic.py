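"""Simulate the bundled toy9 network in fuzzy and Boolean modes.

toy9 carries a negative feedback loop (c -> h -> j -| c), so the Boolean
dynamics oscillate instead of settling; the fuzzy steady-state search
reports this honestly through its convergence flag.
"""

import numpy as np

import fuzzysig as fs

model = fs.toy9()
print(f"toy9: {model.m} nodes, {int(model.B.sum())} edges,"
      f" stimulated = {model.stimulated}")

state, converged, iters = fs.simulate_steady_state(model, {"a": 1.0, "b": 1.0})
print(f"fuzzy steady-state search: converged={converged} after {iters} iterations")
print("  last state:", np.round(state, 3))
# converged=False is expected: the feedback loop keeps c/h/j cycling.

traj = fs.simulate_timeseries(model, np.zeros(model.m), {"a": 1.0, "b": 1.0},
                              n_points=8, config=fs.SimulationConfig(mode="boolean"))
print("Boolean trajectory of the loop nodes (c, h, j):")
for t, row in enumerate(traj):
    c, h, j = (row[model.index(n)] for n in "chj")
    print(f"  t={t}: c={c:.0f} h={h:.0f} j={j:.0f}")
# The 0/1 pattern travels around the loop with period 6.
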