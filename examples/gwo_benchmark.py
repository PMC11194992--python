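"""Run the grey wolf optimizer on a benchmark objective.

Twenty wolves minimize the 2-D sphere function over [-5, 5]^2 for 50
iterations.  The printed trace is the best fitness ever evaluated: it can
only decrease, and should fall many orders of magnitude below the random
initialization, showing the encircle-and-hunt dynamics converging onto the
optimum at the origin.
"""

import numpy as np

from wolfscan.gwo import GWOConfig, SearchSpace, optimize, sphere

space = SearchSpace(lower=-5 * np.ones(2), upper=5 * np.ones(2))
result = optimize(sphere, space, GWOConfig(n_wolves=20, n_iterations=50, seed=1))

for h in result.history[::10]:
    print(f"iteration {h['iteration']:3d}: best fitness {h['best_fitness']:.3e}")
print(f"\nbest position {np.round(result.best_position, 6).tolist()}")
print(f"best fitness  {result.best_fitness:.3e}")
print("(the sphere's true optimum is 0 at the origin; a final fitness this")
print(" small means the pack collapsed onto it)")
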