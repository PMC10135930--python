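"""Run the Marine Predator Algorithm on benchmark objectives.

The optimizer moves a prey population through Brownian exploration,
a mixed Lévy/Brownian transition and CF-damped Lévy exploitation,
with elitist memory and FADs long jumps.  The trace of best fitness
per iteration is non-increasing by construction.
"""

import numpy as np

from ecgmpa import MPAParams, SearchSpace, optimize
from ecgmpa.mpa import rastrigin, sphere

space = SearchSpace(lower=[-10.0] * 5, upper=[10.0] * 5)

for name, objective in (("sphere", sphere), ("rastrigin", rastrigin)):
    result = optimize(objective, space, MPAParams(n=25, tmax=100, seed=0))
    print(f"{name}: best fitness {result.best_fitness:.3e} "
          f"after {result.evaluations} evaluations")
    print(f"  best position: {np.round(result.best_position, 4)}")
    print(f"  trace monotone: {bool(np.all(np.diff(result.trace) <= 0))}")
    print(f"  fitness after 10/50/100 iterations: "
          f"{result.trace[9]:.2e} / {result.trace[49]:.2e} / {result.trace[99]:.2e}")
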