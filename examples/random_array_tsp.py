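"""Approximate travelling-salesman performance on random flower arrays.

For 10 flowers scattered uniformly in a 25 m square the model bee's best
route after one day is compared against the exact optimum (Held-Karp) and
against the greedy nearest-neighbour tour.
"""

import numpy as np

from traplinesim import ModelParams, nearest_neighbour_circuit, optimal_circuit, random_uniform
from traplinesim.experiments import tsp_ratio_experiment

params = ModelParams(enhancement_factor=2.0, n_bouts=65)
res = tsp_ratio_experiment(10, n_arrangements=10, n_bees=10, params=params, seed=42)

nn = []
for ss in np.random.SeedSequence(42).spawn(10):
    arr = random_uniform(10, 25.0, rng_seed=ss)
    nn.append(nearest_neighbour_circuit(arr).length / optimal_circuit(arr).length)

print(f"cohort mean L/L_min (best route, 65 bouts): {res['mean_ratio']:.3f}")
print(f"bees finding the exact optimum            : {res['fraction_optimal']:.2%}")
print(f"bees within 10% of the optimum            : {res['fraction_within_10pct']:.2%}")
print(f"greedy nearest-neighbour mean L/L_min     : {np.mean(nn):.3f}")

# The learned traplines land within ~25-30% of the exact optimum on
# average at N = 10; the greedy tour's excess on the same arrays is the
# classical reference against which that performance is judged.
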