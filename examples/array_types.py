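"""Why some flower arrangements never yield stable optimal traplines.

Compares three 10-flower flight-cage geometries in which proximity and
flight directionality are positively, independently or negatively linked.
Because initial transition probabilities fall with squared distance, an
arrangement whose short transitions chain into the optimal circuit is
easy to optimise; one whose short transitions cut across it is not.
"""

from traplinesim import ModelParams, run_cohort, small_cage_array

for factor in (1.1, 1.5):
    print(f"enhancement factor {factor}:")
    for kind in ("positive", "independent", "negative"):
        array = small_cage_array(kind)
        cohort = run_cohort(
            array, ModelParams(enhancement_factor=factor, n_bouts=65, rng_seed=1), 200
        )
        print(
            f"  {kind:11s} ever-optimal {cohort.fraction_optimal_by(65):5.2f}   "
            f"stable {cohort.fraction_stable_by(65):5.2f}"
        )

# The ordering positive > independent > negative, with the negative array
# pinned at zero, reproduces the qualitative finding that stable optimal
# traplines cannot be established in every spatial configuration.  The
# geometries are synthetic stand-ins for the published cage layouts.
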