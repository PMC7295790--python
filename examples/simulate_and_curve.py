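"""Generate a synthetic screen and compare greedy vs random accumulation.

The species-accumulation curve shows how fast cumulative richness grows
as conditions are added: the greedy order (by marginal gain) against the
mean over random condition orders.
"""

from culturopt import SyntheticParams, accumulation_curve, generate

matrix, conditions, species = generate(SyntheticParams(n_species=150, n_conditions=20, seed=4))
print(matrix)

curve = accumulation_curve(matrix, n_permutations=200, seed=4)
print(curve.to_string(index=False,
                      formatters={"random_mean": "{:.1f}".format}))

# The greedy curve dominates the random-order mean at every rank: an
# optimized condition order reaches near-total richness with far fewer
# conditions than an arbitrary one.
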