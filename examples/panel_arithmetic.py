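"""Cumulative coverage arithmetic on a published marginal-gain column.

Feeds the 16-condition panel's "species added and not previously
isolated" column through the cumulative-coverage report: the running sum
reaches 487 species, i.e. 98% of the 497 isolated by the full screen.
"""

from culturopt import cumulative_coverage

gains = [306, 64, 29, 21, 17, 13, 8, 5, 5, 4, 4, 3, 3, 2, 2, 1]
table = cumulative_coverage(gains, total_species=497)
print(table.to_string(index=False))
print(f"\nfinal: {table['cumulative_covered'].iloc[-1]} species "
      f"({table['cumulative_percent'].iloc[-1]}% of 497)")

# The 16 best conditions jointly recover 487 of 497 species: dropping the
# other 42 conditions loses only 2% of the captured diversity.
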