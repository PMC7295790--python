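"""16S identity novelty calls.

An isolate whose 16S identity to its nearest named species falls below
98.65% is a candidate new species; below 95%, a candidate new genus.
"""

from culturopt import classify_identity, tally_novelty

identities = [99.8, 98.7, 98.64, 97.2, 95.0, 94.99, 91.3]
calls = [classify_identity(x) for x in identities]
for c in calls:
    print(f"  {c.percent_identity:6.2f}%  ->  {c.call}")
print("tally:", tally_novelty(calls))

# Equality falls in the higher (less novel) class: 95.0% is still a new
# species, not a new genus; 98.65% is a known species.
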