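"""Partition species among three condition groups (Venn regions).

The synthetic screen tags its 58 conditions with three disjoint panel
groups (18 standard / 18 new / 22 alcohol-pretreated).  The partition
counts species in every overlap region and what each group adds over a
baseline.
"""

from culturopt import added_and_specific, partition, study_shaped_fixture

matrix, conditions, species = study_shaped_fixture(seed=1)
groups = ["18_standard", "18_new", "22_alcohol"]

part = partition(matrix, groups)
print(f"union: {part.union_size} species; "
      f"shared by all three groups: {part.common} ({part.percent_common}%)")
for g in groups:
    print(f"  {g:12s} isolates {part.group_total(g)} species")
print("Venn regions (signature = membership in", "/".join(groups), "):")
for sig, count in sorted(part.region_counts.items()):
    print(f"  {sig}: {count}")

added, specific = added_and_specific(matrix, baseline="18_standard", other="18_new")
print(f"\nthe 18 new conditions add {added} species over the standard 18, "
      f"{specific} of which no other group isolates")

# Region counts always sum to the union; 'added' counts species absent
# from the baseline, 'specific' those absent from every other group too.
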