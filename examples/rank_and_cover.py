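"""Rank culture conditions by richness and reduce them to a minimal panel.

Builds a study-shaped synthetic screen (497 species × 58 conditions),
ranks the conditions by how many species each isolated, then greedily
selects the smallest panel keeping 98% of the captured diversity.
"""

from culturopt import greedy_cover, panel_report, rank_by_richness, study_shaped_fixture

matrix, conditions, species = study_shaped_fixture(seed=1)

print("Top 5 conditions by species richness:")
for cond, richness in rank_by_richness(matrix, top_k=5):
    print(f"  {cond:8s} {richness:4d} species")

cover = greedy_cover(matrix, target_fraction=0.98)
report = panel_report(cover, matrix)
print(f"\n98% panel: {len(cover)} of {matrix.n_conditions} conditions "
      f"keep {cover.covered}/{matrix.n_species} species")
print(report[["condition", "marginal_gain", "richness",
              "cumulative_covered", "cumulative_percent"]].head(8).to_string(index=False))

# Each row is one greedy pick: marginal_gain counts the species that no
# earlier pick isolated; the cumulative percent shows how fast a handful
# of conditions recovers almost everything the full screen found.
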