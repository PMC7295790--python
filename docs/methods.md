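# Methods

## The optimization problem

A culturomics screen applies many culture conditions to the same
specimens and records, per condition, which species were isolated. The
analysis substrate is the binary incidence matrix `M ∈ {0,1}^{S×C}`
(`S` species, `C` conditions). Two structural rules are enforced at
construction: a species row must contain at least one 1 (species exist in
the data only because some condition grew them), while an all-zero
condition column is legal (conditions are designed a priori and may grow
nothing). Duplicate detection records collapse to a single 1. Species
identity is exact string match after normalization (strip, case-fold,
collapse internal whitespace); no synonym resolution is attempted.

Panel reduction is maximum coverage over the condition sets
`A_j = {i : M_ij = 1}`. The greedy rule selects, at each step, the
condition maximizing the marginal gain `|A_j \ covered|` until the
covered fraction reaches a target `t ∈ (0,1]`. Ties are broken
deterministically: larger standalone richness `|A_j|` first, then
ascending condition id. The first pick may be forced (`seed_condition`)
to reproduce an analysis framed around a pre-declared best condition;
when that condition is also the globally richest — the usual case — the
seeded and unseeded runs are identical, which the tests assert.
`force_include` appends named conditions after the target is met,
recorded with their actual (possibly zero) marginal gain: this models the
manual addition of a condition valued for reasons outside the coverage
criterion, without letting it perturb the greedy order.

Because coverage is submodular, greedy marginal gains are non-increasing
and the k-step greedy coverage is ≥ (1 − 1/e) of the best k-condition
coverage. Both properties are asserted in the test-suite — the second
against `best_k_coverage`, an exhaustive oracle. `exact_min_cover`
enumerates subsets by increasing size (bitmask unions, lexicographic
witness) and refuses instances above 20 conditions (2^20 subsets is the
desk-scale limit); on every random instance tested the greedy panel is
never smaller than the optimum, as theory requires.

Percentages in panel reports are rounded half-up to integers, so a
cumulative coverage of 487/497 = 97.99…% prints as 98%.

## Partitions and contrasts

Condition groups are single tags on conditions (a condition carries at
most one tag, so groups are disjoint *as condition sets*). For 2–3 groups
the species Venn regions are computed by direct set algebra over the
group species-unions; region counts always sum to the union and each
group's total is recoverable by summing the regions containing it
(tested). `added_and_specific(baseline, other)` is
`|other \ baseline|` and `|other \ (baseline ∪ rest)|`, with `rest`
defaulting to all remaining tagged groups. Catalogue comparison
(`compare_to_catalogue`) is exact-match on normalized names against a
plain-text reference list; the list is user-supplied, never bundled.

The paired supplement contrast takes two equal-length, disjoint condition
arms (the same media with and without a supplement), computes per-arm
union richness, arm-specific and shared species counts, and tests the
arm-specific proportions with a Pearson chi-square on
`[[specific_a, shared], [specific_b, shared]]`. The statistic is the
classical cellwise `Σ (O − E)²/E` with margins-based expectations;
`p = erfc(√(χ²/2))` is the exact df-1 upper tail. The continuity
correction is off by default (flag available): with tables of this size
the conclusion is insensitive to it, and no correction matches the plain
Pearson formula. If both arms recover identical species sets the table
would have a zero column margin; that case short-circuits to χ² = 0,
p = 1 rather than an error, since "no arm-specific species" is a valid
null outcome. The implementation is checked against an independent
reference (`scipy.stats.chi2_contingency`) to 1e-9 relative on random
tables.

The atmosphere crosstab assigns each species to exactly one recovery
class — anaerobic-only, aerobic-only, or both — from the union of its
detections over same-atmosphere conditions, cross-tabulated against the
oxygen phenotype. Species without a phenotype are counted under
`unknown`, never dropped. The two-way phenotype split (strict anaerobe vs
oxygen tolerant) aggregates facultative and aerotolerant organisms into
the tolerant class.

## 16S novelty thresholds

Identity to the nearest named species classifies an isolate:
`< 95%` new genus, `95% ≤ x < 98.65%` new species, `≥ 98.65%` known
species. Both thresholds are strict on the low side, so equality falls in
the higher (less novel) class; the boundary behaviour at exactly 95 and
98.65 is tested with `nextafter` probes. Computing the identity
(alignment) is out of scope — the percentage is an input.

## Synthetic screens

The generator draws each cell independently as Bernoulli with

```
p[i,j] = clip( base_i · effect_j · boost^{rumen_j} · penalty^{anaerobe_i ∧ aerobic_j}, 0, 1 )
```

- `base_i` — per-species detectability, log-normal (default median 0.08,
  σ = 1.0, clipped to [0,1]): the heavy tail yields both ubiquitous and
  rare species, hence the long non-increasing tail of greedy gains.
- `effect_j` — per-condition productivity, log-normal (σ = 0.7), capped
  at 3.0 for non-dominant conditions so the designated dominant condition
  cannot be out-drawn by the tail; the cap puts the runner-up's expected
  richness near 0.35·S, matching the shape of a real screen where the
  second-best condition isolates roughly a third of all species.
- the dominant condition's effect is fixed at 4.6 and it carries the
  rumen supplement; together (4.6 × 1.6) its expected richness is
  ≈ 0.62·S. Measured over 50 seeds the mean is 0.622, within the ±5%
  calibration band the test asserts.
- `boost` (default 1.6) multiplies supplemented (rumen-fluid) conditions;
  `penalty` (default 0.08) multiplies a strict anaerobe's probability
  under aerobic conditions. With `penalty = 0` strict anaerobes are never
  recovered aerobically — an exact property the tests use.
- 67% of species are flagged strict anaerobes; `new_taxon_rate` (default
  0.15) flags candidate new taxa in the species metadata. The source
  material is ambiguous about the overall new-taxon share (single-digit
  percent by one count, far higher within specific subsets), so a
  mid-range value was chosen once; the flag feeds no computed statistic.

Species rows that come out all-zero are redrawn (up to 100 retries per
species) rather than conditioning the distribution — simpler, and the
bias is negligible at default parameters; pathological parameters raise a
generation error naming the offending species count.

`study_shaped_fixture(seed)` is the preset used throughout the tests and
the acceptance script: 497 species × 58 conditions (40 anaerobic, 18
aerobic), three disjoint group tags sized 18/18/22 (the 22 with alcohol
pre-treatment), and a 7-condition rumen arm whose members share their
condition effect with a matched rumen-free arm — pairing by medium, so
the arm contrast isolates the supplement effect. Under these defaults the
anaerobic union is ≈ 99% of species and the rumen arm out-recovers the
matched arm in ≥ 95% of seeds (measured 100/100 over seeds 0–99).

What the generator does **not** model: co-occurrence between species
(cells are independent), per-donor structure, colony-count abundances,
and enrichment-time dynamics. Passing tests therefore demonstrate the
correctness of the set arithmetic, the greedy procedure and the tests on
matrices with realistic marginal structure — not that any biological
co-occurrence pattern is recovered.

## Numerical and design choices

- All randomness flows through `numpy.random.default_rng(seed)`;
  identical seeds reproduce matrices, curves and report bundles byte for
  byte (asserted end to end).
- Matrix equality compares the detection relation (species set, condition
  set, cells), not row/column order, because the long format cannot in
  general preserve both orders simultaneously.
- The accumulation curve compares the greedy condition ordering (extended
  past the coverage target through zero-gain picks, same tie-breaks) with
  uniformly random orderings; greedy dominates the random mean at every
  rank by construction, and the Monte-Carlo test confirms it.
- Problem sizes in the randomized test batteries (matrices up to ~30
  species × 10 conditions, 100–1000 replicates; 100 full study-shaped
  fixtures) were chosen so the whole suite runs in a few seconds while
  the Monte-Carlo assertions still have negligible flake probability at
  their fixed seeds.
- The replication path for a real screen's supplementary species-by-
  condition list is implemented (long-TSV reader + the full analysis);
  the corresponding acceptance test documents the expected file locations
  and fails with an explanatory message when the externally distributed
  list is absent.

## Known limitations

- No weighted or cost-aware set cover (media cost, hands-on time).
- No Fisher exact test or multiple-testing machinery — a single Pearson
  chi-square, as the analysis design calls for.
- Catalogue comparison is exact-match on names; taxonomic synonyms or
  spelling variants count as novel.
- `exact_min_cover` is exponential by design and capped at 20 conditions.
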