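"""Species-set algebra over condition groups.

Conditions carry an optional ``group`` tag (e.g. the 18 standard
culturomics conditions vs 18 newly designed ones vs 22 alcohol-pretreated
ones).  This module computes the Venn-region counts of the species sets
those groups isolate, added/specific counts of one group against a
baseline, and comparison against an external reference catalogue of
species names.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

from .cover import round_half_up
from .errors import UnknownGroupError
from .model import IncidenceMatrix, normalize_name


@dataclass(frozen=True)
class GroupPartition:
    """Venn-region species counts for 2 or 3 condition groups.

    ``region_counts`` maps a membership signature — one '0'/'1' character
    per group, in ``groups`` order, e.g. ``"110"`` for species isolated by
    the first two groups but not the third — to the number of species in
    that region.  Only non-empty signatures appear.
    """

    groups: tuple[str, ...]
    region_counts: dict[str, int]
    union_size: int

    @property
    def common(self) -> int:
        """Species isolated by every group (the all-ones region)."""
        return self.region_counts.get("1" * len(self.groups), 0)

    @property
    def percent_common(self) -> int:
        """Share of the union isolated by all groups, half-up percent."""
        return round_half_up(100 * self.common / self.union_size) if self.union_size else 0

    def group_total(self, group: str) -> int:
        """Total species of one group, recovered by summing its regions."""
        i = self.groups.index(group)
        return sum(n for sig, n in self.region_counts.items() if sig[i] == "1")


def group_conditions(matrix: IncidenceMatrix, group: str) -> list[str]:
    """Condition ids carrying a group tag."""
    conds = [c for c in matrix.conditions if matrix.condition(c).group == group]
    if not conds:
        raise UnknownGroupError(group)
    return conds


def group_species(matrix: IncidenceMatrix, group: str) -> frozenset[str]:
    """Union of species over a group's conditions (normalized names)."""
    return matrix.species_for_any(group_conditions(matrix, group))


def partition(matrix: IncidenceMatrix, groups: Sequence[str]) -> GroupPartition:
    """Venn partition of species among 2 or 3 condition groups.

    A condition may carry at most one group tag, so groups are disjoint as
    condition sets; their species sets of course overlap, and that overlap
    is what the region counts quantify.
    """
    if not 2 <= len(groups) <= 3:
        raise ValueError(f"partition supports 2 or 3 groups, got {len(groups)}")
    if len(set(groups)) != len(groups):
        raise ValueError(f"duplicate group tags: {list(groups)}")
    sets = [group_species(matrix, g) for g in groups]
    union = frozenset().union(*sets)
    region_counts: dict[str, int] = {}
    for bits in product("10", repeat=len(groups)):
        sig = "".join(bits)
        if sig == "0" * len(groups):
            continue
        region = union
        for s, b in zip(sets, bits):
            region = region & s if b == "1" else region - s
        if region:
            region_counts[sig] = len(region)
    return GroupPartition(tuple(groups), region_counts, len(union))


def added_and_specific(
    matrix: IncidenceMatrix,
    baseline: str,
    other: str,
    rest: Iterable[str] | None = None,
) -> tuple[int, int]:
    """Species a group adds over a baseline group, and how many are its own.

    ``added`` is ``|other \\ baseline|``; ``specific`` is
    ``|other \\ (baseline ∪ rest)|`` where ``rest`` defaults to every
    remaining tagged group in the matrix.
    """
    if baseline == other:
        raise ValueError("baseline and other must differ")
    if rest is None:
        tags = {matrix.condition(c).group for c in matrix.conditions}
        rest = sorted(t for t in tags if t not in (None, baseline, other))
    else:
        rest = list(rest)
        if {baseline, other} & set(rest):
            raise ValueError("rest overlaps baseline/other tags")
    base = group_species(matrix, baseline)
    oth = group_species(matrix, other)
    excluded = set(base)
    for g in rest:
        excluded |= group_species(matrix, g)
    return len(oth - base), len(oth - excluded)


def compare_to_catalogue(
    species: Iterable[str], catalogue: Iterable[str]
) -> tuple[int, frozenset[str]]:
    """Count and name the species absent from a reference catalogue.

    Both sides are normalized (case-fold, whitespace collapse) before the
    exact-match comparison; no fuzzy synonym resolution is attempted.
    """
    cat = {normalize_name(n) for n in catalogue}
    if not cat:
        raise ValueError("catalogue must be non-empty")
    novel = frozenset(normalize_name(s) for s in species) - cat
    return len(novel), novel
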