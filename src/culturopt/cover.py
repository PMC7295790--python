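"""Condition-panel optimization: richness ranking and greedy set cover.

The reduction of a large culture-condition panel to a small one that keeps
the captured species diversity is a maximum-coverage problem.  Each
condition covers the set of species it isolated; the procedure picks, at
every step, the condition adding the most species not yet covered (its
*marginal gain*) until a coverage target is reached.  Coverage is a
submodular set function, so the greedy gains are non-increasing and the
greedy panel is within a factor ``1 - 1/e`` of the best panel of the same
size — both properties are asserted in the test-suite.

Tie-breaking is deterministic: at equal marginal gain the condition with
the larger standalone richness wins, then the lexicographically smaller
condition id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import CapacityError, ConsistencyError, UnknownConditionError
from .model import IncidenceMatrix


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero-ward .5 up."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class CoverStep:
    """One greedy pick: the condition, what it added, and the running total."""

    condition: str
    marginal_gain: int
    cumulative_covered: int
    cumulative_fraction: float


@dataclass(frozen=True)
class CoverResult:
    """Ordered greedy selection with per-step bookkeeping.

    ``exhausted`` is True when the candidate pool ran out of positive
    gains before the target fraction was reached (impossible on a valid
    matrix with target 1.0, since every species is covered by some
    condition).  ``forced`` lists conditions appended by explicit request
    rather than picked by the greedy rule.
    """

    steps: tuple[CoverStep, ...]
    total_species: int
    target_fraction: float
    seeded_first: str | None = None
    exhausted: bool = False
    forced: tuple[str, ...] = field(default_factory=tuple)

    @property
    def selected(self) -> tuple[str, ...]:
        return tuple(s.condition for s in self.steps)

    @property
    def covered(self) -> int:
        return self.steps[-1].cumulative_covered if self.steps else 0

    @property
    def fraction(self) -> float:
        return self.steps[-1].cumulative_fraction if self.steps else 0.0

    def __len__(self) -> int:
        return len(self.steps)


def rank_by_richness(
    matrix: IncidenceMatrix, top_k: int | None = None
) -> list[tuple[str, int]]:
    """Rank conditions by number of species isolated (descending).

    Ties are broken by ascending condition id.  ``top_k`` truncates.
    """
    if top_k is not None and top_k <= 0:
        raise ValueError(f"top_k must be positive, got {top_k}")
    ranked = sorted(
        ((c, matrix.richness(c)) for c in matrix.conditions),
        key=lambda cr: (-cr[1], cr[0]),
    )
    return ranked[:top_k] if top_k is not None else ranked


def marginal_gain(
    matrix: IncidenceMatrix, selected: Iterable[str], candidate: str
) -> int:
    """Species grown by ``candidate`` and by no condition in ``selected``."""
    selected = set(selected)
    if candidate in selected:
        raise ValueError(f"candidate {candidate!r} already selected")
    covered = matrix.mask_for_any(selected)
    return int((matrix.column(candidate) & ~covered).sum())


def _pick(matrix: IncidenceMatrix, covered: np.ndarray, candidates: Sequence[str]):
    """Best candidate by (gain, standalone richness, ascending id)."""
    best = None
    best_key = None
    for c in candidates:
        col = matrix.column(c)
        gain = int((col & ~covered).sum())
        key = (-gain, -int(col.sum()), c)
        if best_key is None or key < best_key:
            best, best_key = c, key
    return best, -best_key[0]


def greedy_cover(
    matrix: IncidenceMatrix,
    target_fraction: float = 1.0,
    seed_condition: str | None = None,
    force_include: Sequence[str] = (),
) -> CoverResult:
    """Greedy maximum-coverage selection of a condition panel.

    Picks conditions by maximal marginal gain until ``target_fraction`` of
    the species are covered.  ``seed_condition`` forces the first pick
    (the study's framing of "our best reported condition"); by default the
    first pick is the globally richest condition, which is the same thing
    whenever that condition is in fact the richest.  ``force_include``
    appends the listed conditions after the target is reached — the manual
    panel additions a practitioner may insist on — each recorded with its
    actual marginal gain at that point.
    """
    if not 0 < target_fraction <= 1:
        raise ValueError(f"target_fraction must be in (0, 1], got {target_fraction}")
    for c in (seed_condition, *force_include):
        if c is not None and c not in matrix.conditions:
            raise UnknownConditionError(c)

    total = matrix.n_species
    covered = np.zeros(total, dtype=bool)
    remaining = list(matrix.conditions)
    steps: list[CoverStep] = []
    exhausted = False

    def take(cond: str) -> int:
        col = matrix.column(cond)
        gain = int((col & ~covered).sum())
        covered[:] |= col
        n_cov = int(covered.sum())
        steps.append(CoverStep(cond, gain, n_cov, n_cov / total))
        remaining.remove(cond)
        return gain

    if seed_condition is not None:
        take(seed_condition)
    while (steps[-1].cumulative_fraction if steps else 0.0) < target_fraction:
        if not remaining:
            exhausted = True
            break
        cond, gain = _pick(matrix, covered, remaining)
        if gain == 0:
            exhausted = True
            break
        take(cond)

    forced = tuple(c for c in force_include if c not in {s.condition for s in steps})
    for c in forced:
        take(c)

    return CoverResult(
        steps=tuple(steps),
        total_species=total,
        target_fraction=target_fraction,
        seeded_first=seed_condition,
        exhausted=exhausted,
        forced=forced,
    )


def greedy_order(matrix: IncidenceMatrix) -> list[str]:
    """Full greedy ordering of *all* conditions (zero-gain picks included,
    still tie-broken by richness then id).  Used for accumulation curves."""
    covered = np.zeros(matrix.n_species, dtype=bool)
    remaining = list(matrix.conditions)
    order = []
    while remaining:
        cond, _ = _pick(matrix, covered, remaining)
        covered |= matrix.column(cond)
        remaining.remove(cond)
        order.append(cond)
    return order


def exact_min_cover(matrix: IncidenceMatrix) -> tuple[int, tuple[str, ...]]:
    """Exhaustive minimum set cover, for validating the greedy heuristic.

    Searches subsets in increasing size and, within a size, lexicographic
    order of condition ids, so the witness is the lexicographically
    smallest optimum.  Refuses instances with more than 20 conditions.
    """
    n = matrix.n_conditions
    if n > 20:
        raise CapacityError(f"exact search limited to 20 conditions, got {n}")
    ids = sorted(matrix.conditions)
    masks = {c: int(sum(1 << i for i in np.flatnonzero(matrix.column(c)))) for c in ids}
    full = (1 << matrix.n_species) - 1
    for size in range(1, n + 1):
        for subset in combinations(ids, size):
            acc = 0
            for c in subset:
                acc |= masks[c]
            if acc == full:
                return size, subset
    raise ConsistencyError("no cover exists; matrix invariant violated")  # pragma: no cover


def best_k_coverage(matrix: IncidenceMatrix, k: int) -> int:
    """Exhaustive best coverage achievable with exactly ``k`` conditions
    (oracle for the greedy approximation guarantee; small instances only)."""
    if matrix.n_conditions > 20:
        raise CapacityError("exact search limited to 20 conditions")
    best = 0
    cols = {c: matrix.column(c) for c in matrix.conditions}
    for subset in combinations(matrix.conditions, k):
        cov = np.zeros(matrix.n_species, dtype=bool)
        for c in subset:
            cov |= cols[c]
        best = max(best, int(cov.sum()))
    return best


def cumulative_coverage(gains: Sequence[int], total_species: int) -> pd.DataFrame:
    """Cumulative count and percent table from a marginal-gain sequence.

    This is the arithmetic behind a published panel table: the running sum
    of the "species added" column and its percentage of the study total,
    rounded half-up to an integer.
    """
    cum = np.cumsum(np.asarray(gains, dtype=int))
    return pd.DataFrame(
        {
            "marginal_gain": list(gains),
            "cumulative_covered": cum,
            "cumulative_percent": [round_half_up(100 * c / total_species) for c in cum],
        }
    )


def panel_report(cover: CoverResult, matrix: IncidenceMatrix) -> pd.DataFrame:
    """Tabular panel report: one row per selected condition.

    Columns: condition id, label, marginal gain ("species added and not
    previously isolated"), standalone richness ("species isolated"),
    cumulative covered and cumulative percent (half-up integer).  Raises
    :class:`ConsistencyError` if ``cover`` was not produced from
    ``matrix`` (gains are re-derived and compared).
    """
    covered = np.zeros(matrix.n_species, dtype=bool)
    rows = []
    for step in cover.steps:
        try:
            col = matrix.column(step.condition)
        except UnknownConditionError:
            raise ConsistencyError(
                f"cover references condition {step.condition!r} absent from matrix"
            ) from None
        gain = int((col & ~covered).sum())
        if gain != step.marginal_gain or cover.total_species != matrix.n_species:
            raise ConsistencyError(
                f"cover does not match matrix at step {step.condition!r} "
                f"(recomputed gain {gain}, stored {step.marginal_gain})"
            )
        covered |= col
        rows.append(
            {
                "condition": step.condition,
                "label": matrix.condition(step.condition).label,
                "marginal_gain": step.marginal_gain,
                "richness": int(col.sum()),
                "cumulative_covered": step.cumulative_covered,
                "cumulative_percent": round_half_up(
                    100 * step.cumulative_covered / cover.total_species
                ),
            }
        )
    return pd.DataFrame(rows)


def accumulation_curve(
    matrix: IncidenceMatrix, n_permutations: int, seed: int
) -> pd.DataFrame:
    """Species-accumulation curves: greedy order vs random condition orders.

    Returns a per-rank table with the greedy cumulative species count and
    the mean/min/max cumulative count over ``n_permutations`` uniformly
    random orderings of the conditions.  Deterministic under a fixed seed.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    cells = matrix.cells
    n_cond = matrix.n_conditions

    order = greedy_order(matrix)
    idx = [matrix.conditions.index(c) for c in order]
    greedy_curve = np.maximum.accumulate(cells[:, idx], axis=1).sum(axis=0)

    rand = np.empty((n_permutations, n_cond), dtype=int)
    for p in range(n_permutations):
        perm = rng.permutation(n_cond)
        rand[p] = np.maximum.accumulate(cells[:, perm], axis=1).sum(axis=0)

    return pd.DataFrame(
        {
            "rank": np.arange(1, n_cond + 1),
            "greedy": greedy_curve,
            "random_mean": rand.mean(axis=0),
            "random_min": rand.min(axis=0),
            "random_max": rand.max(axis=0),
        }
    )
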