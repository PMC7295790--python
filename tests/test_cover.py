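"""Ranking, greedy cover, exact oracle, panel report and accumulation curve."""

import numpy as np
import pytest

from culturopt.cover import (
    accumulation_curve,
    best_k_coverage,
    cumulative_coverage,
    exact_min_cover,
    greedy_cover,
    greedy_order,
    marginal_gain,
    panel_report,
    rank_by_richness,
)
from culturopt.errors import CapacityError, ConsistencyError, UnknownConditionError
from culturopt.model import IncidenceMatrix

from conftest import random_matrix


def replay_greedy(matrix):
    """Independent re-implementation of the greedy rule on explicit sets.

    Kept deliberately naive (dict of python sets, max() over tuples) so it
    shares no code with the vectorized implementation it checks.
    """
    col = {c: set(np.flatnonzero(matrix.column(c))) for c in matrix.conditions}
    covered, picks = set(), []
    while len(covered) < matrix.n_species:
        best = max(
            (c for c in col if c not in {p for p, _ in picks}),
            key=lambda c: (len(col[c] - covered), len(col[c]), [-ord(x) for x in c]),
        )
        gain = len(col[best] - covered)
        if gain == 0:
            break
        covered |= col[best]
        picks.append((best, gain))
    return picks


class TestRank:
    def test_ties_broken_by_ascending_id(self):
        m = IncidenceMatrix([[1, 1], [1, 1]], ["a", "b"], ["z", "a"])
        assert rank_by_richness(m) == [("a", 2), ("z", 2)]

    def test_matches_brute_force_column_sums(self):
        rng = np.random.default_rng(11)
        m = random_matrix(rng, 20, 6)
        tally = {c: int(sum(m.cells[:, j])) for j, c in enumerate(m.conditions)}
        expected = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
        assert rank_by_richness(m) == expected

    def test_top_k_truncates_and_validates(self, toy_matrix):
        assert len(rank_by_richness(toy_matrix, top_k=2)) == 2
        with pytest.raises(ValueError):
            rank_by_richness(toy_matrix, top_k=0)


class TestMarginalGain:
    def test_empty_selection_equals_richness(self, toy_matrix):
        for c in toy_matrix.conditions:
            assert marginal_gain(toy_matrix, set(), c) == toy_matrix.richness(c)

    def test_subset_candidate_gains_nothing(self):
        m = IncidenceMatrix([[1, 1], [1, 0], [1, 0]], ["a", "b", "c"], ["big", "sub"])
        assert marginal_gain(m, {"big"}, "sub") == 0

    def test_already_selected_candidate_rejected(self, toy_matrix):
        with pytest.raises(ValueError, match="already selected"):
            marginal_gain(toy_matrix, {"c1"}, "c1")


class TestGreedyCover:
    def test_single_condition_covering_all(self):
        m = IncidenceMatrix([[1, 0], [1, 1]], ["a", "b"], ["all", "some"])
        res = greedy_cover(m)
        assert res.selected == ("all",)
        assert res.fraction == 1.0 and not res.exhausted

    def test_matches_naive_replay_on_crafted_matrix(self):
        # 8 species × 5 conditions with overlapping coverage
        cells = np.array(
            [
                [1, 0, 0, 1, 0],
                [1, 1, 0, 0, 0],
                [1, 0, 1, 0, 0],
                [0, 1, 0, 0, 1],
                [0, 1, 1, 0, 0],
                [0, 0, 1, 1, 0],
                [0, 0, 0, 1, 1],
                [1, 0, 0, 0, 1],
            ]
        )
        m = IncidenceMatrix(cells, [f"s{i}" for i in range(8)], list("abcde"))
        res = greedy_cover(m)
        assert [(s.condition, s.marginal_gain) for s in res.steps] == replay_greedy(m)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_replay_on_random_matrices(self, seed):
        m = random_matrix(np.random.default_rng(seed), 18, 7)
        res = greedy_cover(m)
        assert [(s.condition, s.marginal_gain) for s in res.steps] == replay_greedy(m)

    @pytest.mark.parametrize("seed", range(20))
    def test_gains_non_increasing_and_full_cover(self, seed):
        m = random_matrix(np.random.default_rng(100 + seed), 25, 8)
        res = greedy_cover(m)
        gains = [s.marginal_gain for s in res.steps]
        assert gains == sorted(gains, reverse=True)
        assert res.covered == m.n_species and not res.exhausted
        fracs = [s.cumulative_fraction for s in res.steps]
        assert fracs == sorted(fracs)
        assert fracs[-1] == 1.0

    def test_seeding_with_richest_equals_unseeded(self, study_fixture):
        m, _, _ = study_fixture
        richest = rank_by_richness(m, 1)[0][0]
        assert greedy_cover(m).selected == greedy_cover(m, seed_condition=richest).selected

    def test_seed_condition_forced_first(self, toy_matrix):
        res = greedy_cover(toy_matrix, seed_condition="c3")
        assert res.selected[0] == "c3"
        assert res.seeded_first == "c3"

    def test_force_include_appended_with_actual_gain(self, toy_matrix):
        res = greedy_cover(toy_matrix, force_include=["c2"])
        assert res.selected[-1] == "c2"
        assert res.steps[-1].marginal_gain == 0  # everything already covered
        assert res.forced == ("c2",)

    def test_target_fraction_stops_early(self, study_fixture):
        m, _, _ = study_fixture
        res = greedy_cover(m, target_fraction=0.9)
        assert res.fraction >= 0.9
        assert res.steps[-2].cumulative_fraction < 0.9  # minimal panel

    def test_unknown_seed_condition(self, toy_matrix):
        with pytest.raises(UnknownConditionError):
            greedy_cover(toy_matrix, seed_condition="zz")
        with pytest.raises(ValueError):
            greedy_cover(toy_matrix, target_fraction=0)


class TestExactMinCover:
    def test_single_covering_condition(self):
        m = IncidenceMatrix([[1, 1], [1, 0]], ["a", "b"], ["all", "one"])
        assert exact_min_cover(m) == (1, ("all",))

    def test_disjoint_partition_forces_all(self):
        cells = np.eye(3, dtype=int)
        m = IncidenceMatrix(cells, ["a", "b", "c"], ["c1", "c2", "c3"])
        assert exact_min_cover(m) == (3, ("c1", "c2", "c3"))

    def test_capacity_cap(self):
        m = IncidenceMatrix(
            np.ones((1, 21), dtype=int), ["a"], [f"c{i:02d}" for i in range(21)]
        )
        with pytest.raises(CapacityError):
            exact_min_cover(m)

    @pytest.mark.parametrize("seed", range(15))
    def test_optimum_never_exceeds_greedy(self, seed):
        m = random_matrix(np.random.default_rng(200 + seed), 12, 8)
        size, witness = exact_min_cover(m)
        assert size <= len(greedy_cover(m))
        assert m.species_for_any(witness) == frozenset(m.normalized_species())

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_greedy_k_coverage_within_1_minus_1_over_e(self, seed, k):
        m = random_matrix(np.random.default_rng(300 + seed), 15, 7)
        res = greedy_cover(m)
        if len(res) < k:
            return  # greedy finished before k picks: full coverage already
        greedy_k = res.steps[k - 1].cumulative_covered
        assert greedy_k >= (1 - 1 / np.e) * best_k_coverage(m, k)


class TestPanelReport:
    def test_published_gain_column_arithmetic(self):
        gains = [306, 64, 29, 21, 17, 13, 8, 5, 5, 4, 4, 3, 3, 2, 2, 1]
        table = cumulative_coverage(gains, total_species=497)
        assert table["cumulative_covered"].iloc[-1] == 487
        assert table["cumulative_percent"].iloc[-1] == 98  # 487/497 = 97.99 → half-up

    def test_cumulative_equals_running_sum_and_monotone_percent(self, study_fixture):
        m, _, _ = study_fixture
        report = panel_report(greedy_cover(m), m)
        assert (
            report["cumulative_covered"] == report["marginal_gain"].cumsum()
        ).all()
        pct = report["cumulative_percent"].tolist()
        assert pct == sorted(pct)
        assert pct[-1] == 100

    def test_single_step_report(self):
        m = IncidenceMatrix([[1, 0], [1, 1]], ["a", "b"], ["all", "x"])
        report = panel_report(greedy_cover(m), m)
        assert len(report) == 1
        row = report.iloc[0]
        assert row["marginal_gain"] == row["richness"] == row["cumulative_covered"] == 2

    def test_mismatched_matrix_rejected(self, toy_matrix):
        other = IncidenceMatrix([[1, 1, 1]], ["only"], ["c1", "c2", "c3"])
        res = greedy_cover(toy_matrix)
        with pytest.raises(ConsistencyError):
            panel_report(res, other)


class TestAccumulationCurve:
    def test_identical_columns_flat_after_rank_one(self):
        m = IncidenceMatrix([[1, 1, 1], [1, 1, 1]], ["a", "b"], ["c1", "c2", "c3"])
        curve = accumulation_curve(m, n_permutations=5, seed=0)
        assert (curve["greedy"] == 2).all()
        assert (curve["random_mean"] == 2).all()

    def test_greedy_dominates_random_orders_and_ends_at_total(self):
        m = random_matrix(np.random.default_rng(42), 30, 10)
        curve = accumulation_curve(m, n_permutations=200, seed=5)
        assert (curve["greedy"] >= curve["random_mean"] - 1e-12).all()
        assert curve["greedy"].iloc[-1] == m.n_species
        assert curve["random_max"].iloc[-1] == m.n_species

    def test_deterministic_under_fixed_seed(self, toy_matrix):
        a = accumulation_curve(toy_matrix, 20, seed=3)
        b = accumulation_curve(toy_matrix, 20, seed=3)
        assert a.equals(b)
        with pytest.raises(ValueError):
            accumulation_curve(toy_matrix, 0, seed=3)

    def test_greedy_order_includes_every_condition(self, toy_matrix):
        assert sorted(greedy_order(toy_matrix)) == sorted(toy_matrix.conditions)
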