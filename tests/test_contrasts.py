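"""Chi-square, paired supplement contrast and atmosphere crosstab."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from culturopt.contrasts import (
    atmosphere_crosstab,
    paired_supplement_contrast,
    pearson_chi2,
)
from culturopt.errors import DegenerateTableError
from culturopt.model import Condition, IncidenceMatrix
from culturopt.simulate import arm_conditions, study_shaped_fixture


class TestPearsonChi2:
    def test_homogeneous_table_is_null(self):
        res = pearson_chi2([[10, 10], [10, 10]])
        assert res.chi2 == 0.0
        assert res.p_value == 1.0
        assert res.df == 1

    def test_reconstructed_supplement_table_is_significant(self):
        # arm totals 359 vs 254 with 232 shared ⇒ specific 127 vs 22
        res = pearson_chi2([[127, 232], [22, 232]])
        assert res.p_value < 1e-6
        # conclusion robust to the continuity correction
        assert pearson_chi2([[127, 232], [22, 232]], correction=True).p_value < 1e-6

    @pytest.mark.parametrize("correction", [False, True])
    def test_matches_scipy_oracle_on_random_tables(self, correction):
        rng = np.random.default_rng(99)
        for _ in range(300):
            table = rng.integers(1, 60, size=(2, 2))
            ours = pearson_chi2(table, correction=correction)
            chi2, p, df, _ = chi2_contingency(table, correction=correction)
            assert ours.chi2 == pytest.approx(chi2, rel=1e-9)
            assert ours.p_value == pytest.approx(p, rel=1e-9, abs=1e-300)
            assert df == 1

    def test_invariant_under_transposition_and_row_col_swap(self):
        t = np.array([[12, 30], [7, 41]])
        base = pearson_chi2(t).chi2
        assert pearson_chi2(t.T).chi2 == pytest.approx(base, rel=1e-12)
        assert pearson_chi2(t[::-1, ::-1]).chi2 == pytest.approx(base, rel=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateTableError):
            pearson_chi2([[0, 5], [0, 7]])

    def test_monotone_in_exclusive_count(self):
        # growing one arm's specific count (other cells fixed) cannot
        # shrink the statistic
        stats = [pearson_chi2([[k, 50], [5, 50]]).chi2 for k in range(6, 40)]
        assert all(b >= a for a, b in zip(stats, stats[1:]))


def two_arm_matrix(cells):
    n_sp, n_c = np.asarray(cells).shape
    ids = [f"a{j}" if j < n_c // 2 else f"b{j}" for j in range(n_c)]
    return IncidenceMatrix(cells, [f"sp{i}" for i in range(n_sp)], ids)


class TestPairedContrast:
    def test_counts_and_table_layout(self):
        m = two_arm_matrix(
            [
                [1, 0],  # specific to arm a
                [1, 0],
                [1, 1],  # shared
                [0, 1],  # specific to arm b
            ]
        )
        res = paired_supplement_contrast(m, ["a0"], ["b1"])
        assert (res.richness_a, res.richness_b) == (3, 2)
        assert (res.specific_a, res.specific_b, res.shared) == (2, 1, 1)
        assert res.test.table == ((2, 1), (1, 1))
        assert res.richness_a == res.specific_a + res.shared
        assert res.richness_b == res.specific_b + res.shared

    def test_identical_arm_species_sets_give_null_test(self):
        m = two_arm_matrix([[1, 1], [1, 1]])
        res = paired_supplement_contrast(m, ["a0"], ["b1"])
        assert res.specific_a == res.specific_b == 0
        assert res.test.chi2 == 0.0 and res.test.p_value == 1.0

    def test_argument_validation(self, toy_matrix):
        with pytest.raises(ValueError, match="overlap"):
            paired_supplement_contrast(toy_matrix, ["c1"], ["c1"])
        with pytest.raises(ValueError, match="non-empty"):
            paired_supplement_contrast(toy_matrix, [], ["c1"])
        with pytest.raises(ValueError, match="equal length"):
            paired_supplement_contrast(toy_matrix, ["c1", "c2"], ["c3"])

    def test_synthetic_supplement_boost_detected(self, study_fixture):
        m, cond_df, _ = study_fixture
        arm_a, arm_b = arm_conditions(cond_df)
        res = paired_supplement_contrast(m, arm_a, arm_b)
        assert res.richness_a > res.richness_b
        assert res.specific_a > res.specific_b


class TestAtmosphereCrosstab:
    @pytest.fixture
    def crafted(self):
        meta = {
            "an1": Condition(id="an1", atmosphere="anaerobic"),
            "an2": Condition(id="an2", atmosphere="anaerobic"),
            "ae1": Condition(id="ae1", atmosphere="aerobic"),
        }
        cells = [
            [1, 0, 0],  # anaerobic only
            [0, 1, 0],  # anaerobic only
            [0, 0, 1],  # aerobic only
            [1, 0, 1],  # both
            [0, 1, 1],  # both
            [1, 1, 0],  # anaerobic only
        ]
        return IncidenceMatrix(
            cells, [f"sp{i}" for i in range(6)], ["an1", "an2", "ae1"], meta
        )

    def test_crafted_assignment(self, crafted):
        phen = {
            "sp0": "strict_anaerobe",
            "sp1": "strict_anaerobe",
            "sp2": "oxygen_tolerant",
            "sp3": "oxygen_tolerant",
            "sp4": "strict_anaerobe",
            # sp5 has no phenotype → counted as unknown, never dropped
        }
        tab = atmosphere_crosstab(crafted, phen)
        assert tab.loc["anaerobic_only", "strict_anaerobe"] == 2
        assert tab.loc["anaerobic_only", "unknown"] == 1
        assert tab.loc["aerobic_only", "oxygen_tolerant"] == 1
        assert tab.loc["both", "strict_anaerobe"] == 1
        assert tab.loc["both", "oxygen_tolerant"] == 1
        assert tab.loc["total", "total"] == 6

    def test_recovery_classes_partition_species(self, crafted):
        tab = atmosphere_crosstab(crafted, {})
        classes = tab.loc[["anaerobic_only", "aerobic_only", "both"], "total"]
        assert classes.sum() == crafted.n_species

    def test_only_anaerobic_conditions(self):
        meta = {"a": Condition(id="a", atmosphere="anaerobic")}
        m = IncidenceMatrix([[1], [1]], ["x", "y"], ["a"], meta)
        tab = atmosphere_crosstab(m, {})
        assert tab.loc["anaerobic_only", "total"] == 2
        assert tab.loc["aerobic_only", "total"] == 0

    def test_percentages_attached_half_up(self, crafted):
        tab = atmosphere_crosstab(crafted, {})
        pct = tab.attrs["percent"]
        assert pct.loc["total", "total"] == 100
        assert pct.loc["anaerobic_only", "total"] == 50  # 3/6

    def test_phenotypes_default_to_matrix_metadata(self, study_fixture):
        m, _, species_df = study_fixture
        tab = atmosphere_crosstab(m)
        assert tab.loc["total", "strict_anaerobe"] == int(
            (species_df["oxygen_phenotype"] == "strict_anaerobe").sum()
        )
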