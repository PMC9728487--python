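"""Z-transformation, covariance rules, hierarchical merging, classification."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from survscore import scoring as sc
from survscore.hierarchy import enumerate_ordered_pairs


class TestEnumerateOrderedPairs:
    def test_three_conditions_adjacent_first(self):
        pairs = enumerate_ordered_pairs({"c1": 0.5, "c2": 0.3, "c3": 0.1})
        assert pairs == [("c1", "c2"), ("c2", "c3"), ("c1", "c3")]

    def test_pair_counts(self):
        assert len(enumerate_ordered_pairs({"a": 2.0, "b": 1.0})) == 1
        assert len(enumerate_ordered_pairs({c: r for c, r in zip("abcd", [4, 3, 2, 1])})) == 6

    def test_orientation_high_death_first(self):
        for a, b in enumerate_ordered_pairs({"x": 0.2, "y": 1.3, "z": 0.7}):
            rates = {"x": 0.2, "y": 1.3, "z": 0.7}
            assert rates[a] >= rates[b]

    def test_ties_broken_lexicographically(self, caplog):
        with caplog.at_level("WARNING"):
            pairs = enumerate_ordered_pairs({"b": 0.5, "a": 0.5})
        assert pairs == [("a", "b")]
        assert any("tie" in r.message for r in caplog.records)

    def test_single_condition_rejected(self):
        with pytest.raises(ValueError):
            enumerate_ordered_pairs({"a": 1.0})


class TestZFromPair:
    def test_significance_threshold_quantile(self):
        # two-sided p = 0.2 is one-sided 0.1, the study's Z = 1.28 cut-off
        assert sc.z_from_pair(0.8, 0.2) == pytest.approx(1.28, abs=0.005)

    def test_sign_antisymmetry(self):
        assert sc.z_from_pair(-0.8, 0.2) == pytest.approx(-1.28, abs=0.005)

    def test_p_one_gives_zero(self):
        assert sc.z_from_pair(3.0, 1.0) == 0.0

    def test_zero_fold_change_gives_zero(self):
        assert sc.z_from_pair(0.0, 0.01) == 0.0

    def test_one_sided_convention(self):
        assert sc.z_from_pair(1.0, 0.1, tail="one") == pytest.approx(1.2816, abs=1e-3)

    def test_magnitude_capped_by_p_floor(self):
        z = sc.z_from_pair(5.0, 1e-300, p_floor=1e-15)
        assert z == pytest.approx(sc.z_from_pair(5.0, 1e-15), abs=1e-9)
        assert z < 8.2

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            sc.z_from_pair(1.0, 0.0)
        with pytest.raises(ValueError):
            sc.z_from_pair(1.0, 1.5)


class TestPairCovariance:
    @pytest.mark.parametrize(
        "p1,p2,expected",
        [
            (("c1", "c2"), ("c1", "c2"), 1.0),
            (("c1", "c2"), ("c1", "c3"), 0.5),
            (("c1", "c3"), ("c2", "c3"), 0.5),
            (("c1", "c2"), ("c3", "c4"), 0.0),
            (("c1", "c2"), ("c2", "c3"), 0.0),  # opposite roles: printed rule says 0
        ],
    )
    def test_paper_rule(self, p1, p2, expected):
        assert sc.pair_covariance(p1, p2, rule="paper") == expected

    def test_signed_rule_opposite_role_share(self):
        assert sc.pair_covariance(("c1", "c2"), ("c2", "c3"), rule="signed") == -0.5

    def test_signed_rule_matches_monte_carlo(self):
        # oracle: standardized mean differences of iid condition effects
        rng = np.random.default_rng(0)
        m = rng.normal(size=(200_000, 3))
        z12 = (m[:, 1] - m[:, 0]) / math.sqrt(2)
        z23 = (m[:, 2] - m[:, 1]) / math.sqrt(2)
        z13 = (m[:, 2] - m[:, 0]) / math.sqrt(2)
        assert np.cov(z12, z23)[0, 1] == pytest.approx(-0.5, abs=0.01)
        assert np.cov(z12, z13)[0, 1] == pytest.approx(0.5, abs=0.01)

    def test_different_datasets_rejected(self):
        with pytest.raises(ValueError):
            sc.pair_covariance(
                ("c1", "c2"), ("c1", "c3"), dataset1="D1", dataset2="D2"
            )


class TestMerging:
    def test_single_pair_identity(self):
        assert sc.merge_pairs_to_dataset({("c1", "c2"): 1.5}) == pytest.approx(1.5)

    def test_disjoint_pairs_independent(self):
        z = sc.merge_pairs_to_dataset({("c1", "c2"): 1.0, ("c3", "c4"): 1.0})
        assert z == pytest.approx(2 / math.sqrt(2))

    def test_chain_design_paper_rule(self):
        # 3x3 covariance matrix summed by hand: diagonal 3, off-diagonals
        # 0 ((c1,c2)x(c2,c3)), 0.5 ((c1,c2)x(c1,c3)), 0.5 ((c2,c3)x(c1,c3))
        z = sc.merge_pairs_to_dataset(
            {("c1", "c2"): 1.0, ("c2", "c3"): 1.0, ("c1", "c3"): 1.0}, rule="paper"
        )
        assert z == pytest.approx(3 / math.sqrt(5))

    def test_dataset_merge_examples(self):
        assert sc.merge_datasets_to_perturbation([2.0]) == pytest.approx(2.0)
        assert sc.merge_datasets_to_perturbation([1, 1, 1]) == pytest.approx(math.sqrt(3))
        assert sc.merge_datasets_to_perturbation([2, -1]) == pytest.approx(1 / math.sqrt(2))

    def test_survival_merge_skips_missing_perturbations(self):
        z, n = sc.merge_to_survival_score([2, 2, 2, 2, 2])
        assert (z, n) == (pytest.approx(10 / math.sqrt(5)), 5)
        z, n = sc.merge_to_survival_score([2, 2, 2, np.nan, np.nan])
        assert (z, n) == (pytest.approx(6 / math.sqrt(3)), 3)
        z, n = sc.merge_to_survival_score([1.5])
        assert (z, n) == (pytest.approx(1.5), 1)

    def test_empty_merges_rejected(self):
        with pytest.raises(ValueError):
            sc.merge_pairs_to_dataset({})
        with pytest.raises(ValueError):
            sc.merge_datasets_to_perturbation([])
        with pytest.raises(ValueError):
            sc.merge_to_survival_score([np.nan])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.permutations(list(range(4))))
    def test_order_invariance(self, perm):
        pairs = [("c1", "c2"), ("c2", "c3"), ("c1", "c3"), ("c1", "c4")]
        zs = [0.5, -1.0, 2.0, 0.3]
        ref = sc.merge_pairs_to_dataset(dict(zip(pairs, zs)))
        permuted = sc.merge_pairs_to_dataset(
            {pairs[i]: zs[i] for i in perm}
        )
        assert permuted == pytest.approx(ref)
        assert sc.merge_datasets_to_perturbation(
            [zs[i] for i in perm]
        ) == pytest.approx(sc.merge_datasets_to_perturbation(zs))


def _pair_stats_frame(records):
    return pd.DataFrame(
        records,
        columns=[
            "protein_id",
            "perturbation",
            "dataset_id",
            "cond_high_death",
            "cond_low_death",
            "log2fc",
            "pvalue",
        ],
    )


class TestScoreProteins:
    def test_single_source_identity(self):
        # one pair in one dataset of one perturbation: Z^S = Z_pair
        stats = _pair_stats_frame([("X", "C", "C_d1", "c1", "c2", 0.8, 0.2)])
        zt = sc.score_proteins(stats)
        expected = sc.z_from_pair(0.8, 0.2)
        assert zt.scores.loc["X", "survival_score"] == pytest.approx(expected)
        assert zt.scores.loc["X", "n_perturbations"] == 1

    def test_hierarchical_merge_against_manual_composition(self):
        z = sc.z_from_pair(1.0, 0.05)
        stats = _pair_stats_frame(
            [
                ("X", "C", "C_d1", "c1", "c2", 1.0, 0.05),
                ("X", "C", "C_d1", "c1", "c3", 1.0, 0.05),
                ("X", "C", "C_d2", "c4", "c5", 1.0, 0.05),
                ("X", "S", "S_d1", "c6", "c7", 1.0, 0.05),
            ]
        )
        zt = sc.score_proteins(stats)
        zd1 = 2 * z / math.sqrt(3.0)  # two pairs sharing c1: var = 2 + 2*0.5
        zc = (zd1 + z) / math.sqrt(2)
        zs = (zc + z) / math.sqrt(2)
        assert zt.scores.loc["X", "survival_score"] == pytest.approx(zs)
        assert zt.scores.loc["X", "n_perturbations"] == 2

    def test_missing_pairs_excluded_from_covariance(self):
        # protein Y measured in one of the two sharing pairs only
        stats = _pair_stats_frame(
            [
                ("X", "C", "D", "c1", "c2", 1.0, 0.1),
                ("X", "C", "D", "c1", "c3", 1.0, 0.1),
                ("Y", "C", "D", "c1", "c2", 1.0, 0.1),
            ]
        )
        zt = sc.score_proteins(stats)
        z = sc.z_from_pair(1.0, 0.1)
        assert zt.scores.loc["Y", "survival_score"] == pytest.approx(z)
        assert zt.scores.loc["X", "survival_score"] == pytest.approx(
            2 * z / math.sqrt(3.0)
        )

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            sc.score_proteins(pd.DataFrame({"protein_id": ["X"]}))


class TestClassifyPairwise:
    @pytest.mark.parametrize(
        "za,zb,expected",
        [
            (2.0, 1.5, "correlated"),
            (-2.0, -1.5, "correlated"),
            (2.0, -1.5, "anticorrelated"),
            (1.0, 3.0, "insignificant"),
        ],
    )
    def test_quadrant_rule(self, za, zb, expected):
        cats, _ = sc.classify_pairwise(
            pd.Series({"X": za}), pd.Series({"X": zb}), threshold=1.28
        )
        assert cats["X"] == expected

    def test_fractions_sum_to_one_over_comeasured(self):
        a = pd.Series({"P1": 2.0, "P2": 2.0, "P3": 1.0, "P4": np.nan})
        b = pd.Series({"P1": 1.5, "P2": -1.5, "P3": 3.0, "P4": 2.0})
        cats, frac = sc.classify_pairwise(a, b)
        assert len(cats) == 3  # P4 not co-measured
        assert sum(frac.values()) == pytest.approx(1.0)
        assert frac["correlated"] == pytest.approx(1 / 3)
        assert frac["anticorrelated"] == pytest.approx(1 / 3)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            sc.classify_pairwise(pd.Series([1.0]), pd.Series([1.0]), threshold=0.0)
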