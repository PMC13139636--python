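import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from enterostrat import (
    CountTable,
    alpha_diversity,
    bray_curtis,
    compare_groups,
    faith_pd,
    permanova,
    permdisp,
    rarefy,
    upset_partition,
)


def _table(rows, sample_ids=None, taxon_ids=None):
    arr = np.asarray(rows)
    return CountTable(
        pd.DataFrame(
            arr,
            index=sample_ids or [f"s{i}" for i in range(arr.shape[0])],
            columns=taxon_ids or [f"t{j}" for j in range(arr.shape[1])],
        )
    )


class TestAlphaDiversity:
    def test_uniform_sample_closed_forms(self):
        tbl = alpha_diversity(_table([[5, 5, 5, 5]]))
        assert tbl.loc["s0", "observed"] == 4
        assert tbl.loc["s0", "shannon"] == pytest.approx(np.log(4), abs=1e-12)

    def test_chao1_without_singletons_equals_observed(self):
        tbl = alpha_diversity(_table([[4, 7, 2, 9]]))
        assert tbl.loc["s0", "chao1"] == tbl.loc["s0", "observed"]

    def test_chao1_hand_value(self):
        tbl = alpha_diversity(_table([[1, 1, 2]]))
        assert tbl.loc["s0", "chao1"] == pytest.approx(3.5)

    def test_ace_equals_observed_when_all_abundant(self):
        tbl = alpha_diversity(_table([[20, 30, 40]]))
        assert tbl.loc["s0", "ace"] == tbl.loc["s0", "observed"]

    def test_estimators_bounded_below_by_observed(self, multinomial_table):
        tbl = alpha_diversity(multinomial_table)
        assert (tbl["chao1"] >= tbl["observed"] - 1e-9).all()
        assert (tbl["ace"] >= tbl["observed"] - 1e-9).all()

    def test_ace_matches_skbio(self, multinomial_table):
        from skbio.diversity.alpha import ace, chao1

        tbl = alpha_diversity(multinomial_table)
        for sid in multinomial_table.sample_ids[:5]:
            c = multinomial_table.data.loc[sid].to_numpy()
            assert tbl.loc[sid, "ace"] == pytest.approx(ace(c), rel=1e-9)
            assert tbl.loc[sid, "chao1"] == pytest.approx(chao1(c), rel=1e-9)


class TestFaithPD:
    @pytest.fixture
    def four_tip_tree(self):
        return TreeNode.read(["((a:1,b:2):0.5,(c:1.5,d:0.5):1):0;"])

    def test_all_tips_observed_sums_all_branches(self, four_tip_tree):
        ct = _table([[1, 1, 1, 1]], taxon_ids=list("abcd"))
        assert faith_pd(ct, four_tip_tree)["s0"] == pytest.approx(6.5)

    def test_subset_spans_root_path_by_default(self, four_tip_tree):
        ct = _table([[1, 1, 0, 0]], taxon_ids=list("abcd"))
        # a + b + their stem to the root
        assert faith_pd(ct, four_tip_tree)["s0"] == pytest.approx(1 + 2 + 0.5)
        # without the root path only the spanned subtree counts
        assert faith_pd(ct, four_tip_tree, include_root_path=False)["s0"] == (
            pytest.approx(3.0)
        )

    def test_adding_a_taxon_never_decreases_pd(self, four_tip_tree):
        smaller = faith_pd(_table([[1, 1, 0, 0]], taxon_ids=list("abcd")), four_tip_tree)
        larger = faith_pd(_table([[1, 1, 1, 0]], taxon_ids=list("abcd")), four_tip_tree)
        assert larger["s0"] >= smaller["s0"]

    def test_missing_tip_is_named(self, four_tip_tree):
        ct = _table([[1, 1]], taxon_ids=["a", "zzz"])
        with pytest.raises(ValueError, match="zzz"):
            faith_pd(ct, four_tip_tree)


class TestBrayCurtis:
    def test_identical_samples_give_zero(self):
        dm = bray_curtis(_table([[3, 1], [6, 2]]))
        assert dm.data[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_give_one(self):
        dm = bray_curtis(_table([[3, 0], [0, 5]]))
        assert dm.data[0, 1] == pytest.approx(1.0)

    def test_hand_value(self):
        rel = pd.DataFrame([[0.5, 0.5, 0.0], [0.25, 0.25, 0.5]], index=["a", "b"])
        dm = bray_curtis(rel, relative=False)
        assert dm.data[0, 1] == pytest.approx(0.5)

    def test_bounded_symmetric_zero_diagonal(self, multinomial_table):
        d = np.asarray(bray_curtis(multinomial_table).data)
        assert (d >= 0).all() and (d <= 1 + 1e-12).all()
        np.testing.assert_allclose(d, d.T)
        np.testing.assert_allclose(np.diag(d), 0)


class TestPermanova:
    def test_f_statistic_matches_skbio(self, multinomial_table):
        from skbio.stats.distance import permanova as sk_permanova

        dm = bray_curtis(multinomial_table)
        groups = ["a"] * 15 + ["b"] * 15
        ours = permanova(dm, pd.Series(groups, index=multinomial_table.sample_ids),
                         n_perm=99, seed=0)
        ref = sk_permanova(dm, grouping=list(groups), permutations=9)
        assert ours.pseudo_F == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_separated_blobs_reach_minimal_p(self, rng):
        x = np.vstack([rng.normal(0, 0.1, (10, 4)), rng.normal(8, 0.1, (10, 4))])
        from scipy.spatial.distance import pdist, squareform
        from skbio import DistanceMatrix

        dm = DistanceMatrix(squareform(pdist(x)), ids=[str(i) for i in range(20)])
        res = permanova(dm, ["a"] * 10 + ["b"] * 10, n_perm=199, seed=1)
        assert res.p == pytest.approx(1 / 200)
        assert res.R2 > 0.9

    def test_r2_plus_residual_is_one(self, multinomial_table):
        dm = bray_curtis(multinomial_table)
        res = permanova(dm, ["a"] * 15 + ["b"] * 15, n_perm=49, seed=0)
        assert 0 <= res.R2 <= 1

    def test_degenerate_grouping_rejected(self, multinomial_table):
        dm = bray_curtis(multinomial_table)
        with pytest.raises(ValueError):
            permanova(dm, ["a"] * 29 + ["b"], n_perm=49, seed=0)


class TestPermdisp:
    def test_inflated_group_dispersion_detected(self, rng):
        base = rng.normal(0, 1, (15, 3))
        x = np.vstack([base, base * 4 + rng.normal(0, 0.1, (15, 3))])
        from scipy.spatial.distance import pdist, squareform
        from skbio import DistanceMatrix

        dm = DistanceMatrix(squareform(pdist(x)), ids=[str(i) for i in range(30)])
        res = permdisp(dm, ["a"] * 15 + ["b"] * 15, n_perm=199, seed=2)
        assert res["p"] < 0.05

    def test_single_axis_equal_spreads_gives_tiny_f(self):
        # two groups on a line, mirrored spreads -> identical dispersion
        x = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        from scipy.spatial.distance import pdist, squareform
        from skbio import DistanceMatrix

        dm = DistanceMatrix(squareform(pdist(x)), ids=list("abcdef"))
        res = permdisp(dm, ["g1"] * 3 + ["g2"] * 3, n_perm=99, seed=0)
        assert res["F"] == pytest.approx(0.0, abs=1e-9)


class TestUpset:
    def test_disjoint_groups_share_nothing(self):
        ct = _table([[1, 0], [1, 0], [0, 1], [0, 1]])
        cells = upset_partition(ct, ["a", "a", "b", "b"])
        assert ("a", "b") not in cells
        assert cells[("a",)]["count"] == 1 and cells[("b",)]["count"] == 1

    def test_identical_groups_fully_shared(self):
        ct = _table([[1, 2], [1, 2], [1, 2], [1, 2]])
        cells = upset_partition(ct, ["a", "a", "b", "b"])
        assert cells == {("a", "b"): {"count": 2, "fraction": 1.0}}

    def test_six_taxon_hand_enumeration(self):
        # membership by hand: t0 both, t1 a-only, t2 b-only, t3 both,
        # t4 a-only, t5 b-only
        ct = _table(
            [
                [1, 1, 0, 2, 3, 0],
                [1, 0, 0, 1, 0, 0],
                [2, 0, 1, 1, 0, 0],
                [1, 0, 0, 3, 0, 2],
            ]
        )
        cells = upset_partition(ct, ["a", "a", "b", "b"])
        assert cells[("a", "b")]["count"] == 2
        assert cells[("a",)]["count"] == 2
        assert cells[("b",)]["count"] == 2
        assert sum(c["count"] for c in cells.values()) == 6


class TestCompareGroups:
    def test_identical_groups_are_not_significant(self):
        vals = pd.DataFrame({"v": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]},
                            index=[f"s{i}" for i in range(6)])
        res = compare_groups(vals, ["a"] * 3 + ["b"] * 3)
        assert res.loc["v", "p"] > 0.9

    def test_bh_adjustment_hand_case(self):
        # BH on p = [0.01, 0.02, 0.03, 0.04] gives q = 0.04 for all
        rng = np.random.default_rng(0)
        from statsmodels.stats.multitest import multipletests

        q = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(q, 0.04)
        # and our wrapper applies the same correction across columns
        vals = pd.DataFrame(
            rng.normal(size=(10, 4)), index=[f"s{i}" for i in range(10)]
        )
        res = compare_groups(vals, ["a"] * 5 + ["b"] * 5)
        assert "q" in res.columns and (res["q"] >= res["p"] - 1e-12).all()

    def test_large_shift_is_detected(self, rng):
        vals = pd.DataFrame(
            {"v": np.concatenate([rng.normal(0, 1, 20), rng.normal(6, 1, 20)])},
            index=[f"s{i}" for i in range(40)],
        )
        res = compare_groups(vals, ["a"] * 20 + ["b"] * 20)
        assert res.loc["v", "p"] < 1e-3
        res_t = compare_groups(vals, ["a"] * 20 + ["b"] * 20, test="t")
        assert res_t.loc["v", "p"] < 1e-3


class TestRarefy:
    def test_depth_equalized_and_counts_bounded(self, multinomial_table):
        out = rarefy(multinomial_table, 500, seed=0)
        assert (out.totals() == 500).all()
        assert (out.data.to_numpy() <= multinomial_table.data.to_numpy()).all()
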