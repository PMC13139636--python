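import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from enterostrat import (
    CountTable,
    NeutralSimSpec,
    beta_mntd,
    beta_mntd_matrix,
    beta_nti,
    classify_processes,
    fit_ncm,
    raup_crick_bray,
    simulate_neutral_communities,
    simulate_yule_tree,
)
from enterostrat.assembly import ncm_predicted_freq


def _ct(arr, taxon_ids=None):
    arr = np.asarray(arr)
    return CountTable(
        pd.DataFrame(
            arr,
            index=[f"s{i}" for i in range(arr.shape[0])],
            columns=taxon_ids or [f"t{j}" for j in range(arr.shape[1])],
        )
    )


@pytest.fixture(scope="module")
def neutral_table():
    rng = np.random.default_rng(2)
    w = rng.lognormal(0, 1.5, 200)
    spec = NeutralSimSpec(w / w.sum(), local_size=1000, migration=0.1,
                          n_samples=40, reads_per_sample=1000, seed=3)
    return simulate_neutral_communities(spec)


class TestNcm:
    def test_fit_minimizes_sse_against_grid_search(self, neutral_table):
        fit = fit_ncm(neutral_table)
        p = fit.table["mean_relabund"].to_numpy()
        occ = fit.table["occ_freq"].to_numpy()

        def sse(m):
            return ((occ - ncm_predicted_freq(p, fit.N, m)) ** 2).sum()

        grid = np.linspace(max(fit.m - 0.05, 1e-4), min(fit.m + 0.05, 1.0), 201)
        assert sse(fit.m) <= min(sse(m) for m in grid) + 1e-9

    def test_nm_identity_and_r2_bounds(self, neutral_table):
        fit = fit_ncm(neutral_table)
        assert fit.Nm == pytest.approx(fit.N * fit.m)
        assert fit.r2 <= 1.0

    def test_ubiquitous_taxon_predicted_near_one_and_within(self, neutral_table):
        fit = fit_ncm(neutral_table)
        top = fit.table["mean_relabund"].idxmax()
        assert fit.table.loc[top, "predicted_freq"] > 0.99
        assert fit.table.loc[top, "partition"] == "within"

    def test_selection_structured_data_fits_worse_than_neutral(self):
        rng = np.random.default_rng(4)
        tree = simulate_yule_tree(150, seed=5, ultrametric=True)
        from enterostrat import SelectionSimSpec, simulate_selection_communities

        sel, _ = simulate_selection_communities(
            SelectionSimSpec(tree, group_optima=(("anchor", 30),), seed=6)
        )
        w = rng.lognormal(0, 1.5, 150)
        neu = simulate_neutral_communities(
            NeutralSimSpec(w / w.sum(), local_size=1000, migration=0.1,
                           n_samples=30, reads_per_sample=1000, seed=6)
        )
        assert fit_ncm(sel).r2 < fit_ncm(neu).r2

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_ncm(_ct(np.ones((5, 10), dtype=int)))


class TestBetaMntd:
    def test_identical_communities_have_zero_turnover(self, small_tree):
        tips = [t.name for t in small_tree.tips()]
        row = np.arange(1, len(tips) + 1)
        bm = beta_mntd_matrix(_ct([row, row], taxon_ids=tips), small_tree)
        assert bm.iloc[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_two_singletons_equal_patristic_distance(self):
        tree = TreeNode.read(["(a:2.5,b:1.5):0;"])
        ct = _ct([[3, 0], [0, 7]], taxon_ids=["a", "b"])
        assert beta_mntd(ct, tree, ("s0", "s1")) == pytest.approx(4.0)

    def test_four_tip_toy_matches_hand_computation(self):
        tree = TreeNode.read(["((a:1,b:1):1,(c:1,d:1):1):0;"])
        # sample A: a=3, b=1; sample B: c=1, d=1
        ct = _ct([[3, 1, 0, 0], [0, 0, 1, 1]], taxon_ids=list("abcd"))
        # every cross-clade nearest distance is 4: 0.5*(1*4 + 1*4) = 4
        assert beta_mntd(ct, tree, ("s0", "s1")) == pytest.approx(4.0)
        # mixed membership: B holds b as well -> A's b finds itself at 0
        ct2 = _ct([[3, 1, 0, 0], [0, 1, 1, 1]], taxon_ids=list("abcd"))
        # A side: a (w .75) -> nearest in B is b at 2; b (w .25) -> 0: 1.5
        # B side: b (1/3) -> 0; c (1/3) -> 4; d (1/3) -> 4: 8/3
        expected = 0.5 * (1.5 + 8 / 3)
        assert beta_mntd(ct2, tree, ("s0", "s1")) == pytest.approx(expected)

    def test_symmetry(self, small_tree, rng):
        tips = [t.name for t in small_tree.tips()]
        arr = rng.integers(0, 5, size=(3, len(tips)))
        arr[:, 0] += 1
        bm = beta_mntd_matrix(_ct(arr, taxon_ids=tips), small_tree)
        np.testing.assert_allclose(bm.to_numpy(), bm.to_numpy().T)


class TestBetaNti:
    def test_invariant_to_taxon_column_order(self, small_tree, rng):
        tips = [t.name for t in small_tree.tips()]
        arr = rng.integers(0, 6, size=(4, len(tips)))
        arr[:, 0] += 1
        ct = _ct(arr, taxon_ids=tips)
        z1 = beta_nti(ct, small_tree, n_null=49, seed=7)
        shuffled = list(rng.permutation(tips))
        ct2 = CountTable(ct.data[shuffled])
        z2 = beta_nti(ct2, small_tree, n_null=49, seed=7)
        np.testing.assert_allclose(
            z1.to_numpy(), z2.loc[z1.index, z1.columns].to_numpy(), atol=1e-6
        )

    def test_seeded_and_deterministic(self, small_tree, rng):
        tips = [t.name for t in small_tree.tips()]
        arr = rng.integers(0, 6, size=(4, len(tips)))
        arr[:, 0] += 1
        ct = _ct(arr, taxon_ids=tips)
        z1 = beta_nti(ct, small_tree, n_null=49, seed=7)
        z2 = beta_nti(ct, small_tree, n_null=49, seed=7)
        pd.testing.assert_frame_equal(z1, z2)


class TestRaupCrick:
    def test_identical_pair_reaches_minus_one(self, rng):
        base = rng.lognormal(0, 1, 60)
        counts = np.vstack([rng.multinomial(1500, base / base.sum()) for _ in range(8)])
        counts[1] = counts[0]
        ct = _ct(counts)
        assert raup_crick_bray(ct, ("s0", "s1"), n_null=199, seed=0) == -1.0

    def test_disjoint_extreme_pair_reaches_plus_one(self, rng):
        counts = rng.integers(1, 20, size=(8, 40))
        counts[0, 20:] = 0
        counts[1, :20] = 0
        ct = _ct(counts)
        assert raup_crick_bray(ct, ("s0", "s1"), n_null=199, seed=0) == 1.0

    def test_value_consistent_between_single_and_matrix_paths(self, rng):
        from enterostrat import raup_crick_matrix

        counts = rng.integers(0, 20, size=(6, 30)) + 1
        ct = _ct(counts)
        m = raup_crick_matrix(ct, n_null=99, seed=5)
        single = raup_crick_bray(ct, ("s1", "s3"), n_null=99, seed=5)
        assert m.loc["s1", "s3"] == pytest.approx(single)


class TestClassifyProcesses:
    def _pairs(self, values):
        ids = [f"s{i}" for i in range(len(values) + 1)]
        bnti = pd.DataFrame(0.0, index=ids, columns=ids)
        rc = pd.DataFrame(0.0, index=ids, columns=ids)
        for k, (z, r) in enumerate(values):
            bnti.iloc[0, k + 1] = bnti.iloc[k + 1, 0] = z
            rc.iloc[0, k + 1] = rc.iloc[k + 1, 0] = r
        return bnti, rc

    @pytest.mark.parametrize(
        "z,r,expected",
        [
            (-2.5, 0.3, "homogeneous_selection"),
            (2.5, 0.3, "heterogeneous_selection"),
            (0.5, 0.97, "dispersal_limitation"),
            (0.5, -0.97, "homogenizing_dispersal"),
            (0.0, 0.0, "drift"),
            # exact boundaries fall through to drift (strict inequalities)
            (-2.0, 0.0, "drift"),
            (2.0, 0.99, "drift"),
            (0.0, 0.95, "drift"),
            (0.0, -0.95, "drift"),
        ],
    )
    def test_threshold_map(self, z, r, expected):
        from enterostrat.assembly import _classify_one

        assert _classify_one(z, r) == expected

    def test_fractions_partition_all_pairs(self, rng):
        ids = [f"s{i}" for i in range(6)]
        z = rng.normal(0, 3, (6, 6))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0)
        r = np.clip(rng.normal(0, 1, (6, 6)), -1, 1)
        r = (r + r.T) / 2
        np.fill_diagonal(r, 0)
        res = classify_processes(
            pd.DataFrame(z, index=ids, columns=ids),
            pd.DataFrame(r, index=ids, columns=ids),
        )
        assert len(res.pairs) == 15
        assert sum(res.fractions.values()) == pytest.approx(1.0, abs=1e-9)
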