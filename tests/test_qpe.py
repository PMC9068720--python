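"""betaMNTD/betaNTI/RC_bray and the five-way process classification."""

import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from assemblage.io_core import CountTable, patristic_distances
from assemblage.qpe import (PROCESSES, beta_mntd, beta_nti, classify_pair,
                            process_percentages, qpe_analysis,
                            raup_crick_bray)


def brute_force_beta_mntd(p1, p2, dmat):
    """Independent oracle: explicit loops over present taxa."""
    idx1 = [i for i, v in enumerate(p1) if v > 0]
    idx2 = [j for j, v in enumerate(p2) if v > 0]
    d12 = sum(p1[i] * min(dmat[i][j] for j in idx2) for i in idx1)
    d21 = sum(p2[j] * min(dmat[j][i] for i in idx1) for j in idx2)
    return 0.5 * (d12 + d21)


class TestBetaMntd:
    def test_single_taxon_pair_is_patristic_distance(self, four_tip_tree):
        d = beta_mntd([1, 0, 0, 0], [0, 0, 1, 0], four_tip_tree,
                      otu_ids=list("ABCD"))
        assert d == pytest.approx(4.0)

    def test_identical_communities_give_zero(self, four_tip_tree):
        assert beta_mntd([0.5, 0.5, 0, 0], [0.5, 0.5, 0, 0], four_tip_tree,
                         otu_ids=list("ABCD")) == pytest.approx(0.0)

    def test_matches_brute_force_on_enumerated_abundance_grids(self):
        trees = [TreeNode.read(["((A:1,B:1):1,(C:1,D:1):1);"]),
                 TreeNode.read(["((A:1,B:2):0.5,((C:1,D:3):1,E:2):0.5);"])]
        grid = [0.0, 0.25, 0.5, 1.0]
        for tree in trees:
            otus = [t.name for t in tree.tips()]
            dmat = patristic_distances(tree, otus)
            n = len(otus)
            combos = [c for c in itertools.product(grid, repeat=n)
                      if abs(sum(c) - 1.0) < 1e-9]
            for p1 in combos[::3]:
                for p2 in combos[::4]:
                    got = beta_mntd(np.array(p1), np.array(p2), dmat=dmat)
                    want = brute_force_beta_mntd(p1, p2, dmat.tolist())
                    assert got == pytest.approx(want, abs=1e-12)

    def test_empty_community_rejected(self, four_tip_tree):
        with pytest.raises(ValueError):
            beta_mntd([0, 0, 0, 0], [1, 0, 0, 0], four_tip_tree,
                      otu_ids=list("ABCD"))


class TestBetaNti:
    def test_exhaustive_null_matches_independent_enumeration(self,
                                                             four_tip_tree):
        otus = list("ABCD")
        dmat = patristic_distances(four_tip_tree, otus)
        p1 = np.array([0.7, 0.0, 0.3, 0.0])
        p2 = np.array([0.0, 0.5, 0.0, 0.5])
        got = beta_nti(p1, p2, dmat=dmat, exhaustive=True)
        obs = brute_force_beta_mntd(p1, p2, dmat.tolist())
        null = []
        for perm in itertools.permutations(range(4)):
            pd_ = dmat[np.ix_(perm, perm)]
            null.append(brute_force_beta_mntd(p1, p2, pd_.tolist()))
        null = np.array(null)
        want = (obs - null.mean()) / null.std(ddof=1)
        assert got == pytest.approx(want, abs=1e-12)

    def test_star_tree_is_degenerate(self):
        star = TreeNode.read(["(A:1,B:1,C:1,D:1);"])
        v = beta_nti([0.5, 0.5, 0, 0], [0, 0, 0.5, 0.5], star,
                     otu_ids=list("ABCD"), n_iter=49)
        assert np.isnan(v)

    def test_sampled_null_approaches_exhaustive(self, four_tip_tree):
        otus = list("ABCD")
        dmat = patristic_distances(four_tip_tree, otus)
        p1 = np.array([0.7, 0.0, 0.3, 0.0])
        p2 = np.array([0.0, 0.5, 0.0, 0.5])
        exact = beta_nti(p1, p2, dmat=dmat, exhaustive=True)
        sampled = beta_nti(p1, p2, dmat=dmat, n_iter=999, seed=0)
        assert sampled == pytest.approx(exact, abs=0.4)


@pytest.fixture(scope="module")
def rc_table():
    """12 samples sharing a common core + 2 disjoint-membership outliers."""
    rng = np.random.default_rng(8)
    core = rng.integers(20, 60, size=(10, 10))
    rows = np.zeros((12, 20), dtype=int)
    rows[:10, :10] = core
    rows[10, 10:15] = 200
    rows[11, 15:20] = 200
    return CountTable(pd.DataFrame(
        rows, index=[f"s{i}" for i in range(12)],
        columns=[f"o{i}" for i in range(20)]))


class _FixedKernel:
    """Stub null model emitting a predetermined sequence of null samples."""

    def __init__(self, samples_a, samples_b):
        self._queue = [np.asarray(samples_a), np.asarray(samples_b)]

    def null_like(self, counts, n, rng):
        out = self._queue.pop(0)
        assert len(out) == n
        return out


class TestRaupCrick:
    def test_obs_above_all_nulls_is_plus_one(self, rc_table):
        # formula boundary: every null pair identical (BC=0), observed pair
        # disjoint (BC=1)
        base = np.zeros((4, 20), dtype=int)
        base[:, 0] = 100
        kernel = _FixedKernel(base, base.copy())
        c = rc_table.counts
        rc = raup_crick_bray(c[10], c[11], rc_table, n_iter=4, kernel=kernel,
                             rng=np.random.default_rng(0))
        assert rc == pytest.approx(1.0)

    def test_obs_at_exact_null_median_is_zero(self, rc_table):
        # two null pairs below the observed BC and two above it
        a = np.zeros((4, 20), dtype=int)
        b = np.zeros((4, 20), dtype=int)
        a[:, 0] = 100
        b[:2, 0] = 100          # pairs 0,1: identical -> BC 0
        b[2:, 1] = 100          # pairs 2,3: disjoint -> BC 1
        kernel = _FixedKernel(a, b)
        s1 = np.array([100] + [0] * 19)
        s2 = np.array([50, 50] + [0] * 18)   # obs BC = 0.5
        rc = raup_crick_bray(s1, s2, rc_table, n_iter=4, kernel=kernel,
                             rng=np.random.default_rng(0))
        assert rc == pytest.approx(0.0)

    def test_disjoint_outliers_read_as_dispersal_limited(self, rc_table):
        # the two outliers are completely dissimilar (BC=1) while nulls are
        # built from the common core occupancy: obs beats nearly every null
        c = rc_table.counts
        rc = raup_crick_bray(c[10], c[11], rc_table, n_iter=199, seed=2)
        assert rc >= 0.95

    def test_identical_common_pair_is_strongly_negative(self, rc_table):
        c = rc_table.counts
        rc = raup_crick_bray(c[0], c[0].copy(), rc_table, n_iter=199, seed=2)
        assert rc <= -0.95

    def test_bounds_on_random_pairs(self, rc_table, rng):
        c = rc_table.counts
        for _ in range(10):
            i, j = rng.choice(10, 2, replace=False)
            rc = raup_crick_bray(c[i], c[j], rc_table, n_iter=49, seed=3)
            assert -1.0 <= rc <= 1.0

    def test_iteration_domain(self, rc_table):
        c = rc_table.counts
        with pytest.raises(ValueError):
            raup_crick_bray(c[0], c[1], rc_table, n_iter=0)


class TestClassification:
    @pytest.mark.parametrize("bnti,rc,label", [
        (2.5, None, "variable_selection"),
        (-2.5, None, "homogeneous_selection"),
        (0.3, 0.99, "dispersal_limitation"),
        (0.3, -0.99, "homogenizing_dispersal"),
        (0.3, 0.0, "undominated"),
        (1.99, 0.95, "undominated"),   # boundary: strictly greater
        (-2.0, -0.95, "undominated"),  # boundary: strictly less
    ])
    def test_decision_tree(self, bnti, rc, label):
        assert classify_pair(bnti, rc) == label

    def test_rc_required_in_the_middle(self):
        with pytest.raises(ValueError):
            classify_pair(0.5, None)
        with pytest.raises(ValueError):
            classify_pair(float("nan"), 0.0)

    def test_percentages_count_and_sum(self, rng):
        df = pd.DataFrame({
            "group": ["g1"] * 4,
            "process": ["dispersal_limitation", "dispersal_limitation",
                        "undominated", "variable_selection"]})
        out = process_percentages(df)
        assert out.loc["g1", "dispersal_limitation"] == pytest.approx(50.0)
        assert out.loc["g1", "undominated"] == pytest.approx(25.0)
        assert out.loc["g1", "homogeneous_selection"] == 0.0
        # random label sets always sum to 100
        labels = rng.choice(PROCESSES, size=30)
        df2 = pd.DataFrame({"group": ["a"] * 15 + ["b"] * 15,
                            "process": labels})
        assert process_percentages(df2).sum(axis=1).tolist() == \
            pytest.approx([100.0, 100.0])


class TestQpeAnalysis:
    def test_within_vs_cross_group_pair_sets(self, small_table):
        from assemblage.simulate import simulate_tree

        tree = simulate_tree(5, seed=2)
        tab = CountTable(pd.DataFrame(
            small_table.counts, index=small_table.sample_ids,
            columns=[t.name for t in tree.tips()]))
        groups = pd.Series(["a", "a", "a", "b", "b", "b"],
                           index=tab.sample_ids)
        within = qpe_analysis(tab, tree, groups, n_iter=49, seed=1)
        cross = qpe_analysis(tab, tree, groups, n_iter=49, seed=1,
                             cross_group=True)
        assert len(within) == 6   # 2 groups x C(3,2)
        assert len(cross) == 9    # 3 x 3
        assert set(within["group"]) == {"a", "b"}
        assert set(cross["group"]) == {"a|b"}
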