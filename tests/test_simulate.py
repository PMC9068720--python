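"""Ground-truth generators: determinism, conservation, planted structure."""

import numpy as np
import pandas as pd
import pytest

from assemblage.io_core import patristic_distances
from assemblage.simulate import (SimConfig, plant_lottery_clades,
                                 simulate_community_series,
                                 simulate_genome_functions,
                                 simulate_metacommunity,
                                 simulate_recruitment_series,
                                 simulate_taxonomy, simulate_tree)


class TestTree:
    def test_ultrametric_and_deterministic(self):
        t1 = simulate_tree(20, 1.0, 0.2, seed=7)
        t2 = simulate_tree(20, 1.0, 0.2, seed=7)
        assert str(t1) == str(t2)
        depths = [t1.distance(tip) for tip in t1.tips()]
        assert max(depths) - min(depths) < 1e-9

    def test_total_branch_length_exceeds_depth(self):
        tree = simulate_tree(50, 1.0, 0.0, seed=11)
        total = sum(n.length for n in tree.traverse(include_self=False))
        depth = max(tree.distance(t) for t in tree.tips())
        assert total > depth

    def test_parameter_domain(self):
        with pytest.raises(ValueError):
            simulate_tree(2, 1.0, 0.0, seed=1)
        with pytest.raises(ValueError):
            simulate_tree(5, 0.5, 0.5, seed=1)


class TestMetacommunity:
    def test_sigma_zero_is_uniform(self):
        tree = simulate_tree(10, seed=1)
        mc = simulate_metacommunity(tree, sigma=0.0, seed=2)
        np.testing.assert_allclose(mc.to_numpy(), 0.1)

    def test_sums_to_one_and_skewed_when_sigma_large(self):
        tree = simulate_tree(40, seed=1)
        ratios = []
        for seed in range(6):
            mc = simulate_metacommunity(tree, sigma=1.5, seed=seed)
            assert mc.sum() == pytest.approx(1.0, abs=1e-12)
            ratios.append(mc.max() / mc.min())
        assert np.mean(ratios) > 10


class TestCommunitySeries:
    @pytest.fixture(scope="class")
    def tree_meta(self):
        tree = simulate_tree(60, seed=3)
        return tree, simulate_metacommunity(tree, 1.2, seed=3)

    def test_deterministic_and_conserves_library_size(self, tree_meta):
        tree, mc = tree_meta
        cfg = SimConfig(seed=5, n_otus=60, n_groups=2, n_samples=3,
                        library_size=500, regime="neutral")
        t1, m1, _ = simulate_community_series(tree, mc, cfg)
        t2, _, _ = simulate_community_series(tree, mc, cfg)
        pd.testing.assert_frame_equal(t1.data, t2.data)
        assert (t1.data.sum(axis=1) == 500).all()
        assert m1.loc[t1.sample_ids, "group"].nunique() == 2

    def test_zero_selection_strength_equals_neutral_regime(self, tree_meta):
        tree, mc = tree_meta
        shared = dict(seed=9, n_otus=60, n_groups=2, n_samples=2,
                      migration_rate=0.4, community_size=400, n_generations=20)
        sel, _, _ = simulate_community_series(
            tree, mc, SimConfig(regime="homogeneous_selection",
                                selection_strength=0.0, **shared))
        neu, _, _ = simulate_community_series(
            tree, mc, SimConfig(regime="neutral", **shared))
        pd.testing.assert_frame_equal(sel.data, neu.data)

    def test_full_migration_tracks_metacommunity(self, tree_meta):
        # one generation at m=1 makes offspring probabilities equal the
        # metacommunity; the mean composition over samples recovers it
        tree, mc = tree_meta
        cfg = SimConfig(seed=2, n_otus=60, n_groups=1, n_samples=40,
                        migration_rate=1.0, n_generations=1,
                        community_size=2000, library_size=2000,
                        regime="neutral", founder_sigma=0.0)
        tab, _, _ = simulate_community_series(tree, mc, cfg)
        mean_rel = tab.relative().mean(axis=0)
        assert np.abs(mean_rel - mc.reindex(mean_rel.index)).max() < 0.03

    def test_dispersal_limitation_is_more_divergent_than_neutral(self, tree_meta):
        from scipy.spatial.distance import pdist

        tree, mc = tree_meta
        div = {}
        for regime in ("dispersal_limited", "neutral"):
            vals = []
            for seed in range(5):
                cfg = SimConfig(seed=seed, n_otus=60, n_groups=1, n_samples=6,
                                regime=regime, migration_rate=None)
                tab, _, _ = simulate_community_series(tree, mc, cfg)
                vals.append(pdist(tab.relative().to_numpy(), "braycurtis").mean())
            div[regime] = np.mean(vals)
        assert div["dispersal_limited"] > div["neutral"]


class TestLotteryPlanting:
    @pytest.fixture(scope="class")
    def planted(self):
        tree = simulate_tree(30, seed=4)
        mc = simulate_metacommunity(tree, 0.8, seed=4)
        cfg = SimConfig(seed=6, n_otus=30, n_groups=1, n_samples=20,
                        regime="neutral", library_size=3000)
        table, meta, _ = simulate_community_series(tree, mc, cfg)
        tax = simulate_taxonomy(tree, genus_size=3)
        return table, tax

    def test_fixed_winner_same_otu_everywhere(self, planted):
        table, tax = planted
        out, truth = plant_lottery_clades(table, tax, n_clades=2, clade_size=3,
                                          winner_mode="fixed", seed=1)
        for clade in truth.lottery_clades.values():
            winners = set(clade["winners"].values())
            assert winners == {clade["fixed_winner"]}

    def test_winner_share_exceeds_95_percent(self, planted):
        table, tax = planted
        out, truth = plant_lottery_clades(table, tax, n_clades=2, clade_size=3,
                                          winner_mode="fixed", seed=1)
        rel = out.relative()
        for clade in truth.lottery_clades.values():
            for sid, winner in clade["winners"].items():
                tot = rel.loc[sid, clade["members"]].sum()
                assert rel.loc[sid, winner] / tot > 0.95

    def test_random_winners_split_roughly_evenly(self, planted):
        table, tax = planted
        out, truth = plant_lottery_clades(table, tax, n_clades=1, clade_size=2,
                                          winner_mode="per_sample_random",
                                          seed=3)
        clade = next(iter(truth.lottery_clades.values()))
        wins = pd.Series(list(clade["winners"].values())).value_counts()
        n = wins.sum()
        # binomial check: each of 2 members wins ~half of the samples
        assert wins.max() <= n - 1
        assert abs(wins.iloc[0] / n - 0.5) < 0.35


class TestRecruitmentSeries:
    @pytest.fixture(scope="class")
    def tree(self):
        return simulate_tree(60, seed=8)

    def test_deterministic_and_counts(self, tree):
        s1, g1 = simulate_recruitment_series(tree, 1.0, 5, 6, seed=2)
        s2, _ = simulate_recruitment_series(tree, 1.0, 5, 6, seed=2)
        assert s1 == s2
        assert all(len(new) == 6 for _, new in s1)
        all_taxa = set().union(*(new for _, new in s1))
        assert len(all_taxa) == 30  # no taxon recruited twice

    def test_pool_exhaustion_raises(self, tree):
        with pytest.raises(ValueError, match="pool exhausted"):
            simulate_recruitment_series(tree, 0.0, 10, 10, seed=1)

    def test_dispersion_sign_shifts_cross_clade_recruitment(self, tree):
        # on a two-clade tree, D>0 recruits the opposite clade earlier than
        # D=0, and D<0 later (median first-crossing rank over replicates)
        otus = [t.name for t in tree.tips()]
        dmat = patristic_distances(tree, otus)
        left = {t.name for t in tree.children[0].tips()}
        ranks = {}
        for d in (-2.0, 0.0, 2.0):
            rs = []
            for seed in range(40):
                series, truth = simulate_recruitment_series(tree, d, 6, 8,
                                                            seed=seed)
                order = truth.extra["order"]
                start_left = order[0] in left
                for rank, otu in enumerate(order):
                    if (otu in left) != start_left:
                        rs.append(rank)
                        break
            ranks[d] = np.median(rs)
        assert ranks[2.0] <= ranks[0.0] <= ranks[-2.0]
        assert ranks[2.0] < ranks[-2.0]


class TestGenomeFunctions:
    def test_identical_option_gives_zero_dissimilarity(self):
        funcs, truth = simulate_genome_functions([f"o{i}" for i in range(5)],
                                                 20, "high", 0.2, seed=1,
                                                 identical=True)
        v = funcs.to_numpy()
        sim = v @ v.T
        norms = np.linalg.norm(v, axis=1)
        np.testing.assert_allclose(sim / np.outer(norms, norms), 1.0)
        assert truth.redundancy == "identical"

    def test_redundancy_orders_mean_cosine_dissimilarity(self):
        def mean_dis(level):
            vals = []
            for seed in range(10):
                funcs, _ = simulate_genome_functions(
                    [f"o{i}" for i in range(12)], 40, level, 0.3, seed=seed)
                v = funcs.to_numpy()
                norms = np.linalg.norm(v, axis=1)
                sim = (v @ v.T) / np.outer(norms, norms)
                iu = np.triu_indices(len(v), 1)
                vals.append(1 - sim[iu].mean())
            return np.mean(vals)

        low, mid, high = (mean_dis(k) for k in ("low", "mid", "high"))
        assert low > mid > high

    def test_every_genome_has_a_function(self):
        funcs, _ = simulate_genome_functions([f"o{i}" for i in range(30)],
                                             10, "low", 0.3, seed=2)
        assert (funcs.sum(axis=1) > 0).all()
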