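"""Taxa-function robustness: shifts, power-law fit, GDFs, ordination."""

import numpy as np
import pandas as pd
import pytest

from assemblage.io_core import CountTable
from assemblage.robustness import (community_function_profile,
                                   fit_robustness, functional_shift,
                                   gdf_ordination,
                                   gene_distribution_features,
                                   perturb_sample, robustness_profile,
                                   taxonomic_shift)
from assemblage.simulate import (simulate_genome_functions, simulate_tree)


class TestFunctionProfile:
    def test_weighted_sum_matches_brute_force(self, rng):
        funcs = pd.DataFrame(rng.random((5, 4)),
                             index=[f"o{i}" for i in range(5)],
                             columns=[f"k{i}" for i in range(4)])
        p = rng.dirichlet(np.ones(5))
        got = community_function_profile(p, funcs)
        want = [sum(p[s] * funcs.iloc[s, k] for s in range(5))
                for k in range(4)]
        np.testing.assert_allclose(got, want)

    def test_single_and_even_mixtures(self):
        funcs = pd.DataFrame([[1.0, 2.0], [3.0, 0.0]], index=["a", "b"],
                             columns=["k1", "k2"])
        np.testing.assert_allclose(
            community_function_profile([1.0, 0.0], funcs), [1.0, 2.0])
        np.testing.assert_allclose(
            community_function_profile([0.5, 0.5], funcs), [2.0, 1.0])


class TestPerturbation:
    def test_sums_to_one_and_support_shrinks(self, rng):
        p = rng.dirichlet(np.ones(8))
        pert = perturb_sample(p, n_perturbations=50, rng=rng)
        np.testing.assert_allclose(pert.sum(axis=1), 1.0, atol=1e-12)
        assert ((pert > 0).sum(axis=1) < 8).all()
        assert ((pert > 0).sum(axis=1) >= 1).all()

    def test_two_taxon_removal_leaves_single_survivor(self):
        pert = perturb_sample([0.5, 0.5], n_perturbations=10, seed=3)
        assert set(pert.max(axis=1)) == {1.0}

    def test_needs_two_taxa(self):
        with pytest.raises(ValueError):
            perturb_sample([1.0, 0.0], n_perturbations=5, seed=1)


class TestShifts:
    def test_taxonomic_shift_zero_for_noop_and_tree_aware(self, four_tip_tree):
        p = np.array([0.4, 0.1, 0.4, 0.1])
        assert taxonomic_shift(p, p, four_tip_tree,
                               otu_ids=list("ABCD")) == pytest.approx(0.0)
        # removing mass on the far subtree shifts more than a close relative
        drop_far = np.array([0.4, 0.1, 0.0, 0.1])
        drop_near = np.array([0.4, 0.0, 0.4, 0.1])
        far = taxonomic_shift(p, drop_far / drop_far.sum(), four_tip_tree,
                              otu_ids=list("ABCD"))
        near = taxonomic_shift(p, drop_near / drop_near.sum(), four_tip_tree,
                               otu_ids=list("ABCD"))
        assert far > near

    def test_functional_shift_anchors_and_scale_invariance(self):
        v = np.array([1.0, 2.0, 0.0])
        assert functional_shift(v, v) == pytest.approx(0.0)
        assert functional_shift([1, 0], [0, 1]) == pytest.approx(1.0)
        w = np.array([0.5, 0.1, 3.0])
        assert functional_shift(v, w) == pytest.approx(
            functional_shift(v * 7.3, w * 0.2))
        with pytest.raises(ValueError):
            functional_shift(v, [0.0, 0.0, 0.0])


class TestFit:
    def test_identity_line(self):
        t = np.linspace(0.05, 0.9, 12)
        a, b, diag = fit_robustness(np.column_stack([t, t]))
        assert a == pytest.approx(0.0, abs=1e-12)
        assert b == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_power_law(self):
        t = np.linspace(0.05, 0.9, 20)
        f = t ** 2 * np.exp(-3.0)
        a, b, diag = fit_robustness(np.column_stack([t, f]))
        assert a == pytest.approx(3.0, abs=1e-10)
        assert b == pytest.approx(2.0, abs=1e-10)
        assert diag["r_squared"] == pytest.approx(1.0)

    def test_degenerate_when_function_profile_never_moves(self):
        t = np.linspace(0.1, 0.9, 10)
        f = np.zeros(10)
        a, b, diag = fit_robustness(np.column_stack([t, f]))
        assert diag["degenerate"]
        assert np.isinf(a)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_robustness([(0.5, 0.1)] * 4)


class TestGdf:
    def test_identical_genomes(self):
        funcs = pd.DataFrame(np.tile([1.0, 2.0, 0.0, 1.0], (3, 1)),
                             index=list("xyz"), columns=list("KLMN"))
        g = gene_distribution_features([0.5, 0.3, 0.2], funcs)
        assert g["genome_size_variability"] == pytest.approx(0.0)
        assert g["avg_functional_dissimilarity"] == pytest.approx(0.0)
        assert g["unique_function_abundance"] == pytest.approx(0.0)

    def test_disjoint_single_function_genomes(self):
        funcs = pd.DataFrame(np.eye(3), index=list("xyz"), columns=list("KLM"))
        g = gene_distribution_features([0.5, 0.3, 0.2], funcs)
        assert g["avg_functional_dissimilarity"] == pytest.approx(1.0)
        assert g["avg_functional_redundancy"] == pytest.approx(1.0)
        assert g["unique_function_abundance"] == pytest.approx(1.0)

    def test_matches_brute_force_on_random_instance(self, rng):
        funcs = pd.DataFrame(rng.integers(0, 3, size=(4, 6)).astype(float),
                             index=[f"o{i}" for i in range(4)],
                             columns=[f"k{i}" for i in range(6)])
        funcs.iloc[0, 0] += 1  # ensure no empty genome
        p = rng.dirichlet(np.ones(4))
        g = gene_distribution_features(p, funcs)
        V = funcs.to_numpy()
        w = p / p.sum()
        sizes = V.sum(axis=1)
        assert g["avg_genome_size"] == pytest.approx(float(w @ sizes))
        mean = float(w @ sizes)
        assert g["genome_size_variability"] == pytest.approx(
            np.sqrt(float(w @ (sizes - mean) ** 2)))
        # brute-force pairwise cosine dissimilarity
        num = den = 0.0
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                cos = V[i] @ V[j] / (np.linalg.norm(V[i]) * np.linalg.norm(V[j]))
                num += w[i] * w[j] * (1 - cos)
                den += w[i] * w[j]
        assert g["avg_functional_dissimilarity"] == pytest.approx(num / den)

    def test_single_taxon_dissimilarity_missing(self):
        funcs = pd.DataFrame([[1.0, 2.0]], index=["a"], columns=["k1", "k2"])
        g = gene_distribution_features([1.0], funcs)
        assert np.isnan(g["avg_functional_dissimilarity"])


class TestProfileAndCategories:
    @pytest.fixture(scope="class")
    def dataset(self):
        tree = simulate_tree(12, seed=44)
        otus = [t.name for t in tree.tips()]
        rng = np.random.default_rng(44)
        counts = rng.integers(5, 60, size=(4, 12))
        table = CountTable(pd.DataFrame(
            counts, index=[f"s{i}" for i in range(4)], columns=otus))
        funcs, _ = simulate_genome_functions(otus, 30, "mid", 0.3, seed=44)
        return table, tree, funcs

    def test_profile_is_seed_reproducible(self, dataset):
        table, tree, funcs = dataset
        p1 = robustness_profile(table, tree, funcs, n_perturbations=40, seed=5)
        p2 = robustness_profile(table, tree, funcs, n_perturbations=40, seed=5)
        pd.testing.assert_frame_equal(p1.samples, p2.samples)

    def test_copy_number_rescaling_leaves_coefficients_unchanged(self, dataset):
        table, tree, funcs = dataset
        p1 = robustness_profile(table, tree, funcs, n_perturbations=40, seed=5)
        p2 = robustness_profile(table, tree, funcs * 13.7,
                                n_perturbations=40, seed=5)
        np.testing.assert_allclose(p1.samples["a"], p2.samples["a"])
        np.testing.assert_allclose(p1.samples["b"], p2.samples["b"])

    def test_whole_category_equals_global_fit(self, dataset):
        table, tree, funcs = dataset
        cats = {f: "all" for f in funcs.columns}
        prof = robustness_profile(table, tree, funcs, n_perturbations=40,
                                  seed=5, category_map=cats)
        merged = prof.by_category.merge(prof.samples, on="sample",
                                        suffixes=("_cat", ""))
        np.testing.assert_allclose(merged["a_cat"], merged["a"])
        np.testing.assert_allclose(merged["b_cat"], merged["b"])

    def test_attenuation_increases_with_redundancy(self):
        tree = simulate_tree(15, seed=55)
        otus = [t.name for t in tree.tips()]
        rng = np.random.default_rng(55)
        table = CountTable(pd.DataFrame(
            rng.integers(10, 80, size=(6, 15)),
            index=[f"s{i}" for i in range(6)], columns=otus))
        means = []
        for level in ("low", "mid", "high"):
            funcs, _ = simulate_genome_functions(otus, 40, level, 0.3, seed=6)
            prof = robustness_profile(table, tree, funcs,
                                      n_perturbations=60, seed=7)
            ok = prof.samples[~prof.samples.degenerate]
            means.append(ok["a"].mean())
        assert means[0] < means[1] < means[2]


class TestOrdination:
    def test_two_clusters_separate_on_axis_one(self):
        gdf = pd.DataFrame(
            [[1.0, 0.5, 0.2, 3.0, 0.1]] * 3 + [[4.0, 1.5, 0.8, 1.0, 0.6]] * 3,
            index=[f"s{i}" for i in range(6)],
            columns=list("abcde"))
        coords, loadings, pct = gdf_ordination(gdf)
        axis1 = coords.iloc[:, 0]
        assert (axis1[:3].round(6).nunique() == 1
                and axis1[3:].round(6).nunique() == 1)
        assert pct.iloc[0] == pytest.approx(100.0)

    def test_duplicate_sample_coincides_and_distances_preserved(self, rng):
        base = rng.random((5, 4))
        base = np.vstack([base, base[0]])
        gdf = pd.DataFrame(base, index=[f"s{i}" for i in range(6)],
                           columns=list("wxyz"))
        coords, _, _ = gdf_ordination(gdf)
        np.testing.assert_allclose(coords.iloc[0], coords.iloc[5], atol=1e-9)
        # full-rank embedding reproduces Euclidean distances on z-scores
        from scipy.spatial.distance import pdist

        z = (gdf - gdf.mean()) / gdf.std(ddof=0)
        np.testing.assert_allclose(pdist(coords.to_numpy()),
                                   pdist(z.to_numpy()), atol=1e-9)

    def test_constant_feature_dropped(self, rng, caplog):
        gdf = pd.DataFrame(rng.random((4, 3)), columns=list("abc"),
                           index=[f"s{i}" for i in range(4)])
        gdf["const"] = 1.0
        with caplog.at_level("WARNING", logger="assemblage"):
            coords, loadings, _ = gdf_ordination(gdf)
        assert "constant" in caplog.text
        assert "const" not in loadings.index
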