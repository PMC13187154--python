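"""Tree handling, Brownian-motion covariance, and PGLS against explicit oracles."""


import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aeroferm import comparative, simulate
from aeroferm.comparative import (
    bm_covariance,
    pearson_by_family,
    pgls_by_family,
    pgls_fit,
    prune_to_overlap,
    read_newick,
    significance_stars,
    tip_labels,
    with_total,
    write_newick,
)


def random_tree(n, seed):
    return simulate.simulate_yule_tree(n, np.random.default_rng(seed))


def gls_oracle(y, x, C):
    """GLS slope and se by explicit matrix inversion (independent route)."""
    n = len(y)
    X = np.column_stack([np.ones(n), x])
    Ci = np.linalg.inv(C)
    XtCiX_inv = np.linalg.inv(X.T @ Ci @ X)
    beta = XtCiX_inv @ X.T @ Ci @ y
    e = y - X @ beta
    sigma2 = (e @ Ci @ e) / (n - 2)
    se = np.sqrt((sigma2 * XtCiX_inv)[1, 1])
    return beta[1], se


def patristic_matrix(tree):
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(tip_labels(tree))
    taxa = {t.label: t for t in tree.taxon_namespace}
    return {
        (a, b): pdm.distance(taxa[a], taxa[b]) for a in labels for b in labels if a < b
    }


class TestNewick:
    def test_three_tip_tree_depths(self):
        tree = read_newick("((A:1,B:1):1,C:2);")
        C, labels = bm_covariance(tree)
        assert sorted(labels) == ["A", "B", "C"]
        assert np.allclose(np.diag(C), 2.0)

    def test_round_trip_preserves_structure(self):
        text = "((A:1,B:1):1,C:2);"
        again = read_newick(write_newick(read_newick(text)))
        assert patristic_matrix(read_newick(text)) == pytest.approx(
            patristic_matrix(again)
        )

    def test_random_tree_round_trips_branch_lengths(self):
        tree = random_tree(50, seed=3)
        again = read_newick(write_newick(tree))
        d0, d1 = patristic_matrix(tree), patristic_matrix(again)
        assert all(abs(d0[k] - d1[k]) < 1e-9 for k in d0)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            read_newick("((A:1,A:1):1,C:2);")

    def test_missing_branch_lengths_rejected(self):
        with pytest.raises(ValueError, match="branch length"):
            read_newick("((A:1,B):1,C:2);")

    def test_unparseable_text_rejected(self):
        with pytest.raises(ValueError, match="unparseable"):
            read_newick("((A:1,B:1;")


class TestPrune:
    def test_prune_to_all_tips_is_identity(self):
        tree = random_tree(12, seed=1)
        pruned = prune_to_overlap(tree, tip_labels(tree))
        assert patristic_matrix(tree) == pytest.approx(patristic_matrix(pruned))

    def test_collapsed_branches_sum(self):
        pruned = prune_to_overlap(read_newick("((A:1,B:1):1,C:2);"), {"A", "C"})
        C, labels = bm_covariance(pruned)
        assert sorted(labels) == ["A", "C"]
        assert np.allclose(np.diag(C), 2.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_prunes_preserve_patristic_distances(self, seed):
        tree = random_tree(20, seed=seed)
        rng = np.random.default_rng(seed)
        keep = rng.choice(tip_labels(tree), size=8, replace=False)
        pruned = prune_to_overlap(tree, keep)
        d_full = patristic_matrix(tree)
        d_sub = patristic_matrix(pruned)
        for (a, b), d in d_sub.items():
            assert d == pytest.approx(d_full[(a, b)], abs=1e-9)

    def test_empty_overlap_is_an_error(self):
        with pytest.raises(ValueError, match="no overlap"):
            prune_to_overlap(read_newick("((A:1,B:1):1,C:2);"), {"X"})


class TestBmCovariance:
    def test_cherry(self):
        C, _ = bm_covariance(read_newick("(A:0.5,B:0.5):0.5;"))
        # stem below the root contributes to every entry equally
        assert C[0, 1] == pytest.approx(C[1, 0])

    def test_cherry_with_stem_via_outgroup(self):
        C, labels = bm_covariance(read_newick("((A:0.5,B:0.5):0.5,O:1.0);"))
        i, j = labels.index("A"), labels.index("B")
        assert C[i, j] == pytest.approx(0.5)
        assert C[i, i] == pytest.approx(1.0)

    def test_star_tree_is_diagonal(self):
        C, _ = bm_covariance(read_newick("(A:1,B:1,C:1,D:1);"))
        assert np.allclose(C, np.eye(4))

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_mrca_depth_oracle(self, seed):
        tree = random_tree(14, seed=seed)
        C, labels = bm_covariance(tree)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    # depth(mrca) = (depth_i + depth_j - patristic(i,j)) / 2
                    expect = (C[i, i] + C[j, j] - pdm.distance(taxa[a], taxa[b])) / 2
                    assert C[i, j] == pytest.approx(expect, abs=1e-9)

    def test_symmetric_positive_semidefinite_on_random_trees(self):
        for seed in range(100):
            C, _ = bm_covariance(random_tree(10, seed=seed))
            assert np.allclose(C, C.T)
            assert np.linalg.eigvalsh(C).min() >= -1e-9

    def test_negative_branch_length_rejected(self):
        tree = read_newick("((A:1,B:1):1,C:2);")
        next(tree.leaf_node_iter()).edge.length = -0.1
        with pytest.raises(ValueError, match="negative"):
            bm_covariance(tree)


class TestPglsFit:
    def _data(self, n, seed, beta=0.5):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = beta * x + rng.normal(size=n)
        return y, x

    def test_identity_covariance_equals_ols(self):
        y, x = self._data(16, 0)
        fit = pgls_fit(y, x, np.eye(16))
        ols = stats.linregress(x, y)
        assert fit.beta == pytest.approx(ols.slope, abs=1e-10)
        assert fit.se == pytest.approx(ols.stderr, abs=1e-10)
        assert fit.p_value == pytest.approx(ols.pvalue, abs=1e-10)
        assert fit.r_signed == pytest.approx(ols.rvalue, abs=1e-10)

    def test_collinear_data_has_unit_signed_correlation(self):
        C, _ = bm_covariance(random_tree(8, seed=2))
        x = np.arange(8.0)
        assert pgls_fit(3 - 2 * x, x, C).r_signed == pytest.approx(-1.0)
        assert pgls_fit(1 + 2 * x, x, C).r_signed == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_explicit_inversion_oracle(self, seed):
        tree = random_tree(16, seed=seed)
        C, _ = bm_covariance(tree)
        y, x = self._data(16, seed + 100)
        fit = pgls_fit(y, x, C, lam=1.0)
        beta, se = gls_oracle(y, x, C)
        assert fit.beta == pytest.approx(beta, abs=1e-8)
        assert fit.se == pytest.approx(se, abs=1e-8)

    def test_lambda_zero_equals_weighted_ols_oracle(self):
        C, _ = bm_covariance(random_tree(16, seed=9))
        y, x = self._data(16, 9)
        fit = pgls_fit(y, x, C, lam=0.0)
        beta, se = gls_oracle(y, x, np.diag(np.diag(C)))
        assert fit.beta == pytest.approx(beta, abs=1e-10)
        assert fit.se == pytest.approx(se, abs=1e-10)

    def test_ml_lambda_beats_the_grid_nowhere(self):
        # profiled lambda must achieve at least the best fixed-lambda likelihood
        tree = random_tree(24, seed=4)
        C, _ = bm_covariance(tree)
        rng = np.random.default_rng(4)
        y = simulate.draw_bm_noise(C, 1.0, rng)[0]
        x = rng.normal(size=24)
        fit = pgls_fit(y, x, C, lam="ml")
        assert 0.0 <= fit.lambda_used <= 1.0
        for lam in np.linspace(0, 1, 21):
            assert fit.log_likelihood >= pgls_fit(y, x, C, lam=lam).log_likelihood - 1e-6

    def test_pruning_invariance(self):
        tree = random_tree(20, seed=5)
        labels = tip_labels(tree)
        keep = labels[:10]
        C_full, l_full = bm_covariance(tree)
        idx = [l_full.index(k) for k in keep]
        rng = np.random.default_rng(5)
        y = rng.normal(size=20)
        x = rng.normal(size=20)
        C_sub, l_sub = bm_covariance(prune_to_overlap(tree, keep))
        order = [keep.index(l) for l in l_sub]
        fit_a = pgls_fit(y[idx][order], x[idx][order], C_sub)
        fit_b = pgls_fit(y[idx], x[idx], C_full[np.ix_(idx, idx)])
        assert fit_a.beta == pytest.approx(fit_b.beta, abs=1e-9)
        assert fit_a.p_value == pytest.approx(fit_b.p_value, abs=1e-9)

    def test_duplicated_zero_length_tips_are_singular(self):
        tree = read_newick("((A:0.0,B:0.0):1,(C:1,D:1):0.5);")
        C, _ = bm_covariance(tree)
        with pytest.raises(ValueError, match="singular"):
            pgls_fit([1.0, 2.0, 3.0, 4.0], [1.0, 3.0, 2.0, 4.0], C)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            pgls_fit([1, 2, 3], [1, 2, 3], np.eye(3))


class TestFamilyTables:
    @staticmethod
    def _tables(n=10, seed=0):
        rng = np.random.default_rng(seed)
        species = [f"sp{i}" for i in range(n)]
        counts = pd.DataFrame(
            {"species": species,
             "HXK": rng.integers(1, 5, n),
             "PYK": rng.integers(1, 5, n),
             "FLAT": 2}
        )
        trait = pd.DataFrame({"species": species, "mean_ecar": rng.normal(size=n)})
        return trait, counts

    def test_counts_identical_to_trait_give_r_one(self):
        trait, counts = self._tables()
        counts["HXK"] = trait["mean_ecar"]
        out = pearson_by_family(trait, counts).set_index("family")
        assert out.loc["HXK", "r"] == pytest.approx(1.0)
        counts["HXK"] = -trait["mean_ecar"]
        out = pearson_by_family(trait, counts).set_index("family")
        assert out.loc["HXK", "r"] == pytest.approx(-1.0)

    def test_matches_textbook_formula_oracle(self):
        trait, counts = self._tables(seed=3)
        out = pearson_by_family(trait, counts).set_index("family")
        x = counts["PYK"].to_numpy(float)
        y = trait["mean_ecar"].to_numpy(float)
        r = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert out.loc["PYK", "r"] == pytest.approx(r, abs=1e-12)

    def test_zero_variance_family_is_missing_not_zero(self):
        trait, counts = self._tables()
        out = pearson_by_family(trait, counts).set_index("family")
        assert np.isnan(out.loc["FLAT", "r"])
        assert out.loc["FLAT", "note"] == "zero variance"

    def test_total_column_is_row_sum(self):
        _, counts = self._tables()
        tot = with_total(counts)
        assert (tot["total"] == counts[["HXK", "PYK", "FLAT"]].sum(axis=1)).all()

    def test_stars_follow_thresholds(self):
        assert significance_stars(0.004) == "***"
        assert significance_stars(0.009) == "**"
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.2) == ""

    def test_star_tree_pgls_equals_pearson_p_values(self):
        trait, counts = self._tables(n=12, seed=6)
        star = read_newick("(" + ",".join(f"sp{i}:1" for i in range(12)) + ");")
        pg = pgls_by_family(trait, counts, star).set_index("family")
        pe = pearson_by_family(trait, counts).set_index("family")
        for fam in ["HXK", "PYK", "total"]:
            assert pg.loc[fam, "p"] == pytest.approx(pe.loc[fam, "p"], abs=1e-9)
            assert pg.loc[fam, "r_signed"] == pytest.approx(pe.loc[fam, "r"], abs=1e-9)

    def test_single_family_agrees_with_direct_fit(self, tree_sim):
        trait, counts, tree = tree_sim.trait, tree_sim.counts, tree_sim.tree
        out = pgls_by_family(trait, counts, tree).set_index("family")
        C, labels = bm_covariance(tree)
        t = trait.set_index("species").loc[labels, "mean_ecar"].to_numpy()
        x = counts.set_index("species").loc[labels, "fam01"].to_numpy(float)
        direct = pgls_fit(t, x, C)
        assert out.loc["fam01", "beta"] == pytest.approx(direct.beta, abs=1e-10)
        assert out.loc["fam01", "p"] == pytest.approx(direct.p_value, abs=1e-10)

    def test_failing_family_reported_not_fatal(self, tree_sim):
        counts = tree_sim.counts.copy()
        counts["fam01"] = 2  # constant: zero-variance predictor
        out = pgls_by_family(tree_sim.trait, counts, tree_sim.tree).set_index("family")
        assert np.isnan(out.loc["fam01", "beta"])
        assert "variance" in out.loc["fam01", "note"]
        assert out.loc["fam02", "p"] <= 1.0

    def test_subset_restricts_species(self, tree_sim):
        sub = tree_sim.counts.loc[tree_sim.counts["order"] == "order_A", "species"]
        assert len(sub) >= 4  # fixed seed gives a usable root split
        out = pgls_by_family(tree_sim.trait, tree_sim.counts, tree_sim.tree, subset=sub)
        assert (out["n"] == len(sub)).all()
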