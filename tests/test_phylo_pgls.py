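"""Brownian VCV construction and PGLS/OLS estimation.

The 5-taxon PGLS expectations were computed independently with R
(ape::vcv + nlme::gls with a Brownian correlation, and an explicit GLS
matrix computation with the n-p denominator) and frozen here; the two R
routes agreed to 1e-12.
"""

import numpy as np
import pandas as pd
import pytest

from phosevol.phylo_pgls import (
    brownian_vcv,
    BrownianVCV,
    leaf_labels,
    ols_fit,
    pgls_fit,
    prune_and_match,
    read_newick,
    tree_from_string,
)
from phosevol.synthetic_data import SimulationConfig, simulate_tree


def mrca_path_oracle(tree, taxa):
    """Brute force: per pair, intersect ancestor chains and sum root path."""

    def chain(leaf):
        nodes, n = [], leaf
        while n is not None:
            nodes.append(n)
            n = n.parent_node
        return nodes

    def depth(node):
        d, n = 0.0, node
        while n.parent_node is not None:
            d += n.edge.length or 0.0
            n = n.parent_node
        return d

    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    n = len(taxa)
    C = np.zeros((n, n))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            if i == j:
                C[i, j] = depth(leaves[a])
            else:
                anc_a = chain(leaves[a])
                anc_b = set(chain(leaves[b]))
                mrca = next(x for x in anc_a if x in anc_b)
                C[i, j] = depth(mrca)
    return C


class TestReadNewick:
    def test_three_leaf_tree(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((A:1,B:1):1,C:2);\n")
        tree = read_newick(p)
        assert sorted(leaf_labels(tree)) == ["A", "B", "C"]
        assert len(tree.seed_node.child_nodes()) == 2

    def test_missing_semicolon_rejected(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((A:1,B:1):1,C:2)")
        with pytest.raises(Exception):
            read_newick(p)

    def test_missing_branch_length_rejected(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((A:1,B):1,C:2);\n")
        with pytest.raises(ValueError, match="no length"):
            read_newick(p)

    def test_round_trip_preserves_leaves_and_path_lengths(self, tmp_path):
        tree = simulate_tree(SimulationConfig(n_species=12, seed=5))
        p = tmp_path / "t.nwk"
        tree.write(path=str(p), schema="newick", suppress_rooting=True)
        again = read_newick(p)
        taxa = sorted(leaf_labels(tree))
        assert sorted(leaf_labels(again)) == taxa
        np.testing.assert_allclose(
            brownian_vcv(again, taxa).matrix,
            brownian_vcv(tree, taxa).matrix,
            atol=1e-9,
        )


class TestPruneAndMatch:
    def _traits(self, species):
        return pd.DataFrame(
            {"species_id": species, "log10_lifespan": np.linspace(0.5, 2.0, len(species))}
        )

    def test_identical_name_sets_unchanged(self):
        tree = tree_from_string("((A:1,B:1):1,C:2);")
        pruned, traits = prune_and_match(tree, self._traits(["A", "B", "C"]))
        assert sorted(leaf_labels(pruned)) == ["A", "B", "C"]
        assert len(traits) == 3

    def test_space_underscore_and_case_normalization(self):
        tree = tree_from_string("((Homo_sapiens:1,Mus_musculus:1):1,Bos_taurus:2);")
        pruned, traits = prune_and_match(
            tree, self._traits(["homo sapiens", "MUS MUSCULUS"])
        )
        assert sorted(leaf_labels(pruned)) == ["Homo_sapiens", "Mus_musculus"]
        assert sorted(traits["species_id"]) == ["Homo_sapiens", "Mus_musculus"]

    def test_empty_intersection_rejected(self):
        tree = tree_from_string("(A:1,B:1);")
        with pytest.raises(ValueError, match="no species shared"):
            prune_and_match(tree, self._traits(["X", "Y"]))

    def test_pruning_preserves_shared_path_lengths(self):
        tree = simulate_tree(SimulationConfig(n_species=20, seed=9))
        taxa = sorted(leaf_labels(tree))
        keep = taxa[::2]
        full = brownian_vcv(tree, keep).matrix
        pruned, _ = prune_and_match(tree, self._traits(keep))
        np.testing.assert_allclose(
            brownian_vcv(pruned, keep).matrix, full, atol=1e-9
        )


class TestBrownianVCV:
    def test_cherry_has_no_shared_path(self):
        tree = tree_from_string("(A:1,B:1);")
        np.testing.assert_allclose(
            brownian_vcv(tree, ["A", "B"]).matrix, np.eye(2)
        )

    def test_three_taxon_path_sums(self):
        tree = tree_from_string("((A:1,B:1):1,C:2);")
        expected = np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 2.0]])
        np.testing.assert_allclose(
            brownian_vcv(tree, ["A", "B", "C"]).matrix, expected
        )

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_random_tree_matches_pairwise_traversal_oracle(self, seed):
        tree = simulate_tree(SimulationConfig(n_species=15, seed=seed))
        taxa = sorted(leaf_labels(tree))
        C = brownian_vcv(tree, taxa).matrix
        np.testing.assert_allclose(C, mrca_path_oracle(tree, taxa), atol=1e-10)
        # structural invariants
        np.testing.assert_allclose(C, C.T)
        assert np.all(np.linalg.eigvalsh(C) > -1e-9)
        offdiag_max = (C - np.diag(np.diag(C))).max()
        assert offdiag_max <= np.diag(C).min() + 1e-12

    def test_unknown_taxon_rejected(self):
        tree = tree_from_string("(A:1,B:1);")
        with pytest.raises(ValueError, match="absent"):
            brownian_vcv(tree, ["A", "Z"])


def _traits(y, x, species=None):
    species = species or [f"s{i}" for i in range(len(y))]
    return pd.DataFrame({"species_id": species, "y": y, "x": x})


class TestPGLSFit:
    def test_identity_covariance_noise_free(self):
        traits = _traits([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        vcv = BrownianVCV(list(traits.species_id), np.eye(3))
        res = pgls_fit(traits, ["x"], vcv, response="y")
        assert res.coef("x") == pytest.approx(1.0, abs=1e-12)
        assert res.coef("intercept") == pytest.approx(0.0, abs=1e-12)
        assert res.sigma2 == pytest.approx(0.0, abs=1e-20)

    def test_three_taxon_hand_matrix_computation(self):
        # independent route: explicit inverses, no shared code with gls_core
        C = np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 2.0]])
        y = np.array([1.0, 3.0, 2.0])
        x = np.array([2.0, 5.0, 3.0])
        X = np.column_stack([np.ones(3), x])
        Ci = np.linalg.inv(C)
        beta_hand = np.linalg.inv(X.T @ Ci @ X) @ X.T @ Ci @ y
        traits = _traits(y, x, ["A", "B", "C"])
        res = pgls_fit(traits, ["x"], BrownianVCV(["A", "B", "C"], C), response="y")
        np.testing.assert_allclose(res.beta, beta_hand, atol=1e-12)
        r = y - X @ beta_hand
        sigma2_hand = float(r @ Ci @ r) / (3 - 2)
        assert res.sigma2 == pytest.approx(sigma2_hand, abs=1e-12)

    def test_frozen_r_oracle_five_taxa(self):
        """Agreement with ape/nlme GLS under corBrownian (values frozen)."""
        tree = tree_from_string("(((A:1,B:1):1,(C:1.5,D:1.5):0.5):1,E:3);")
        traits = _traits(
            [1.0, 1.4, 0.8, 1.9, 0.2], [2.0, 3.0, 1.0, 4.0, 0.5], list("ABCDE")
        )
        res = pgls_fit(traits, ["x"], brownian_vcv(tree, list("ABCDE")), response="y")
        np.testing.assert_allclose(
            res.beta, [0.172240802676, 0.404682274247], atol=1e-9
        )
        np.testing.assert_allclose(
            res.se, [0.130737641767, 0.046613288133], atol=1e-9
        )
        np.testing.assert_allclose(
            res.t, [1.317453797907, 8.681693363792], atol=1e-8
        )
        np.testing.assert_allclose(
            res.p, [0.279268318632, 0.003215833787], atol=1e-9
        )
        assert res.sigma2 == pytest.approx(0.009461166852, abs=1e-10)

    def test_exact_linear_relation_recovered_under_any_c(self, rng):
        tree = simulate_tree(SimulationConfig(n_species=10, seed=11))
        taxa = sorted(leaf_labels(tree))
        x = rng.normal(size=10)
        traits = _traits(2.0 + 3.0 * x, x, taxa)
        res = pgls_fit(traits, ["x"], brownian_vcv(tree, taxa), response="y")
        assert res.coef("x") == pytest.approx(3.0, abs=1e-9)
        assert res.pvalue("x") < 1e-12

    def test_star_tree_equals_ols_exactly(self, rng):
        n = 8
        taxa = [f"s{i}" for i in range(n)]
        star = BrownianVCV(taxa, 2.5 * np.eye(n))
        y, x = rng.normal(size=n), rng.normal(size=n)
        traits = _traits(y, x, taxa)
        g = pgls_fit(traits, ["x"], star, response="y")
        o = ols_fit(traits, ["x"], response="y")
        np.testing.assert_allclose(g.beta, o.beta, atol=1e-10)
        np.testing.assert_allclose(g.t, o.t, atol=1e-10)
        np.testing.assert_allclose(g.p, o.p, atol=1e-10)

    def test_branch_length_scale_invariance(self, rng):
        tree = simulate_tree(SimulationConfig(n_species=12, seed=21))
        taxa = sorted(leaf_labels(tree))
        y, x = rng.normal(size=12), rng.normal(size=12)
        traits = _traits(y, x, taxa)
        C = brownian_vcv(tree, taxa).matrix
        k = 7.3
        r1 = pgls_fit(traits, ["x"], BrownianVCV(taxa, C), response="y")
        rk = pgls_fit(traits, ["x"], BrownianVCV(taxa, k * C), response="y")
        np.testing.assert_allclose(r1.beta, rk.beta, atol=1e-10)
        np.testing.assert_allclose(r1.t, rk.t, atol=1e-10)
        np.testing.assert_allclose(r1.p, rk.p, atol=1e-10)
        assert rk.sigma2 == pytest.approx(r1.sigma2 / k, rel=1e-10)

    def test_collinear_predictors_rejected(self):
        traits = pd.DataFrame(
            {
                "species_id": list("ABCD"),
                "y": [1.0, 2.0, 3.0, 4.0],
                "x1": [1.0, 2.0, 3.0, 4.0],
                "x2": [2.0, 4.0, 6.0, 8.0],
            }
        )
        vcv = BrownianVCV(list("ABCD"), np.eye(4))
        with pytest.raises(ValueError, match="collinear"):
            pgls_fit(traits, ["x1", "x2"], vcv, response="y")


class TestOLSFit:
    def test_textbook_five_point_closed_form(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.1, 3.9, 6.2, 8.1, 9.8])
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        intercept = y.mean() - slope * x.mean()
        res = ols_fit(_traits(y, x), ["x"], response="y")
        assert res.coef("x") == pytest.approx(slope, abs=1e-12)
        assert res.coef("intercept") == pytest.approx(intercept, abs=1e-12)

    def test_constant_response_gives_zero_slope(self, rng):
        res = ols_fit(_traits(np.ones(6), rng.normal(size=6)), ["x"], response="y")
        assert res.coef("x") == pytest.approx(0.0, abs=1e-12)

    def test_boolean_predictor_encoded_01(self):
        traits = pd.DataFrame(
            {
                "species_id": list("ABCD"),
                "y": [1.0, 1.0, 2.0, 2.0],
                "flag": [False, False, True, True],
            }
        )
        res = ols_fit(traits, ["flag"], response="y")
        assert res.coef("flag") == pytest.approx(1.0, abs=1e-12)
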