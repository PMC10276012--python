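import shutil
import subprocess

import dendropy
import numpy as np
import pandas as pd
import pytest

import pulsekin as pk
from pulsekin.phylo import _k_statistic_many, random_tree


def oracle_blomberg_k(C: pd.DataFrame, traits: pd.Series) -> float:
    """Dense linear-algebra oracle: explicit inverse, formula verbatim."""
    x = traits.loc[list(C.index)].to_numpy(float)
    Cn = C.to_numpy()
    n = len(x)
    Cinv = np.linalg.inv(Cn)
    one = np.ones(n)
    a = (one @ Cinv @ x) / (one @ Cinv @ one)
    mse0 = (x - a) @ (x - a) / (n - 1)
    mse = (x - a) @ Cinv @ (x - a) / (n - 1)
    expected = (np.trace(Cn) - n / (one @ Cinv @ one)) / (n - 1)
    return (mse0 / mse) / expected


def oracle_root_state(C: pd.DataFrame, traits: pd.Series) -> float:
    x = traits.loc[list(C.index)].to_numpy(float)
    Cinv = np.linalg.inv(C.to_numpy())
    one = np.ones(len(x))
    return float((one @ Cinv @ x) / (one @ Cinv @ one))


def oracle_node_state_by_rerooting(tree: dendropy.Tree, traits: pd.Series, node) -> float:
    """Re-root at the node; its ML state is the GLS mean from the new root."""
    clone = tree.clone(depth=1)
    target_leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
    for cand in clone.preorder_node_iter():
        if frozenset(lf.taxon.label for lf in cand.leaf_iter()) == target_leaves \
                and not cand.is_leaf():
            clone.reroot_at_node(cand)
            break
    C = pk.phylo_vcv(clone)
    return oracle_root_state(C, traits)


class TestNewickIO:
    def test_two_tip_parse(self):
        t = pk.parse_newick("(A:1,B:1);")
        labels = {lf.taxon.label for lf in t.leaf_node_iter()}
        assert labels == {"A", "B"}

    def test_path_lengths(self):
        t = pk.parse_newick("((A:1,B:1):0.5,C:1.5);")
        pdm = t.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in t.taxon_namespace}
        assert pdm.distance(taxa["A"], taxa["C"]) == pytest.approx(3.0)

    def test_malformed_raises(self):
        with pytest.raises(ValueError):
            pk.parse_newick("(A:1,B;")

    def test_duplicate_tips_raise(self):
        with pytest.raises(ValueError, match="duplicate"):
            pk.parse_newick("(A:1,A:2);")

    def test_missing_lengths_need_default(self):
        with pytest.raises(ValueError):
            pk.parse_newick("(A,B);")
        t = pk.parse_newick("(A,B);", default_edge_length=1.0)
        assert all(e.length == 1.0 for e in t.leaf_edge_iter())

    def test_roundtrip_preserves_lengths(self):
        s = "((A:1.25,B:0.5):0.75,C:2.0);"
        t = pk.parse_newick(s)
        t2 = pk.parse_newick(pk.write_newick(t))
        np.testing.assert_allclose(
            pk.phylo_vcv(t2).to_numpy(), pk.phylo_vcv(t).to_numpy()
        )

    def test_zero_length_branches_replaced(self):
        with pytest.warns(UserWarning, match="zero-length"):
            t = pk.parse_newick("((A:0,B:1):1,C:2);")
        assert np.linalg.det(pk.phylo_vcv(t).to_numpy()) != 0


class TestPrune:
    def test_prune_to_all_is_identity(self, study_tree):
        tips = [lf.taxon.label for lf in study_tree.leaf_node_iter()]
        pruned = pk.prune_to_taxa(study_tree, tips)
        np.testing.assert_allclose(
            pk.phylo_vcv(pruned).loc[tips, tips].to_numpy(),
            pk.phylo_vcv(study_tree).loc[tips, tips].to_numpy(),
        )

    def test_unifurcation_lengths_summed(self):
        pruned = pk.prune_to_taxa(pk.parse_newick("((A:1,B:1):1,C:2);"), ["A", "C"])
        C = pk.phylo_vcv(pruned)
        assert C.loc["A", "A"] == pytest.approx(2.0)
        assert C.loc["A", "C"] == pytest.approx(0.0)

    def test_patristic_distances_preserved(self, study_tree):
        rng = np.random.default_rng(0)
        tips = sorted(lf.taxon.label for lf in study_tree.leaf_node_iter())
        keep = sorted(rng.choice(tips, size=8, replace=False))
        pruned = pk.prune_to_taxa(study_tree, keep)
        pdm0 = study_tree.phylogenetic_distance_matrix()
        pdm1 = pruned.phylogenetic_distance_matrix()
        tax0 = {x.label: x for x in study_tree.taxon_namespace}
        tax1 = {x.label: x for x in pruned.taxon_namespace}
        for i, a in enumerate(keep):
            for b in keep[i + 1:]:
                assert pdm1.distance(tax1[a], tax1[b]) == pytest.approx(
                    pdm0.distance(tax0[a], tax0[b])
                )

    def test_unknown_taxon_listed(self, study_tree):
        with pytest.raises(ValueError, match="nosuch"):
            pk.prune_to_taxa(study_tree, ["nosuch"])


class TestVCV:
    def test_two_tip(self):
        C = pk.phylo_vcv(pk.parse_newick("(A:1,B:1);"))
        np.testing.assert_allclose(C.to_numpy(), np.eye(2))

    def test_three_tip(self):
        C = pk.phylo_vcv(pk.parse_newick("((A:1,B:1):0.5,C:1.5);"))
        assert C.loc["A", "B"] == pytest.approx(0.5)
        assert C.loc["A", "A"] == pytest.approx(1.5)
        assert C.loc["A", "C"] == pytest.approx(0.0)

    def test_symmetric_psd_on_random_trees(self):
        for seed in range(100):
            t = random_tree(np.random.default_rng(seed).integers(3, 12), seed=seed)
            C = pk.phylo_vcv(t).to_numpy()
            np.testing.assert_allclose(C, C.T)
            assert np.linalg.eigvalsh(C).min() > -1e-10


class TestBlombergK:
    def test_matches_dense_oracle_on_random_trees(self):
        rng = np.random.default_rng(1)
        for seed in range(100):
            t = random_tree(int(rng.integers(3, 11)), seed=1000 + seed)
            C = pk.phylo_vcv(t)
            x = pd.Series(rng.standard_normal(len(C)), index=C.index)
            assert pk.blomberg_k(t, x) == pytest.approx(
                oracle_blomberg_k(C, x), abs=1e-8
            )

    def test_affine_trait_invariance(self, study_tree):
        rng = np.random.default_rng(2)
        x = pk.simulate_bm_traits(study_tree, 1.0, seed=5)
        k0 = pk.blomberg_k(study_tree, x)
        assert pk.blomberg_k(study_tree, 3.2 * x - 7.0) == pytest.approx(k0, rel=1e-9)

    def test_branch_scaling_invariance(self, study_tree):
        x = pk.simulate_bm_traits(study_tree, 1.0, seed=6)
        scaled = study_tree.clone(depth=1)
        for e in scaled.preorder_edge_iter():
            if e.length is not None:
                e.length *= 4.0
        assert pk.blomberg_k(scaled, x) == pytest.approx(
            pk.blomberg_k(study_tree, x), rel=1e-9
        )

    def test_bm_traits_give_k_near_one(self, study_tree):
        C = pk.phylo_vcv(study_tree)
        X = pk.simulate_bm_traits(study_tree, 1.0, seed=7, n_replicates=300)
        ks = _k_statistic_many(C.to_numpy(), X.to_numpy())
        assert 0.85 < ks.mean() < 1.15

    def test_white_noise_gives_low_k(self, deep_balanced_tree):
        # deep balanced 16-tip tree, phylogeny-free traits
        C = pk.phylo_vcv(deep_balanced_tree)
        rng = np.random.default_rng(8)
        ks = _k_statistic_many(C.to_numpy(), rng.standard_normal((300, 16)))
        assert ks.mean() < 0.5

    def test_constant_trait_rejected(self, four_tip_tree):
        with pytest.raises(ValueError):
            pk.blomberg_k(four_tip_tree, pd.Series(1.0, index=list("ABCD")))

    def test_tip_mismatch_rejected(self, four_tip_tree):
        with pytest.raises(ValueError, match="mismatch"):
            pk.blomberg_k(four_tip_tree, pd.Series({"A": 1.0, "B": 2.0, "C": 0.5}))


class TestRandomizationTest:
    def test_fixed_seed_reproducible(self, study_tree):
        x = pk.simulate_bm_traits(study_tree, 1.0, seed=9)
        r1 = pk.blomberg_k_test(study_tree, x, n_perm=199, seed=42)
        r2 = pk.blomberg_k_test(study_tree, x, n_perm=199, seed=42)
        assert r1 == r2

    def test_needs_enough_permutations(self, study_tree):
        x = pk.simulate_bm_traits(study_tree, 1.0, seed=10)
        with pytest.raises(ValueError):
            pk.blomberg_k_test(study_tree, x, n_perm=50)

    def test_null_p_values_calibrated(self, study_tree):
        """Mean p over shuffled (signal-free) traits is ~0.5."""
        C = pk.phylo_vcv(study_tree)
        rng = np.random.default_rng(11)
        ps = []
        for i in range(200):
            x = pd.Series(rng.standard_normal(len(C)), index=C.index)
            ps.append(pk.blomberg_k_test(C, x, n_perm=199, seed=i).p)
        assert 0.45 <= np.mean(ps) <= 0.55

    def test_power_against_strong_bm_signal(self, deep_balanced_tree):
        """BM traits on a deep tree (short terminal branches, so related
        tips are nearly identical) should usually be declared significant."""
        t = deep_balanced_tree
        hits = 0
        n_rep = 50
        for i in range(n_rep):
            x = pk.simulate_bm_traits(t, 1.0, seed=100 + i)
            res = pk.blomberg_k_test(t, x, n_perm=199, seed=i)
            hits += res.p <= 0.05
        assert hits >= int(0.8 * n_rep)


class TestAncestralStates:
    def test_symmetric_two_tip_root(self):
        t = pk.parse_newick("(A:1,B:1);")
        am = pk.ancestral_states_ml(t, pd.Series({"A": 0.0, "B": 2.0}))
        assert am.node_states.iloc[0] == pytest.approx(1.0)

    def test_asymmetric_two_tip_closed_form(self):
        # root = (x_A/b_A + x_B/b_B) / (1/b_A + 1/b_B)
        t = pk.parse_newick("(A:1,B:3);")
        am = pk.ancestral_states_ml(t, pd.Series({"A": 0.0, "B": 4.0}))
        assert am.node_states.iloc[0] == pytest.approx(1.0)

    def test_constant_tips_propagate(self, four_tip_tree):
        am = pk.ancestral_states_ml(four_tip_tree, pd.Series(2.0, index=list("ABCD")))
        np.testing.assert_allclose(am.node_states.to_numpy(), 2.0)

    def test_translation_equivariance(self, four_tip_tree):
        x = pd.Series({"A": 1.2, "B": 0.8, "C": -0.5, "D": -1.1})
        a0 = pk.ancestral_states_ml(four_tip_tree, x).node_states
        a1 = pk.ancestral_states_ml(four_tip_tree, x + 10.0).node_states
        np.testing.assert_allclose(a1.to_numpy(), a0.to_numpy() + 10.0, atol=1e-9)

    def test_root_equals_gls_mean(self):
        rng = np.random.default_rng(3)
        for seed in range(30):
            t = random_tree(int(rng.integers(3, 11)), seed=2000 + seed)
            C = pk.phylo_vcv(t)
            x = pd.Series(rng.standard_normal(len(C)), index=C.index)
            am = pk.ancestral_states_ml(t, x)
            assert am.node_states.iloc[0] == pytest.approx(
                oracle_root_state(C, x), abs=1e-8
            )

    def test_internal_nodes_match_reroot_oracle(self):
        rng = np.random.default_rng(4)
        t = random_tree(8, seed=77)
        C = pk.phylo_vcv(t)
        x = pd.Series(rng.standard_normal(len(C)), index=C.index)
        am = pk.ancestral_states_ml(t, x)
        labels = {}
        k = 0
        for node in t.preorder_node_iter():
            from pulsekin.phylo import _node_label

            labels[id(node)] = _node_label(node, k)
            k += 1
        for node in t.preorder_node_iter():
            if node.is_leaf() or node is t.seed_node:
                continue
            expect = oracle_node_state_by_rerooting(t, x, node)
            assert am.node_states[labels[id(node)]] == pytest.approx(expect, abs=1e-8)

    def test_edge_grid_endpoints_match_node_states(self, four_tip_tree):
        x = pd.Series({"A": 1.0, "B": 2.0, "C": 0.0, "D": -1.0})
        am = pk.ancestral_states_ml(four_tip_tree, x, grid=5)
        for (parent, child), grp in am.edge_grid.groupby(["parent", "child"]):
            assert grp[grp["position"] == 0.0]["state"].iloc[0] == pytest.approx(
                am.node_states[parent]
            )
            assert grp[grp["position"] == 1.0]["state"].iloc[0] == pytest.approx(
                am.node_states[child]
            )


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
class TestPhytoolsCrossCheck:
    """Independent R/phytools oracle for K and ancestral states."""

    def test_k_and_ancestral_states_agree(self, four_tip_tree, tmp_path):
        x = pd.Series({"A": 1.2, "B": 0.8, "C": -0.5, "D": -1.1})
        script = tmp_path / "check.R"
        script.write_text(
            'suppressMessages(library(phytools))\n'
            'tree <- read.tree(text="((A:1,B:1):0.5,(C:0.8,D:1.2):0.7);")\n'
            "x <- c(A=1.2,B=0.8,C=-0.5,D=-1.1)\n"
            'cat(phylosig(tree, x, method="K"), "\\n")\n'
            'cat(fastAnc(tree, x), "\\n")\n'
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        ).stdout.strip().splitlines()
        k_ref = float(out[0].split()[0])
        anc_ref = [float(v) for v in out[1].split()]
        assert pk.blomberg_k(four_tip_tree, x) == pytest.approx(k_ref, abs=1e-5)
        am = pk.ancestral_states_ml(four_tip_tree, x)
        internal = [v for lbl, v in am.node_states.items() if lbl.startswith("node")]
        np.testing.assert_allclose(internal, anc_ref, atol=1e-5)
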