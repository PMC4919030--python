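"""LG+Gamma likelihood machinery: discretisation, NJ, pruning likelihood
against enumeration, optimisation contracts, aLRT, collapse, rooting,
monophyly and bootstrap."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import gamma as gamma_dist

from hrsurvey import phylo
from hrsurvey.msa import DistanceMatrix, MultipleAlignment
from hrsurvey.ratemodel import discretize_gamma, lg_model
from hrsurvey.scoring import AMINO_ACIDS
from hrsurvey.synth import evolve_along_tree
from hrsurvey.tree import Tree

MODEL = lg_model(1.151, 6)


class TestDiscretizeGamma:
    def test_single_category(self):
        rates, weights = discretize_gamma(0.5, 1)
        assert rates.tolist() == [1.0]

    def test_large_alpha_limit(self):
        # as alpha -> infinity the gamma collapses to a point mass at 1
        rates, _ = discretize_gamma(10000.0, 6)
        assert np.all(np.abs(rates - 1.0) < 0.05)

    def test_mean_exactly_one(self):
        for alpha in (0.2, 1.151, 1.224, 5.0):
            rates, weights = discretize_gamma(alpha, 6)
            assert (rates * weights).sum() == pytest.approx(1.0, abs=1e-12)

    def test_against_quadrature_oracle(self):
        alpha, n = 1.151, 6
        rates, _ = discretize_gamma(alpha, n)
        dist = gamma_dist(a=alpha, scale=1.0 / alpha)
        bounds = [0] + list(dist.ppf(np.arange(1, n) / n)) + [np.inf]
        for k in range(n):
            mean_k, _ = quad(lambda x: x * dist.pdf(x), bounds[k], bounds[k + 1])
            assert rates[k] == pytest.approx(n * mean_k, abs=1e-6)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            discretize_gamma(-1.0, 6)


class TestRateModel:
    def test_transition_rows_sum_to_one(self):
        for t in (0.0, 0.1, 1.0, 10.0):
            P = MODEL.transition_matrix(t)
            assert np.abs(P.sum(axis=1) - 1.0).max() < 1e-10
        assert np.abs(MODEL.transition_matrix(0.0) - np.eye(20)).max() < 1e-12

    def test_generator_rows_sum_to_zero(self):
        assert np.abs(MODEL.Q.sum(axis=1)).max() < 1e-12

    def test_frequencies_normalised(self):
        assert MODEL.frequencies.sum() == pytest.approx(1.0, abs=1e-12)


class TestNeighborJoining:
    def test_additive_four_taxon_exact(self):
        # tree ((a:2,b:3):1,(c:4,d:5):1) as an additive distance matrix
        labels = ["a", "b", "c", "d"]
        m = np.array([[0, 5, 8, 9], [5, 0, 9, 10],
                      [8, 9, 0, 9], [9, 10, 9, 0]], dtype=float)
        t = phylo.nj_tree(DistanceMatrix(labels, m))
        d = t.tip_distances()
        for (x, y), expect in {("a", "b"): 5, ("a", "c"): 8, ("a", "d"): 9,
                               ("b", "c"): 9, ("b", "d"): 10, ("c", "d"): 9}.items():
            assert d[(x, y)] == pytest.approx(expect)
        assert t.bipartitions() == {frozenset({"a", "b"})}

    def test_two_taxa_trivial(self):
        t = phylo.nj_tree(DistanceMatrix(["a", "b"],
                                         np.array([[0, 4.0], [4.0, 0]])))
        assert t.tip_distances()[("a", "b")] == pytest.approx(4.0)

    def test_label_permutation_consistent(self):
        labels = ["a", "b", "c", "d", "e"]
        rng = np.random.default_rng(3)
        m = rng.random((5, 5))
        m = m + m.T
        np.fill_diagonal(m, 0)
        t1 = phylo.nj_tree(DistanceMatrix(labels, m))
        perm = [3, 1, 4, 0, 2]
        t2 = phylo.nj_tree(DistanceMatrix([labels[i] for i in perm],
                                          m[np.ix_(perm, perm)]))
        assert t1.bipartitions() == t2.bipartitions()


class TestLikelihood:
    def test_one_tip_equals_log_frequencies(self):
        aln = MultipleAlignment([("a", "ARNDW")])
        tree = Tree.from_newick("(a:1);") if False else None
        code = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
        expect = sum(math.log(MODEL.frequencies[code[c]]) for c in "ARNDW")
        got = phylo.log_likelihood(None, aln, MODEL)
        assert got == pytest.approx(expect, rel=1e-12)

    def test_three_taxon_enumeration_oracle(self):
        tree = Tree.from_newick("(a:0.2,b:0.35,c:0.5);")
        aln = MultipleAlignment([("a", "ARL"), ("b", "AKL"), ("c", "LRW")])
        ll = phylo.log_likelihood(tree, aln, MODEL)
        code = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
        Ps = {n.name: MODEL.category_matrices(n.length)
              for n in tree.root.children}
        expect = 0.0
        for site in range(3):
            s = 0.0
            for c in range(6):
                for root_state in range(20):
                    p = MODEL.frequencies[root_state] * MODEL.weights[c]
                    for rid, seq in aln.rows:
                        p *= Ps[rid][c][root_state, code[seq[site]]]
                    s += p
            expect += math.log(s)
        assert ll == pytest.approx(expect, rel=1e-10)

    def test_gaps_treated_as_missing(self):
        tree = Tree.from_newick("(a:0.2,b:0.3);")
        full = MultipleAlignment([("a", "AR"), ("b", "AK")])
        gapped = MultipleAlignment([("a", "AR-"), ("b", "AKX")])
        assert phylo.log_likelihood(tree, gapped, MODEL) == pytest.approx(
            phylo.log_likelihood(tree, full, MODEL))

    def test_saturation_limit_factorises(self):
        model = lg_model(1.0, 1)
        tree = Tree.from_newick("(a:50,b:50,c:50);")
        aln = MultipleAlignment([("a", "A"), ("b", "R"), ("c", "W")])
        code = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
        expect = sum(math.log(model.frequencies[code[c]]) for c in "ARW")
        assert phylo.log_likelihood(tree, aln, model) == pytest.approx(
            expect, abs=1e-6)

    def test_pulley_principle(self):
        aln = evolve_along_tree(
            80, Tree.from_newick("(a:0.3,(b:0.2,c:0.4):0.2);"), MODEL, seed=4)
        lls = []
        for x in (0.05, 0.2, 0.35):
            # slide length across the root: a<->(b,c) path length constant
            tree = Tree.from_newick(
                f"(a:{x:.2f},(b:0.2,c:0.4):{0.6 - x:.2f});")
            lls.append(phylo.log_likelihood(tree, aln, MODEL))
        assert max(lls) - min(lls) < 1e-9

    def test_tip_mismatch_rejected(self):
        tree = Tree.from_newick("(a:0.1,b:0.1);")
        aln = MultipleAlignment([("a", "AR"), ("c", "AK")])
        with pytest.raises(ValueError):
            phylo.log_likelihood(tree, aln, MODEL)


class TestOptimisationAndSearch:
    def test_optimizer_monotone_and_true_tree_competitive(self):
        true = Tree.from_newick(
            "((a:0.2,b:0.2):0.15,(c:0.2,d:0.2):0.15);")
        for seed in range(3):
            aln = evolve_along_tree(200, true, MODEL, seed=seed)
            t0 = true.copy()
            _, ll0 = phylo.optimize_branch_lengths(t0, aln, MODEL)
            start = phylo.nj_tree(phylo.ml_distance_matrix(aln, MODEL))
            ll_start = phylo.log_likelihood(start, aln, MODEL)
            _, ll_opt = phylo.optimize_branch_lengths(start, aln, MODEL)
            assert ll_opt >= ll_start - 1e-9   # optimisation never hurts
            # the optimised true topology beats the raw NJ starting tree
            assert ll0 >= ll_start - 1e-9

    def test_zero_length_internal_branch_nni_indifferent(self):
        aln = evolve_along_tree(
            100, Tree.from_newick("((a:0.2,b:0.2):0.1,(c:0.2,d:0.2):0.1);"),
            MODEL, seed=9)
        lls = []
        for topo in ["((a:0.2,b:0.2):0.0,(c:0.2,d:0.2):0.0);",
                     "((a:0.2,c:0.2):0.0,(b:0.2,d:0.2):0.0);",
                     "((a:0.2,d:0.2):0.0,(b:0.2,c:0.2):0.0);"]:
            lls.append(phylo.log_likelihood(Tree.from_newick(topo), aln, MODEL))
        assert max(lls) - min(lls) < 1e-6

    def test_nni_recovers_simulated_topology(self):
        true = Tree.from_newick(
            "(((a:0.15,b:0.15):0.1,(c:0.15,d:0.15):0.1):0.1,"
            "(e:0.15,f:0.15):0.1);")
        aln = evolve_along_tree(300, true, MODEL, seed=5)
        inferred, ll = phylo.ml_tree(aln, MODEL)
        assert inferred.robinson_foulds(true) == 0


class TestSupportsAndCollapse:
    def test_zero_statistic_gives_zero_support(self):
        # a zero-length internal branch is topologically indistinguishable
        true = Tree.from_newick("((a:0.3,b:0.3):1e-8,(c:0.3,d:0.3):1e-8);")
        aln = evolve_along_tree(150, true, MODEL, seed=6)
        t, _ = phylo.optimize_branch_lengths(true.copy(), aln, MODEL)
        t = phylo.alrt_support(t, aln, MODEL)
        supports = [n.support for n in t.internal_edges()]
        assert min(supports) < 0.6  # weak branch is collapsible

    def test_long_internal_branch_high_support(self):
        true = Tree.from_newick("((a:0.2,b:0.2):0.5,(c:0.2,d:0.2):0.5);")
        high = 0
        for seed in range(10):
            aln = evolve_along_tree(1000, true, MODEL, seed=20 + seed)
            t, _ = phylo.ml_tree(aln, MODEL)
            t = phylo.alrt_support(t, aln, MODEL)
            if t.robinson_foulds(true) == 0:
                high += all(n.support > 0.9 for n in t.internal_edges())
        assert high >= 9

    def test_collapse_boundary_and_idempotence(self):
        t = Tree.from_newick("((a:1,b:1)0.61:1,(c:1,d:1)0.59:1,(e:1,f:1)0.2:1);")
        c = phylo.collapse_low_support(t, 0.6)
        assert c.bipartitions() == {frozenset({"a", "b"})}
        again = phylo.collapse_low_support(c, 0.6)
        assert again.to_newick() == c.to_newick()
        untouched = phylo.collapse_low_support(
            Tree.from_newick("((a:1,b:1)0.9:1,(c:1,d:1)0.8:1);"), 0.6)
        assert untouched.bipartitions() == {frozenset({"a", "b"})}
        star = phylo.collapse_low_support(
            Tree.from_newick("((a:1,b:1)0.1:1,(c:1,d:1)0.2:1);"), 0.6)
        assert star.bipartitions() == set()


class TestRooting:
    def test_two_tips_midpoint(self):
        t = phylo.midpoint_root(Tree.from_newick("(a:3,b:1);"))
        depths = {n.name: n.length for n in t.root.children}
        assert depths["a"] == pytest.approx(2.0)
        assert depths["b"] == pytest.approx(2.0)

    def test_midpoint_against_all_pairs_oracle(self):
        rng = np.random.default_rng(17)
        for case in range(50):
            tree = _random_tree(rng, n_tips=int(rng.integers(4, 10)))
            before = tree.tip_distances()
            (u, v), diameter = max(before.items(), key=lambda kv: (kv[1], kv[0]))
            rooted = phylo.midpoint_root(tree)
            after = rooted.tip_distances()
            for pair, dist in before.items():
                assert after[pair] == pytest.approx(dist, abs=1e-9)
            # the deepest tip on each side of the root sits at diameter/2
            sides = []
            for child in rooted.root.children:
                depths = _tip_depths(child)
                sides.append(max(depths.values()) + child.length)
            assert max(sides) == pytest.approx(diameter / 2, abs=1e-9)

    def test_outgroup_rooting(self):
        t = Tree.from_newick("((a:1,b:1):1,(c:1,d:1):1,e:1);")
        rooted = phylo.outgroup_root(t, ["c", "d"])
        assert phylo.is_monophyletic(rooted, ["a", "b", "e"])


def _tip_depths(node, acc=0.0):
    if node.is_leaf:
        return {node.name: acc}
    out = {}
    for ch in node.children:
        out.update(_tip_depths(ch, acc + ch.length))
    return out


def _random_tree(rng, n_tips):
    nodes = [phylo.Node(f"t{i}", float(rng.uniform(0.1, 2.0)))
             for i in range(n_tips)]
    while len(nodes) > 3:
        a = nodes.pop(int(rng.integers(len(nodes))))
        b = nodes.pop(int(rng.integers(len(nodes))))
        p = phylo.Node("", float(rng.uniform(0.1, 2.0)))
        p.add(a)
        p.add(b)
        nodes.append(p)
    root = phylo.Node("")
    for n in nodes:
        root.add(n)
    return Tree(root)


class TestMonophylyAndBootstrap:
    def test_trivial_cases(self):
        t = Tree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        assert phylo.is_monophyletic(t, ["a", "b", "c", "d"])
        assert phylo.is_monophyletic(t, ["a"])
        assert phylo.is_monophyletic(t, ["a", "b"])
        assert not phylo.is_monophyletic(t, ["a", "c"])
        with pytest.raises(KeyError):
            phylo.is_monophyletic(t, ["zz"])

    def test_bootstrap_supports_strong_split(self):
        true = Tree.from_newick("((a:0.2,b:0.2):0.6,(c:0.2,d:0.2):0.6);")
        aln = evolve_along_tree(400, true, MODEL, seed=30)
        props = phylo.bootstrap(aln, MODEL, n_replicates=30, seed=31)
        assert all(0.0 <= v <= 1.0 for v in props.values())
        assert props.get(frozenset({"a", "b"}), 0.0) >= 0.9

    def test_bootstrap_deterministic_given_seed(self):
        true = Tree.from_newick("((a:0.2,b:0.2):0.4,(c:0.2,d:0.2):0.4);")
        aln = evolve_along_tree(100, true, MODEL, seed=32)
        p1 = phylo.bootstrap(aln, MODEL, n_replicates=10, seed=33)
        p2 = phylo.bootstrap(aln, MODEL, n_replicates=10, seed=33)
        assert p1 == p2


class TestGammaShapeEstimation:
    def test_recovery_within_band(self):
        true = Tree.from_newick(
            "(((a:0.15,b:0.15):0.1,(c:0.15,d:0.15):0.1):0.1,"
            "((e:0.15,f:0.15):0.1,(g:0.15,h:0.15):0.1):0.1);")
        aln = evolve_along_tree(500, true, MODEL, seed=40)
        t, _ = phylo.optimize_branch_lengths(true.copy(), aln, MODEL)
        a = phylo.estimate_gamma_shape(t, aln, MODEL)
        assert 0.7 <= a <= 1.8
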