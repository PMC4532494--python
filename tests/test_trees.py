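import itertools

import dendropy
import numpy as np
import pytest
from scipy.cluster.hierarchy import average as scipy_average
from scipy.cluster.hierarchy import cophenet
from scipy.spatial.distance import squareform

from sdm_phylo import (
    DissimilarityMatrix,
    extract_clusters,
    fm_clock,
    neighbor_joining,
    read_newick,
    robinson_foulds,
    upgma,
    write_newick,
)
from sdm_phylo.errors import FormatError, InputError
from sdm_phylo.trees import (
    Node,
    PhyloTree,
    clock_fit_score,
    enumerate_rooted_topologies,
    fit_clock_topology,
)

from _oracles import bipartition_sets


def random_matrix(rng, n, low=1.0, high=10.0):
    v = rng.uniform(low, high, (n, n))
    v = (v + v.T) / 2.0
    np.fill_diagonal(v, 0.0)
    return DissimilarityMatrix([f"x{i}" for i in range(n)], v)


def random_rooted_tree(rng, n):
    nodes = [Node(f"t{i}", rng.uniform(0.1, 1.0)) for i in range(n)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b, a = nodes.pop(j), nodes.pop(i)
        nodes.append(Node(length=rng.uniform(0.1, 1.0), children=[a, b]))
    return PhyloTree(nodes[0], rooted=True)


class TestUpgma:
    def test_two_taxa_cherry(self):
        m = DissimilarityMatrix(["A", "B"], np.array([[0.0, 3.0], [3.0, 0.0]]))
        t = upgma(m)
        assert sorted(t.leaf_labels()) == ["A", "B"]
        assert all(leaf.length == pytest.approx(1.5) for leaf in t.leaves())

    def test_three_taxa_hand_case(self):
        m = DissimilarityMatrix(
            ["A", "B", "C"], np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]], float))
        t = upgma(m)
        depths = t.leaf_depths()
        assert depths == {"A": 3.0, "B": 3.0, "C": 3.0}
        blocks, _ = extract_clusters(t, k=2)
        assert blocks == [["A", "B"], ["C"]]

    def test_recovers_ultrametric_matrix_exactly(self, rng):
        truth = DissimilarityMatrix(
            list("ABCDE"),
            np.array([
                [0, 2, 8, 8, 8],
                [2, 0, 8, 8, 8],
                [8, 8, 0, 4, 6],
                [8, 8, 4, 0, 6],
                [8, 8, 6, 6, 0],
            ], float))
        t = upgma(truth)
        _, d = t.distance_matrix(truth.labels)
        assert np.allclose(d, truth.values, atol=1e-12)
        assert t.is_ultrametric()

    def test_matches_scipy_average_linkage_cophenetic(self, rng):
        m = random_matrix(rng, 8)
        t = upgma(m)
        _, ours = t.distance_matrix(m.labels)
        link = scipy_average(squareform(m.values))
        theirs = squareform(cophenet(link))
        assert np.allclose(ours, theirs, atol=1e-9)


class TestClockTree:
    def test_ultrametric_input_fits_perfectly(self):
        m = DissimilarityMatrix(
            list("ABCD"),
            np.array([[0, 2, 8, 8], [2, 0, 8, 8], [8, 8, 0, 4], [8, 8, 4, 0]], float))
        tree, score = fm_clock(m)
        assert score == pytest.approx(0.0, abs=1e-12)
        _, t = tree.distance_matrix(m.labels)
        assert np.allclose(t, m.values, atol=1e-9)

    def test_output_is_ultrametric(self, rng):
        for _ in range(5):
            tree, _ = fm_clock(random_matrix(rng, 6))
            assert tree.is_ultrametric()

    def test_perturbed_clock_matrix_recovers_topology(self, rng):
        truth = np.array([[0, 2, 8, 8], [2, 0, 8, 8], [8, 8, 0, 4], [8, 8, 4, 0]], float)
        labels = list("ABCD")
        for _ in range(5):
            noise = 1.0 + rng.uniform(-0.01, 0.01, truth.shape)
            v = truth * (noise + noise.T) / 2.0
            np.fill_diagonal(v, 0.0)
            m = DissimilarityMatrix(labels, v)
            tree, score = fm_clock(m)
            best_score, best_tree = min(
                ((fit_clock_topology(tp, m)[1], tp)
                 for tp in enumerate_rooted_topologies(labels)),
                key=lambda x: x[0])
            assert score == pytest.approx(best_score, abs=1e-9)
            blocks, _ = extract_clusters(tree, k=2)
            assert blocks == [["A", "B"], ["C", "D"]]

    def test_matches_exhaustive_enumeration(self, rng):
        for n in (4, 5):
            for _ in range(3):
                m = random_matrix(rng, n)
                _, score = fm_clock(m)
                best = min(fit_clock_topology(tp, m)[1]
                           for tp in enumerate_rooted_topologies(m.labels))
                assert score == pytest.approx(best, abs=1e-9)

    def test_never_worse_than_upgma_initializer(self, rng):
        for _ in range(5):
            m = random_matrix(rng, 7)
            _, score = fm_clock(m)
            assert score <= clock_fit_score(upgma(m), m) + 1e-9

    def test_height_fit_matches_generic_constrained_optimizer(self, rng):
        """Exact isotonic block merging vs scipy SLSQP on random topologies."""
        from scipy.optimize import minimize

        from sdm_phylo.trees import _pair_weights, _topology_stats

        for _ in range(5):
            m = random_matrix(rng, 6)
            topos = list(enumerate_rooted_topologies(m.labels))
            tp = topos[rng.integers(len(topos))]
            _, score = fit_clock_topology(tp, m)
            d, w = m.values, _pair_weights(m.values, 2.0)
            index = {lab: i for i, lab in enumerate(m.labels)}
            _, parents, a, b, c = _topology_stats(tp.copy().root, index, d, w)
            k = len(a)

            def obj(h, a=a, b=b, c=c):
                return float((c - 4 * h * b + 4 * h * h * a).sum())

            cons = []
            for i, p in enumerate(parents):
                if p is not None:
                    cons.append({"type": "ineq",
                                 "fun": lambda h, i=i, p=p: h[p] - h[i]})
            res = minimize(obj, np.full(k, float(d.max()) / 2), method="SLSQP",
                           bounds=[(0, None)] * k, constraints=cons,
                           options={"maxiter": 500, "ftol": 1e-14})
            assert score == pytest.approx(res.fun, abs=1e-6)

    def test_fit_score_equals_path_length_residual(self, rng):
        m = random_matrix(rng, 6)
        tree, score = fm_clock(m)
        assert score == pytest.approx(clock_fit_score(tree, m), abs=1e-8)


class TestNeighborJoining:
    def test_additive_matrix_recovered_exactly(self):
        # tree ((A:2,B:3):1,(C:4,D:5)) -> additive distances
        v = np.array([[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]], float)
        m = DissimilarityMatrix(list("ABCD"), v)
        t = neighbor_joining(m)
        _, d = t.distance_matrix(m.labels)
        assert np.abs(d - v).max() <= 1e-9

    def test_three_taxa_closed_form(self):
        v = np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], float)
        t = neighbor_joining(DissimilarityMatrix(list("ABC"), v))
        lengths = {leaf.label: leaf.length for leaf in t.leaves()}
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(4.0)

    def test_tie_breaking_is_deterministic(self):
        v = np.full((4, 4), 5.0)
        np.fill_diagonal(v, 0.0)
        m = DissimilarityMatrix(list("ABCD"), v)
        assert write_newick(neighbor_joining(m)) == write_newick(neighbor_joining(m))

    def test_branch_lengths_nonnegative(self, rng):
        for _ in range(5):
            t = neighbor_joining(random_matrix(rng, 7))
            assert all(n.length >= 0 for n in t.postorder())


class TestNewick:
    @pytest.mark.parametrize("text", [
        "((A:1,B:1):1,C:2);",
        "((d1tvqa_:0.5,d1liba_:0.5):1.5,(d2fr2a1:1,d2o62a1:1):1);",
    ])
    def test_round_trip(self, text):
        assert write_newick(read_newick(text)) == text

    def test_label_with_metacharacters_is_quoted(self):
        t = PhyloTree(Node(children=[Node("a b(c)", 1.0), Node("plain", 2.0)]))
        text = write_newick(t)
        assert "'a b(c)'" in text
        back = read_newick(text)
        assert sorted(back.leaf_labels()) == ["a b(c)", "plain"]

    def test_random_tree_round_trip_is_isomorphic(self, rng):
        for _ in range(5):
            t = random_rooted_tree(rng, 20)
            back = read_newick(write_newick(t))
            assert robinson_foulds(t, back) == 0
            assert sorted(back.leaf_labels()) == sorted(t.leaf_labels())
            total = sum(n.length for n in t.postorder() if n.parent)
            total_back = sum(n.length for n in back.postorder() if n.parent)
            assert total_back == pytest.approx(total, rel=1e-5)

    def test_malformed_string_raises(self):
        with pytest.raises(FormatError):
            read_newick("((A:1,B:1;")


class TestRobinsonFoulds:
    def test_identity_and_four_leaf_cases(self):
        a = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        b = read_newick("((A:1,C:1):1,(B:1,D:1):1);")
        assert robinson_foulds(a, a) == 0
        assert robinson_foulds(a, b) == 2

    def test_leaf_set_mismatch_reported(self):
        a = read_newick("((A:1,B:1):1,C:1);")
        b = read_newick("((A:1,B:1):1,D:1);")
        with pytest.raises(InputError, match="only-in-a"):
            robinson_foulds(a, b)

    def test_matches_dendropy_and_set_algebra(self, rng):
        for _ in range(5):
            ta, tb = random_rooted_tree(rng, 10), random_rooted_tree(rng, 10)
            ours = robinson_foulds(ta, tb)
            assert ours == len(bipartition_sets(ta) ^ bipartition_sets(tb))
            tns = dendropy.TaxonNamespace()
            da = dendropy.Tree.get(data=write_newick(ta), schema="newick",
                                   taxon_namespace=tns)
            db = dendropy.Tree.get(data=write_newick(tb), schema="newick",
                                   taxon_namespace=tns)
            assert ours == dendropy.calculate.treecompare.symmetric_difference(da, db)


class TestClusterExtraction:
    def test_trivial_cuts(self):
        t = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        blocks, _ = extract_clusters(t, k=1)
        assert blocks == [["A", "B", "C", "D"]]
        blocks, outliers = extract_clusters(t, k=4)
        assert blocks == [["A"], ["B"], ["C"], ["D"]]
        assert outliers == ["A", "B", "C", "D"]

    def test_three_block_guide_recovered(self):
        text = "(((A:1,B:1):5,(C:1,D:1):4):1,((E:1,F:1):2,G:3):1);"
        t = read_newick(text)
        blocks, outliers = extract_clusters(t, k=3)
        assert blocks == [["A", "B"], ["C", "D"], ["E", "F", "G"]]
        assert outliers == []

    def test_height_cut(self):
        t = read_newick("((A:1,B:1):3,(C:2,D:2):2);")
        blocks, _ = extract_clusters(t, height=1.5)
        assert blocks == [["A", "B"], ["C"], ["D"]]

    def test_argument_validation(self):
        t = read_newick("((A:1,B:1):1,C:2);")
        with pytest.raises(InputError):
            extract_clusters(t)
        with pytest.raises(InputError):
            extract_clusters(t, k=2, height=1.0)
        with pytest.raises(InputError):
            extract_clusters(t, k=9)
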