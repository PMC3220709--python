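import math

import numpy as np
import pytest

from famscan.msa import MSA, InputError
from famscan.phylo import (
    MAX_DISTANCE,
    DistanceMatrix,
    SupportTree,
    TreeNode,
    bootstrap_supports,
    distance_matrix,
    extract_subclade,
    nj_tree,
    read_newick,
    rf_distance,
    tree_path_distances,
    write_newick,
)

from _oracle import least_squares_topology


def random_binary_tree(labels, rng):
    nodes = [TreeNode(label=l, length=float(rng.uniform(0.1, 1.0))) for l in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = TreeNode(
            children=[nodes[i], nodes[j]], length=float(rng.uniform(0.1, 1.0))
        )
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return SupportTree(root=TreeNode(children=nodes))


class TestDistanceMatrix:
    def test_identical_sequences_zero(self):
        msa = MSA(ids=["a", "b", "c"], rows=["ACDW", "ACDW", "ACDW"])
        dm = distance_matrix(msa, "p")
        assert dm.matrix[0, 1] == 0.0

    def test_p_and_poisson_closed_form(self):
        msa = MSA(ids=["a", "b", "c"], rows=["AAAA", "AAAT", "AATT"])
        p = distance_matrix(msa, "p")
        assert p.matrix[0, 1] == pytest.approx(0.25)
        poisson = distance_matrix(msa, "poisson")
        assert poisson.matrix[0, 1] == pytest.approx(-math.log(0.75), abs=1e-12)

    def test_saturated_pair_capped(self):
        msa = MSA(ids=["a", "b", "c"], rows=["AAAA", "TTTT", "AATT"])
        with pytest.warns(UserWarning, match="capping"):
            dm = distance_matrix(msa, "poisson")
        assert dm.matrix[0, 1] == MAX_DISTANCE

    def test_gaps_excluded_from_overlap(self):
        msa = MSA(ids=["a", "b", "c"], rows=["A-CD", "AAC-", "AACD"])
        dm = distance_matrix(msa, "p")
        assert dm.matrix[0, 1] == pytest.approx(0.0)  # overlap columns 1,3 agree

    def test_zero_overlap_pair_named(self):
        msa = MSA(ids=["x", "y", "z"], rows=["A--", "-C-", "ACD"])
        with pytest.raises(InputError, match="'x'.*'y'"):
            distance_matrix(msa, "p")

    def test_symmetry_zero_diagonal(self, rng):
        alphabet = "ACDW"
        rows = [
            "".join(alphabet[int(rng.integers(0, 4))] for _ in range(30))
            for _ in range(6)
        ]
        dm = distance_matrix(MSA(ids=[f"s{i}" for i in range(6)], rows=rows), "p")
        np.testing.assert_array_equal(dm.matrix, dm.matrix.T)
        assert np.all(np.diag(dm.matrix) == 0)


class TestNJ:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = nj_tree(DistanceMatrix(labels=["A", "B", "C"], matrix=d))
        lengths = {c.label: c.length for c in tree.root.children}
        assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)

    def test_four_taxon_additive_topology_and_internal_branch(self):
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]], float
        )
        tree = nj_tree(DistanceMatrix(labels=labels, matrix=d))
        # canonical split side is the one not containing the smallest label "A"
        assert list(tree.bipartitions().keys()) == [frozenset({"C", "D"})]
        # least-squares brute force over the three topologies agrees
        assert least_squares_topology(labels, d) in (
            frozenset({"A", "B"}),
            frozenset({"C", "D"}),
        )
        pd = tree_path_distances(tree)
        idx = {l: i for i, l in enumerate(pd.labels)}
        # internal branch = dAC - dAB/2 - dCD/2 = 4 - 1 - 1 = 2
        internal = (
            pd.matrix[idx["A"], idx["C"]]
            - pd.matrix[idx["A"], idx["B"]] / 2
            - pd.matrix[idx["C"], idx["D"]] / 2
        )
        assert internal == pytest.approx(2.0, abs=1e-9)

    def test_additive_matrix_reproduced(self, rng):
        labels = [f"t{i}" for i in range(6)]
        truth = random_binary_tree(labels, rng)
        dm = tree_path_distances(truth)
        rebuilt = nj_tree(dm)
        np.testing.assert_allclose(
            tree_path_distances(rebuilt).matrix, dm.matrix, atol=1e-9
        )

    def test_nj_consistency_random_additive(self, rng):
        for trial in range(15):
            n = int(rng.integers(4, 9))
            truth = random_binary_tree([f"t{i}" for i in range(n)], rng)
            rebuilt = nj_tree(tree_path_distances(truth))
            assert rf_distance(truth, rebuilt) == 0

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], float)
        with pytest.raises(ValueError):
            DistanceMatrix(labels=list("ABC"), matrix=d)

    def test_too_few_labels_rejected(self):
        with pytest.raises(InputError):
            nj_tree(DistanceMatrix(labels=["A", "B"], matrix=np.zeros((2, 2))))


def two_block_msa(n_per_block=4, n_cols=60, seed=3):
    rng = np.random.default_rng(seed)
    base_a = "".join("ACDW"[int(rng.integers(0, 4))] for _ in range(n_cols))
    base_b = "".join("KLMN"[int(rng.integers(0, 4))] for _ in range(n_cols))

    def jitter(base):
        chars = list(base)
        for i in range(len(chars)):
            if rng.random() < 0.05:
                chars[i] = "ACDWKLMN"[int(rng.integers(0, 8))]
        return "".join(chars)

    ids = [f"a{i}" for i in range(n_per_block)] + [f"b{i}" for i in range(n_per_block)]
    rows = [jitter(base_a) for _ in range(n_per_block)] + [
        jitter(base_b) for _ in range(n_per_block)
    ]
    return MSA(ids=ids, rows=rows)


class TestBootstrap:
    def test_zero_replicates_no_supports(self):
        msa = two_block_msa()
        tree = bootstrap_supports(msa, B=0)
        assert all(
            n.support is None for n in SupportTree._walk(tree.root)
        )

    def test_negative_replicates_rejected(self):
        with pytest.raises(InputError):
            bootstrap_supports(two_block_msa(), B=-1)

    def test_planted_split_high_support(self):
        msa = two_block_msa()
        tree = bootstrap_supports(msa, B=100, seed=3)
        splits = tree.bipartitions()
        block_a = frozenset({"a0", "a1", "a2", "a3"})
        block_b = frozenset({"b0", "b1", "b2", "b3"})
        central = [s for side, s in splits.items() if side in (block_a, block_b)]
        assert central and central[0] >= 95

    def test_supports_in_range(self):
        tree = bootstrap_supports(two_block_msa(), B=20, seed=1)
        for node in SupportTree._walk(tree.root):
            if node.support is not None:
                assert 0 <= node.support <= 100

    def test_deterministic(self):
        msa = two_block_msa()
        t1 = bootstrap_supports(msa, B=25, seed=7)
        t2 = bootstrap_supports(msa, B=25, seed=7)
        assert t1.newick() == t2.newick()

    def test_invariant_to_leaf_permutation(self):
        msa = two_block_msa()
        perm = MSA(ids=list(reversed(msa.ids)), rows=list(reversed(msa.rows)))
        t1 = bootstrap_supports(msa, B=30, seed=11)
        t2 = bootstrap_supports(perm, B=30, seed=11)
        assert t1.bipartitions() == t2.bipartitions()


EXAMPLE_NEWICK = "((A:1,B:1)90:1,(C:1,D:1)60:1,E:1);"


class TestSubclade:
    def test_all_leaves(self):
        tree = read_newick(EXAMPLE_NEWICK, is_path=False)
        sc = extract_subclade(tree, {"A", "B", "C", "D", "E"})
        assert sc.leaves == frozenset("ABCDE")
        assert "span the root" in sc.note

    def test_supported_pair(self):
        tree = read_newick(EXAMPLE_NEWICK, is_path=False)
        sc = extract_subclade(tree, {"A", "B"}, min_support=70)
        assert sc.leaves == frozenset({"A", "B"})
        assert sc.support == 90
        assert not sc.low_support

    def test_low_support_pair(self):
        tree = read_newick(EXAMPLE_NEWICK, is_path=False)
        sc = extract_subclade(tree, {"C", "D"}, min_support=70)
        assert sc.leaves == frozenset({"C", "D"})
        assert sc.support == 60
        assert sc.low_support

    def test_unknown_seed_rejected(self):
        tree = read_newick(EXAMPLE_NEWICK, is_path=False)
        with pytest.raises(InputError, match="Q"):
            extract_subclade(tree, {"A", "Q"})

    def test_empty_seeds_rejected(self):
        tree = read_newick(EXAMPLE_NEWICK, is_path=False)
        with pytest.raises(InputError):
            extract_subclade(tree, set())

    def test_agrees_with_bipartition_enumeration(self, rng):
        for trial in range(10):
            n = int(rng.integers(5, 13))
            labels = [f"L{i}" for i in range(n)]
            tree = random_binary_tree(labels, rng)
            seeds = set(
                rng.choice(labels, size=int(rng.integers(1, 4)), replace=False)
            )
            sc = extract_subclade(tree, seeds)
            # oracle: smallest side over all bipartitions (both orientations)
            sides = [frozenset(labels)]
            for node in SupportTree._walk(tree.root):
                if node is tree.root:
                    continue
                side = node.leaf_set()
                sides.append(side)
                sides.append(frozenset(labels) - side)
            containing = [s for s in sides if seeds <= s]
            assert sc.leaves == min(containing, key=lambda s: (len(s), sorted(s)))


class TestNewickIO:
    def test_round_trip(self, tmp_path):
        tree = read_newick(EXAMPLE_NEWICK, is_path=False)
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        again = read_newick(path)
        assert again.bipartitions() == tree.bipartitions()
        assert again.leaf_labels == tree.leaf_labels

    def test_supports_parsed_from_internal_labels(self):
        tree = read_newick(EXAMPLE_NEWICK, is_path=False)
        assert set(tree.bipartitions().values()) == {90.0, 60.0}
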