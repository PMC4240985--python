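"""Tree inference: closed-form distances, NJ recovery (with an independent
scikit-bio oracle), Fitch against brute-force state enumeration, exact
parsimony, monophyly/RF and Newick round trips."""

import itertools

import dendropy
import numpy as np
import pytest

from hybparent import simgen
from hybparent import treekit as tk
from hybparent.alignment import Alignment
from hybparent.markerstats import variable_site_count


def aln(*rows, labels=None):
    labels = labels or [f"t{i}" for i in range(len(rows))]
    return Alignment.from_seqs(labels, list(rows))


def random_tree_with_distances(seed, n):
    """A random binary tree with strictly positive branches and its exact
    path-length distance matrix."""
    tree = simgen.simulate_species_tree(n, 1.0, seed=seed)
    rng = np.random.default_rng(seed + 1)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = float(edge.length) + rng.uniform(0.05, 0.5)
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    pdm = tree.phylogenetic_distance_matrix()
    tns = tree.taxon_namespace
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        D[i, j] = D[j, i] = pdm.distance(
            tns.get_taxon(labels[i]), tns.get_taxon(labels[j])
        )
    return tree, tk.DistanceMatrix(labels, D)


# -- distances --------------------------------------------------------------


def test_p_distance_identical_rows_zero():
    D = tk.pairwise_distance(aln("ACGT", "ACGT", "ACGA"))
    assert D.get("t0", "t1") == 0.0
    assert D.get("t0", "t2") == pytest.approx(0.25)


def test_jc_distance_closed_form():
    # p = 0.1 -> -(3/4) ln(1 - 4*0.1/3) = 0.10732
    rows = ["A" * 9 + "C", "A" * 9 + "G"]
    a = aln("A" * 10, rows[1])
    D = tk.pairwise_distance(a, "JC69")
    assert D.get("t0", "t1") == pytest.approx(0.10732, abs=1e-5)


def test_jc_saturation_flagged_and_capped():
    a = aln("ACGT", "CATG")  # p = 1.0
    D = tk.pairwise_distance(a, "JC69")
    assert frozenset(("t0", "t1")) in D.saturated
    assert D.get("t0", "t1") == tk.SATURATION_CAP


def test_distance_requires_comparable_sites():
    with pytest.raises(ValueError, match="t0.*t1"):
        tk.pairwise_distance(aln("A-", "-A"))


# -- neighbor joining -------------------------------------------------------

FOUR_POINT = tk.DistanceMatrix(
    list("ABCD"),
    np.array(
        [
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ],
        dtype=float,
    ),
)


def test_nj_recovers_four_point_split():
    tree = tk.neighbor_joining(FOUR_POINT)
    assert tk.bipartitions(tree) == {frozenset("CD")}  # AB|CD


def test_nj_realizes_additive_distances_exactly():
    tree = tk.neighbor_joining(FOUR_POINT)
    pdm = tree.phylogenetic_distance_matrix()
    tns = tree.taxon_namespace
    for a, b in itertools.combinations("ABCD", 2):
        assert pdm.distance(tns.get_taxon(a), tns.get_taxon(b)) == pytest.approx(
            FOUR_POINT.get(a, b)
        )


def test_nj_three_taxa_closed_form():
    D = tk.DistanceMatrix(
        list("ABC"), np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
    )
    tree = tk.neighbor_joining(D)
    lengths = {
        lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
    }
    assert lengths == pytest.approx({"A": 0.0, "B": 2.0, "C": 3.0})


def test_nj_rejects_asymmetric_input():
    with pytest.raises(ValueError, match="symmetric"):
        tk.DistanceMatrix(list("AB"), np.array([[0.0, 1.0], [2.0, 0.0]]))


def test_nj_negative_branch_clamped_with_warning():
    D = tk.DistanceMatrix(
        list("ABCD"),
        np.array(
            [
                [0.0, 0.1, 1.0, 1.0],
                [0.1, 0.0, 0.2, 1.0],
                [1.0, 0.2, 0.0, 1.0],
                [1.0, 1.0, 1.0, 0.0],
            ]
        ),
    )
    with pytest.warns(UserWarning, match="clamped"):
        tree = tk.neighbor_joining(D)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            assert edge.length >= 0


def test_nj_consistency_against_skbio_oracle():
    """On additive distances NJ must recover the generating topology and
    agree with scikit-bio's independent implementation."""
    import skbio

    for seed in range(5):
        true_tree, D = random_tree_with_distances(seed, 4 + seed)
        mine = tk.neighbor_joining(D)
        assert tk.robinson_foulds(mine, true_tree) == 0
        sk = skbio.tree.nj(
            skbio.DistanceMatrix(D.matrix, ids=D.labels)
        )
        ref = tk.tree_from_newick_string(str(sk))
        assert tk.robinson_foulds(mine, ref) == 0


# -- Fitch ------------------------------------------------------------------


def _brute_fitch(tree, alignment):
    """Minimal changes by enumerating every internal-state assignment."""
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    edges = [
        (n.parent_node, n)
        for n in tree.preorder_node_iter()
        if n.parent_node is not None
    ]
    row = {lbl: i for i, lbl in enumerate(alignment.labels)}
    total = 0
    for col in range(alignment.length):
        leaf_state = {
            n: chr(alignment.matrix[row[n.taxon.label], col])
            for n in tree.leaf_node_iter()
        }
        best = None
        for combo in itertools.product("ACGT", repeat=len(internals)):
            state = dict(zip(internals, combo))
            state.update(leaf_state)
            cost = sum(state[u] != state[v] for u, v in edges)
            best = cost if best is None else min(best, cost)
        total += best
    return total


def test_fitch_hand_examples():
    ab_cd = tk.tree_from_newick_string("((A,B),(C,D));")
    ac_bd = tk.tree_from_newick_string("((A,C),(B,D));")
    col = aln("A", "A", "G", "G", labels=list("ABCD"))
    assert tk.fitch_score(ab_cd, col) == 1
    assert tk.fitch_score(ac_bd, col) == 2
    invariant = aln("A", "A", "A", "A", labels=list("ABCD"))
    assert tk.fitch_score(ab_cd, invariant) == 0


def test_fitch_matches_assignment_enumeration_oracle(rng):
    for seed in range(6):
        n = int(rng.integers(4, 7))
        tree = simgen.simulate_species_tree(n, 1.0, seed=seed)
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        rows = ["".join(rng.choice(list("ACGT"), 10)) for _ in labels]
        a = Alignment.from_seqs(labels, rows)
        assert tk.fitch_score(tree, a) == _brute_fitch(tree, a)


def test_fitch_reports_label_mismatch():
    tree = tk.tree_from_newick_string("((A,B),(C,D));")
    with pytest.raises(ValueError, match="E"):
        tk.fitch_score(tree, aln("A", "A", "G", "G", labels=list("ABCE")))


# -- parsimony search -------------------------------------------------------


def test_topology_enumeration_census():
    # (2n-5)!! unrooted binary topologies
    for n, expect in ((4, 3), (5, 15), (6, 105)):
        trees = tk.enumerate_topologies(n)
        labels = [f"t{i}" for i in range(n)]
        splits = {frozenset(t.splits(labels)) for t in trees}
        assert len(trees) == len(splits) == expect


def test_exact_parsimony_single_informative_column():
    a = aln("ATTT", "ATTA", "GTTT", "GTTA", labels=list("ABCD"))
    # column 4 supports AC|BD (A,G split is uninformative: col 1 A,A,G,G
    # supports AB|CD; col 4 T,A,T,A supports AC|BD) -> build a clean case
    a = aln("A", "A", "G", "G", labels=list("ABCD"))
    trees, score = tk.parsimony_search(a, exhaustive_max=4)
    assert score == 1
    assert len(trees) == 1
    assert tk.bipartitions(trees[0]) == {frozenset("CD")}


def test_exact_parsimony_zero_variable_sites_all_cooptimal():
    a = aln("AAAA", "AAAA", "AAAA", "AAAA", "AAAA", labels=list("ABCDE"))
    trees, score = tk.parsimony_search(a, exhaustive_max=5)
    assert score == 0
    assert len(trees) == 15


def test_exact_parsimony_equals_enumeration_with_oracle_scores(rng):
    for seed in range(3):
        n = 6
        labels = [f"t{i}" for i in range(n)]
        rows = ["".join(rng.choice(list("ACGT"), 8)) for _ in range(n)]
        a = Alignment.from_seqs(labels, rows)
        trees, score = tk.parsimony_search(a, exhaustive_max=6)
        oracle = min(
            _brute_fitch(t.to_dendropy(labels), a)
            for t in tk.enumerate_topologies(n)
        )
        assert score == oracle
        assert all(tk.fitch_score(t, a) == score for t in trees)


def test_exhaustive_refused_above_hard_cap():
    labels = [f"t{i}" for i in range(10)]
    a = Alignment.from_seqs(labels, ["ACGTACGT"] * 10)
    with pytest.raises(ValueError, match="refused"):
        tk.parsimony_search(a, exhaustive_max=12)


def test_heuristic_never_worse_than_nj_topology(rng):
    for seed in range(5):
        n = 10
        tree = simgen.simulate_species_tree(n, 1.0, seed=100 + seed)
        a = simgen.evolve_locus(tree, 300, 0.05, seed=200 + seed)
        _, heur = tk.parsimony_search(a, exhaustive_max=0, seed=seed)
        nj = tk.neighbor_joining(tk.pairwise_distance(a, "p"))
        assert heur <= tk.fitch_score(nj, a)


# -- monophyly and RF -------------------------------------------------------


def test_monophyly_examples():
    tree = tk.tree_from_newick_string("((A,B),(C,D));")
    assert tk.is_monophyletic(tree, {"A"})
    assert tk.is_monophyletic(tree, {"A", "B", "C", "D"})
    assert tk.is_monophyletic(tree, {"A", "B"})
    assert not tk.is_monophyletic(tree, {"A", "C"})
    with pytest.raises(ValueError, match="Z"):
        tk.is_monophyletic(tree, {"Z"})


def test_rf_examples_and_symmetry():
    t1 = tk.tree_from_newick_string("((A,B),(C,D));")
    t2 = tk.tree_from_newick_string("((A,C),(B,D));")
    assert tk.robinson_foulds(t1, t1) == 0
    assert tk.robinson_foulds(t1, t2) == 2
    assert tk.robinson_foulds(t2, t1) == 2


def test_rf_agrees_with_dendropy():
    for seed in range(5):
        t1, _ = random_tree_with_distances(seed, 8)
        t2, _ = random_tree_with_distances(seed + 50, 8)
        tns = dendropy.TaxonNamespace()
        a = dendropy.Tree.get(
            data=tk.tree_to_newick_string(t1), schema="newick",
            taxon_namespace=tns, preserve_underscores=True,
        )
        b = dendropy.Tree.get(
            data=tk.tree_to_newick_string(t2), schema="newick",
            taxon_namespace=tns, preserve_underscores=True,
        )
        a.encode_bipartitions()
        b.encode_bipartitions()
        ref = dendropy.calculate.treecompare.symmetric_difference(a, b)
        assert tk.robinson_foulds(t1, t2) == ref


def test_rf_rejects_leafset_mismatch():
    t1 = tk.tree_from_newick_string("((A,B),(C,D));")
    t2 = tk.tree_from_newick_string("((A,B),(C,E));")
    with pytest.raises(ValueError, match="E"):
        tk.robinson_foulds(t1, t2)


# -- bootstrap and concatenation --------------------------------------------


def test_bootstrap_reproducible_and_bounded():
    tree = simgen.simulate_species_tree(6, 1.0, seed=3)
    a = simgen.evolve_locus(tree, 500, 0.03, seed=4)
    b1 = tk.bootstrap_support(a, reps=25, seed=9)
    b2 = tk.bootstrap_support(a, reps=25, seed=9)
    assert b1.split_support == b2.split_support
    assert all(0 <= v <= 100 for v in b1.split_support.values())
    # support annotations survive Newick round trip
    s = tk.tree_to_newick_string(b1)
    back = tk.tree_from_newick_string(s)
    assert tk.robinson_foulds(back, b1) == 0


def test_concatenate_lengths_and_column_local_stats_add():
    t = simgen.simulate_species_tree(5, 1.0, seed=7)
    l1 = simgen.evolve_locus(t, 100, 0.05, seed=8)
    l2 = simgen.evolve_locus(t, 200, 0.05, seed=9)
    l1.locus, l2.locus = "l1", "l2"
    cat = tk.concatenate([l1, l2])
    assert cat.length == 300
    assert cat.partitions == [("l1", 0, 100), ("l2", 100, 300)]
    assert variable_site_count(cat) == variable_site_count(
        l1
    ) + variable_site_count(l2)


def test_concatenate_pads_missing_taxa_with_warning():
    l1 = aln("ACGT", "ACGA", labels=["x", "y"])
    l2 = aln("GGGG", "GGGA", labels=["x", "z"])
    l1.locus, l2.locus = "l1", "l2"
    with pytest.warns(UserWarning, match="padded"):
        cat = tk.concatenate([l1, l2])
    assert cat.row("y") == "ACGANNNN"
    assert cat.row("z") == "NNNNGGGA"


# -- Newick I/O -------------------------------------------------------------


def test_newick_round_trip_files(tmp_path):
    path = tmp_path / "t.nwk"
    t = tk.tree_from_newick_string("(A:1,(B:1,C:1):1);")
    tk.write_newick(t, path)
    back = tk.read_newick(path)
    assert tk.robinson_foulds(back, t) == 0


def test_newick_round_trip_random_trees(tmp_path):
    for seed in range(10):
        t, _ = random_tree_with_distances(seed, 4 + seed % 6)
        path = tmp_path / f"t{seed}.nwk"
        tk.write_newick(t, path)
        assert tk.robinson_foulds(tk.read_newick(path), t) == 0


def test_newick_parse_error_reported():
    with pytest.raises(Exception):
        tk.tree_from_newick_string("((A,B),(C,D);")
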