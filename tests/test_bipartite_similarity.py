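"""PCC association index, vaccine projection, clustering, strata comparison."""

import math

import numpy as np
import pytest

from vaersnet import (
    PlantedSignal,
    SimilarityMatrix,
    SyntheticConfig,
    build_network,
    cluster_vaccines,
    compare_strata,
    compute_prrs,
    count_pairs,
    generate_reports,
    pcc_index,
    significant_associations,
    similarity_matrix,
)

from oracles import binary_vector_pearson, random_bipartite_network


def test_pcc_closed_forms():
    # perfect overlap → 1 for any valid degree
    assert pcc_index(3, 3, 3, 10) == 1.0
    # expected-by-chance overlap (4·5/10 = 2) → 0
    assert pcc_index(4, 5, 2, 10) == 0.0
    # maximal disjointness → -1
    assert pcc_index(5, 5, 0, 10) == -1.0


def test_pcc_undefined_at_degree_extremes():
    assert math.isnan(pcc_index(0, 3, 0, 10))
    assert math.isnan(pcc_index(10, 3, 3, 10))  # node connected to every AE


@pytest.mark.parametrize(
    "args", [(3, 2, 3, 10), (11, 2, 1, 10), (-1, 2, 0, 10), (2, 2, -1, 10)]
)
def test_pcc_precondition_violations(args):
    with pytest.raises(ValueError):
        pcc_index(*args)


def test_pcc_symmetric_and_monotone():
    rng = np.random.default_rng(0)
    for _ in range(100):
        n_y = int(rng.integers(3, 40))
        a = int(rng.integers(1, n_y))
        b = int(rng.integers(1, n_y))
        hi = min(a, b)
        s = int(rng.integers(0, hi + 1))
        assert pcc_index(a, b, s, n_y) == pcc_index(b, a, s, n_y)
        if s < hi:  # strictly increasing in the overlap
            assert pcc_index(a, b, s + 1, n_y) > pcc_index(a, b, s, n_y)


def test_pcc_equals_binary_vector_pearson():
    """The index is the textbook Pearson correlation of incidence vectors."""
    rng = np.random.default_rng(1)
    for _ in range(200):
        n_y = int(rng.integers(3, 60))
        a = int(rng.integers(1, n_y))
        b = int(rng.integers(1, n_y))
        # realisable overlap: the union of the two neighbourhoods fits in n_y
        s = int(rng.integers(max(0, a + b - n_y), min(a, b) + 1))
        got = pcc_index(a, b, s, n_y)
        want = binary_vector_pearson(a, b, s, n_y)
        assert got == pytest.approx(want, abs=1e-12)


def test_identical_neighbourhoods_give_one():
    net = build_network([("V1", "a"), ("V1", "b"), ("V2", "a"), ("V2", "b"), ("V3", "c")])
    sim = similarity_matrix(net)
    i, j = sim.labels.index("V1"), sim.labels.index("V2")
    assert sim.values[i, j] == 1.0
    assert sim.n_y == 3


def test_matrix_symmetric_and_unit_diagonal():
    rng = np.random.default_rng(2)
    net = random_bipartite_network(rng, max_nodes=60)
    sim = similarity_matrix(net)
    assert np.array_equal(sim.values, sim.values.T, equal_nan=True)
    deg = {v: sum(1 for e in net.edges if e[0] == v) for v in sim.labels}
    for i, lab in enumerate(sim.labels):
        if 0 < deg[lab] < sim.n_y:
            assert sim.values[i, i] == 1.0


@pytest.mark.parametrize("seed", range(5))
def test_matrix_matches_set_based_oracle(seed):
    """Vectorised matrix equals per-pair recomputation from materialised sets."""
    rng = np.random.default_rng(seed)
    net = random_bipartite_network(rng, max_nodes=50)
    if len(net.vaccine_nodes) < 2:
        pytest.skip("degenerate draw")
    sim = similarity_matrix(net)
    nbrs = {v: {s for (vv, s) in net.edges if vv == v} for v in sim.labels}
    for i, a in enumerate(sim.labels):
        for j, b in enumerate(sim.labels):
            expected = pcc_index(len(nbrs[a]), len(nbrs[b]), len(nbrs[a] & nbrs[b]), sim.n_y)
            got = sim.values[i, j]
            assert (math.isnan(expected) and math.isnan(got)) or expected == got


def test_matrix_requires_two_nodes():
    net = build_network([("V1", "a"), ("V1", "b")])
    with pytest.raises(ValueError, match="at least 2"):
        similarity_matrix(net, project_onto="vaccine")


def test_first_merge_is_forced():
    """A,B at PCC 0.9 and each at 0.1 with C must merge first."""
    values = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.1], [0.1, 0.1, 1.0]])
    sim = SimilarityMatrix(labels=("A", "B", "C"), values=values, n_y=10)
    tree = cluster_vaccines(sim)
    first = tree.linkage[0]
    merged = {tree.labels[int(first[0])], tree.labels[int(first[1])]}
    assert merged == {"A", "B"}
    assert tree.cut(2) == {"A": tree.cut(2)["B"], "B": tree.cut(2)["B"], "C": tree.cut(2)["C"]}


def test_merge_heights_monotone(small_corpus):
    reports, _ = small_corpus
    records, ctx = count_pairs(reports)
    compute_prrs(records, ctx)
    net = build_network(significant_associations(records, "overall"))
    tree = cluster_vaccines(similarity_matrix(net))
    heights = tree.merge_heights()
    assert np.all(np.diff(heights) >= -1e-12)


def test_permutation_gives_isomorphic_tree():
    rng = np.random.default_rng(7)
    net = random_bipartite_network(rng, max_nodes=40)
    sim = similarity_matrix(net)
    perm = rng.permutation(len(sim.labels))
    shuffled = SimilarityMatrix(
        labels=tuple(sim.labels[i] for i in perm),
        values=sim.values[np.ix_(perm, perm)],
        n_y=sim.n_y,
    )
    t1, t2 = cluster_vaccines(sim), cluster_vaccines(shuffled)
    assert t1.labels == t2.labels  # both lexicographically ordered
    assert np.allclose(t1.merge_heights(), t2.merge_heights())
    for k in (2, 3):
        c1, c2 = t1.cut(k), t2.cut(k)
        part1 = {frozenset(l for l, c in c1.items() if c == g) for g in set(c1.values())}
        part2 = {frozenset(l for l, c in c2.items() if c == g) for g in set(c2.values())}
        assert part1 == part2


def test_all_undefined_matrix_rejected():
    values = np.full((2, 2), np.nan)
    with pytest.raises(ValueError, match="undefined"):
        cluster_vaccines(SimilarityMatrix(labels=("A", "B"), values=values, n_y=4))


def test_two_planted_groups_recovered():
    """Vaccine groups sharing distinct AE sets separate at a 2-cluster cut."""
    group1 = ["G1a", "G1b", "G1c"]
    group2 = ["G2a", "G2b", "G2c"]
    aes1 = [f"A{i}" for i in range(4)]
    aes2 = [f"B{i}" for i in range(4)]
    cfg = SyntheticConfig(
        n_reports=8000,
        seed=13,
        vaccine_catalog={v: 1 / 6 for v in group1 + group2},
        symptom_catalog={s: 0.002 for s in aes1 + aes2},
        planted_signals=[PlantedSignal(v, s, "both", 100.0) for v in group1 for s in aes1]
        + [PlantedSignal(v, s, "both", 100.0) for v in group2 for s in aes2],
    )
    reports, _ = generate_reports(cfg)
    records, ctx = count_pairs(reports)
    compute_prrs(records, ctx)
    net = build_network(significant_associations(records, "overall"))
    tree = cluster_vaccines(similarity_matrix(net))
    cut = tree.cut(2)
    assert len({cut[v] for v in group1}) == 1
    assert len({cut[v] for v in group2}) == 1
    assert cut[group1[0]] != cut[group2[0]]


def test_newick_is_valid(small_corpus):
    dendropy = pytest.importorskip("dendropy")
    reports, _ = small_corpus
    records, ctx = count_pairs(reports)
    compute_prrs(records, ctx)
    net = build_network(significant_associations(records, "overall"))
    tree = cluster_vaccines(similarity_matrix(net))
    parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
    leaves = {leaf.taxon.label.replace(" ", "_") for leaf in parsed.leaf_node_iter()}
    assert leaves == {l.replace(" ", "_") for l in tree.labels}


def test_compare_identical_matrices():
    values = np.array([[1.0, 0.4], [0.4, 1.0]])
    sim = SimilarityMatrix(labels=("A", "B"), values=values, n_y=5)
    comp = compare_strata(sim, sim)
    assert comp.ks_distance == 0.0
    assert np.array_equal(comp.values_a, comp.values_b)


def test_compare_restricts_to_common_labels():
    v1 = np.eye(3) * 0.5 + 0.5
    a = SimilarityMatrix(labels=("A", "B", "C"), values=v1, n_y=5)
    b = SimilarityMatrix(labels=("B", "C", "D"), values=v1, n_y=5)
    comp = compare_strata(a, b)
    assert comp.common_labels == ("B", "C")
    assert comp.values_a.size == 1  # single off-diagonal pair
    single = SimilarityMatrix(labels=("X", "B"), values=np.eye(2), n_y=5)
    with pytest.raises(ValueError, match="common labels"):
        compare_strata(a, single)


def test_compare_sexes_on_planted_corpus(small_corpus):
    """A female-only planted signal separates the two PCC distributions."""
    reports, _ = small_corpus
    records, ctx = count_pairs(reports)
    compute_prrs(records, ctx)
    sims = {}
    for g in ("F", "M"):
        net = build_network(significant_associations(records, ("sex", g)))
        sims[g] = similarity_matrix(net)
    comp = compare_strata(sims["F"], sims["M"])
    assert comp.ks_distance > 0
    assert len(comp.common_labels) >= 2
    assert comp.density["count_a"].sum() == comp.values_a.size
    assert (comp.density["bin_right"] - comp.density["bin_left"]).round(6).eq(0.05).all()
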