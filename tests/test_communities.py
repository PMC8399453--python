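import networkx as nx
import numpy as np
import pytest

from patentscape.communities import (
    community_keywords,
    louvain,
    modularity,
    partition_to_frame,
    profiles_to_frame,
    profiles_to_wide,
)
from patentscape.vectorize import PatentVector

from oracles import exhaustive_best_modularity, modularity_oracle


def two_triangles() -> nx.Graph:
    return nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])


def two_cliques(k=4) -> nx.Graph:
    g = nx.disjoint_union(nx.complete_graph(k), nx.complete_graph(k))
    return g


# ---------------------------------------------------------------------------
# modularity closed forms
# ---------------------------------------------------------------------------


def test_one_community_partition_has_zero_modularity():
    for g in (two_triangles(), nx.path_graph(6), nx.karate_club_graph()):
        q = modularity(g, {n: 0 for n in g.nodes()})
        assert q == pytest.approx(0.0, abs=1e-15)


def test_two_disconnected_triangles_give_half():
    g = two_triangles()
    membership = {0: "a", 1: "a", 2: "a", 3: "b", 4: "b", 5: "b"}
    # hand evaluation: 2 * (3/6 - (6/12)^2) = 0.5
    assert modularity(g, membership) == pytest.approx(0.5, abs=1e-15)


def test_single_edge_split_gives_minus_half():
    g = nx.Graph([(0, 1)])
    # 2 * (0 - (1/2)^2) = -0.5
    assert modularity(g, {0: 0, 1: 1}) == pytest.approx(-0.5, abs=1e-15)


def test_modularity_undefined_without_edges():
    with pytest.raises(ValueError):
        modularity(nx.empty_graph(3), {n: 0 for n in range(3)})


def test_modularity_agrees_with_networkx_on_random_partitions():
    rng = np.random.default_rng(3)
    for _ in range(10):
        g = nx.gnp_random_graph(12, 0.3, seed=int(rng.integers(2**31)))
        if g.number_of_edges() == 0:
            continue
        labels = rng.integers(0, 3, size=12)
        membership = {n: int(labels[n]) for n in g.nodes()}
        blocks = [[n for n in g.nodes() if membership[n] == c] for c in set(labels)]
        blocks = [b for b in blocks if b]
        expected = nx.community.modularity(g, blocks)
        assert modularity(g, membership) == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# louvain
# ---------------------------------------------------------------------------


def test_louvain_recovers_two_cliques_exactly():
    g = two_cliques(4)
    part = louvain(g, seed=0)
    assert part.n_communities == 2
    assert {frozenset(part.community(c)) for c in part.sizes} == {
        frozenset(range(4)),
        frozenset(range(4, 8)),
    }
    # exhaustive oracle over all partitions of the 8 nodes
    assert part.q == pytest.approx(exhaustive_best_modularity(g), abs=1e-12)


def test_louvain_merges_single_edge():
    part = louvain(nx.Graph([(0, 1)]), seed=0)
    assert part.n_communities == 1
    assert part.q == pytest.approx(0.0, abs=1e-15)
    # exhaustive check: Q=0 (together) beats Q=-0.5 (apart)
    assert exhaustive_best_modularity(nx.Graph([(0, 1)])) == pytest.approx(0.0, abs=1e-15)


def test_louvain_never_beats_exhaustive_optimum_small_graphs():
    rng = np.random.default_rng(17)
    graphs = [two_triangles(), nx.path_graph(5), nx.cycle_graph(6), nx.star_graph(5)]
    for _ in range(10):
        g = nx.gnp_random_graph(7, 0.35, seed=int(rng.integers(2**31)))
        if g.number_of_edges() > 0:
            graphs.append(g)
    for g in graphs:
        part = louvain(g, seed=1)
        best = exhaustive_best_modularity(g)
        q = modularity_oracle(
            g, [list(part.community(c)) for c in part.sizes]
        )
        assert q <= best + 1e-12


def test_louvain_not_below_singleton_start():
    rng = np.random.default_rng(23)
    for _ in range(5):
        g = nx.gnp_random_graph(15, 0.2, seed=int(rng.integers(2**31)))
        if g.number_of_edges() == 0:
            continue
        singleton_q = modularity(g, {n: n for n in g.nodes()})
        part = louvain(g, seed=2)
        assert part.q >= singleton_q - 1e-12
        assert part.q >= -1e-12  # never worse than the trivial one-community split


def test_louvain_deterministic_given_seed():
    g = nx.karate_club_graph()
    a = louvain(g, seed=5)
    b = louvain(g, seed=5)
    assert a.membership == b.membership and a.q == b.q


def test_louvain_relabeling_invariance():
    from sklearn.metrics import normalized_mutual_info_score

    g = two_cliques(5)
    part = louvain(g, seed=0)
    relabel = {n: f"z{(n * 7) % 10:02d}" for n in g.nodes()}
    g2 = nx.relabel_nodes(g, relabel)
    part2 = louvain(g2, seed=0)
    a = [part.membership[n] for n in sorted(g.nodes())]
    b = [part2.membership[relabel[n]] for n in sorted(g.nodes())]
    assert normalized_mutual_info_score(a, b) == pytest.approx(1.0)


def test_louvain_labels_ordered_by_size():
    g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(3))
    part = louvain(g, seed=0)
    sizes = [part.sizes[c] for c in sorted(part.sizes)]
    assert sizes == sorted(sizes, reverse=True)
    assert min(part.sizes) == 1  # labels numbered from 1


def test_louvain_rejects_edgeless_graph():
    with pytest.raises(ValueError):
        louvain(nx.empty_graph(4), seed=0)


# ---------------------------------------------------------------------------
# community keyword profiles
# ---------------------------------------------------------------------------


def test_profile_single_patent_community():
    g = nx.Graph([("P1", "P2")])
    part = louvain(g, seed=0)
    vectors = {
        "P1": PatentVector("P1", [("a", 2), ("b", 1)]),
        "P2": PatentVector("P2", [("a", 1), ("c", 4)]),
    }
    profiles = community_keywords(part, vectors, n=10)
    assert len(profiles) == 1
    top = dict(profiles[0].top_words)
    assert top == {"a": 1.0, "b": 0.5, "c": 0.5}
    # non-increasing frequencies, ties alphabetical
    assert [w for w, _ in profiles[0].top_words] == ["a", "b", "c"]


def test_profile_frequencies_are_document_proportions():
    g = two_cliques(2)  # two components of 2 nodes each
    part = louvain(g, seed=0)
    vectors = {
        0: PatentVector(0, [("x", 9)]),
        1: PatentVector(1, [("x", 1), ("y", 1)]),
        2: PatentVector(2, [("z", 3)]),
        3: PatentVector(3, [("z", 1)]),
    }
    profiles = community_keywords(part, vectors, n=5)
    by_label = {p.label: dict(p.top_words) for p in profiles}
    # frequency counts documents containing the word, not token share
    assert {"x": 1.0, "y": 0.5} in by_label.values()
    assert {"z": 1.0} in by_label.values()
    for p in profiles:
        assert all(0.0 <= f <= 1.0 for _, f in p.top_words)
        freqs = [f for _, f in p.top_words]
        assert freqs == sorted(freqs, reverse=True)


def test_profile_requires_vector_per_node():
    g = nx.Graph([("P1", "P2")])
    part = louvain(g, seed=0)
    with pytest.raises(KeyError):
        community_keywords(part, {"P1": PatentVector("P1", [("a", 1)])})


def test_profile_exports():
    g = two_cliques(3)
    part = louvain(g, seed=0)
    vectors = {n: PatentVector(n, [(f"w{n % 2}", 1)]) for n in g.nodes()}
    profiles = community_keywords(part, vectors, n=5)
    long_df = profiles_to_frame(profiles)
    assert list(long_df.columns) == ["community", "size", "rank", "word", "frequency"]
    wide = profiles_to_wide(profiles, n=5)
    assert wide.shape[0] == 5
    pf = partition_to_frame(part)
    assert set(pf["patent_id"]) == set(g.nodes())
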