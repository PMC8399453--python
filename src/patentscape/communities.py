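"""Modularity communities and per-community keyword profiles.

The community structure of a patent network — groups whose internal links
are denser than their links to the rest of the network — is found by a
from-scratch Louvain algorithm: greedy two-phase modularity maximization
(local single-node moves to the best-gain neighboring community until no
move helps, then aggregation of communities into super-nodes, iterated to
convergence).  Modularity is the standard Newman–Girvan quality

    Q = sum_c [ e_c / m  -  (d_c / 2m)^2 ]

with m edges, e_c intra-community edges and d_c the total degree of
community c (edge weights generalize all three quantities during the
aggregation phase).  Resolution is fixed at 1.

Each community is profiled by the words of its members' top-M keyword
vectors: a word's relative frequency in a community is the fraction of
the community's patents whose keyword list contains it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .vectorize import PatentVector

__all__ = [
    "Partition",
    "CommunityProfile",
    "modularity",
    "louvain",
    "community_keywords",
    "partition_to_frame",
    "profiles_to_frame",
    "profiles_to_wide",
]

logger = logging.getLogger(__name__)

_GAIN_EPS = 1e-12


@dataclass
class Partition:
    """A node -> community-label map with its modularity.

    Labels are integers 1..k assigned in decreasing community size
    (ties by smallest member id), matching the usual presentation of
    community tables.
    """

    membership: dict
    q: float
    sizes: dict[int, int]

    @property
    def n_communities(self) -> int:
        return len(self.sizes)

    def community(self, label: int) -> list:
        return [n for n, c in self.membership.items() if c == label]


@dataclass
class CommunityProfile:
    label: int
    size: int
    top_words: list[tuple[str, float]]  # (word, relative frequency), non-increasing


def modularity(g: nx.Graph, membership: Mapping) -> float:
    """Newman–Girvan modularity of a node->community map (weights honored;
    a self-loop counts twice toward its node's degree, as usual)."""
    m = g.size(weight="weight")
    if m == 0:
        raise ValueError("modularity undefined on an edgeless graph")
    intra: dict = {}
    deg_tot: dict = {}
    for node, deg in g.degree(weight="weight"):
        deg_tot[membership[node]] = deg_tot.get(membership[node], 0.0) + deg
    for u, v, w in g.edges(data="weight", default=1.0):
        if membership[u] == membership[v]:
            intra[membership[u]] = intra.get(membership[u], 0.0) + w
    q = 0.0
    for c in deg_tot:
        q += intra.get(c, 0.0) / m - (deg_tot[c] / (2.0 * m)) ** 2
    return q


def _one_level(
    neighbors: list[dict[int, float]],
    loops: list[float],
    m: float,
    rng,
) -> tuple[list[int], bool]:
    """One local-move phase on the (possibly aggregated) weighted graph.

    Nodes are integers 0..n-1; returns (community of each node, moved?).
    Node visit order is shuffled once per phase; ties in modularity gain
    go to the lowest community label so runs are reproducible.
    """
    n = len(neighbors)
    comm = list(range(n))
    deg = [sum(nb.values()) + 2.0 * loops[i] for i, nb in enumerate(neighbors)]
    tot = deg.copy()

    order = list(range(n))
    rng.shuffle(order)

    moved_any = False
    improved = True
    while improved:
        improved = False
        for i in order:
            c_old = comm[i]
            tot[c_old] -= deg[i]
            links: dict[int, float] = {}
            for j, w in neighbors[i].items():
                links[comm[j]] = links.get(comm[j], 0.0) + w
            best_c = c_old
            best_gain = links.get(c_old, 0.0) - tot[c_old] * deg[i] / (2.0 * m)
            for c in sorted(links):
                gain = links[c] - tot[c] * deg[i] / (2.0 * m)
                if gain > best_gain + _GAIN_EPS or (
                    abs(gain - best_gain) <= _GAIN_EPS and c < best_c
                ):
                    best_gain = gain
                    best_c = c
            tot[best_c] += deg[i]
            if best_c != c_old:
                comm[i] = best_c
                improved = True
                moved_any = True
    return comm, moved_any


def _aggregate(
    neighbors: list[dict[int, float]],
    loops: list[float],
    comm: list[int],
) -> tuple[list[dict[int, float]], list[float], list[int]]:
    """Phase two: communities become super-nodes; intra-community weight
    becomes a self-loop.  Returns (new neighbors, new loops, node->new id)."""
    labels = sorted(set(comm))
    remap = {c: i for i, c in enumerate(labels)}
    k = len(labels)
    new_neighbors: list[dict[int, float]] = [dict() for _ in range(k)]
    new_loops = [0.0] * k
    for i, nb in enumerate(neighbors):
        ci = remap[comm[i]]
        new_loops[ci] += loops[i]
        for j, w in nb.items():
            if j <= i:
                continue  # each undirected edge once
            cj = remap[comm[j]]
            if ci == cj:
                new_loops[ci] += w
            else:
                new_neighbors[ci][cj] = new_neighbors[ci].get(cj, 0.0) + w
                new_neighbors[cj][ci] = new_neighbors[cj].get(ci, 0.0) + w
    return new_neighbors, new_loops, [remap[c] for c in comm]


def louvain(g: nx.Graph, seed: int = 0) -> Partition:
    """Detect communities by greedy two-phase modularity optimization.

    Deterministic given ``seed`` (which only shuffles the node visit
    order).  The returned modularity is recomputed on the original graph
    and is never below the singleton-partition value.
    """
    import random

    if g.number_of_edges() == 0:
        raise ValueError("community detection undefined on an edgeless graph")
    nodes = sorted(g.nodes(), key=str)
    idx = {node: i for i, node in enumerate(nodes)}
    neighbors: list[dict[int, float]] = [dict() for _ in nodes]
    loops = [0.0] * len(nodes)
    for u, v, w in g.edges(data="weight", default=1.0):
        if u == v:
            loops[idx[u]] += w
        else:
            neighbors[idx[u]][idx[v]] = neighbors[idx[u]].get(idx[v], 0.0) + w
            neighbors[idx[v]][idx[u]] = neighbors[idx[v]].get(idx[u], 0.0) + w
    m = g.size(weight="weight")

    rng = random.Random(seed)
    assignment = list(range(len(nodes)))  # original node -> current super-node
    while True:
        comm, moved = _one_level(neighbors, loops, m, rng)
        if not moved:
            break
        neighbors, loops, node_map = _aggregate(neighbors, loops, comm)
        # node_map already composes this phase's moves with the aggregation
        assignment = [node_map[a] for a in assignment]
        if len(neighbors) == 1:
            break

    # relabel 1..k by decreasing size, ties by smallest member id
    groups: dict[int, list] = {}
    for node, a in zip(nodes, (assignment[idx[n]] for n in nodes)):
        groups.setdefault(a, []).append(node)
    ordered = sorted(groups.values(), key=lambda ns: (-len(ns), str(ns[0])))
    membership = {node: lab for lab, ns in enumerate(ordered, start=1) for node in ns}
    q = modularity(g, membership)
    sizes = {lab: len(ns) for lab, ns in enumerate(ordered, start=1)}
    logger.info("louvain: %d communities, Q=%.4f", len(sizes), q)
    return Partition(membership=membership, q=q, sizes=sizes)


def community_keywords(
    partition: Partition,
    vectors: Mapping[str, PatentVector],
    n: int = 10,
) -> list[CommunityProfile]:
    """Profile each community by its members' keyword vectors.

    A word's relative frequency is the fraction of the community's
    patents whose top-M list contains it; the top-n words are reported,
    frequency ties broken alphabetically.
    """
    missing = [node for node in partition.membership if node not in vectors]
    if missing:
        raise KeyError(f"partition nodes without keyword vectors: {missing[:5]}")
    profiles: list[CommunityProfile] = []
    for label in sorted(partition.sizes):
        members = partition.community(label)
        counts: dict[str, int] = {}
        for pid in members:
            for w in {word for word, _ in vectors[pid].words}:
                counts[w] = counts.get(w, 0) + 1
        size = len(members)
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:n]
        profiles.append(
            CommunityProfile(
                label=label,
                size=size,
                top_words=[(w, c / size) for w, c in ranked],
            )
        )
    return profiles


def partition_to_frame(partition: Partition) -> pd.DataFrame:
    rows = [{"patent_id": n, "community": c} for n, c in sorted(partition.membership.items(), key=lambda kv: str(kv[0]))]
    return pd.DataFrame(rows, columns=["patent_id", "community"])


def profiles_to_frame(profiles: Sequence[CommunityProfile]) -> pd.DataFrame:
    rows = [
        {"community": p.label, "size": p.size, "rank": r + 1, "word": w, "frequency": round(f, 6)}
        for p in profiles
        for r, (w, f) in enumerate(p.top_words)
    ]
    return pd.DataFrame(rows, columns=["community", "size", "rank", "word", "frequency"])


def profiles_to_wide(profiles: Sequence[CommunityProfile], n: int = 5) -> pd.DataFrame:
    """Wide export with the top-n words per community: one row per rank,
    paired word/frequency columns per community."""
    data: dict[str, list] = {}
    for p in profiles:
        words = p.top_words[:n] + [("", float("nan"))] * max(0, n - len(p.top_words))
        data[f"C{p.label}_W"] = [w for w, _ in words]
        data[f"C{p.label}_F"] = [round(f, 2) if w else "" for w, f in words]
    df = pd.DataFrame(data)
    df.insert(0, "rank", range(1, n + 1))
    return df
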