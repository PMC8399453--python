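"""Independent oracles shared by unit and acceptance tests.

These deliberately avoid the package's own implementations: modularity
is recomputed from raw edge/degree counts, and the optimum is found by
brute force over all partitions of the node set.
"""

import networkx as nx


def set_partitions(items):
    """All partitions of a sequence."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [block + [first]] + smaller[i + 1 :]
        yield [[first]] + smaller


def modularity_oracle(g: nx.Graph, blocks) -> float:
    """Newman-Girvan Q from explicit intra-edge and degree sums."""
    m = g.number_of_edges()
    membership = {n: i for i, block in enumerate(blocks) for n in block}
    q = 0.0
    for i, block in enumerate(blocks):
        e_c = sum(1 for u, v in g.edges() if membership[u] == i and membership[v] == i)
        d_c = sum(g.degree(n) for n in block)
        q += e_c / m - (d_c / (2 * m)) ** 2
    return q


def exhaustive_best_modularity(g: nx.Graph) -> float:
    """Ceiling for any modularity optimizer: brute force over all
    partitions of the node set (feasible up to ~10 nodes)."""
    return max(modularity_oracle(g, blocks) for blocks in set_partitions(g.nodes()))


def atlas_connected_graphs(max_nodes=6):
    """All non-isomorphic connected graphs with 2..max_nodes nodes and at
    least one edge, from the networkx graph atlas."""
    out = []
    for g in nx.graph_atlas_g():
        n = g.number_of_nodes()
        if 2 <= n <= max_nodes and g.number_of_edges() >= 1 and nx.is_connected(g):
            out.append(g)
    return out
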