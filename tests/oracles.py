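"""Independent brute-force oracles for the network and parsimony checks.

These deliberately avoid the package's own median-network code paths:
parsimony is computed by exhaustive enumeration of unrooted binary topologies
with Fitch counting, and the minimum Steiner tree inside a candidate graph by
the Dreyfus-Wagner dynamic program.
"""

from itertools import combinations

import networkx as nx


def all_unrooted_topologies(taxa):
    """All unrooted binary tree topologies on the taxa (1, 3, 15, ... trees)."""
    taxa = list(taxa)
    if len(taxa) == 1:
        g = nx.Graph()
        g.add_node(taxa[0])
        return [g]
    if len(taxa) == 2:
        g = nx.Graph()
        g.add_edge(taxa[0], taxa[1])
        return [g]
    base = nx.Graph()
    base.add_edges_from([("_i0", taxa[0]), ("_i0", taxa[1]), ("_i0", taxa[2])])
    trees = [base]
    for k, taxon in enumerate(taxa[3:], start=1):
        nxt = []
        for t in trees:
            for u, v in list(t.edges):
                g = t.copy()
                g.remove_edge(u, v)
                internal = f"_i{k}_{u}_{v}"
                g.add_edges_from([(u, internal), (internal, v), (internal, taxon)])
                nxt.append(g)
        trees = nxt
    return trees


def fitch_length(tree: nx.Graph, states: dict) -> int:
    """Fitch small-parsimony count for one binary character on an unrooted
    topology; ``states`` maps each leaf (degree-1 or singleton) to 0/1."""
    if tree.number_of_nodes() <= 1:
        return 0
    root = next(iter(states))  # hang the tree from one labelled leaf
    changes = [0]

    def down(node, parent):
        if node in states:
            return {states[node]}
        sets = [down(c, node) for c in tree.neighbors(node) if c != parent]
        inter = set.intersection(*sets)
        if inter:
            return inter
        changes[0] += len(sets) - 1
        return set.union(*sets)

    top = down(next(iter(tree.neighbors(root))), root)
    return changes[0] + (0 if states[root] in top else 1)


def mp_length(rows) -> int:
    """Most-parsimonious tree length for binary haplotype rows: minimum over
    all unrooted binary topologies of the summed Fitch counts."""
    rows = list(rows)
    labels = [f"t{i}" for i in range(len(rows))]
    n_chars = len(rows[0]) if rows else 0
    best = None
    for topo in all_unrooted_topologies(labels):
        total = 0
        for j in range(n_chars):
            states = {labels[i]: rows[i][j] for i in range(len(rows))}
            total += fitch_length(topo, states)
        if best is None or total < best:
            best = total
    return best


def steiner_minimum_edges(graph: nx.Graph, terminals) -> int:
    """Exact minimum Steiner tree size (edges, unit weights) connecting the
    terminals inside ``graph`` — Dreyfus-Wagner dynamic program."""
    return _dreyfus_wagner(
        list(graph.nodes), dict(nx.all_pairs_shortest_path_length(graph)), terminals
    )


def steiner_minimum_hamming(nodes, terminals) -> int:
    """Exact minimum Steiner length over ``nodes`` as allowed branch points
    with Hamming-distance links (links may traverse latent intermediate
    states, as multi-mutation edges do in a drawn median network)."""
    nodes = list(nodes)
    dist = {
        a: {b: sum(x != y for x, y in zip(a, b)) for b in nodes} for a in nodes
    }
    return _dreyfus_wagner(nodes, dist, terminals)


def _dreyfus_wagner(nodes, dist, terminals) -> int:
    terminals = list(dict.fromkeys(terminals))
    if len(terminals) <= 1:
        return 0
    INF = float("inf")
    t0, rest = terminals[0], terminals[1:]
    full = (1 << len(rest)) - 1
    # dp[mask][v] = min edges of a Steiner tree for rest-subset mask plus node v
    dp = [{v: INF for v in nodes} for _ in range(full + 1)]
    for i, t in enumerate(rest):
        for v in nodes:
            dp[1 << i][v] = dist[t].get(v, INF)
    for mask in range(1, full + 1):
        if mask & (mask - 1):  # not a singleton: merge sub-splits
            for v in nodes:
                sub = (mask - 1) & mask
                best = dp[mask][v]
                s = sub
                while s:
                    if s < (mask ^ s):  # each split once
                        s = (s - 1) & mask
                        continue
                    cand = dp[s][v] + dp[mask ^ s][v]
                    if cand < best:
                        best = cand
                    s = (s - 1) & mask
                dp[mask][v] = best
        # relax through the graph (tree grafted onto v, then path v -> u)
        for u in nodes:
            best = dp[mask][u]
            for v in nodes:
                cand = dp[mask][v] + dist[v].get(u, INF)
                if cand < best:
                    best = cand
            dp[mask][u] = best
    return int(dp[full][t0])


def random_compatible_matrix(rng, n_taxa, n_chars):
    """Rows of a random perfect phylogeny: characters assigned to edges of a
    random rooted tree, taxa = tips; pairwise-compatible by construction."""
    parents = {0: None}
    for i in range(1, n_taxa):
        parents[i] = int(rng.integers(0, i))
    node_of_char = [int(rng.integers(1, n_taxa)) for _ in range(n_chars)]

    def row(i):
        anc = set()
        j = i
        while j is not None:
            anc.add(j)
            j = parents[j]
        return tuple(1 if node_of_char[c] in anc else 0 for c in range(n_chars))

    return [row(i) for i in range(n_taxa)]
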