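"""Reduced-median haplotype networks.

Haplotypes are converted to a binary matrix (one column per observed variant,
multistate sites split into one column per derived state), closed under the
coordinatewise majority of all triples — the median hull, which for binary
data contains every most-parsimonious tree — and linked at Hamming distance
one.  Reticulations (cycles, reflecting homoplasy) are resolved by a
deterministic mutation-frequency rule: in each cycle, the character with the
highest carrier frequency is taken to be the recurrent one and is retained on
two branches, while a link of the slowest character is deleted.  Every
resolution is recorded in an audit report.  Rooting against a designated
ancestral haplotype (attached by parsimony when unsampled) yields a
:class:`~phylofounder.tree.RootedMutationTree` for dating and founder walks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import pandas as pd

from .errors import StructureError
from .haplotype_io import SamplePanel, VariantCall
from .tree import RootedMutationTree

State = tuple[int, ...]


@dataclass(frozen=True)
class BinaryMatrix:
    """Distinct haplotype rows over binary characters.

    ``columns[j]`` is the variant whose presence character j encodes;
    ``rows[i]`` is a 0/1 state vector; identical haplotypes are collapsed with
    their multiplicity and member sample ids.  ``char_freq[j]`` counts
    carriers of character j weighted by multiplicity.  Characters shared by
    every sample (constant columns) are removed and listed separately.
    """

    columns: tuple[VariantCall, ...]
    rows: tuple[State, ...]
    multiplicities: tuple[int, ...]
    sample_ids: tuple[tuple[str, ...], ...]
    char_freq: tuple[int, ...]
    shared_variants: tuple[VariantCall, ...] = ()

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_chars(self) -> int:
        return len(self.columns)


def binarize(panel: SamplePanel) -> BinaryMatrix:
    """Encode a panel as a binary matrix (GeneSyn-style variants-to-binary
    conversion).  One column per distinct variant call; a site with several
    derived states contributes one column per state."""
    if len(panel) == 0:
        raise ValueError("empty panel")
    variants = sorted(
        {v for p in panel.profiles for v in p.variants},
        key=lambda v: (v.position, v.insert_index, v.kind, v.derived_state),
    )
    n = len(panel)
    # drop constant (all-carrier) columns: uninformative for the network
    shared = tuple(
        v for v in variants if all(v in p.variants for p in panel.profiles)
    ) if n > 1 else ()
    columns = tuple(v for v in variants if v not in shared)
    by_state: dict[State, list[str]] = {}
    mult: dict[State, int] = {}
    for p in panel.profiles:
        state = tuple(1 if c in p.variants else 0 for c in columns)
        by_state.setdefault(state, []).append(p.sample_id)
        mult[state] = mult.get(state, 0) + 1
    rows = tuple(sorted(by_state))
    freq = tuple(
        sum(m for s, m in mult.items() if s[j] == 1) for j in range(len(columns))
    )
    return BinaryMatrix(
        columns=columns,
        rows=rows,
        multiplicities=tuple(mult[r] for r in rows),
        sample_ids=tuple(tuple(sorted(by_state[r])) for r in rows),
        char_freq=freq,
        shared_variants=shared,
    )


# ---------------------------------------------------------------------------
# median hull and network
# ---------------------------------------------------------------------------

def median_hull(rows, max_nodes: int = 20000) -> set[State]:
    """Closure of binary vectors under coordinatewise majority of all triples.

    For binary data this is the median hull; with fewer than three distinct
    vectors it is the input set itself.
    """
    nodes: set[State] = set(rows)
    changed = True
    while changed:
        changed = False
        current = sorted(nodes)
        for a, b, c in combinations(current, 3):
            m = tuple((x + y + z >= 2) * 1 for x, y, z in zip(a, b, c))
            if m not in nodes:
                nodes.add(m)
                changed = True
                if len(nodes) > max_nodes:
                    raise StructureError(
                        f"median hull exceeded {max_nodes} nodes; "
                        "reduce the input or raise max_nodes"
                    )
    return nodes


def _hamming(a: State, b: State) -> int:
    return sum(x != y for x, y in zip(a, b))


def _link_graph(nodes: set[State]) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for a, b in combinations(sorted(nodes), 2):
        diff = [j for j, (x, y) in enumerate(zip(a, b)) if x != y]
        if len(diff) == 1:
            g.add_edge(a, b, char=diff[0])
    return g


def _complete_paths(g: nx.Graph) -> None:
    """Connect components by inserting the intermediate nodes of the greedy
    shortest Hamming path between the closest cross-component pair, flipping
    characters in ascending column order (deterministic)."""
    while nx.number_connected_components(g) > 1:
        comps = [sorted(c) for c in nx.connected_components(g)]
        comps.sort()
        best = None
        for ca, cb in combinations(comps, 2):
            for a in ca:
                for b in cb:
                    key = (_hamming(a, b), a, b)
                    if best is None or key < best:
                        best = key
        _, a, b = best
        cur = a
        for j in [j for j, (x, y) in enumerate(zip(a, b)) if x != y]:
            nxt = tuple(1 - s if k == j else s for k, s in enumerate(cur))
            if nxt not in g:
                g.add_node(nxt, multiplicity=0, sample_ids=())
            g.add_edge(cur, nxt, char=j)
            cur = nxt


def median_closure(m: BinaryMatrix, max_nodes: int = 20000) -> nx.Graph:
    """Median network of the matrix: the median hull of the observed rows,
    linked at Hamming distance 1 and connected by path completion.

    Node attributes: ``multiplicity`` (0 for inferred medians) and
    ``sample_ids``; edge attribute ``char`` (column index).
    """
    hull = median_hull(m.rows, max_nodes=max_nodes)
    g = _link_graph(hull)
    nx.set_node_attributes(g, 0, "multiplicity")
    nx.set_node_attributes(g, (), "sample_ids")
    for row, mult, ids in zip(m.rows, m.multiplicities, m.sample_ids):
        g.nodes[row]["multiplicity"] = mult
        g.nodes[row]["sample_ids"] = ids
    g.graph["columns"] = m.columns
    g.graph["char_freq"] = m.char_freq
    _complete_paths(g)
    return g


# ---------------------------------------------------------------------------
# reticulation resolution
# ---------------------------------------------------------------------------

@dataclass
class ResolutionReport:
    """Audit trail of every resolved cycle and rooting tie."""

    resolved_cycles: list[dict] = field(default_factory=list)
    rooting_ties: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.resolved_cycles)


def reduce_and_resolve(
    net: nx.Graph,
    site_freq: dict[int, float] | None = None,
    r: float = 2.0,
) -> tuple[nx.Graph, ResolutionReport]:
    """Resolve every reticulation of the median network into a tree.

    In each cycle the two (or more) alternative characters are compared by
    their global carrier frequency ``site_freq`` (default: the matrix's
    ``char_freq``); the most frequent character is treated as recurrent and
    retained twice, and one link of the least frequent character is deleted.
    Frequency ties treat the character at the larger site position as the
    recurrent one.  Cycles whose frequency ratio is below ``r`` are resolved
    by the same rule but flagged ``weak`` in the report.
    """
    if net.number_of_nodes() and not nx.is_connected(net):
        raise StructureError("median network must be connected")
    if r < 1:
        raise ValueError("reduction parameter r must be >= 1")
    g = net.copy()
    columns: tuple[VariantCall, ...] = g.graph.get("columns", ())
    if site_freq is None:
        site_freq = {j: f for j, f in enumerate(g.graph.get("char_freq", ()))}

    def char_key(j: int) -> tuple:
        # sort key: least frequent first; on ties the SMALLER site position is
        # the slower character (larger position treated as recurrent)
        pos = columns[j].position if j < len(columns) else j
        return (site_freq.get(j, 0), pos, j)

    report = ResolutionReport()
    while True:
        cycles = nx.cycle_basis(g)
        if not cycles:
            break
        cycles = sorted((sorted(c), c) for c in cycles)
        _, cycle = cycles[0]
        edges = [
            (cycle[i], cycle[(i + 1) % len(cycle)]) for i in range(len(cycle))
        ]
        chars = sorted({g.edges[e]["char"] for e in edges}, key=char_key)
        slow = chars[0]
        freqs = [site_freq.get(j, 0) for j in chars]
        candidates = sorted(
            (tuple(sorted(e)) for e in edges if g.edges[e]["char"] == slow)
        )
        drop = candidates[0]
        g.remove_edge(*drop)
        ratio = (max(freqs) / min(freqs)) if min(freqs) > 0 else float("inf")
        report.resolved_cycles.append(
            {
                "cycle_length": len(cycle),
                "characters": tuple(columns[j].token() if j < len(columns) else j for j in chars),
                "frequencies": tuple(freqs),
                "deleted_link": (str(drop[0]), str(drop[1])),
                "weak": bool(ratio < r or len(set(freqs)) < len(freqs)),
            }
        )
        # prune inferred medians left dangling by the deletion
        while True:
            leaves = [
                n for n in g
                if g.degree(n) <= 1 and g.nodes[n].get("multiplicity", 0) == 0
                and g.number_of_nodes() > 1
            ]
            if not leaves:
                break
            g.remove_nodes_from(leaves)
    return g, report


# ---------------------------------------------------------------------------
# rooting
# ---------------------------------------------------------------------------

def root_tree(
    resolved: nx.Graph,
    root_state: State | None = None,
    report: ResolutionReport | None = None,
) -> RootedMutationTree:
    """Orient a resolved (acyclic) network away from the root haplotype.

    ``root_state`` defaults to the all-ancestral (reference) vector.  If it is
    not a node of the network it is attached by maximum parsimony (fewest
    additional mutations); attachment ties are broken toward the
    lexicographically smallest node and flagged in the report.
    """
    if resolved.number_of_nodes() == 0:
        raise StructureError("empty network")
    if not nx.is_forest(resolved):
        raise StructureError("network still contains cycles; resolve first")
    columns: tuple[VariantCall, ...] = resolved.graph.get("columns", ())
    g = resolved.copy()
    n_chars = len(next(iter(g.nodes)))
    if root_state is None:
        root_state = tuple([0] * n_chars)
    root_state = tuple(root_state)
    if root_state not in g:
        dists = sorted((_hamming(root_state, n), n) for n in g.nodes)
        best_d, best_node = dists[0]
        ties = [n for d, n in dists if d == best_d]
        if len(ties) > 1 and report is not None:
            report.rooting_ties.append(
                {"root_state": root_state, "candidates": [str(t) for t in ties],
                 "chosen": str(best_node)}
            )
        cur = root_state
        g.add_node(cur, multiplicity=0, sample_ids=())
        for j in [j for j, (x, y) in enumerate(zip(root_state, best_node)) if x != y]:
            nxt = tuple(1 - s if k == j else s for k, s in enumerate(cur))
            if nxt not in g:
                g.add_node(nxt, multiplicity=0, sample_ids=())
            g.add_edge(cur, nxt, char=j)
            cur = nxt

    order = {s: i for i, s in enumerate(sorted(g.nodes))}

    def name(state: State) -> str:
        return f"N{order[state]:04d}"

    tree = RootedMutationTree(
        name(root_state),
        multiplicity=g.nodes[root_state].get("multiplicity", 0),
        sample_ids=g.nodes[root_state].get("sample_ids", ()),
    )
    tree.state_of = {name(root_state): root_state}  # type: ignore[attr-defined]
    for parent, child in nx.bfs_edges(g, root_state):
        j = g.edges[parent, child]["char"]
        mut = columns[j] if j < len(columns) else VariantCall(j + 1, "A")
        tree.add_child(
            name(parent),
            name(child),
            [mut],
            multiplicity=g.nodes[child].get("multiplicity", 0),
            sample_ids=g.nodes[child].get("sample_ids", ()),
        )
        tree.state_of[name(child)] = child  # type: ignore[attr-defined]
    return tree


def build_network_tree(
    panel: SamplePanel,
    *,
    root_variants: frozenset[VariantCall] = frozenset(),
    r: float = 2.0,
    max_nodes: int = 20000,
) -> tuple[RootedMutationTree, BinaryMatrix, ResolutionReport]:
    """Full pipeline: binarize -> median closure -> resolve -> root.

    ``root_variants`` designates the ancestral haplotype (default: the
    reference itself).
    """
    m = binarize(panel)
    net = median_closure(m, max_nodes=max_nodes)
    resolved, report = reduce_and_resolve(net, r=r)
    root_state = tuple(1 if c in root_variants else 0 for c in m.columns)
    tree = root_tree(resolved, root_state, report)
    return tree, m, report
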