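"""Rooted mutation trees.

The substrate shared by the dating and founder-analysis machinery: a rooted
phylogeny whose branches carry explicit mutation lists (branch length =
number of mutations) and whose nodes carry the sampled haplotypes sitting on
them, with multiplicities.  Trees arise either from the reduced-median
network stage or from an external source (simulation truth, Newick + sidecar
CSV).

Mutation accumulation along root-to-node paths defines each node's haplotype.
A repeated identical mutation on one path toggles (back mutation); a
substitution whose derived state equals the reference base likewise cancels.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .errors import StructureError
from .haplotype_io import SUBSTITUTION, VariantCall, parse_variant_string, write_variant_string


class RootedMutationTree:
    """Rooted tree with per-branch mutation lists and per-node sample sets.

    Node ids are strings.  Every non-root node has exactly one parent; the
    mutation list on the branch into a node is oriented ancestral -> derived.
    """

    def __init__(
        self,
        root: str,
        *,
        multiplicity: int = 0,
        sample_ids: Sequence[str] = (),
        reference_states: dict[int, str] | None = None,
    ):
        self.root = root
        self._parent: dict[str, str] = {}
        self._children: dict[str, list[str]] = {root: []}
        self._branch: dict[str, tuple[VariantCall, ...]] = {}
        self._mult: dict[str, int] = {root: int(multiplicity)}
        self._samples: dict[str, tuple[str, ...]] = {root: tuple(sample_ids)}
        #: ancestral state per position (used to cancel reversions)
        self.reference_states = dict(reference_states or {})

    # -- construction -------------------------------------------------------

    def add_child(
        self,
        parent: str,
        node: str,
        mutations: Iterable[VariantCall] = (),
        *,
        multiplicity: int = 0,
        sample_ids: Sequence[str] = (),
    ) -> str:
        if parent not in self._children:
            raise StructureError(f"unknown parent node {parent!r}")
        if node in self._children:
            raise StructureError(f"duplicate node id {node!r}")
        self._parent[node] = parent
        self._children[parent].append(node)
        self._children[node] = []
        self._branch[node] = tuple(mutations)
        self._mult[node] = int(multiplicity)
        self._samples[node] = tuple(sample_ids)
        return node

    # -- basic accessors ----------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        return list(self.preorder())

    def __contains__(self, node: str) -> bool:
        return node in self._children

    def __len__(self) -> int:
        return len(self._children)

    def parent(self, node: str) -> str | None:
        return self._parent.get(node)

    def children(self, node: str) -> tuple[str, ...]:
        return tuple(self._children[node])

    def branch_mutations(self, node: str) -> tuple[VariantCall, ...]:
        """Mutations on the branch from parent(node) to node."""
        return self._branch.get(node, ())

    def branch_length(self, node: str) -> int:
        return len(self._branch.get(node, ()))

    def multiplicity(self, node: str) -> int:
        return self._mult[node]

    def sample_ids(self, node: str) -> tuple[str, ...]:
        return self._samples[node]

    def preorder(self, start: str | None = None) -> Iterator[str]:
        stack = [start or self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(self._children[node]))

    def path_to_root(self, node: str) -> list[str]:
        """node, parent(node), ..., root."""
        path = [node]
        while path[-1] in self._parent:
            path.append(self._parent[path[-1]])
        return path

    def node_of_sample(self, sample_id: str) -> str:
        for node, ids in self._samples.items():
            if sample_id in ids:
                return node
        raise KeyError(sample_id)

    # -- clade summaries -----------------------------------------------------

    def subtree_multiplicity(self, node: str) -> int:
        """Total sampled multiplicity at and below ``node``."""
        return sum(self._mult[n] for n in self.preorder(node))

    def branches_below(self, clade_root: str) -> Iterator[tuple[str, int, int]]:
        """Yield (child_node, branch_mutations_count, subtree_multiplicity)
        for every branch strictly inside the clade."""
        for node in self.preorder(clade_root):
            if node == clade_root:
                continue
            yield node, self.branch_length(node), self.subtree_multiplicity(node)

    # -- haplotypes ----------------------------------------------------------

    def _apply(self, state: dict, mutations: Iterable[VariantCall]) -> None:
        for v in mutations:
            key = (v.position, v.kind, v.insert_index)
            if state.get(key) == v.derived_state:
                del state[key]  # repeated identical hit = back mutation
            elif (
                v.kind == SUBSTITUTION
                and self.reference_states.get(v.position) == v.derived_state
            ):
                state.pop(key, None)  # explicit reversion to the ancestral base
            else:
                state[key] = v.derived_state

    def node_variants(self, node: str) -> frozenset[VariantCall]:
        """Haplotype of ``node`` as reference-relative variants, accumulated
        from the root."""
        state: dict = {}
        for n in reversed(self.path_to_root(node)):
            self._apply(state, self._branch.get(n, ()))
        return frozenset(
            VariantCall(pos, s, kind, idx) for (pos, kind, idx), s in state.items()
        )

    def all_node_variants(self) -> dict[str, frozenset[VariantCall]]:
        """Haplotypes of all nodes in one preorder pass."""
        out: dict[str, frozenset[VariantCall]] = {}
        states: dict[str, dict] = {}
        for node in self.preorder():
            parent = self._parent.get(node)
            state = dict(states[parent]) if parent is not None else {}
            self._apply(state, self._branch.get(node, ()))
            states[node] = state
            out[node] = frozenset(
                VariantCall(pos, s, kind, idx) for (pos, kind, idx), s in state.items()
            )
        return out

    # -- serialization -------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for node in self.preorder():
            rows.append(
                {
                    "node": node,
                    "parent": self._parent.get(node, ""),
                    "multiplicity": self._mult[node],
                    "sample_ids": ";".join(self._samples[node]),
                    "n_mutations": self.branch_length(node),
                    "mutations": write_variant_string(self._branch.get(node, ())),
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, reference_states: dict[int, str] | None = None
    ) -> "RootedMutationTree":
        df = df.fillna("")
        roots = df[df["parent"] == ""]
        if len(roots) != 1:
            raise StructureError(f"expected exactly one root row, got {len(roots)}")
        r = roots.iloc[0]
        tree = cls(
            str(r["node"]),
            multiplicity=int(r["multiplicity"]),
            sample_ids=[s for s in str(r["sample_ids"]).split(";") if s],
            reference_states=reference_states,
        )
        pending = df[df["parent"] != ""].to_dict("records")
        while pending:
            rest = []
            progressed = False
            for row in pending:
                if str(row["parent"]) in tree:
                    tree.add_child(
                        str(row["parent"]),
                        str(row["node"]),
                        parse_variant_string(str(row["mutations"])),
                        multiplicity=int(row["multiplicity"]),
                        sample_ids=[s for s in str(row["sample_ids"]).split(";") if s],
                    )
                    progressed = True
                else:
                    rest.append(row)
            if not progressed:
                raise StructureError("tree table contains orphan rows (cycle or missing parent)")
            pending = rest
        return tree

    @classmethod
    def from_csv(
        cls, path: str | Path, reference_states: dict[int, str] | None = None
    ) -> "RootedMutationTree":
        return cls.from_frame(pd.read_csv(path, dtype=str).fillna(""), reference_states)

    def to_newick(self, *, lengths: str = "mutations") -> str:
        """Newick export; branch lengths in mutation counts."""

        def fmt(node: str) -> str:
            kids = self._children[node]
            label = node.replace(" ", "_").replace(",", "_").replace("(", "_").replace(")", "_")
            sub = f"({','.join(fmt(k) for k in kids)})" if kids else ""
            blen = "" if node == self.root else f":{self.branch_length(node)}"
            return f"{sub}{label}{blen}"

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(
        cls,
        newick: str,
        mutations: dict[str, Sequence[VariantCall]] | None = None,
        reference_states: dict[int, str] | None = None,
    ) -> "RootedMutationTree":
        """Build a tree from a Newick string with node labels.

        Branch mutation lists are taken from ``mutations`` (node -> list) when
        given; otherwise each branch gets ``round(length)`` anonymous
        substitution placeholders, which preserves branch lengths for dating
        but not haplotypes.
        """
        import dendropy

        dt = dendropy.Tree.get(data=newick, schema="newick")
        counter = [0]

        def name_of(nd) -> str:
            label = nd.taxon.label if nd.taxon else nd.label
            if not label:
                counter[0] += 1
                label = f"__anon{counter[0]}"
            return label.replace(" ", "_")

        anon = [0]

        def muts_for(name: str, edge_len) -> list[VariantCall]:
            if mutations is not None:
                return list(mutations.get(name, ()))
            out = []
            for _ in range(int(round(edge_len or 0))):
                anon[0] += 1  # unique placeholder site per anonymous mutation
                out.append(VariantCall(1_000_000 + anon[0], "A"))
            return out

        root_name = name_of(dt.seed_node)
        tree = cls(root_name, reference_states=reference_states)
        stack = [(dt.seed_node, root_name)]
        while stack:
            nd, name = stack.pop()
            for child in nd.child_nodes():
                cname = name_of(child)
                tree.add_child(name, cname, muts_for(cname, child.edge.length))
                stack.append((child, cname))
        return tree
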