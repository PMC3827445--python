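"""Median hull construction, reticulation resolution and rooting."""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from oracles import mp_length, random_compatible_matrix, steiner_minimum_hamming
from phylofounder.errors import StructureError
from phylofounder.haplotype_io import (
    HaplotypeProfile,
    ReferenceSequence,
    SamplePanel,
    VariantCall,
    parse_variant_string,
)
from phylofounder.median_network import (
    BinaryMatrix,
    binarize,
    build_network_tree,
    median_closure,
    median_hull,
    reduce_and_resolve,
    root_tree,
)

REF = ReferenceSequence("ref", "A" * 1000)


def panel_from(varstrings, ids=None):
    ids = ids or [f"s{i}" for i in range(len(varstrings))]
    return SamplePanel(
        [HaplotypeProfile(i, parse_variant_string(v)) for i, v in zip(ids, varstrings)],
        REF,
    )


def matrix_from_rows(rows, freqs=None):
    """BinaryMatrix straight from 0/1 tuples (synthetic characters)."""
    rows = [tuple(r) for r in rows]
    k = len(rows[0]) if rows else 0
    cols = tuple(VariantCall(i + 1, "T") for i in range(k))
    mult = {r: rows.count(r) for r in set(rows)}
    uniq = tuple(sorted(mult))
    freq = freqs or tuple(sum(m for r, m in mult.items() if r[j]) for j in range(k))
    return BinaryMatrix(
        columns=cols,
        rows=uniq,
        multiplicities=tuple(mult[r] for r in uniq),
        sample_ids=tuple((f"s{i}",) for i in range(len(uniq))),
        char_freq=tuple(freq),
    )


class TestBinarize:
    def test_nested_haplotypes(self):
        m = binarize(panel_from(["", "100T", "100T 200C"]))
        assert m.n_chars == 2
        assert set(m.rows) == {(0, 0), (1, 0), (1, 1)}
        assert m.char_freq == (2, 1)

    def test_identical_profiles_collapse_to_one_row(self):
        m = binarize(panel_from(["100T", "100T", "100T"]))
        assert m.n_rows == 1 and m.n_chars == 0
        assert m.multiplicities == (3,)
        assert m.shared_variants == (VariantCall(100, "T"),)

    def test_multistate_site_splits_into_columns(self):
        m = binarize(panel_from(["100T", "100G"]))
        assert {c.token() for c in m.columns} == {"100T", "100G"}

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            binarize(SamplePanel([], REF))


class TestMedianHull:
    def test_pair_is_its_own_closure(self):
        assert median_hull({(0, 0), (1, 1)}) == {(0, 0), (1, 1)}

    def test_three_rows_star(self):
        rows = {(0, 0), (0, 1), (1, 0)}
        assert median_hull(rows) == rows

    def test_four_cycle_closure(self):
        rows = {(0, 0), (0, 1), (1, 0), (1, 1)}
        assert median_hull(rows) == rows

    def test_median_added_for_generic_triple(self):
        rows = {(1, 0, 0), (0, 1, 0), (0, 0, 1)}
        assert median_hull(rows) == rows | {(0, 0, 0)}

    def test_matches_triple_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            k = int(rng.integers(2, 6))
            rows = {tuple(rng.integers(0, 2, k)) for _ in range(rng.integers(2, 7))}
            hull = median_hull(rows)
            # closed: no triple generates anything new
            for a, b, c in combinations(sorted(hull), 3):
                med = tuple((x + y + z >= 2) * 1 for x, y, z in zip(a, b, c))
                assert med in hull
            # minimal: every hull point reachable from rows by medians
            grown = set(rows)
            changed = True
            while changed:
                changed = False
                for a, b, c in combinations(sorted(grown), 3):
                    med = tuple((x + y + z >= 2) * 1 for x, y, z in zip(a, b, c))
                    if med not in grown:
                        grown.add(med)
                        changed = True
            assert hull == grown


class TestReduceAndResolve:
    def cycle_net(self, freqs):
        m = matrix_from_rows([(0, 0), (0, 1), (1, 0), (1, 1)], freqs=freqs)
        return median_closure(m)

    def test_recurrent_character_kept_twice(self):
        """Character with higher global frequency appears on two branches of
        the resolved tree; the slower one on a single branch."""
        net = self.cycle_net(freqs=(5, 1))
        tree_graph, report = reduce_and_resolve(net)
        counts = {0: 0, 1: 0}
        for _, _, d in tree_graph.edges(data=True):
            counts[d["char"]] += 1
        assert counts == {0: 2, 1: 1}
        assert len(report.resolved_cycles) == 1
        assert report.resolved_cycles[0]["weak"] is False

    def test_tree_input_unchanged(self):
        m = matrix_from_rows([(0, 0), (1, 0), (1, 1)])
        net = median_closure(m)
        resolved, report = reduce_and_resolve(net)
        assert nx.utils.graphs_equal(net, resolved)
        assert report.resolved_cycles == []

    def test_frequency_tie_is_deterministic_and_reported(self):
        runs = []
        for _ in range(2):
            resolved, report = reduce_and_resolve(self.cycle_net(freqs=(2, 2)))
            runs.append((sorted(map(sorted, resolved.edges)), report.resolved_cycles))
        assert runs[0][0] == runs[1][0]
        assert runs[0][1][0]["weak"] is True
        # larger site position treated as recurrent -> char 1 kept twice
        counts = {0: 0, 1: 0}
        for _, _, d in reduce_and_resolve(self.cycle_net(freqs=(2, 2)))[0].edges(data=True):
            counts[d["char"]] += 1
        assert counts == {0: 1, 1: 2}

    def test_low_ratio_cycles_flagged_weak(self):
        _, report = reduce_and_resolve(self.cycle_net(freqs=(3, 2)), r=2.0)
        assert report.resolved_cycles[0]["weak"] is True

    def test_disconnected_input_rejected(self):
        g = nx.Graph()
        g.add_nodes_from([(0, 0), (1, 1)])
        with pytest.raises(StructureError):
            reduce_and_resolve(g)

    def test_sampled_haplotypes_preserved(self):
        """Resolution only deletes links/medians, never observed haplotypes."""
        rng = np.random.default_rng(8)
        for _ in range(20):
            k = int(rng.integers(2, 6))
            rows = [tuple(rng.integers(0, 2, k)) for _ in range(rng.integers(2, 7))]
            m = matrix_from_rows(rows)
            resolved, _ = reduce_and_resolve(median_closure(m))
            for row, mult in zip(m.rows, m.multiplicities):
                assert row in resolved
                assert resolved.nodes[row]["multiplicity"] == mult


class TestRootTree:
    def test_root_at_observed_node(self):
        m = matrix_from_rows([(0, 0), (1, 0), (1, 1)])
        resolved, _ = reduce_and_resolve(median_closure(m))
        tree = root_tree(resolved, (0, 0))
        assert tree.subtree_multiplicity(tree.root) == 3
        assert tree.multiplicity(tree.root) == 1  # (0,0) itself observed

    def test_unobserved_root_attached_by_parsimony(self):
        m = matrix_from_rows([(1, 0), (1, 1)])
        resolved, _ = reduce_and_resolve(median_closure(m))
        tree = root_tree(resolved, (0, 0))
        # one-mutation branch from the root to (1,0)
        child = tree.children(tree.root)[0]
        assert tree.branch_length(child) == 1

    def test_equidistant_attachment_tie_flagged(self):
        from phylofounder.median_network import ResolutionReport

        m = matrix_from_rows([(1, 0, 0), (0, 0, 1)])
        resolved, _ = reduce_and_resolve(median_closure(m))
        report = ResolutionReport()
        # (0,1,0) is two mutations from both observed haplotypes
        root_tree(resolved, (0, 1, 0), report)
        assert len(report.rooting_ties) == 1

    def test_unresolved_cycles_rejected(self):
        net = median_closure(matrix_from_rows([(0, 0), (0, 1), (1, 0), (1, 1)]))
        with pytest.raises(StructureError):
            root_tree(net, (0, 0))


class TestAgainstBruteForce:
    def test_perfect_phylogeny_one_branch_per_character(self):
        """Compatible data: the resolved, rooted network is a perfect
        phylogeny — every character appears on exactly one branch."""
        rng = np.random.default_rng(21)
        for _ in range(30):
            rows = random_compatible_matrix(rng, int(rng.integers(3, 9)), int(rng.integers(2, 9)))
            m = matrix_from_rows(rows)
            resolved, report = reduce_and_resolve(median_closure(m))
            assert report.resolved_cycles == []
            tree = root_tree(resolved, tuple([0] * m.n_chars))
            seen: dict[int, int] = {}
            for node in tree.nodes:
                for mut in tree.branch_mutations(node):
                    seen[mut.position] = seen.get(mut.position, 0) + 1
            informative = {j + 1 for j in range(m.n_chars) if any(r[j] for r in m.rows)}
            assert set(seen) == informative
            assert all(v == 1 for v in seen.values())

    def test_closure_contains_a_most_parsimonious_tree(self):
        """Exact Steiner minimum inside the median network equals the
        brute-force MP length over all topologies (<= 5 taxa x 5 chars)."""
        rng = np.random.default_rng(33)
        checked = 0
        while checked < 15:
            k = int(rng.integers(2, 6))
            rows = list({tuple(rng.integers(0, 2, k)) for _ in range(rng.integers(2, 6))})
            if len(rows) < 2:
                continue
            hull = median_hull(rows)
            # hull nodes are the allowed branch points; links are Hamming
            # geodesics (multi-mutation edges), as in a drawn median network
            assert steiner_minimum_hamming(hull, rows) == mp_length(rows)
            checked += 1


class TestEndToEnd:
    def test_build_network_tree_smoke(self):
        panel = panel_from(["", "100T", "100T 200C", "300G"])
        tree, matrix, report = build_network_tree(panel)
        assert tree.subtree_multiplicity(tree.root) == 4
        assert report.resolved_cycles == []
        # root is the reference haplotype (profile "s0" with no variants)
        assert "s0" in tree.sample_ids(tree.root)
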