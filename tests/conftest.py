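import itertools

import pytest
from hypothesis import HealthCheck, settings

from phylofounder.haplotype_io import VariantCall
from phylofounder.tree import RootedMutationTree

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def unique_mutations():
    """Endless supply of distinct substitution calls (no accidental toggling)."""
    for pos in itertools.count(1):
        yield VariantCall(pos, "T")


def make_star(branch_mutations, root="root"):
    """Star tree with one tip per entry; entry = number of branch mutations."""
    muts = unique_mutations()
    tree = RootedMutationTree(root)
    for i, b in enumerate(branch_mutations):
        tip = f"tip{i}"
        tree.add_child(root, tip, [next(muts) for _ in range(b)],
                       multiplicity=1, sample_ids=(tip,))
    return tree


@pytest.fixture
def toy_founder_tree():
    """Hand-enumerable source/sink tree.

    root -1mut- h [carries source sample S1]
      h -1mut- s2 [source S2]
      h -1mut- k1 [sink K1]
      h -2mut- k2 [sink K2]

    Under f1 the cluster at h has n_f=2, m_f=3, rho_f=1.5 (S2 provides the
    derived source branch); under f2, h fails (one derived source branch).
    """
    muts = unique_mutations()
    t = RootedMutationTree("root")
    t.add_child("root", "h", [next(muts)], multiplicity=1, sample_ids=("S1",))
    t.add_child("h", "s2", [next(muts)], multiplicity=1, sample_ids=("S2",))
    t.add_child("h", "k1", [next(muts)], multiplicity=1, sample_ids=("K1",))
    t.add_child("h", "k2", [next(muts) for _ in range(2)], multiplicity=1, sample_ids=("K2",))
    return t
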