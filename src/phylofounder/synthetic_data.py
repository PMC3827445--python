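"""Coalescent simulation of source/sink founder scenarios with known truth.

The generator emulates the sampling design of an HVS-I phylogeographic
survey: a *source* region and a *sink* region colonized by one or more
founder pulses at known times.  Backward in time, sink lineages coalesce
within the sink deme until their founder event, where the surviving ancestors
are merged into at most k founder lineages and handed to the source
genealogy.  Mutations are dropped on the genealogy as a Poisson process under
a years-per-mutation clock, with optional rate heterogeneity (hotspot sites)
producing recurrent hits and hence homoplasy; a second hit at a site reverts
it to the ancestral state.

Founder events are coupled to source demographic episodes: the oldest event
is the onset of the source expansion (all remaining source lineages coalesce
there), and at younger events the incoming founder lineage attaches to a
small burst of coalescing source lineages.  This keeps founder haplotypes
represented among the sampled source lineages — the regime founder analysis
presupposes; an uncoupled constant-size source essentially never retains a
60-ka-old founder type among 50 modern samples, and every founder walk would
fall through to the root.

Everything is reproducible from the scenario seed, and the emitted truth
record (genealogy, per-branch mutation lists, per-sample founder assignment)
is exactly consistent with the emitted haplotypes.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .clade_dating import BUILTIN_CLOCKS, ClockModel, HVS1_CLOCK
from .errors import ConfigurationError, StructureError
from .haplotype_io import (
    HaplotypeProfile,
    ReferenceSequence,
    SamplePanel,
    VariantCall,
)
from .tree import RootedMutationTree

_ALT = {"A": "G", "G": "A", "C": "T", "T": "C"}  # transition partner per site


@dataclass(frozen=True)
class DemeConfig:
    """Sampled deme: size and effective-size trajectory.

    ``ne_years`` is the coalescent timescale N_e × generation time, in years
    (the pairwise coalescence rate is 1/ne_years).  Trajectories: ``constant``;
    ``exponential`` growth at ``growth_rate`` per year (forward time, so the
    deme shrinks into the past); ``star`` is the infinite-growth limit — no
    coalescence until the relevant founder/onset time.
    """

    n_samples: int
    trajectory: str = "constant"
    ne_years: float = 10_000.0
    growth_rate: float = 0.0

    def __post_init__(self):
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be >= 1")
        if self.trajectory not in ("constant", "exponential", "star"):
            raise ConfigurationError(f"unknown trajectory {self.trajectory!r}")
        if self.trajectory == "exponential" and self.growth_rate <= 0:
            raise ConfigurationError("exponential trajectory needs growth_rate > 0")
        if self.ne_years <= 0:
            raise ConfigurationError("ne_years must be > 0")


@dataclass(frozen=True)
class FounderEvent:
    time_years: float
    n_founders: int = 1

    def __post_init__(self):
        if self.time_years <= 0:
            raise ConfigurationError("founder event time must be > 0")
        if self.n_founders < 1:
            raise ConfigurationError("n_founders must be >= 1")


@dataclass(frozen=True)
class SiteModel:
    """Mutational target: ``n_sites`` positions, a ``hotspot_fraction`` of
    which mutate ``hotspot_multiplier`` times faster.  ``infinite_sites``
    gives every mutation a fresh site (no homoplasy)."""

    n_sites: int = 350
    hotspot_fraction: float = 0.0
    hotspot_multiplier: float = 5.0
    infinite_sites: bool = False

    def __post_init__(self):
        if self.n_sites < 1:
            raise ConfigurationError("n_sites must be >= 1")
        if not (0.0 <= self.hotspot_fraction <= 1.0):
            raise ConfigurationError("hotspot_fraction must be in [0, 1]")
        if self.hotspot_multiplier <= 0:
            raise ConfigurationError("hotspot_multiplier must be > 0")


@dataclass(frozen=True)
class Scenario:
    source: DemeConfig
    sink: DemeConfig
    founder_events: tuple[FounderEvent, ...]
    clock: ClockModel = HVS1_CLOCK
    site_model: SiteModel = SiteModel()
    seed: int = 0
    #: number of source lineages coalescing with an incoming founder lineage
    #: at a (non-oldest) founder event
    attach_burst: int = 4

    def __post_init__(self):
        if not self.founder_events:
            raise ConfigurationError("need at least one founder event")
        object.__setattr__(
            self,
            "founder_events",
            tuple(sorted(self.founder_events, key=lambda e: e.time_years)),
        )
        groups = np.array_split(np.arange(self.sink.n_samples), len(self.founder_events))
        for ev, g in zip(self.founder_events, groups):
            if ev.n_founders > len(g):
                raise ConfigurationError(
                    f"event at {ev.time_years} y asks for {ev.n_founders} founder "
                    f"lineages but only {len(g)} sink lineages are assigned to it"
                )

    def digest(self) -> str:
        d = asdict(self)
        d["clock"] = {"name": self.clock.name, "years_per_mutation": self.clock.years_per_mutation}
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        clock = d.get("clock", "hvs1")
        if isinstance(clock, str):
            clock = BUILTIN_CLOCKS[clock]
        elif isinstance(clock, dict):
            clock = ClockModel(clock.get("name", "custom"), float(clock["years_per_mutation"]))
        return cls(
            source=DemeConfig(**d["source"]),
            sink=DemeConfig(**d["sink"]),
            founder_events=tuple(FounderEvent(**e) for e in d["founder_events"]),
            clock=clock,
            site_model=SiteModel(**d.get("site_model", {})),
            seed=int(d.get("seed", 0)),
            attach_burst=int(d.get("attach_burst", 4)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Scenario":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# genealogy
# ---------------------------------------------------------------------------

@dataclass
class GenNode:
    name: str
    time: float
    parent: str | None = None
    children: list[str] = field(default_factory=list)


class Genealogy:
    """Ultrametric genealogy in years (tips at time 0)."""

    def __init__(self):
        self.nodes: dict[str, GenNode] = {}
        self.root: str | None = None
        self._counter = 0

    def add_tip(self, name: str) -> str:
        self.nodes[name] = GenNode(name, 0.0)
        return name

    def merge(self, children: list[str], time: float, prefix: str = "a") -> str:
        self._counter += 1
        name = f"{prefix}{self._counter:05d}"
        self.nodes[name] = GenNode(name, time, children=list(children))
        for c in children:
            self.nodes[c].parent = name
        return name

    def tips(self) -> list[str]:
        return [n for n, nd in self.nodes.items() if not nd.children]

    def branch_years(self, node: str) -> float:
        nd = self.nodes[node]
        if nd.parent is None:
            return 0.0
        return self.nodes[nd.parent].time - nd.time

    def preorder(self) -> list[str]:
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(reversed(self.nodes[n].children))
        return out

    def newick(self) -> str:
        def fmt(name: str) -> str:
            nd = self.nodes[name]
            sub = f"({','.join(fmt(c) for c in nd.children)})" if nd.children else ""
            blen = "" if nd.parent is None else f":{self.branch_years(name):.6f}"
            return f"{sub}{name}{blen}"

        return fmt(self.root) + ";"


def _coalescence_wait(j: int, t_now: float, deme: DemeConfig, rng) -> float:
    """Waiting time to the next coalescence among j lineages, from t_now."""
    if j < 2 or deme.trajectory == "star":
        return math.inf
    pairs = j * (j - 1) / 2.0
    e = rng.exponential()
    if deme.trajectory == "constant":
        return deme.ne_years * e / pairs
    g = deme.growth_rate
    # ne(t) = ne_years * exp(-g t) backward in time; invert the hazard
    return math.log(math.exp(g * t_now) + g * deme.ne_years * e / pairs) / g - t_now


def simulate_genealogy(sc: Scenario, rng: np.random.Generator | None = None):
    """Simulate the scenario's genealogy.

    Returns ``(genealogy, truth)`` where truth holds the per-sample founder
    assignment and the founder node of each event.
    """
    rng = rng if rng is not None else np.random.default_rng(sc.seed)
    gen = Genealogy()
    sink_tips = [gen.add_tip(f"K{i:04d}") for i in range(sc.sink.n_samples)]
    source_tips = [gen.add_tip(f"S{i:04d}") for i in range(sc.source.n_samples)]

    events = sc.founder_events  # sorted young -> old
    groups = np.array_split(np.array(sink_tips, dtype=object), len(events))
    assignment: dict[str, int] = {}
    founder_nodes: dict[str, int] = {}
    incoming: list[tuple[float, list[str]]] = []   # (event time, founder lineages)

    for ev_idx, (ev, group) in enumerate(zip(events, groups)):
        active = list(group)
        for tip in active:
            assignment[tip] = ev_idx
        t = 0.0
        while len(active) > 1:
            tau = _coalescence_wait(len(active), t, sc.sink, rng)
            if t + tau >= ev.time_years:
                break
            t += tau
            i, j = sorted(rng.choice(len(active), 2, replace=False))
            node = gen.merge([active[i], active[j]], t, prefix="k")
            active = [a for idx, a in enumerate(active) if idx not in (i, j)] + [node]
        # pulse merge down to n_founders lineages at the event time
        perm = rng.permutation(len(active))
        founders = []
        for part in np.array_split(perm, min(ev.n_founders, len(active))):
            members = [active[i] for i in part]
            fnode = gen.merge(members, ev.time_years, prefix="f")
            founder_nodes[fnode] = ev_idx
            founders.append(fnode)
        incoming.append((ev.time_years, founders))

    # source phase: coalesce between events, absorb founder lineages at events
    active = list(source_tips)
    t = 0.0
    oldest = events[-1].time_years
    for ev_idx, (ev_time, founders) in enumerate(incoming):
        is_oldest = ev_idx == len(incoming) - 1
        while len(active) > 1:
            tau = _coalescence_wait(len(active), t, sc.source, rng)
            if t + tau >= ev_time:
                break
            t += tau
            i, j = sorted(rng.choice(len(active), 2, replace=False))
            node = gen.merge([active[i], active[j]], t, prefix="s")
            active = [a for idx, a in enumerate(active) if idx not in (i, j)] + [node]
        t = ev_time
        if is_oldest and sc.source.trajectory == "star":
            # the oldest founder event is the onset of the source expansion
            root = gen.merge(active + founders, ev_time, prefix="r")
            active = [root]
        elif active:
            burst = min(sc.attach_burst, len(active))
            picked = sorted(rng.choice(len(active), burst, replace=False))
            merged = gen.merge(
                [active[i] for i in picked] + founders, ev_time, prefix="b"
            )
            active = [a for idx, a in enumerate(active) if idx not in picked] + [merged]
        else:
            merged = gen.merge(founders, ev_time, prefix="b") if len(founders) > 1 else founders[0]
            active = [merged]
    # finish to the MRCA
    while len(active) > 1:
        if sc.source.trajectory == "star":
            root = gen.merge(active, oldest, prefix="r")
            active = [root]
            break
        tau = _coalescence_wait(len(active), t, sc.source, rng)
        t += tau
        i, j = sorted(rng.choice(len(active), 2, replace=False))
        node = gen.merge([active[i], active[j]], t, prefix="s")
        active = [a for idx, a in enumerate(active) if idx not in (i, j)] + [node]
    gen.root = active[0]
    truth = {
        "assignment": assignment,
        "founder_nodes": founder_nodes,
        "events": [(e.time_years, e.n_founders) for e in events],
    }
    return gen, truth


# ---------------------------------------------------------------------------
# mutations
# ---------------------------------------------------------------------------

def drop_mutations(
    gen: Genealogy,
    clock: ClockModel,
    site_model: SiteModel,
    rng: np.random.Generator,
):
    """Drop Poisson mutations on the genealogy.

    Each branch of length L years receives Poisson(L/μ) mutations assigned to
    sites in proportion to their rate class; a repeat hit at a site reverts it
    to the ancestral base (sites cycle between the reference base and its
    transition partner).  Returns ``(reference, branch_mutations, haplotypes)``
    with haplotypes keyed by tip name.
    """
    n_sites = site_model.n_sites
    ref_bases = "".join(rng.choice(list("ACGT"), n_sites))
    weights = np.ones(n_sites)
    if site_model.hotspot_fraction > 0:
        n_hot = int(round(site_model.hotspot_fraction * n_sites))
        hot = rng.choice(n_sites, size=n_hot, replace=False)
        weights[hot] = site_model.hotspot_multiplier
    weights = weights / weights.sum()
    reference = ReferenceSequence("reference", ref_bases)

    branch_mut: dict[str, list[VariantCall]] = {}
    haplotypes: dict[str, frozenset[VariantCall]] = {}
    state_stack: dict[str, dict[int, str]] = {}
    next_site = [0]

    for node in gen.preorder():
        nd = gen.nodes[node]
        state = dict(state_stack[nd.parent]) if nd.parent else {}
        L = gen.branch_years(node)
        rate = L / clock.years_per_mutation if math.isfinite(clock.years_per_mutation) else 0.0
        n_mut = rng.poisson(rate) if rate > 0 else 0
        muts: list[VariantCall] = []
        if site_model.infinite_sites:
            if next_site[0] + n_mut > n_sites:
                raise StructureError(
                    f"infinite-sites model exhausted {n_sites} sites; increase n_sites"
                )
            sites = list(range(next_site[0], next_site[0] + n_mut))
            next_site[0] += n_mut
        else:
            sites = list(rng.choice(n_sites, size=n_mut, p=weights)) if n_mut else []
        for s in sites:
            pos = int(s) + 1
            ref = ref_bases[s]
            cur = state.get(pos, ref)
            new = _ALT[ref] if cur == ref else ref
            muts.append(VariantCall(pos, new))
            if new == ref:
                state.pop(pos, None)
            else:
                state[pos] = new
        branch_mut[node] = muts
        state_stack[node] = state
        if not nd.children:
            haplotypes[node] = frozenset(
                VariantCall(pos, b) for pos, b in state.items()
            )
    return reference, branch_mut, haplotypes


# ---------------------------------------------------------------------------
# dataset container and emission
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    scenario: Scenario
    genealogy: Genealogy
    reference: ReferenceSequence
    branch_mutations: dict[str, list[VariantCall]]
    haplotypes: dict[str, frozenset[VariantCall]]
    assignment: dict[str, int]          # sink sample -> founder event index
    founder_nodes: dict[str, int]       # genealogy founder node -> event index
    events: list[tuple[float, int]]     # (time_years, n_founders)

    def sink_ids(self) -> set[str]:
        return set(self.assignment)

    def source_ids(self) -> set[str]:
        return {t for t in self.genealogy.tips() if t not in self.assignment}

    def metadata(self) -> pd.DataFrame:
        rows = []
        for tip in sorted(self.genealogy.tips()):
            sink = tip in self.assignment
            rows.append(
                {"sample_id": tip,
                 "population": "sink_pop" if sink else "source_pop",
                 "country": "sinkland" if sink else "sourceland",
                 "region": "southern" if sink else "eastern"}
            )
        return pd.DataFrame(rows)

    def to_panel(self) -> SamplePanel:
        profiles = [
            HaplotypeProfile(
                sample_id=tip,
                variants=self.haplotypes[tip],
                population="sink_pop" if tip in self.assignment else "source_pop",
                country="sinkland" if tip in self.assignment else "sourceland",
                region="southern" if tip in self.assignment else "eastern",
                segment="hvs1",
            )
            for tip in sorted(self.genealogy.tips())
        ]
        return SamplePanel(profiles, self.reference, [f"simulated seed={self.scenario.seed}"])

    def to_mutation_tree(self) -> RootedMutationTree:
        """Truth genealogy as a rooted mutation tree (tips carry their
        sample, multiplicity 1)."""
        gen = self.genealogy
        ref_states = {i + 1: b for i, b in enumerate(self.reference.bases)}
        tree = RootedMutationTree(gen.root, reference_states=ref_states)
        for node in gen.preorder():
            if node == gen.root:
                continue
            nd = gen.nodes[node]
            is_tip = not nd.children
            tree.add_child(
                nd.parent,
                node,
                self.branch_mutations.get(node, ()),
                multiplicity=1 if is_tip else 0,
                sample_ids=(node,) if is_tip else (),
            )
        return tree


def simulate_dataset(sc: Scenario) -> SimulatedDataset:
    """One-call generator: genealogy + mutations, fully seeded."""
    rng = np.random.default_rng(sc.seed)
    gen, truth = simulate_genealogy(sc, rng)
    reference, branch_mut, haplotypes = drop_mutations(gen, sc.clock, sc.site_model, rng)
    return SimulatedDataset(
        scenario=sc,
        genealogy=gen,
        reference=reference,
        branch_mutations=branch_mut,
        haplotypes=haplotypes,
        assignment=truth["assignment"],
        founder_nodes=truth["founder_nodes"],
        events=truth["events"],
    )


def emit_dataset(ds: SimulatedDataset, out_dir: str | Path, force: bool = False) -> dict:
    """Write the dataset as pipeline-ready plain-text files plus truth and a
    manifest.  Refuses a non-empty output directory unless ``force``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty (use force=True to overwrite)")

    from .haplotype_io import write_alignment

    panel = ds.to_panel()
    write_alignment(panel, out / "samples.fasta")
    ds.metadata().to_csv(out / "metadata.csv", index=False)
    tree = ds.to_mutation_tree()
    tree.to_csv(out / "truth_tree.csv")
    (out / "genealogy.nwk").write_text(ds.genealogy.newick() + "\n")
    truth = {
        "events": [{"time_years": t, "n_founders": k} for t, k in ds.events],
        "assignment": ds.assignment,
        "founder_nodes": ds.founder_nodes,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    manifest = {
        "seed": ds.scenario.seed,
        "config_digest": ds.scenario.digest(),
        "n_sink": len(ds.sink_ids()),
        "n_source": len(ds.source_ids()),
        "n_sites": ds.scenario.site_model.n_sites,
        "clock": ds.scenario.clock.name,
        "years_per_mutation": ds.scenario.clock.years_per_mutation,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
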