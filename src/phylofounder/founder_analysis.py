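"""Founder analysis of migration times.

Given a rooted mutation tree containing samples from a *source* and a *sink*
region, each sink lineage is walked toward the root until it reaches a
founder candidate: a node whose haplotype is carried by at least one source
sample.  The f-criteria guard against recent back migration, which shows up
as direct sequence matches on the tips: under f1 the candidate must in
addition show at least one derived branch leading to source samples (minimal
time depth in the source); f2 demands two such branches; f0 accepts plain
matches.  Sink lineages sharing a candidate merge into a founder cluster,
dated by the ρ statistic over the sink-side variation accumulated since the
founder haplotype.

Because mutations within a cluster are not independent (shared branches), the
cluster's sample size is corrected to an effective number of lineages
n_eff = ρ/σ² (star variance over Saillard variance).  The migration-time scan
then spreads each cluster's age likelihood over a regular grid (200-year
steps, 0–120 ka by default): under a Poisson clock the posterior for the
founder arrival time t with m_eff = ρ·n_eff effective mutations and rate
λ = n_eff/μ is the gamma-shaped density t^m_eff·e^(−λt) (uniform grid prior),
which peaks at the cluster's ρ age.  Clusters are aggregated with weights
proportional to their sink lineage counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .clade_dating import AgeEstimate, ClockModel, HVS1_CLOCK, age_from_rho, effective_sample_size
from .errors import ConfigurationError
from .tree import RootedMutationTree

log = logging.getLogger(__name__)

CRITERIA = ("f0", "f1", "f2")


@dataclass
class FounderCluster:
    founder_node: str
    founder_label: str
    sink_members: list[str]              # sample ids, duplicates = multiplicity
    m_f: int                             # total sink-side mutations from the founder
    sigma_f: float                       # Saillard SE over the sink subtree
    n_eff: float
    age: AgeEstimate
    at_root: bool = False                # fell through to the root (warned)

    @property
    def n_f(self) -> int:
        return len(self.sink_members)

    @property
    def rho_f(self) -> float:
        return self.m_f / self.n_f


def _subtree_counts(tree: RootedMutationTree, ids: set[str]) -> dict[str, int]:
    """Per node: number of samples from ``ids`` at or below it."""
    counts = {n: sum(1 for s in tree.sample_ids(n) if s in ids) for n in tree.nodes}
    for node in reversed(list(tree.preorder())):
        for child in tree.children(node):
            counts[node] += counts[child]
    return counts


def identify_founders(
    tree: RootedMutationTree,
    source_ids: set[str],
    sink_ids: set[str],
    criterion: str = "f1",
    clock: ClockModel = HVS1_CLOCK,
) -> list[FounderCluster]:
    """Assign every sink lineage to its founder node and build dated clusters.

    A sink lineage walks rootward to the nearest node whose haplotype is
    carried by a source sample and which satisfies the chosen f-criterion;
    lineages that reach the root without a qualifying node are assigned to a
    root founder with a warning.  The sum of cluster sizes always equals the
    number of sink lineages.
    """
    if criterion not in CRITERIA:
        raise ValueError(f"criterion must be one of {CRITERIA}")
    source_ids, sink_ids = set(source_ids), set(sink_ids)
    if source_ids & sink_ids:
        raise ValueError("source and sink sample sets must be disjoint")
    present = {s for n in tree.nodes for s in tree.sample_ids(n)}
    for label, ids in (("source", source_ids), ("sink", sink_ids)):
        missing = ids - present
        if missing:
            raise ValueError(f"{label} samples absent from tree: {sorted(missing)[:5]}")
    if not sink_ids:
        return []

    haplotypes = tree.all_node_variants()
    source_types = {
        haplotypes[n]
        for n in tree.nodes
        if any(s in source_ids for s in tree.sample_ids(n))
    }
    src_below = _subtree_counts(tree, source_ids)
    need_branches = {"f0": 0, "f1": 1, "f2": 2}[criterion]

    def qualifies(node: str) -> bool:
        if haplotypes[node] not in source_types:
            return False
        derived = sum(1 for c in tree.children(node) if src_below[c] > 0)
        return derived >= need_branches

    # walk each sink lineage rootward
    members: dict[str, list[tuple[str, str]]] = {}   # founder node -> [(sample, tip node)]
    fell_through = 0
    for node in tree.preorder():
        for sample in tree.sample_ids(node):
            if sample not in sink_ids:
                continue
            founder = None
            for anc in tree.path_to_root(node):
                if qualifies(anc):
                    founder = anc
                    break
            if founder is None:
                founder = tree.root
                fell_through += 1
            members.setdefault(founder, []).append((sample, node))
    if fell_through:
        warnings.warn(
            f"{fell_through} sink lineage(s) reached the root without a "
            f"qualifying founder node; assigned to the root founder",
            stacklevel=2,
        )

    order = {n: i for i, n in enumerate(tree.preorder())}
    clusters: list[FounderCluster] = []
    for i, founder in enumerate(sorted(members, key=order.get), start=1):
        mem = members[founder]
        n_f = len(mem)
        # per-branch weights over the union of founder->member paths
        branch_weight: dict[str, int] = {}
        for _, tip in mem:
            for node in tree.path_to_root(tip):
                if node == founder:
                    break
                branch_weight[node] = branch_weight.get(node, 0) + 1
        m_f = sum(w * tree.branch_length(n) for n, w in branch_weight.items())
        var = sum(
            (w / n_f) ** 2 * tree.branch_length(n) for n, w in branch_weight.items()
        )
        rho_f = m_f / n_f
        sigma_f = var ** 0.5
        n_eff = effective_sample_size(rho_f, var, n_f)
        n_eff = min(max(n_eff, 1.0), float(n_f))
        age = age_from_rho(rho_f, sigma_f, clock, n_f)
        clusters.append(
            FounderCluster(
                founder_node=founder,
                founder_label=f"F{i}",
                sink_members=[s for s, _ in mem],
                m_f=m_f,
                sigma_f=sigma_f,
                n_eff=n_eff,
                age=age,
                at_root=(founder == tree.root),
            )
        )
    assert sum(c.n_f for c in clusters) == sum(
        1 for n in tree.nodes for s in tree.sample_ids(n) if s in sink_ids
    )
    return clusters


def founder_age(cluster: FounderCluster, clock: ClockModel) -> AgeEstimate:
    """Date one founder cluster from its sink-side ρ."""
    return age_from_rho(cluster.rho_f, cluster.sigma_f, clock, cluster.n_f)


def founder_table(clusters: list[FounderCluster]) -> pd.DataFrame:
    rows = []
    for c in clusters:
        lo, hi = c.age.ci95
        rows.append(
            {"founder": c.founder_label, "node": c.founder_node, "n_f": c.n_f,
             "m_f": c.m_f, "rho_f": c.rho_f, "sigma_f": c.sigma_f,
             "n_eff": c.n_eff, "age_years": c.age.age_years,
             "ci_low_years": lo, "ci_high_years": hi, "at_root": c.at_root}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# migration-time scan
# ---------------------------------------------------------------------------

@dataclass
class MigrationScanResult:
    grid: np.ndarray                       # years
    per_founder: dict[str, np.ndarray]     # each sums to 1
    aggregate: np.ndarray                  # sums to 1
    weights: dict[str, float] = field(default_factory=dict)

    @property
    def mode_years(self) -> float:
        return float(self.grid[int(np.argmax(self.aggregate))])

    def modes(self, min_height_frac: float = 0.05) -> list[float]:
        """Grid times of local maxima of the aggregate mass, ignoring bumps
        below ``min_height_frac`` of the global maximum."""
        y = self.aggregate
        floor = min_height_frac * float(y.max())
        out = []
        for i in range(len(y)):
            left = y[i - 1] if i > 0 else -np.inf
            right = y[i + 1] if i < len(y) - 1 else -np.inf
            if y[i] > left and y[i] >= right and y[i] >= floor:
                out.append(float(self.grid[i]))
        return out

    def to_frame(self) -> pd.DataFrame:
        data = {"t_years": self.grid, "aggregate_mass": self.aggregate}
        for label, mass in self.per_founder.items():
            data[label] = mass
        return pd.DataFrame(data)


def migration_scan(
    clusters: list[FounderCluster],
    clock: ClockModel = HVS1_CLOCK,
    grid_step: float = 200.0,
    t_max: float = 120_000.0,
) -> MigrationScanResult:
    """Probability mass of founder arrival times on a regular grid.

    Per founder, the unnormalized mass at grid time t is
    t^m_eff · exp(−λ t) with m_eff = ρ_f·n_eff and λ = n_eff/μ (computed in
    log space); m_eff = 0 gives a decreasing exponential peaked at t = 0.
    The aggregate weights clusters by their sink lineage counts n_f.
    """
    if not clusters:
        raise ValueError("need at least one founder cluster")
    if grid_step <= 0:
        raise ValueError("grid_step must be > 0")
    if not clock.is_identity:
        raise ValueError("the scan model assumes a linear (identity-correction) clock")
    grid = np.arange(0.0, t_max + grid_step / 2, grid_step)
    n_total = sum(c.n_f for c in clusters)
    per_founder: dict[str, np.ndarray] = {}
    weights: dict[str, float] = {}
    aggregate = np.zeros_like(grid)
    for c in clusters:
        m_eff = c.rho_f * c.n_eff
        lam = c.n_eff / clock.years_per_mutation
        if m_eff / lam > t_max:
            warnings.warn(
                f"{c.founder_label}: analytic mode {m_eff / lam:.0f} y beyond "
                f"t_max {t_max:.0f} y; mass truncated",
                stacklevel=2,
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            logmass = m_eff * np.log(grid) - lam * grid
        if m_eff == 0:
            logmass[0] = 0.0          # t^0 = 1 at t = 0
        else:
            logmass[0] = -np.inf
        mass = np.exp(logmass - logsumexp(logmass))
        per_founder[c.founder_label] = mass
        w = c.n_f / n_total
        weights[c.founder_label] = w
        aggregate += w * mass
    aggregate = aggregate / aggregate.sum()
    return MigrationScanResult(grid, per_founder, aggregate, weights)


# ---------------------------------------------------------------------------
# sink definition
# ---------------------------------------------------------------------------

def define_sink(
    metadata: pd.DataFrame, sink_spec: str
) -> tuple[set[str], set[str]]:
    """Split the metadata into (sink_ids, source_ids) by a pandas query
    expression over the metadata columns, e.g. ``region == 'southern'`` or
    ``region == 'southern' and population in @eastern_stream``."""
    try:
        sink_rows = metadata.query(sink_spec)
    except Exception as exc:  # pandas raises several types for bad queries
        raise ConfigurationError(f"invalid sink filter {sink_spec!r}: {exc}") from exc
    sink = set(sink_rows["sample_id"])
    if not sink:
        raise ConfigurationError(f"sink filter {sink_spec!r} selected no samples")
    source = set(metadata["sample_id"]) - sink
    log.info("define_sink(%r): %d sink, %d source", sink_spec, len(sink), len(source))
    return sink, source
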