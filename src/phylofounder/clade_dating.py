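"""Rho-statistic clade dating.

ρ is the mean number of mutations separating the sampled sequences of a clade
from the clade's ancestral haplotype; multiplied by a molecular clock (years
per mutation) it estimates the clade age.  The standard error follows the
Saillard branch-weighted formula

    σ² = Σ_b (n_b / n)² ℓ_b

over the branches of the clade, with n_b the number of sampled tips below
branch b, ℓ_b the branch's mutation count and n the clade's sample count.
ρ itself is the same sum with linear weights, ρ = Σ_b (n_b / n) ℓ_b, which
equals the multiplicity-weighted mean root-to-tip mutation count.

The ratio of the star-tree variance (ρ/n) to the Saillard variance gives the
effective number of independent lineages, n_eff = ρ/σ²: n on a star,
1 when every mutation is shared by all tips.

Built-in clocks (years per mutation): whole-mtDNA 3624 (with a pluggable
purifying-selection correction hook, identity by default), synonymous 7884,
HVS-I 16677.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .haplotype_io import HaplotypeProfile, VariantCall
from .tree import RootedMutationTree


# ---------------------------------------------------------------------------
# clocks
# ---------------------------------------------------------------------------

def identity_correction(years: float) -> float:
    return years


@dataclass(frozen=True)
class ClockModel:
    """Years-per-mutation molecular clock with an optional correction
    transform (the purifying-selection hook).  The correction must fix 0 and
    be monotone non-decreasing."""

    name: str
    years_per_mutation: float
    correction: Callable[[float], float] = identity_correction

    def __post_init__(self):
        if self.years_per_mutation <= 0:
            raise ValueError("years_per_mutation must be > 0")
        if abs(self.correction(0.0)) > 1e-9:
            raise ValueError("correction must map 0 -> 0")
        grid = np.linspace(0.0, 1e6, 101)
        vals = [self.correction(float(t)) for t in grid]
        if any(b < a - 1e-9 for a, b in zip(vals, vals[1:])):
            raise ValueError("correction must be monotone non-decreasing")

    @property
    def is_identity(self) -> bool:
        return self.correction is identity_correction

    def slope_at(self, years: float, h: float = 1.0) -> float:
        """Finite-difference local slope of the correction (for SE propagation)."""
        lo = max(0.0, years - h)
        return (self.correction(years + h) - self.correction(lo)) / (years + h - lo)


def piecewise_correction(table: Sequence[tuple[float, float]]) -> Callable[[float], float]:
    """Piecewise-linear correction from (raw_years, corrected_years) pairs,
    extrapolated linearly beyond the last knot."""
    pts = sorted((float(a), float(b)) for a, b in table)
    xs = np.array([0.0] + [p[0] for p in pts])
    ys = np.array([0.0] + [p[1] for p in pts])

    def corr(years: float) -> float:
        if years >= xs[-1] and len(xs) >= 2:
            slope = (ys[-1] - ys[-2]) / max(xs[-1] - xs[-2], 1e-12)
            return float(ys[-1] + slope * (years - xs[-1]))
        return float(np.interp(years, xs, ys))

    return corr


#: whole-mtDNA substitution rate: one substitution per 3624 years (the
#: published purifying-selection correction curve is supplied by the user as a
#: piecewise table; identity by default)
WHOLE_MTDNA_CLOCK = ClockModel("whole_mtdna", 3624.0)
#: synonymous substitutions: one per 7884 years (no selection correction needed)
SYNONYMOUS_CLOCK = ClockModel("synonymous", 7884.0)
#: HVS-I / founder-analysis clock: 16,677 years per mutation
HVS1_CLOCK = ClockModel("hvs1", 16677.0)

BUILTIN_CLOCKS = {c.name: c for c in (WHOLE_MTDNA_CLOCK, SYNONYMOUS_CLOCK, HVS1_CLOCK)}


def get_clock(name: str, correction_table: str | Path | None = None) -> ClockModel:
    """Look up a built-in clock, optionally attaching a correction table
    (CSV with columns raw_years, corrected_years)."""
    if name not in BUILTIN_CLOCKS:
        raise KeyError(f"unknown clock {name!r}; have {sorted(BUILTIN_CLOCKS)}")
    clock = BUILTIN_CLOCKS[name]
    if correction_table is not None:
        df = pd.read_csv(correction_table)
        corr = piecewise_correction(list(zip(df["raw_years"], df["corrected_years"])))
        clock = ClockModel(clock.name, clock.years_per_mutation, corr)
    return clock


# ---------------------------------------------------------------------------
# rho and Saillard variance
# ---------------------------------------------------------------------------

def rho_statistic(tree: RootedMutationTree, clade_root: str | None = None) -> float:
    """Mean number of mutations from the clade's ancestral haplotype to its
    sampled tips (multiplicities respected)."""
    clade_root = clade_root if clade_root is not None else tree.root
    n = tree.subtree_multiplicity(clade_root)
    if n == 0:
        raise ValueError(f"clade {clade_root!r} contains no sampled tips")
    return sum(nb * lb for _, lb, nb in tree.branches_below(clade_root)) / n


def saillard_variance(tree: RootedMutationTree, clade_root: str | None = None) -> float:
    """σ² = Σ_b (n_b/n)² ℓ_b over the clade's branches."""
    clade_root = clade_root if clade_root is not None else tree.root
    n = tree.subtree_multiplicity(clade_root)
    if n == 0:
        raise ValueError(f"clade {clade_root!r} contains no sampled tips")
    return sum((nb / n) ** 2 * lb for _, lb, nb in tree.branches_below(clade_root))


def effective_sample_size(rho: float, variance: float, n: int) -> float:
    """n × (star variance ρ/n) / (Saillard variance) = ρ/σ².

    Equals n exactly on a star genealogy and 1 when all variation is shared;
    when ρ = 0 (hence σ² = 0) it is n by convention.
    """
    if rho < 0 or variance < 0 or n < 1:
        raise ValueError("rho and variance must be >= 0 and n >= 1")
    if rho == 0:
        return float(n)
    if variance == 0:
        # no branch has positive length below any multi-tip split: treat as star
        return float(n)
    return rho / variance


@dataclass(frozen=True)
class AgeEstimate:
    rho: float
    sigma: float
    age_years: float
    se_years: float
    n_tips: int
    clock: str = ""

    @property
    def ci95(self) -> tuple[float, float]:
        return (max(0.0, self.age_years - 1.96 * self.se_years),
                self.age_years + 1.96 * self.se_years)


def age_from_rho(
    rho: float, sigma: float, clock: ClockModel, n_tips: int = 0
) -> AgeEstimate:
    """Convert ρ ± σ (mutations) to years through the clock and its
    correction; the SE is propagated through the correction's local slope."""
    raw = rho * clock.years_per_mutation
    age = clock.correction(raw)
    slope = 1.0 if clock.is_identity else clock.slope_at(raw)
    se = sigma * clock.years_per_mutation * slope
    return AgeEstimate(rho, sigma, age, se, n_tips, clock.name)


def date_clade(
    tree: RootedMutationTree, clade_root: str, clock: ClockModel
) -> AgeEstimate:
    rho = rho_statistic(tree, clade_root)
    sigma = saillard_variance(tree, clade_root) ** 0.5
    return age_from_rho(rho, sigma, clock, tree.subtree_multiplicity(clade_root))


def ages_table(
    tree: RootedMutationTree, clades: Iterable[str], clock: ClockModel
) -> pd.DataFrame:
    """CSV-ready ages table: clade, n, rho, sigma, age_ka, ci_low, ci_high."""
    rows = []
    for clade in clades:
        est = date_clade(tree, clade, clock)
        lo, hi = est.ci95
        rows.append(
            {"clade": clade, "n": est.n_tips, "rho": est.rho, "sigma": est.sigma,
             "age_ka": est.age_years / 1000.0,
             "ci_low_ka": lo / 1000.0, "ci_high_ka": hi / 1000.0}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiversityStats:
    rho: float
    rho_se: float
    pi: float
    n: int


def diversity(
    haplotypes: Sequence[HaplotypeProfile],
    root_profile: Iterable[VariantCall] = frozenset(),
) -> DiversityStats:
    """Sequence diversity of a haplotype set.

    ρ: mean variant-set symmetric difference to the designated root haplotype
    (star-model SE √(total mutations)/n); π: mean pairwise difference.
    """
    if len(haplotypes) == 0:
        raise ValueError("need at least one haplotype")
    root = frozenset(root_profile)
    n = len(haplotypes)
    dists = [len(h.variants ^ root) for h in haplotypes]
    rho = float(np.mean(dists))
    rho_se = float(np.sqrt(sum(dists)) / n)
    if n == 1:
        pi = 0.0
    else:
        pi = float(
            np.mean([len(a.variants ^ b.variants) for a, b in combinations(haplotypes, 2)])
        )
    return DiversityStats(rho, rho_se, pi, n)
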