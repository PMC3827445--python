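"""Haplogroup assignment from hierarchical diagnostic motifs, and mapping of
populations to broad geographic regions.

A motif table is a rooted hierarchy of haplogroup labels; each label carries
the diagnostic variants that define its branch relative to its parent.  A
profile is assigned the deepest label whose *cumulative* motif (union of
motifs along the path from the root) it matches, allowing a configurable
number of missing motif variants (back mutations).  Extra private variants
never penalize a match.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigurationError
from .haplotype_io import HaplotypeProfile, VariantCall, parse_variant_string

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MotifTable:
    """Hierarchy of haplogroup labels with per-branch diagnostic variants."""

    parent: dict[str, str | None]          # label -> parent (None at the root)
    motif: dict[str, frozenset[VariantCall]]

    def __post_init__(self):
        if not self.parent:
            raise ConfigurationError("empty motif table")
        roots = [l for l, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise ConfigurationError(f"motif table must have exactly one root, got {roots}")
        for label, par in self.parent.items():
            if par is not None and par not in self.parent:
                raise ConfigurationError(f"{label}: unknown parent {par!r}")
            # cycle check by walking to the root
            seen = {label}
            node = par
            while node is not None:
                if node in seen:
                    raise ConfigurationError(f"cycle in motif hierarchy at {node!r}")
                seen.add(node)
                node = self.parent[node]

    @property
    def root(self) -> str:
        return next(l for l, p in self.parent.items() if p is None)

    @property
    def labels(self) -> list[str]:
        return sorted(self.parent)

    def depth(self, label: str) -> int:
        d = 0
        node = self.parent[label]
        while node is not None:
            d += 1
            node = self.parent[node]
        return d

    def ancestors(self, label: str) -> list[str]:
        """Path root -> ... -> parent(label), excluding label itself."""
        path = []
        node = self.parent[label]
        while node is not None:
            path.append(node)
            node = self.parent[node]
        return list(reversed(path))

    def cumulative_motif(self, label: str) -> frozenset[VariantCall]:
        acc: set[VariantCall] = set(self.motif.get(label, frozenset()))
        for anc in self.ancestors(label):
            acc |= self.motif.get(anc, frozenset())
        return frozenset(acc)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MotifTable":
        """Load a table of the form ``{label: {parent: <label|null>,
        motif: "<variant string>"}}``."""
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict) or not data:
            raise ConfigurationError(f"motif table {path}: expected a nonempty mapping")
        parent = {}
        motif = {}
        for label, row in data.items():
            row = row or {}
            parent[str(label)] = row.get("parent")
            motif[str(label)] = parse_variant_string(str(row.get("motif", "") or ""))
        return cls(parent, motif)


def classify(
    profile: HaplotypeProfile, table: MotifTable, tolerance: int = 0
) -> tuple[str, int, int]:
    """Assign the deepest haplogroup whose cumulative motif the profile matches
    with at most ``tolerance`` missing variants.

    Returns ``(label, matched_variants, missed_variants)``.  Equal-depth ties
    prefer more matched variants, then the lexicographically smallest label.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    best: tuple[int, int, str] | None = None  # (depth, matched, label) maximized
    best_counts = (0, 0)
    for label in table.labels:
        cum = table.cumulative_motif(label)
        matched = len(cum & profile.variants)
        missed = len(cum) - matched
        if missed > tolerance:
            continue
        key = (table.depth(label), matched, _NegStr(label))
        if best is None or key > best:
            best = key
            best_counts = (matched, missed)
    if best is None:
        # even the root's own motif misses beyond tolerance: report the root
        root = table.root
        cum = table.cumulative_motif(root)
        matched = len(cum & profile.variants)
        return root, matched, len(cum) - matched
    return str(best[2]), best_counts[0], best_counts[1]


class _NegStr(str):
    """String with reversed ordering, so max() picks the lexicographically
    smallest label on ties."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def classify_panel(
    profiles: list[HaplotypeProfile], table: MotifTable, tolerance: int = 0
) -> pd.DataFrame:
    rows = []
    for p in profiles:
        label, matched, missed = classify(p, table, tolerance)
        rows.append(
            {"sample_id": p.sample_id, "haplogroup": label,
             "matched": matched, "missed": missed, "region": p.region}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# geography
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionMap:
    """population/country name -> broad region.  Lookup order: population,
    then country, then ``"other"`` with a warning."""

    mapping: dict[str, str]

    @classmethod
    def from_csv(cls, path: str | Path) -> "RegionMap":
        df = pd.read_csv(path, dtype=str).fillna("")
        if not {"name", "region"} <= set(df.columns):
            raise ConfigurationError("region map needs columns: name, region")
        return cls(dict(zip(df["name"], df["region"])))

    def lookup(self, population: str, country: str = "") -> str:
        if population in self.mapping:
            return self.mapping[population]
        if country and country in self.mapping:
            return self.mapping[country]
        warnings.warn(
            f"population {population!r} (country {country!r}) not in region map; "
            "assigning 'other'",
            stacklevel=2,
        )
        return "other"


def assign_region(profile: HaplotypeProfile, region_map: RegionMap) -> str:
    return region_map.lookup(profile.population, profile.country)
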