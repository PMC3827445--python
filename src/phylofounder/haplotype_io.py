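"""Reading, writing and reference-relative encoding of mtDNA haplotypes.

Samples are expressed as *variant profiles*: the set of positions at which a
sequence differs from a designated reference, in the 1-based,
position-plus-base notation conventional for mtDNA (e.g. ``16129A 16189d
16193.1C``).  Profiles carry the QC and provenance fields (ambiguous-base
counts, population, broad geographic region) that downstream classification,
network construction and founder analysis consume.

The mitochondrial genome is circular but an alignment fixes a linearization;
all positions here are 1-based on that linearization and intervals are closed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlignmentError,
    MissingReferenceError,
    VariantParseError,
)

#: canonical broad geographic regions used throughout the package
REGIONS = ("eastern", "central", "southern", "western", "northern", "sahel", "other")

#: default hypervariable-segment-I window (1-based, closed)
HVS1_WINDOW = (16051, 16400)

_BASES = frozenset("ACGT")
_AMBIGUOUS = frozenset("NRYSWKMBDHV?")  # IUPAC codes + unknown

SUBSTITUTION = "substitution"
INSERTION = "insertion"
DELETION = "deletion"


@dataclass(frozen=True, order=True)
class VariantCall:
    """A single difference from the reference.

    ``position`` is 1-based.  For insertions, ``insert_index`` distinguishes
    successive inserted residues after the same flanking reference position
    (``16193.1C`` = first inserted base after 16193).  ``derived_state`` is the
    inserted/substituted base, or ``"-"`` for a deletion.
    """

    position: int
    derived_state: str
    kind: str = SUBSTITUTION
    insert_index: int = 0

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if not self.derived_state:
            raise ValueError("derived_state must be nonempty")
        if self.kind not in (SUBSTITUTION, INSERTION, DELETION):
            raise ValueError(f"unknown variant kind {self.kind!r}")

    def token(self) -> str:
        if self.kind == SUBSTITUTION:
            return f"{self.position}{self.derived_state}"
        if self.kind == DELETION:
            return f"{self.position}d"
        return f"{self.position}.{self.insert_index}{self.derived_state}"


@dataclass(frozen=True)
class ReferenceSequence:
    name: str
    bases: str

    def __post_init__(self):
        if len(self.bases) == 0:
            raise ValueError("reference must be nonempty")
        bad = set(self.bases.upper()) - (_BASES | {"N"})
        if bad:
            raise ValueError(f"reference contains non-ACGTN residues: {sorted(bad)}")
        object.__setattr__(self, "bases", self.bases.upper())

    def __len__(self) -> int:
        return len(self.bases)

    def base(self, position: int) -> str:
        """1-based access."""
        return self.bases[position - 1]


@dataclass(frozen=True)
class HaplotypeProfile:
    sample_id: str
    variants: frozenset[VariantCall] = frozenset()
    n_ambiguous: int = 0
    population: str = ""
    country: str = ""
    region: str = "other"
    segment: str = "whole_genome"

    def __post_init__(self):
        if self.n_ambiguous < 0:
            raise ValueError("n_ambiguous must be >= 0")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        keys = [(v.position, v.kind, v.insert_index) for v in self.variants]
        if len(keys) != len(set(keys)):
            raise ValueError(f"{self.sample_id}: duplicate variant positions")

    @property
    def substitutions(self) -> frozenset[VariantCall]:
        return frozenset(v for v in self.variants if v.kind == SUBSTITUTION)


@dataclass
class SamplePanel:
    profiles: list[HaplotypeProfile]
    reference: ReferenceSequence
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        ids = [p.sample_id for p in self.profiles]
        if len(ids) != len(set(ids)):
            raise ValueError("sample ids must be unique")
        n = len(self.reference)
        for p in self.profiles:
            for v in p.variants:
                if v.position > n:
                    raise ValueError(
                        f"{p.sample_id}: variant position {v.position} beyond "
                        f"reference length {n}"
                    )

    def __len__(self) -> int:
        return len(self.profiles)

    def ids(self) -> list[str]:
        return [p.sample_id for p in self.profiles]

    def get(self, sample_id: str) -> HaplotypeProfile:
        for p in self.profiles:
            if p.sample_id == sample_id:
                return p
        raise KeyError(sample_id)

    def log(self, message: str) -> None:
        self.provenance.append(message)


# ---------------------------------------------------------------------------
# variant-string notation
# ---------------------------------------------------------------------------

_SUB_RE = re.compile(r"^(\d+)([ACGT])$", re.IGNORECASE)
_DEL_RE = re.compile(r"^(\d+)D$", re.IGNORECASE)
_INS_RE = re.compile(r"^(\d+)\.(\d+)([ACGT]+)$", re.IGNORECASE)


def parse_variant_string(spec: str) -> frozenset[VariantCall]:
    """Parse whitespace-separated position+base tokens into variant calls.

    ``16129A`` substitution, ``16189d`` deletion, ``16193.1C`` insertion
    (first inserted base after position 16193).
    """
    calls: set[VariantCall] = set()
    for token in spec.split():
        m = _SUB_RE.match(token)
        if m:
            calls.add(VariantCall(int(m.group(1)), m.group(2).upper()))
            continue
        m = _DEL_RE.match(token)
        if m:
            calls.add(VariantCall(int(m.group(1)), "-", DELETION))
            continue
        m = _INS_RE.match(token)
        if m:
            calls.add(
                VariantCall(int(m.group(1)), m.group(3).upper(), INSERTION, int(m.group(2)))
            )
            continue
        raise VariantParseError(token)
    return frozenset(calls)


def write_variant_string(variants: Iterable[VariantCall]) -> str:
    """Inverse of :func:`parse_variant_string` (canonical sorted order)."""
    ordered = sorted(variants, key=lambda v: (v.position, v.insert_index, v.kind, v.derived_state))
    return " ".join(v.token() for v in ordered)


# ---------------------------------------------------------------------------
# FASTA alignment -> variant profiles
# ---------------------------------------------------------------------------

def _homopolymer_runs(bases: str, min_run: int) -> set[int]:
    """1-based positions inside reference mononucleotide runs of >= min_run."""
    runs: set[int] = set()
    i = 0
    n = len(bases)
    while i < n:
        j = i
        while j < n and bases[j] == bases[i]:
            j += 1
        if bases[i] != "-" and j - i >= min_run:
            runs.update(range(i + 1, j + 1))
        i = j
    return runs


def encode_against_reference(
    aligned_ref: str,
    aligned_seq: str,
    *,
    min_homopolymer: int | None = 5,
) -> tuple[frozenset[VariantCall], int]:
    """Column-by-column encoding of one aligned sequence against the aligned
    reference row.  Returns (variants, n_ambiguous).

    Gap in the sample over a reference base -> deletion; reference gap under a
    sample base -> insertion keyed to the 5' flanking reference position.
    Ambiguity codes are counted but never emitted as variants.  Indel calls
    inside reference homopolymer runs of >= ``min_homopolymer`` are dropped
    (length polymorphism in such tracts is hypervariable and down-weighted by
    convention); pass ``None`` to keep them.
    """
    if len(aligned_ref) != len(aligned_seq):
        raise AlignmentError("aligned records differ in length")
    hp = (
        _homopolymer_runs(aligned_ref.upper().replace("-", ""), min_homopolymer)
        if min_homopolymer
        else set()
    )
    variants: set[VariantCall] = set()
    n_ambiguous = 0
    ref_pos = 0  # 1-based position of the last reference base seen
    insert_index = 0
    for rbase, sbase in zip(aligned_ref.upper(), aligned_seq.upper()):
        if rbase != "-":
            ref_pos += 1
            insert_index = 0
            if sbase == "-":
                if ref_pos not in hp:
                    variants.add(VariantCall(ref_pos, "-", DELETION))
            elif sbase in _AMBIGUOUS:
                n_ambiguous += 1
            elif sbase != rbase and sbase in _BASES:
                variants.add(VariantCall(ref_pos, sbase))
            elif sbase not in _BASES:
                n_ambiguous += 1
        else:  # insertion column
            if sbase == "-":
                continue
            insert_index += 1
            if sbase in _AMBIGUOUS or sbase not in _BASES:
                n_ambiguous += 1
            elif ref_pos >= 1 and ref_pos not in hp:
                variants.add(VariantCall(ref_pos, sbase, INSERTION, insert_index))
    return frozenset(variants), n_ambiguous


def read_alignment(
    path: str | Path,
    reference_id: str,
    *,
    metadata: pd.DataFrame | None = None,
    segment: str = "whole_genome",
    min_homopolymer: int | None = 5,
) -> SamplePanel:
    """Read a pre-aligned FASTA and encode every non-reference record as a
    variant profile relative to ``reference_id``.

    ``metadata``, if given, must have a ``sample_id`` column and may supply
    ``population``, ``country`` and ``region``.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise AlignmentError(f"unequal aligned record lengths in {path}: {sorted(lengths)}")
    by_id = {r.id: r for r in records}
    if reference_id not in by_id:
        raise MissingReferenceError(f"reference {reference_id!r} not among records")
    aligned_ref = str(by_id[reference_id].seq).upper()
    reference = ReferenceSequence(reference_id, aligned_ref.replace("-", ""))

    meta: dict[str, dict] = {}
    if metadata is not None:
        if "sample_id" not in metadata.columns:
            raise ValueError("metadata must have a sample_id column")
        meta = metadata.set_index("sample_id").to_dict("index")

    profiles = []
    for rec in records:
        if rec.id == reference_id:
            continue
        variants, n_amb = encode_against_reference(
            aligned_ref, str(rec.seq), min_homopolymer=min_homopolymer
        )
        row = meta.get(rec.id, {})
        profiles.append(
            HaplotypeProfile(
                sample_id=rec.id,
                variants=variants,
                n_ambiguous=n_amb,
                population=str(row.get("population", "") or ""),
                country=str(row.get("country", "") or ""),
                region=str(row.get("region", "other") or "other"),
                segment=segment,
            )
        )
    panel = SamplePanel(profiles, reference)
    panel.log(f"read_alignment: {len(profiles)} profiles vs {reference_id} from {path}")
    return panel


def write_alignment(panel: SamplePanel, path: str | Path) -> None:
    """Write the panel back to FASTA (reference first).  Substitutions and
    deletions are materialized; insertion calls are not representable in a
    fixed-length alignment and raise."""
    ref = panel.reference
    records = [SeqRecord(Seq(ref.bases), id=ref.name, description="")]
    for p in panel.profiles:
        seq = list(ref.bases)
        for v in sorted(p.variants):
            if v.kind == INSERTION:
                raise ValueError("cannot write insertion calls to unpadded FASTA")
            seq[v.position - 1] = "-" if v.kind == DELETION else v.derived_state
        records.append(SeqRecord(Seq("".join(seq)), id=p.sample_id, description=""))
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# QC filters and segment windows
# ---------------------------------------------------------------------------

def filter_ambiguous(
    panel: SamplePanel, max_ambiguous: int = 0
) -> tuple[SamplePanel, pd.DataFrame]:
    """Drop profiles with more than ``max_ambiguous`` ambiguous residues.

    Returns the filtered panel (a new object; input untouched) and an
    exclusion report with columns ``sample_id`` and ``n_ambiguous``.
    """
    if max_ambiguous < 0:
        raise ValueError("max_ambiguous must be >= 0")
    kept = [p for p in panel.profiles if p.n_ambiguous <= max_ambiguous]
    removed = [p for p in panel.profiles if p.n_ambiguous > max_ambiguous]
    report = pd.DataFrame(
        {"sample_id": [p.sample_id for p in removed],
         "n_ambiguous": [p.n_ambiguous for p in removed]}
    )
    out = SamplePanel(kept, panel.reference, list(panel.provenance))
    out.log(f"filter_ambiguous(max={max_ambiguous}): removed {len(removed)} of {len(panel)}")
    return out, report


def restrict_segment(
    panel: SamplePanel,
    window: tuple[int, int] = HVS1_WINDOW,
    *,
    hvs1_window: tuple[int, int] = HVS1_WINDOW,
) -> SamplePanel:
    """Keep only variants inside the closed position interval ``window``.

    When the window equals the configured HVS-I window the profiles are
    relabelled ``segment="hvs1"``.
    """
    start, end = window
    if not (1 <= start <= end <= len(panel.reference)):
        raise ValueError(f"invalid window {window} for reference length {len(panel.reference)}")
    is_hvs1 = tuple(window) == tuple(hvs1_window)
    profiles = [
        replace(
            p,
            variants=frozenset(v for v in p.variants if start <= v.position <= end),
            segment="hvs1" if is_hvs1 else p.segment,
        )
        for p in panel.profiles
    ]
    out = SamplePanel(profiles, panel.reference, list(panel.provenance))
    out.log(f"restrict_segment{tuple(window)}")
    return out


# ---------------------------------------------------------------------------
# haplotype tables and metadata
# ---------------------------------------------------------------------------

def read_haplotype_table(
    path: str | Path,
    reference: ReferenceSequence,
    *,
    metadata: pd.DataFrame | None = None,
    segment: str = "hvs1",
) -> SamplePanel:
    """Read a one-sample-per-line ``id<TAB>variant-string`` table."""
    meta: dict[str, dict] = {}
    if metadata is not None:
        meta = metadata.set_index("sample_id").to_dict("index")
    profiles = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t", 1)
        sample_id = parts[0].strip()
        variants = parse_variant_string(parts[1]) if len(parts) > 1 else frozenset()
        row = meta.get(sample_id, {})
        profiles.append(
            HaplotypeProfile(
                sample_id=sample_id,
                variants=variants,
                population=str(row.get("population", "") or ""),
                country=str(row.get("country", "") or ""),
                region=str(row.get("region", "other") or "other"),
                segment=segment,
            )
        )
    return SamplePanel(profiles, reference)


def write_haplotype_table(panel: SamplePanel, path: str | Path) -> None:
    lines = [f"{p.sample_id}\t{write_variant_string(p.variants)}" for p in panel.profiles]
    Path(path).write_text("\n".join(lines) + "\n")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata table (CSV or TSV sniffed by extension)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    missing = {"sample_id", "population", "region"} - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing required columns: {sorted(missing)}")
    return df
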