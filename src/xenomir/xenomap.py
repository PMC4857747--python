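"""Cross-species miRNA catalogs, read mapping, and mapping statistics.

Dietary-xenomiR detection hinges on a sequence-level argument: reads that
match a donor-species (e.g. bovine) mature miRNA with *no* sequence homolog
in the host (human) cannot come from endogenous expression.  This module
partitions two mature-miRNA catalogs into shared / host-unique /
donor-unique sets by edit distance, maps small-RNA reads to mature
sequences with an exact, ungapped aligner, and computes the summary
statistics used downstream (mapping percentage, reads-per-million,
dominance).

The mapper is intentionally simple and fully specified: 5'-anchored
comparison, up to ``trim_3p`` bases of 3'-end length difference (mature
miRNA reads differ mostly by 3' trimming or templated extension), and at
most ``max_mismatch`` substitutions over the aligned region.  No gaps, no
genome, no precursor handling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigError, InputError

__all__ = [
    "MiRNACatalog",
    "CatalogEntry",
    "CatalogPartition",
    "MappingResult",
    "load_catalog",
    "write_catalog",
    "classify_catalog",
    "map_reads",
    "mapping_percentage",
    "rpm_normalize",
    "dominance_fraction",
    "read_fastq",
    "write_fastq",
]

_VALID = frozenset("ACGT")
MIN_MATURE_LEN = 16
MAX_MATURE_LEN = 28


def _normalize_seq(seq: str, name: str) -> str:
    s = str(seq).upper().replace("U", "T")
    if not set(s) <= _VALID:
        raise InputError(f"{name}: illegal characters in sequence {s!r}")
    if not MIN_MATURE_LEN <= len(s) <= MAX_MATURE_LEN:
        raise InputError(
            f"{name}: mature length {len(s)} outside [{MIN_MATURE_LEN}, {MAX_MATURE_LEN}]"
        )
    return s


@dataclass(frozen=True)
class CatalogEntry:
    name: str
    species: str
    sequence: str  # ACGT, U already converted


@dataclass
class MiRNACatalog:
    """Named mature miRNA sequences for one species.

    Sequences are stored DNA-alphabet (U→T), upper-case, validated to the
    mature length range.  Names must be unique within the catalog.
    """

    species: str
    entries: list[CatalogEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise InputError(f"duplicate miRNA names in {self.species} catalog: {dupes}")
        for e in self.entries:
            _normalize_seq(e.sequence, e.name)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    @property
    def sequences(self) -> dict[str, str]:
        return {e.name: e.sequence for e in self.entries}

    @classmethod
    def from_pairs(cls, species: str, pairs) -> "MiRNACatalog":
        """Build from (name, sequence) pairs; sequences may contain U."""
        entries = [CatalogEntry(n, species, _normalize_seq(s, n)) for n, s in pairs]
        return cls(species, entries)


def load_catalog(path, species: str) -> MiRNACatalog:
    """Load a mature-miRNA FASTA (names from the first header token)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"empty or unparseable FASTA: {path}")
    return MiRNACatalog.from_pairs(species, [(r.id, str(r.seq)) for r in records])


def write_catalog(catalog: MiRNACatalog, path) -> None:
    records = [
        SeqRecord(Seq(e.sequence), id=e.name, description=f"species={e.species}")
        for e in catalog
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Catalog partition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CatalogPartition:
    """Host/donor catalog split by sequence identity.

    ``shared`` holds (host name, donor name, edit distance) for every donor
    entry with a host sequence within the distance threshold (closest host
    entry; ties by name).  ``donor_unique`` entries have no host homolog at
    the threshold — reads mapping there cannot be endogenous to the host.
    """

    shared: tuple[tuple[str, str, int], ...]
    host_unique: tuple[str, ...]
    donor_unique: tuple[str, ...]


def _min_edit(seq: str, others: dict[str, str]) -> tuple[int, str | None]:
    """Closest entry in *others* by global (NW) edit distance."""
    best_d, best_name = None, None
    for name in sorted(others):
        d = edlib.align(seq, others[name], mode="NW", task="distance")["editDistance"]
        if best_d is None or d < best_d:
            best_d, best_name = d, name
            if d == 0:
                break
    return best_d, best_name


def classify_catalog(host: MiRNACatalog, donor: MiRNACatalog, max_distance: int = 0) -> CatalogPartition:
    """Partition the two catalogs into shared / host-unique / donor-unique.

    A donor miRNA is *shared* iff some host mature sequence lies within
    ``max_distance`` edits (default 0: byte-identical sequences only — the
    strict criterion under which donor-unique reads are un-fakeable by the
    host genome).  The symmetric rule defines host-unique entries.
    """
    if len(host) == 0 or len(donor) == 0:
        raise InputError("both catalogs must be non-empty")
    host_seqs = host.sequences
    donor_seqs = donor.sequences
    host_exact: dict[str, str] = {}
    for name in sorted(host_seqs):  # lexicographically first host name wins
        host_exact.setdefault(host_seqs[name], name)

    shared: list[tuple[str, str, int]] = []
    donor_unique: list[str] = []
    matched_host: set[str] = set()
    for e in donor:
        if e.sequence in host_exact:
            hname = host_exact[e.sequence]
            shared.append((hname, e.name, 0))
            matched_host.add(hname)
            continue
        if max_distance > 0:
            d, hname = _min_edit(e.sequence, host_seqs)
            if d is not None and d <= max_distance:
                shared.append((hname, e.name, d))
                matched_host.add(hname)
                continue
        donor_unique.append(e.name)

    donor_seq_set = set(donor_seqs.values())
    host_unique: list[str] = []
    for e in host:
        if e.sequence in donor_seq_set:
            continue
        if max_distance > 0:
            d, _ = _min_edit(e.sequence, donor_seqs)
            if d is not None and d <= max_distance:
                continue
        host_unique.append(e.name)
    return CatalogPartition(tuple(shared), tuple(host_unique), tuple(donor_unique))


# ---------------------------------------------------------------------------
# Read mapping
# ---------------------------------------------------------------------------

@dataclass
class MappingResult:
    """One sample's counts and mapping statistics.

    ``counts`` is indexed by catalog miRNA name; fractional values arise
    from ambiguous reads split across equally good hits of the same
    species class.  ``mapped + unmapped == total`` always holds.
    """

    counts: pd.Series
    total: int
    mapped: float
    unmapped: float
    ambiguous: int
    label: str = "sample"


def _mismatches(read: str, ref: str, limit: int) -> int | None:
    """Substitution count over the shared 5' prefix, or None if > limit."""
    m = 0
    for a, b in zip(read, ref):
        if a != b:
            m += 1
            if m > limit:
                return None
    return m


def map_reads(
    reads,
    catalog: MiRNACatalog,
    max_mismatch: int = 1,
    trim_3p: int = 2,
    label: str = "sample",
) -> MappingResult:
    """Map small-RNA reads to mature miRNA sequences.

    A read maps to a catalog entry when their lengths differ by at most
    ``trim_3p`` bases (3'-end trimming / extension tolerance) and the
    5'-anchored overlap has at most ``max_mismatch`` substitutions.  Among
    the best hits (fewest mismatches):

    * a unique best hit gets the whole read;
    * multiple best hits of the same species class share it fractionally;
    * best hits of different classes go to the lexicographically first
      name, and the ambiguity counter is incremented.

    Reads outside the mature length range [16, 28] are counted unmapped.
    *reads* may be Biopython SeqRecords or plain sequence strings.
    """
    if max_mismatch < 0 or trim_3p < 0:
        raise ConfigError("max_mismatch and trim_3p must be non-negative")
    if len(catalog) == 0:
        raise InputError("empty catalog")

    entries = sorted(catalog, key=lambda e: e.name)
    counts = pd.Series(0.0, index=[e.name for e in entries])
    total = mapped = 0.0
    ambiguous = 0
    cache: dict[str, tuple[tuple[str, ...], bool]] = {}

    def assign(seq: str) -> tuple[tuple[str, ...], bool]:
        """Best-hit names (already reduced to the share list) + ambiguity."""
        if not (MIN_MATURE_LEN <= len(seq) <= MAX_MATURE_LEN) or not set(seq) <= _VALID:
            return (), False
        best: list[CatalogEntry] = []
        best_m = None
        for e in entries:
            if abs(len(seq) - len(e.sequence)) > trim_3p:
                continue
            m = _mismatches(seq, e.sequence, max_mismatch)
            if m is None:
                continue
            if best_m is None or m < best_m:
                best, best_m = [e], m
            elif m == best_m:
                best.append(e)
        if not best:
            return (), False
        if len(best) == 1:
            return (best[0].name,), False
        classes = {e.species for e in best}
        if len(classes) == 1:
            return tuple(e.name for e in best), False  # fractional split
        return (best[0].name,), True  # cross-class tie: first name, flag it

    for rec in reads:
        seq = str(rec.seq) if hasattr(rec, "seq") else str(rec)
        seq = seq.upper().replace("U", "T")
        total += 1
        if seq not in cache:
            cache[seq] = assign(seq)
        names, ambig = cache[seq]
        if ambig:
            ambiguous += 1
        if names:
            share = 1.0 / len(names)
            for n in names:
                counts[n] += share
            mapped += 1
    return MappingResult(
        counts=counts,
        total=int(total),
        mapped=float(mapped),
        unmapped=float(total - mapped),
        ambiguous=ambiguous,
        label=label,
    )


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def mapping_percentage(mapped: float, total: float | None = None) -> float:
    """Percent of reads mapped, to one decimal place.

    Accepts either a :class:`MappingResult` or explicit (mapped, total).
    """
    if isinstance(mapped, MappingResult):
        result = mapped
        mapped, total = result.mapped, result.total
    if total is None:
        raise ConfigError("total read count required")
    if total <= 0:
        raise InputError("mapping percentage undefined for zero total reads")
    return round(100.0 * mapped / total, 1)


def rpm_normalize(counts: pd.Series) -> pd.Series:
    """Reads-per-million-mapped normalization of one count column."""
    s = pd.Series(counts, dtype=float)
    tot = s.sum()
    if tot <= 0:
        raise InputError("rpm normalization undefined with zero mapped reads")
    return s * 1e6 / tot


def dominance_fraction(counts: pd.Series) -> tuple[str, float, bool]:
    """The most abundant miRNA and its share of mapped reads.

    Returns ``(name, fraction, tied)``; on a tie the lexicographically
    first name is reported and ``tied`` is True.
    """
    s = pd.Series(counts, dtype=float)
    tot = s.sum()
    if tot <= 0:
        raise InputError("dominance undefined with zero mapped reads")
    top = s.max()
    winners = sorted(s.index[s == top])
    return winners[0], float(top / tot), len(winners) > 1


# ---------------------------------------------------------------------------
# FASTQ I/O (Sanger Phred+33)
# ---------------------------------------------------------------------------

def read_fastq(path) -> list[SeqRecord]:
    return list(SeqIO.parse(str(path), "fastq"))


def write_fastq(records, path) -> None:
    SeqIO.write(records, str(path), "fastq")
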