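"""Small-RNA read cleaning and collapsing.

Raw adapter-ligated small-RNA reads are screened through the "impurity"
rules used for egg small-RNA libraries: 3' (and optionally 5') adapter
trimming, a low-resolution screen (N-containing or low-quality reads),
junk-sequence rules (mono-base dominance, N content, two-letter alphabets),
a 15-26 nt size window and a minimum copy number of 3, plus an optional
user-supplied exclusion database (e.g. mRNA/rRNA/repeat sequences).
Surviving reads are collapsed to unique tags carrying copy numbers.

Every input read lands in exactly one rejection category or survives, and
the :class:`FilterReport` reconciles the accounting exactly.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

__all__ = [
    "SmallRNARead",
    "UniqueTag",
    "FilterReport",
    "trim_adapter",
    "is_junk",
    "collapse_reads",
    "apply_filters",
    "length_histogram",
    "run_filter_pipeline",
    "read_fastx",
    "write_tag_fasta",
    "read_tag_fasta",
]

VALID = set("ACGTN")

# default minimum adapter overlap and mismatch tolerance
MIN_OVERLAP = 6
ADAPTER_MAX_MISMATCH = 1


@dataclass(frozen=True)
class SmallRNARead:
    """One raw sequencing read (sequence over A/C/G/T/N, optional Phred scores)."""

    read_id: str
    sequence: str
    quality: Optional[Sequence[int]] = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty read sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError("quality length differs from sequence length")


@dataclass(frozen=True)
class UniqueTag:
    """A distinct trimmed insert with the number of identical reads."""

    sequence: str
    copy_number: int

    def __post_init__(self):
        if self.copy_number < 1:
            raise ValueError("copy_number must be >= 1")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class FilterReport:
    """Per-category read accounting for one filtering run.

    Category counts are copy-number weighted reads; ``surviving_reads`` plus
    all categories equals ``input_reads`` exactly.
    """

    input_reads: int = 0
    adapter_only: int = 0
    low_resolution: int = 0
    junk: int = 0
    length: int = 0
    copy_number: int = 0
    exclusion_db: int = 0
    invalid: int = 0
    surviving_reads: int = 0
    surviving_tags: int = 0
    notes: list = field(default_factory=list)

    CATEGORIES = (
        "adapter_only", "low_resolution", "junk", "length",
        "copy_number", "exclusion_db", "invalid",
    )

    def rejected_total(self) -> int:
        return sum(getattr(self, c) for c in self.CATEGORIES)

    def is_balanced(self) -> bool:
        return self.input_reads == self.rejected_total() + self.surviving_reads

    def to_dict(self) -> dict:
        d = {c: getattr(self, c) for c in self.CATEGORIES}
        d.update(
            input_reads=self.input_reads,
            surviving_reads=self.surviving_reads,
            surviving_tags=self.surviving_tags,
        )
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_tsv(self) -> str:
        lines = ["category\treads"]
        for c in self.CATEGORIES:
            lines.append(f"{c}\t{getattr(self, c)}")
        lines.append(f"surviving\t{self.surviving_reads}")
        lines.append(f"total\t{self.input_reads}")
        lines.append(f"surviving_tags\t{self.surviving_tags}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Per-read operations
# ---------------------------------------------------------------------------

def _match_with_mismatches(text: str, pattern: str, start: int, max_mm: int) -> bool:
    mm = 0
    for k, p in enumerate(pattern):
        if text[start + k] != p:
            mm += 1
            if mm > max_mm:
                return False
    return True


def trim_adapter(
    read: SmallRNARead,
    adapter3: str,
    adapter5: Optional[str] = None,
    min_overlap: int = MIN_OVERLAP,
    max_mismatch: int = ADAPTER_MAX_MISMATCH,
) -> str:
    """Remove the 3' (and optionally 5') adapter from a read.

    The 3' adapter is located as the longest suffix of the read matching a
    prefix of ``adapter3`` with at least ``min_overlap`` bases and at most
    ``max_mismatch`` mismatches; everything from the match on is removed.
    A 5' adapter, when given, is trimmed symmetrically from the front.
    An empty return value signals an adapter dimer (no insert).

    Raises ``ValueError`` for non-ACGTN characters in the read.
    """
    if not adapter3:
        raise ValueError("adapter3 must be non-empty")
    seq = read.sequence.upper()
    bad = set(seq) - VALID
    if bad:
        raise ValueError(f"read {read.read_id}: non-ACGTN characters {sorted(bad)}")
    n = len(seq)
    insert_end = n
    # earliest (longest-removal) suffix position whose overlap with adapter3
    # is >= min_overlap and has <= max_mismatch mismatches
    for start in range(0, n - min_overlap + 1):
        overlap = min(n - start, len(adapter3))
        if overlap < min_overlap:
            break
        if _match_with_mismatches(seq, adapter3[:overlap], start, max_mismatch):
            insert_end = start
            break
    insert = seq[:insert_end]
    if adapter5:
        # prefix-anchored: longest suffix of adapter5 matching the read start
        for length in range(min(len(adapter5), len(insert)), min_overlap - 1, -1):
            if _match_with_mismatches(insert, adapter5[-length:], 0, max_mismatch):
                insert = insert[length:]
                break
    return insert


def is_junk(sequence: str) -> tuple[bool, str]:
    """Apply the junk-sequence rules; returns (verdict, first triggered rule).

    Rules, in order: any single base >= 80% of the length; >= 3 N characters;
    alphabet a subset of {A, C}; alphabet a subset of {G, T}.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    counts = Counter(seq)
    n = len(seq)
    for base in "ACGT":
        if counts.get(base, 0) >= 0.8 * n:
            return True, f"single-base>=80% ({base})"
    if counts.get("N", 0) >= 3:
        return True, ">=3 Ns"
    alphabet = set(seq)
    if alphabet <= {"A", "C"}:
        return True, "only A,C"
    if alphabet <= {"G", "T"}:
        return True, "only G,T"
    return False, ""


def collapse_reads(inserts: Iterable[str]) -> list[UniqueTag]:
    """Collapse trimmed inserts into unique tags with copy numbers.

    The sum of copy numbers equals the number of input inserts; output order
    is deterministic (descending copy number, then sequence).
    """
    counts = Counter(inserts)
    return [
        UniqueTag(seq, c)
        for seq, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def _hits_exclusion_db(seq: str, db: Sequence[str]) -> bool:
    # exact full-length or substring containment in any database sequence
    return any(seq in entry for entry in db)


def apply_filters(
    tags: Iterable[UniqueTag],
    min_copy: int = 3,
    min_len: int = 15,
    max_len: int = 26,
    exclusion_db: Optional[Sequence[str]] = None,
    report: Optional[FilterReport] = None,
) -> tuple[list[UniqueTag], FilterReport]:
    """Apply junk, length, copy-number and exclusion-database screens to tags.

    Order (documented, fixed): junk and length rules first, copy number
    second (so borderline tags cannot be rescued by junk reads), exclusion
    database last.  Counts in the report are read-weighted.
    """
    if min_len > max_len:
        raise ValueError("min_len > max_len")
    report = report or FilterReport()
    db = [s.upper() for s in exclusion_db] if exclusion_db else []
    survivors: list[UniqueTag] = []
    tags = list(tags)
    if report.input_reads == 0:
        report.input_reads = sum(t.copy_number for t in tags)
    for tag in tags:
        junk, _ = is_junk(tag.sequence)
        if junk:
            report.junk += tag.copy_number
        elif not (min_len <= len(tag) <= max_len):
            report.length += tag.copy_number
        elif tag.copy_number < min_copy:
            report.copy_number += tag.copy_number
        elif db and _hits_exclusion_db(tag.sequence, db):
            report.exclusion_db += tag.copy_number
        else:
            survivors.append(tag)
    report.surviving_reads = sum(t.copy_number for t in survivors)
    report.surviving_tags = len(survivors)
    return survivors, report


def length_histogram(tags: Iterable[UniqueTag]) -> dict[int, tuple[int, float]]:
    """Copy-number-weighted read counts and fractions per insert length."""
    counts: Counter = Counter()
    for t in tags:
        counts[len(t)] += t.copy_number
    total = sum(counts.values())
    if total == 0:
        return {}
    return {L: (c, c / total) for L, c in sorted(counts.items())}


# ---------------------------------------------------------------------------
# Whole-pipeline convenience
# ---------------------------------------------------------------------------

def run_filter_pipeline(
    reads: Iterable[SmallRNARead],
    adapter3: str,
    adapter5: Optional[str] = None,
    min_copy: int = 3,
    min_len: int = 15,
    max_len: int = 26,
    min_mean_quality: float = 20.0,
    exclusion_db: Optional[Sequence[str]] = None,
) -> tuple[list[UniqueTag], FilterReport]:
    """Clean raw reads end to end: trim, screen, collapse, filter.

    Per-read stages (adapter trimming, low-resolution screen) run first;
    tag-level stages run via :func:`apply_filters`.  "Low resolution" reads
    are those containing any N before trimming or with mean Phred quality
    below ``min_mean_quality`` when qualities are present.
    """
    report = FilterReport()
    inserts: list[str] = []
    for read in reads:
        report.input_reads += 1
        try:
            insert = trim_adapter(read, adapter3, adapter5)
        except ValueError as exc:
            report.invalid += 1
            if len(report.notes) < 10:
                report.notes.append(str(exc))
            continue
        if not insert:
            report.adapter_only += 1
            continue
        if "N" in read.sequence.upper() or (
            read.quality is not None
            and sum(read.quality) / len(read.quality) < min_mean_quality
        ):
            report.low_resolution += 1
            continue
        inserts.append(insert)
    tags = collapse_reads(inserts)
    return apply_filters(
        tags, min_copy=min_copy, min_len=min_len, max_len=max_len,
        exclusion_db=exclusion_db, report=report,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fastx(path) -> list[SmallRNARead]:
    """Load reads from FASTQ (Phred+33) or FASTA, sniffing the format."""
    path = str(path)
    with open(path) as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    reads = []
    for rec in SeqIO.parse(path, fmt):
        qual = rec.letter_annotations.get("phred_quality")
        reads.append(SmallRNARead(rec.id, str(rec.seq).upper(), qual))
    return reads


def write_tag_fasta(tags: Sequence[UniqueTag], path) -> None:
    """Write collapsed tags in the ``tag{serial}_x{copies}`` FASTA dialect."""
    with open(path, "w") as fh:
        for i, tag in enumerate(tags, start=1):
            fh.write(f">tag{i}_x{tag.copy_number}\n{tag.sequence}\n")


def read_tag_fasta(path) -> list[UniqueTag]:
    """Read a collapsed-tag FASTA (``..._x{copies}`` headers; default copy 1)."""
    tags = []
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        copies = 1
        if "_x" in name:
            try:
                copies = int(name.rsplit("_x", 1)[1])
            except ValueError:
                pass
        tags.append(UniqueTag(str(rec.seq).upper(), copies))
    return tags
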