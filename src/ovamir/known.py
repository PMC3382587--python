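"""Assignment of unique tags to known mature miRNAs and family profiling.

Tags are matched to a mature miRNA reference (miRBase-style FASTA, U
normalized to T) by ungapped alignment allowing at most one substitution
and up to +/-3 nt of terminal offset, the deterministic counterpart of the
BLAST screen used for short miRNA reads (at these lengths the E-value
criterion is redundant with the mismatch cap).  Assignments are pooled into
miRNA families by stripping species prefixes, arm suffixes and paralog
letters, and family abundances are reported as copy-number-weighted read
fractions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

from .filtering import UniqueTag

__all__ = [
    "MatureMiRNA",
    "MiRNAAssignment",
    "FamilyAbundance",
    "family_name",
    "match_known",
    "summarize_families",
    "read_mature_fasta",
]

log = logging.getLogger(__name__)

MAX_TERMINAL_OFFSET = 3


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA reference entry (DNA-normalized sequence)."""

    name: str
    sequence: str

    def __post_init__(self):
        if not (15 <= len(self.sequence) <= 30):
            raise ValueError(f"{self.name}: mature length {len(self.sequence)} outside 15-30")

    @property
    def family(self) -> str:
        return family_name(self.name)


@dataclass(frozen=True)
class MiRNAAssignment:
    """A tag assigned to a mature miRNA (ungapped, <=1 substitution)."""

    tag: UniqueTag
    mature: str
    family: str
    mismatches: int
    offset: int  # alignment start of the tag on the mature (may be negative)


@dataclass(frozen=True)
class FamilyAbundance:
    family: str
    read_count: int
    fraction: float


_SPECIES_PREFIX = re.compile(r"^[a-z]{3,4}-")
_ARM_SUFFIX = re.compile(r"-(5p|3p)$", re.IGNORECASE)
_PARALOG_COPY = re.compile(r"-\d+$")
_PARALOG_LETTER = re.compile(r"(?<=\d)[a-z]+$")


def family_name(mature_name: str, mapping: Optional[dict] = None) -> str:
    """Derive a family name from a mature miRNA name.

    Strips the leading species code (``omy-``, ``dre-`` ...), a trailing
    ``-5p``/``-3p`` arm suffix, a trailing numeric paralog copy (``-1``) and
    trailing paralog letters (``let-7a`` -> ``let-7``).  An explicit
    ``mapping`` (name -> family) overrides the rule.
    """
    if mapping and mature_name in mapping:
        return mapping[mature_name]
    name = mature_name
    m = _SPECIES_PREFIX.match(name)
    # species codes are 3-4 lowercase letters, but family stems like
    # "let-"/"lin-"/"mir-" must survive ("let-7" is already a family name)
    if m and m.group(0)[:-1] not in {"let", "lin", "mir", "miR", "ban"}:
        name = name[m.end():]
    name = _ARM_SUFFIX.sub("", name)
    # trailing "-N" is a paralog copy only when a number remains (miR-24-1
    # -> miR-24) -- never the family number itself (miR-24 stays miR-24)
    stripped = _PARALOG_COPY.sub("", name)
    if stripped != name and any(c.isdigit() for c in stripped):
        name = stripped
    name = _PARALOG_LETTER.sub("", name)
    return name


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _best_ungapped(
    tag_seq: str, mature_seq: str, max_offset: int,
    mm_cap: Optional[int] = None,
) -> Optional[tuple[int, int]]:
    """Best (mismatches, offset) of an ungapped tag-on-mature alignment.

    ``offset`` is where the tag's first base sits on the mature; offsets are
    limited so that no more than ``max_offset`` tag bases overhang either
    end of the mature.  Overhanging bases do not count as mismatches (they
    are isomiR end variation) but are limited by the offset budget.
    Returns None when no admissible offset exists.
    """
    lt, lm = len(tag_seq), len(mature_seq)
    best: Optional[tuple[int, int]] = None
    for off in range(-max_offset, lm - lt + max_offset + 1):
        left_overhang = max(0, -off)
        right_overhang = max(0, off + lt - lm)
        if left_overhang > max_offset or right_overhang > max_offset:
            continue
        mm = 0
        for i in range(left_overhang, lt - right_overhang):
            if tag_seq[i] != mature_seq[off + i]:
                mm += 1
                if mm_cap is not None and mm > mm_cap:
                    break
        if mm_cap is not None and mm > mm_cap:
            continue
        cand = (mm, off)
        if best is None or (cand[0], abs(cand[1])) < (best[0], abs(best[1])):
            best = cand
    return best


def match_known(
    tags: Iterable[UniqueTag],
    db: Sequence[MatureMiRNA],
    max_mismatch: int = 1,
    max_offset: int = MAX_TERMINAL_OFFSET,
    family_mapping: Optional[dict] = None,
) -> tuple[list[MiRNAAssignment], list[UniqueTag]]:
    """Assign each tag to its closest mature miRNA, or leave it unmatched.

    The best database entry is chosen by (fewest mismatches, smallest
    absolute offset, lexicographic mature name).  Tags with no ungapped
    alignment at <= ``max_mismatch`` substitutions are returned unmatched.
    """
    db = list(db)
    if not db:
        log.warning("empty mature miRNA database: all tags unmatched")
        return [], list(tags)
    norm_db = [(m, _normalize(m.sequence)) for m in db]
    assignments: list[MiRNAAssignment] = []
    unmatched: list[UniqueTag] = []
    for tag in tags:
        tseq = _normalize(tag.sequence)
        best_key = None
        best_hit = None
        for mature, mseq in norm_db:
            res = _best_ungapped(tseq, mseq, max_offset, mm_cap=max_mismatch)
            if res is None:
                continue
            mm, off = res
            if mm > max_mismatch:
                continue
            key = (mm, abs(off), mature.name)
            if best_key is None or key < best_key:
                best_key = key
                best_hit = (mature, mm, off)
        if best_hit is None:
            unmatched.append(tag)
        else:
            mature, mm, off = best_hit
            assignments.append(
                MiRNAAssignment(
                    tag=tag,
                    mature=mature.name,
                    family=family_name(mature.name, family_mapping),
                    mismatches=mm,
                    offset=off,
                )
            )
    return assignments, unmatched


def summarize_families(assignments: Sequence[MiRNAAssignment]) -> list[FamilyAbundance]:
    """Rank miRNA families by copy-number-weighted read counts.

    Fractions are relative to all assigned reads and sum to 1; ties in
    read count rank lexicographically.
    """
    counts: dict[str, int] = {}
    for a in assignments:
        counts[a.family] = counts.get(a.family, 0) + a.tag.copy_number
    total = sum(counts.values())
    if total == 0:
        return []
    return [
        FamilyAbundance(fam, c, c / total)
        for fam, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def top_k_fraction(families: Sequence[FamilyAbundance], k: int = 10) -> float:
    """Cumulative read fraction of the ``k`` most abundant families."""
    return sum(f.fraction for f in families[:k])


def read_mature_fasta(path) -> list[MatureMiRNA]:
    """Load a mature miRNA FASTA (miRBase dialect; U allowed)."""
    return [
        MatureMiRNA(rec.id, _normalize(str(rec.seq)))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_assignments_tsv(assignments: Sequence[MiRNAAssignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("tag\tmature\tfamily\tmismatches\toffset\tcopies\n")
        for a in assignments:
            fh.write(
                f"{a.tag.sequence}\t{a.mature}\t{a.family}\t"
                f"{a.mismatches}\t{a.offset}\t{a.tag.copy_number}\n"
            )


def write_families_tsv(families: Sequence[FamilyAbundance], path) -> None:
    with open(path, "w") as fh:
        fh.write("family\treads\tfraction\n")
        for f in families:
            fh.write(f"{f.family}\t{f.read_count}\t{f.fraction:.6f}\n")
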