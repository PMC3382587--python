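"""Novel miRNA prediction from unmatched tags.

Tags that match no known mature miRNA are mapped to a reference genome
(both strands), the hit is extended 60 nt in both directions, the extended
sequence is folded (:mod:`ovamir.folding`), and the fold is screened with
pre-miRNA hairpin criteria: the mature tag must sit on one arm of a single
dominant stem-loop with most of its bases paired across the loop, and the
precursor fold must be stable.  Survivors are named ``nov{serial}-5p/3p``
by the arm the mature occupies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

from .filtering import UniqueTag
from .folding import SecondaryStructure, fold_rna

__all__ = [
    "GenomeLocus",
    "HairpinCriteria",
    "PrecursorCandidate",
    "map_tag_to_genome",
    "extract_precursor",
    "call_hairpin",
    "predict_novel",
    "read_genome_fasta",
]

DEFAULT_FLANK = 60


@dataclass(frozen=True)
class GenomeLocus:
    """A 0-based half-open interval on a genome strand."""

    chrom: str
    start: int
    end: int
    strand: str  # '+' or '-'

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        if not (0 <= self.start < self.end):
            raise ValueError("invalid locus coordinates")


@dataclass(frozen=True)
class HairpinCriteria:
    """Thresholds for calling a folded precursor a pre-miRNA hairpin."""

    # 18/22 mature bases paired: near-perfect-stem regime; lower (e.g. 14)
    # admits many dinucleotide-shuffle decoys of stem-rich precursors
    min_mature_paired: int = 18
    min_loop: int = 3
    max_loop: int = 20
    energy_max: float = -18.0  # kcal/mol under the package energy model


@dataclass
class PrecursorCandidate:
    """A tag, its genomic locus and the folded +/-60 nt extension."""

    tag: UniqueTag
    locus: GenomeLocus
    precursor_seq: str
    mature_offset: int  # tag start within the precursor
    structure: Optional[SecondaryStructure] = None
    hairpin: bool = False
    scores: dict = field(default_factory=dict)
    name: str = ""


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def map_tag_to_genome(
    tag: UniqueTag,
    genome: dict[str, str],
    max_mismatch: int = 0,
) -> list[GenomeLocus]:
    """All loci (both strands) where the tag aligns with <= max_mismatch
    substitutions, in deterministic (chrom, start, strand) order."""
    t = tag.sequence.upper()
    rc = _revcomp(t)
    hits: list[GenomeLocus] = []
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        for query, strand in ((t, "+"), (rc, "-")):
            if max_mismatch == 0:
                pos = seq.find(query)
                while pos != -1:
                    hits.append(GenomeLocus(chrom, pos, pos + len(query), strand))
                    pos = seq.find(query, pos + 1)
            else:
                m = len(query)
                for pos in range(0, len(seq) - m + 1):
                    mm = 0
                    for k in range(m):
                        if seq[pos + k] != query[k]:
                            mm += 1
                            if mm > max_mismatch:
                                break
                    else:
                        hits.append(GenomeLocus(chrom, pos, pos + m, strand))
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits


def extract_precursor(
    locus: GenomeLocus,
    genome: dict[str, str],
    tag: UniqueTag,
    flank: int = DEFAULT_FLANK,
) -> PrecursorCandidate:
    """Extend a mapped tag ``flank`` nt both directions on its strand.

    Flanks are truncated at chromosome boundaries; on the minus strand the
    precursor is the reverse complement of the genomic window and the
    mature offset is measured from the precursor 5' end.
    """
    chrom_seq = genome[locus.chrom]
    if locus.end > len(chrom_seq):
        raise ValueError("locus outside chromosome")
    lo = max(0, locus.start - flank)
    hi = min(len(chrom_seq), locus.end + flank)
    window = chrom_seq[lo:hi].upper()
    if locus.strand == "+":
        offset = locus.start - lo
    else:
        window = _revcomp(window)
        offset = hi - locus.end
    return PrecursorCandidate(tag=tag, locus=locus, precursor_seq=window, mature_offset=offset)


def _hairpin_loops(pairs: dict, n: int) -> list[tuple[int, int]]:
    """Hairpin loops as (loop_start, loop_end) half-open unpaired intervals
    directly closed by a pair with nothing paired inside."""
    loops = []
    for i, j in pairs.items():
        if i < j and all(k not in pairs for k in range(i + 1, j)):
            loops.append((i + 1, j))
    loops.sort()
    return loops


def _stem_size(pairs: dict, loop: tuple[int, int], loops: Sequence[tuple[int, int]]) -> int:
    """Number of pairs enclosing ``loop`` and no other hairpin loop."""
    count = 0
    for i, j in pairs.items():
        if i < j and i < loop[0] and j >= loop[1]:
            if not any(lo != loop and i < lo[0] and j >= lo[1] for lo in loops):
                count += 1
    return count


def call_hairpin(
    candidate: PrecursorCandidate,
    criteria: HairpinCriteria = HairpinCriteria(),
) -> bool:
    """Decide whether a folded precursor candidate is a pre-miRNA hairpin.

    Criteria (all thresholds configurable via :class:`HairpinCriteria`):

    * at least ``min_mature_paired`` mature bases pair across one common
      hairpin loop (a single consistent stem);
    * the mature does not overlap that loop (it lies entirely on one arm);
    * the loop is ``min_loop``-``max_loop`` nt;
    * that stem is dominant: no other loop's exclusive stem holds more pairs;
    * the fold energy is at most ``energy_max``.

    Per-criterion scores are stored in ``candidate.scores`` and the verdict
    in ``candidate.hairpin``.
    """
    if candidate.structure is None:
        candidate.structure = fold_rna(candidate.precursor_seq)
    st = candidate.structure
    pairs = st.pairs
    n = len(candidate.precursor_seq)
    m0 = candidate.mature_offset
    m1 = m0 + len(candidate.tag.sequence)
    loops = _hairpin_loops(pairs, n)
    scores = {
        "energy": st.energy,
        "n_loops": len(loops),
        "mature_paired": 0,
        "loop_len": None,
        "arm": None,
        "dominant": False,
    }
    verdict = False
    if loops and st.energy <= criteria.energy_max:
        # count mature pairs spanning each hairpin loop; pick the best loop
        best_loop = None
        best_count = 0
        for loop in loops:
            cnt = 0
            for i in range(m0, m1):
                j = pairs.get(i)
                if j is None:
                    continue
                a, b = min(i, j), max(i, j)
                if a < loop[0] and b >= loop[1]:
                    cnt += 1
            if cnt > best_count:
                best_count = cnt
                best_loop = loop
        scores["mature_paired"] = best_count
        if best_loop is not None:
            loop_len = best_loop[1] - best_loop[0]
            scores["loop_len"] = loop_len
            on_arm = m1 <= best_loop[0] or m0 >= best_loop[1]
            scores["arm"] = "5p" if m1 <= best_loop[0] else ("3p" if m0 >= best_loop[1] else None)
            stem = _stem_size(pairs, best_loop, loops)
            dominant = all(
                _stem_size(pairs, lo, loops) <= stem for lo in loops if lo != best_loop
            )
            scores["dominant"] = dominant
            verdict = (
                best_count >= criteria.min_mature_paired
                and on_arm
                and criteria.min_loop <= loop_len <= criteria.max_loop
                and dominant
            )
    candidate.scores = scores
    candidate.hairpin = verdict
    return verdict


def predict_novel(
    tags: Iterable[UniqueTag],
    genome: dict[str, str],
    flank: int = DEFAULT_FLANK,
    criteria: HairpinCriteria = HairpinCriteria(),
    max_mismatch: int = 0,
    name_prefix: str = "nov",
) -> list[PrecursorCandidate]:
    """Predict novel miRNA precursors from unmatched tags.

    One candidate per (tag, locus) passing :func:`call_hairpin`; candidates
    with identical precursor sequences (repeated genome regions) are
    collapsed.  Survivors are named ``{prefix}{serial}-5p/3p`` by arm.
    """
    results: list[PrecursorCandidate] = []
    seen: set[str] = set()
    serial = 0
    for tag in tags:
        for locus in map_tag_to_genome(tag, genome, max_mismatch=max_mismatch):
            cand = extract_precursor(locus, genome, tag, flank=flank)
            if cand.precursor_seq in seen:
                continue
            if call_hairpin(cand, criteria):
                seen.add(cand.precursor_seq)
                serial += 1
                arm = cand.scores.get("arm") or "5p"
                cand.name = f"{name_prefix}{serial}-{arm}"
                results.append(cand)
    return results


def read_genome_fasta(path) -> dict[str, str]:
    """Load a genome FASTA as a chrom -> sequence dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_candidates_tsv(candidates: Sequence[PrecursorCandidate], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "name\ttag\tcopies\tchrom\tstart\tend\tstrand\t"
            "precursor\tdot_bracket\tenergy\thairpin\n"
        )
        for c in candidates:
            db = c.structure.dot_bracket if c.structure else ""
            en = f"{c.structure.energy:.2f}" if c.structure else ""
            fh.write(
                f"{c.name}\t{c.tag.sequence}\t{c.tag.copy_number}\t"
                f"{c.locus.chrom}\t{c.locus.start}\t{c.locus.end}\t{c.locus.strand}\t"
                f"{c.precursor_seq}\t{db}\t{en}\t{int(c.hairpin)}\n"
            )
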