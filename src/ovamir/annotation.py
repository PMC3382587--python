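"""Approximate 5'UTR / CDS / 3'UTR partitioning of transcript cDNAs.

Transcripts without genome annotation are partitioned by translated
homology: a six-frame, ungapped, seeded extension search of each cDNA
against a protein reference (BLOSUM62 scoring, exact 6-residue seed words,
windowed-entropy low-complexity masking, ungapped Karlin-Altschul
E-values).  The best homolog (longest aligned region) defines the
approximate coding region; the 5'UTR is taken as the 60 nt upstream of the
5' end of the match (5'UTRs typically run 60-90 nt), and the 3'UTR runs
from the 3' end of the match to the end of the cDNA.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

from Bio import SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

__all__ = [
    "HomologyMatch",
    "GeneModel",
    "translated_search",
    "select_homolog",
    "partition_transcript",
    "annotate_transcripts",
    "read_protein_fasta",
]

log = logging.getLogger(__name__)

BLOSUM62 = substitution_matrices.load("BLOSUM62")

# ungapped Karlin-Altschul parameters for BLOSUM62
KA_LAMBDA = 0.3176
KA_K = 0.134

UTR5_CUT = 60
XDROP = 20.0

ENTROPY_WINDOW = 12
ENTROPY_THRESHOLD = 2.2  # bits


@dataclass(frozen=True)
class HomologyMatch:
    """An ungapped translated match of a cDNA against a reference protein."""

    transcript_id: str
    protein_id: str
    frame: int  # 1..3 forward, -1..-3 reverse
    nt_start: int  # 0-based half-open on the cDNA (forward coordinates)
    nt_end: int
    score: float  # bit score
    evalue: float
    shorter_coverage: float
    aligned_aa: int

    @property
    def aligned_nt(self) -> int:
        return self.nt_end - self.nt_start


@dataclass(frozen=True)
class GeneModel:
    """A cDNA partitioned into approximate 5'UTR, CDS and 3'UTR intervals."""

    transcript_id: str
    cdna: str
    five_utr: tuple[int, int]
    cds: tuple[int, int]
    three_utr: tuple[int, int]
    reverse: bool = False  # match was on the reverse frames

    def region_seq(self, region: str) -> str:
        lo, hi = {"5UTR": self.five_utr, "CDS": self.cds, "3UTR": self.three_utr}[region]
        return self.cdna[lo:hi]


def _score(a: str, b: str) -> float:
    try:
        return float(BLOSUM62[a, b])
    except (KeyError, IndexError):
        return -4.0


def mask_low_complexity(protein: str, window: int = ENTROPY_WINDOW,
                        threshold: float = ENTROPY_THRESHOLD) -> str:
    """Mask (with ``X``) residues inside low-entropy windows of a query."""
    n = len(protein)
    if n < window:
        return protein
    masked = list(protein)
    flagged = [False] * n
    for i in range(0, n - window + 1):
        seg = protein[i:i + window]
        counts: dict[str, int] = {}
        for c in seg:
            counts[c] = counts.get(c, 0) + 1
        ent = -sum((v / window) * math.log2(v / window) for v in counts.values())
        if ent < threshold:
            for k in range(i, i + window):
                flagged[k] = True
    for i, f in enumerate(flagged):
        if f:
            masked[i] = "X"
    return "".join(masked)


def _frames(cdna: str):
    """Yield (frame, aa string) for all six reading frames."""
    seq = cdna.upper()
    rc = str(Seq(seq).reverse_complement())
    for f in (1, 2, 3):
        sub = seq[f - 1:]
        sub = sub[: len(sub) - len(sub) % 3]
        yield f, str(Seq(sub).translate()) if sub else ""
    for f in (1, 2, 3):
        sub = rc[f - 1:]
        sub = sub[: len(sub) - len(sub) % 3]
        yield -f, str(Seq(sub).translate()) if sub else ""


def _extend(query: str, subject: str, qpos: int, spos: int, word: int,
            xdrop: float = XDROP) -> tuple[int, int, float]:
    """Ungapped X-drop extension of a seeded word; returns (qstart, alen, score)."""
    score = sum(_score(query[qpos + k], subject[spos + k]) for k in range(word))
    # extend right
    best = score
    cur = score
    qr, sr = qpos + word, spos + word
    best_r = 0
    k = 0
    while qr + k < len(query) and sr + k < len(subject):
        cur += _score(query[qr + k], subject[sr + k])
        k += 1
        if cur > best:
            best = cur
            best_r = k
        elif best - cur > xdrop:
            break
    # extend left
    cur = best
    best_l = 0
    k = 0
    while qpos - k - 1 >= 0 and spos - k - 1 >= 0:
        cur += _score(query[qpos - k - 1], subject[spos - k - 1])
        k += 1
        if cur > best:
            best = cur
            best_l = k
        elif best - cur > xdrop:
            break
    qstart = qpos - best_l
    alen = best_l + word + best_r
    return qstart, alen, best


def translated_search(
    transcript_id: str,
    cdna: str,
    proteins: dict[str, str],
    word_size: int = 6,
    evalue_max: float = 10.0,
    min_shorter_coverage: float = 0.60,
) -> list[HomologyMatch]:
    """Six-frame ungapped homology search of a cDNA against a protein set.

    Seeds on exact ``word_size``-residue words (after masking low-complexity
    query segments), extends without gaps under BLOSUM62 with an X-drop, and
    reports matches with ``evalue <= evalue_max`` whose aligned length
    covers at least ``min_shorter_coverage`` of the shorter of the two
    sequences (translated query frame vs protein).
    """
    if not proteins:
        raise ValueError("empty protein reference")
    if len(cdna) < 3 * word_size:
        log.warning("%s: cDNA shorter than 3*word_size, skipping", transcript_id)
        return []
    # seed index over the database
    index: dict[str, list[tuple[str, int]]] = {}
    for pid, pseq in proteins.items():
        for i in range(0, len(pseq) - word_size + 1):
            index.setdefault(pseq[i:i + word_size], []).append((pid, i))
    db_len = sum(len(p) for p in proteins.values())
    matches: list[HomologyMatch] = []
    n = len(cdna)
    for frame, aa in _frames(cdna):
        if len(aa) < word_size:
            continue
        query = mask_low_complexity(aa)
        best_by_hit: dict[tuple[str, int], tuple[int, int, float]] = {}
        for q in range(0, len(query) - word_size + 1):
            word = query[q:q + word_size]
            if "X" in word or "*" in word:
                continue
            for pid, s in index.get(word, ()):
                diag = q - s
                qstart, alen, raw = _extend(aa, proteins[pid], q, s, word_size)
                key = (pid, diag)
                if key not in best_by_hit or raw > best_by_hit[key][2]:
                    best_by_hit[key] = (qstart, alen, raw)
        for (pid, diag), (qstart, alen, raw) in best_by_hit.items():
            cov = alen / min(len(aa), len(proteins[pid]))
            evalue = KA_K * len(aa) * db_len * math.exp(-KA_LAMBDA * raw)
            if evalue > evalue_max or cov < min_shorter_coverage:
                continue
            if frame > 0:
                nt_start = (frame - 1) + 3 * qstart
                nt_end = nt_start + 3 * alen
            else:
                rc_start = (-frame - 1) + 3 * qstart
                nt_end = n - rc_start
                nt_start = nt_end - 3 * alen
            bits = (KA_LAMBDA * raw - math.log(KA_K)) / math.log(2)
            matches.append(
                HomologyMatch(
                    transcript_id=transcript_id, protein_id=pid, frame=frame,
                    nt_start=nt_start, nt_end=nt_end, score=round(bits, 2),
                    evalue=evalue, shorter_coverage=cov, aligned_aa=alen,
                )
            )
    matches.sort(key=lambda m: (-m.aligned_aa, -m.score, m.evalue, m.protein_id))
    return matches


def select_homolog(matches: Sequence[HomologyMatch]) -> Optional[HomologyMatch]:
    """The homolog with the maximal aligned region.

    Ties break by higher score, then lower E-value, then lexicographic
    protein id.  Returns None for an empty match list.
    """
    if not matches:
        return None
    return min(
        matches,
        key=lambda m: (-m.aligned_nt, -m.score, m.evalue, m.protein_id),
    )


def partition_transcript(transcript_id: str, cdna: str, match: HomologyMatch) -> GeneModel:
    """Partition a cDNA around its homology match.

    CDS = the matched region; 5'UTR = up to 60 nt immediately upstream;
    3'UTR = from the match end to the end of the cDNA.  Reverse-frame
    matches partition the reverse complement (flagged on the model).
    """
    seq = cdna.upper()
    n = len(seq)
    if not (0 <= match.nt_start < match.nt_end <= n):
        raise ValueError("homology match outside cDNA bounds")
    reverse = match.frame < 0
    if reverse:
        seq = str(Seq(seq).reverse_complement())
        lo = n - match.nt_end
        hi = n - match.nt_start
        log.info("%s: reverse-frame homolog, partitioning reverse complement",
                 transcript_id)
    else:
        lo, hi = match.nt_start, match.nt_end
    return GeneModel(
        transcript_id=transcript_id,
        cdna=seq,
        five_utr=(max(0, lo - UTR5_CUT), lo),
        cds=(lo, hi),
        three_utr=(hi, n),
        reverse=reverse,
    )


def annotate_transcripts(
    cdnas: dict[str, str],
    proteins: dict[str, str],
    word_size: int = 6,
    evalue_max: float = 10.0,
    min_shorter_coverage: float = 0.60,
) -> dict[str, GeneModel]:
    """Run search -> select -> partition over a set of transcripts."""
    models: dict[str, GeneModel] = {}
    for tid in sorted(cdnas):
        matches = translated_search(
            tid, cdnas[tid], proteins, word_size=word_size,
            evalue_max=evalue_max, min_shorter_coverage=min_shorter_coverage,
        )
        best = select_homolog(matches)
        if best is not None:
            models[tid] = partition_transcript(tid, cdnas[tid], best)
    return models


def read_protein_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_models_tsv(models: dict[str, GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript\tregion\tstart\tend\treverse\n")
        for tid in sorted(models):
            m = models[tid]
            for region, (lo, hi) in (
                ("5UTR", m.five_utr), ("CDS", m.cds), ("3UTR", m.three_utr),
            ):
                fh.write(f"{tid}\t{region}\t{lo}\t{hi}\t{int(m.reverse)}\n")


def write_region_fastas(models: dict[str, GeneModel], outdir) -> None:
    import os

    names = {"5UTR": "5utr.fa", "CDS": "cds.fa", "3UTR": "3utr.fa"}
    os.makedirs(outdir, exist_ok=True)
    for region, fname in names.items():
        with open(os.path.join(outdir, fname), "w") as fh:
            for tid in sorted(models):
                seq = models[tid].region_seq(region)
                if seq:
                    fh.write(f">{tid}|{region}\n{seq}\n")
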