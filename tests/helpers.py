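"""Independent oracles used by the test suite.

Everything here is deliberately naive (exhaustive enumeration, single-rule
re-scans, brute-force searches) and independent of the optimized code paths
it checks.
"""

from __future__ import annotations

import numpy as np

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def random_seq(rng, n: int) -> str:
    return "".join("ACGT"[k] for k in rng.integers(0, 4, size=n))


# ---------------------------------------------------------------------------
# Folding: exhaustive enumeration of nested structures
# ---------------------------------------------------------------------------

_PAIRABLE = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def all_nested_pairsets(seq: str, i: int = 0, j: int | None = None):
    """Yield every nested pair set (list of (a, b)) of seq[i:j], min loop 3."""
    if j is None:
        j = len(seq)
    if j - i < 5:
        yield []
        return
    for rest in all_nested_pairsets(seq, i + 1, j):
        yield rest
    for k in range(i + 4, j):
        if (seq[i], seq[k]) in _PAIRABLE:
            for inner in all_nested_pairsets(seq, i + 1, k):
                for outer in all_nested_pairsets(seq, k + 1, j):
                    yield [(i, k)] + inner + outer


def enum_min_energy(seq: str, structure_energy, forbidden: set | None = None) -> float:
    """Minimum model energy over all nested structures by brute enumeration.

    ``forbidden`` positions may not appear in any pair (accessibility
    constraint).  The empty structure (energy 0) is always admissible.
    """
    best = 0.0
    for ps in all_nested_pairsets(seq):
        if not ps:
            continue
        if forbidden and any(a in forbidden or b in forbidden for a, b in ps):
            continue
        pm = {}
        for a, b in ps:
            pm[a] = b
            pm[b] = a
        e = structure_energy(seq, pm)
        if e < best:
            best = e
    return best


# ---------------------------------------------------------------------------
# Adapter trimming: naive re-scan
# ---------------------------------------------------------------------------

def naive_trim(seq: str, adapter3: str, min_overlap: int = 6, max_mm: int = 1) -> str:
    """Longest-removal suffix match of adapter3 (>= min_overlap, <= max_mm)."""
    n = len(seq)
    for start in range(0, n - min_overlap + 1):
        overlap = min(n - start, len(adapter3))
        if overlap < min_overlap:
            break
        mm = sum(1 for k in range(overlap) if seq[start + k] != adapter3[k])
        if mm <= max_mm:
            return seq[:start]
    return seq


# ---------------------------------------------------------------------------
# Known-miRNA matching: exhaustive Hamming search
# ---------------------------------------------------------------------------

def brute_best_assignment(tag_seq: str, db: list, max_offset: int = 3,
                          max_mm: int = 1):
    """Best (mature name, mm, offset) over all entries/offsets, or None.

    Same tie-break as the implementation contract: fewest mismatches,
    smallest |offset|, lexicographic name.
    """
    best = None
    for name, mseq in db:
        lt, lm = len(tag_seq), len(mseq)
        for off in range(-max_offset, lm - lt + max_offset + 1):
            lo = max(0, -off)
            ro = max(0, off + lt - lm)
            if lo > max_offset or ro > max_offset:
                continue
            mm = sum(
                1 for i in range(lo, lt - ro) if tag_seq[i] != mseq[off + i]
            )
            if mm > max_mm:
                continue
            key = (mm, abs(off), name, off)
            if best is None or key < best[0]:
                best = (key, (name, mm, off))
    return best[1] if best else None


# ---------------------------------------------------------------------------
# Duplex alignment: exhaustive local trace enumeration (tiny inputs)
# ---------------------------------------------------------------------------

def brute_best_duplex_score(mirna: str, window: str, match_wc=5, match_gu=1,
                            mismatch=-3, gap_open=-9, gap_ext=-4,
                            seed_weight=2, seed_from=2, seed_to=8) -> float:
    """Max local alignment score by explicit enumeration of all traces.

    The miRNA is reversed (3'->5' vs window 5'->3'); scores follow the
    documented table with the 5'-seed weighting.  Exponential: only use on
    sequences of ~5 nt or less.
    """
    n = len(mirna)
    r = mirna[::-1]
    s = window

    def col_score(i, j):
        a, b = r[i], s[j]
        pair = (b, a)
        if pair in {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}:
            base = match_wc
        elif pair in {("G", "T"), ("T", "G")}:
            base = match_gu
        else:
            base = mismatch
        pos = n - i  # original 1-based miRNA position
        return base * (seed_weight if seed_from <= pos <= seed_to else 1)

    best = 0.0

    def rec(i, j, score, last):
        nonlocal best
        if score > best:
            best = score
        if i >= len(r) or j >= len(s):
            return
        rec(i + 1, j + 1, score + col_score(i, j), "M")
        gx = gap_ext if last == "X" else gap_open
        rec(i + 1, j, score + gx, "X")
        gy = gap_ext if last == "Y" else gap_open
        rec(i, j + 1, score + gy, "Y")

    for i0 in range(len(r)):
        for j0 in range(len(s)):
            rec(i0, j0, 0.0, "start")
    return best


# ---------------------------------------------------------------------------
# Dinucleotide shuffle (Altschul-Erickson)
# ---------------------------------------------------------------------------

def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Random permutation of ``seq`` preserving dinucleotide counts."""
    if len(seq) < 3:
        return seq
    chars = sorted(set(seq))
    edges: dict[str, list[str]] = {c: [] for c in chars}
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    last = seq[-1]
    for _ in range(10_000):
        last_edge = {}
        for c in chars:
            if c == last or not edges[c]:
                continue
            last_edge[c] = edges[c][int(rng.integers(0, len(edges[c])))]

        def leads_to_last(c):
            seen = set()
            while c != last:
                if c in seen or c not in last_edge:
                    return False
                seen.add(c)
                c = last_edge[c]
            return True

        if all(leads_to_last(c) for c in last_edge):
            break
    else:  # pragma: no cover
        raise RuntimeError("dinucleotide shuffle failed to find an Eulerian order")
    pools = {}
    for c in chars:
        lst = list(edges[c])
        if c in last_edge:
            lst.remove(last_edge[c])
        order = rng.permutation(len(lst))
        lst = [lst[int(i)] for i in order]
        if c in last_edge:
            lst.append(last_edge[c])
        pools[c] = lst
    out = [seq[0]]
    ptr = {c: 0 for c in chars}
    for _ in range(len(seq) - 1):
        c = out[-1]
        out.append(pools[c][ptr[c]])
        ptr[c] += 1
    return "".join(out)
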