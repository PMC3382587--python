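"""miRNA target-site prediction with two independent scorers.

``miranda_scan`` slides a complementarity alignment (dynamic programming,
affine gaps, 5'-seed weighting) over a transcript region and scores each
candidate site with an alignment score S and a nearest-neighbor duplex
free energy dG; sites pass at S >= 140 and dG < -17 kcal/mol (the S
threshold is inclusive, the energy threshold strict).

``pita_scan`` finds seed matches (6-8 nt starting at miRNA position 2;
G:U wobble permitted only in 8-mers) and scores each site with the
accessibility difference ddG = dG_duplex + dG_open, where dG_open is the
energetic cost of unpairing the site in its local secondary-structure
context (computed with the same folding engine used for hairpin
discovery, run with and without an unpaired constraint).

Only genes reported by both scorers are consensus targets; genes are then
classified by targeting mode (single 3'UTR site, multiple miRNAs in one
3'UTR, or 3'UTR plus coding region).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .folding import PARAMS, STACK, _PT, _SCALE, encode, min_energy

__all__ = [
    "DuplexAlignment",
    "AccessibilitySite",
    "ConsensusTarget",
    "align_duplex",
    "duplex_energy",
    "miranda_scan",
    "open_energy",
    "pita_scan",
    "intersect_targets",
    "classify_mode",
    "passes_miranda",
]

# alignment scoring (documented package defaults; the S/dG acceptance
# thresholds below them are the anchored values)
MATCH_WC = 5
MATCH_GU = 1
MISMATCH = -3
GAP_OPEN = -9
GAP_EXTEND = -4
SEED_WEIGHT = 2       # multiplier for miRNA positions 2-8 (1-based, 5' end)
SEED_FROM, SEED_TO = 2, 8

S_MIN_DEFAULT = 140.0
DG_MAX_DEFAULT = -17.0
CONTEXT_FLANK = 70

_DUP = PARAMS["duplex"]
DUPLEX_INIT = _DUP["initiation"]
AU_END = _DUP["au_end"]
DUPLEX_BULGE = _DUP["bulge"]
DUPLEX_INTERNAL = _DUP["internal"]

REGION_PRIORITY = ("3UTR", "CDS", "5UTR")


@dataclass(frozen=True)
class DuplexAlignment:
    """One alignment-scored target site."""

    mirna: str
    mirna_seq: str
    gene: str
    region: str  # 5UTR / CDS / 3UTR
    site_start: int  # half-open on the region sequence
    site_end: int
    trace: tuple  # columns of (mirna position | -1, site position | -1)
    S: float
    dG: float


@dataclass(frozen=True)
class AccessibilitySite:
    """One accessibility-scored target site."""

    mirna: str
    gene: str
    region: str
    seed_start: int
    seed_len: int
    site_start: int
    site_end: int
    dG_duplex: float
    dG_open: float
    ddG: float


@dataclass
class ConsensusTarget:
    """A gene x miRNA pair reported by both scorers."""

    gene: str
    mirna: str
    region: str  # highest-priority region with dual support
    regions: tuple  # all regions with dual support, priority order
    miranda_sites: list = field(default_factory=list)
    pita_sites: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Complementarity alignment
# ---------------------------------------------------------------------------

_NEG = np.int64(-(1 << 30))


@njit(cache=True)
def _duplex_sw(r, s, w, mask, pt, match_wc, match_gu, mismatch, gap_open, gap_ext):
    """Local affine-gap complementarity alignment of reversed-miRNA r vs site s.

    Returns (M, X, Y) score matrices; M[i, j] is the best local score of an
    alignment ending with column (r[i-1], s[j-1]).
    """
    n, m = r.shape[0], s.shape[0]
    M = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    X = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    Y = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    for i in range(n + 1):
        M[i, 0] = 0
    for j in range(m + 1):
        M[0, j] = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if mask[j - 1]:
                sub = np.int64(-100000)
            else:
                a = r[i - 1]
                b = s[j - 1]
                if a < 4 and b < 4 and pt[b, a] >= 0:
                    p = pt[b, a]
                    base = match_wc if p < 4 else match_gu
                else:
                    base = mismatch
                sub = np.int64(base * w[i - 1])
            prev = M[i - 1, j - 1]
            if X[i - 1, j - 1] > prev:
                prev = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > prev:
                prev = Y[i - 1, j - 1]
            v = prev + sub
            if v < 0:
                v = 0
            M[i, j] = v
            xo = M[i - 1, j] + gap_open
            xe = X[i - 1, j] + gap_ext
            X[i, j] = xo if xo > xe else xe
            yo = M[i, j - 1] + gap_open
            ye = Y[i, j - 1] + gap_ext
            Y[i, j] = yo if yo > ye else ye
    return M, X, Y


def _weights(n: int) -> np.ndarray:
    # weight on reversed-miRNA index i: original 1-based position = n - i
    w = np.ones(n, dtype=np.int64)
    for i in range(n):
        if SEED_FROM <= n - i <= SEED_TO:
            w[i] = SEED_WEIGHT
    return w


def _pair_score(a_mirna: int, b_site: int) -> int:
    if a_mirna < 4 and b_site < 4 and _PT[b_site, a_mirna] >= 0:
        return MATCH_WC if _PT[b_site, a_mirna] < 4 else MATCH_GU
    return MISMATCH


def align_duplex(
    mirna_seq: str,
    window: str,
    mask: Optional[np.ndarray] = None,
) -> tuple[float, tuple]:
    """Best local complementarity alignment of a miRNA against a site window.

    The miRNA is aligned 3'->5' against the window 5'->3'.  Watson-Crick
    pairs score +5, G:U +1, mismatches -3 (all scaled x2 at miRNA positions
    2-8), gaps -9 to open and -4 to extend; the maximum-scoring local trace
    is returned as (S, columns), where each column is (miRNA position,
    window position) with -1 marking a gap.

    Raises ``ValueError`` on non-nucleotide characters.
    """
    for name, seq in (("miRNA", mirna_seq), ("window", window)):
        if set(seq.upper()) - set("ACGTUN"):
            raise ValueError(f"non-nucleotide characters in {name}")
    n = len(mirna_seq)
    r = encode(mirna_seq)[::-1].copy()
    s = encode(window)
    w = _weights(n)
    msk = mask if mask is not None else np.zeros(len(window), dtype=np.bool_)
    M, X, Y = _duplex_sw(
        r, s, w, msk, _PT, MATCH_WC, MATCH_GU, MISMATCH, GAP_OPEN, GAP_EXTEND
    )
    best = int(M[1:, 1:].max()) if n and len(window) else 0
    if best <= 0:
        return 0.0, ()
    # traceback from the first best cell (row-major -> 5'-most site start)
    loc = np.argwhere(M[1:, 1:] == best)[0]
    i, j = int(loc[0]) + 1, int(loc[1]) + 1
    cols = []
    state = "M"
    while i > 0 and j > 0:
        if state == "M":
            if M[i, j] == 0:
                break
            mirna_pos = n - 1 - (i - 1)  # original miRNA coordinate
            cols.append((mirna_pos, j - 1))
            prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            if prev == M[i - 1, j - 1]:
                state = "M"
            elif prev == X[i - 1, j - 1]:
                state = "X"
            else:
                state = "Y"
            i -= 1
            j -= 1
        elif state == "X":
            cols.append((n - 1 - (i - 1), -1))
            if X[i, j] == M[i - 1, j] + GAP_OPEN:
                state = "M"
            i -= 1
        else:
            cols.append((-1, j - 1))
            if Y[i, j] == M[i, j - 1] + GAP_OPEN:
                state = "M"
            j -= 1
    cols.reverse()
    return float(best), tuple(cols)


# ---------------------------------------------------------------------------
# Duplex free energy
# ---------------------------------------------------------------------------

def duplex_energy(mirna_seq: str, site_seq: str, trace: Sequence[tuple]) -> float:
    """Nearest-neighbor free energy (kcal/mol) of a miRNA:site duplex trace.

    Sums stacking energies over consecutive paired columns, plus the duplex
    initiation penalty, terminal AU/GU penalties, and fixed penalties per
    internal-loop/mismatch or bulge interruption.  A trace with no paired
    columns costs the initiation penalty alone.
    """
    me = encode(mirna_seq)
    se = encode(site_seq)
    # paired columns: both coordinates present and bases actually pair
    paired = []
    interruptions: list[str] = []
    gap_run = False
    mism_run = False
    pending: list[str] = []
    for mp, sp in trace:
        if mp >= 0 and sp >= 0 and _PT[se[sp], me[mp]] >= 0:
            if paired and pending:
                interruptions.append("bulge" if "gap" in pending else "internal")
            pending = []
            paired.append((mp, sp))
        elif mp < 0 or sp < 0:
            pending.append("gap")
        else:
            pending.append("mismatch")
    energy = DUPLEX_INIT
    if not paired:
        return energy
    for (mp1, sp1), (mp2, sp2) in zip(paired, paired[1:]):
        if mp2 == mp1 - 1 and sp2 == sp1 + 1:
            p = _PT[se[sp1], me[mp1]]
            q = _PT[se[sp2], me[mp2]]
            energy += STACK[p, q] / _SCALE
    energy += sum(DUPLEX_BULGE if k == "bulge" else DUPLEX_INTERNAL for k in interruptions)
    for mp, sp in (paired[0], paired[-1]):
        if _PT[se[sp], me[mp]] in (0, 1, 4, 5):  # AU/UA/GU/UG terminal pair
            energy += AU_END
    return round(energy, 4)


def passes_miranda(S: float, dG: float, S_min: float = S_MIN_DEFAULT,
                   dG_max: float = DG_MAX_DEFAULT) -> bool:
    """Acceptance predicate: S >= S_min (inclusive) and dG < dG_max (strict)."""
    return S >= S_min and dG < dG_max


def miranda_scan(
    mirna: tuple[str, str],
    gene: str,
    region: str,
    region_seq: str,
    S_min: float = S_MIN_DEFAULT,
    dG_max: float = DG_MAX_DEFAULT,
    max_sites: int = 20,
) -> list[DuplexAlignment]:
    """Alignment-scored sites of one miRNA on one transcript region.

    The best local alignment is extracted, masked out, and the scan
    repeated, so reported sites never overlap (greedy by descending S).
    Sites must satisfy :func:`passes_miranda`.
    """
    name, seq = mirna
    if not region_seq:
        return []
    mask = np.zeros(len(region_seq), dtype=np.bool_)
    out: list[DuplexAlignment] = []
    for _ in range(max_sites):
        S, trace = align_duplex(seq, region_seq, mask)
        if S < S_min or not trace:
            break
        spos = [sp for _, sp in trace if sp >= 0]
        lo, hi = min(spos), max(spos) + 1
        mask[lo:hi] = True
        dG = duplex_energy(seq, region_seq, trace)
        if passes_miranda(S, dG, S_min, dG_max):
            out.append(
                DuplexAlignment(
                    mirna=name, mirna_seq=seq, gene=gene, region=region,
                    site_start=lo, site_end=hi, trace=trace, S=S, dG=dG,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Accessibility scoring
# ---------------------------------------------------------------------------

def open_energy(region_seq: str, site: tuple[int, int],
                context_flank: int = CONTEXT_FLANK) -> float:
    """Energetic cost (kcal/mol, >= 0) of unpairing a site in its context.

    The context is the site extended ``context_flank`` nt both directions
    (truncated at region ends); the cost is the difference between the
    minimum fold energy with the site constrained unpaired and the
    unconstrained minimum.
    """
    lo, hi = site
    if not (0 <= lo < hi <= len(region_seq)):
        raise ValueError("site outside region")
    clo = max(0, lo - context_flank)
    chi = min(len(region_seq), hi + context_flank)
    context = region_seq[clo:chi]
    constrained = min_energy(context, unpaired=set(range(lo - clo, hi - clo)))
    free = min_energy(context)
    return round(max(0.0, constrained - free), 4)


_WOBBLE_ALLOWED = {"G": "T", "T": "G"}  # miRNA base -> wobble partner on target


def _complement(b: str) -> str:
    return {"A": "T", "C": "G", "G": "C", "T": "A"}[b]


def _seed_site_chars(mirna_seq: str, k: int) -> list[tuple[str, Optional[str]]]:
    """Per-position (WC char, wobble char|None) of the target seed site.

    The seed spans miRNA positions 2..k+1 (1-based).  On the target the
    seed site reads 3'->5' relative to the miRNA, so position i of the site
    pairs miRNA base ``k - i + 1``.
    """
    seed = mirna_seq.upper().replace("U", "T")[1:1 + k]
    chars = []
    for b in reversed(seed):
        chars.append((_complement(b), _WOBBLE_ALLOWED.get(b)))
    return chars


def find_seed_matches(mirna_seq: str, region_seq: str) -> list[tuple[int, int, int]]:
    """Seed matches as (site_start, seed_len, n_wobbles).

    6- and 7-mer seeds (miRNA positions 2-7 / 2-8) must match by strict
    Watson-Crick pairing; 8-mers (positions 2-9) tolerate one G:U wobble.
    Overlapping hits at the same seed 3'-anchor keep the longest seed.
    """
    region = region_seq.upper().replace("U", "T")
    found: dict[int, tuple[int, int, int]] = {}
    for k in (8, 7, 6):
        if len(mirna_seq) < k + 1:
            continue
        chars = _seed_site_chars(mirna_seq, k)
        max_wob = 1 if k == 8 else 0
        for x in range(0, len(region) - k + 1):
            wob = 0
            ok = True
            for i, (wc, wobble) in enumerate(chars):
                c = region[x + i]
                if c == wc:
                    continue
                if wobble is not None and c == wobble:
                    wob += 1
                    if wob > max_wob:
                        ok = False
                        break
                else:
                    ok = False
                    break
            if ok:
                anchor = x + k  # position just 3' of the site's seed region
                if anchor not in found or found[anchor][1] < k:
                    found[anchor] = (x, k, wob)
    return sorted(found.values())


def pita_scan(
    mirna: tuple[str, str],
    gene: str,
    region: str,
    region_seq: str,
    ddG_max: Optional[float] = None,
    context_flank: int = CONTEXT_FLANK,
) -> list[AccessibilitySite]:
    """Accessibility-scored sites of one miRNA on one transcript region.

    For each seed match the full miRNA is hybridized against a window
    around the seed (duplex energy dG_duplex), the opening cost dG_open of
    the paired site is computed, and ddG = dG_duplex + dG_open reported.
    All sites are kept unless ``ddG_max`` is set; overlapping sites are
    resolved greedily by ascending ddG.
    """
    name, seq = mirna
    if not region_seq:
        return []
    m = len(seq)
    sites: list[AccessibilitySite] = []
    for x, k, _wob in find_seed_matches(seq, region_seq):
        wlo = max(0, x - (m - k) - 8)
        whi = min(len(region_seq), x + k + 2)
        window = region_seq[wlo:whi]
        S, trace = align_duplex(seq, window)
        if not trace:
            continue
        spos = [sp for _, sp in trace if sp >= 0]
        lo, hi = wlo + min(spos), wlo + max(spos) + 1
        dG_dup = duplex_energy(seq, window, trace)
        dG_open = open_energy(region_seq, (lo, hi), context_flank)
        ddG = round(dG_dup + dG_open, 4)
        if ddG_max is not None and ddG > ddG_max:
            continue
        sites.append(
            AccessibilitySite(
                mirna=name, gene=gene, region=region, seed_start=x, seed_len=k,
                site_start=lo, site_end=hi,
                dG_duplex=dG_dup, dG_open=dG_open, ddG=ddG,
            )
        )
    # non-overlap: greedy by ascending ddG
    sites.sort(key=lambda s: (s.ddG, s.site_start))
    kept: list[AccessibilitySite] = []
    for s in sites:
        if all(s.site_end <= t.site_start or s.site_start >= t.site_end for t in kept):
            kept.append(s)
    kept.sort(key=lambda s: s.site_start)
    return kept


# ---------------------------------------------------------------------------
# Consensus and modes
# ---------------------------------------------------------------------------

def intersect_targets(
    miranda_hits: Sequence[DuplexAlignment],
    pita_hits: Sequence[AccessibilitySite],
) -> list[ConsensusTarget]:
    """Gene x miRNA pairs reported by both scorers.

    A consensus target records every region where *both* scorers found a
    site, in 3'UTR > CDS > 5'UTR priority order; the pair qualifies as soon
    as both scorers hit the gene in any region.
    """
    mir_by_pair: dict[tuple[str, str], list[DuplexAlignment]] = {}
    for h in miranda_hits:
        mir_by_pair.setdefault((h.gene, h.mirna), []).append(h)
    pita_by_pair: dict[tuple[str, str], list[AccessibilitySite]] = {}
    for h in pita_hits:
        pita_by_pair.setdefault((h.gene, h.mirna), []).append(h)
    out = []
    for pair in sorted(set(mir_by_pair) & set(pita_by_pair)):
        msites = mir_by_pair[pair]
        psites = pita_by_pair[pair]
        both_regions = tuple(
            r for r in REGION_PRIORITY
            if any(s.region == r for s in msites) and any(s.region == r for s in psites)
        )
        any_regions = tuple(
            r for r in REGION_PRIORITY
            if any(s.region == r for s in msites) or any(s.region == r for s in psites)
        )
        regions = both_regions or any_regions
        out.append(
            ConsensusTarget(
                gene=pair[0], mirna=pair[1], region=regions[0], regions=both_regions,
                miranda_sites=msites, pita_sites=psites,
            )
        )
    return out


MODE_SINGLE_3UTR = "single-3UTR"
MODE_MULTI_MIRNA_3UTR = "multi-miRNA-3UTR"
MODE_3UTR_PLUS_CDS = "3UTR-plus-CDS"


def classify_mode(targets: Sequence[ConsensusTarget]) -> dict[str, list[str]]:
    """Targeting-mode labels per gene (a gene may carry several).

    * ``single-3UTR``: exactly one miRNA with exactly one dual-supported
      3'UTR site on the gene;
    * ``multi-miRNA-3UTR``: two or more distinct miRNAs with 3'UTR sites;
    * ``3UTR-plus-CDS``: one miRNA with dual-supported sites in both the
      3'UTR and the coding region.
    """
    by_gene: dict[str, list[ConsensusTarget]] = {}
    for t in targets:
        by_gene.setdefault(t.gene, []).append(t)
    modes: dict[str, list[str]] = {}
    for gene, ts in sorted(by_gene.items()):
        labels = []
        with_3utr = [t for t in ts if "3UTR" in t.regions]
        if len(with_3utr) == 1:
            n_sites = sum(1 for s in with_3utr[0].miranda_sites if s.region == "3UTR")
            if n_sites == 1:
                labels.append(MODE_SINGLE_3UTR)
        if len(with_3utr) >= 2:
            labels.append(MODE_MULTI_MIRNA_3UTR)
        if any({"3UTR", "CDS"} <= set(t.regions) for t in ts):
            labels.append(MODE_3UTR_PLUS_CDS)
        modes[gene] = labels
    return modes


def summarize_targets(targets: Sequence[ConsensusTarget]) -> dict:
    """Per-miRNA counts of genes by region combination (3'UTR only,
    3'UTR+CDS, 3'UTR+5'UTR)."""
    summary: dict[str, dict[str, int]] = {}
    for t in targets:
        d = summary.setdefault(t.mirna, {"3UTR": 0, "3UTR+CDS": 0, "3UTR+5UTR": 0})
        regions = set(t.regions)
        if "3UTR" in regions:
            if "CDS" in regions:
                d["3UTR+CDS"] += 1
            elif "5UTR" in regions:
                d["3UTR+5UTR"] += 1
            else:
                d["3UTR"] += 1
    return summary
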