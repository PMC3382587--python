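"""Synthetic study generator: every input the pipeline consumes, seeded.

The generator emulates an adapter-ligated egg small-RNA library sequenced
from a toy genome with planted miRNA hairpins, transcripts with planted
3'UTR/CDS target sites, a 10-tissue qPCR panel with a planted
egg-predominant effect, and a 3-tissue ranked-expression matrix.  All
outputs are byte-deterministic functions of :class:`SyntheticConfig`, and
the accompanying :class:`GroundTruth` records every planted feature so
each pipeline stage can be scored without re-deriving anything.

What it does *not* emulate: sequencer error profiles, GC/ligation bias,
isochore structure (background sequence is i.i.d. uniform ACGT).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .discovery import GenomeLocus, HairpinCriteria, PrecursorCandidate, call_hairpin
from .filtering import SmallRNARead, UniqueTag

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticBundle",
    "make_genome_with_hairpins",
    "simulate_small_rna_library",
    "make_gene_models_with_sites",
    "simulate_qpcr_plate",
    "simulate_expression_matrix",
    "generate_all",
    "write_fixtures",
    "reads_for_species",
]

STOPS = {"TAA", "TAG", "TGA"}
TISSUES_10 = (
    "gill", "liver", "stomach", "head_kidney", "muscle",
    "egg", "heart", "small_intestine", "brain", "spleen",
)

# default insert-length mix over 15-26 nt, peaked at 22-25 like a typical
# mappable small-RNA size profile (21-26 nt carrying ~89% of reads)
DEFAULT_LENGTH_MIX = {
    15: 0.010, 16: 0.010, 17: 0.015, 18: 0.020, 19: 0.025, 20: 0.030,
    21: 0.090, 22: 0.184, 23: 0.165, 24: 0.182, 25: 0.153, 26: 0.116,
}

# miRBase-flavoured names for the synthetic known set; paralog letters and
# shared cores exercise the family-pooling rule (let-7a/let-7e -> let-7)
KNOWN_NAME_POOL = [
    "omy-let-7a-5p", "omy-let-7e-5p", "omy-miR-21-5p", "omy-miR-21b-5p",
    "omy-miR-24-3p", "omy-miR-202-5p", "omy-miR-148-3p", "omy-miR-30a-5p",
    "omy-miR-10b-5p", "omy-miR-146a-5p", "omy-miR-25-3p", "omy-miR-143-3p",
    "omy-miR-22a-3p", "omy-miR-26a-5p", "omy-miR-27b-3p", "omy-miR-92a-3p",
    "omy-miR-99-5p", "omy-miR-100-5p", "omy-miR-101a-3p", "omy-miR-122-5p",
    "omy-miR-125b-5p", "omy-miR-126-3p", "omy-miR-128-3p", "omy-miR-130a-3p",
    "omy-miR-133a-3p", "omy-miR-140-3p", "omy-miR-142a-5p", "omy-miR-150-5p",
    "omy-miR-181a-5p", "omy-miR-199a-5p",
]

ADAPTER3_DEFAULT = "TCGTATGCCGTCTTCTGCTTG"  # classic small-RNA 3' adapter


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study; defaults are the study conditions."""

    seed: int = 1
    # genome / hairpins
    genome_length: int = 30_000
    n_chroms: int = 2
    n_known_mirnas: int = 25
    n_novel_hairpins: int = 20
    n_focal_novel: int = 3
    mature_len: int = 22
    loop_range: tuple = (6, 12)
    max_wobbles: int = 2
    # library
    library_depth: int = 50_000
    junk_fraction: float = 0.10
    adapter_dimer_fraction: float = 0.05
    background_fraction: float = 0.15
    novel_fraction: float = 0.15
    # remainder of the categorical mix is known-miRNA reads
    length_mix: dict = field(default_factory=lambda: dict(DEFAULT_LENGTH_MIX))
    background_species_per_length: int = 20
    # fraction of background fragments longer than the mappable window
    # (27-40 nt; removed by the length filter, as in a 15-50 nt library)
    background_long_fraction: float = 0.15
    zipf_exponent: float = 1.5
    isomir_jitter_rate: float = 0.15
    isomir_subst_rate: float = 0.05
    adapter3: str = ADAPTER3_DEFAULT
    read_length: int = 36
    # transcripts / target sites
    n_transcripts: int = 30
    protein_len_range: tuple = (80, 180)
    utr5_range: tuple = (20, 80)
    utr3_range: tuple = (150, 300)
    # qPCR panel
    tissues: tuple = TISSUES_10
    n_replicates: int = 4
    egg_fold: float = 50.0
    cq_sigma: float = 0.2
    quantity_cv: float = 0.2
    curve_slope: float = -3.3219
    curve_intercept: float = 35.0
    dilution_points: int = 5
    reference_targets: tuple = ("beta_actin", "histone_h2a")
    # ranked-expression matrix (egg/liver/muscle analogue)
    n_matrix_genes: int = 60
    n_matrix_target_genes: int = 12
    matrix_egg_factor: float = 0.6
    matrix_noise_sigma: float = 0.5

    @property
    def known_fraction(self) -> float:
        f = 1.0 - (self.junk_fraction + self.adapter_dimer_fraction
                   + self.background_fraction + self.novel_fraction)
        if f < 0:
            raise ValueError("category fractions exceed 1")
        return f


@dataclass
class GroundTruth:
    """Everything planted by the generator, sufficient to score the pipeline."""

    genome: dict = field(default_factory=dict)
    hairpins: list = field(default_factory=list)
    known_matures: list = field(default_factory=list)  # (name, seq)
    focal: list = field(default_factory=list)  # (name, seq) egg-predominant novels
    tag_truth: dict = field(default_factory=dict)  # insert -> {species, category, copies}
    category_counts: dict = field(default_factory=dict)
    transcripts: dict = field(default_factory=dict)
    planted_sites: list = field(default_factory=list)
    qpcr: dict = field(default_factory=dict)
    matrix_target_genes: list = field(default_factory=list)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(type(o))

        d = dataclasses.asdict(self)
        d.pop("genome")  # genome lives in its own FASTA
        return json.dumps(d, indent=1, sort_keys=True, default=default)


@dataclass
class SyntheticBundle:
    """A fully generated study: inputs plus ground truth."""

    config: SyntheticConfig
    truth: GroundTruth
    reads: list
    cdnas: dict
    proteins: dict
    cq_table: pd.DataFrame
    dilutions: pd.DataFrame
    matrix: pd.DataFrame


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[k] for k in rng.integers(0, 4, size=n))


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _zipf_weights(n: int, a: float) -> np.ndarray:
    w = np.arange(1, n + 1, dtype=float) ** (-a)
    return w / w.sum()


def _stop_free(mature: str) -> bool:
    """True when revcomp(mature) carries no stop codon in frame 0 over its
    full codons (required before planting into a coding region)."""
    rc = _revcomp(mature)
    return all(rc[i:i + 3] not in STOPS for i in range(0, len(rc) - 2, 3))


# ---------------------------------------------------------------------------
# Genome with planted hairpins
# ---------------------------------------------------------------------------

def _build_precursor(rng: np.random.Generator, cfg: SyntheticConfig,
                     require_stop_free: bool) -> tuple[str, str, int, str, int]:
    """One planted precursor: (precursor, mature, mature_offset, arm, loop_len)."""
    while True:
        mature = _rand_seq(rng, cfg.mature_len)
        if require_stop_free and not _stop_free(mature):
            continue
        break
    loop_len = int(rng.integers(cfg.loop_range[0], cfg.loop_range[1] + 1))
    loop = _rand_seq(rng, loop_len)
    partner = list(_revcomp(mature))
    # up to max_wobbles G:U wobbles at positions where the mature has G or T
    wobble_sites = [i for i, b in enumerate(mature) if b in "GT"]
    n_wob = int(rng.integers(0, cfg.max_wobbles + 1))
    if wobble_sites and n_wob:
        chosen = rng.choice(len(wobble_sites), size=min(n_wob, len(wobble_sites)),
                            replace=False)
        for ci in np.atleast_1d(chosen):
            i = wobble_sites[int(ci)]
            # partner index of mature position i in the reverse complement
            j = cfg.mature_len - 1 - i
            partner[j] = "T" if mature[i] == "G" else "G"
    partner = "".join(partner)
    arm = "5p" if rng.random() < 0.5 else "3p"
    if arm == "5p":
        precursor = mature + loop + partner
        offset = 0
    else:
        precursor = partner + loop + mature
        offset = len(partner) + loop_len
    return precursor, mature, offset, arm, loop_len


def make_genome_with_hairpins(
    cfg: SyntheticConfig, rng: np.random.Generator,
    criteria: HairpinCriteria = HairpinCriteria(),
) -> tuple[dict, list, list]:
    """Random background genome with planted, verified miRNA hairpins.

    Returns (genome, hairpin records, focal (name, seq) list).  Each
    precursor is planted on a random strand, then checked: the +/-60 nt
    extension around the mature must pass :func:`~ovamir.discovery.call_hairpin`
    and the mature (and its reverse complement) must occur exactly once in
    the genome; failing plants are resampled in place.
    """
    if cfg.genome_length < cfg.n_novel_hairpins * 200:
        raise ValueError("genome too short for the requested hairpin count")
    per_chrom = cfg.genome_length // cfg.n_chroms
    chroms = {f"chr{i + 1}": list(_rand_seq(rng, per_chrom)) for i in range(cfg.n_chroms)}
    names = sorted(chroms)
    # non-overlapping slots with generous spacing, round-robin over chroms
    slot_len = cfg.mature_len * 2 + cfg.loop_range[1] + 4
    spacing = max(160, (per_chrom - 200) // max(1, -(-cfg.n_novel_hairpins // cfg.n_chroms)))
    hairpins: list[dict] = []
    focal: list[tuple[str, str]] = []
    for h in range(cfg.n_novel_hairpins):
        chrom = names[h % cfg.n_chroms]
        slot_start = 100 + (h // cfg.n_chroms) * spacing
        if slot_start + slot_len + 100 > per_chrom:
            raise ValueError("genome too short for hairpin slots")
        require_sf = h < cfg.n_focal_novel
        placed = None
        for _attempt in range(60):
            precursor, mature, offset, arm, loop_len = _build_precursor(
                rng, cfg, require_sf)
            strand = "+" if rng.random() < 0.5 else "-"
            planted = precursor if strand == "+" else _revcomp(precursor)
            saved = chroms[chrom][slot_start:slot_start + len(planted)]
            chroms[chrom][slot_start:slot_start + len(planted)] = list(planted)
            genome = {c: "".join(s) for c, s in chroms.items()}
            if strand == "+":
                m0 = slot_start + offset
            else:
                m0 = slot_start + len(planted) - (offset + cfg.mature_len)
            m1 = m0 + cfg.mature_len
            text = "".join(genome.values())
            unique = (text.count(mature) + text.count(_revcomp(mature))) == 1
            locus = GenomeLocus(chrom, m0, m1, strand)
            lo = max(0, m0 - 60)
            hi = min(per_chrom, m1 + 60)
            window = genome[chrom][lo:hi]
            if strand == "-":
                window = _revcomp(window)
                moff = hi - m1
            else:
                moff = m0 - lo
            cand = PrecursorCandidate(
                tag=UniqueTag(mature, 1), locus=locus,
                precursor_seq=window, mature_offset=moff,
            )
            if unique and call_hairpin(cand, criteria):
                placed = dict(
                    name=f"nov{h + 1}-{arm}", mature=mature, chrom=chrom,
                    mature_start=m0, mature_end=m1, strand=strand, arm=arm,
                    loop_len=loop_len, precursor=precursor,
                )
                break
            chroms[chrom][slot_start:slot_start + len(planted)] = saved
        if placed is None:
            raise RuntimeError(f"could not plant hairpin {h} after 60 attempts")
        hairpins.append(placed)
        if require_sf:
            focal.append((placed["name"], placed["mature"]))
    genome = {c: "".join(s) for c, s in chroms.items()}
    return genome, hairpins, focal


# ---------------------------------------------------------------------------
# Small-RNA library
# ---------------------------------------------------------------------------

def reads_for_species(insert: str, copies: int, adapter3: str, read_length: int,
                      start_serial: int = 0, quality: int = 35) -> list[SmallRNARead]:
    """Adapter-ligate and truncate one insert ``copies`` times."""
    seq = (insert + adapter3)[:read_length]
    return [
        SmallRNARead(f"read{start_serial + k}", seq, [quality] * len(seq))
        for k in range(copies)
    ]


_JUNK_POOL = [
    "A" * 20, "C" * 18, "G" * 22, "T" * 19,
    "ACACACACACACACACAC", "CACACACACACACACACACA",
    "GTGTGTGTGTGTGTGTGT", "TGTGTGTGTGTGTGTGTGTG",
    "AAAAAAAAAAAAAAAAAGAA",  # >=80% single base with a non-A
    "ACGTNNNACGTACGTACGTN",  # N-rich (screens as low-resolution)
]


def simulate_small_rna_library(
    genome: dict,
    hairpins: Sequence[dict],
    known_matures: Sequence[tuple],
    cfg: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[list, dict]:
    """Sample an adapter-ligated read library from the planted truth.

    Each read draws a category (known / novel / background / junk /
    adapter-dimer) from the configured fractions, then a species within the
    category: knowns and novels by Zipf-weighted rank, background fragments
    by drawing an insert length from ``length_mix`` and a species uniformly
    within that length.  Known reads suffer isomiR end jitter (1-2 nt
    truncation) and single substitutions at the configured rates; novel
    reads are emitted verbatim.  Returns (reads, per-insert truth).
    """
    known_seqs = [s for _, s in known_matures]
    known_names = [n for n, _ in known_matures]
    novel_seqs = [h["mature"] for h in hairpins]
    novel_names = [h["name"] for h in hairpins]
    w_known = _zipf_weights(len(known_seqs), cfg.zipf_exponent) if known_seqs else None
    w_novel = _zipf_weights(len(novel_seqs), cfg.zipf_exponent) if novel_seqs else None

    # background fragment pool: per length, a fixed number of genome slices
    lengths = sorted(cfg.length_mix)
    mix_p = np.array([cfg.length_mix[L] for L in lengths], dtype=float)
    mix_p = mix_p / mix_p.sum()
    text = "".join(genome[c] for c in sorted(genome)) if genome else _rand_seq(rng, 5000)
    long_lengths = list(range(27, 41))
    bg_pool: dict[int, list[str]] = {}
    for L in lengths + long_lengths:
        pool = []
        for _ in range(cfg.background_species_per_length):
            pos = int(rng.integers(0, len(text) - L))
            pool.append(text[pos:pos + L])
        bg_pool[L] = pool
    w_bg = _zipf_weights(cfg.background_species_per_length, cfg.zipf_exponent)

    cats = ("known", "novel", "background", "junk", "dimer")
    p_cat = np.array([
        cfg.known_fraction, cfg.novel_fraction, cfg.background_fraction,
        cfg.junk_fraction, cfg.adapter_dimer_fraction,
    ])
    p_cat = p_cat / p_cat.sum()

    reads: list[SmallRNARead] = []
    tag_truth: dict[str, dict] = {}
    cat_counts = {c: 0 for c in cats}
    dimer_insert = cfg.adapter3  # read is pure adapter
    draws = rng.choice(len(cats), size=cfg.library_depth, p=p_cat)
    for serial, ci in enumerate(draws):
        cat = cats[int(ci)]
        cat_counts[cat] += 1
        if cat == "known" and known_seqs:
            k = int(rng.choice(len(known_seqs), p=w_known))
            insert = known_seqs[k]
            species = known_names[k]
            if rng.random() < cfg.isomir_jitter_rate:
                cut = int(rng.integers(1, 3))
                insert = insert[cut:] if rng.random() < 0.5 else insert[:-cut]
            if rng.random() < cfg.isomir_subst_rate:
                pos = int(rng.integers(0, len(insert)))
                base = "ACGT"[int(rng.integers(0, 4))]
                insert = insert[:pos] + base + insert[pos + 1:]
        elif cat == "novel" and novel_seqs:
            k = int(rng.choice(len(novel_seqs), p=w_novel))
            insert = novel_seqs[k]
            species = novel_names[k]
        elif cat == "background":
            if rng.random() < cfg.background_long_fraction:
                L = long_lengths[int(rng.integers(0, len(long_lengths)))]
            else:
                L = lengths[int(rng.choice(len(lengths), p=mix_p))]
            k = int(rng.choice(cfg.background_species_per_length, p=w_bg))
            insert = bg_pool[L][k]
            species = f"bg_{L}_{k}"
        elif cat == "junk":
            k = int(rng.integers(0, len(_JUNK_POOL)))
            insert = _JUNK_POOL[k]
            species = f"junk_{k}"
        else:  # dimer
            insert = dimer_insert
            species = "adapter_dimer"
        if cat == "dimer":
            seq = (cfg.adapter3 * 2)[:cfg.read_length]
        else:
            seq = (insert + cfg.adapter3)[:cfg.read_length]
        reads.append(SmallRNARead(f"read{serial}", seq, [35] * len(seq)))
        rec = tag_truth.setdefault(
            insert, {"species": species, "category": cat, "copies": 0})
        rec["copies"] += 1
    return reads, {"tags": tag_truth, "categories": cat_counts}


# ---------------------------------------------------------------------------
# Transcripts with planted target sites
# ---------------------------------------------------------------------------

_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT" if a + b + c not in STOPS]


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(_CODONS), size=n_codons)
    return "ATG" + "".join(_CODONS[int(i)] for i in idx)


def _plant_cds_site(cds: str, site: str, rng: np.random.Generator) -> tuple[str, int]:
    """Overwrite a codon-aligned CDS window with a (stop-free) site; the
    trailing partial codon is completed without creating a stop."""
    n_codons = len(cds) // 3
    span_codons = -(-len(site) // 3)
    c0 = int(rng.integers(1, n_codons - span_codons - 1))
    pos = c0 * 3
    out = cds[:pos] + site
    tail = len(site) % 3
    if tail:
        fill = 3 - tail
        nxt = pos + len(site)
        completion = cds[nxt:nxt + fill]
        if (site[-tail:] + completion) in STOPS:
            completion = "C" * fill
        out += completion
        nxt += fill
    else:
        nxt = pos + len(site)
    out += cds[nxt:]
    return out, pos


def make_gene_models_with_sites(
    focal: Sequence[tuple],
    cfg: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[dict, dict, dict, list]:
    """Transcripts (5'UTR + CDS + 3'UTR) with planted miRNA target sites.

    Site plan covers every targeting mode: gene 0 a single 3'UTR site of
    the first focal miRNA, gene 1 3'UTR sites of two miRNAs, gene 2 3'UTR
    plus CDS sites of one miRNA, genes 3-4 single sites of the remaining
    focal miRNAs; all other transcripts carry no planted site.  Proteins
    are exact translations of the final planted CDS.

    Returns (cdnas, proteins, transcript records, planted site table).
    """
    mirnas = list(focal)
    cdnas: dict[str, str] = {}
    proteins: dict[str, str] = {}
    transcripts: dict[str, dict] = {}
    sites: list[dict] = []
    for g in range(cfg.n_transcripts):
        tid = f"t{g:03d}"
        pid = f"p{g:03d}"
        n_aa = int(rng.integers(cfg.protein_len_range[0], cfg.protein_len_range[1] + 1))
        cds = _random_cds(rng, n_aa - 1)
        utr5_len = int(rng.integers(cfg.utr5_range[0], cfg.utr5_range[1] + 1))
        utr3_len = int(rng.integers(cfg.utr3_range[0], cfg.utr3_range[1] + 1))
        utr5 = _rand_seq(rng, utr5_len)
        utr3 = list(_rand_seq(rng, utr3_len))

        plan: list[tuple[str, str]] = []  # (mirna name, region)
        if mirnas:
            if g == 0:
                plan = [(mirnas[0][0], "3UTR")]
            elif g == 1 and len(mirnas) >= 2:
                plan = [(mirnas[0][0], "3UTR"), (mirnas[1][0], "3UTR")]
            elif g == 2:
                plan = [(mirnas[0][0], "3UTR"), (mirnas[0][0], "CDS")]
            elif g == 3 and len(mirnas) >= 2:
                plan = [(mirnas[1][0], "3UTR")]
            elif g == 4 and len(mirnas) >= 3:
                plan = [(mirnas[2][0], "3UTR")]
        by_name = dict(mirnas)
        used: list[tuple[int, int]] = []
        for name, region in plan:
            site = _revcomp(by_name[name])
            if region == "3UTR":
                for _ in range(40):
                    pos = int(rng.integers(4, utr3_len - len(site) - 4))
                    if all(pos + len(site) + 4 <= a or pos >= b + 4 for a, b in used):
                        break
                used.append((pos, pos + len(site)))
                utr3[pos:pos + len(site)] = list(site)
                sites.append(dict(gene=tid, mirna=name, region="3UTR", start=pos))
            else:
                cds, pos = _plant_cds_site(cds, site, rng)
                sites.append(dict(gene=tid, mirna=name, region="CDS", start=pos))
        utr3 = "".join(utr3)
        protein = str(Seq(cds).translate())
        assert "*" not in protein, "stop codon slipped into a planted CDS"
        cdna = utr5 + cds + utr3
        cdnas[tid] = cdna
        proteins[pid] = protein
        transcripts[tid] = dict(
            protein=pid, utr5_len=utr5_len,
            cds=(utr5_len, utr5_len + len(cds)),
            utr3=(utr5_len + len(cds), len(cdna)),
        )
    return cdnas, proteins, transcripts, sites


# ---------------------------------------------------------------------------
# qPCR panel and expression matrix
# ---------------------------------------------------------------------------

def simulate_qpcr_plate(
    cfg: SyntheticConfig,
    focal_names: Sequence[str],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Tissue-panel Cq table plus 10-fold dilution series.

    Focal miRNA quantities are 1 in every tissue except egg, where they are
    multiplied by the planted fold; reference genes sit at 1 everywhere.
    Replicate quantities scatter log-normally (CV ~ ``quantity_cv``) and
    Cq values get Gaussian noise ``cq_sigma`` on top of the fixed standard
    curve (slope -3.3219 = 100% efficiency by default).
    """
    targets = list(focal_names) + list(cfg.reference_targets)
    truth_q = {
        t: {
            tis: (cfg.egg_fold if (tis == "egg" and t not in cfg.reference_targets) else 1.0)
            for tis in cfg.tissues
        }
        for t in targets
    }
    rows = []
    for tis in cfg.tissues:
        for rep in range(cfg.n_replicates):
            sample = f"{tis}_{rep + 1}"
            for t in targets:
                q = truth_q[t][tis] * float(np.exp(rng.normal(0.0, cfg.quantity_cv)))
                cq = (cfg.curve_slope * np.log10(q) + cfg.curve_intercept
                      + rng.normal(0.0, cfg.cq_sigma))
                rows.append(dict(sample=sample, tissue=tis, target=t, cq=round(float(cq), 4)))
    cq_table = pd.DataFrame(rows)
    drows = []
    for t in targets:
        for d in range(cfg.dilution_points):
            lg = -float(d)
            cq = (cfg.curve_slope * lg + cfg.curve_intercept
                  + rng.normal(0.0, 0.05))
            drows.append(dict(target=t, dilution_log10=lg, cq=round(float(cq), 4)))
    dilutions = pd.DataFrame(drows)
    qpcr_truth = dict(
        targets=targets, truth_quantity=truth_q, slope=cfg.curve_slope,
        intercept=cfg.curve_intercept, egg_fold=cfg.egg_fold,
    )
    return cq_table, dilutions, qpcr_truth


def simulate_expression_matrix(
    cfg: SyntheticConfig, rng: np.random.Generator,
) -> tuple[pd.DataFrame, list]:
    """Egg/liver/muscle ranked-expression analogue with an egg-low effect.

    The first ``n_matrix_target_genes`` genes (the planted "target" set)
    have their egg values multiplied by ``matrix_egg_factor`` (< 1); the
    effect is deliberately modest relative to the log-normal noise.
    Returns (long-format matrix, target gene list).
    """
    tissues = {"egg": 4, "liver": 3, "muscle": 3}
    genes = [f"g{k:03d}" for k in range(cfg.n_matrix_genes)]
    target_genes = genes[: cfg.n_matrix_target_genes]
    rows = []
    for gene in genes:
        base = float(np.exp(rng.normal(3.0, 1.0)))
        for tis, n in tissues.items():
            factor = cfg.matrix_egg_factor if (tis == "egg" and gene in target_genes) else 1.0
            for rep in range(n):
                val = base * factor * float(np.exp(rng.normal(0.0, cfg.matrix_noise_sigma)))
                rows.append(dict(gene=gene, tissue=tis, replicate=rep + 1,
                                 value=round(val, 4)))
    return pd.DataFrame(rows), target_genes


# ---------------------------------------------------------------------------
# Bundles and fixture files
# ---------------------------------------------------------------------------

def _make_known_matures(cfg: SyntheticConfig, rng: np.random.Generator,
                        avoid: set) -> list:
    out = []
    names = KNOWN_NAME_POOL[: cfg.n_known_mirnas]
    if cfg.n_known_mirnas > len(KNOWN_NAME_POOL):
        names = names + [
            f"omy-miR-{500 + k}-5p"
            for k in range(cfg.n_known_mirnas - len(KNOWN_NAME_POOL))
        ]
    for name in names:
        while True:
            L = int(rng.integers(20, 24))
            seq = _rand_seq(rng, L)
            if seq not in avoid:
                avoid.add(seq)
                break
        out.append((name, seq))
    return out


def generate_all(cfg: Optional[SyntheticConfig] = None) -> SyntheticBundle:
    """Generate the complete synthetic study from one seeded config."""
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    truth = GroundTruth()
    genome, hairpins, focal = make_genome_with_hairpins(cfg, rng)
    truth.genome = genome
    truth.hairpins = hairpins
    truth.focal = focal
    avoid = {h["mature"] for h in hairpins}
    truth.known_matures = _make_known_matures(cfg, rng, avoid)
    reads, lib_truth = simulate_small_rna_library(
        genome, hairpins, truth.known_matures, cfg, rng)
    truth.tag_truth = lib_truth["tags"]
    truth.category_counts = lib_truth["categories"]
    cdnas, proteins, transcripts, sites = make_gene_models_with_sites(focal, cfg, rng)
    truth.transcripts = transcripts
    truth.planted_sites = sites
    cq_table, dilutions, qpcr_truth = simulate_qpcr_plate(
        cfg, [n for n, _ in focal], rng)
    truth.qpcr = qpcr_truth
    matrix, target_genes = simulate_expression_matrix(cfg, rng)
    truth.matrix_target_genes = target_genes
    return SyntheticBundle(
        config=cfg, truth=truth, reads=reads, cdnas=cdnas, proteins=proteins,
        cq_table=cq_table, dilutions=dilutions, matrix=matrix,
    )


def write_fixtures(bundle: SyntheticBundle, outdir) -> None:
    """Write the generated study as plain-text fixture files."""
    import os

    os.makedirs(outdir, exist_ok=True)

    def fa(path, items):
        with open(path, "w") as fh:
            for name, seq in items:
                fh.write(f">{name}\n{seq}\n")

    fa(os.path.join(outdir, "genome.fa"), sorted(bundle.truth.genome.items()))
    fa(os.path.join(outdir, "mature_known.fa"), bundle.truth.known_matures)
    fa(os.path.join(outdir, "cdna.fa"), sorted(bundle.cdnas.items()))
    fa(os.path.join(outdir, "proteins.fa"), sorted(bundle.proteins.items()))
    with open(os.path.join(outdir, "reads.fastq"), "w") as fh:
        for r in bundle.reads:
            qual = "".join(chr(q + 33) for q in (r.quality or [35] * len(r.sequence)))
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")
    bundle.cq_table.to_csv(os.path.join(outdir, "plate_cq.tsv"), sep="\t", index=False)
    bundle.dilutions.to_csv(os.path.join(outdir, "dilutions.tsv"), sep="\t", index=False)
    bundle.matrix.to_csv(os.path.join(outdir, "expression_matrix.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        fh.write(bundle.truth.to_json())
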