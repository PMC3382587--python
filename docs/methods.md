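# Methods

This note documents the models, parameter choices and limitations behind
`ovamir`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Read cleaning

Reads are processed in a fixed, documented order; each read is charged to
exactly one category so the filter report reconciles to the input count.

1. **Adapter trimming.** The 3' adapter is found as the longest-removal
   suffix match: the earliest read position where ≥6 nt of the read match
   a prefix of the adapter with ≤1 mismatch. An empty insert is an
   adapter dimer. A 5' adapter, when configured, is trimmed
   prefix-anchored with the same tolerance; reads with neither adapter
   are kept as-is (insert-only dialect). The kit defines the adapters but
   not the matching algorithm; this rule is the package's own and is the
   one the tests' naive re-scan oracle checks.
2. **Low resolution.** "Low resolution" is not a standard term; here it
   means any `N` in the raw read, or mean Phred quality < 20 when
   qualities exist. Both knobs are configurable.
3. **Junk rules.** ≥80% of one base; ≥3 `N`; alphabet ⊆ {A,C} or ⊆
   {G,T}. The first triggered rule is reported.
4. **Collapse, then size/copy filters.** 15–26 nt, copy number ≥ 3.
   The copy filter runs after junk/length removal so junk reads cannot
   rescue borderline tags. An optional exclusion database (user-supplied
   FASTA, e.g. mRNA/rRNA/repeats) removes tags occurring as exact
   substrings of any entry; we do not ship such databases.

## Known-miRNA assignment

Tags are matched to mature references by ungapped alignment with at most
one substitution. BLAST-style E-values add nothing at 15–26 nt query
lengths, so the deterministic mismatch rule replaces them. Terminal
offsets up to ±3 nt accommodate isomiR end variation; overhanging tag
bases are not counted as mismatches but are capped by the same ±3
budget. Ties break by fewest mismatches, smallest |offset|, then mature
name. Family pooling strips the species code, the `-5p/-3p` arm, a
numeric paralog copy (only when a number remains — `miR-24-1` → `miR-24`
but `let-7` stays `let-7`) and trailing paralog letters; a mapping file
can override the rule. Multi-mapping tags count once, toward the
tie-break winner, so family fractions sum to 1.

## RNA folding model

Folding is a Zuker-style single-optimal dynamic program over nested
structures (no pseudoknots), minimum loop 3 nt, pairs AU/UA/GC/CG/GU/UG.
The energy model is deliberately small and fully evaluable on any
structure:

* stacking energies for all 36 pair stacks
  (`src/ovamir/data/energy_params.yaml`), Turner-inspired, with the
  built-in ordering that any stack containing a G:U wobble is strictly
  weaker than the same stack with the corresponding Watson–Crick pair;
* linear loop penalties — hairpin 4.0 + 0.25·n, bulge 3.0 + 0.40·n,
  interior 2.0 + 0.35·(n₁+n₂) capped at 30 nt total, multiloop
  3.4 + 0.40·branch + 0.10·nt (kcal/mol);
* interior arithmetic in integer centi-kcal, so DP and reference
  evaluator agree bit-exactly.

`structure_energy` evaluates the model on an arbitrary structure; the DP
optimum is property-tested against exhaustive enumeration of all nested
structures for sequences ≤12 nt, and the traceback's structure is checked
to re-evaluate to the reported energy. Ties resolve deterministically
toward the 5'-most opening pair by fixed candidate order. Sequences
shorter than 5 nt (cannot contain a pair) return an unpaired structure at
energy 0. A constrained mode forbids chosen positions from pairing; it is
the engine behind accessibility scoring.

The parameterization is the package's own; it is *not* a fit to Turner
2004 and absolute energies should not be compared to laboratory values.
An external thermodynamics engine can be used as a cross-check but is
never on the implementation path.

## Novel miRNA discovery

Unmatched tags are mapped to the genome exactly (configurable to ≤2
substitutions; cross-species mapping noise is out of scope), extended
±60 nt (truncated at chromosome ends; minus-strand hits are reverse
complemented), folded, and screened:

* ≥18 of the mature's bases pair across one common hairpin loop — the
  mature's stem;
* the mature does not overlap that loop (pure 5p or 3p arm);
* the loop is 3–20 nt;
* no other loop's exclusive stem carries more pairs (dominance);
* fold energy ≤ −18 kcal/mol in model units.

The mature-pairing default deserves a note: with near-perfect planted
stems, planted matures pair 21–22 of 22 bases while dinucleotide-shuffled
decoys of the same precursors (which keep the global self-complementarity
of a stem-rich sequence) reach only 14–18. A looser threshold like 14 —
closer to what one would use on real data with bulged precursors —
admits roughly 9% of such decoys; 18 keeps planted recovery complete with
a decoy pass rate under the 5% design bound. On real data this knob
should be lowered and the consequences re-measured; it is a field in
`HairpinCriteria`.

Candidates are deduplicated by precursor sequence (repeat regions) and
named `nov{serial}-5p/3p` by the arm relative to the loop.

## Transcript partitioning

A six-frame translated search against a protein reference: exact 6-residue
seed words, ungapped BLOSUM62 X-drop extension (X = 20), windowed-entropy
low-complexity masking of the query (window 12, threshold 2.2 bits),
ungapped Karlin–Altschul E-values (λ = 0.3176, K = 0.134), E ≤ 10, and
aligned coverage ≥ 60% of the shorter of translated query frame and
protein. "Maximal match" is the longest aligned region in nucleotides;
score, then E-value, then protein id break ties. The partition is:
CDS = matched region; 5'UTR = min(60, match start) nt immediately
upstream (typical 5'UTRs run 60–90 nt); 3'UTR = match end to cDNA end.
Reverse-frame homologs partition the reverse complement and are flagged.

## Target prediction

**Alignment/energy scorer.** Local affine-gap complementarity alignment
of the miRNA (3'→5') against the region (5'→3'): Watson–Crick +5, G:U +1,
mismatch −3 (all ×2 at miRNA positions 2–8), gap open −9, extend −4.
These constants are this package's documented defaults — published tools
vary by version — while the acceptance thresholds S ≥ 140 (inclusive) and
ΔG < −17 kcal/mol (strict) are the anchored screening values. ΔG is a
nearest-neighbor sum over consecutive paired stacks in the trace, plus a
duplex initiation penalty (4.09), per-terminal AU/GU penalties (0.45) and
fixed bulge/internal interruption penalties (3.8/3.0). Sites are
extracted best-first and masked, so reported sites never overlap.

**Accessibility scorer.** Seeds of length 6–8 starting at miRNA position
2; 6/7-mers require strict Watson–Crick complement, 8-mers tolerate one
G:U. For each seed the full miRNA is hybridized against a local window
(ΔG_duplex as above) and the opening cost ΔG_open is the constrained
minus unconstrained fold energy of the site's ±70 nt context (≥0 by
construction). ΔΔG = ΔG_duplex + ΔG_open; no ΔΔG cutoff is applied by
default — specificity comes from the consensus step. Overlaps resolve
greedily by ascending ΔΔG.

**Consensus and modes.** A gene×miRNA pair is a target only when both
scorers report it; regions with dual support are recorded in 3'UTR →
CDS → 5'UTR priority. Modes per gene: `single-3UTR` (one miRNA, one
3'UTR site), `multi-miRNA-3UTR` (≥2 miRNAs), `3UTR-plus-CDS` (same miRNA
in both). With non-overlapping gene models, 3'UTR+5'UTR double targets
cannot occur; the pipeline asserts that as a structural check.

## Expression statistics

Quantities interpolate from per-target standard curves
(Cq = slope·log₁₀ q + intercept; slope −3.3219 ⇔ 100% efficiency).
Efficiency is reported but not used to re-correct quantities. Each
target quantity is divided by the geometric mean of the two reference
genes; fold changes are group means over the lowest group mean (the
"lowest expression" calibrator is read as lowest *group mean*, otherwise
group-level folds are undefined). Group differences: one-way ANOVA plus
all-pairs Tukey HSD at α = 0.05; the compact letter display assigns one
letter per maximal clique of the not-significantly-different graph, so
two groups share a letter exactly when the test does not separate them.
The multiple-comparison procedure is a package choice (configurable in
principle to Bonferroni-style pairwise tests). Rank analysis: values are
ranked over the pooled set (average ranks for ties), the tie-corrected
Kruskal–Wallis H is computed on the chosen gene subset, and per-tissue
mean ranks are reported. Degenerate inputs are defined, not errors:
identical values give H = 0, p = 1, and all-identical ANOVA groups give
one shared letter with F reported as NaN.

## Synthetic study

The generator is the package's definition of the study conditions; all
outputs are byte-deterministic functions of `SyntheticConfig`.

* **Genome**: i.i.d. uniform ACGT background (no isochores — keeps decoy
  statistics analyzable), default 30 kb over 2 chromosomes, with 20
  planted precursors: 22 nt mature, reverse-complement arm with 0–2 G:U
  wobbles, 6–12 nt loop, random strand. Each plant is verified in place
  (±60 nt window passes the hairpin call; mature unique in the genome)
  and resampled on failure, so recovery failures downstream indicate
  pipeline defects, not generator bad luck. The first three matures (the
  focal, "egg-predominant" set) are additionally rejection-sampled so
  their reverse complement is stop-codon-free in frame, allowing clean
  CDS site planting.
* **Library**: default 50k reads; per-read category draw — 10% junk, 5%
  adapter dimer, 15% genome-background fragments (15% of those 27–40 nt,
  removed later by the length filter), 15% novel, remainder known.
  Species within knowns/novels are Zipf-weighted (exponent 1.5) to mimic
  the heavy skew of real miRNA libraries; background fragments draw a
  length from the documented 15–26 nt mix *first*, then a species, so
  the read-level length distribution equals the planted mix. Known reads
  suffer isomiR end truncation (rate 0.15) and single substitutions
  (rate 0.05); novel reads are verbatim so the ≥3-copy recovery
  denominator is exact. Reads are adapter-ligated and truncated to 36 nt.
* **Transcripts**: 30 cDNAs = 20–80 nt 5'UTR + CDS (random non-stop
  codons) + 150–300 nt 3'UTR. Perfect-complement sites of the focal
  miRNAs are planted to realize every targeting mode; proteins are exact
  translations of the *final* (site-containing) CDS, so homology recovery
  is guaranteed and partition boundaries are known exactly.
* **qPCR panel**: 10 tissues × 4 replicates; focal miRNA quantity 1
  everywhere, ×50 in egg; references constant; replicate quantities
  log-normal (CV 0.2), Cq noise σ = 0.2 on a slope −3.3219 / intercept
  35 curve; 5-point 10-fold dilution series per target. The slope
  default makes the efficiency closed form exact (10^(1/3.3219) = 2).
* **Expression matrix**: 60 genes × (4 egg + 3 liver + 3 muscle)
  values, log-normal; the 12 planted "target" genes have egg values
  ×0.6 — a deliberately modest effect against σ = 0.5 noise, so the rank
  test exercises the regime where mean ranks, not necessarily p-values,
  carry the signal.

What the generator does **not** emulate: sequencing error profiles, GC
and ligation bias, adapter synthesis errors, transcript secondary
structure shaped by selection, or correlated expression noise. Passing
tests therefore demonstrate algorithmic correctness and planted-signal
recovery under idealized noise, not field performance on real libraries.

## Numerical and engineering choices

* All sequence handling is DNA-alphabet internally; folding treats T as U.
* The folding and duplex-alignment inner loops are numba-compiled;
  results are integer-exact and independent of compilation.
* Fold-change and normalization arithmetic is in linear quantity space;
  Cq noise therefore propagates log-normally, which the tolerance of the
  simulation tests reflects.
* The fold-change calibrator (minimum group mean) is a downward-biased
  estimate of the true minimum under noise, so planted-fold recovery is
  assessed against the mean of non-egg groups rather than the raw
  calibrator fold.
* Problem sizes in the test suite (10k–20k reads, 30 kb genome, ≤12 nt
  enumeration oracles, 100-decoy shuffle experiments) were chosen as the
  smallest scales at which every planted signal is comfortably above
  sampling noise; the full default study (50k reads) runs in seconds.

## Known limitations

* The hairpin criteria are calibrated for near-perfect synthetic stems
  (see above); real pre-miRNAs with large internal loops need looser
  settings and will then admit more shuffle decoys.
* The energy model is a teaching-grade parameterization: no dangling
  ends, no terminal-mismatch terms, no special hairpin loops, linear
  (not logarithmic) loop penalties.
* The translated search is ungapped; frameshifted or intron-containing
  cDNAs will partition incorrectly.
* Multi-mapping tags contribute to a single family; no expectation
  -maximization style rescue is attempted.
* The exclusion-database screen is exact substring matching, not an
  aligner.
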