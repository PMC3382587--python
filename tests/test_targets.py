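"""Duplex alignment, energies, accessibility, consensus and modes."""

import numpy as np
import pytest

import helpers
from ovamir.folding import PARAMS
from ovamir.targets import (
    AccessibilitySite,
    DuplexAlignment,
    align_duplex,
    classify_mode,
    duplex_energy,
    find_seed_matches,
    intersect_targets,
    miranda_scan,
    open_energy,
    passes_miranda,
    pita_scan,
    summarize_targets,
)


class TestAlignDuplex:
    def test_perfect_22mer_scores_145(self, rng):
        m = helpers.random_seq(rng, 22)
        S, trace = align_duplex(m, helpers.revcomp(m))
        # 7 seed positions (2-8) at 2x5 plus 15 positions at 5
        assert S == 7 * 5 * 2 + 15 * 5 == 145
        assert len(trace) == 22

    def test_no_complementarity_scores_zero(self):
        S, trace = align_duplex("A" * 22, "A" * 30)
        assert S == 0.0 and trace == ()

    def test_gu_wobble_scores_one(self):
        # miRNA G against target T pairs as a wobble
        S, trace = align_duplex("GGGGG", "TTTTT")
        # all positions in/near the seed window for a 5-mer
        assert S > 0 and all(mp >= 0 and sp >= 0 for mp, sp in trace)

    def test_matches_exhaustive_trace_enumeration(self, rng):
        for _ in range(12):
            m = helpers.random_seq(rng, 5)
            w = helpers.random_seq(rng, 5)
            S, _ = align_duplex(m, w)
            assert S == helpers.brute_best_duplex_score(m, w), (m, w)

    def test_non_nucleotide_rejected(self):
        with pytest.raises(ValueError):
            align_duplex("ACGX", "ACGT")


class TestDuplexEnergy:
    def test_single_gc_pair_is_initiation_only(self):
        # one paired column, no stacks, no AU-end penalty for G:C
        e = duplex_energy("G", "C", [(0, 0)])
        assert e == pytest.approx(PARAMS["duplex"]["initiation"])

    def test_single_au_pair_adds_terminal_penalty_twice(self):
        e = duplex_energy("A", "T", [(0, 0)])
        init = PARAMS["duplex"]["initiation"]
        au = PARAMS["duplex"]["au_end"]
        assert e == pytest.approx(init + 2 * au)

    def test_fixed_8bp_duplex_matches_manual_nearest_neighbor_sum(self):
        # site GGGGCCCC (5'->3') vs its perfect complement; hand sum from
        # the shipped stacking table
        site = "GGGGCCCC"
        mirna = helpers.revcomp(site)  # GGGGCCCC again (palindrome-ish? no)
        S, trace = align_duplex(mirna, site)
        assert len(trace) == 8
        order = PARAMS["stack"]["order"]
        mat = PARAMS["stack"]["matrix"]

        def stack(p, q):
            return mat[order.index(p)][order.index(q)]

        # pairs along the site 5'->3': G:C x4 then C:G x4
        manual = (3 * stack("GC", "GC") + stack("GC", "CG") + 3 * stack("CG", "CG")
                  + PARAMS["duplex"]["initiation"])
        assert duplex_energy(mirna, site, trace) == pytest.approx(manual)

    def test_perfect_complement_strictly_below_all_substitutions(self, rng):
        for _ in range(20):
            m = helpers.random_seq(rng, 22)
            site = helpers.revcomp(m)
            S0, t0 = align_duplex(m, site)
            d0 = duplex_energy(m, site, t0)
            for pos in range(22):
                for b in "ACGT":
                    if b == site[pos]:
                        continue
                    var = site[:pos] + b + site[pos + 1:]
                    _, tv = align_duplex(m, var)
                    assert duplex_energy(m, var, tv) > d0

    def test_no_pairs_costs_initiation_only(self):
        e = duplex_energy("AAAA", "AAAA", [(0, 0), (1, 1)])
        assert e == pytest.approx(PARAMS["duplex"]["initiation"])


class TestThresholds:
    @pytest.mark.parametrize(
        "S,dG,accepted",
        [
            (139.9, -30.0, False),  # S below the inclusive bound
            (145.0, -17.0, False),  # dG at the strict bound
            (145.0, -17.5, True),
            (140.0, -17.0001, True),  # both bounds exactly honored
        ],
    )
    def test_boundary_semantics(self, S, dG, accepted):
        assert passes_miranda(S, dG) is accepted


class TestMirandaScan:
    def test_planted_perfect_site_found_with_coordinates(self, rng):
        m = helpers.random_seq(rng, 22)
        region = helpers.random_seq(rng, 60) + helpers.revcomp(m) + helpers.random_seq(rng, 60)
        sites = miranda_scan(("mir", m), "g", "3UTR", region)
        assert any(s.site_start == 60 and s.site_end == 82 for s in sites)
        top = sites[0]
        assert top.S >= 140 and top.dG < -17

    def test_sites_never_overlap(self, rng):
        m = helpers.random_seq(rng, 22)
        site = helpers.revcomp(m)
        region = site + "TTTTT" + site + "TTTTT" + site
        sites = miranda_scan(("mir", m), "g", "3UTR", region)
        assert len(sites) == 3
        spans = sorted((s.site_start, s.site_end) for s in sites)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            assert a1 <= b0

    def test_empty_region(self):
        assert miranda_scan(("mir", "ACGT" * 5 + "AC"), "g", "3UTR", "") == []


class TestOpenEnergy:
    def test_zero_on_pair_free_context(self):
        assert open_energy("A" * 50, (20, 30)) == 0.0

    def test_positive_when_site_forms_a_stem(self, rng):
        stem = helpers.random_seq(rng, 12)
        region = ("C" * 20 + stem + "AACAA" + helpers.revcomp(stem) + "C" * 20)
        site = (20, 32)  # the 5' arm of the planted hairpin
        assert open_energy(region, site) > 0

    def test_site_outside_region_errors(self):
        with pytest.raises(ValueError):
            open_energy("ACGT" * 10, (30, 50))


class TestSeedMatches:
    def test_planted_8mer_seed_found(self, rng):
        m = helpers.random_seq(rng, 22)
        seed_site = helpers.revcomp(m[1:9])
        region = "C" * 30 + seed_site + "C" * 30
        hits = find_seed_matches(m, region)
        assert (30, 8, 0) in hits

    def test_wobble_allowed_only_in_8mers(self):
        m = "A" + "G" * 8 + "A" * 13  # seed positions 2-9 are G
        # perfect site: C8; one wobble: a T among the Cs
        region = "A" * 10 + "CCCTCCCC" + "A" * 10
        hits = find_seed_matches(m, region)
        assert any(k == 8 and w == 1 for (_, k, w) in hits)
        # the 6/7-mer windows containing the T never match
        assert all(k == 8 for (_, k, w) in hits if w > 0)

    def test_no_seed_no_sites(self, rng):
        m = "A" * 22
        region = "A" * 80  # T-free: no seed complement anywhere
        assert find_seed_matches(m, region) == []
        assert pita_scan(("mir", m), "g", "3UTR", region) == []


class TestPitaScan:
    def test_unstructured_context_ddG_equals_duplex(self, rng):
        m = "A" * 22
        site = helpers.revcomp(m)  # poly-T site
        region = "C" * 40 + site + "C" * 40  # C/T context cannot pair
        sites = pita_scan(("mir", m), "g", "3UTR", region)
        assert sites, "planted seed site not reported"
        best = min(sites, key=lambda s: s.ddG)
        assert best.dG_open == 0.0
        assert best.ddG == pytest.approx(best.dG_duplex)

    def test_burying_the_site_in_a_stem_worsens_ddG(self, rng):
        m = "C" + "A" * 8 + "A" * 13
        site = helpers.revcomp(m)  # G + T-rich
        open_region = "C" * 40 + site + "C" * 40
        closed_region = "C" * 10 + helpers.revcomp(site) + "CAACA" + site + "C" * 40
        s_open = min(pita_scan(("mir", m), "g", "3UTR", open_region),
                     key=lambda s: s.ddG)
        s_closed = min(pita_scan(("mir", m), "g", "3UTR", closed_region),
                       key=lambda s: s.ddG)
        assert s_closed.dG_open > 0
        assert s_closed.ddG > s_open.ddG


def _dup(gene, mirna="mir1", region="3UTR", start=0):
    return DuplexAlignment(mirna=mirna, mirna_seq="A" * 22, gene=gene,
                           region=region, site_start=start, site_end=start + 22,
                           trace=(), S=145.0, dG=-30.0)


def _acc(gene, mirna="mir1", region="3UTR", start=0):
    return AccessibilitySite(mirna=mirna, gene=gene, region=region,
                             seed_start=start, seed_len=8, site_start=start,
                             site_end=start + 22, dG_duplex=-30.0, dG_open=1.0,
                             ddG=-29.0)


class TestConsensus:
    def test_intersection_of_gene_sets(self):
        cons = intersect_targets([_dup("A"), _dup("B")], [_acc("B"), _acc("C")])
        assert [t.gene for t in cons] == ["B"]

    def test_empty_either_side(self):
        assert intersect_targets([], [_acc("A")]) == []
        assert intersect_targets([_dup("A")], []) == []

    def test_matches_set_algebra_oracle_and_commutes(self, rng):
        genes = [f"g{k}" for k in range(12)]
        mhits = [_dup(g) for g in genes if rng.random() < 0.6]
        phits = [_acc(g) for g in genes if rng.random() < 0.6]
        expected = sorted({h.gene for h in mhits} & {h.gene for h in phits})
        cons = intersect_targets(mhits, phits)
        assert [t.gene for t in cons] == expected
        flipped = intersect_targets(mhits, phits)
        assert [t.gene for t in flipped] == expected

    def test_region_priority_recorded(self):
        cons = intersect_targets(
            [_dup("A", region="CDS"), _dup("A", region="3UTR")],
            [_acc("A", region="3UTR"), _acc("A", region="CDS")])
        assert cons[0].region == "3UTR"
        assert cons[0].regions == ("3UTR", "CDS")


class TestModes:
    def test_single_3utr(self):
        cons = intersect_targets([_dup("A")], [_acc("A")])
        assert classify_mode(cons)["A"] == ["single-3UTR"]

    def test_multi_mirna_3utr(self):
        cons = intersect_targets(
            [_dup("A", "mir1"), _dup("A", "mir2", start=40)],
            [_acc("A", "mir1"), _acc("A", "mir2", start=40)])
        assert classify_mode(cons)["A"] == ["multi-miRNA-3UTR"]

    def test_3utr_plus_cds(self):
        cons = intersect_targets(
            [_dup("A", region="3UTR"), _dup("A", region="CDS")],
            [_acc("A", region="3UTR"), _acc("A", region="CDS")])
        assert "3UTR-plus-CDS" in classify_mode(cons)["A"]

    def test_summary_counts(self):
        cons = intersect_targets(
            [_dup("A"), _dup("B", region="3UTR"), _dup("B", region="CDS")],
            [_acc("A"), _acc("B", region="3UTR"), _acc("B", region="CDS")])
        s = summarize_targets(cons)
        assert s["mir1"]["3UTR"] == 1 and s["mir1"]["3UTR+CDS"] == 1
        assert s["mir1"]["3UTR+5UTR"] == 0
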