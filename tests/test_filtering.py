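"""Read cleaning, junk rules, collapsing and the filter report."""

from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import helpers
from ovamir.filtering import (
    FilterReport,
    SmallRNARead,
    UniqueTag,
    apply_filters,
    collapse_reads,
    is_junk,
    length_histogram,
    run_filter_pipeline,
    trim_adapter,
)

ADAPTER = "TCGTATGCCGTCTTCTGCTTG"
INSERT = "ACGTACGTACGTACGTACGT"


class TestTrimAdapter:
    def test_exact_adapter_suffix_removed(self):
        read = SmallRNARead("r1", INSERT + ADAPTER)
        assert trim_adapter(read, ADAPTER) == INSERT

    def test_adapter_dimer_trims_to_empty(self):
        assert trim_adapter(SmallRNARead("r2", ADAPTER), ADAPTER) == ""

    def test_one_internal_mismatch_tolerated(self):
        mutated = ADAPTER[:4] + ("A" if ADAPTER[4] != "A" else "C") + ADAPTER[5:]
        read = SmallRNARead("r3", INSERT + mutated)
        assert trim_adapter(read, ADAPTER) == INSERT
        # agrees with a naive suffix-alignment scan
        assert helpers.naive_trim(read.sequence, ADAPTER) == INSERT

    def test_truncated_adapter_still_found(self):
        read = SmallRNARead("r4", INSERT + ADAPTER[:8])
        assert trim_adapter(read, ADAPTER) == INSERT

    def test_overlap_below_minimum_keeps_read(self):
        read = SmallRNARead("r5", INSERT + ADAPTER[:4])
        assert trim_adapter(read, ADAPTER) == INSERT + ADAPTER[:4]

    def test_five_prime_adapter_trimmed(self):
        read = SmallRNARead("r6", "GGGAATTCC" + INSERT + ADAPTER)
        assert trim_adapter(read, ADAPTER, adapter5="GGGAATTCC") == INSERT

    def test_non_nucleotide_characters_rejected(self):
        with pytest.raises(ValueError, match="non-ACGTN"):
            trim_adapter(SmallRNARead("r7", "ACGXACGTACGT"), ADAPTER)


@pytest.mark.parametrize(
    "seq,junk,rule",
    [
        ("AAAAAAAAAAAAAAAAAAAA", True, "single-base"),
        ("ACACACACACACACACAC", True, "only A,C"),
        ("ACGTNNACGTACGTACGTN", True, "Ns"),
        ("GTGTGTGTGTTTGGTT", True, "only G,T"),
        ("ACGTTGCAGGTCCAATGCAT", False, ""),  # every rule verified not to fire
        ("AAAAAAAAAAAAAAAAGCGC", True, "single-base"),  # 16/20 = 80% exactly
    ],
)
def test_junk_rules(seq, junk, rule):
    verdict, reason = is_junk(seq)
    assert verdict is junk
    if junk:
        assert rule.split()[0].lower() in reason.lower() or rule in reason


class TestCollapse:
    def test_duplicates_collapse_with_counts(self):
        tags = collapse_reads(
            ["ACGTACGTACGTACG", "ACGTACGTACGTACG", "TTGACCTTGACCTTG"])
        assert {(t.sequence, t.copy_number) for t in tags} == {
            ("ACGTACGTACGTACG", 2), ("TTGACCTTGACCTTG", 1)}

    def test_empty_input(self):
        assert collapse_reads([]) == []

    def test_counts_match_independent_tally(self, rng):
        pool = [helpers.random_seq(rng, 16) for _ in range(40)]
        inserts = [pool[int(rng.integers(0, len(pool)))] for _ in range(1000)]
        tags = collapse_reads(inserts)
        # hash-free tally: sorted-run counting
        runs = Counter()
        for s in sorted(inserts):
            runs[s] += 1
        assert {t.sequence: t.copy_number for t in tags} == dict(runs)
        assert sum(t.copy_number for t in tags) == 1000


class TestApplyFilters:
    def make(self, seq, n):
        return UniqueTag(seq, n)

    def test_copy_number_below_three_removed(self):
        tag = self.make("ACGTTGCAGGTCCAATGCAT", 2)
        survivors, rep = apply_filters([tag])
        assert survivors == [] and rep.copy_number == 2

    def test_length_window_boundaries(self):
        tags = [
            self.make("ACGTTGCAGGTCCA", 10),        # 14 nt -> removed
            self.make("ACGTTGCAGGTCCAT", 10),       # 15 nt -> kept
            self.make("ACGTTGCAGGTCCATGCAGGTCATGC", 10),   # 26 -> kept
            self.make("ACGTTGCAGGTCCATGCAGGTCATGCA", 10),  # 27 -> removed
        ]
        survivors, rep = apply_filters(tags)
        assert {len(t) for t in survivors} == {15, 26}
        assert rep.length == 20

    def test_exclusion_db_substring_hit(self):
        tag = self.make("ACGTTGCAGGTCCAATGCAT", 5)
        db = ["TTTT" + tag.sequence + "GGGG"]
        survivors, rep = apply_filters([tag], exclusion_db=db)
        assert survivors == [] and rep.exclusion_db == 5

    def test_min_len_above_max_len_is_config_error(self):
        with pytest.raises(ValueError):
            apply_filters([], min_len=20, max_len=15)

    def test_idempotent_on_survivors(self, rng):
        tags = [self.make(helpers.random_seq(rng, int(rng.integers(13, 29))),
                          int(rng.integers(1, 9))) for _ in range(200)]
        survivors, _ = apply_filters(tags)
        again, rep = apply_filters(survivors)
        assert again == survivors
        assert rep.rejected_total() == 0


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.lists(st.sampled_from(
    ["ACGTTGCAGGTCCAT", "ACGTTGCAGGTCCAATGCAT", "AAAAAAAAAAAAAAAA",
     "ACGTACGTACGTACG", "TTGACCTTGACCTTGAC"]), max_size=60),
    st.randoms(use_true_random=False))
def test_collapse_and_filter_are_order_invariant(inserts, pyrandom):
    shuffled = list(inserts)
    pyrandom.shuffle(shuffled)
    t1, r1 = apply_filters(collapse_reads(inserts))
    t2, r2 = apply_filters(collapse_reads(shuffled))
    assert t1 == t2
    assert r1.to_dict() == r2.to_dict()


class TestPipelineAccounting:
    def test_every_read_lands_in_exactly_one_bucket(self, rng):
        reads = []
        for k in range(300):
            choice = k % 5
            if choice == 0:
                reads.append(SmallRNARead(f"r{k}", ADAPTER))  # dimer
            elif choice == 1:
                reads.append(SmallRNARead(f"r{k}", "A" * 20 + ADAPTER))  # junk
            elif choice == 2:
                reads.append(SmallRNARead(f"r{k}", "ACGNNACGTACGTACGTACG" + ADAPTER))
            else:
                reads.append(SmallRNARead(
                    f"r{k}", helpers.random_seq(rng, 20) + ADAPTER))
        tags, report = run_filter_pipeline(reads, ADAPTER)
        assert report.is_balanced()
        assert report.input_reads == 300
        assert report.adapter_only == 60
        assert report.junk == 60
        assert report.low_resolution == 60

    def test_low_quality_reads_screened(self):
        good = SmallRNARead("g", "ACGTTGCAGGTCCAATGCAT" + ADAPTER,
                            [35] * len("ACGTTGCAGGTCCAATGCAT" + ADAPTER))
        bad = SmallRNARead("b", "ACGTTGCAGGTCCAATGCAT" + ADAPTER,
                           [10] * len("ACGTTGCAGGTCCAATGCAT" + ADAPTER))
        _, report = run_filter_pipeline([good, bad, good], ADAPTER, min_copy=1)
        assert report.low_resolution == 1
        assert report.surviving_reads == 2


class TestLengthHistogram:
    def test_single_tag(self):
        h = length_histogram([UniqueTag("A" * 22, 5)])
        assert h == {22: (5, 1.0)}

    def test_weighted_fractions(self):
        h = length_histogram([UniqueTag("A" * 21, 3), UniqueTag("C" * 22, 1)])
        assert h[21] == (3, 0.75) and h[22] == (1, 0.25)

    def test_empty(self):
        assert length_histogram([]) == {}

    def test_fractions_sum_to_one(self, rng):
        tags = [UniqueTag(helpers.random_seq(rng, int(rng.integers(15, 27))),
                          int(rng.integers(1, 50))) for _ in range(100)]
        h = length_histogram(tags)
        assert abs(sum(f for _, f in h.values()) - 1.0) < 1e-9


def test_report_roundtrip_formats():
    rep = FilterReport(input_reads=10, junk=3, surviving_reads=7, surviving_tags=4)
    assert "junk\t3" in rep.to_tsv()
    assert rep.to_dict()["surviving_tags"] == 4
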