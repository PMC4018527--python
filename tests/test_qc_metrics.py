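"""Pairing, duplicate marking, insert statistics, edge diagnostics."""

import itertools
import random
from collections import Counter

import pytest

from refless_qc.assembler import Contig
from refless_qc.mapper import Alignment
from refless_qc.qc_metrics import (
    PairAlignment,
    dup_key,
    edge_effect_diagnostic,
    insert_size_stats,
    library_report,
    mark_duplicates,
    pair_up,
)


def aln(contig="c1", start=0, end=100, strand="+", mapped=True, clip_left=0,
        clip_right=0, qual_sum=3700, read_id="r", mate=1):
    return Alignment(
        read_id=read_id, mate_index=mate, contig_id=contig if mapped else None,
        start=start, end=end, strand=strand, mapped=mapped,
        clip_left=clip_left, clip_right=clip_right, read_len=end - start,
        qual_sum=qual_sum,
    )


class TestPairUp:
    def test_fr_outer_distance(self):
        p = pair_up(aln(start=100, end=200, strand="+"),
                    aln(start=300, end=400, strand="-"), "PE")
        assert p.proper and p.orientation == "FR" and p.insert_len == 300

    def test_rf_not_proper_for_pe(self):
        p = pair_up(aln(start=100, end=200, strand="-"),
                    aln(start=300, end=400, strand="+"), "PE")
        assert not p.proper and p.orientation == "RF" and p.insert_len is None

    def test_rf_proper_for_mp(self):
        p = pair_up(aln(start=100, end=200, strand="-"),
                    aln(start=2500, end=2600, strand="+"), "MP")
        assert p.proper and p.insert_len == 2500

    def test_unmapped_mate(self):
        p = pair_up(aln(), aln(mapped=False), "PE")
        assert not p.proper and p.insert_len is None and p.orientation == "NA"

    def test_different_contigs(self):
        p = pair_up(aln(contig="c1"), aln(contig="c2", strand="-"), "PE")
        assert not p.proper

    def test_tandem_orientation(self):
        p = pair_up(aln(start=0, end=100), aln(start=200, end=300), "PE")
        assert p.orientation == "TANDEM" and not p.proper

    def test_clips_extend_insert(self):
        # soft-clipped edge alignments still yield the unclipped outer span
        p = pair_up(
            aln(start=0, end=80, strand="+", clip_left=20),
            aln(start=180, end=280, strand="-"),
            "PE",
        )
        assert p.proper and p.insert_len == 280 - (0 - 20)


def make_pair(pid, c1="c1", p1=0, s1="+", c2="c1", p2=300, s2="-", qual=3700):
    a1 = aln(contig=c1, start=p1, end=p1 + 100, strand=s1, qual_sum=qual // 2,
             read_id=f"{pid}/1")
    a2 = aln(contig=c2, start=p2, end=p2 + 100, strand=s2, qual_sum=qual - qual // 2,
             read_id=f"{pid}/2", mate=2)
    return pair_up(a1, a2, "PE", pair_id=pid)


def bruteforce_duplicate_count(pairs):
    """O(n^2) oracle: count pairs sharing a key with an earlier-grouped pair."""
    seen = []
    marked = 0
    for p in pairs:
        if not p.both_mapped:
            continue
        seen.append(p)
    groups = []
    for p in seen:
        for g in groups:
            if dup_key(g[0]) == dup_key(p):
                g.append(p)
                break
        else:
            groups.append([p])
    return sum(len(g) - 1 for g in groups if len(g) > 1)


class TestMarkDuplicates:
    def test_two_identical_pairs(self):
        pairs = [make_pair("a"), make_pair("b")]
        flags, n = mark_duplicates(pairs)
        assert n == 1 and sum(flags) == 1

    def test_single_pair_never_marked(self):
        flags, n = mark_duplicates([make_pair("a")])
        assert n == 0 and flags == [False]

    def test_strand_pattern_distinguishes(self):
        pairs = [make_pair("a", s1="+", s2="-"), make_pair("b", s1="-", s2="+")]
        _, n = mark_duplicates(pairs)
        assert n == 0

    def test_mate_swap_shares_key(self):
        p1 = make_pair("a", p1=0, s1="+", p2=300, s2="-")
        p2 = pair_up(
            aln(start=300, end=400, strand="-", read_id="b/1"),
            aln(start=0, end=100, strand="+", read_id="b/2", mate=2),
            "PE", pair_id="b",
        )
        _, n = mark_duplicates([p1, p2])
        assert n == 1

    def test_highest_quality_retained(self):
        pairs = [make_pair("low", qual=1000), make_pair("high", qual=5000)]
        flags, _ = mark_duplicates(pairs)
        assert flags == [True, False]

    def test_unmapped_pairs_never_marked(self):
        p = pair_up(aln(mapped=False), aln(mapped=False), "PE", pair_id="x")
        flags, n = mark_duplicates([p, p])
        assert n == 0

    def test_matches_bruteforce_oracle_on_random_instances(self):
        rnd = random.Random(1234)
        for trial in range(20):
            pairs = []
            for i in range(rnd.randint(1, 200)):
                pairs.append(
                    make_pair(
                        f"p{i}",
                        c1=rnd.choice(["c1", "c2"]),
                        p1=rnd.randrange(0, 5) * 100,
                        s1=rnd.choice("+-"),
                        c2=rnd.choice(["c1", "c2"]),
                        p2=rnd.randrange(0, 5) * 100,
                        s2=rnd.choice("+-"),
                        qual=rnd.randrange(1000, 5000),
                    )
                )
            _, n = mark_duplicates(pairs)
            assert n == bruteforce_duplicate_count(pairs), f"trial {trial}"

    def test_permutation_invariant_count(self):
        rnd = random.Random(7)
        pairs = [
            make_pair(f"p{i}", p1=rnd.randrange(0, 3) * 100, p2=rnd.randrange(3, 6) * 100)
            for i in range(50)
        ]
        _, n0 = mark_duplicates(pairs)
        shuffled = pairs[:]
        rnd.shuffle(shuffled)
        _, n1 = mark_duplicates(shuffled)
        assert n0 == n1


class TestSingleEndDuplicates:
    def test_same_five_prime_and_strand_marked(self):
        a = aln(start=0, end=100, read_id="a")
        b = aln(start=0, end=100, read_id="b")
        c = aln(start=0, end=100, strand="-", read_id="c")  # other strand
        from refless_qc.qc_metrics import mark_duplicates_single

        flags, n = mark_duplicates_single([a, b, c])
        assert n == 1 and flags == [False, True, False]

    def test_clip_aware_five_prime(self):
        # a left-clipped forward read shares its 5' unclipped coordinate
        from refless_qc.qc_metrics import mark_duplicates_single

        a = aln(start=10, end=100, read_id="a")
        b = aln(start=20, end=100, clip_left=10, read_id="b")
        _, n = mark_duplicates_single([a, b])
        assert n == 1


def test_strict_mode_excludes_multimapped_pairs():
    clean = make_pair("a")
    multi = make_pair("b", p1=100, p2=400)
    multi.aln1.multimapped = True
    rep = library_report([clean, multi], exclude_multimapped=True)
    assert rep.n_reads_total == 2 and rep.n_reads_mapped == 2
    rep_default = library_report([clean, multi])
    assert rep_default.n_reads_mapped == 4


def proper_pairs_with_inserts(inserts):
    out = []
    for i, ins in enumerate(inserts):
        out.append(
            pair_up(
                aln(start=0, end=100, strand="+", read_id=f"i{i}/1"),
                aln(start=ins - 100, end=ins, strand="-", read_id=f"i{i}/2", mate=2),
                "PE", pair_id=f"i{i}",
            )
        )
    return out


class TestInsertStats:
    def test_constant_inserts(self):
        st = insert_size_stats(proper_pairs_with_inserts([300, 300, 300]))
        assert st.mean == 300 and st.sd == 0

    def test_symmetric_inserts(self):
        st = insert_size_stats(proper_pairs_with_inserts([290] * 100 + [310] * 100))
        assert st.mean == pytest.approx(300)

    def test_outlier_excluded_under_degenerate_mad(self):
        st = insert_size_stats(proper_pairs_with_inserts([300] * 1000 + [50000]))
        assert st.mean == pytest.approx(300)
        assert st.n_core == 1000
        assert st.histogram[50000] == 1  # full histogram keeps the outlier

    def test_too_few_pairs_warns(self):
        with pytest.warns(UserWarning):
            st = insert_size_stats(proper_pairs_with_inserts([300]))
        assert st.mean is None


class TestEdgeEffectDiagnostic:
    def test_expected_mappable_small_contig(self):
        frac, expected = edge_effect_diagnostic([], [Contig("c", "A" * 150)], 100)
        assert expected == pytest.approx(51 / 150)

    def test_expected_mappable_limit(self):
        _, expected = edge_effect_diagnostic([], [Contig("c", "A" * 1_000_000)], 100)
        assert expected > 0.999

    def test_interior_reads_no_edge_unmapped(self):
        alns = [aln(read_id=f"r{i}") for i in range(10)]
        frac, _ = edge_effect_diagnostic(alns, [Contig("c", "A" * 1000)], 100)
        assert frac == 0.0

    def test_edge_unmapped_counted(self):
        alns = [aln(), Alignment("x", mapped=False, edge_overhang=40, read_len=100)]
        frac, _ = edge_effect_diagnostic(alns, [Contig("c", "A" * 1000)], 100)
        assert frac == 0.5


class TestLibraryReport:
    def test_basic_counts(self):
        pairs = [make_pair(f"p{i}", p2=300 + i) for i in range(10)]
        rep = library_report(pairs, library="lib")
        assert rep.n_reads_total == 20 and rep.n_reads_mapped == 20
        assert rep.pct_mapped == 100.0
        assert rep.n_proper_pairs == 10

    def test_duplicate_percentage(self):
        pairs = [make_pair("a"), make_pair("b")]  # identical coordinates
        rep = library_report(pairs)
        assert rep.n_dup_reads == 2
        assert rep.pct_dup == pytest.approx(50.0)

    def test_zero_reads_no_division_error(self):
        rep = library_report([], n_reads_total=0)
        assert rep.pct_mapped == 0.0 and rep.pct_dup == 0.0
        assert rep.insert_mean is None

    def test_serializes_to_table_row(self):
        rep = library_report([make_pair("a", p2=250), make_pair("b", p2=300),
                              make_pair("c", p2=350)])
        d = rep.as_dict()
        for col in ("n_reads_mapped", "pct_mapped", "n_dup_reads", "pct_dup",
                    "insert_mean", "insert_sd"):
            assert col in d
        assert d["insert_histogram"] == {350: 1, 400: 1, 450: 1}
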