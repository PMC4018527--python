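"""Seed-and-extend mapping, contig-edge policies and SAM round trips."""

import numpy as np
import pytest

from refless_qc.assembler import Contig
from refless_qc._kmers import revcomp
from refless_qc.mapper import (
    MapperParams,
    SeedIndex,
    map_pairs,
    map_read,
    map_reads,
    read_sam,
    write_sam,
)

from .conftest import make_read, random_seq


@pytest.fixture(scope="module")
def contig():
    rng = np.random.default_rng(7)
    return Contig("contig_0", random_seq(rng, 500))


@pytest.fixture(scope="module")
def index(contig):
    return SeedIndex([contig], seed_len=31)


class TestSeedIndex:
    def test_self_lookup(self, contig, index):
        assert index.lookup(contig.seq[:31]) == [("contig_0", 0, "+")]

    def test_absent_kmer(self, index):
        hits = index.lookup("A" * 31)
        assert hits == [] or all(h[0] != "missing" for h in hits)

    def test_absent_kmer_strict(self, contig):
        # an index over a repeat-free contig never contains a poly-A seed
        idx = SeedIndex([Contig("c", "ACGT" * 30)], seed_len=31)
        assert idx.lookup("A" * 31) == []

    def test_duplicate_kmer_multiplicity(self):
        rng = np.random.default_rng(3)
        block = random_seq(rng, 40)
        idx = SeedIndex([Contig("c", block + "T" * 10 + block)], seed_len=31)
        assert len(idx.lookup(block[:31])) == 2

    def test_reverse_strand_lookup(self, contig, index):
        assert index.lookup(revcomp(contig.seq[:31])) == [("contig_0", 0, "-")]

    def test_seed_longer_than_contigs(self):
        with pytest.raises(ValueError, match="seed_len"):
            SeedIndex([Contig("c", "ACGT" * 5)], seed_len=31)

    def test_empty_contigs(self):
        with pytest.raises(ValueError):
            SeedIndex([], seed_len=31)


class TestMapRead:
    def test_exact_interior_substring(self, contig, index):
        read = make_read(contig.seq[100:200])
        aln = map_read(read, index)
        assert aln.mapped and aln.contig_id == "contig_0"
        assert (aln.start, aln.end) == (100, 200)
        assert aln.strand == "+" and aln.n_mismatches == 0

    def test_reverse_strand_read(self, contig, index):
        aln = map_read(make_read(revcomp(contig.seq[100:200])), index)
        assert aln.mapped and (aln.start, aln.end) == (100, 200)
        assert aln.strand == "-"

    def test_edge_overhang_unmapped_policy(self, contig, index):
        read = make_read(contig.seq[-60:] + "A" * 40)
        aln = map_read(read, index, MapperParams(edge_policy="unmapped"))
        assert not aln.mapped
        assert aln.edge_overhang == 40

    def test_edge_overhang_clip_policy(self, contig, index):
        read = make_read(contig.seq[-60:] + "A" * 40)
        aln = map_read(read, index, MapperParams(edge_policy="clip"))
        assert aln.mapped and aln.clip_right == 40 and aln.clip_left == 0
        assert aln.end == contig.length
        assert aln.unclipped_end == contig.length + 40

    def test_left_edge_clip(self, contig, index):
        read = make_read("G" * 30 + contig.seq[:70])
        aln = map_read(read, index, MapperParams(edge_policy="clip"))
        assert aln.mapped and aln.clip_left == 30 and aln.start == 0
        assert aln.unclipped_start == -30

    def test_mismatch_budget(self, contig, index):
        base = list(contig.seq[100:200])
        for i in (40, 50, 60):
            base[i] = "A" if base[i] != "A" else "C"
        aln = map_read(make_read("".join(base)), index)
        assert aln.mapped and aln.n_mismatches == 3
        for i in (10, 70):
            base[i] = "A" if base[i] != "A" else "C"
        aln = map_read(make_read("".join(base)), index)  # 5 > 4% of 100
        assert not aln.mapped

    def test_mismatch_count_matches_reconstruction(self, contig, index, rng):
        for _ in range(20):
            start = int(rng.integers(0, 400))
            base = list(contig.seq[start : start + 100])
            for i in rng.choice(100, size=int(rng.integers(0, 4)), replace=False):
                base[i] = "ACGT"[int(rng.integers(0, 4))]
            aln = map_read(make_read("".join(base)), index)
            if not aln.mapped:
                continue
            ref = contig.seq[aln.start : aln.end]
            query = "".join(base) if aln.strand == "+" else revcomp("".join(base))
            clipped = query[aln.clip_left : len(query) - aln.clip_right]
            assert sum(a != b for a, b in zip(ref, clipped)) == aln.n_mismatches

    def test_unmappable_read(self, index):
        aln = map_read(make_read("ACGT" * 25), index)
        assert not aln.mapped and aln.contig_id is None


class TestMapBatchProperties:
    @pytest.fixture(scope="class")
    @staticmethod
    def sim_reads(contig):
        rng = np.random.default_rng(11)
        reads = []
        for i in range(300):
            start = int(rng.integers(0, contig.length - 100 + 1))
            seq = list(contig.seq[start : start + 100])
            for j in rng.choice(100, size=int(rng.integers(0, 5)), replace=False):
                seq[j] = "ACGT"[int(rng.integers(0, 4))]
            s = "".join(seq)
            if rng.integers(0, 2):
                s = revcomp(s)
            reads.append(make_read(s, read_id=f"r{i}"))
        return reads

    def test_mapping_rate_monotone_in_mismatch_budget(self, sim_reads, index):
        rates = []
        for frac in (0.0, 0.01, 0.02, 0.04):
            alns = map_reads(sim_reads, index, MapperParams(max_mismatch_frac=frac))
            rates.append(sum(a.mapped for a in alns))
        assert rates == sorted(rates)

    def test_error_free_reads_all_map_to_origin(self, contig, index):
        reads = [make_read(contig.seq[s : s + 100], read_id=f"e{s}") for s in range(0, 400, 13)]
        alns = map_reads(reads, index)
        assert all(a.mapped and a.n_mismatches == 0 for a in alns)
        assert [a.start for a in alns] == list(range(0, 400, 13))

    def test_unmapped_policy_never_maps_more(self, sim_reads, contig, index):
        pieces = [Contig(f"f{i}", contig.seq[i : i + 150]) for i in range(0, 450, 150)]
        pidx = SeedIndex(pieces, seed_len=31)
        n_clip = sum(a.mapped for a in map_reads(sim_reads, pidx, MapperParams(edge_policy="clip")))
        n_unm = sum(
            a.mapped for a in map_reads(sim_reads, pidx, MapperParams(edge_policy="unmapped"))
        )
        assert n_unm <= n_clip

    def test_strided_seeding_subset_of_exhaustive(self, sim_reads, index):
        # stride-7 seeding can only lose placements relative to querying
        # every k-mer; wherever it maps, the placement must agree exactly
        a1 = map_reads(sim_reads, index, MapperParams(seed_stride=1))
        a7 = map_reads(sim_reads, index, MapperParams(seed_stride=7))
        assert sum(a.mapped for a in a7) <= sum(a.mapped for a in a1)
        for full, strided in zip(a1, a7):
            if strided.mapped:
                assert (full.contig_id, full.start, full.strand) == (
                    strided.contig_id, strided.start, strided.strand
                )


class TestMapPairs:
    def test_fr_pair_same_contig(self, contig, index):
        r1 = make_read(contig.seq[100:200], read_id="p/1", mate=1)
        r2 = make_read(revcomp(contig.seq[300:400]), read_id="p/2", mate=2)
        (a1, a2), = map_pairs([(r1, r2)], index)
        assert a1.mapped and a2.mapped
        assert a1.contig_id == a2.contig_id
        assert (a1.strand, a2.strand) == ("+", "-")

    def test_foreign_mate_unmapped(self, contig, index, rng):
        r1 = make_read(contig.seq[0:100], read_id="p/1", mate=1)
        r2 = make_read(random_seq(rng, 100), read_id="p/2", mate=2)
        (a1, a2), = map_pairs([(r1, r2)], index)
        assert a1.mapped and not a2.mapped

    def test_empty_input(self, index):
        assert map_pairs([], index) == []


class TestSamRoundTrip:
    def test_coordinates_survive(self, contig, index, tmp_path):
        r1 = make_read(contig.seq[50:150], read_id="p/1", mate=1)
        r2 = make_read(revcomp(contig.seq[250:350]), read_id="p/2", mate=2)
        r3 = make_read(contig.seq[-60:] + "A" * 40, read_id="q/1", mate=1)
        r4 = make_read("T" * 100, read_id="q/2", mate=2)
        pairs = [(r1, r2), (r3, r4)]
        alns = map_pairs(pairs, index)
        path = tmp_path / "out.sam"
        write_sam(path, pairs, alns, [contig])
        back = read_sam(path)
        assert len(back) == 2
        for (a1, a2), (b1, b2) in zip(alns, back):
            for a, b in ((a1, b1), (a2, b2)):
                assert a.mapped == b.mapped
                if a.mapped:
                    assert (a.contig_id, a.start, a.end, a.strand) == (
                        b.contig_id, b.start, b.end, b.strand,
                    )
                    assert (a.clip_left, a.clip_right, a.n_mismatches) == (
                        b.clip_left, b.clip_right, b.n_mismatches,
                    )
                assert a.qual_sum == b.qual_sum
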