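"""Seed-and-extend read mapping back onto draft contigs, plus SAM I/O.

The mapper is intentionally simple: exact seed lookup of every
``seed_len``-mer of the read on both strands, ungapped extension of each
candidate placement, acceptance when the mismatch count stays within
``max_mismatch_frac`` of the read length. Placements that run past a
contig end are either soft-clipped (``edge_policy="clip"``, the default
for QC) or reported unmapped with the overhang recorded
(``edge_policy="unmapped"``, mirroring how BWA treats reads spanning
concatenated-reference junctions, which is what biases QC metrics on
fragmented assemblies).

Alignments round-trip through SAM via pysam, so externally produced SAM
can substitute for the internal mapper anywhere alignments are consumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._kmers import revcomp, seq_kmer_codes
from .assembler import Contig
from .io_preprocess import ReadRecord

__all__ = [
    "Alignment",
    "MapperParams",
    "SeedIndex",
    "build_index",
    "map_read",
    "map_reads",
    "map_pairs",
    "write_sam",
    "read_sam",
]


@dataclass(slots=True)
class Alignment:
    """Ungapped placement of one read on one contig (0-based half-open)."""

    read_id: str
    mate_index: int | None = None
    contig_id: str | None = None
    start: int = 0
    end: int = 0
    strand: str = "+"
    n_mismatches: int = 0
    clip_left: int = 0
    clip_right: int = 0
    mapped: bool = False
    edge_overhang: int = 0
    multimapped: bool = False
    read_len: int = 0
    qual_sum: int = 0

    @property
    def unclipped_start(self) -> int:
        return self.start - self.clip_left

    @property
    def unclipped_end(self) -> int:
        return self.end + self.clip_right

    @property
    def five_prime(self) -> int:
        """5' unclipped coordinate (duplicate-marking anchor)."""
        return self.unclipped_start if self.strand == "+" else self.unclipped_end

    @property
    def aligned_len(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, slots=True)
class MapperParams:
    """Seeding/extension settings.

    ``seed_stride`` samples seed start offsets every that many bases
    (the final window is always included), which preserves detection of
    every placement with an error-free stretch of ``seed_len`` bases at
    a sampled offset; stride 1 queries every read k-mer.
    """

    seed_len: int = 31
    max_mismatch_frac: float = 0.04
    edge_policy: str = "clip"
    seed_stride: int = 7
    max_candidates: int = 100  # per read per strand, repeat guard

    def __post_init__(self):
        if not (0 <= self.max_mismatch_frac < 0.5):
            raise ValueError("max_mismatch_frac must be in [0, 0.5)")
        if self.edge_policy not in ("clip", "unmapped"):
            raise ValueError("edge_policy must be 'clip' or 'unmapped'")
        if not (1 <= self.seed_len <= 32):
            raise ValueError("seed_len must be in [1, 32]")
        if self.seed_stride < 1:
            raise ValueError("seed_stride must be >= 1")


class SeedIndex:
    """Exact-match lookup from every seed_len-mer of every contig."""

    def __init__(self, contigs: Sequence[Contig], seed_len: int = 31):
        if not contigs:
            raise ValueError("contigs must be nonempty")
        if seed_len > max(c.length for c in contigs):
            raise ValueError("seed_len exceeds the longest contig")
        self.seed_len = seed_len
        self.contigs = list(contigs)
        self.contig_ids = [c.contig_id for c in contigs]
        self.seqs = [c.seq for c in contigs]
        starts = np.zeros(len(contigs) + 1, dtype=np.int64)
        np.cumsum([len(c.seq) + 1 for c in contigs], out=starts[1:])
        self._starts = starts[:-1]
        big = "N".join(self.seqs)
        kc, kv = seq_kmer_codes(big, seed_len)
        gpos = np.flatnonzero(kv)
        codes = kc[gpos]
        cid = np.searchsorted(self._starts, gpos, side="right") - 1
        lpos = gpos - self._starts[cid]
        order = np.argsort(codes, kind="stable")
        self.codes = codes[order]
        self.cid = cid[order].astype(np.int32)
        self.pos = lpos[order].astype(np.int64)

    def lookup(self, seq: str) -> list[tuple[str, int, str]]:
        """Positions of an exact seed match, both strands, multiplicity kept."""
        if len(seq) != self.seed_len:
            raise ValueError("query length must equal seed_len")
        out = []
        for strand, q in (("+", seq), ("-", revcomp(seq))):
            kc, kv = seq_kmer_codes(q, self.seed_len)
            if kc.size == 0 or not kv[0]:
                continue
            lo = np.searchsorted(self.codes, kc[0], side="left")
            hi = np.searchsorted(self.codes, kc[0], side="right")
            for i in range(lo, hi):
                out.append((self.contig_ids[self.cid[i]], int(self.pos[i]), strand))
        return out


def build_index(contigs: Sequence[Contig], seed_len: int = 31) -> SeedIndex:
    return SeedIndex(contigs, seed_len)


def _candidates_for_chunk(reads, index: SeedIndex, params: MapperParams):
    """Vectorized seeding: (read_idx, strand, cid, start) candidate rows."""
    sl = index.seed_len
    rows = []
    for strand_code, seqs in (
        (0, [r.bases for r in reads]),
        (1, [revcomp(r.bases) for r in reads]),
    ):
        lens = np.array([len(s) for s in seqs], dtype=np.int64)
        starts = np.zeros(len(seqs) + 1, dtype=np.int64)
        np.cumsum(lens + 1, out=starts[1:])
        starts = starts[:-1]
        big = "N".join(seqs)
        kc, kv = seq_kmer_codes(big, sl)
        gpos = np.flatnonzero(kv)
        if params.seed_stride > 1 and gpos.size:
            r0 = np.searchsorted(starts, gpos, side="right") - 1
            off0 = gpos - starts[r0]
            sel = (off0 % params.seed_stride == 0) | (off0 == lens[r0] - sl)
            gpos = gpos[sel]
        q = kc[gpos]
        lo = np.searchsorted(index.codes, q, side="left")
        hi = np.searchsorted(index.codes, q, side="right")
        cnt = hi - lo
        hitq = cnt > 0
        if not hitq.any():
            continue
        gpos, lo, cnt = gpos[hitq], lo[hitq], cnt[hitq]
        total = int(cnt.sum())
        # expand [lo, lo+cnt) ranges
        rep = np.repeat(np.arange(gpos.size), cnt)
        offs = np.arange(total) - np.repeat(np.cumsum(cnt) - cnt, cnt)
        ii = lo[rep] + offs
        g = gpos[rep]
        ridx = np.searchsorted(starts, g, side="right") - 1
        off = g - starts[ridx]
        cid = index.cid[ii].astype(np.int64)
        cstart = index.pos[ii] - off
        rows.append(
            np.stack([ridx, np.full(total, strand_code, dtype=np.int64), cid, cstart])
        )
    if not rows:
        return np.empty((4, 0), dtype=np.int64)
    allrows = np.concatenate(rows, axis=1)
    order = np.lexsort((allrows[3], allrows[2], allrows[1], allrows[0]))
    allrows = allrows[:, order]
    keep = np.concatenate(([True], (np.diff(allrows, axis=1) != 0).any(axis=0)))
    return allrows[:, keep]


def _extend(read: ReadRecord, cands, index: SeedIndex, params: MapperParams) -> Alignment:
    """Evaluate dedup'd candidates of one read and pick the best placement."""
    L = len(read.bases)
    budget = int(params.max_mismatch_frac * L)
    qual_sum = int(sum(read.quals))
    rc = None
    best = None  # (mm, cid_str, start, strand, qs, qe)
    n_best = 0
    best_edge_overhang = 0
    evaluated = 0
    for strand_code, cid, start in cands:
        if evaluated >= params.max_candidates * 2:
            break
        evaluated += 1
        seq = index.seqs[cid]
        clen = len(seq)
        qs = max(0, -start)
        qe = min(L, clen - start)
        if qe - qs < index.seed_len:
            continue
        if strand_code == 1 and rc is None:
            rc = revcomp(read.bases)
        q = read.bases if strand_code == 0 else rc
        qsub = q[qs:qe]
        ssub = seq[start + qs : start + qe]
        if qsub == ssub:
            mm = 0
        else:
            mm = sum(a != b for a, b in zip(qsub, ssub))
            if mm > budget:
                continue
        overhang = qs + (L - qe)
        if overhang and params.edge_policy == "unmapped":
            best_edge_overhang = max(best_edge_overhang, overhang)
            continue
        strand = "+" if strand_code == 0 else "-"
        key = (mm, index.contig_ids[cid], start, strand)
        if best is None or key[:1] < best[:1]:
            best = (*key, qs, qe)
            n_best = 1
        elif key[0] == best[0]:
            n_best += 1
            if key < best[:4]:
                best = (*key, qs, qe)
    if best is None:
        return Alignment(
            read_id=read.read_id,
            mate_index=read.mate_index,
            mapped=False,
            edge_overhang=best_edge_overhang,
            read_len=L,
            qual_sum=qual_sum,
        )
    mm, cid_str, start, strand, qs, qe = best
    return Alignment(
        read_id=read.read_id,
        mate_index=read.mate_index,
        contig_id=cid_str,
        start=start + qs,
        end=start + qe,
        strand=strand,
        n_mismatches=mm,
        clip_left=qs,
        clip_right=L - qe,
        mapped=True,
        edge_overhang=qs + (L - qe),
        multimapped=n_best > 1,
        read_len=L,
        qual_sum=qual_sum,
    )


def map_reads(
    reads: Sequence[ReadRecord],
    index: SeedIndex,
    params: MapperParams | None = None,
    chunk_size: int = 100_000,
) -> list[Alignment]:
    """Map a batch of reads; one Alignment per read, input order kept."""
    params = params or MapperParams()
    out: list[Alignment] = []
    for base in range(0, len(reads), chunk_size):
        chunk = reads[base : base + chunk_size]
        rows = _candidates_for_chunk(chunk, index, params)
        ridx = rows[0]
        bounds = np.searchsorted(ridx, np.arange(len(chunk) + 1))
        for i, read in enumerate(chunk):
            cands = rows[1:, bounds[i] : bounds[i + 1]].T.tolist()
            if len(read.bases) < index.seed_len:
                out.append(
                    Alignment(read.read_id, read.mate_index, mapped=False,
                              read_len=len(read.bases), qual_sum=int(sum(read.quals)))
                )
            else:
                out.append(_extend(read, cands, index, params))
    return out


def map_read(read: ReadRecord, index: SeedIndex, params: MapperParams | None = None) -> Alignment:
    return map_reads([read], index, params)[0]


def map_pairs(
    pairs: Sequence[tuple[ReadRecord, ReadRecord]],
    index: SeedIndex,
    params: MapperParams | None = None,
) -> list[tuple[Alignment, Alignment]]:
    """Map each mate independently; pair-level calls happen downstream."""
    flat: list[ReadRecord] = []
    for r1, r2 in pairs:
        flat.append(r1)
        flat.append(r2)
    alns = map_reads(flat, index, params)
    return [(alns[2 * i], alns[2 * i + 1]) for i in range(len(pairs))]


# ---------------------------------------------------------------------------
# SAM interchange (pysam)
# ---------------------------------------------------------------------------

def _sam_header(contigs: Sequence[Contig]) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c.contig_id, "LN": c.length} for c in contigs],
    }


def write_sam(
    dest,
    pairs: Sequence[tuple[ReadRecord, ReadRecord]],
    alignments: Sequence[tuple[Alignment, Alignment]],
    contigs: Sequence[Contig],
) -> None:
    """Write mate pairs and their alignments as SAM (soft clips, NM tags)."""
    import pysam

    header = pysam.AlignmentHeader.from_dict(_sam_header(contigs))
    ref_ids = {c.contig_id: i for i, c in enumerate(contigs)}
    with pysam.AlignmentFile(str(dest), "w", header=header) as fh:
        for (r1, r2), (a1, a2) in zip(pairs, alignments):
            for read, aln, mate_aln, first in ((r1, a1, a2, True), (r2, a2, a1, False)):
                seg = pysam.AlignedSegment(header)
                seg.query_name = _base_name(read.read_id)
                flag = 0x1 | (0x40 if first else 0x80)
                rev = aln.mapped and aln.strand == "-"
                mate_rev = mate_aln.mapped and mate_aln.strand == "-"
                if not aln.mapped:
                    flag |= 0x4
                if not mate_aln.mapped:
                    flag |= 0x8
                if rev:
                    flag |= 0x10
                if mate_rev:
                    flag |= 0x20
                seg.flag = flag
                seq = read.bases if not rev else revcomp(read.bases)
                quals = read.quals if not rev else read.quals[::-1]
                seg.query_sequence = seq
                seg.query_qualities = list(quals)
                if aln.mapped:
                    seg.reference_id = ref_ids[aln.contig_id]
                    seg.reference_start = aln.start
                    seg.mapping_quality = 0 if aln.multimapped else 60
                    cigar = []
                    if aln.clip_left:
                        cigar.append((4, aln.clip_left))
                    cigar.append((0, aln.aligned_len))
                    if aln.clip_right:
                        cigar.append((4, aln.clip_right))
                    seg.cigartuples = cigar
                    seg.set_tag("NM", aln.n_mismatches)
                else:
                    seg.reference_id = -1
                    seg.reference_start = -1
                if mate_aln.mapped:
                    seg.next_reference_id = ref_ids[mate_aln.contig_id]
                    seg.next_reference_start = mate_aln.start
                fh.write(seg)


def _base_name(read_id: str) -> str:
    return read_id[:-2] if read_id.endswith(("/1", "/2")) else read_id


def read_sam(source) -> list[tuple[Alignment, Alignment]]:
    """Load primary paired alignments from SAM into Alignment pairs.

    Accepts SAM from this package or from an external mapper; soft clips
    come from the CIGAR, mismatches from the NM tag when present.
    """
    import pysam

    by_name: dict[str, dict[int, Alignment]] = {}
    order: list[str] = []
    with pysam.AlignmentFile(str(source), "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_secondary or seg.is_supplementary:
                continue
            mate = 2 if seg.is_read2 else 1
            aln = _segment_to_alignment(seg, mate)
            slot = by_name.get(seg.query_name)
            if slot is None:
                slot = {}
                by_name[seg.query_name] = slot
                order.append(seg.query_name)
            slot[mate] = aln
    out = []
    for name in order:
        slot = by_name[name]
        a1 = slot.get(1) or Alignment(read_id=name, mate_index=1)
        a2 = slot.get(2) or Alignment(read_id=name, mate_index=2)
        out.append((a1, a2))
    return out


def _segment_to_alignment(seg, mate: int) -> Alignment:
    quals = seg.query_qualities
    qual_sum = int(sum(quals)) if quals is not None else 0
    read_len = seg.query_length or (len(seg.query_sequence) if seg.query_sequence else 0)
    if seg.is_unmapped:
        return Alignment(read_id=seg.query_name, mate_index=mate, mapped=False,
                         read_len=read_len, qual_sum=qual_sum)
    clip_left = clip_right = 0
    if seg.cigartuples:
        if seg.cigartuples[0][0] in (4, 5):
            clip_left = seg.cigartuples[0][1]
        if len(seg.cigartuples) > 1 and seg.cigartuples[-1][0] in (4, 5):
            clip_right = seg.cigartuples[-1][1]
    nm = seg.get_tag("NM") if seg.has_tag("NM") else 0
    return Alignment(
        read_id=seg.query_name,
        mate_index=mate,
        contig_id=seg.reference_name,
        start=seg.reference_start,
        end=seg.reference_end,
        strand="-" if seg.is_reverse else "+",
        n_mismatches=int(nm),
        clip_left=clip_left,
        clip_right=clip_right,
        mapped=True,
        multimapped=seg.mapping_quality == 0,
        read_len=read_len,
        qual_sum=qual_sum,
    )
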