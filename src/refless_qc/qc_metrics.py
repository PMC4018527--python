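"""Reference-free library QC metrics from pair alignments.

Implements the mapping-rate / PCR-duplicate / insert-size metrics that a
reference-based pipeline would obtain from BWA + Picard + samtools, but
computed directly from :class:`~refless_qc.mapper.Alignment` pairs
against a draft assembly:

* pairing and orientation calls (FR for paired-end, RF for mate-pair),
  with the insert length measured as the outer distance between the
  mates' unclipped coordinates;
* pair-based duplicate marking on the 5' unclipped outer coordinates and
  strands of both mates (the retained copy is the one with the highest
  summed base quality);
* insert-size mean/SD over a robust core of the distribution (median
  +/- 10 MAD, with a +/-10%-of-median fallback when the MAD degenerates
  to zero) plus the full histogram;
* a contig-edge diagnostic quantifying how assembly fragmentation
  removes mappable read placements.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .assembler import Contig
from .mapper import Alignment

__all__ = [
    "PairAlignment",
    "DupKey",
    "InsertStats",
    "LibraryQCReport",
    "pair_up",
    "pair_up_all",
    "mark_duplicates",
    "mark_duplicates_single",
    "insert_size_stats",
    "edge_effect_diagnostic",
    "library_report",
]

MAD_CORE_FACTOR = 10.0  # insert-core filter half-width, in MADs


@dataclass(slots=True)
class PairAlignment:
    """A read pair's joint placement: orientation, properness, insert."""

    pair_id: str
    aln1: Alignment
    aln2: Alignment
    proper: bool
    orientation: str  # FR | RF | TANDEM | NA
    insert_len: int | None

    @property
    def both_mapped(self) -> bool:
        return self.aln1.mapped and self.aln2.mapped

    @property
    def qual_sum(self) -> int:
        return self.aln1.qual_sum + self.aln2.qual_sum


DupKey = tuple[tuple[str, int, str], tuple[str, int, str]]


def dup_key(pair: PairAlignment) -> DupKey:
    """Canonical duplicate key: both mates' (contig, 5' unclipped, strand).

    The mate with the lexicographically smaller (contig, position) comes
    first so a pair and its mate-swapped representation share one key.
    """
    a, b = pair.aln1, pair.aln2
    ka = (a.contig_id, a.five_prime, a.strand)
    kb = (b.contig_id, b.five_prime, b.strand)
    return (ka, kb) if ka <= kb else (kb, ka)


def pair_up(
    aln1: Alignment,
    aln2: Alignment,
    library_type: str = "PE",
    insert_cap: int = 100_000,
    pair_id: str | None = None,
) -> PairAlignment:
    """Combine two mate alignments into a PairAlignment.

    A pair is proper iff both mates map to the same contig in the
    orientation expected for the library type (FR for PE, RF for MP)
    with an outer-distance insert in (0, insert_cap]. The insert is
    (rightmost unclipped end) - (leftmost unclipped start).
    """
    pid = pair_id if pair_id is not None else _strip_mate(aln1.read_id)
    if not (aln1.mapped and aln2.mapped):
        return PairAlignment(pid, aln1, aln2, False, "NA", None)
    if aln1.contig_id != aln2.contig_id:
        return PairAlignment(pid, aln1, aln2, False, "NA", None)
    left, right = sorted((aln1, aln2), key=lambda a: (a.unclipped_start, a.unclipped_end))
    if left.strand == right.strand:
        orientation = "TANDEM"
    elif left.strand == "+":
        orientation = "FR"
    else:
        orientation = "RF"
    insert = max(aln1.unclipped_end, aln2.unclipped_end) - min(
        aln1.unclipped_start, aln2.unclipped_start
    )
    expected = "FR" if library_type == "PE" else "RF"
    proper = orientation == expected and 0 < insert <= insert_cap
    return PairAlignment(pid, aln1, aln2, proper, orientation, insert if proper else None)


def _strip_mate(read_id: str) -> str:
    return read_id[:-2] if read_id.endswith(("/1", "/2")) else read_id


def pair_up_all(
    alignment_pairs: Iterable[tuple[Alignment, Alignment]],
    library_type: str = "PE",
    insert_cap: int = 100_000,
) -> list[PairAlignment]:
    return [
        pair_up(a1, a2, library_type=library_type, insert_cap=insert_cap)
        for a1, a2 in alignment_pairs
    ]


def mark_duplicates(pairs: Sequence[PairAlignment]) -> tuple[list[bool], int]:
    """Flag duplicate pairs; returns (per-pair flags, number marked).

    Pairs sharing a duplicate key form one set; the retained pair is the
    one with the highest summed base quality (ties: smallest pair_id,
    then input order). Pairs with an unmapped mate are never marked.
    """
    groups: dict[DupKey, list[int]] = {}
    for i, p in enumerate(pairs):
        if not p.both_mapped:
            continue
        groups.setdefault(dup_key(p), []).append(i)
    flags = [False] * len(pairs)
    n_marked = 0
    for members in groups.values():
        if len(members) < 2:
            continue
        keep = min(members, key=lambda i: (-pairs[i].qual_sum, pairs[i].pair_id, i))
        for i in members:
            if i != keep:
                flags[i] = True
                n_marked += 1
    return flags, n_marked


def mark_duplicates_single(alignments: Sequence[Alignment]) -> tuple[list[bool], int]:
    """Single-end duplicate marking on (contig, 5' unclipped, strand).

    Provided for orphan reads that lost their mate in trimming; these
    never enter the headline pair-based duplicate percentage. Retention
    follows the same rule as pairs: highest base-quality sum, ties by
    read id then input order.
    """
    groups: dict[tuple[str, int, str], list[int]] = {}
    for i, a in enumerate(alignments):
        if not a.mapped:
            continue
        groups.setdefault((a.contig_id, a.five_prime, a.strand), []).append(i)
    flags = [False] * len(alignments)
    n_marked = 0
    for members in groups.values():
        if len(members) < 2:
            continue
        keep = min(members, key=lambda i: (-alignments[i].qual_sum,
                                           alignments[i].read_id, i))
        for i in members:
            if i != keep:
                flags[i] = True
                n_marked += 1
    return flags, n_marked


@dataclass(slots=True)
class InsertStats:
    mean: float | None
    sd: float | None
    n_proper: int
    n_core: int
    histogram: Counter = field(default_factory=Counter)


def insert_size_stats(pairs: Sequence[PairAlignment]) -> InsertStats:
    """Core-filtered insert mean/SD plus the full insert histogram.

    The core keeps proper pairs within 10 MADs of the median insert;
    when the MAD is 0 (very tight libraries) the fallback window is
    median +/- 10% of the median. SD is the sample SD (ddof=1).
    """
    inserts = np.array([p.insert_len for p in pairs if p.proper], dtype=np.int64)
    hist = Counter(inserts.tolist())
    if inserts.size < 2:
        warnings.warn("fewer than 2 proper pairs: insert stats undefined")
        return InsertStats(None, None, int(inserts.size), 0, hist)
    med = float(np.median(inserts))
    mad = float(np.median(np.abs(inserts - med)))
    half_width = MAD_CORE_FACTOR * mad if mad > 0 else 0.1 * med
    core = inserts[np.abs(inserts - med) <= half_width]
    if core.size < 2:
        core = inserts
    return InsertStats(
        mean=float(core.mean()),
        sd=float(core.std(ddof=1)),
        n_proper=int(inserts.size),
        n_core=int(core.size),
        histogram=hist,
    )


def edge_effect_diagnostic(
    alignments: Iterable[Alignment],
    contigs: Sequence[Contig],
    read_len: int,
) -> tuple[float, float]:
    """(edge_unmapped_frac, expected_mappable_frac) for a contig set.

    ``edge_unmapped_frac`` is the fraction of reads left unmapped solely
    because their best placement overhung a contig end (edge_policy=
    "unmapped"); ``expected_mappable_frac`` is the model fraction of
    start positions admitting a full-length alignment,
    sum(max(0, L_i - read_len + 1)) / sum(L_i).
    """
    total = 0
    edge_unmapped = 0
    for a in alignments:
        total += 1
        if not a.mapped and a.edge_overhang > 0:
            edge_unmapped += 1
    tot_len = sum(c.length for c in contigs)
    mappable = sum(max(0, c.length - read_len + 1) for c in contigs)
    expected = mappable / tot_len if tot_len else 0.0
    return (edge_unmapped / total if total else 0.0, expected)


@dataclass(slots=True)
class LibraryQCReport:
    """Per-library QC summary mirroring a mapping-statistics table row."""

    library: str
    library_type: str
    n_reads_total: int
    n_reads_mapped: int
    pct_mapped: float
    n_dup_reads: int
    pct_dup: float
    insert_mean: float | None
    insert_sd: float | None
    n_proper_pairs: int
    insert_histogram: Counter
    edge_unmapped_frac: float
    multimap_frac: float

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "library", "library_type", "n_reads_total", "n_reads_mapped",
            "pct_mapped", "n_dup_reads", "pct_dup", "insert_mean",
            "insert_sd", "n_proper_pairs", "edge_unmapped_frac",
            "multimap_frac",
        )}
        d["insert_histogram"] = {int(k): int(v) for k, v in sorted(self.insert_histogram.items())}
        return d


def library_report(
    pairs: Sequence[PairAlignment],
    n_reads_total: int | None = None,
    library: str = "library",
    library_type: str = "PE",
    exclude_multimapped: bool = False,
) -> LibraryQCReport:
    """Assemble the full QC report for one library from its pairs.

    ``n_reads_total`` defaults to the reads entering mapping (2 per
    pair); reads removed by trimming are reported separately upstream.
    Multi-mapped reads count as mapped and stay duplicate-eligible by
    default (they retain one primary placement); ``exclude_multimapped``
    is the strict mode that drops them from both tallies.
    """
    if exclude_multimapped:
        pairs = [p for p in pairs
                 if not (p.aln1.multimapped or p.aln2.multimapped)]
    if n_reads_total is None:
        n_reads_total = 2 * len(pairs)
    alns = [a for p in pairs for a in (p.aln1, p.aln2)]
    n_mapped = sum(1 for a in alns if a.mapped)
    n_multi = sum(1 for a in alns if a.mapped and a.multimapped)
    edge_unmapped = sum(1 for a in alns if not a.mapped and a.edge_overhang > 0)
    _, n_marked = mark_duplicates(pairs)
    n_dup_reads = 2 * n_marked
    stats = (
        insert_size_stats(pairs)
        if sum(1 for p in pairs if p.proper) >= 2
        else InsertStats(None, None, 0, 0, Counter())
    )
    return LibraryQCReport(
        library=library,
        library_type=library_type,
        n_reads_total=n_reads_total,
        n_reads_mapped=n_mapped,
        pct_mapped=100.0 * n_mapped / n_reads_total if n_reads_total else 0.0,
        n_dup_reads=n_dup_reads,
        pct_dup=100.0 * n_dup_reads / n_mapped if n_mapped else 0.0,
        insert_mean=stats.mean,
        insert_sd=stats.sd,
        n_proper_pairs=stats.n_proper,
        insert_histogram=stats.histogram,
        edge_unmapped_frac=edge_unmapped / len(alns) if alns else 0.0,
        multimap_frac=n_multi / n_mapped if n_mapped else 0.0,
    )
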