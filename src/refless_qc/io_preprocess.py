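"""FASTQ I/O, adapter/quality trimming and paired filtering.

Reads are trimmed with the rules used throughout the pipeline: adapter
overlap removal at the 3' end first, then removal of the longest 3'
suffix of bases below the quality cutoff, then rejection of reads that
end up shorter than the minimum length or below the minimum mean
quality. Only Sanger Phred+33 FASTQ is supported; Phred+64-looking input
raises instead of being silently misdecoded.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "ReadRecord",
    "TrimPolicy",
    "TrimCounts",
    "FastqParseError",
    "read_fastq",
    "read_fastq_pairs",
    "write_fastq",
    "trim_read",
    "trim_pairs",
]

_MAX_PHRED33 = 74  # '!'..'J' == Q0..Q41; anything above looks like Phred+64


class FastqParseError(ValueError):
    """Malformed FASTQ input, carrying the 1-based record index."""


@dataclass(frozen=True, slots=True)
class ReadRecord:
    """One sequencing read: id, bases over {A,C,G,T,N}, Phred scores."""

    read_id: str
    bases: str
    quals: tuple[int, ...]
    mate_index: int | None = None

    def __post_init__(self):
        if not self.read_id:
            raise ValueError("read_id must be nonempty")
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.bases)} bases vs "
                f"{len(self.quals)} quality values"
            )

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def mean_qual(self) -> float:
        return sum(self.quals) / len(self.quals) if self.quals else 0.0


@dataclass(frozen=True, slots=True)
class TrimPolicy:
    """Trimming thresholds: quality cutoff, minimum length, minimum mean."""

    qual_cutoff: int = 30
    min_length: int = 35
    min_mean_qual: float = 30.0
    adapters: tuple[str, ...] = ()
    min_adapter_overlap: int = 6

    def __post_init__(self):
        if self.qual_cutoff < 0:
            raise ValueError("qual_cutoff must be >= 0")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


@dataclass
class TrimCounts:
    pairs_in: int = 0
    pairs_out: int = 0
    pairs_rejected: int = 0
    orphans: int = 0
    reads_in: int = 0
    reads_out: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _open_text(path) -> io.TextIOBase:
    p = Path(path)
    if p.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(p, "rb"))
    return open(p, "rt")


def _decode_quals(qual_str: str, idx: int, title: str) -> tuple[int, ...]:
    out = []
    for ch in qual_str:
        q = ord(ch) - 33
        if q < 0 or ord(ch) > _MAX_PHRED33:
            raise FastqParseError(
                f"record {idx}: quality character {ch!r} in read {title!r} is "
                "outside the Phred+33 range (Phred+64 input is not supported)"
            )
        out.append(q)
    return tuple(out)


def _mate_index(title: str) -> int | None:
    name = title.split()[0]
    if name.endswith("/1"):
        return 1
    if name.endswith("/2"):
        return 2
    return None


def read_fastq(source) -> list[ReadRecord]:
    """Parse a FASTQ file/handle (Phred+33) into ReadRecords, order kept.

    `source` may be a path (optionally .gz) or an open text handle.
    Malformed records raise :class:`FastqParseError` naming the 1-based
    record index.
    """
    handle = source if hasattr(source, "read") else _open_text(source)
    records: list[ReadRecord] = []
    idx = 0
    try:
        for title, seq, qual in FastqGeneralIterator(handle):
            idx += 1
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"record {idx}: sequence length {len(seq)} != quality length {len(qual)}"
                )
            name = title.split()[0]
            records.append(
                ReadRecord(name, seq.upper(), _decode_quals(qual, idx, name), _mate_index(title))
            )
    except FastqParseError:
        raise
    except ValueError as exc:  # Biopython's truncation/format errors
        raise FastqParseError(f"record {idx + 1}: {exc}") from exc
    finally:
        if handle is not source:
            handle.close()
    return records


def read_fastq_pairs(r1_source, r2_source) -> list[tuple[ReadRecord, ReadRecord]]:
    """Read two synchronized FASTQ files into mate pairs."""
    r1 = read_fastq(r1_source)
    r2 = read_fastq(r2_source)
    if len(r1) != len(r2):
        raise FastqParseError(
            f"unpaired input: {len(r1)} reads in R1 vs {len(r2)} in R2"
        )
    pairs = []
    for a, b in zip(r1, r2):
        if _base_id(a.read_id) != _base_id(b.read_id):
            raise FastqParseError(
                f"mate id mismatch: {a.read_id!r} vs {b.read_id!r}"
            )
        pairs.append((replace(a, mate_index=1), replace(b, mate_index=2)))
    return pairs


def _base_id(read_id: str) -> str:
    return read_id[:-2] if read_id.endswith(("/1", "/2")) else read_id


def write_fastq(records: Iterable[ReadRecord], dest) -> None:
    """Write ReadRecords as Phred+33 FASTQ (path, .gz path, or handle)."""
    own = not hasattr(dest, "write")
    handle = _open_write(dest) if own else dest
    try:
        for r in records:
            qual = "".join(chr(q + 33) for q in r.quals)
            handle.write(f"@{r.read_id}\n{r.bases}\n+\n{qual}\n")
    finally:
        if own:
            handle.close()


def _open_write(path):
    p = Path(path)
    if p.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(p, "wb"))
    return open(p, "wt")


def _adapter_trim_point(bases: str, adapters: Sequence[str], min_overlap: int) -> int | None:
    """Leftmost position where an adapter occurrence starts, or None.

    An adapter is recognized when its prefix overlaps the read suffix by
    at least `min_overlap` bases with at most one mismatch per 10
    overlapped bases.
    """
    n = len(bases)
    best: int | None = None
    for adapter in adapters:
        if not adapter:
            continue
        upper = n - min_overlap
        for pos in range(0, upper + 1):
            if best is not None and pos >= best:
                break
            overlap = min(len(adapter), n - pos)
            if overlap < min_overlap:
                break
            allowed = overlap // 10
            mismatches = 0
            for a, b in zip(bases[pos : pos + overlap], adapter[:overlap]):
                if a != b:
                    mismatches += 1
                    if mismatches > allowed:
                        break
            else:
                best = pos
                break
    return best


def trim_read(read: ReadRecord, policy: TrimPolicy) -> ReadRecord | None:
    """Trim one read; return the trimmed read or None when rejected.

    Adapter removal happens before quality trimming; rejection means the
    surviving read is shorter than ``min_length`` or its mean quality is
    below ``min_mean_qual``.
    """
    bases, quals = read.bases, read.quals
    if policy.adapters:
        cut = _adapter_trim_point(bases, policy.adapters, policy.min_adapter_overlap)
        if cut is not None:
            bases, quals = bases[:cut], quals[:cut]
    end = len(bases)
    while end > 0 and quals[end - 1] < policy.qual_cutoff:
        end -= 1
    bases, quals = bases[:end], quals[:end]
    if len(bases) < policy.min_length:
        return None
    if quals and sum(quals) / len(quals) < policy.min_mean_qual:
        return None
    return ReadRecord(read.read_id, bases, quals, read.mate_index)


def trim_pairs(
    pairs: Iterable[tuple[ReadRecord, ReadRecord]], policy: TrimPolicy
) -> tuple[list[tuple[ReadRecord, ReadRecord]], TrimCounts]:
    """Trim mate pairs; a pair survives only when both mates survive.

    Pairs where exactly one mate survives are dropped and counted as
    orphans (downstream duplicate/insert metrics are pair-based).
    """
    counts = TrimCounts()
    out: list[tuple[ReadRecord, ReadRecord]] = []
    for r1, r2 in pairs:
        counts.pairs_in += 1
        counts.reads_in += 2
        t1 = trim_read(r1, policy)
        t2 = trim_read(r2, policy)
        if t1 is not None and t2 is not None:
            out.append((t1, t2))
            counts.pairs_out += 1
            counts.reads_out += 2
        elif t1 is None and t2 is None:
            counts.pairs_rejected += 1
        else:
            counts.pairs_rejected += 1
            counts.orphans += 1
    return out, counts
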