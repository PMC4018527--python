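"""Draft de Bruijn assembly for QC purposes, plus assembly-shape metrics.

The assembler builds unitigs (maximal unbranched paths) over canonical
k-mers and applies two conservative error-cleaning passes — tip clipping
and redundant-weak-branch (bubble side) removal — so that isolated
sequencing errors do not shatter the draft. It deliberately does no
scaffolding, repeat resolution or polishing: the goal is a mapping
target for QC metrics, not a finished genome.

Determinism: k-mers are canonicalized as min(kmer, revcomp); unitig
seeds are visited in ascending packed-code order; output contigs are
sorted by canonical sequence and named ``contig_<index>`` in that order.

Internally the k-mer set is kept doubled (both orientations of every
k-mer present) in one sorted uint64 array; successor/predecessor links
are resolved for all nodes at once with vectorized binary search, so
only the linear chain-following loop stays scalar.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._kmers import count_canonical, decode, rc_codes, revcomp

__all__ = [
    "Contig",
    "AssemblyParams",
    "AssemblyStats",
    "assemble",
    "assembly_stats",
    "gc_percent",
    "write_fasta",
    "read_fasta",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True, slots=True)
class Contig:
    contig_id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def gc_pct(self) -> float | None:
        return gc_percent(self.seq)


def gc_percent(seq: str) -> float | None:
    """GC percentage over unambiguous bases; None if no A/C/G/T present."""
    gc = sum(seq.count(b) for b in "GCgc")
    at = sum(seq.count(b) for b in "ATat")
    if gc + at == 0:
        return None
    return 100.0 * gc / (gc + at)


@dataclass(frozen=True, slots=True)
class AssemblyParams:
    """k-mer size, contig length cutoff and k-mer coverage cutoff."""

    k: int = 31
    min_contig_len: int = 100
    min_kmer_cov: int = 1

    def __post_init__(self):
        if not (15 <= self.k <= 63) or self.k % 2 == 0:
            raise ValueError("k must be odd and in [15, 63]")
        if self.k > 32:
            # packed-uint64 representation bounds the implementation at 32
            raise ValueError("this implementation supports k <= 32 (packed 2-bit k-mers)")
        if self.min_contig_len < self.k:
            raise ValueError("min_contig_len must be >= k")
        if self.min_kmer_cov < 1:
            raise ValueError("min_kmer_cov must be >= 1")


@dataclass(frozen=True, slots=True)
class AssemblyStats:
    n_contigs: int
    total_bases: int
    max_len: int
    n50: int | None
    gc_pct: float | None
    n_over_1kb: int
    bases_over_1kb: int
    chaff_pct: float
    assembly_size_pct: float | None

    def as_dict(self) -> dict:
        return {
            "n_contigs": self.n_contigs,
            "total_bases": self.total_bases,
            "max_len": self.max_len,
            "n50": self.n50,
            "gc_pct": self.gc_pct,
            "n_over_1kb": self.n_over_1kb,
            "bases_over_1kb": self.bases_over_1kb,
            "chaff_pct": self.chaff_pct,
            "assembly_size_pct": self.assembly_size_pct,
        }


CHAFF_MAX_LEN = 300  # contigs at or below this length count as chaff


class _Graph:
    """Doubled de Bruijn k-mer set over a sorted packed-code array."""

    def __init__(self, codes: np.ndarray, counts: np.ndarray, k: int):
        self.U = codes
        self.C = counts
        self.k = k
        self.mask = np.uint64((1 << (2 * k)) - 1)
        self.hi = np.uint64(2 * (k - 1))
        self.removed = np.zeros(codes.size, dtype=bool)
        self.rc_idx = np.searchsorted(codes, rc_codes(codes, k))
        self._link()

    def _link(self) -> None:
        """Vectorized unique-successor/predecessor resolution."""
        U, n = self.U, self.U.size
        two = np.uint64(2)
        succ_idx = np.full(n, -1, dtype=np.int64)
        outdeg = np.zeros(n, dtype=np.int8)
        base = (U << two) & self.mask
        for b in range(4):
            cand = base | np.uint64(b)
            pos = np.searchsorted(U, cand)
            ok = U[np.minimum(pos, n - 1)] == cand
            outdeg += ok
            succ_idx[ok] = pos[ok]
        pred_idx = np.full(n, -1, dtype=np.int64)
        indeg = np.zeros(n, dtype=np.int8)
        pbase = U >> two
        for b in range(4):
            cand = pbase | (np.uint64(b) << self.hi)
            pos = np.searchsorted(U, cand)
            ok = U[np.minimum(pos, n - 1)] == cand
            indeg += ok
            pred_idx[ok] = pos[ok]
        self.outdeg, self.indeg = outdeg, indeg
        linkable = (outdeg == 1) & (indeg[np.maximum(succ_idx, 0)] == 1) & (succ_idx >= 0)
        self.next = np.where(linkable, succ_idx, -1)
        linkable = (indeg == 1) & (outdeg[np.maximum(pred_idx, 0)] == 1) & (pred_idx >= 0)
        self.prev = np.where(linkable, pred_idx, -1)

    # scalar neighbor queries honoring removals (cleanup passes only)
    def _member(self, code: int) -> int:
        pos = int(np.searchsorted(self.U, np.uint64(code)))
        if pos < self.U.size and int(self.U[pos]) == code and not self.removed[pos]:
            return pos
        return -1

    def succs(self, i: int) -> list[int]:
        base = (int(self.U[i]) << 2) & int(self.mask)
        out = []
        for b in range(4):
            j = self._member(base | b)
            if j >= 0:
                out.append(j)
        return out

    def preds(self, i: int) -> list[int]:
        base = int(self.U[i]) >> 2
        hi = 2 * (self.k - 1)
        out = []
        for b in range(4):
            j = self._member(base | (b << hi))
            if j >= 0:
                out.append(j)
        return out

    def remove(self, indices: Iterable[int]) -> None:
        for i in indices:
            self.removed[i] = True
            self.removed[self.rc_idx[i]] = True

    def compacted(self) -> "_Graph | None":
        """New graph without removed nodes, or None if nothing removed."""
        if not self.removed.any():
            return None
        keep = ~self.removed
        return _Graph(self.U[keep], self.C[keep], self.k)

    def unitigs(self) -> list[np.ndarray]:
        """Maximal unbranched chains as index arrays, deterministically."""
        n = self.U.size
        visited = np.zeros(n, dtype=bool)
        nxt, prv, rc = self.next, self.prev, self.rc_idx
        out: list[np.ndarray] = []
        for i in range(n):
            if visited[i]:
                continue
            visited[i] = True
            visited[rc[i]] = True
            chain = [i]
            j = nxt[i]
            while j != -1 and not visited[j]:
                visited[j] = True
                visited[rc[j]] = True
                chain.append(j)
                j = nxt[j]
            left = []
            j = prv[i]
            while j != -1 and not visited[j]:
                visited[j] = True
                visited[rc[j]] = True
                left.append(j)
                j = prv[j]
            left.reverse()
            out.append(np.array(left + chain, dtype=np.int64))
        return out

    def seq(self, chain: np.ndarray) -> str:
        head = decode(int(self.U[chain[0]]), self.k)
        if chain.size == 1:
            return head
        tail = _BASES[(self.U[chain[1:]] & np.uint64(3)).astype(np.int64)]
        return head + tail.tobytes().decode("ascii")

    def mean_count(self, chain: np.ndarray) -> float:
        return float(self.C[chain].mean())


def _weak_threshold(graph: _Graph, junctions: list[int]) -> float:
    """Coverage-relative weakness cutoff next to the given junction k-mers."""
    if not junctions:
        return 2.0
    return max(2.0, 0.25 * max(int(graph.C[j]) for j in junctions))


def _clip_tips(graph: _Graph, unitigs: list[np.ndarray]) -> bool:
    """Remove dead-end unitigs shorter than 2k with error-like coverage."""
    k = graph.k
    removed = False
    for chain in unitigs:
        if chain.size + k - 1 >= 2 * k:
            continue
        if graph.removed[chain[0]]:
            continue
        node_set = set(chain.tolist())
        preds = [p for p in graph.preds(int(chain[0])) if p not in node_set]
        succs = [s for s in graph.succs(int(chain[-1])) if s not in node_set]
        if preds and succs:
            continue  # connected on both sides: not a tip
        if graph.mean_count(chain) <= _weak_threshold(graph, preds + succs):
            graph.remove(chain.tolist())
            removed = True
    return removed


def _pop_weak_branches(graph: _Graph, unitigs: list[np.ndarray]) -> bool:
    """Remove low-coverage unitigs whose junctions keep another branch.

    This is the bubble-side case: an interior sequencing error makes a
    short parallel path that rejoins the main path. A unitig is removed
    only when every predecessor of its first k-mer still has another
    successor and every successor of its last k-mer still has another
    predecessor, so removal can never create a new dead end. Candidates
    are processed weakest-first and conditions re-checked at removal
    time, so the stronger of two parallel paths always survives.
    """
    k = graph.k
    candidates = []
    for chain in unitigs:
        if chain.size + k - 1 > 3 * k:
            continue
        candidates.append((graph.mean_count(chain), graph.seq(chain), chain))
    candidates.sort(key=lambda t: (t[0], t[1]))
    removed = False
    for mc, _seq, chain in candidates:
        if graph.removed[chain[0]]:
            continue
        node_set = set(chain.tolist())
        preds = [p for p in graph.preds(int(chain[0])) if p not in node_set]
        succs = [s for s in graph.succs(int(chain[-1])) if s not in node_set]
        if not preds or not succs:
            continue
        if mc > _weak_threshold(graph, preds + succs):
            continue
        if any(len([s for s in graph.succs(p) if s not in node_set]) < 1 for p in preds):
            continue
        if any(len([p for p in graph.preds(s) if p not in node_set]) < 1 for s in succs):
            continue
        graph.remove(chain.tolist())
        removed = True
    return removed


def assemble(reads, params: AssemblyParams | None = None) -> list[Contig]:
    """Assemble reads (ReadRecords or plain strings) into unitig contigs.

    Pairs are treated as single-end: callers pass all mates in one
    collection. Reads containing N are split at the Ns during k-mer
    extraction. Returns contigs of length >= ``min_contig_len`` sorted by
    canonical sequence.
    """
    params = params or AssemblyParams()
    k = params.k
    seqs = (getattr(r, "bases", r) for r in reads)
    codes, counts = count_canonical(seqs, k)
    if params.min_kmer_cov > 1:
        keep = counts >= params.min_kmer_cov
        codes, counts = codes[keep], counts[keep]
    if codes.size == 0:
        warnings.warn("no k-mer survives the coverage cutoff; empty assembly")
        return []
    graph = _Graph(codes, counts, k)

    unitigs = graph.unitigs()
    if params.min_kmer_cov == 1:
        # error cleaning: tips, then bubble sides, then newly exposed tips
        if _clip_tips(graph, unitigs):
            graph = graph.compacted() or graph
            unitigs = graph.unitigs()
        if _pop_weak_branches(graph, unitigs):
            graph = graph.compacted() or graph
            unitigs = graph.unitigs()
            if _clip_tips(graph, unitigs):
                graph = graph.compacted() or graph
                unitigs = graph.unitigs()

    contigs: list[str] = []
    for chain in unitigs:
        if chain.size + k - 1 < params.min_contig_len:
            continue
        seq = graph.seq(chain)
        contigs.append(min(seq, revcomp(seq)))
    contigs.sort()
    return [Contig(f"contig_{i}", seq) for i, seq in enumerate(contigs)]


def assembly_stats(
    contigs: Sequence[Contig], reference_size: int | None = None
) -> AssemblyStats:
    """Shape metrics of a contig set (N50, chaff %, assembly size %...).

    ``chaff_pct`` is the share of assembly bases in contigs of at most
    300 bp; ``assembly_size_pct`` is total bases over ``reference_size``
    and may exceed 100 for redundant assemblies.
    """
    if reference_size is not None and reference_size <= 0:
        raise ValueError("reference_size must be positive")
    lengths = sorted((c.length for c in contigs), reverse=True)
    total = int(sum(lengths))
    if not lengths or total == 0:
        return AssemblyStats(0, 0, 0, None, None, 0, 0, 0.0,
                             0.0 if reference_size else None)
    n50 = None
    cum = 0
    for ln in lengths:
        cum += ln
        if cum * 2 >= total:
            n50 = ln
            break
    gc = sum(c.seq.count("G") + c.seq.count("C") for c in contigs)
    acgt = sum(sum(c.seq.count(b) for b in "ACGT") for c in contigs)
    chaff = sum(ln for ln in lengths if ln <= CHAFF_MAX_LEN)
    over1kb = [ln for ln in lengths if ln > 1000]
    return AssemblyStats(
        n_contigs=len(lengths),
        total_bases=total,
        max_len=lengths[0],
        n50=n50,
        gc_pct=100.0 * gc / acgt if acgt else None,
        n_over_1kb=len(over1kb),
        bases_over_1kb=int(sum(over1kb)),
        chaff_pct=100.0 * chaff / total,
        assembly_size_pct=(100.0 * total / reference_size) if reference_size else None,
    )


def write_fasta(contigs: Iterable[Contig], dest, width: int = 80) -> None:
    own = not hasattr(dest, "write")
    handle = open(dest, "wt") if own else dest
    try:
        for c in contigs:
            handle.write(f">{c.contig_id}\n")
            for i in range(0, len(c.seq), width):
                handle.write(c.seq[i : i + width] + "\n")
    finally:
        if own:
            handle.close()


def read_fasta(source) -> list[Contig]:
    from Bio import SeqIO

    own = not hasattr(source, "read")
    handle = open(source, "rt") if own else source
    try:
        return [Contig(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(handle, "fasta")]
    finally:
        if own:
            handle.close()
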