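"""Low-level 2-bit k-mer machinery shared by the assembler and the mapper.

Sequences are encoded base-per-byte (A=0, C=1, G=2, T=3, anything else
invalid); k-mers (k <= 32) are packed into uint64 words, most significant
base first, so integer order equals lexicographic order on the sequence.
All hot paths are vectorized with numpy; only graph walking stays scalar.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_RC_TRANS = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# reverse-complement of an 8-base (16-bit) chunk, used to rc packed k-mers
_x = np.arange(65536, dtype=np.uint64)
_r = np.zeros_like(_x)
for _j in range(8):
    _r = (_r << np.uint64(2)) | ((_x >> np.uint64(2 * _j)) & np.uint64(3))
_RC16 = (_r ^ np.uint64(0xFFFF)).astype(np.uint64)
_RC16_LIST = _RC16.tolist()
del _x, _r


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_RC_TRANS)[::-1]


def encode(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Return (2-bit codes, validity mask); invalid bases coded as 0/A."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw]
    valid = codes != 255
    return np.where(valid, codes, 0), valid


def kmer_codes(codes: np.ndarray, valid: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed uint64 codes for every k-window plus a window-validity mask.

    A window is valid iff it contains no invalid base; callers typically
    join sequences with 'N' so windows never span two sequences.
    """
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    m = n - k + 1
    codes64 = codes.astype(np.uint64)
    kc = np.zeros(m, dtype=np.uint64)
    two = np.uint64(2)
    for j in range(k):
        kc <<= two
        kc |= codes64[j : j + m]
    if valid.all():
        kvalid = np.ones(m, dtype=bool)
    else:
        bad = np.zeros(n + 1, dtype=np.int32)
        np.cumsum(~valid, dtype=np.int32, out=bad[1:])
        kvalid = (bad[k:] - bad[:-k]) == 0
    return kc, kvalid


def seq_kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    codes, valid = encode(seq)
    return kmer_codes(codes, valid, k)


def rc_code(code: int, k: int) -> int:
    """Reverse complement of one packed k-mer (scalar, table-driven)."""
    r = 0
    c = code
    for _ in range(4):
        r = (r << 16) | _RC16_LIST[c & 0xFFFF]
        c >>= 16
    return r >> (64 - 2 * k)


def rc_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Vectorized reverse complement of packed k-mers."""
    c = codes.astype(np.uint64, copy=True)
    r = np.zeros_like(c)
    for _ in range(4):
        r = (r << np.uint64(16)) | _RC16[(c & np.uint64(0xFFFF)).astype(np.int64)]
        c >>= np.uint64(16)
    return r >> np.uint64(64 - 2 * k)


def decode(code: int, k: int) -> str:
    return "".join("ACGT"[(code >> (2 * (k - 1 - i))) & 3] for i in range(k))


def count_canonical(seqs, k: int, chunk_bases: int = 8_000_000) -> tuple[np.ndarray, np.ndarray]:
    """Count k-mers of `seqs` merged with their reverse complements.

    Returns (unique_codes, counts) where for every observed k-mer both the
    forward and reverse-complement code are present with the identical
    merged count, i.e. counts[x] == occurrences of x plus occurrences of
    rc(x) across the input. k-mers containing non-ACGT bases are skipped.
    """
    partial: list[tuple[np.ndarray, np.ndarray]] = []
    buf: list[str] = []
    size = 0

    def flush():
        nonlocal buf, size
        if not buf:
            return
        big = "N".join(buf)
        streams = []
        for s in (big, revcomp(big)):
            kc, kv = seq_kmer_codes(s, k)
            streams.append(kc[kv])
        cat = np.concatenate(streams) if streams else np.empty(0, dtype=np.uint64)
        if cat.size:
            u, c = np.unique(cat, return_counts=True)
            partial.append((u, c))
        buf, size = [], 0

    for s in seqs:
        buf.append(s)
        size += len(s)
        if size >= chunk_bases:
            flush()
    flush()

    if not partial:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    allu = np.concatenate([u for u, _ in partial])
    allc = np.concatenate([c for _, c in partial])
    order = np.argsort(allu, kind="stable")
    allu, allc = allu[order], allc[order]
    first = np.concatenate(([True], allu[1:] != allu[:-1]))
    starts = np.flatnonzero(first)
    counts = np.add.reduceat(allc, starts)
    return allu[first], counts
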