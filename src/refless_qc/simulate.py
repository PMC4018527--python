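"""Synthetic genome and library generator with full ground truth.

Emulates the benchmark library designs the QC pipeline is meant for:
paired-end libraries with target inserts around 180/300/600 bp, a
multi-kb mate-pair (RF) library, fragment-level PCR duplication,
uniform substitution error, and a mock-contaminated mixture of two
genomes at an exact host:contaminant read ratio. Everything is
deterministic given the seed, and the returned :class:`SimTruth` records
per-fragment origin, insert, duplicate links and per-read error
positions so every downstream estimate can be checked against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._kmers import revcomp
from .io_preprocess import ReadRecord

__all__ = [
    "SimConfig",
    "SpikeConfig",
    "SimTruth",
    "LibraryResult",
    "simulate_genome",
    "simulate_library",
    "write_truth_hits",
]


@dataclass(frozen=True, slots=True)
class SpikeConfig:
    """Second-genome spiking: host:contaminant read-count ratio."""

    contaminant_label: str = "contaminant"
    ratio_host: int = 20
    ratio_contaminant: int = 1


@dataclass(frozen=True, slots=True)
class SimConfig:
    """Full generative description of one synthetic library."""

    seed: int = 0
    library_type: str = "PE"  # PE (FR) | MP (RF outer span)
    n_pairs: int = 20_000
    read_len: int = 100
    insert_mean: float = 300.0
    insert_sd: float = 20.0
    dup_prob: float = 0.0
    error_rate: float = 0.001
    qual_const: int = 37
    qual_tail_len: int = 0  # optional low-quality 3' tail
    qual_tail_q: int = 2
    spike: SpikeConfig | None = None
    host_label: str = "host"
    # mate-pair protocol leakage: fraction of MP fragments emitted as
    # short-insert FR (paired-end-like) pairs, to stress orientation filters
    mp_fr_fraction: float = 0.0
    mp_fr_insert_mean: float = 300.0
    mp_fr_insert_sd: float = 30.0

    def __post_init__(self):
        if not (0 <= self.dup_prob < 1):
            raise ValueError("dup_prob must be in [0, 1)")
        if not (0 <= self.error_rate < 0.1):
            raise ValueError("error_rate must be in [0, 0.1)")
        if self.library_type not in ("PE", "MP"):
            raise ValueError("library_type must be PE or MP")
        if self.library_type == "PE" and self.insert_mean < self.read_len:
            raise ValueError("insert_mean must be >= read_len for PE")
        if not (0 <= self.mp_fr_fraction <= 1):
            raise ValueError("mp_fr_fraction must be in [0, 1]")


@dataclass(slots=True)
class SimTruth:
    """Ground truth per emitted pair and per read."""

    genome: list[str]  # genome label per pair
    start: np.ndarray  # fragment start on its genome
    insert: np.ndarray  # true fragment / outer-span length
    duplicate_of: list[int | None]  # original pair index, or None
    error_positions: dict[tuple[int, int], list[int]]  # (pair, mate) -> positions
    mp_fr_leak: np.ndarray | None = None  # MP only: pair emitted as FR leakage

    @property
    def n_pairs(self) -> int:
        return len(self.genome)

    @property
    def n_duplicate_pairs(self) -> int:
        return sum(1 for d in self.duplicate_of if d is not None)

    @property
    def realized_dup_fraction(self) -> float:
        return self.n_duplicate_pairs / self.n_pairs if self.n_pairs else 0.0

    def pair_counts_by_genome(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for g in self.genome:
            out[g] = out.get(g, 0) + 1
        return out


@dataclass(slots=True)
class LibraryResult:
    r1: list[ReadRecord]
    r2: list[ReadRecord]
    truth: SimTruth

    @property
    def all_reads(self) -> list[ReadRecord]:
        out = []
        for a, b in zip(self.r1, self.r2):
            out.append(a)
            out.append(b)
        return out

    @property
    def pairs(self) -> list[tuple[ReadRecord, ReadRecord]]:
        return list(zip(self.r1, self.r2))


def simulate_genome(seed: int, genome_len: int, gc_target: float = 50.0) -> str:
    """Random genome with i.i.d. bases, P(G)=P(C)=gc_target/200."""
    if genome_len < 1000:
        raise ValueError("genome_len must be >= 1000")
    g = gc_target / 200.0
    rng = np.random.default_rng(seed)
    at = (1 - 2 * g) / 2
    bases = rng.choice(
        np.frombuffer(b"ACGT", dtype=np.uint8),
        size=genome_len,
        p=[at, g, g, at],
    )
    return bases.tobytes().decode("ascii")


def _partition_pairs(n_pairs: int, spike: SpikeConfig) -> tuple[int, int]:
    """Deterministic host/contaminant split matching the ratio exactly."""
    total = spike.ratio_host + spike.ratio_contaminant
    n_cont = round(n_pairs * spike.ratio_contaminant / total)
    return n_pairs - n_cont, n_cont


def simulate_library(
    genomes: dict[str, str] | str,
    config: SimConfig,
) -> LibraryResult:
    """Generate a paired library (R1, R2, truth) from one or two genomes.

    ``genomes`` is either the host sequence or a {label: sequence} dict;
    with ``config.spike`` set, the dict must contain both the host and
    the contaminant label and pair counts are partitioned so the
    host:contaminant ratio holds exactly among original fragments.
    PCR duplication copies a fragment before error injection, so
    duplicate copies differ only by their independent sequencing errors.
    """
    if isinstance(genomes, str):
        genomes = {config.host_label: genomes}
    rng = np.random.default_rng(config.seed)
    if config.spike is not None:
        n_host, n_cont = _partition_pairs(config.n_pairs, config.spike)
        plan = [(config.host_label, n_host), (config.spike.contaminant_label, n_cont)]
    else:
        plan = [(config.host_label, config.n_pairs)]

    labels: list[str] = []
    starts: list[np.ndarray] = []
    lengths: list[np.ndarray] = []
    for label, n in plan:
        genome = genomes[label]
        glen = len(genome)
        if config.insert_mean + 3 * config.insert_sd > glen:
            raise ValueError(f"genome {label!r} too short for the insert model")
        flen = np.rint(rng.normal(config.insert_mean, config.insert_sd, size=n))
        flen = np.clip(flen, config.read_len, glen).astype(np.int64)
        fstart = rng.integers(0, glen - flen + 1)
        labels.extend([label] * n)
        starts.append(fstart)
        lengths.append(flen)
    start = np.concatenate(starts) if starts else np.empty(0, dtype=np.int64)
    insert = np.concatenate(lengths) if lengths else np.empty(0, dtype=np.int64)
    n_orig = len(labels)

    fr_leak = np.zeros(n_orig, dtype=bool)
    if config.library_type == "MP" and config.mp_fr_fraction > 0:
        # protocol leakage: some fragments behave like short-insert PE pairs
        fr_leak = rng.random(n_orig) < config.mp_fr_fraction
        idx = np.flatnonzero(fr_leak)
        if idx.size:
            short = np.rint(rng.normal(config.mp_fr_insert_mean,
                                       config.mp_fr_insert_sd, size=idx.size))
            short = np.clip(short.astype(np.int64), config.read_len, insert[idx])
            insert[idx] = short  # same start; a shorter fragment always fits

    dup_mask = rng.random(n_orig) < config.dup_prob
    dup_src = np.flatnonzero(dup_mask)
    genome_per_pair = labels + [labels[i] for i in dup_src]
    start = np.concatenate([start, start[dup_src]])
    insert = np.concatenate([insert, insert[dup_src]])
    fr_leak = np.concatenate([fr_leak, fr_leak[dup_src]])
    duplicate_of: list[int | None] = [None] * n_orig + [int(i) for i in dup_src]
    n_total = len(genome_per_pair)

    frag_strand = rng.integers(0, 2, size=n_total)
    mate_swap = rng.integers(0, 2, size=n_total)

    quals = _qual_template(config)
    r1: list[ReadRecord] = []
    r2: list[ReadRecord] = []
    raw: list[tuple[str, str]] = []
    rl = config.read_len
    for i in range(n_total):
        genome = genomes[genome_per_pair[i]]
        s, ln = int(start[i]), int(insert[i])
        frag = genome[s : s + ln]
        if frag_strand[i]:
            frag = revcomp(frag)
        if config.library_type == "PE" or fr_leak[i]:
            a = frag[:rl]
            b = revcomp(frag[-rl:])
        else:  # MP: outward-facing mates, RF orientation on the source
            a = revcomp(frag[:rl])
            b = frag[-rl:]
        if mate_swap[i]:
            a, b = b, a
        raw.append((a, b))

    error_positions = _inject_errors(raw, config, rng)
    for i, (a, b) in enumerate(raw):
        r1.append(ReadRecord(f"p{i}/1", a, quals[: len(a)], 1))
        r2.append(ReadRecord(f"p{i}/2", b, quals[: len(b)], 2))
    truth = SimTruth(genome_per_pair, start, insert, duplicate_of, error_positions,
                     mp_fr_leak=fr_leak if config.library_type == "MP" else None)
    return LibraryResult(r1, r2, truth)


def _qual_template(config: SimConfig) -> tuple[int, ...]:
    q = [config.qual_const] * config.read_len
    if config.qual_tail_len:
        for i in range(max(0, config.read_len - config.qual_tail_len), config.read_len):
            q[i] = config.qual_tail_q
    return tuple(q)


_ALT = {b: [o for o in "ACGT" if o != b] for b in "ACGT"}


def _inject_errors(raw, config: SimConfig, rng) -> dict[tuple[int, int], list[int]]:
    """Mutate reads in place (raw is a list of (r1, r2) strings)."""
    out: dict[tuple[int, int], list[int]] = {}
    if config.error_rate <= 0:
        return out
    n_reads = 2 * len(raw)
    counts = rng.binomial(config.read_len, config.error_rate, size=n_reads)
    for j in np.flatnonzero(counts):
        pair, mate = divmod(int(j), 2)
        seq = raw[pair][mate]
        positions = sorted(
            rng.choice(len(seq), size=min(int(counts[j]), len(seq)), replace=False).tolist()
        )
        chars = list(seq)
        for pos in positions:
            if chars[pos] not in _ALT:
                continue
            chars[pos] = _ALT[chars[pos]][rng.integers(0, 3)]
        mutated = "".join(chars)
        raw[pair] = (mutated, raw[pair][1]) if mate == 0 else (raw[pair][0], mutated)
        out[(pair, mate + 1)] = positions
    return out


def write_truth_hits(
    contigs,
    genomes: dict[str, str],
    taxon_labels: dict[str, str],
    k: int = 31,
    hits_dest=None,
    taxmap_dest=None,
) -> tuple[list, dict[str, str]]:
    """Assign each contig to its majority source genome as synthetic hits.

    For each contig, count canonical k-mers shared with each genome; the
    majority genome yields one hit line (evalue 1e-100, bitscore =
    contig length) consumable by :func:`refless_qc.tagc.annotate_contigs`
    unchanged. Equal splits are labelled ``ambiguous``; contigs sharing
    no k-mer with any genome get no hit line. Returns (TaxonHits,
    subject->taxon map) and optionally writes the outfmt-6-style TSVs.
    """
    from ._kmers import rc_codes, seq_kmer_codes
    from .tagc import OUTFMT6_COLUMNS, TaxonHit

    genome_sets: dict[str, set[int]] = {}
    for label, seq in genomes.items():
        kc, kv = seq_kmer_codes(seq, k)
        kc = kc[kv]
        canon = np.minimum(kc, rc_codes(kc, k))
        genome_sets[label] = set(canon.tolist())

    taxmap = {label: taxon_labels.get(label, label) for label in genomes}
    taxmap["ambiguous"] = "ambiguous"
    hits: list[TaxonHit] = []
    rows = []
    for c in contigs:
        kc, kv = seq_kmer_codes(c.seq, k)
        kc = kc[kv]
        if kc.size == 0:
            continue
        canon = np.minimum(kc, rc_codes(kc, k)).tolist()
        scores = {
            label: sum(1 for x in canon if x in s) for label, s in genome_sets.items()
        }
        top = max(scores.values())
        if top == 0:
            continue
        winners = sorted(label for label, v in scores.items() if v == top)
        subject = winners[0] if len(winners) == 1 else "ambiguous"
        hits.append(TaxonHit(c.contig_id, subject, 1e-100, float(c.length),
                             taxmap[subject]))
        rows.append(
            [c.contig_id, subject, 100.0, c.length, 0, 0, 1, c.length, 1,
             c.length, 1e-100, float(c.length)]
        )
    if hits_dest is not None:
        import pandas as pd

        pd.DataFrame(rows, columns=OUTFMT6_COLUMNS).to_csv(
            hits_dest, sep="\t", index=False, header=False
        )
    if taxmap_dest is not None:
        import pandas as pd

        pd.DataFrame(sorted(taxmap.items())).to_csv(
            taxmap_dest, sep="\t", index=False, header=False
        )
    return hits, taxmap
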