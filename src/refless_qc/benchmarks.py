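"""Desk-scale benchmark designs for parameter-recovery validation.

Each function runs the full reference-free protocol (trim -> draft
assembly -> map-back -> metrics) on a simulated library whose design
mirrors the benchmark libraries the method targets — paired-end
libraries with target inserts of 180/300/600 bp, a 2.5 kb mate-pair
library estimated against a paired-end draft, PCR duplication levels,
and a two-genome mock-contaminated mixture at an exact 20:1
host:contaminant read ratio — and returns the recovered quantity next
to the simulation truth. Genome sizes are scaled to fractions of a
megabase so a full design runs on one CPU in minutes while keeping the
per-base coverage of the real designs' regime.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import tagc
from .assembler import AssemblyParams, Contig, assemble
from .io_preprocess import TrimPolicy, trim_pairs
from .mapper import MapperParams, SeedIndex, map_pairs
from .qc_metrics import insert_size_stats, library_report, pair_up_all
from .simulate import SimConfig, SpikeConfig, simulate_genome, simulate_library
from .tagc import make_points, quantify_contamination
from .simulate import write_truth_hits

HOST_TAXON = "Primates"
CONTAMINANT_TAXON = "Enterobacteriales"


def _run_qc(pairs, contigs, library_type="PE", mapper_params=None):
    trimmed, counts = trim_pairs(pairs, TrimPolicy())
    index = SeedIndex(contigs, (mapper_params or MapperParams()).seed_len)
    aln_pairs = map_pairs(trimmed, index, mapper_params)
    pair_alns = pair_up_all(aln_pairs, library_type=library_type)
    report = library_report(pair_alns, n_reads_total=counts.reads_out,
                            library_type=library_type)
    return report, aln_pairs, pair_alns


def recover_insert_pe(
    target_insert: float,
    seed: int,
    n_pairs: int = 20_000,
    genome_len: int = 500_000,
    insert_sd: float = 20.0,
    error_rate: float = 0.001,
) -> dict:
    """Full pipeline insert-mean recovery for one paired-end design."""
    genome = simulate_genome(seed, genome_len, 50.0)
    cfg = SimConfig(seed=seed + 1, n_pairs=n_pairs, insert_mean=target_insert,
                    insert_sd=insert_sd, error_rate=error_rate)
    lib = simulate_library(genome, cfg)
    contigs = assemble(lib.all_reads, AssemblyParams())
    report, _, _ = _run_qc(lib.pairs, contigs, "PE")
    return {
        "target_insert": target_insert,
        "recovered_mean": report.insert_mean,
        "recovered_sd": report.insert_sd,
        "true_mean": float(lib.truth.insert.mean()),
        "pct_mapped": report.pct_mapped,
        "n_pairs": n_pairs,
    }


def recover_insert_mp(
    seed: int,
    target_insert: float = 2500.0,
    insert_sd: float = 300.0,
    n_pairs: int = 20_000,
    genome_len: int = 1_000_000,
    pe_pairs: int = 60_000,
    error_rate: float = 0.001,
) -> dict:
    """Mate-pair insert recovery against a paired-end draft assembly.

    The draft comes from a companion PE library (insert 300) only; the
    MP reads are mapped onto it, following the recommendation to
    estimate long-insert distributions against standard-library drafts.
    """
    genome = simulate_genome(seed, genome_len, 50.0)
    pe = simulate_library(genome, SimConfig(seed=seed + 1, n_pairs=pe_pairs,
                                            insert_mean=300, insert_sd=20,
                                            error_rate=error_rate))
    contigs = assemble(pe.all_reads, AssemblyParams())
    mp = simulate_library(genome, SimConfig(seed=seed + 2, n_pairs=n_pairs,
                                            library_type="MP",
                                            insert_mean=target_insert,
                                            insert_sd=insert_sd,
                                            error_rate=error_rate))
    report, _, _ = _run_qc(mp.pairs, contigs, "MP")
    return {
        "target_insert": target_insert,
        "recovered_mean": report.insert_mean,
        "recovered_sd": report.insert_sd,
        "true_mean": float(mp.truth.insert.mean()),
        "n_proper": report.n_proper_pairs,
        "n_pairs": n_pairs,
    }


def recover_dup_rate(
    dup_prob: float,
    seed: int,
    n_pairs: int = 20_000,
    genome_len: int = 500_000,
    error_rate: float = 0.001,
) -> dict:
    """Duplicate-rate recovery with reads mapped to their source genome."""
    genome = simulate_genome(seed, genome_len, 50.0)
    lib = simulate_library(genome, SimConfig(seed=seed + 1, n_pairs=n_pairs,
                                             insert_mean=300, insert_sd=20,
                                             dup_prob=dup_prob,
                                             error_rate=error_rate))
    contigs = [Contig("genome", genome)]
    report, _, _ = _run_qc(lib.pairs, contigs, "PE")
    return {
        "dup_prob": dup_prob,
        "estimated_pct_dup": report.pct_dup,
        "realized_pct_dup": 100.0 * lib.truth.realized_dup_fraction,
        "pct_mapped": report.pct_mapped,
        "n_pairs": lib.truth.n_pairs,
    }


def contamination_mock(
    seed: int,
    n_pairs: int = 315_000,
    genome_len: int = 500_000,
    host_gc: float = 40.0,
    contaminant_gc: float = 50.0,
    error_rate: float = 0.001,
    subset_reps: int = 0,
    subset_fraction: float = 0.05,
) -> dict:
    """Mock-contaminated mixture at an exact 20:1 host:contaminant ratio.

    Host and contaminant genomes are the same size, so the contaminant's
    1-in-21 read share still gives it assemblable coverage once the
    total library is deep enough — mirroring how a small contaminant
    genome reaches high coverage inside a large host library. Returns
    the TAGC-recovered contaminant read fraction, host:contaminant
    ratio, and (optionally) how many of ``subset_reps`` random 5%
    contig subsets detect the contaminant taxon.
    """
    host = simulate_genome(seed, genome_len, host_gc)
    cont = simulate_genome(seed + 1, genome_len, contaminant_gc)
    genomes = {"host": host, "contaminant": cont}
    cfg = SimConfig(seed=seed + 2, n_pairs=n_pairs, insert_mean=300, insert_sd=20,
                    error_rate=error_rate,
                    spike=SpikeConfig("contaminant", ratio_host=20, ratio_contaminant=1))
    lib = simulate_library(genomes, cfg)
    contigs = assemble(lib.all_reads, AssemblyParams())
    report, aln_pairs, _ = _run_qc(lib.pairs, contigs, "PE")
    hits, _ = write_truth_hits(
        contigs, genomes, {"host": HOST_TAXON, "contaminant": CONTAMINANT_TAXON}
    )
    taxon_map = tagc.annotate_contigs(hits)
    flat = [a for p in aln_pairs for a in p]
    points = make_points(contigs, flat, taxon_map)
    total_reads = 2 * lib.truth.n_pairs
    quant = quantify_contamination(points, flat, total_reads, mode="all")
    host_pct = quant.pct_reads(HOST_TAXON)
    cont_pct = quant.pct_reads(CONTAMINANT_TAXON)
    counts = lib.truth.pair_counts_by_genome()
    realized = 100.0 * counts["contaminant"] / lib.truth.n_pairs
    out = {
        "contaminant_pct": cont_pct,
        "realized_contaminant_pct": realized,
        "host_pct": host_pct,
        "ratio": host_pct / cont_pct if cont_pct else float("inf"),
        "realized_ratio": counts["host"] / counts["contaminant"],
        "pct_mapped": report.pct_mapped,
        "n_pairs": lib.truth.n_pairs,
    }
    if subset_reps:
        detections = 0
        for rep in range(subset_reps):
            sub = quantify_contamination(points, flat, total_reads, mode="subset",
                                         subset_fraction=subset_fraction,
                                         seed=seed + 100 + rep)
            if sub.reads(CONTAMINANT_TAXON) > 0:
                detections += 1
        out["subset_detections"] = detections
        out["subset_reps"] = subset_reps
    return out


def edge_effect_experiment(
    seed: int,
    n_pairs: int = 10_000,
    genome_len: int = 200_000,
    dup_prob: float = 0.15,
    piece_len: int = 300,
) -> dict:
    """Mapping/duplicate rates on an intact genome vs 300 bp fragments.

    Both runs use edge_policy="unmapped", so reads spanning piece
    boundaries are lost on the fragmented target, depressing both the
    mapping rate and the measured duplicate rate.
    """
    genome = simulate_genome(seed, genome_len, 50.0)
    lib = simulate_library(genome, SimConfig(seed=seed + 1, n_pairs=n_pairs,
                                             insert_mean=300, insert_sd=20,
                                             dup_prob=dup_prob, error_rate=0.0))
    params = MapperParams(edge_policy="unmapped")
    intact, _, _ = _run_qc(lib.pairs, [Contig("genome", genome)], "PE", params)
    pieces = [
        Contig(f"piece_{i}", genome[p : p + piece_len])
        for i, p in enumerate(range(0, genome_len, piece_len))
    ]
    fragmented, _, _ = _run_qc(lib.pairs, pieces, "PE", params)
    return {
        "intact_pct_mapped": intact.pct_mapped,
        "intact_pct_dup": intact.pct_dup,
        "fragmented_pct_mapped": fragmented.pct_mapped,
        "fragmented_pct_dup": fragmented.pct_dup,
        "fragmented_edge_unmapped_frac": fragmented.edge_unmapped_frac,
    }
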