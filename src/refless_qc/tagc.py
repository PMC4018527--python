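"""Taxon-annotated GC-coverage (TAGC) contamination screening.

Each contig of the draft assembly becomes a point (GC%, mean read
coverage, taxon), where the taxon is the taxonomic order of the contig's
best similarity hit under an E-value threshold. Contaminant genomes
separate from the target as distinct clusters in GC-coverage space, and
the per-taxon read counts quantify the contamination level, either over
the whole assembly or over a random contig subset (a cheaper screen at
the cost of quantification accuracy).

Similarity search itself is external by construction: this module
consumes BLAST-style tabular hits (outfmt-6 column order) plus a
subject-to-taxon map; the simulator can write equivalent truth tables so
the whole path runs offline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .assembler import Contig, gc_percent
from .mapper import Alignment

__all__ = [
    "TaxonHit",
    "TAGCPoint",
    "ContaminationReport",
    "NO_HIT",
    "contig_gc",
    "contig_coverage",
    "annotate_contigs",
    "read_hits_tsv",
    "quantify_contamination",
    "tagc_table",
    "tagc_plot",
]

NO_HIT = "no-hit"
DEFAULT_EVALUE_MAX = 1e-50

OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass(frozen=True, slots=True)
class TaxonHit:
    contig_id: str
    subject_id: str
    evalue: float
    bitscore: float
    taxon_order: str


@dataclass(frozen=True, slots=True)
class TAGCPoint:
    contig_id: str
    length: int
    gc_pct: float | None
    coverage: float
    taxon_order: str = NO_HIT


@dataclass(slots=True)
class ContaminationReport:
    """Per-taxon contig/base/read tallies with the documented denominators."""

    rows: pd.DataFrame  # taxon_order, n_contigs, total_bases, n_reads_mapped, pct_reads
    mode: str
    subset_fraction: float | None
    total_reads_denominator: int

    def pct_reads(self, taxon: str) -> float:
        sel = self.rows.loc[self.rows["taxon_order"] == taxon, "pct_reads"]
        return float(sel.iloc[0]) if len(sel) else 0.0

    def reads(self, taxon: str) -> int:
        sel = self.rows.loc[self.rows["taxon_order"] == taxon, "n_reads_mapped"]
        return int(sel.iloc[0]) if len(sel) else 0


def contig_gc(contig: Contig) -> float | None:
    """GC% of a contig over unambiguous bases; None (with warning) if all N."""
    gc = gc_percent(contig.seq)
    if gc is None:
        warnings.warn(f"contig {contig.contig_id} has no unambiguous bases")
    return gc


def contig_coverage(alignments: Iterable[Alignment], contig: Contig) -> float:
    """Mean per-base depth: aligned (non-clipped) bases over contig length."""
    aligned = sum(
        a.aligned_len for a in alignments if a.mapped and a.contig_id == contig.contig_id
    )
    return aligned / contig.length if contig.length else 0.0


def coverage_by_contig(
    alignments: Iterable[Alignment], contigs: Sequence[Contig]
) -> dict[str, float]:
    """Mean depth per contig in one pass over the alignments."""
    acc: dict[str, int] = {c.contig_id: 0 for c in contigs}
    for a in alignments:
        if a.mapped and a.contig_id in acc:
            acc[a.contig_id] += a.aligned_len
    return {c.contig_id: acc[c.contig_id] / c.length for c in contigs if c.length}


def annotate_contigs(
    hits: Iterable[TaxonHit],
    evalue_max: float = DEFAULT_EVALUE_MAX,
    known_contigs: set[str] | None = None,
) -> dict[str, str]:
    """Best-hit taxon per contig under the E-value threshold.

    Among hits with evalue < evalue_max the winner has the highest
    bitscore (ties: lowest evalue, then first in input order). Hits for
    contigs not in ``known_contigs`` (when given) are skipped with a
    warning. Contigs without a qualifying hit are absent from the map
    and read as ``no-hit`` downstream.
    """
    best: dict[str, tuple[float, float, int, str]] = {}
    for i, h in enumerate(hits):
        if known_contigs is not None and h.contig_id not in known_contigs:
            warnings.warn(f"hit references unknown contig {h.contig_id!r}; skipped")
            continue
        if not (h.evalue < evalue_max):
            continue
        key = (-h.bitscore, h.evalue, i)
        cur = best.get(h.contig_id)
        if cur is None or key < cur[:3]:
            best[h.contig_id] = (*key, h.taxon_order)
    return {cid: v[3] for cid, v in best.items()}


def read_hits_tsv(hits_path, taxmap_path) -> list[TaxonHit]:
    """Load outfmt-6 hits and a subject->taxon TSV into TaxonHits."""
    hits = pd.read_csv(hits_path, sep="\t", names=OUTFMT6_COLUMNS, comment="#")
    taxmap = pd.read_csv(taxmap_path, sep="\t", names=["sseqid", "taxon_order"])
    tax = dict(zip(taxmap["sseqid"], taxmap["taxon_order"]))
    out = []
    for row in hits.itertuples(index=False):
        out.append(
            TaxonHit(
                contig_id=str(row.qseqid),
                subject_id=str(row.sseqid),
                evalue=float(row.evalue),
                bitscore=float(row.bitscore),
                taxon_order=tax.get(str(row.sseqid), NO_HIT),
            )
        )
    return out


def make_points(
    contigs: Sequence[Contig],
    alignments: Iterable[Alignment],
    taxon_map: Mapping[str, str] | None = None,
) -> list[TAGCPoint]:
    cov = coverage_by_contig(alignments, contigs)
    taxon_map = taxon_map or {}
    return [
        TAGCPoint(
            contig_id=c.contig_id,
            length=c.length,
            gc_pct=gc_percent(c.seq),
            coverage=cov.get(c.contig_id, 0.0),
            taxon_order=taxon_map.get(c.contig_id, NO_HIT),
        )
        for c in contigs
    ]


def quantify_contamination(
    points: Sequence[TAGCPoint],
    alignments: Iterable[Alignment],
    total_library_reads: int,
    mode: str = "all",
    subset_fraction: float = 0.05,
    seed: int = 0,
) -> ContaminationReport:
    """Per-taxon read quantification over all contigs or a random subset.

    mode="all": pct_reads = 100 * reads on that taxon's contigs /
    total_library_reads. mode="subset": floor(subset_fraction *
    n_contigs) contigs are drawn uniformly without replacement with the
    given seed and pct_reads uses reads mapped to the subset as the
    denominator. Each read counts once via its primary alignment.
    """
    if mode not in ("all", "subset"):
        raise ValueError("mode must be 'all' or 'subset'")
    taxon_of = {p.contig_id: p.taxon_order for p in points}
    info = {p.contig_id: p for p in points}
    selected = set(taxon_of)
    if mode == "subset":
        ids = sorted(taxon_of)
        n_take = int(subset_fraction * len(ids))
        if n_take == 0:
            raise ValueError("subset of size 0; increase subset_fraction")
        rng = np.random.default_rng(seed)
        selected = set(rng.choice(ids, size=n_take, replace=False).tolist())
    read_counts: dict[str, int] = {}
    subset_mapped = 0
    for a in alignments:
        if not a.mapped or a.contig_id not in selected:
            continue
        subset_mapped += 1
        taxon = taxon_of.get(a.contig_id, NO_HIT)
        read_counts[taxon] = read_counts.get(taxon, 0) + 1
    denom = total_library_reads if mode == "all" else subset_mapped
    taxa = sorted(
        {taxon_of[c] for c in selected} | set(read_counts),
    )
    rows = []
    for taxon in taxa:
        cids = [c for c in selected if taxon_of[c] == taxon]
        rows.append(
            {
                "taxon_order": taxon,
                "n_contigs": len(cids),
                "total_bases": int(sum(info[c].length for c in cids)),
                "n_reads_mapped": read_counts.get(taxon, 0),
                "pct_reads": 100.0 * read_counts.get(taxon, 0) / denom if denom else 0.0,
            }
        )
    return ContaminationReport(
        rows=pd.DataFrame(rows, columns=["taxon_order", "n_contigs", "total_bases",
                                         "n_reads_mapped", "pct_reads"]),
        mode=mode,
        subset_fraction=subset_fraction if mode == "subset" else None,
        total_reads_denominator=denom,
    )


def tagc_table(points: Sequence[TAGCPoint], dest=None) -> pd.DataFrame:
    """TAGC points as a DataFrame (optionally written as TSV)."""
    df = pd.DataFrame(
        [
            {
                "contig_id": p.contig_id,
                "length": p.length,
                "gc_pct": p.gc_pct,
                "coverage": p.coverage,
                "taxon_order": p.taxon_order,
            }
            for p in points
        ],
        columns=["contig_id", "length", "gc_pct", "coverage", "taxon_order"],
    )
    if dest is not None:
        df.to_csv(dest, sep="\t", index=False)
    return df


COVERAGE_FLOOR = 0.01  # zero-coverage contigs are drawn at this pseudo-depth


def tagc_plot(points: Sequence[TAGCPoint], dest) -> None:
    """GC (x) vs log-coverage (y) scatter, one color per taxon, gray no-hit."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not points:
        warnings.warn("no TAGC points; plot skipped")
        return
    taxa = sorted({p.taxon_order for p in points} - {NO_HIT})
    cmap = plt.get_cmap("tab10")
    colors = {t: cmap(i % 10) for i, t in enumerate(taxa)}
    colors[NO_HIT] = (0.6, 0.6, 0.6, 1.0)
    fig, ax = plt.subplots(figsize=(7, 5))
    for taxon in [NO_HIT] + taxa:
        xs = [p.gc_pct for p in points if p.taxon_order == taxon and p.gc_pct is not None]
        ys = [max(p.coverage, COVERAGE_FLOOR)
              for p in points if p.taxon_order == taxon and p.gc_pct is not None]
        if xs:
            ax.scatter(xs, ys, s=8, alpha=0.6, label=taxon, color=colors[taxon])
    ax.set_xlim(0, 100)
    ax.set_yscale("log")
    ax.set_xlabel("GC (%)")
    ax.set_ylabel("read coverage")
    ax.legend(fontsize=8, markerscale=2)
    fig.tight_layout()
    fig.savefig(dest, dpi=120)
    plt.close(fig)
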