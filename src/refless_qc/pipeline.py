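"""End-to-end reference-free QC protocol and consolidated reporting.

Stages: trim -> draft assembly (from the standard paired-end libraries)
-> map every library back to the draft -> per-library QC metrics ->
optional TAGC contamination screen. Mate-pair libraries are never fed
into the draft; they are mapped against the assembly built from the
paired-end libraries, which is how multi-kb insert distributions are
estimated reliably. When a reference FASTA is supplied, every library
is additionally mapped to it and the report carries draft-vs-reference
metrics side by side (validation mode).

All stage artifacts (trimmed FASTQ, contigs FASTA, SAM, TSV/JSON
tables, plots) are written under the output directory with stable
names; re-running with the same config and inputs reproduces them
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import assembler, io_preprocess, mapper, qc_metrics, tagc
from .assembler import AssemblyParams, Contig
from .io_preprocess import TrimPolicy
from .mapper import MapperParams

__all__ = [
    "LibraryDecl",
    "PipelineConfig",
    "QCReportBundle",
    "PipelineError",
    "run_pipeline",
    "render_report",
]

log = logging.getLogger("refless_qc")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass(frozen=True, slots=True)
class LibraryDecl:
    name: str
    library_type: str  # PE | MP
    r1: str
    r2: str


@dataclass(slots=True)
class PipelineConfig:
    libraries: list[LibraryDecl]
    trim: TrimPolicy = field(default_factory=TrimPolicy)
    assembly: AssemblyParams = field(default_factory=AssemblyParams)
    mapper_params: MapperParams = field(default_factory=MapperParams)
    assembly_source: list[str] | None = None  # default: all PE libraries
    hits: str | None = None
    taxmap: str | None = None
    evalue_max: float = tagc.DEFAULT_EVALUE_MAX
    subset_fraction: float | None = None
    reference: str | None = None
    reference_size: int | None = None
    seed: int = 0

    def __post_init__(self):
        names = [d.name for d in self.libraries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate library names")
        sources = self.assembly_source or [
            d.name for d in self.libraries if d.library_type == "PE"
        ]
        has_mp = any(d.library_type == "MP" for d in self.libraries)
        feeds_pe = any(
            d.library_type == "PE" for d in self.libraries if d.name in sources
        )
        if has_mp and not feeds_pe:
            raise ValueError(
                "a mate-pair library is declared but no paired-end library "
                "feeds the draft assembly"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        libs = [
            LibraryDecl(d["name"], d.get("type", "PE"), d["r1"], d["r2"])
            for d in doc.get("libraries", [])
        ]
        trim = TrimPolicy(**doc.get("trim", {}))
        assembly = AssemblyParams(**doc.get("assembly", {}))
        mp = MapperParams(**doc.get("mapper", {}))
        t = doc.get("tagc", {})
        return cls(
            libraries=libs,
            trim=trim,
            assembly=assembly,
            mapper_params=mp,
            assembly_source=doc.get("assembly_source"),
            hits=t.get("hits"),
            taxmap=t.get("taxmap"),
            evalue_max=float(t.get("evalue_max", tagc.DEFAULT_EVALUE_MAX)),
            subset_fraction=t.get("subset_fraction"),
            reference=doc.get("reference"),
            reference_size=doc.get("reference_size"),
            seed=int(doc.get("seed", 0)),
        )


@dataclass(slots=True)
class QCReportBundle:
    """Everything the pipeline computed, JSON-serializable."""

    libraries: dict[str, dict]  # name -> LibraryQCReport dict (draft mapping)
    reference_libraries: dict[str, dict]  # same, vs reference (validation mode)
    assembly: dict
    contamination: dict | None  # None == not screened
    trim_counts: dict[str, dict]
    provenance: dict

    def to_json(self, dest=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if dest is not None:
            Path(dest).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "QCReportBundle":
        if isinstance(source, Path) or (
            isinstance(source, str) and "\n" not in source and Path(source).exists()
        ):
            source = Path(source).read_text()
        return cls(**json.loads(source))


def _md5(path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir) -> QCReportBundle:
    """Run the full protocol; artifacts land under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # validation before any stage runs
    for d in config.libraries:
        for p in (d.r1, d.r2):
            if not Path(p).exists():
                raise PipelineError("validate", f"missing FASTQ {p}")
    for p in (config.hits, config.taxmap, config.reference):
        if p is not None and not Path(p).exists():
            raise PipelineError("validate", f"missing input {p}")

    trimmed: dict[str, list] = {}
    trim_counts: dict[str, dict] = {}
    for d in config.libraries:
        try:
            pairs = io_preprocess.read_fastq_pairs(d.r1, d.r2)
            kept, counts = io_preprocess.trim_pairs(pairs, config.trim)
        except Exception as exc:
            raise PipelineError("trim", f"library {d.name}: {exc}") from exc
        trimmed[d.name] = kept
        trim_counts[d.name] = counts.as_dict()
        io_preprocess.write_fastq((r for p in kept for r in p[:1]), out / f"{d.name}.trimmed.R1.fastq")
        io_preprocess.write_fastq((r for p in kept for r in p[1:]), out / f"{d.name}.trimmed.R2.fastq")
        log.info("trim %s: %s", d.name, counts.as_dict())

    sources = config.assembly_source or [
        d.name for d in config.libraries if d.library_type == "PE"
    ]
    try:
        reads = [r for name in sources for pair in trimmed[name] for r in pair]
        contigs = assembler.assemble(reads, config.assembly)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("assemble", str(exc)) from exc
    assembler.write_fasta(contigs, out / "contigs.fasta")
    stats = assembler.assembly_stats(contigs, config.reference_size)
    log.info("assembly: %s", stats.as_dict())

    reference_contigs = None
    if config.reference:
        reference_contigs = assembler.read_fasta(config.reference)

    lib_reports: dict[str, dict] = {}
    ref_reports: dict[str, dict] = {}
    all_draft_alignments = []
    for d in config.libraries:
        kept = trimmed[d.name]
        try:
            report, aln_pairs = _map_and_report(
                d, kept, contigs, config.mapper_params, out, suffix="draft"
            )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("map", f"library {d.name}: {exc}") from exc
        lib_reports[d.name] = report.as_dict()
        all_draft_alignments.extend(a for pair in aln_pairs for a in pair)
        _insert_plot(report, out / f"{d.name}.insert_hist.png")
        if reference_contigs:
            ref_report, _ = _map_and_report(
                d, kept, reference_contigs, config.mapper_params, out, suffix="reference"
            )
            ref_reports[d.name] = ref_report.as_dict()

    contamination = None
    if config.hits and config.taxmap:
        try:
            hits = tagc.read_hits_tsv(config.hits, config.taxmap)
            taxon_map = tagc.annotate_contigs(
                hits, config.evalue_max, known_contigs={c.contig_id for c in contigs}
            )
            points = tagc.make_points(contigs, all_draft_alignments, taxon_map)
            total_reads = sum(c["reads_in"] for c in trim_counts.values())
            mode = "subset" if config.subset_fraction else "all"
            report = tagc.quantify_contamination(
                points,
                all_draft_alignments,
                total_reads,
                mode=mode,
                subset_fraction=config.subset_fraction or 0.05,
                seed=config.seed,
            )
            tagc.tagc_table(points, out / "tagc_points.tsv")
            tagc.tagc_plot(points, out / "tagc_plot.png")
            report.rows.to_csv(out / "contamination.tsv", sep="\t", index=False)
            contamination = {
                "mode": report.mode,
                "subset_fraction": report.subset_fraction,
                "total_reads_denominator": report.total_reads_denominator,
                "rows": report.rows.to_dict(orient="records"),
            }
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("tagc", str(exc)) from exc

    provenance = {
        "seed": config.seed,
        "trim": asdict(config.trim),
        "assembly": asdict(config.assembly),
        "mapper": asdict(config.mapper_params),
        "assembly_source": sources,
        "libraries": [asdict(d) for d in config.libraries],
        "input_md5": {
            d.name: {"r1": _md5(d.r1), "r2": _md5(d.r2)} for d in config.libraries
        },
    }
    bundle = QCReportBundle(
        libraries=lib_reports,
        reference_libraries=ref_reports,
        assembly=stats.as_dict(),
        contamination=contamination,
        trim_counts=trim_counts,
        provenance=provenance,
    )
    bundle.to_json(out / "report.json")
    (out / "report.md").write_text(render_report(bundle))
    return bundle


def _map_and_report(decl: LibraryDecl, kept, contigs, params, out: Path, suffix: str):
    index = mapper.SeedIndex(contigs, params.seed_len)
    aln_pairs = mapper.map_pairs(kept, index, params)
    mapper.write_sam(out / f"{decl.name}.{suffix}.sam", kept, aln_pairs, contigs)
    pair_alns = qc_metrics.pair_up_all(aln_pairs, library_type=decl.library_type)
    report = qc_metrics.library_report(
        pair_alns, library=decl.name, library_type=decl.library_type
    )
    return report, aln_pairs


def _insert_plot(report, dest) -> None:
    if not report.insert_histogram:
        return
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs = sorted(report.insert_histogram)
    ys = [report.insert_histogram[x] for x in xs]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(xs, ys, lw=1)
    ax.set_xlabel("insert size (bp)")
    ax.set_ylabel("pairs")
    ax.set_title(f"{report.library}: insert size distribution")
    fig.tight_layout()
    fig.savefig(dest, dpi=120)
    plt.close(fig)


def render_report(bundle: QCReportBundle) -> str:
    """Render the bundle as Markdown mirroring the standard QC tables."""
    lines = ["# Reference-free QC report", ""]
    lines.append("## Assembly metrics")
    lines.append("")
    a = bundle.assembly
    header = ["#Contigs", "Total bases", "Max contig (bp)", "N50 (bp)",
              "GC contigs (%)", "#Contigs >1 kb", "Bases >1 kb",
              "Chaff size (%)", "Assembly size (%)"]
    vals = [a["n_contigs"], a["total_bases"], a["max_len"], a["n50"],
            _fmt(a["gc_pct"]), a["n_over_1kb"], a["bases_over_1kb"],
            _fmt(a["chaff_pct"]), _fmt(a["assembly_size_pct"])]
    lines.append("| " + " | ".join(header) + " |")
    lines.append("|" + "---|" * len(header))
    lines.append("| " + " | ".join(str(v) for v in vals) + " |")
    lines.append("")
    for title, reports in (
        ("## Mapping statistics (draft assembly)", bundle.libraries),
        ("## Mapping statistics (reference)", bundle.reference_libraries),
    ):
        if not reports:
            continue
        lines.append(title)
        lines.append("")
        cols = ["Sample ID", "#Reads mapped", "%Reads mapped", "#Duplicate reads",
                "%Duplicate reads", "Mean insert length", "SD insert length"]
        lines.append("| " + " | ".join(cols) + " |")
        lines.append("|" + "---|" * len(cols))
        for name, r in reports.items():
            lines.append(
                "| " + " | ".join(str(v) for v in [
                    name, r["n_reads_mapped"], _fmt(r["pct_mapped"]),
                    r["n_dup_reads"], _fmt(r["pct_dup"]),
                    _fmt(r["insert_mean"]), _fmt(r["insert_sd"]),
                ]) + " |"
            )
        lines.append("")
    lines.append("## Contamination screen")
    lines.append("")
    if bundle.contamination is None:
        lines.append("not screened (no hits/taxon map supplied)")
    else:
        c = bundle.contamination
        cols = ["Taxon", "#Contigs", "Total bases", "#Reads mapped", "%Reads mapped"]
        lines.append("| " + " | ".join(cols) + " |")
        lines.append("|" + "---|" * len(cols))
        for row in c["rows"]:
            lines.append(
                "| " + " | ".join(str(v) for v in [
                    row["taxon_order"], row["n_contigs"], row["total_bases"],
                    row["n_reads_mapped"], _fmt(row["pct_reads"]),
                ]) + " |"
            )
        lines.append("")
        lines.append(f"mode: {c['mode']}; denominator: {c['total_reads_denominator']} reads")
    lines.append("")
    lines.append("## Provenance")
    lines.append("")
    lines.append("```json")
    lines.append(json.dumps(bundle.provenance, indent=2, sort_keys=True))
    lines.append("```")
    return "\n".join(lines) + "\n"


def _fmt(v) -> str:
    if v is None:
        return "-"
    if isinstance(v, float):
        return f"{v:.2f}"
    return str(v)
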