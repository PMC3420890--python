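"""End-to-end pipeline: trim -> filter -> exact map -> poly(A) -> editing -> quantify.

Stage order is fixed. Exact once-per-read mapping runs first; only reads it
leaves unannotated enter the poly(A) rescue; only reads still unannotated
after that are re-mapped with mismatches for the editing analysis. The run
report carries the per-stage read dispositions and asserts the conservation
identity perfect + polyA + mismatch + unannotated == filtered input on
every execution.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import editing as ed
from . import quantify as qt
from .mapper import (
    AnnotationLedger,
    Disposition,
    annotate_once,
    rescue_with_mismatches,
    write_alignment_table,
)
from .model import AnalysisConfig, PlasmidRef, load_reference
from .polya import PolyAJunction, detect_polya, write_junction_bed, write_junction_table
from .readprep import RawRead, TrimStats, prepare_reads, read_fastq

logger = logging.getLogger(__name__)


@dataclass
class RunReport:
    parameters: dict
    trim_stats: dict
    dispositions: dict[str, int]
    multihit: int
    library_stats: dict
    warnings: list[str] = field(default_factory=list)
    manifest: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "parameters": self.parameters,
            "trim_stats": self.trim_stats,
            "dispositions": self.dispositions,
            "multihit": self.multihit,
            "library_stats": self.library_stats,
            "warnings": self.warnings,
            "manifest": self.manifest,
        }


@dataclass
class PipelineResult:
    ref: PlasmidRef
    cfg: AnalysisConfig
    ledger: AnnotationLedger
    trim_stats: TrimStats
    junctions: list[PolyAJunction]
    spectrum: ed.SubstitutionSpectrum
    multi_conversions: ed.MultiConversionTable
    profile: ed.EditedReadProfile
    quant: pd.DataFrame
    coverage: qt.CoverageTrack
    library_stats: qt.LibraryStats
    report: RunReport


def run(
    raw_reads: list[RawRead],
    ref: PlasmidRef,
    cfg: AnalysisConfig,
    genome_mapped: int = 0,
    drop_multihit: bool = False,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Execute all stages on in-memory reads and collect every product."""
    kept, trim_stats = prepare_reads(raw_reads, cfg)
    logger.info("trim/filter: %s", trim_stats.as_dict())

    ledger = annotate_once(kept, ref, cfg, drop_multihit=drop_multihit)
    logger.info("first-round exact mapping: %s (multi-hit %d)", ledger.counts(), ledger.multihit)

    junctions = detect_polya(ledger, ref, cfg)
    logger.info("polyA rescue: %d junctions", len(junctions))

    rescued = rescue_with_mismatches(ledger, ref, cfg)
    logger.info("mismatch remapping rescued %d reads", rescued)

    ledger.assert_conservation(len(kept))

    mm_alignments = [
        a for a in ledger.alignments(Disposition.MISMATCH) if a.n_mismatch >= 1
    ]
    spectrum = ed.substitution_spectrum(mm_alignments, cfg)
    multi = ed.multi_conversion_counts(mm_alignments, cfg)
    profile = ed.edited_read_profile(mm_alignments, ref, cfg)

    counts = ledger.counts()
    lib = qt.LibraryStats(
        total_raw_reads=trim_stats.input_reads,
        reads_after_filter=len(kept),
        plasmid_mapped=counts[Disposition.PERFECT.value],
        genome_mapped=genome_mapped,
    )
    library_size = cfg.library_size or lib.library_size
    coverage = qt.coverage_track(ledger, ref, cfg, denominator=library_size)
    quant = qt.quantify_features(ledger, ref, library_size)

    warnings = []
    if ledger.multihit:
        warnings.append(f"{ledger.multihit} reads hit multiple loci (tie-break applied)")
    if trim_stats.rejected_invalid:
        warnings.append(f"{trim_stats.rejected_invalid} reads rejected (N or invalid characters)")

    report = RunReport(
        parameters={
            "adapter": cfg.adapter,
            "min_adapter_match": cfg.min_adapter_match,
            "read_len_window": [cfg.read_min_len, cfg.read_max_len],
            "editing_max_mismatch": cfg.editing_max_mismatch,
            "short_class": list(cfg.short_class),
            "editing_profile_window": list(cfg.editing_profile_window),
            "polya_min_remap_len": cfg.polya_min_remap_len,
            "library_size": library_size,
            "drop_multihit": drop_multihit,
        },
        trim_stats=trim_stats.as_dict(),
        dispositions=counts,
        multihit=ledger.multihit,
        library_stats={
            "total_raw_reads": lib.total_raw_reads,
            "reads_after_filter": lib.reads_after_filter,
            "plasmid_mapped": lib.plasmid_mapped,
            "genome_mapped": lib.genome_mapped,
            "library_size": lib.library_size,
        },
        warnings=warnings,
    )

    result = PipelineResult(
        ref=ref,
        cfg=cfg,
        ledger=ledger,
        trim_stats=trim_stats,
        junctions=junctions,
        spectrum=spectrum,
        multi_conversions=multi,
        profile=profile,
        quant=quant,
        coverage=coverage,
        library_stats=lib,
        report=report,
    )
    if outdir is not None:
        _write_products(result, Path(outdir))
    return result


def _write_products(res: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []

    def _add(p: Path) -> Path:
        manifest.append(str(p))
        return p

    write_alignment_table(
        res.ledger.alignments(Disposition.PERFECT, Disposition.POLYA, Disposition.MISMATCH),
        _add(outdir / "alignments.tsv"),
    )
    write_junction_table(res.junctions, _add(outdir / "polya_junctions.tsv"))
    write_junction_bed(res.junctions, _add(outdir / "polya_junctions.bed"))
    ed.write_spectrum(res.spectrum, _add(outdir / "substitution_spectrum.tsv"))
    res.multi_conversions.counts.to_csv(_add(outdir / "multi_conversions.tsv"), sep="\t")
    ed.write_profile_bedgraph(res.profile, outdir / "edited_profile")
    qt.write_coverage_bedgraph(res.coverage, outdir / "coverage")
    res.quant.to_csv(_add(outdir / "feature_quant.tsv"), sep="\t", index=False)
    res.report.manifest = manifest
    (outdir / "run_report.json").write_text(json.dumps(res.report.as_dict(), indent=2) + "\n")


def parse_config_file(path: str | Path) -> dict[str, str]:
    """Flat key=value configuration ('#' comments, blank lines ignored)."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value")
        k, v = line.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def run_pipeline(config_path: str | Path) -> RunReport:
    """File-driven entry point: read config, execute all stages, write outputs."""
    conf = parse_config_file(config_path)
    base = Path(config_path).parent

    def _path(key: str) -> Path:
        p = Path(conf[key])
        return p if p.is_absolute() else base / p

    ref = load_reference(_path("fasta"), _path("annotation") if "annotation" in conf else None)
    cfg = AnalysisConfig(
        adapter=conf["adapter"],
        min_adapter_match=int(conf.get("min_adapter_match", 3)),
        read_min_len=int(conf.get("read_min_len", 18)),
        read_max_len=int(conf.get("read_max_len", 50)),
        editing_max_mismatch=int(conf.get("editing_max_mismatch", 5)),
        polya_min_remap_len=int(conf.get("polya_min_remap_len", 18)),
        library_size=int(conf["library_size"]) if "library_size" in conf else None,
    )
    reads = list(read_fastq(_path("fastq")))
    outdir = _path("outdir") if "outdir" in conf else base / "pipeline_out"
    res = run(
        reads,
        ref,
        cfg,
        genome_mapped=int(conf.get("genome_mapped", 0)),
        drop_multihit=conf.get("drop_multihit", "false").lower() == "true",
        outdir=outdir,
    )
    return res.report
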