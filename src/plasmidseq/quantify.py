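"""Strand-specific coverage tracks and RPKM/RPM feature quantification.

Normalisation conventions:

* RPKM = count x 10^9 / (feature length in nt x library size), where the
  library size is the number of reads mapping perfectly to the genome or
  the transfected plasmid (the genome-mapped count enters as an external
  parameter);
* RPM = count x 10^6 / library size, for unit-length entities (miRNAs);
* coverage tracks are counts-per-million (CPM): raw per-base (or
  per-start) counts x 10^6 / denominator. The denominator defaults to the
  library size so tracks are comparable across samples; a
  plasmid-mapped-only denominator is available and recorded in the track
  metadata either way.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .editing import overlap_fraction
from .mapper import Alignment, AnnotationLedger, Disposition
from .model import ANTISENSE, SENSE, AnalysisConfig, Feature, PlasmidRef


def rpkm(count: int, length_nt: int, library_size: int) -> float:
    """Reads per kilobase of feature per million mapped reads."""
    if length_nt <= 0:
        raise ValueError("length_nt must be positive")
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return count * 1e9 / (length_nt * library_size)


def rpm(count: int, library_size: int) -> float:
    """Reads per million mapped reads."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return count * 1e6 / library_size


@dataclass
class LibraryStats:
    total_raw_reads: int
    reads_after_filter: int
    plasmid_mapped: int  # perfect first-round placements
    genome_mapped: int  # supplied externally (out-of-scope aligner)

    @property
    def library_size(self) -> int:
        return self.plasmid_mapped + self.genome_mapped


@dataclass
class CoverageTrack:
    plasmid: str
    raw: dict[str, np.ndarray]
    denominator: int
    mode: str  # "base" (per-base density) or "start"

    @property
    def cpm(self) -> dict[str, np.ndarray]:
        return {s: arr * 1e6 / self.denominator for s, arr in self.raw.items()}


def coverage_track(
    ledger: AnnotationLedger,
    ref: PlasmidRef,
    cfg: AnalysisConfig,
    denominator: int | None = None,
    mode: str = "base",
    dispositions: Sequence[Disposition] = (Disposition.PERFECT, Disposition.POLYA),
) -> CoverageTrack:
    """Per-position strand-specific coverage over mapped reads.

    Default input are first-round perfect placements plus the exact
    placements of poly(A)-trimmed remainders; wraps circularly.
    """
    if mode not in ("base", "start"):
        raise ValueError(f"unknown coverage mode {mode!r}")
    raw = {SENSE: np.zeros(ref.length), ANTISENSE: np.zeros(ref.length)}
    for aln in ledger.alignments(*dispositions):
        if not cfg.read_min_len <= aln.aligned_length <= cfg.read_max_len:
            continue
        if mode == "start":
            raw[aln.strand][aln.position] += 1
        else:
            for p in aln.covered_positions(ref.length):
                raw[aln.strand][p] += 1
    denom = denominator if denominator is not None else cfg.library_size
    if not denom or denom <= 0:
        raise ValueError("a positive CPM denominator (library_size) is required")
    return CoverageTrack(plasmid=ref.name, raw=raw, denominator=denom, mode=mode)


def quantify_features(
    ledger: AnnotationLedger,
    ref: PlasmidRef,
    library_size: int,
    min_overlap: float = 0.5,
    dispositions: Sequence[Disposition] = (Disposition.PERFECT, Disposition.POLYA),
) -> pd.DataFrame:
    """Per-feature read counts and RPKM, Table-style.

    A read counts toward a feature when >= ``min_overlap`` of its aligned
    bases lie inside it.
    """
    alignments = ledger.alignments(*dispositions)
    rows = []
    for feat in ref.features:
        count = sum(
            1
            for aln in alignments
            if overlap_fraction(aln, feat, ref.length) >= min_overlap
        )
        rows.append(
            {
                "feature": feat.name,
                "length_nt": feat.length,
                "count": count,
                "RPKM": rpkm(count, feat.length, library_size) if count else 0.0,
            }
        )
    return pd.DataFrame(rows)


def write_coverage_bedgraph(
    track: CoverageTrack,
    path_prefix: str | Path,
    cutoff: float | None = None,
    negate_antisense: bool = False,
) -> None:
    """CPM bedGraph per strand; ``cutoff`` clips displayed values at export."""
    for strand, arr in track.cpm.items():
        vals = arr.copy()
        if cutoff is not None:
            vals = np.minimum(vals, cutoff)
        if negate_antisense and strand == ANTISENSE:
            vals = -vals
        out = Path(f"{path_prefix}.{strand}.bedgraph")
        lines = [
            f'track type=bedGraph name="{track.plasmid}_{strand}_CPM_{track.mode}" '
            f"# denominator={track.denominator}"
        ]
        for p in np.flatnonzero(arr):
            lines.append(f"{track.plasmid}\t{p}\t{p + 1}\t{vals[p]:.4f}")
        out.write_text("\n".join(lines) + "\n")
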