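"""A-to-I editing analysis over mismatch-remapped reads.

Inosine is read as G by the sequencer, so editing of a transcript appears
as an A->G substitution against the reference, *on the strand the RNA was
transcribed from*. All conversion counting here therefore works in
transcript orientation (see :func:`plasmidseq.mapper.transcript_conversions`):
an antisense read whose sense-strand mismatch is T->C is counted as A->G.

Three complementary statistics:

* the 12-way substitution spectrum stratified by read-length class
  (short 21-26 nt vs long full-length reads) — editing inflates the A>G
  cell of the short class;
* counts of reads carrying multiple identical conversions — repeated A->G
  within one read is far more likely under deamination than under
  independent sequencing errors;
* the positional profile of short edited reads along the plasmid — editing
  requires double-stranded RNA and therefore clusters where sense and
  antisense transcription overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .mapper import Alignment, transcript_conversions
from .model import ANTISENSE, SENSE, AnalysisConfig, Feature, PlasmidRef

BASES = "ACGT"
CONVERSIONS = [f"{r}>{q}" for r in BASES for q in BASES if r != q]

SHORT, LONG, OTHER = "short", "long", "other"


def _check_alignment(aln: Alignment) -> None:
    for off, r, q in aln.mismatches:
        if r == q or not (0 <= off < aln.aligned_length):
            raise ValueError(f"inconsistent mismatch list on read {aln.read_id!r}: {aln.mismatches}")


def length_class(aln_length: int, cfg: AnalysisConfig) -> str:
    lo, hi = cfg.short_class
    if lo <= aln_length <= hi:
        return SHORT
    if aln_length == cfg.read_max_len:
        return LONG
    return OTHER


@dataclass
class SubstitutionSpectrum:
    """12-way conversion counts per length class, plus reads evaluated."""

    counts: pd.DataFrame  # index CONVERSIONS, columns [short, long, other]
    reads_evaluated: dict[str, int]

    def frequency(self, klass: str = SHORT) -> pd.Series:
        """Conversions per evaluated read in one length class."""
        n = self.reads_evaluated.get(klass, 0)
        if n == 0:
            return self.counts[klass] * 0.0
        return self.counts[klass] / n

    @property
    def total_substitutions(self) -> int:
        return int(self.counts.to_numpy().sum())


def substitution_spectrum(
    alignments: Iterable[Alignment], cfg: AnalysisConfig
) -> SubstitutionSpectrum:
    counts = pd.DataFrame(0, index=CONVERSIONS, columns=[SHORT, LONG, OTHER])
    evaluated = {SHORT: 0, LONG: 0, OTHER: 0}
    for aln in alignments:
        _check_alignment(aln)
        klass = length_class(aln.aligned_length, cfg)
        evaluated[klass] += 1
        for r, q in transcript_conversions(aln):
            counts.loc[f"{r}>{q}", klass] += 1
    return SubstitutionSpectrum(counts=counts, reads_evaluated=evaluated)


@dataclass
class MultiConversionTable:
    """Short-class reads with >=k identical conversions, k in {2,3,4}."""

    counts: pd.DataFrame  # index CONVERSIONS, columns ["k>=2","k>=3","k>=4"]
    ag_share: float  # fraction of multi-conversion reads whose repeat is A>G

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if not ((arr[:, 0] >= arr[:, 1]).all() and (arr[:, 1] >= arr[:, 2]).all()):
            raise AssertionError("multi-conversion counts must be non-increasing in k")


def multi_conversion_counts(
    alignments: Iterable[Alignment], cfg: AnalysisConfig
) -> MultiConversionTable:
    cols = ["k>=2", "k>=3", "k>=4"]
    counts = pd.DataFrame(0, index=CONVERSIONS, columns=cols)
    n_multi = 0
    n_multi_ag = 0
    for aln in alignments:
        if length_class(aln.aligned_length, cfg) != SHORT:
            continue
        per_type: dict[str, int] = {}
        for r, q in transcript_conversions(aln):
            key = f"{r}>{q}"
            per_type[key] = per_type.get(key, 0) + 1
        repeated = {t for t, n in per_type.items() if n >= 2}
        if repeated:
            n_multi += 1
            if "A>G" in repeated:
                n_multi_ag += 1
        for t, n in per_type.items():
            for k, col in ((2, "k>=2"), (3, "k>=3"), (4, "k>=4")):
                if n >= k:
                    counts.loc[t, col] += 1
    share = n_multi_ag / n_multi if n_multi else float("nan")
    return MultiConversionTable(counts=counts, ag_share=share)


@dataclass
class EditedReadProfile:
    """Positions of short edited reads along the plasmid, by strand.

    Two representations are kept, labelled in the metadata: ``density``
    adds 1 to every covered position of a qualifying read; ``starts``
    counts the 5'-most sense coordinate only.
    """

    plasmid: str
    density: dict[str, np.ndarray]
    starts: dict[str, np.ndarray]
    window: tuple[int, int]
    n_reads: dict[str, int]

    def mass_in(self, start: int, end: int, mode: str = "density") -> float:
        """Fraction of total profile mass inside sense interval [start, end)."""
        tracks = self.density if mode == "density" else self.starts
        L = len(next(iter(tracks.values())))
        sel = np.zeros(L, dtype=bool)
        for p in range(start, end):
            sel[p % L] = True
        total = sum(t.sum() for t in tracks.values())
        if total == 0:
            return float("nan")
        return float(sum(t[sel].sum() for t in tracks.values()) / total)


def edited_read_profile(
    alignments: Iterable[Alignment], ref: PlasmidRef, cfg: AnalysisConfig
) -> EditedReadProfile:
    lo, hi = cfg.editing_profile_window
    density = {SENSE: np.zeros(ref.length), ANTISENSE: np.zeros(ref.length)}
    starts = {SENSE: np.zeros(ref.length), ANTISENSE: np.zeros(ref.length)}
    n_reads = {SENSE: 0, ANTISENSE: 0}
    for aln in alignments:
        if not lo <= aln.aligned_length <= hi:
            continue
        if not any(r == "A" and q == "G" for r, q in transcript_conversions(aln)):
            continue
        n_reads[aln.strand] += 1
        starts[aln.strand][aln.position] += 1
        for p in aln.covered_positions(ref.length):
            density[aln.strand][p] += 1
    return EditedReadProfile(
        plasmid=ref.name,
        density=density,
        starts=starts,
        window=(lo, hi),
        n_reads=n_reads,
    )


def overlap_fraction(aln: Alignment, feature: Feature, plasmid_length: int) -> float:
    """Fraction of a read's aligned bases lying inside the feature."""
    fpos = feature.positions(plasmid_length)
    covered = aln.covered_positions(plasmid_length)
    inside = sum(1 for p in covered if p in fpos)
    return inside / len(covered)


def size_distribution(
    alignments: Sequence[Alignment],
    feature: Feature,
    ref: PlasmidRef,
    cfg: AnalysisConfig,
    lengths: range = range(18, 27),
    min_overlap: float = 0.5,
) -> pd.DataFrame:
    """Per-length read counts over a feature with edited (A>G) subcounts.

    A read counts toward the feature when at least ``min_overlap`` of its
    aligned bases fall inside it (set 1.0 for full containment).
    """
    rows = {n: {"total": 0, "edited": 0} for n in lengths}
    for aln in alignments:
        n = aln.aligned_length
        if n not in rows:
            continue
        if overlap_fraction(aln, feature, ref.length) < min_overlap:
            continue
        rows[n]["total"] += 1
        if any(r == "A" and q == "G" for r, q in transcript_conversions(aln)):
            rows[n]["edited"] += 1
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "length"
    return df


def write_spectrum(spec: SubstitutionSpectrum, path: str | Path) -> None:
    df = spec.counts.copy()
    df.index.name = "conversion"
    with open(path, "w") as fh:
        fh.write(f"# reads evaluated: {spec.reads_evaluated}\n")
        df.to_csv(fh, sep="\t")


def write_profile_bedgraph(profile: EditedReadProfile, path_prefix: str | Path) -> None:
    """One bedGraph per strand and representation (4 files)."""
    for mode, tracks in (("density", profile.density), ("starts", profile.starts)):
        for strand, arr in tracks.items():
            out = Path(f"{path_prefix}.{mode}.{strand}.bedgraph")
            lines = [
                f'track type=bedGraph name="edited_{profile.window[0]}-{profile.window[1]}nt_{strand}_{mode}"'
            ]
            for p in np.flatnonzero(arr):
                lines.append(f"{profile.plasmid}\t{p}\t{p + 1}\t{arr[p]:g}")
            out.write_text("\n".join(lines) + "\n")
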