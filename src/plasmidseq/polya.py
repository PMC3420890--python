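"""Poly(A)-junction detection among reads that failed exact mapping.

Reads carrying an untemplated adenosine tail do not place exactly on the
plasmid. The rescue rule: if a read ends in A, strip the maximal terminal
A-run; if the remainder is still long enough (>17 nt by default) and maps
exactly, the 3' end of that alignment is a putative polyadenylation
junction. Junction coordinates follow transcript orientation: for a sense
read the junction is the sense coordinate of the last aligned base; for an
antisense read the transcript's 3' end is the lowest covered sense
coordinate, reported together with the strand.

Terminal A's that happen to match the reference (templated) are trimmed
like any other — the per-junction ``templated`` tally records how many
trimmed A's the reference could account for, so analyses of canonical
polyadenylation signals can correct for the resulting 5'-ward shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .mapper import (
    AnnotationLedger,
    Disposition,
    ReadRecord,
    choose_hit,
    map_exact,
)
from .model import ANTISENSE, SENSE, AnalysisConfig, PlasmidRef, subseq


@dataclass
class PolyAJunction:
    plasmid: str
    position: int  # sense coordinate of the last transcribed (aligned) base
    strand: str
    tail_lengths: list[int] = field(default_factory=list)
    templated: int = 0  # trimmed A's that are reference-templated, summed over reads

    @property
    def supporting_reads(self) -> int:
        return len(self.tail_lengths)

    @property
    def mean_tail(self) -> float:
        return sum(self.tail_lengths) / len(self.tail_lengths)


def _terminal_a_run(seq: str) -> int:
    n = 0
    for c in reversed(seq):
        if c != "A":
            break
        n += 1
    return n


def _templated_count(ref: PlasmidRef, junction: int, strand: str, tail: int) -> int:
    """How many of the trimmed tail A's the reference continues to template."""
    count = 0
    for i in range(1, tail + 1):
        if strand == SENSE:
            base = subseq(ref, (junction + i) % ref.length, 1, SENSE)
        else:
            base = subseq(ref, (junction - i) % ref.length, 1, ANTISENSE)
        if base == "A":
            count += 1
        else:
            break
    return count


def detect_polya(
    ledger: AnnotationLedger, ref: PlasmidRef, cfg: AnalysisConfig, min_support: int = 1
) -> list[PolyAJunction]:
    """Scan unannotated reads for trimmed-A junctions, updating the ledger.

    Rescued reads move to the polyA_mapped disposition; their alignment is
    the exact placement of the A-trimmed remainder. ``min_support`` only
    filters the reported junction list (default 1: report everything); it
    never undoes a read's rescue.
    """
    junctions: dict[tuple[int, str], PolyAJunction] = {}
    for rec in ledger.reads_with(Disposition.UNANNOTATED):
        if rec.read.id in ledger.multihit_dropped:
            continue
        seq = rec.read.sequence
        tail = _terminal_a_run(seq)
        if tail == 0:
            continue
        remainder = seq[:-tail]
        if len(remainder) < cfg.polya_min_remap_len:
            continue
        hits = map_exact(remainder, ref, read_id=rec.read.id)
        if not hits:
            continue
        aln = choose_hit(hits)
        if aln.strand == SENSE:
            junction = (aln.position + aln.aligned_length - 1) % ref.length
        else:
            junction = aln.position
        key = (junction, aln.strand)
        j = junctions.setdefault(key, PolyAJunction(ref.name, junction, aln.strand))
        j.tail_lengths.append(tail)
        j.templated += _templated_count(ref, junction, aln.strand, tail)
        rec.disposition = Disposition.POLYA
        rec.alignment = aln
        rec.polya_tail = tail
    out = [j for j in junctions.values() if j.supporting_reads >= min_support]
    return sorted(out, key=lambda j: (j.position, j.strand))


def write_junction_table(junctions: Iterable[PolyAJunction], path: str | Path) -> None:
    lines = ["#plasmid\tposition\tstrand\tsupporting_reads\tmean_tail\ttemplated_A"]
    for j in junctions:
        lines.append(
            f"{j.plasmid}\t{j.position}\t{j.strand}\t{j.supporting_reads}\t"
            f"{j.mean_tail:.2f}\t{j.templated}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_junction_bed(junctions: Iterable[PolyAJunction], path: str | Path) -> None:
    strand_out = {SENSE: "+", ANTISENSE: "-"}
    lines = []
    for j in junctions:
        lines.append(
            f"{j.plasmid}\t{j.position}\t{j.position + 1}\tpolyA_junction\t"
            f"{j.supporting_reads}\t{strand_out[j.strand]}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
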