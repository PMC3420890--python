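"""Read mapping to circular double-stranded plasmid references.

Two mapping modes, both substitution-only (no indels):

* exact mapping (:func:`map_exact`) over a doubled-sequence index, so
  matches are free to wrap the plasmid origin;
* minimal-Hamming-distance mapping (:func:`map_with_mismatches`) with a
  mismatch cap, used to re-map reads that failed exact placement when
  scanning for A-to-I editing signatures.

Alignment positions are the sense-strand coordinate of the 5'-most aligned
base *in sense coordinates* (i.e. the leftmost covered position). Mismatches
are stored in reference-sense orientation as (offset-in-window, ref_base,
read_base); offset 0 is the leftmost sense position of the window. Antisense
alignments compare the sense-strand window against the reverse complement
of the read.

Once-per-read annotation (:func:`annotate_once`) realises the rule that a
read is removed from the dataset as soon as it is successfully annotated:
each read receives at most one alignment, multi-locus hits are resolved by
a deterministic tie-break (lowest sense coordinate, sense before antisense)
and tallied.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .model import ANTISENSE, SENSE, PlasmidRef, reverse_complement
from .readprep import TrimmedRead

Mismatch = tuple[int, str, str]  # (offset in sense window, ref base, read base)

_BASE_CODE = {ord(b): i for i, b in enumerate("ACGT")}


@dataclass(frozen=True)
class Alignment:
    read_id: str
    plasmid: str
    position: int  # sense coordinate of the leftmost covered base
    strand: str
    aligned_length: int
    mismatches: tuple[Mismatch, ...] = ()

    @property
    def n_mismatch(self) -> int:
        return len(self.mismatches)

    def covered_positions(self, plasmid_length: int) -> list[int]:
        return [(self.position + i) % plasmid_length for i in range(self.aligned_length)]


class Disposition(str, Enum):
    PERFECT = "perfect_mapped"
    POLYA = "polyA_mapped"
    MISMATCH = "mismatch_mapped"
    UNANNOTATED = "unannotated"


@dataclass
class ReadRecord:
    read: TrimmedRead
    disposition: Disposition
    alignment: Alignment | None = None
    polya_tail: int | None = None  # trimmed terminal-A run for polyA-mapped reads


@dataclass
class AnnotationLedger:
    """Per-read dispositions and chosen alignments for one sample."""

    plasmid: str
    records: dict[str, ReadRecord] = field(default_factory=dict)
    multihit: int = 0
    multihit_dropped: set[str] = field(default_factory=set)

    def counts(self) -> dict[str, int]:
        out = {d.value: 0 for d in Disposition}
        for rec in self.records.values():
            out[rec.disposition.value] += 1
        return out

    def reads_with(self, disposition: Disposition) -> list[ReadRecord]:
        return [r for r in self.records.values() if r.disposition is disposition]

    def alignments(self, *dispositions: Disposition) -> list[Alignment]:
        wanted = set(dispositions) or set(Disposition)
        return [
            r.alignment
            for r in self.records.values()
            if r.disposition in wanted and r.alignment is not None
        ]

    def assert_conservation(self, n_input: int) -> None:
        c = self.counts()
        total = sum(c.values())
        if total != n_input:
            raise AssertionError(
                f"read conservation violated: {c} sums to {total}, expected {n_input}"
            )


class _CircularIndex:
    """Doubled-sequence view of a plasmid for wrap-around scanning."""

    def __init__(self, sequence: str):
        self.length = len(sequence)
        self.doubled = sequence + sequence
        self.arr = np.frombuffer(self.doubled.encode(), dtype=np.uint8).copy()
        for byte, code in _BASE_CODE.items():
            self.arr[self.arr == byte] = code

    @functools.lru_cache(maxsize=8)
    def windows(self, k: int) -> np.ndarray:
        """All L circular windows of length k as an (L, k) uint8 view."""
        return np.lib.stride_tricks.sliding_window_view(self.arr, k)[: self.length]


@functools.lru_cache(maxsize=16)
def _index(sequence: str) -> _CircularIndex:
    return _CircularIndex(sequence)


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    for byte, code in _BASE_CODE.items():
        arr[arr == byte] = code
    return arr


def _find_all(haystack: str, needle: str, limit: int) -> list[int]:
    """Start positions of needle in haystack that are < limit."""
    hits = []
    i = haystack.find(needle)
    while i != -1 and i < limit:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def _sort_key(aln: Alignment) -> tuple[int, int]:
    return (aln.position, 0 if aln.strand == SENSE else 1)


def map_exact(read_sequence: str, ref: PlasmidRef, read_id: str = "") -> list[Alignment]:
    """All zero-mismatch placements of a read on the circular reference.

    Returns one alignment per (position, strand) hit, sorted by
    (position, sense-before-antisense). Raises for reads longer than the
    plasmid.
    """
    k = len(read_sequence)
    if k > ref.length:
        raise ValueError(f"read of {k} nt longer than plasmid {ref.name} ({ref.length} nt)")
    if k == 0:
        return []
    idx = _index(ref.sequence)
    hits: list[Alignment] = []
    for pos in _find_all(idx.doubled, read_sequence, ref.length):
        hits.append(Alignment(read_id, ref.name, pos, SENSE, k))
    rc = reverse_complement(read_sequence)
    for pos in _find_all(idx.doubled, rc, ref.length):
        hits.append(Alignment(read_id, ref.name, pos, ANTISENSE, k))
    hits.sort(key=_sort_key)
    return hits


def _mismatch_list(window: str, oriented_read: str) -> tuple[Mismatch, ...]:
    return tuple(
        (i, r, q) for i, (r, q) in enumerate(zip(window, oriented_read)) if r != q
    )


def map_with_mismatches(
    read_sequence: str, ref: PlasmidRef, max_mm: int, read_id: str = ""
) -> list[Alignment]:
    """Minimal-substitution placements of a read, capped at ``max_mm``.

    Scans every circular position on both strands with a vectorised
    Hamming comparison and returns all alignments achieving the minimum
    mismatch count, provided it does not exceed ``max_mm``. Empty list
    otherwise.
    """
    if max_mm < 0:
        raise ValueError("max_mm must be >= 0")
    k = len(read_sequence)
    if k > ref.length:
        raise ValueError(f"read of {k} nt longer than plasmid {ref.name} ({ref.length} nt)")
    if k == 0:
        return []
    idx = _index(ref.sequence)
    windows = idx.windows(k)
    fwd = _encode(read_sequence)
    rev = _encode(reverse_complement(read_sequence))
    mm_fwd = (windows != fwd).sum(axis=1)
    mm_rev = (windows != rev).sum(axis=1)
    best = int(min(mm_fwd.min(), mm_rev.min()))
    if best > max_mm:
        return []
    hits: list[Alignment] = []
    L = ref.length
    for pos in np.flatnonzero(mm_fwd == best):
        window = idx.doubled[pos : pos + k]
        hits.append(
            Alignment(read_id, ref.name, int(pos), SENSE, k, _mismatch_list(window, read_sequence))
        )
    rc = reverse_complement(read_sequence)
    for pos in np.flatnonzero(mm_rev == best):
        window = idx.doubled[pos : pos + k]
        hits.append(
            Alignment(read_id, ref.name, int(pos), ANTISENSE, k, _mismatch_list(window, rc))
        )
    hits.sort(key=_sort_key)
    return hits


def choose_hit(hits: Sequence[Alignment]) -> Alignment:
    """Deterministic tie-break: lowest sense coordinate, sense first."""
    return min(hits, key=_sort_key)


def annotate_once(
    reads: Iterable[TrimmedRead],
    ref: PlasmidRef,
    cfg=None,
    drop_multihit: bool = False,
) -> AnnotationLedger:
    """First-round exact annotation: each read mapped at most once.

    Reads hitting several loci are either assigned by the deterministic
    tie-break (default) or, with ``drop_multihit``, left unannotated and
    excluded from downstream rescue stages; both ways the multi-hit tally
    is incremented.
    """
    ledger = AnnotationLedger(plasmid=ref.name)
    for read in reads:
        if read.id in ledger.records:
            raise ValueError(f"duplicate read id {read.id!r}")
        hits = map_exact(read.sequence, ref, read_id=read.id)
        if not hits:
            ledger.records[read.id] = ReadRecord(read, Disposition.UNANNOTATED)
            continue
        if len(hits) > 1:
            ledger.multihit += 1
            if drop_multihit:
                ledger.multihit_dropped.add(read.id)
                ledger.records[read.id] = ReadRecord(read, Disposition.UNANNOTATED)
                continue
        ledger.records[read.id] = ReadRecord(read, Disposition.PERFECT, choose_hit(hits))
    return ledger


def rescue_with_mismatches(ledger: AnnotationLedger, ref: PlasmidRef, cfg) -> int:
    """Re-map still-unannotated reads allowing up to cfg.editing_max_mismatch.

    Ties between equally good loci follow the same deterministic rule as
    first-round mapping. Returns the number of reads rescued; the ledger is
    updated in place (disposition mismatch_mapped).
    """
    rescued = 0
    for rec in ledger.reads_with(Disposition.UNANNOTATED):
        if rec.read.id in ledger.multihit_dropped:
            continue
        hits = map_with_mismatches(
            rec.read.sequence, ref, cfg.editing_max_mismatch, read_id=rec.read.id
        )
        if not hits:
            continue
        rec.disposition = Disposition.MISMATCH
        rec.alignment = choose_hit(hits)
        rescued += 1
    return rescued


def verify_alignment(aln: Alignment, read_sequence: str, ref: PlasmidRef) -> bool:
    """Soundness check: re-derive the mismatch list from the reference."""
    from .model import subseq

    window = subseq(ref, aln.position, aln.aligned_length, SENSE)
    oriented = read_sequence if aln.strand == SENSE else reverse_complement(read_sequence)
    return _mismatch_list(window, oriented) == aln.mismatches


def transcript_conversions(aln: Alignment) -> list[tuple[str, str]]:
    """Mismatches as (ref, read) base pairs in transcript orientation.

    Stored mismatches are sense-strand oriented; for antisense alignments
    each pair is complemented so that, e.g., A-to-I editing of an antisense
    transcript appears as A->G rather than T->C.
    """
    if aln.strand == SENSE:
        return [(r, q) for _, r, q in aln.mismatches]
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return [(comp[r], comp[q]) for _, r, q in aln.mismatches]


def write_alignment_table(alignments: Iterable[Alignment], path: str | Path) -> None:
    lines = ["#read_id\tplasmid\tposition\tstrand\tlength\tn_mismatch\tmismatches"]
    for a in alignments:
        mm = ",".join(f"{o}:{r}>{q}" for o, r, q in a.mismatches)
        lines.append(
            f"{a.read_id}\t{a.plasmid}\t{a.position}\t{a.strand}\t"
            f"{a.aligned_length}\t{a.n_mismatch}\t{mm}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_sam(
    alignments: Iterable[Alignment],
    reads: dict[str, str],
    ref: PlasmidRef,
    path: str | Path,
) -> None:
    """Plain-text SAM export with the plasmid as the reference contig.

    Wrap-around alignments are emitted against a doubled virtual contig
    would be misleading, so reads crossing the origin are soft-reported at
    their start with a 'co:i:1' tag instead of being split.
    """
    lines = [
        "@HD\tVN:1.6\tSO:unsorted",
        f"@SQ\tSN:{ref.name}\tLN:{ref.length}",
    ]
    for a in alignments:
        seq = reads[a.read_id]
        flag = 0 if a.strand == SENSE else 16
        out_seq = seq if a.strand == SENSE else reverse_complement(seq)
        crosses = int(a.position + a.aligned_length > ref.length)
        lines.append(
            f"{a.read_id}\t{flag}\t{ref.name}\t{a.position + 1}\t255\t"
            f"{a.aligned_length}M\t*\t0\t0\t{out_seq}\t*\t"
            f"NM:i:{a.n_mismatch}\tco:i:{crosses}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
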