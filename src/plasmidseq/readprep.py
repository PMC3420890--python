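"""Adapter trimming and length filtering of raw sequencing reads.

The trimming rule is 3'-anchored exact matching: the leftmost read suffix
that equals a prefix of the adapter (at least ``min_adapter_match`` nt, the
full adapter when the suffix is longer) marks the insert/adapter boundary
and everything from there on is removed. Reads containing N cannot take
part in exact matching downstream and are rejected with a logged reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from .model import AnalysisConfig

logger = logging.getLogger(__name__)

_READ_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class RawRead:
    id: str
    sequence: str
    qualities: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.id!r}: empty sequence")


@dataclass(frozen=True)
class TrimmedRead:
    id: str
    sequence: str
    adapter_found: bool
    trimmed_from: int | None  # position in the raw read where the adapter match began
    original_length: int
    qualities: tuple[int, ...] | None = None

    def __len__(self) -> int:
        return len(self.sequence)


def read_fastq(path: str | Path) -> Iterator[RawRead]:
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = tuple(rec.letter_annotations.get("phred_quality", ()))
        yield RawRead(id=rec.id, sequence=str(rec.seq).upper(), qualities=quals or None)


def read_fasta_reads(path: str | Path) -> Iterator[RawRead]:
    for rec in SeqIO.parse(str(path), "fasta"):
        yield RawRead(id=rec.id, sequence=str(rec.seq).upper())


def trim_adapter(read: RawRead, cfg: AnalysisConfig) -> TrimmedRead | None:
    """Remove the 3' adapter from one read.

    Returns ``None`` for reads containing characters outside {A,C,G,T,N} or
    containing N (exact mapping cannot place them); the rejection is logged.
    """
    if not cfg.adapter:
        raise ValueError("cfg.adapter is empty")
    seq = read.sequence
    bad = set(seq) - _READ_ALPHABET
    if bad:
        logger.warning("read %s rejected: non-nucleotide characters %s", read.id, sorted(bad))
        return None
    if "N" in seq:
        logger.debug("read %s rejected: contains N", read.id)
        return None
    adapter = cfg.adapter
    n, a = len(seq), len(adapter)
    # leftmost suffix start i whose overlap with the adapter matches exactly
    for i in range(0, n - cfg.min_adapter_match + 1):
        m = min(n - i, a)
        if m < cfg.min_adapter_match:
            break
        if seq[i : i + m] == adapter[:m]:
            return TrimmedRead(
                id=read.id,
                sequence=seq[:i],
                adapter_found=True,
                trimmed_from=i,
                original_length=n,
                qualities=read.qualities[:i] if read.qualities else None,
            )
    return TrimmedRead(
        id=read.id,
        sequence=seq,
        adapter_found=False,
        trimmed_from=None,
        original_length=n,
        qualities=read.qualities,
    )


def length_filter(
    reads: Iterable[TrimmedRead], cfg: AnalysisConfig
) -> tuple[list[TrimmedRead], int]:
    """Keep reads whose trimmed length lies in [read_min_len, read_max_len]."""
    kept: list[TrimmedRead] = []
    rejected = 0
    for r in reads:
        if cfg.read_min_len <= len(r.sequence) <= cfg.read_max_len:
            kept.append(r)
        else:
            rejected += 1
    return kept, rejected


@dataclass
class TrimStats:
    input_reads: int = 0
    rejected_invalid: int = 0
    adapter_found: int = 0
    length_kept: int = 0
    length_rejected: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def prepare_reads(
    reads: Iterable[RawRead], cfg: AnalysisConfig
) -> tuple[list[TrimmedRead], TrimStats]:
    """Trim and length-filter a read stream, collecting summary counts."""
    stats = TrimStats()
    trimmed: list[TrimmedRead] = []
    for raw in reads:
        stats.input_reads += 1
        t = trim_adapter(raw, cfg)
        if t is None:
            stats.rejected_invalid += 1
            continue
        if t.adapter_found:
            stats.adapter_found += 1
        trimmed.append(t)
    kept, rejected = length_filter(trimmed, cfg)
    stats.length_kept = len(kept)
    stats.length_rejected = rejected
    return kept, stats


def write_fasta_reads(reads: Iterable[TrimmedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.id}\n{r.sequence}\n")
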