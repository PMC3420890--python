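"""Deliberately naive reference mappers used as independent oracles.

These scan every circular rotation on both strands with plain Python
string comparison. They exist so the production mappers in
:mod:`plasmidseq.mapper` can be checked against an implementation with no
shared machinery (no doubled-sequence index, no vectorisation). Slow on
purpose; only for tests and verification runs on small references.
"""

from __future__ import annotations

from .model import ANTISENSE, SENSE, PlasmidRef, reverse_complement


def _window(seq: str, pos: int, k: int) -> str:
    L = len(seq)
    return "".join(seq[(pos + i) % L] for i in range(k))


def exact_hits(read: str, ref: PlasmidRef) -> list[tuple[int, str]]:
    """All (position, strand) exact placements, by full rotation scan."""
    k = len(read)
    rc = reverse_complement(read)
    hits = []
    for pos in range(ref.length):
        w = _window(ref.sequence, pos, k)
        if w == read:
            hits.append((pos, SENSE))
        if w == rc:
            hits.append((pos, ANTISENSE))
    hits.sort(key=lambda h: (h[0], 0 if h[1] == SENSE else 1))
    return hits


def hamming_hits(
    read: str, ref: PlasmidRef, max_mm: int
) -> list[tuple[int, str, int, tuple[tuple[int, str, str], ...]]]:
    """Minimal-Hamming placements as (pos, strand, n_mm, mismatch list)."""
    k = len(read)
    rc = reverse_complement(read)
    scored = []
    for pos in range(ref.length):
        w = _window(ref.sequence, pos, k)
        for strand, oriented in ((SENSE, read), (ANTISENSE, rc)):
            mm = tuple(
                (i, r, q) for i, (r, q) in enumerate(zip(w, oriented)) if r != q
            )
            scored.append((pos, strand, len(mm), mm))
    best = min(s[2] for s in scored)
    if best > max_mm:
        return []
    hits = [s for s in scored if s[2] == best]
    hits.sort(key=lambda h: (h[0], 0 if h[1] == SENSE else 1))
    return hits
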