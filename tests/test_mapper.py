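"""Exact and Hamming mapping vs brute-force rotation oracles."""

import numpy as np
import pytest

from plasmidseq import bruteforce
from plasmidseq.mapper import (
    Disposition,
    annotate_once,
    choose_hit,
    map_exact,
    map_with_mismatches,
    transcript_conversions,
    verify_alignment,
)
from plasmidseq.model import ANTISENSE, SENSE, AnalysisConfig, PlasmidRef, rotate, subseq
from plasmidseq.readprep import TrimmedRead

from conftest import random_sequence


def _read(rid, seq):
    return TrimmedRead(rid, seq, False, None, len(seq))


def test_planted_exact_hits(toy_ref):
    hits = map_exact(subseq(toy_ref, 0, 20, SENSE), toy_ref)
    assert [(h.position, h.strand) for h in hits] == [(0, SENSE)]

    hits = map_exact(subseq(toy_ref, 295, 10, SENSE), toy_ref)
    assert [(h.position, h.strand) for h in hits] == [(295, SENSE)]  # wraps origin

    from plasmidseq.model import reverse_complement

    hits = map_exact(reverse_complement(subseq(toy_ref, 40, 22, SENSE)), toy_ref)
    assert [(h.position, h.strand) for h in hits] == [(40, ANTISENSE)]


def test_read_longer_than_plasmid_rejected(toy_ref):
    with pytest.raises(ValueError):
        map_exact("A" * 301, toy_ref)


def test_exact_mapping_equals_rotation_oracle(toy_ref):
    """500 random/planted reads: hit sets identical to the full rotation scan."""
    rng = np.random.default_rng(99)
    bases = np.array(list("ACGT"))
    for i in range(500):
        k = int(rng.integers(15, 35))
        if i % 3 == 0:  # planted (guaranteed-hit) read, possibly wrapping
            start = int(rng.integers(0, 300))
            strand = SENSE if rng.random() < 0.5 else ANTISENSE
            seq = subseq(toy_ref, start, k, strand)
        else:
            seq = "".join(bases[rng.integers(0, 4, k)])
        ours = [(h.position, h.strand) for h in map_exact(seq, toy_ref)]
        assert ours == bruteforce.exact_hits(seq, toy_ref)


def test_hamming_mapping_equals_bruteforce_oracle(toy_ref):
    rng = np.random.default_rng(1234)
    bases = np.array(list("ACGT"))
    for i in range(150):
        k = int(rng.integers(18, 30))
        if i % 2 == 0:  # mutated planted read
            start = int(rng.integers(0, 300))
            strand = SENSE if rng.random() < 0.5 else ANTISENSE
            seq = list(subseq(toy_ref, start, k, strand))
            for _ in range(int(rng.integers(0, 4))):
                p = int(rng.integers(0, k))
                seq[p] = str(bases[rng.integers(0, 4)])
            seq = "".join(seq)
        else:
            seq = "".join(bases[rng.integers(0, 4, k)])
        ours = [(h.position, h.strand, h.n_mismatch, h.mismatches) for h in map_with_mismatches(seq, toy_ref, 5)]
        assert ours == bruteforce.hamming_hits(seq, toy_ref, 5)


def test_exact_equals_zero_mismatch_mapping(toy_ref):
    rng = np.random.default_rng(5)
    bases = np.array(list("ACGT"))
    for i in range(50):
        k = int(rng.integers(15, 30))
        seq = (
            subseq(toy_ref, int(rng.integers(0, 300)), k, SENSE)
            if i % 2
            else "".join(bases[rng.integers(0, 4, k)])
        )
        exact = [(h.position, h.strand) for h in map_exact(seq, toy_ref)]
        zero = [(h.position, h.strand) for h in map_with_mismatches(seq, toy_ref, 0)]
        assert exact == zero


def test_planted_substitutions_recovered(toy_ref):
    seq = list(subseq(toy_ref, 10, 24, SENSE))
    orig5, orig12 = seq[5], seq[12]
    seq[5] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[5]]
    seq[12] = {"A": "G", "C": "T", "G": "A", "T": "C"}[seq[12]]
    hits = map_with_mismatches("".join(seq), toy_ref, 5)
    best = choose_hit(hits)
    assert (best.position, best.strand, best.n_mismatch) == (10, SENSE, 2)
    assert best.mismatches == ((5, orig5, seq[5]), (12, orig12, seq[12]))
    assert verify_alignment(best, "".join(seq), toy_ref)


def test_six_substitutions_exceed_cap(toy_ref):
    seq = list(subseq(toy_ref, 50, 25, SENSE))
    for p in (0, 4, 8, 12, 16, 20):
        seq[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[p]]
    assert map_with_mismatches("".join(seq), toy_ref, 5) == []
    # the same read is accepted once the cap admits its distance
    hits = map_with_mismatches("".join(seq), toy_ref, 6)
    assert hits and hits[0].n_mismatch == 6


def test_rotation_equivariance(toy_ref):
    seq = subseq(toy_ref, 120, 25, SENSE)
    for k in (1, 37, 299):
        rot = rotate(toy_ref, k)
        hits = map_exact(seq, rot)
        assert [(h.position, h.strand) for h in hits] == [((120 - k) % 300, SENSE)]


def test_annotate_once_dispositions(toy_ref):
    reads = [
        _read("hit1", subseq(toy_ref, 33, 22, SENSE)),
        _read("miss", "T" * 22),
    ]
    ledger = annotate_once(reads, toy_ref)
    assert ledger.records["hit1"].disposition is Disposition.PERFECT
    assert ledger.records["hit1"].alignment.position == 33
    assert ledger.records["miss"].disposition is Disposition.UNANNOTATED
    ledger.assert_conservation(2)


def test_multihit_tiebreak_and_tally():
    """A planted duplicate 25-mer: one deterministic assignment, tally +1."""
    core = random_sequence(250, seed=11)
    dup = subseq(PlasmidRef(name="t", sequence=core), 10, 25, SENSE)
    seq = core + dup + random_sequence(25, seed=12)
    ref = PlasmidRef(name="dup", sequence=seq)
    oracle = bruteforce.exact_hits(dup, ref)
    assert len(oracle) >= 2  # the duplication is real
    ledger = annotate_once([_read("r", dup)], ref)
    assert ledger.multihit == 1
    aln = ledger.records["r"].alignment
    assert (aln.position, aln.strand) == oracle[0]  # lowest coord, sense first

    dropped = annotate_once([_read("r", dup)], ref, drop_multihit=True)
    assert dropped.multihit == 1
    assert dropped.records["r"].disposition is Disposition.UNANNOTATED
    assert "r" in dropped.multihit_dropped


def test_antisense_mismatches_reported_in_sense_orientation(toy_ref):
    """An A->G change on an antisense transcript is stored as T->C in sense
    coordinates and recovered as A>G in transcript orientation."""
    window = subseq(toy_ref, 60, 24, SENSE)
    p = window.index("T")  # sense T = transcript A
    transcript = list(subseq(toy_ref, 60, 24, ANTISENSE))
    tp = 24 - 1 - p  # transcript offset of that base
    assert transcript[tp] == "A"
    transcript[tp] = "G"
    hits = map_with_mismatches("".join(transcript), toy_ref, 5)
    best = choose_hit(hits)
    assert (best.position, best.strand, best.n_mismatch) == (60, ANTISENSE, 1)
    assert best.mismatches == ((p, "T", "C"),)
    assert transcript_conversions(best) == [("A", "G")]
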