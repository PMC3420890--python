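"""Poly(A)-junction detection: trim terminal A-runs, remap, aggregate."""

import numpy as np

from plasmidseq.mapper import Disposition, annotate_once
from plasmidseq.model import ANTISENSE, SENSE, AnalysisConfig, PlasmidRef, subseq
from plasmidseq.polya import detect_polya
from plasmidseq.readprep import TrimmedRead

from conftest import random_sequence

ADAPTER = "CGCCTTGGCCGTACAGCAG"


def _read(rid, seq):
    return TrimmedRead(rid, seq, False, None, len(seq))


def _cfg():
    return AnalysisConfig(adapter=ADAPTER)


def test_planted_junction_recovered(toy_ref):
    # boundary chosen so neither the junction base nor its successor is A
    assert toy_ref.sequence[120] != "A" and toy_ref.sequence[121] != "A"
    read = _read("j1", subseq(toy_ref, 101, 20, SENSE) + "AAAAAA")
    ledger = annotate_once([read], toy_ref)
    assert ledger.records["j1"].disposition is Disposition.UNANNOTATED
    junctions = detect_polya(ledger, toy_ref, _cfg())
    assert len(junctions) == 1
    j = junctions[0]
    assert (j.position, j.strand) == (120, SENSE)
    assert j.supporting_reads == 1 and j.tail_lengths == [6]
    assert ledger.records["j1"].disposition is Disposition.POLYA


def test_all_a_read_stays_unannotated(toy_ref):
    ledger = annotate_once([_read("allA", "A" * 30)], toy_ref)
    junctions = detect_polya(ledger, toy_ref, _cfg())
    assert junctions == []
    assert ledger.records["allA"].disposition is Disposition.UNANNOTATED


def test_short_remainder_not_remapped(toy_ref):
    # 17-nt remainder after the tail: below the >17 nt remap threshold
    read = _read("short", subseq(toy_ref, 50, 17, SENSE) + "A" * 10)
    ledger = annotate_once([read], toy_ref)
    assert detect_polya(ledger, toy_ref, _cfg()) == []
    assert ledger.records["short"].disposition is Disposition.UNANNOTATED
    # one base longer clears it (18 nt = the minimum remap length)
    assert toy_ref.sequence[218] != "A" and toy_ref.sequence[219] != "A"
    read2 = _read("ok", subseq(toy_ref, 201, 18, SENSE) + "A" * 10)
    ledger2 = annotate_once([read2], toy_ref)
    assert len(detect_polya(ledger2, toy_ref, _cfg())) == 1


def test_read_not_ending_in_a_untouched(toy_ref):
    seq = subseq(toy_ref, 10, 25, SENSE)
    seq = seq[:-1] + ("C" if seq[-1] != "C" else "G")  # unmappable, ends non-A
    ledger = annotate_once([_read("noA", seq)], toy_ref)
    assert detect_polya(ledger, toy_ref, _cfg()) == []
    assert ledger.records["noA"].disposition is Disposition.UNANNOTATED


def test_trim_then_map_soundness(toy_ref):
    seq = subseq(toy_ref, 30, 22, SENSE) + "AAAA"
    ledger = annotate_once([_read("s", seq)], toy_ref)
    detect_polya(ledger, toy_ref, _cfg())
    rec = ledger.records["s"]
    remainder = subseq(toy_ref, rec.alignment.position, rec.alignment.aligned_length, SENSE)
    assert remainder + "A" * rec.polya_tail == seq


def test_templated_run_shifts_junction_to_5prime_edge():
    """Terminal A's matching the reference are trimmed too, so junctions
    cluster at the 5' edge of a templated A-run; the templated tally says
    how many trimmed A's the reference accounts for."""
    seq = random_sequence(200, seed=3)
    # plant a templated AAA run at 120-122, flanked by G and C
    seq = seq[:119] + "GAAAC" + seq[124:]
    ref = PlasmidRef(name="templ", sequence=seq)
    # transcript really ends at 122 with 2 untemplated A's appended
    read = _read("t", subseq(ref, 100, 23, SENSE) + "AA")
    ledger = annotate_once([read], ref)
    junctions = detect_polya(ledger, ref, _cfg())
    assert len(junctions) == 1
    j = junctions[0]
    assert j.position == 119  # 5' edge: the G before the templated run
    assert j.tail_lengths == [5]  # 3 templated + 2 untemplated A's trimmed
    assert j.templated == 3


def test_simulated_tail_distribution_recovered(toy_ref):
    """2,000 reads with geometric tails at one true junction: exact position,
    tail histogram equal to the planted one."""
    rng = np.random.default_rng(77)
    junction = 150
    assert toy_ref.sequence[junction + 1] != "A"  # junction is unambiguous
    reads, tails = [], []
    for i in range(2000):
        k = int(rng.integers(18, 26))
        tail = int(rng.geometric(0.4))
        tails.append(tail)
        reads.append(_read(f"p{i}", subseq(toy_ref, junction - k + 1, k, SENSE) + "A" * tail))
    ledger = annotate_once(reads, toy_ref)
    junctions = detect_polya(ledger, toy_ref, _cfg())
    assert [(j.position, j.strand) for j in junctions] == [(junction, SENSE)]
    assert sorted(junctions[0].tail_lengths) == sorted(tails)
    # no read is counted in more than one junction
    assert sum(j.supporting_reads for j in junctions) == 2000


def test_antisense_junction_coordinate(toy_ref):
    """For an antisense transcript the 3' end is the lowest covered sense
    coordinate."""
    transcript = subseq(toy_ref, 200, 20, ANTISENSE)
    assert transcript[-1] != "A"  # transcript's own 3' base is not A
    read = _read("anti", transcript + "AAAA")
    ledger = annotate_once([read], toy_ref)
    junctions = detect_polya(ledger, toy_ref, _cfg())
    assert [(j.position, j.strand) for j in junctions] == [(200, ANTISENSE)]
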