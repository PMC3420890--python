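"""Substitution spectra, multi-conversion tables and edited-read profiles."""

import numpy as np
import pytest

from plasmidseq.editing import (
    edited_read_profile,
    multi_conversion_counts,
    overlap_fraction,
    size_distribution,
    substitution_spectrum,
)
from plasmidseq.mapper import Alignment
from plasmidseq.model import ANTISENSE, SENSE, AnalysisConfig, Feature, PlasmidRef
from plasmidseq.simulate import DEFAULT_ADAPTER, SimConfig, SimFeature, generate
from plasmidseq.pipeline import run
from plasmidseq.readprep import RawRead


def _cfg():
    return AnalysisConfig(adapter=DEFAULT_ADAPTER)


def _aln(length, mismatches, strand=SENSE, pos=0, rid="r"):
    return Alignment(rid, "p", pos, strand, length, tuple(mismatches))


def test_spectrum_counts_single_alignments():
    spec = substitution_spectrum([_aln(22, [(3, "A", "G"), (9, "A", "G")])], _cfg())
    assert spec.counts.loc["A>G", "short"] == 2
    assert spec.counts.drop("A>G").to_numpy().sum() == 0
    assert spec.reads_evaluated["short"] == 1

    spec2 = substitution_spectrum(
        [_aln(22, [(3, "A", "G"), (9, "C", "T")])], _cfg()
    )
    assert spec2.counts.loc["A>G", "short"] == 1
    assert spec2.counts.loc["C>T", "short"] == 1


def test_spectrum_length_classes():
    cfg = _cfg()
    spec = substitution_spectrum(
        [
            _aln(21, [(0, "G", "A")]),
            _aln(26, [(0, "G", "A")]),
            _aln(50, [(0, "T", "C")]),
            _aln(30, [(0, "C", "A")]),  # neither short nor long
        ],
        cfg,
    )
    assert spec.counts.loc["G>A", "short"] == 2
    assert spec.counts.loc["T>C", "long"] == 1
    assert spec.counts.loc["C>A", "other"] == 1
    # spectrum conservation: cells sum to total mismatches
    assert spec.total_substitutions == 4


def test_spectrum_rejects_inconsistent_mismatch_list():
    with pytest.raises(ValueError, match="inconsistent"):
        substitution_spectrum([_aln(22, [(3, "A", "A")])], _cfg())


def test_antisense_conversions_counted_on_transcript_strand():
    # sense-stored T>C on an antisense alignment is transcript A>G
    spec = substitution_spectrum([_aln(22, [(3, "T", "C")], strand=ANTISENSE)], _cfg())
    assert spec.counts.loc["A>G", "short"] == 1
    assert spec.counts.loc["T>C", "short"] == 0


def test_multi_conversion_at_least_k_semantics():
    cfg = _cfg()
    table = multi_conversion_counts(
        [_aln(22, [(1, "A", "G"), (5, "A", "G"), (9, "A", "G")])], cfg
    )
    assert table.counts.loc["A>G", "k>=2"] == 1
    assert table.counts.loc["A>G", "k>=3"] == 1
    assert table.counts.loc["A>G", "k>=4"] == 0
    assert table.ag_share == 1.0

    # one A>G plus one G>A is not a repeated identical conversion
    t2 = multi_conversion_counts([_aln(22, [(1, "A", "G"), (5, "G", "A")])], cfg)
    assert t2.counts.to_numpy().sum() == 0
    assert np.isnan(t2.ag_share)


def test_multi_conversion_monotone_in_k():
    rng = np.random.default_rng(0)
    alns = []
    for i in range(200):
        n = int(rng.integers(0, 5))
        mm = [(int(j), "A", "G") for j in range(n)]
        alns.append(_aln(22, mm, rid=f"r{i}"))
    table = multi_conversion_counts(alns, _cfg())
    arr = table.counts.to_numpy()
    assert (arr[:, 0] >= arr[:, 1]).all() and (arr[:, 1] >= arr[:, 2]).all()


def test_order_invariance():
    rng = np.random.default_rng(1)
    alns = [
        _aln(int(rng.integers(18, 51)), [(0, "A", "G")] if rng.random() < 0.5 else [(0, "C", "T")], rid=f"r{i}")
        for i in range(50)
    ]
    cfg = _cfg()
    a = substitution_spectrum(alns, cfg)
    b = substitution_spectrum(list(reversed(alns)), cfg)
    assert a.counts.equals(b.counts)


def test_profile_single_read(toy_ref):
    cfg = _cfg()
    aln = _aln(22, [(3, "A", "G")], pos=100)
    prof = edited_read_profile([aln], toy_ref, cfg)
    assert prof.density[SENSE][100:122].sum() == 22
    assert prof.density[SENSE].sum() == 22
    assert prof.density[ANTISENSE].sum() == 0
    assert prof.starts[SENSE][100] == 1
    # a read outside the 20-24 nt window does not qualify
    prof2 = edited_read_profile([_aln(26, [(3, "A", "G")], pos=10)], toy_ref, cfg)
    assert sum(t.sum() for t in prof2.density.values()) == 0
    # an unedited read does not qualify
    prof3 = edited_read_profile([_aln(22, [(3, "C", "T")], pos=10)], toy_ref, cfg)
    assert sum(t.sum() for t in prof3.density.values()) == 0


def test_size_distribution_over_feature(toy_ref):
    cfg = _cfg()
    feat = Feature("toyCDS", 0, 30, SENSE, "CDS")
    alns = [
        _aln(21, [], pos=2, rid="a"),
        _aln(21, [], pos=4, rid="b"),
        _aln(21, [], pos=6, rid="c"),
        _aln(21, [(0, "A", "G")], pos=3, rid="d"),
        _aln(22, [], pos=250, rid="far"),  # no overlap with the feature
    ]
    df = size_distribution(alns, feat, toy_ref, cfg)
    assert df.loc[21, "total"] == 4 and df.loc[21, "edited"] == 1
    assert df.loc[22, "total"] == 0
    assert df["total"].sum() == 4


def test_overlap_rule_half_of_read():
    ref = PlasmidRef(name="p", sequence="ACGT" * 25)  # 100 nt
    feat = Feature("f", 0, 20, SENSE)
    inside = _aln(20, [], pos=5)  # 15/20 bases inside
    outside = _aln(20, [], pos=15)  # 5/20 inside
    assert overlap_fraction(inside, feat, 100) == 0.75
    assert overlap_fraction(outside, feat, 100) == 0.25


def test_null_sample_shows_no_editing_signal():
    """With editing rate 0 and symmetric errors no cell dominates."""
    feats = (
        SimFeature("ds", 100, 800, weight=1.0, sense_fraction=0.5, dsrna=True),
    )
    sim = SimConfig(
        plasmid_length=1500,
        features=feats,
        total_reads=15_000,
        editing_rate=0.0,
        error_rate=0.01,
        background_fraction=0.0,
        polya_fraction=0.0,
        rng_seed=2024,
    )
    truth = generate(sim)
    reads = [RawRead(i, s) for i, s in zip(truth.reads.read_id, truth.reads.sequence)]
    res = run(reads, truth.ref, _cfg())
    cells = res.spectrum.counts.sum(axis=1)  # all length classes pooled
    mean = cells.mean()
    assert mean > 20  # enough mass for the calibration to be meaningful
    # every cell within generous binomial bounds of the common mean
    assert (cells <= 2 * mean + 5).all() and (cells >= mean / 2 - 5).all()
    # and in particular A>G does not stand out
    assert cells["A>G"] < 2 * cells.drop("A>G").max()


def test_edited_profile_mass_concentrates_in_dsrna_cassette():
    """Editing planted only in one cassette: profile mass recovers it."""
    feats = (
        SimFeature("reporter", 100, 900, weight=0.6),
        SimFeature("cassette", 1100, 795, weight=0.4, sense_fraction=0.5, dsrna=True),
    )
    sim = SimConfig(
        plasmid_length=2500,
        features=feats,
        total_reads=20_000,
        rng_seed=5,
        background_fraction=0.02,
        polya_fraction=0.0,
    )
    truth = generate(sim)
    # by construction every edited read originates in the cassette
    edited = truth.reads[truth.reads.n_edits > 0]
    assert (edited.feature == "cassette").all()
    reads = [RawRead(i, s) for i, s in zip(truth.reads.read_id, truth.reads.sequence)]
    res = run(reads, truth.ref, _cfg())
    assert res.profile.mass_in(1100, 1895) >= 0.9
    assert res.profile.mass_in(1100, 1895, mode="starts") >= 0.9
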