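"""Seeded generator of plasmid references and small-RNA reads with truth.

The generator emulates the transcriptional landscape the pipeline is built
to analyse: a dominant reporter mRNA, spurious sense/antisense read
clusters over backbone regions, one cassette with overlapping sense and
antisense transcription whose reads carry A->G conversions at an elevated
per-adenosine rate (double-stranded RNA editing), templated-plus-
untemplated poly(A) tails at defined junctions, 3' adapters, uniform
substitution noise, and a fraction of unmappable background reads.

Per-read construction order: pick a source (background / poly(A) junction /
feature by weight), draw strand and length, extract the transcript-oriented
insert, inject A->G edits (dsRNA features only), inject sequencing errors,
append the poly(A) tail, append the adapter and pad/truncate to the raw
read length. Every stochastic choice is logged to the truth table, and the
same seed always yields byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ANTISENSE, SENSE, Feature, PlasmidRef, subseq, write_annotations

# SOLiD small-RNA P2 adapter; the fixture adapter of this package.
DEFAULT_ADAPTER = "CGCCTTGGCCGTACAGCAG"

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimFeature:
    name: str
    start: int
    length: int
    weight: float
    sense_fraction: float = 1.0  # probability a read is sense-strand
    dsrna: bool = False  # A->G editing applies here
    category: str = "CDS"

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class SimConfig:
    plasmid_length: int = 4700
    features: tuple[SimFeature, ...] = ()
    total_reads: int = 100_000
    editing_rate: float = 0.1  # per-adenosine, inside dsRNA features
    error_rate: float = 0.002  # per-base substitution noise
    adapter: str = DEFAULT_ADAPTER
    adapter_fraction: float = 1.0
    raw_read_len: int = 50
    polya_fraction: float = 0.03  # reads carrying an untemplated tail
    polya_features: tuple[str, ...] = ()  # junction at each named feature's 3' end
    polya_tail_p: float = 0.35  # geometric tail-length parameter (mean ~1/p)
    background_fraction: float = 0.05
    length_probs: dict[int, float] | None = None  # over [18, raw_read_len]
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.editing_rate,
            self.error_rate,
            self.adapter_fraction,
            self.polya_fraction,
            self.background_fraction,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0,1]")
        w = sum(f.weight for f in self.features)
        if self.features and not np.isclose(w, 1.0):
            raise ValueError(f"feature weights must sum to 1, got {w}")
        for f in self.features:
            if f.length < self.raw_read_len:
                raise ValueError(
                    f"feature {f.name!r} shorter than the maximum read length; "
                    "reads are drawn fully inside features"
                )
        if self.length_probs is None:
            self.length_probs = default_length_distribution(self.raw_read_len)


def default_length_distribution(max_len: int = 50) -> dict[int, float]:
    """Mixture read-length law: a small-RNA mode at ~22 nt, a broad
    component over [18, max_len], and a full-length spike at max_len."""
    lengths = np.arange(18, max_len + 1)
    gauss = np.exp(-0.5 * ((lengths - 22) / 2.0) ** 2)
    gauss[lengths > 28] = 0.0
    gauss /= gauss.sum()
    broad = np.full(len(lengths), 1.0 / len(lengths))
    probs = 0.65 * gauss + 0.25 * broad
    probs[-1] += 0.10
    probs /= probs.sum()
    return {int(l): float(p) for l, p in zip(lengths, probs)}


def pegfp_like(seed: int = 0, total_reads: int = 100_000) -> SimConfig:
    """Default scenario: a 4,700-nt plasmid shaped like a reporter vector.

    A 798-nt sense-only reporter CDS dominates; a 795-nt resistance-style
    cassette is transcribed on both strands (the dsRNA / editing locus); an
    861-nt backbone cluster is antisense-biased; a 600-nt ori-like cluster
    is weakly expressed. One poly(A) junction sits at the reporter's 3' end.
    """
    feats = (
        SimFeature("reporter CDS", 600, 798, weight=0.62 / 0.90, sense_fraction=1.0),
        SimFeature(
            "overlap cassette", 1600, 795, weight=0.14 / 0.90,
            sense_fraction=0.5, dsrna=True,
        ),
        SimFeature(
            "backbone AmpR-like", 2600, 861, weight=0.09 / 0.90,
            sense_fraction=0.1, category="CDS",
        ),
        SimFeature(
            "backbone ori-like", 3600, 600, weight=0.05 / 0.90,
            sense_fraction=0.7, category="ori",
        ),
    )
    return SimConfig(
        plasmid_length=4700,
        features=feats,
        total_reads=total_reads,
        polya_features=("reporter CDS",),
        rng_seed=seed,
    )


@dataclass
class SimTruth:
    """Ground truth of one generated sample."""

    ref: PlasmidRef
    reads: pd.DataFrame  # one row per emitted read
    junctions: list[tuple[int, str]]  # planted (sense position, strand)
    config: SimConfig

    def feature_counts(self) -> pd.Series:
        feat = self.reads[self.reads["category"] == "feature"]
        return feat["feature"].value_counts()

    @property
    def total_edits(self) -> int:
        return int(self.reads["n_edits"].sum())


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def _build_reference(cfg: SimConfig, rng: np.random.Generator) -> tuple[PlasmidRef, list[int]]:
    seq = list(_random_seq(rng, cfg.plasmid_length))
    # Plant poly(A) junctions at feature 3' ends; keep the junction base and
    # the two downstream bases non-A so trimmed tails remap unambiguously.
    junction_positions = []
    by_name = {f.name: f for f in cfg.features}
    for name in cfg.polya_features:
        f = by_name[name]
        j = (f.end - 1) % cfg.plasmid_length
        for p in (j, (j + 1) % cfg.plasmid_length, (j + 2) % cfg.plasmid_length):
            if seq[p] == "A":
                seq[p] = str(BASES[1 + rng.integers(0, 3)])  # C, G or T
        junction_positions.append(j)
    features = tuple(
        Feature(
            name=f.name,
            start=f.start,
            end=f.end,
            strand=SENSE if f.sense_fraction >= 0.5 else ANTISENSE,
            category=f.category + (";dsRNA" if f.dsrna else ""),
        )
        for f in cfg.features
    )
    ref = PlasmidRef(name="simPlasmid", sequence="".join(seq), features=features)
    return ref, junction_positions


def _inject(seq: str, rng: np.random.Generator, edit_rate: float, error_rate: float) -> tuple[str, int, int]:
    """A->G edits then uniform substitution errors; returns (seq, n_edit, n_err)."""
    chars = list(seq)
    n_edit = 0
    if edit_rate > 0:
        draws = rng.random(len(chars))
        for i, c in enumerate(chars):
            if c == "A" and draws[i] < edit_rate:
                chars[i] = "G"
                n_edit += 1
    n_err = 0
    if error_rate > 0:
        draws = rng.random(len(chars))
        for i, c in enumerate(chars):
            if draws[i] < error_rate:
                alternatives = [b for b in "ACGT" if b != chars[i]]
                chars[i] = alternatives[rng.integers(0, 3)]
                n_err += 1
    return "".join(chars), n_edit, n_err


def generate(cfg: SimConfig) -> SimTruth:
    rng = np.random.default_rng(cfg.rng_seed)
    ref, junctions = _build_reference(cfg, rng)
    lengths = np.array(sorted(cfg.length_probs))
    length_p = np.array([cfg.length_probs[int(l)] for l in lengths])

    n_feat = len(cfg.features)
    feat_weights = np.array([f.weight for f in cfg.features]) if n_feat else None

    rows = []
    read_seqs: list[str] = []
    adapter = cfg.adapter
    for i in range(cfg.total_reads):
        rid = f"r{i:06d}"
        u = rng.random()
        length = int(rng.choice(lengths, p=length_p))
        tail = 0
        junction = -1
        if u < cfg.background_fraction:
            category, feature, strand, start = "background", "", SENSE, -1
            insert = _random_seq(rng, length)
            insert, n_edit, n_err = _inject(insert, rng, 0.0, cfg.error_rate)
        elif u < cfg.background_fraction + cfg.polya_fraction and junctions:
            category, feature = "polya", ""
            strand = SENSE
            junction = junctions[int(rng.integers(0, len(junctions)))]
            rem_len = int(np.clip(length, 18, cfg.raw_read_len - 5))
            start = (junction - rem_len + 1) % cfg.plasmid_length
            insert = subseq(ref, start, rem_len, SENSE)
            insert, n_edit, n_err = _inject(insert, rng, 0.0, cfg.error_rate)
            tail = int(min(rng.geometric(cfg.polya_tail_p), cfg.raw_read_len - rem_len))
            insert = insert + "A" * tail
            length = rem_len
        else:
            category = "feature"
            fi = int(rng.choice(n_feat, p=feat_weights))
            f = cfg.features[fi]
            feature = f.name
            strand = SENSE if rng.random() < f.sense_fraction else ANTISENSE
            offset = int(rng.integers(0, f.length - length + 1))
            start = (f.start + offset) % cfg.plasmid_length
            insert = subseq(ref, start, length, strand)
            insert, n_edit, n_err = _inject(
                insert, rng, cfg.editing_rate if f.dsrna else 0.0, cfg.error_rate
            )
        adapter_present = rng.random() < cfg.adapter_fraction
        raw = insert + (adapter if adapter_present else "")
        if len(raw) < cfg.raw_read_len and adapter_present:
            raw += _random_seq(rng, cfg.raw_read_len - len(raw))
        raw = raw[: cfg.raw_read_len]
        read_seqs.append(raw)
        rows.append(
            (rid, category, feature, strand, start, length, tail, n_edit, n_err,
             adapter_present, junction, len(raw))
        )
    reads = pd.DataFrame(
        rows,
        columns=[
            "read_id", "category", "feature", "strand", "start", "insert_len",
            "tail_len", "n_edits", "n_errors", "adapter_present", "junction",
            "raw_len",
        ],
    )
    reads["sequence"] = read_seqs
    planted = [(j, SENSE) for j in junctions]
    return SimTruth(ref=ref, reads=reads, junctions=planted, config=cfg)


def write_outputs(truth: SimTruth, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA reference, BED-like annotation, FASTQ reads, and truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "reference.fasta",
        "annotation": outdir / "annotation.tsv",
        "fastq": outdir / "reads.fastq",
        "truth_tsv": outdir / "truth.tsv",
        "truth_json": outdir / "truth.json",
    }
    seq = truth.ref.sequence
    wrapped = "\n".join(seq[i : i + 70] for i in range(0, len(seq), 70))
    paths["fasta"].write_text(f">{truth.ref.name}\n{wrapped}\n")
    write_annotations(list(truth.ref.features), truth.ref.name, paths["annotation"])
    with open(paths["fastq"], "w") as fh:
        for rid, s in zip(truth.reads["read_id"], truth.reads["sequence"]):
            fh.write(f"@{rid}\n{s}\n+\n{'I' * len(s)}\n")
    truth.reads.to_csv(paths["truth_tsv"], sep="\t", index=False)
    summary = {
        "total_reads": int(len(truth.reads)),
        "junctions": [[int(p), s] for p, s in truth.junctions],
        "feature_counts": {k: int(v) for k, v in truth.feature_counts().items()},
        "total_edits": truth.total_edits,
        "rng_seed": truth.config.rng_seed,
    }
    paths["truth_json"].write_text(json.dumps(summary, indent=2) + "\n")
    return paths
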