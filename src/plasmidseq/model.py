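"""Circular plasmid references, feature annotations, and analysis configuration.

A plasmid is modelled as a circular double-stranded DNA molecule. All
coordinates are 0-based, half-open, on the *sense* strand, which is defined
as the strand deposited in the reference FASTA. Features that span the
sequence origin are encoded with ``end > length`` and interpreted modulo the
plasmid length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO

SENSE = "sense"
ANTISENSE = "antisense"

_STRAND_TOKENS = {
    "+": SENSE,
    "-": ANTISENSE,
    "sense": SENSE,
    "antisense": ANTISENSE,
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_VALID_BASES = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N allowed)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Feature:
    """An annotated interval on a plasmid.

    ``end`` may exceed the plasmid length to denote an origin-spanning
    feature; positions are then read modulo the plasmid length.
    """

    name: str
    start: int
    end: int  # exclusive; may exceed plasmid length (origin-spanning)
    strand: str
    category: str = ""

    def __post_init__(self) -> None:
        if self.strand not in (SENSE, ANTISENSE):
            raise ValueError(f"unknown strand token: {self.strand!r}")
        if self.end <= self.start:
            raise ValueError(f"feature {self.name!r}: end must exceed start")
        if self.start < 0:
            raise ValueError(f"feature {self.name!r}: negative start")

    @property
    def length(self) -> int:
        return self.end - self.start

    def positions(self, plasmid_length: int) -> set[int]:
        """The set of sense-strand positions the feature covers (mod length)."""
        return {p % plasmid_length for p in range(self.start, self.end)}


@dataclass(frozen=True)
class PlasmidRef:
    """A validated circular plasmid reference sequence with annotations."""

    name: str
    sequence: str
    circular: bool = True
    features: tuple[Feature, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty plasmid sequence")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(
                f"plasmid {self.name!r}: sequence contains non-ACGT "
                f"characters {sorted(bad)}; ambiguity codes are rejected"
            )
        L = len(self.sequence)
        for f in self.features:
            if f.start >= L:
                raise ValueError(f"feature {f.name!r}: start {f.start} outside [0,{L})")
            if f.length > L:
                raise ValueError(f"feature {f.name!r}: longer than the plasmid")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def feature(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)


def subseq(ref: PlasmidRef, start: int, length: int, strand: str = SENSE) -> str:
    """Extract ``length`` bases starting at sense position ``start``.

    Wraps past the origin when the reference is circular. For the antisense
    strand the reverse complement of the sense-strand window is returned, so
    the result reads 5'->3' on the antisense strand.
    """
    if not 0 <= start < ref.length:
        raise ValueError(f"start {start} outside [0,{ref.length})")
    if length > ref.length:
        raise ValueError(f"requested length {length} exceeds plasmid length {ref.length}")
    end = start + length
    if end <= ref.length:
        window = ref.sequence[start:end]
    else:
        if not ref.circular:
            raise ValueError("window runs past the end of a linear reference")
        window = ref.sequence[start:] + ref.sequence[: end - ref.length]
    if strand == SENSE:
        return window
    if strand == ANTISENSE:
        return reverse_complement(window)
    raise ValueError(f"unknown strand token: {strand!r}")


@dataclass
class AnalysisConfig:
    """Thresholds of the read-processing pipeline.

    Defaults are the study values: adapter matches require >=3 exact nt,
    reads are kept at 18-50 nt after trimming, editing remapping allows up
    to five substitutions, the "short" read class is 21-26 nt, the edited
    read positional profile uses 20-24 nt reads, and poly(A)-trimmed
    remainders must be >17 nt to be remapped.
    """

    adapter: str = ""
    min_adapter_match: int = 3
    read_min_len: int = 18
    read_max_len: int = 50
    editing_max_mismatch: int = 5
    short_class: tuple[int, int] = (21, 26)
    editing_profile_window: tuple[int, int] = (20, 24)
    polya_min_remap_len: int = 18
    library_size: int | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.read_min_len > self.read_max_len:
            raise ValueError("read_min_len exceeds read_max_len")
        if self.min_adapter_match < 1:
            raise ValueError("min_adapter_match must be >= 1")
        if self.editing_max_mismatch < 0:
            raise ValueError("editing_max_mismatch must be >= 0")
        if self.library_size is not None and self.library_size <= 0:
            raise ValueError("library_size must be positive when set")


def parse_strand(token: str) -> str:
    try:
        return _STRAND_TOKENS[token]
    except KeyError:
        raise ValueError(f"unknown strand token: {token!r}") from None


def load_annotations(path: str | Path, plasmid: str | None = None) -> list[Feature]:
    """Read a 6-column TSV (name, start, end, strand, category, plasmid).

    Lines starting with '#' are ignored. When ``plasmid`` is given, only
    rows for that plasmid are returned.
    """
    feats = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 6:
            raise ValueError(f"{path}:{lineno}: expected 6 tab-separated columns")
        name, start, end, strand, category, plas = parts
        if plasmid is not None and plas != plasmid:
            continue
        feats.append(
            Feature(
                name=name,
                start=int(start),
                end=int(end),
                strand=parse_strand(strand),
                category=category,
            )
        )
    return feats


def load_reference(fasta_path: str | Path, annotation_path: str | Path | None = None) -> PlasmidRef:
    """Load a single-record plasmid FASTA plus its annotation table."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{fasta_path}: expected exactly one FASTA record, found {len(records)}")
    rec = records[0]
    seq = str(rec.seq).upper()
    feats: tuple[Feature, ...] = ()
    if annotation_path is not None:
        feats = tuple(load_annotations(annotation_path, plasmid=rec.id))
    return PlasmidRef(name=rec.id, sequence=seq, features=feats)


def write_annotations(features: list[Feature], plasmid: str, path: str | Path) -> None:
    strand_out = {SENSE: "+", ANTISENSE: "-"}
    lines = ["#name\tstart\tend\tstrand\tcategory\tplasmid"]
    for f in features:
        lines.append(
            f"{f.name}\t{f.start}\t{f.end}\t{strand_out[f.strand]}\t{f.category}\t{plasmid}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def rotate(ref: PlasmidRef, k: int) -> PlasmidRef:
    """Rotate the plasmid origin by ``k`` positions (sequence and features)."""
    L = ref.length
    k %= L
    seq = ref.sequence[k:] + ref.sequence[:k]
    feats = []
    for f in ref.features:
        start = (f.start - k) % L
        feats.append(replace(f, start=start, end=start + f.length))
    return replace(ref, sequence=seq, features=tuple(feats))
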