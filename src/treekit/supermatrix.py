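"""Supermatrix construction: concatenating per-gene alignments.

Gene alignments are concatenated column-wise into one matrix for species
tree inference. Species are matched by exact label only (silent fuzzy joins
are the worst failure mode of supermatrices). Under the ``union`` policy a
species absent from a partition is padded with ``?`` — *missing data*,
deliberately distinct from the alignment gap ``-`` — while ``intersection``
keeps only species present everywhere. A partition table records the 1-based
inclusive column range each source alignment occupies, writable as a
RAxML-style partition file or plain TSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError

_NT_CHARS = set("ACGTUNRYSWKMBDHV-?.")
_AA_CHARS = set("ACDEFGHIKLMNPQRSTVWYBXZJUO*-?.")


@dataclass
class Alignment:
    """A multiple sequence alignment keyed by species label.

    ``records`` preserves insertion order (the order rows are written out).
    All sequences must have equal length and draw from the declared alphabet
    (``nt`` or ``aa``) plus gap ``-`` and missing ``?``.
    """

    records: dict[str, str]
    alphabet: str = "aa"
    name: str = ""

    def __post_init__(self):
        if self.alphabet not in ("nt", "aa"):
            raise AlignmentError(f"alphabet must be 'nt' or 'aa', "
                                 f"got {self.alphabet!r}")
        if not self.records:
            raise AlignmentError("alignment has no sequences")
        lengths = {len(s) for s in self.records.values()}
        if len(lengths) != 1:
            raise AlignmentError(
                f"sequences have unequal lengths: {sorted(lengths)}")
        allowed = _NT_CHARS if self.alphabet == "nt" else _AA_CHARS
        for label, seq in self.records.items():
            bad = set(seq.upper()) - allowed
            if bad:
                raise AlignmentError(
                    f"invalid {self.alphabet} characters in {label!r}: "
                    f"{''.join(sorted(bad))}")

    @property
    def length(self) -> int:
        return len(next(iter(self.records.values())))

    @property
    def species(self) -> list[str]:
        return list(self.records)


@dataclass(frozen=True)
class Partition:
    """1-based inclusive column range of one source alignment."""

    name: str
    start: int
    end: int


def detect_alphabet(sequences) -> str:
    """'nt' when every residue fits the nucleotide alphabet, else 'aa'."""
    chars = set()
    for seq in sequences:
        chars |= set(seq.upper())
    return "nt" if chars <= _NT_CHARS else "aa"


def read_fasta(path, alphabet: str = "auto", name: str = "") -> Alignment:
    """Read an aligned FASTA file; ``alphabet='auto'`` sniffs nt vs aa."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise AlignmentError(f"duplicate species label {rec.id!r} "
                                 f"in {path}")
        records[rec.id] = str(rec.seq)
    if not records:
        raise AlignmentError(f"{path}: no FASTA records found")
    if alphabet == "auto":
        alphabet = detect_alphabet(records.values())
    return Alignment(records, alphabet, name=name)


def write_fasta(aln: Alignment, path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=label, description="")
         for label, seq in aln.records.items()),
        str(path), "fasta")


def concat_alignments(alignments: Sequence[Alignment],
                      species_policy: str = "union"
                      ) -> tuple[Alignment, list[Partition]]:
    """Concatenate alignments column-wise into a supermatrix.

    Columns are appended in input order. ``union`` pads species missing from
    a partition with ``?`` of that partition's length; ``intersection`` keeps
    only species present in every alignment (an empty intersection is an
    error, as is mixing alphabets).
    """
    if species_policy not in ("union", "intersection"):
        raise AlignmentError(f"unknown species policy: {species_policy!r}")
    if not alignments:
        raise AlignmentError("need at least one alignment to concatenate")
    alphabets = {a.alphabet for a in alignments}
    if len(alphabets) != 1:
        raise AlignmentError(
            f"cannot concatenate mixed alphabets: {sorted(alphabets)}")

    if species_policy == "union":
        species: list[str] = []
        for a in alignments:
            for s in a.species:
                if s not in species:
                    species.append(s)
    else:
        shared = set(alignments[0].species)
        for a in alignments[1:]:
            shared &= set(a.species)
        if not shared:
            raise AlignmentError(
                "species intersection across alignments is empty")
        species = [s for s in alignments[0].species if s in shared]

    rows = {s: [] for s in species}
    partitions: list[Partition] = []
    cursor = 1
    for i, a in enumerate(alignments):
        for s in species:
            rows[s].append(a.records.get(s, "?" * a.length))
        name = a.name or f"part{i + 1}"
        partitions.append(Partition(name, cursor, cursor + a.length - 1))
        cursor += a.length
    merged = Alignment({s: "".join(rows[s]) for s in species},
                       alignments[0].alphabet, name="supermatrix")
    return merged, partitions


def write_partitions_raxml(partitions: Sequence[Partition], path,
                           model: str | None = None,
                           alphabet: str = "aa") -> None:
    """RAxML-style partition file: ``MODEL, name = start-end`` per line."""
    if model is None:
        model = "GTR" if alphabet == "nt" else "LG"
    with open(path, "w") as fh:
        for p in partitions:
            fh.write(f"{model}, {p.name} = {p.start}-{p.end}\n")


def write_partitions_tsv(partitions: Sequence[Partition], path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tstart\tend\n")
        for p in partitions:
            fh.write(f"{p.name}\t{p.start}\t{p.end}\n")
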