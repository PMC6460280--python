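"""Shared sequence types and I/O.

Everything downstream (simulation, screening, assembly, TAG mapping, ORF
calling) moves sequences around as :class:`SeqRecord` objects and genomic
spans as :class:`Interval` objects.  Coordinates are 0-based half-open
throughout; minus-strand features report their span on the forward strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

DNA_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaError(ValueError):
    """Malformed FASTA input (empty file, duplicate ids, illegal residues)."""


class TranslationError(ValueError):
    """A putative CDS violates the coding-sequence contract."""


@dataclass(frozen=True)
class SeqRecord:
    """A named sequence (read, TAG, contig, insert or protein).

    ``residues`` is an uppercase string over the DNA alphabet ``ACGTN`` or
    the protein alphabet (20 amino acids plus ``X`` and ``*``).
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: residues must be non-empty")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def is_dna(self) -> bool:
        return set(self.residues) <= DNA_ALPHABET


@dataclass(frozen=True)
class Interval:
    """0-based half-open span on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.seq_id == other.seq_id and self.start < other.end and other.start < self.end


def _table11_codon_map() -> dict[str, str]:
    # Bacterial/archaeal code: standard codon assignments, stops TAA/TGA/TAG.
    bases = "TCAG"
    aas = (
        "FFLLSSSSYY**CC*W"
        "LLLLPPPPHHQQRRRR"
        "IIIMTTTTNNKKSSRR"
        "VVVVAAAADDEEGGGG"
    )
    table = {}
    i = 0
    for b1 in bases:
        for b2 in bases:
            for b3 in bases:
                table[b1 + b2 + b3] = aas[i]
                i += 1
    return table


@dataclass(frozen=True)
class GeneticCode:
    """Translation table 11 with the prokaryotic start/stop convention.

    Starts are ATG, GTG and TTG; stops are TAA, TGA and TAG.  Alternative
    starts render as M at CDS position 1 only.
    """

    codon_table: dict[str, str] = field(default_factory=_table11_codon_map)
    start_codons: frozenset[str] = frozenset({"ATG", "GTG", "TTG"})
    stop_codons: frozenset[str] = frozenset({"TAA", "TGA", "TAG"})

    def aa(self, codon: str) -> str:
        """Translate one codon; any codon containing N yields X."""
        if "N" in codon:
            return "X"
        return self.codon_table[codon]

    def is_start(self, codon: str) -> bool:
        return codon in self.start_codons

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons


TABLE11 = GeneticCode()


def revcomp(dna: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    if not set(dna) <= DNA_ALPHABET:
        bad = sorted(set(dna) - DNA_ALPHABET)
        raise ValueError(f"not a DNA sequence (illegal characters {bad})")
    return dna.translate(_COMPLEMENT)[::-1]


def translate(cds: str, code: GeneticCode = TABLE11) -> str:
    """Translate a complete CDS (start codon ... stop codon) to protein.

    The protein excludes the stop, so its length is ``len(cds)/3 - 1``.
    The initiator codon is rendered as M whichever of ATG/GTG/TTG it is.

    Raises
    ------
    TranslationError
        If the length is not a multiple of 3, the first codon is not a
        start, the last codon is not a stop, or an internal stop occurs
        (the error message carries the offending nucleotide position).
    """
    n = len(cds)
    if n % 3 != 0:
        raise TranslationError(f"CDS length {n} is not a multiple of 3")
    if n < 6:
        raise TranslationError("CDS must contain at least a start and a stop codon")
    first = cds[:3]
    if not code.is_start(first):
        raise TranslationError(f"first codon {first!r} is not a start codon")
    last = cds[-3:]
    if not code.is_stop(last):
        raise TranslationError(f"last codon {last!r} is not a stop codon")
    out = ["M"]
    for pos in range(3, n - 3, 3):
        codon = cds[pos : pos + 3]
        if code.is_stop(codon):
            raise TranslationError(f"internal stop codon {codon!r} at position {pos}")
        out.append(code.aa(codon))
    return "".join(out)


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a multi-record FASTA file into :class:`SeqRecord` objects.

    Residues are uppercased.  Raises :class:`FastaError` on an empty file,
    duplicate ids, or residues outside the DNA/protein alphabets, naming
    the offending record.
    """
    path = Path(path)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        if not residues:
            raise FastaError(f"{path}: record {rec.id!r} has no residues")
        if not (set(residues) <= DNA_ALPHABET or set(residues) <= PROTEIN_ALPHABET):
            bad = sorted(set(residues) - PROTEIN_ALPHABET - DNA_ALPHABET)
            raise FastaError(f"{path}: record {rec.id!r} has illegal characters {bad}")
        desc = rec.description[len(rec.id) :].strip() if rec.description else ""
        records.append(SeqRecord(rec.id, residues, desc))
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA wrapped at ``width`` columns."""
    path = Path(path)
    bio = []
    for r in records:
        bio.append(_BioRecord(Seq(r.residues), id=r.id, description=r.description))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def write_tsv(path: str | Path, header: Sequence[str], rows: Iterable[Sequence], comments: Sequence[str] = ()) -> None:
    """Write a TSV with a header row and optional leading '#' comment lines."""
    with open(path, "w") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
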