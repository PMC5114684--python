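"""Sequence primitives, miRBase-dialect FASTA I/O and a synthetic miRNA generator.

Everything downstream (thermodynamics, hybridization, sponge design) trades in
:class:`NucleotideSequence` objects.  The canonical internal alphabet is RNA;
DNA appears only at the oligo-emission boundary of the design module.
Coordinates follow two conventions used consistently across the package:
miRNA positions are 1-based from the miRNA 5' end, sponge/target intervals are
0-based half-open.
"""

from __future__ import annotations

import gzip
import io
import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "Alphabet",
    "NucleotideSequence",
    "MiRNARecord",
    "ValidationError",
    "FastaError",
    "reverse_complement",
    "convert_alphabet",
    "read_mirna_fasta",
    "write_fasta",
    "generate_synthetic_mirna_set",
]


class ValidationError(ValueError):
    """A sequence or record violates its invariants."""


class FastaError(ValueError):
    """A FASTA file cannot be parsed into miRNA records."""


class Alphabet(str, Enum):
    RNA = "RNA"
    DNA = "DNA"


_LETTERS = {Alphabet.RNA: set("ACGU"), Alphabet.DNA: set("ACGT")}
_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: miRBase mature.fa accession dialect (MIMAT for mature entries, MI for hairpins)
_ACCESSION_RE = re.compile(r"MI(?:MAT)?\d+$")


@dataclass(frozen=True)
class NucleotideSequence:
    """A validated 5'->3' nucleotide string in a fixed alphabet.

    Residues are canonicalised to uppercase.  Ambiguity codes (N, R, Y, ...)
    are rejected outright: sponge design against ambiguous bases is
    meaningless, and silently skipping them would corrupt coordinates.
    """

    residues: str
    alphabet: Alphabet = Alphabet.RNA

    def __post_init__(self) -> None:
        object.__setattr__(self, "alphabet", Alphabet(self.alphabet))
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise ValidationError("empty sequence")
        allowed = _LETTERS[self.alphabet]
        for pos, ch in enumerate(self.residues):
            if ch not in allowed:
                raise ValidationError(
                    f"invalid {self.alphabet.value} character {ch!r} at position "
                    f"{pos + 1} (1-based)"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues

    def __getitem__(self, item) -> str:
        return self.residues[item]

    def as_rna(self) -> "NucleotideSequence":
        return convert_alphabet(self, Alphabet.RNA)

    def as_dna(self) -> "NucleotideSequence":
        return convert_alphabet(self, Alphabet.DNA)

    def reverse_complement(self, out_alphabet: Optional[Alphabet] = None) -> "NucleotideSequence":
        return reverse_complement(self, out_alphabet or self.alphabet)


def rna(residues: str) -> NucleotideSequence:
    """Shorthand constructor for an RNA sequence (accepts T, normalised to U)."""
    return NucleotideSequence(residues.upper().replace("T", "U"), Alphabet.RNA)


def dna(residues: str) -> NucleotideSequence:
    """Shorthand constructor for a DNA sequence (accepts U, normalised to T)."""
    return NucleotideSequence(residues.upper().replace("U", "T"), Alphabet.DNA)


def convert_alphabet(seq: NucleotideSequence, to: Alphabet) -> NucleotideSequence:
    """U<->T substitution; idempotent and round-trip safe."""
    to = Alphabet(to)
    if to is seq.alphabet:
        return seq
    if to is Alphabet.DNA:
        return NucleotideSequence(seq.residues.replace("U", "T"), Alphabet.DNA)
    return NucleotideSequence(seq.residues.replace("T", "U"), Alphabet.RNA)


def reverse_complement(seq: NucleotideSequence, out_alphabet: Optional[Alphabet] = None) -> NucleotideSequence:
    """Reverse complement of ``seq`` in the requested output alphabet.

    Complementation happens in the sequence's own alphabet (U<->A for RNA,
    T<->A for DNA); the result is then converted, so the operation is an
    involution whenever input and output alphabets match.
    """
    out_alphabet = Alphabet(out_alphabet) if out_alphabet is not None else seq.alphabet
    table = _RNA_COMPLEMENT if seq.alphabet is Alphabet.RNA else _DNA_COMPLEMENT
    comp = seq.residues.translate(table)[::-1]
    return convert_alphabet(NucleotideSequence(comp, seq.alphabet), out_alphabet)


@dataclass(frozen=True)
class MiRNARecord:
    """A named mature miRNA: the query unit of every screen.

    ``name`` follows the miRBase convention (e.g. ``hsa-miR-145-5p``); the
    species code is the prefix before the first dash.  Mature miRNAs are
    15-35 nt; lengths outside that range trigger a warning, anything under
    6 nt is rejected (no seed region could exist).
    """

    name: str
    sequence: NucleotideSequence
    accession: str = ""
    species_code: str = field(default="", compare=True)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("miRNA record requires a non-empty name")
        if self.sequence.alphabet is not Alphabet.RNA:
            object.__setattr__(self, "sequence", self.sequence.as_rna())
        n = len(self.sequence)
        if n < 6:
            raise ValidationError(
                f"miRNA {self.name!r} is only {n} nt; mature miRNAs must be >= 6 nt"
            )
        if not 15 <= n <= 35:
            warnings.warn(
                f"miRNA {self.name!r} length {n} nt is outside the mature range 15-35 nt",
                stacklevel=2,
            )
        if not self.species_code:
            object.__setattr__(self, "species_code", _species_code(self.name))

    def __len__(self) -> int:
        return len(self.sequence)


def _species_code(name: str) -> str:
    head, dash, _ = name.partition("-")
    return head if dash else ""


def _open_maybe_gzip(path) -> io.TextIOBase:
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def read_mirna_fasta(path, species_filter: Optional[str] = None) -> list[MiRNARecord]:
    """Read mature miRNAs from a miRBase-dialect FASTA file.

    Header token 1 becomes the name; token 2 becomes the accession when it
    looks like a miRBase accession (``MIMATnnnn``/``MInnnn``), otherwise the
    remainder of the header is ignored.  T is normalised to U.  Input order is
    preserved; ``species_filter`` keeps only records whose name prefix (before
    the first dash) equals the given code.
    """
    records: list[MiRNARecord] = []
    with _open_maybe_gzip(path) as handle:
        for entry in SeqIO.parse(handle, "fasta"):
            header = entry.description.strip()
            tokens = header.split()
            if not tokens:
                warnings.warn(f"{path}: blank FASTA header; record skipped")
                continue
            name = tokens[0]
            accession = ""
            if len(tokens) > 1 and _ACCESSION_RE.fullmatch(tokens[1]):
                accession = tokens[1]
            elif len(tokens) == 1 and header != name:
                # unreachable with split(); kept for clarity of intent
                pass
            if len(tokens) > 1 and not accession:
                warnings.warn(
                    f"{path}: header {header!r} has no miRBase accession token; "
                    "stored with empty accession"
                )
            try:
                seq = rna(str(entry.seq))
            except ValidationError as exc:
                raise FastaError(f"{path}: record {name!r}: {exc}") from exc
            records.append(MiRNARecord(name=name, sequence=seq, accession=accession))
    if not records:
        raise FastaError(f"{path}: no FASTA records found (empty miRNA set)")
    names = [r.name for r in records]
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise FastaError(f"{path}: duplicate miRNA names: {', '.join(dupes)}")
    if species_filter:
        records = [r for r in records if r.species_code == species_filter]
    return records


def write_fasta(records: Iterable[MiRNARecord], path) -> None:
    """Write records in the miRBase dialect; round-trips through read_mirna_fasta."""
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.name} {rec.accession}".rstrip()
            fh.write(f"{header}\n{rec.sequence}\n")


def generate_synthetic_mirna_set(
    n: int,
    length_range: Sequence[int] = (19, 25),
    gc_fraction: float = 0.5,
    seed: int = 0,
    planted: Optional[Sequence[NucleotideSequence | str]] = None,
) -> list[MiRNARecord]:
    """Seeded synthetic mature-miRNA set, a stand-in for a miRBase download.

    ``n`` random records named ``syn-miR-0001`` ... are drawn with lengths
    uniform in ``length_range`` and base composition matching ``gc_fraction``
    in expectation (G and C equiprobable within the GC mass, likewise A/U).
    Any ``planted`` sequences are appended as ``planted-0001`` ... so tests can
    construct known on- and off-targets.  Identical seeds give byte-identical
    sets.
    """
    lo, hi = int(length_range[0]), int(length_range[1])
    if n < 0:
        raise ValidationError("n must be >= 0")
    if not (15 <= lo <= hi <= 35):
        raise ValidationError(
            f"length_range must satisfy 15 <= min <= max <= 35, got [{lo}, {hi}]"
        )
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValidationError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    bases = np.array(list("ACGU"))
    records = []
    for k in range(n):
        length = int(rng.integers(lo, hi + 1))
        residues = "".join(bases[rng.choice(4, size=length, p=probs)])
        records.append(
            MiRNARecord(name=f"syn-miR-{k + 1:04d}", sequence=rna(residues))
        )
    for k, seq in enumerate(planted or []):
        if isinstance(seq, str):
            seq = rna(seq)
        records.append(MiRNARecord(name=f"planted-{k + 1:04d}", sequence=seq.as_rna()))
    return records
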