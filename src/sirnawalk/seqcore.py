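"""Nucleotide sequence model, strand conventions and FASTA I/O.

Conventions used throughout the package:

* Sequences are read 5'->3' and carry an explicit alphabet (RNA or DNA).
* All transcript coordinates are 1-based, inclusive, on the sense strand.
* Input is case-insensitive; canonical output is uppercase.
* IUPAC ambiguity codes are rejected: every downstream design rule is defined
  only on concrete bases.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Alphabet",
    "AlphabetError",
    "NucleotideSequence",
    "AlleleLocus",
    "reverse_complement",
    "convert_alphabet",
    "read_fasta",
    "write_fasta",
    "random_locus",
]

_RNA_BASES = frozenset("ACGU")
_DNA_BASES = frozenset("ACGT")


class Alphabet(str, enum.Enum):
    RNA = "RNA"
    DNA = "DNA"


class AlphabetError(ValueError):
    """A base is not valid in the declared (or any) nucleotide alphabet."""


@dataclass(frozen=True)
class NucleotideSequence:
    """An unambiguous RNA or DNA sequence, 5'->3'.

    Parameters
    ----------
    bases : str
        Sequence letters; lower case is accepted and canonicalised to upper.
    alphabet : Alphabet
        ``Alphabet.RNA`` ({A,C,G,U}) or ``Alphabet.DNA`` ({A,C,G,T}).
    """

    bases: str
    alphabet: Alphabet

    def __post_init__(self) -> None:
        up = self.bases.upper()
        object.__setattr__(self, "bases", up)
        valid = _RNA_BASES if self.alphabet is Alphabet.RNA else _DNA_BASES
        for i, b in enumerate(up, start=1):
            if b not in valid:
                raise AlphabetError(
                    f"base {b!r} at position {i} is not a valid "
                    f"{self.alphabet.value} base"
                )

    def __len__(self) -> int:
        return len(self.bases)

    def __str__(self) -> str:
        return self.bases

    def __getitem__(self, key):
        return self.bases[key]

    def slice1(self, start: int, end: int) -> "NucleotideSequence":
        """Return the 1-based inclusive slice [start, end]."""
        if not (1 <= start <= end <= len(self)):
            raise IndexError(
                f"slice [{start}, {end}] out of range for length {len(self)}"
            )
        return NucleotideSequence(self.bases[start - 1 : end], self.alphabet)


def _detect_alphabet(s: str, default: Alphabet = Alphabet.DNA) -> Alphabet:
    up = s.upper()
    has_u, has_t = "U" in up, "T" in up
    if has_u and has_t:
        raise AlphabetError("sequence contains both U and T")
    if has_u:
        return Alphabet.RNA
    if has_t:
        return Alphabet.DNA
    return default


def rna(bases: str) -> NucleotideSequence:
    """Shorthand constructor for an RNA sequence."""
    return NucleotideSequence(bases, Alphabet.RNA)


def dna(bases: str) -> NucleotideSequence:
    """Shorthand constructor for a DNA sequence."""
    return NucleotideSequence(bases, Alphabet.DNA)


def reverse_complement(s: NucleotideSequence) -> NucleotideSequence:
    """5'->3' reverse complement in the same alphabet (A<->U or A<->T, G<->C)."""
    if s.alphabet is Alphabet.RNA:
        out = str(Seq(s.bases).reverse_complement_rna())
    else:
        out = str(Seq(s.bases).reverse_complement())
    return NucleotideSequence(out, s.alphabet)


def convert_alphabet(s: NucleotideSequence, to: Alphabet) -> NucleotideSequence:
    """Swap U<->T; all other bases and the strand orientation are unchanged."""
    to = Alphabet(to)
    if to is s.alphabet:
        return s
    if to is Alphabet.RNA:
        return NucleotideSequence(str(Seq(s.bases).transcribe()), Alphabet.RNA)
    return NucleotideSequence(str(Seq(s.bases).back_transcribe()), Alphabet.DNA)


@dataclass(frozen=True)
class AlleleLocus:
    """A sense transcript with a single nucleotide variant.

    ``snv_position`` is 1-based on ``sense_sequence``; the sequence itself
    carries the wild-type base at that position, ``mut_base`` is the variant.
    Flank sufficiency for a particular guide design is checked at design time,
    not here.
    """

    transcript_id: str
    sense_sequence: NucleotideSequence
    snv_position: int
    wt_base: str
    mut_base: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "wt_base", self.wt_base.upper())
        object.__setattr__(self, "mut_base", self.mut_base.upper())
        n = len(self.sense_sequence)
        if not (1 <= self.snv_position <= n):
            raise ValueError(
                f"snv_position {self.snv_position} outside sequence of length {n}"
            )
        valid = _RNA_BASES if self.sense_sequence.alphabet is Alphabet.RNA else _DNA_BASES
        for name, b in (("wt_base", self.wt_base), ("mut_base", self.mut_base)):
            if b not in valid:
                raise AlphabetError(f"{name} {b!r} not valid in {self.sense_sequence.alphabet.value}")
        if self.wt_base == self.mut_base:
            raise ValueError("wt_base and mut_base must differ")
        actual = self.sense_sequence[self.snv_position - 1]
        if actual != self.wt_base:
            raise ValueError(
                f"sense sequence has {actual!r} at position {self.snv_position}, "
                f"declared wt_base is {self.wt_base!r}"
            )

    @property
    def alphabet(self) -> Alphabet:
        return self.sense_sequence.alphabet

    def allele_sequence(self, allele: str) -> NucleotideSequence:
        """Full sense sequence of the requested allele ('wt' or 'mut')."""
        if allele == "wt":
            return self.sense_sequence
        if allele == "mut":
            b = self.sense_sequence.bases
            i = self.snv_position - 1
            return NucleotideSequence(b[:i] + self.mut_base + b[i + 1 :], self.alphabet)
        raise ValueError(f"allele must be 'wt' or 'mut', got {allele!r}")


def read_fasta(
    path, default_alphabet: Alphabet = Alphabet.DNA
) -> list[tuple[str, NucleotideSequence]]:
    """Read a FASTA file into ``(id, NucleotideSequence)`` pairs.

    The alphabet is auto-detected per record (U => RNA, T => DNA, neither =>
    ``default_alphabet``); a record mixing U and T, duplicate ids, or an empty
    file are errors.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    out: list[tuple[str, NucleotideSequence]] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        s = str(rec.seq)
        out.append((rec.id, NucleotideSequence(s, _detect_alphabet(s, default_alphabet))))
    return out


def write_fasta(
    records: Iterable[tuple[str, NucleotideSequence]], path, width: int = 70
) -> None:
    """Write ``(id, sequence)`` pairs as FASTA, wrapped at ``width`` columns."""
    seqrecs = [
        SeqRecord(Seq(s.bases), id=name, description="") for name, s in records
    ]
    path = Path(path)
    with path.open("w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


def random_locus(
    rng: np.random.Generator,
    length: int = 300,
    snv_position: int | None = None,
    alphabet: Alphabet = Alphabet.DNA,
    transcript_id: str = "synthetic",
) -> AlleleLocus:
    """Generate a uniform-random synthetic transcript with one SNV.

    The SNV defaults to the middle of the transcript; the mutant base is drawn
    uniformly from the three non-wild-type bases. Intended for simulations and
    tests, where any real transcript context is irrelevant to the coordinate
    arithmetic being exercised.
    """
    letters = "ACGU" if alphabet is Alphabet.RNA else "ACGT"
    bases = "".join(rng.choice(list(letters), size=length))
    pos = snv_position if snv_position is not None else length // 2
    wt = bases[pos - 1]
    mut = rng.choice([b for b in letters if b != wt])
    return AlleleLocus(
        transcript_id=transcript_id,
        sense_sequence=NucleotideSequence(bases, alphabet),
        snv_position=pos,
        wt_base=wt,
        mut_base=str(mut),
    )
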