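"""Codon / protein alignment containers with FASTA IO (Biopython-backed)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetics import translate_codon


@dataclass
class CodonAlignment:
    """In-frame coding-sequence alignment (aligned length divisible by 3).

    ``seqs`` maps species label to the aligned nucleotide string (gaps ``-``).
    ``ref_species`` designates the sequence whose ungapped positions define
    reference coordinates (residue numbering à la human PON1 N270).
    """

    seqs: dict[str, str] = field(default_factory=dict)
    ref_species: str | None = None

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.seqs.values()}
        if len(lengths) > 1:
            raise ValueError("aligned sequences must share one length")
        if lengths and next(iter(lengths)) % 3 != 0:
            raise ValueError("aligned length must be a multiple of 3")
        if self.ref_species is not None and self.ref_species not in self.seqs:
            raise KeyError(f"ref_species {self.ref_species!r} not in alignment")

    @property
    def species(self) -> list[str]:
        return list(self.seqs)

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.seqs.values()))) if self.seqs else 0

    @property
    def n_codons(self) -> int:
        return self.n_columns // 3

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.seqs.items())

    def codon(self, species: str, index: int) -> str:
        """1-based aligned codon triplet."""
        if not 1 <= index <= self.n_codons:
            raise IndexError(f"codon index {index} out of range 1..{self.n_codons}")
        s = self.seqs[species]
        return s[3 * (index - 1): 3 * index]

    def to_protein(self) -> "ProteinAlignment":
        prot = {}
        for sp, seq in self.seqs.items():
            residues = []
            for i in range(0, len(seq), 3):
                codon = seq[i:i + 3]
                residues.append("-" if "-" in codon else translate_codon(codon))
            prot[sp] = "".join(residues)
        return ProteinAlignment(prot, ref_species=self.ref_species)

    def write_fasta(self, path: str | Path) -> None:
        records = [SeqRecord(Seq(s), id=sp, description="") for sp, s in self.seqs.items()]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def read_fasta(cls, path: str | Path, ref_species: str | None = None) -> "CodonAlignment":
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        if not seqs:
            raise ValueError(f"no sequences in {path}")
        return cls(seqs, ref_species=ref_species)


@dataclass
class ProteinAlignment:
    seqs: dict[str, str]
    ref_species: str | None = None

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.seqs.values()}
        if len(lengths) > 1:
            raise ValueError("aligned sequences must share one length")
        if self.ref_species is not None and self.ref_species not in self.seqs:
            raise KeyError(f"ref_species {self.ref_species!r} not in alignment")

    @property
    def species(self) -> list[str]:
        return list(self.seqs)

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.seqs.values()))) if self.seqs else 0

    def write_fasta(self, path: str | Path) -> None:
        records = [SeqRecord(Seq(s), id=sp, description="") for sp, s in self.seqs.items()]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def read_fasta(cls, path: str | Path, ref_species: str | None = None) -> "ProteinAlignment":
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        if not seqs:
            raise ValueError(f"no sequences in {path}")
        return cls(seqs, ref_species=ref_species)
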