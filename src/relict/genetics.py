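"""Standard genetic-code tables and codon indexing shared across modules.

The substitution machinery works on the 61 sense codons of the standard
nuclear code; stop codons are never part of the simulated/likelihood state
space and are only meaningful to the lesion scanner.
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS: tuple[str, ...] = tuple(sorted(_STANDARD.stop_codons))

#: the 61 sense codons in lexicographic order — canonical state ordering
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_STANDARD.forward_table))

CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

#: amino-acid letter per sense codon, aligned with SENSE_CODONS
CODON_AA: tuple[str, ...] = tuple(_STANDARD.forward_table[c] for c in SENSE_CODONS)

NUCLEOTIDES = "ACGT"
_NT_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def is_transition(a: str, b: str) -> bool:
    """True if single-nucleotide change a<->b is a transition (A<->G, C<->T)."""
    return (a in _PURINES and b in _PURINES) or (a in _PYRIMIDINES and b in _PYRIMIDINES)


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a codon, '*' for stops, 'X' otherwise."""
    codon = codon.upper().replace("U", "T")
    if codon in STOP_CODONS:
        return "*"
    return _STANDARD.forward_table.get(codon, "X")


def _pair_structure() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Masks over the 61x61 sense-codon grid.

    Returns (single_diff, transition, nonsynonymous) boolean matrices where
    entries are defined only for pairs differing at exactly one position.
    """
    n = len(SENSE_CODONS)
    single = np.zeros((n, n), dtype=bool)
    transver = np.zeros((n, n), dtype=bool)
    nonsyn = np.zeros((n, n), dtype=bool)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            a, b = diffs[0]
            transver[i, j] = is_transition(a, b)
            nonsyn[i, j] = CODON_AA[i] != CODON_AA[j]
    return single, transver, nonsyn


SINGLE_DIFF, TRANSITION_PAIR, NONSYN_PAIR = _pair_structure()

CODON_NT_INDEX = np.array(
    [[_NT_INDEX[nt] for nt in codon] for codon in SENSE_CODONS], dtype=np.int64
)
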