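"""Standard genetic code tables shared by the coding, alignment and
divergence modules.

Everything here is derived once, at import time, from Biopython's standard
codon table, and exposed as plain dict/list/tuple structures so the hot
loops in the divergence estimators never touch Biopython objects.
"""

from __future__ import annotations

from Bio.Data import CodonTable

NUCLEOTIDES = "TCAG"

_standard = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS: frozenset[str] = frozenset(_standard.stop_codons)

#: codon -> one-letter amino acid, sense codons only
CODON_TO_AA: dict[str, str] = dict(_standard.forward_table)

#: the 61 sense codons in a fixed, reproducible order
SENSE_CODONS: tuple[str, ...] = tuple(
    a + b + c
    for a in NUCLEOTIDES
    for b in NUCLEOTIDES
    for c in NUCLEOTIDES
    if a + b + c not in STOP_CODONS
)

CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def is_transition(x: str, y: str) -> bool:
    """True if the single-nucleotide change x -> y is a transition."""
    return (x in _PURINES and y in _PURINES) or (
        x in _PYRIMIDINES and y in _PYRIMIDINES
    )


def codon_neighbors(codon: str) -> list[tuple[int, str]]:
    """All 9 single-nucleotide neighbors of a codon as (position, codon)."""
    out = []
    for pos in range(3):
        for base in NUCLEOTIDES:
            if base != codon[pos]:
                out.append((pos, codon[:pos] + base + codon[pos + 1 :]))
    return out


def is_synonymous(codon_i: str, codon_j: str) -> bool:
    """True if two sense codons encode the same amino acid."""
    return CODON_TO_AA[codon_i] == CODON_TO_AA[codon_j]


#: per sense codon: degeneracy class (1, 2, 3 or 4) of each position —
#: the number of nucleotides at that position (including the current one)
#: that leave the amino acid unchanged.  4 = four-fold degenerate,
#: 1 = non-degenerate (zero-fold).
DEGENERACY: dict[str, tuple[int, int, int]] = {}
for _codon in SENSE_CODONS:
    _deg = []
    for _pos in range(3):
        _syn = 1
        for _base in NUCLEOTIDES:
            if _base == _codon[_pos]:
                continue
            _alt = _codon[:_pos] + _base + _codon[_pos + 1 :]
            if _alt not in STOP_CODONS and is_synonymous(_codon, _alt):
                _syn += 1
        _deg.append(_syn)
    DEGENERACY[_codon] = tuple(_deg)
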