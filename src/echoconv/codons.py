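"""Standard genetic code tables and codon index arrays for the GY94 model.

The 61 sense codons are ordered alphabetically (AAA, AAC, ... TTT minus
stops), which fixes the row/column order of every codon rate matrix in the
package. All arrays are derived from Biopython's standard codon table.
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]

NUCLEOTIDES = "ACGT"
STOP_CODONS = frozenset(_TABLE.stop_codons)

#: the 61 sense codons in alphabetical order; defines codon-state indices
SENSE_CODONS = tuple(
    sorted(c for c in (a + b + d for a in NUCLEOTIDES for b in NUCLEOTIDES for d in NUCLEOTIDES)
           if c not in STOP_CODONS)
)
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
N_CODONS = len(SENSE_CODONS)  # 61

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
N_AA = 20

#: amino acid encoded by each sense codon, index-aligned with SENSE_CODONS
CODON_AA = tuple(_TABLE.forward_table[c] for c in SENSE_CODONS)
CODON_AA_INDEX = np.array([AA_INDEX[a] for a in CODON_AA], dtype=np.int64)

GAP_CODON = "---"
AMBIG_CODON = "NNN"
GAP_AA = "-"
AMBIG_AA = "X"

_PURINES = {"A", "G"}


def is_transition(x: str, y: str) -> bool:
    """True if the single-nucleotide change x->y is a transition."""
    return (x in _PURINES) == (y in _PURINES)


def _pairwise_tables():
    ndiff = np.zeros((N_CODONS, N_CODONS), dtype=np.int64)
    transition = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    synonymous = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            ndiff[i, j] = len(diffs)
            if len(diffs) == 1:
                transition[i, j] = is_transition(*diffs[0])
                synonymous[i, j] = CODON_AA[i] == CODON_AA[j]
    return ndiff, transition, synonymous


#: number of differing positions, transition flag, synonymy flag (61 x 61)
CODON_NDIFF, CODON_TRANSITION, CODON_SYNONYMOUS = _pairwise_tables()

#: mask of single-step codon pairs (the only nonzero GY94 rates)
CODON_SINGLE_STEP = CODON_NDIFF == 1


def translate_codon(codon: str) -> str:
    """Translate one codon; gaps and ambiguities map to their AA symbols.

    Raises KeyError for stop codons and any other unrecognised triplet.
    """
    if codon == GAP_CODON:
        return GAP_AA
    if codon == AMBIG_CODON:
        return AMBIG_AA
    return _TABLE.forward_table[codon]  # KeyError on stops / bad codons


def codons_of(seq: str) -> list[str]:
    """Split an in-frame nucleotide string into codons."""
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} not divisible by 3")
    return [seq[i:i + 3] for i in range(0, len(seq), 3)]
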