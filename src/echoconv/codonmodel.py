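"""GY94-style codon substitution model over the 61 sense codons.

Off-diagonal rates for single-nucleotide codon changes are
pi_j * {1, kappa, omega, omega*kappa} for synonymous transversions /
synonymous transitions / nonsynonymous transversions / nonsynonymous
transitions; multi-step changes and changes through stop codons have rate
zero. The generator is scaled so the mean rate at equilibrium is one
expected substitution per codon site per unit branch length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from echoconv.align import CodonAlignment
from echoconv.codons import (
    CODON_INDEX,
    CODON_SINGLE_STEP,
    CODON_SYNONYMOUS,
    CODON_TRANSITION,
    GAP_CODON,
    N_CODONS,
    NUCLEOTIDES,
    SENSE_CODONS,
)


def uniform_codon_frequencies() -> np.ndarray:
    return np.full(N_CODONS, 1.0 / N_CODONS)


@dataclass(frozen=True)
class GY94Params:
    """kappa: transition/transversion rate ratio; omega: dN/dS;
    pi: codon equilibrium frequencies (61-vector summing to 1)."""

    kappa: float
    omega: float
    pi: np.ndarray = field(default_factory=uniform_codon_frequencies)

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=float)
        object.__setattr__(self, "pi", pi)
        if self.kappa <= 0:
            raise ValueError(f"kappa must be positive, got {self.kappa}")
        if self.omega < 0:
            raise ValueError(f"omega must be non-negative, got {self.omega}")
        if pi.shape != (N_CODONS,) or not np.isclose(pi.sum(), 1.0, atol=1e-8):
            raise ValueError("pi must be a 61-vector summing to 1")
        if np.any(pi < 0):
            raise ValueError("pi must be non-negative")


def build_gy94_unscaled(params: GY94Params) -> np.ndarray:
    """The raw GY94 generator (rows sum to zero, no rate normalisation)."""
    kappa, omega, pi = params.kappa, params.omega, params.pi
    factor = np.where(CODON_TRANSITION, kappa, 1.0) * np.where(CODON_SYNONYMOUS, 1.0, omega)
    Q = np.where(CODON_SINGLE_STEP, factor * pi[None, :], 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def gy94_mean_rate(params: GY94Params) -> float:
    """Equilibrium mean rate of the unscaled generator."""
    Q = build_gy94_unscaled(params)
    return -float(params.pi @ np.diag(Q))


def neutral_rate(kappa: float, pi: np.ndarray) -> float:
    """Mean rate of the neutral (omega = 1) unscaled generator — the common
    normaliser shared by every site class in mixture models, so that a
    branch length is measured in neutral-equivalent substitutions per codon
    and classes with omega > 1 genuinely evolve faster."""
    return gy94_mean_rate(GY94Params(kappa=kappa, omega=1.0, pi=pi))


def build_gy94(params: GY94Params) -> np.ndarray:
    """Assemble the 61x61 generator scaled to mean rate 1 at equilibrium."""
    Q = build_gy94_unscaled(params)
    rate = -float(params.pi @ np.diag(Q))
    if rate <= 0:
        raise ValueError("degenerate rate matrix (zero mean rate)")
    return Q / rate


def build_gy94_neutral_scaled(params: GY94Params) -> np.ndarray:
    """GY94 generator under the shared neutral-rate normalisation."""
    return build_gy94_unscaled(params) / neutral_rate(params.kappa, params.pi)


def f3x4_frequencies(aln: CodonAlignment, pseudocount: float = 0.5) -> np.ndarray:
    """CodeML-style F3x4 codon frequencies from position-specific nucleotide
    counts, renormalised over the 61 sense codons."""
    counts = np.full((3, 4), pseudocount)
    nt_index = {n: i for i, n in enumerate(NUCLEOTIDES)}
    for seq in aln.sequences:
        for i in range(0, len(seq), 3):
            codon = seq[i:i + 3]
            if codon == GAP_CODON:
                continue
            for pos, ch in enumerate(codon):
                j = nt_index.get(ch)
                if j is not None:
                    counts[pos, j] += 1
    pos_freq = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array([
        pos_freq[0, nt_index[c[0]]] * pos_freq[1, nt_index[c[1]]] * pos_freq[2, nt_index[c[2]]]
        for c in SENSE_CODONS
    ])
    return pi / pi.sum()


def empirical61_frequencies(aln: CodonAlignment, pseudocount: float = 0.5) -> np.ndarray:
    """Observed codon usage across the alignment (61 sense codons)."""
    counts = np.full(N_CODONS, pseudocount)
    for seq in aln.sequences:
        for i in range(0, len(seq), 3):
            idx = CODON_INDEX.get(seq[i:i + 3])
            if idx is not None:
                counts[idx] += 1
    return counts / counts.sum()


def encode_codon_alignment(aln: CodonAlignment) -> np.ndarray:
    """(n_taxa, n_codons) int codon states; gaps/ambiguities -> -1."""
    out = np.full((len(aln.taxa), aln.n_codons), -1, dtype=np.int64)
    for r, seq in enumerate(aln.sequences):
        for s in range(aln.n_codons):
            out[r, s] = CODON_INDEX.get(seq[3 * s:3 * s + 3], -1)
    return out
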