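"""Amino-acid replacement models (Poisson or user-supplied exchangeabilities).

The generator is Q_ij = s_ij * pi_j (i != j) with the diagonal closing rows
to zero, scaled so the mean rate at equilibrium is one expected replacement
per site per unit branch length. Optional discrete-gamma rate heterogeneity
uses k equal-weight categories at quantile midpoints, normalised to mean 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as gamma_dist

from echoconv.codons import AA_INDEX, N_AA


@dataclass(frozen=True)
class AAModel:
    """A reversible 20-state replacement model.

    name: "POISSON" (uniform exchangeabilities) or a label for a supplied
    matrix; frequencies: stationary distribution (sums to 1);
    exchangeabilities: symmetric 20x20 s-matrix (ignored diagonal), required
    unless name == "POISSON"; gamma_shape: alpha for among-site rate
    variation (None = rates homogeneous); gamma_categories: k.
    """

    name: str = "POISSON"
    frequencies: np.ndarray = field(default_factory=lambda: np.full(N_AA, 1.0 / N_AA))
    exchangeabilities: np.ndarray | None = None
    gamma_shape: float | None = None
    gamma_categories: int = 4

    def __post_init__(self):
        freqs = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "frequencies", freqs)
        if freqs.shape != (N_AA,) or not np.isclose(freqs.sum(), 1.0, atol=1e-8):
            raise ValueError("frequencies must be a 20-vector summing to 1")
        if np.any(freqs <= 0):
            raise ValueError("frequencies must be strictly positive")
        if self.name != "POISSON" and self.exchangeabilities is None:
            raise ValueError(f"model {self.name!r} requires an exchangeability matrix")
        if self.exchangeabilities is not None:
            s = np.asarray(self.exchangeabilities, dtype=float)
            if s.shape != (N_AA, N_AA) or not np.allclose(s, s.T):
                raise ValueError("exchangeabilities must be symmetric 20x20")
            object.__setattr__(self, "exchangeabilities", s)

    def generator(self) -> np.ndarray:
        """Assembled Q, rows summing to zero, mean rate 1 at equilibrium."""
        pi = self.frequencies
        s = self.exchangeabilities if self.exchangeabilities is not None else np.ones((N_AA, N_AA))
        Q = s * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        rate = -float(pi @ np.diag(Q))
        return Q / rate

    def rate_categories(self) -> tuple[np.ndarray, np.ndarray]:
        """Discrete-gamma (rates, weights); a single unit rate if no gamma."""
        if self.gamma_shape is None:
            return np.array([1.0]), np.array([1.0])
        k, a = self.gamma_categories, self.gamma_shape
        quantiles = (2 * np.arange(k) + 1) / (2 * k)
        rates = gamma_dist.ppf(quantiles, a=a, scale=1.0 / a)
        rates = rates / rates.mean()
        return rates, np.full(k, 1.0 / k)


def observed_frequencies(sequences: list[str], pseudocount: float = 1.0) -> np.ndarray:
    """Empirical residue frequencies of an alignment (gaps ignored),
    regularised by a small pseudocount so no state has probability zero."""
    counts = np.full(N_AA, pseudocount)
    for seq in sequences:
        for ch in seq:
            idx = AA_INDEX.get(ch)
            if idx is not None:
                counts[idx] += 1
    return counts / counts.sum()
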