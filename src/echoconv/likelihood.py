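"""Scaled pruning over rooted trees, generic in the state alphabet.

One engine serves the 20-state amino-acid models (reconstruction) and the
61-state codon models (branch-site fits). Alignment columns are compressed
to unique patterns before any likelihood work; per-pattern scaling keeps
partial likelihoods in range for alignments up to at least 10,000 sites x
50 taxa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from echoconv.phylo import PhyloTree


@dataclass(frozen=True)
class PatternSet:
    """Unique columns of an encoded alignment.

    ``codes``: (n_taxa, n_patterns) int states, -1 for gap/ambiguity;
    ``weights``: pattern multiplicities; ``site_to_pattern``: per original
    site, the pattern index.
    """

    codes: np.ndarray
    weights: np.ndarray
    site_to_pattern: np.ndarray

    @property
    def n_patterns(self) -> int:
        return self.codes.shape[1]


def compress_columns(encoded: np.ndarray) -> PatternSet:
    """Collapse an (n_taxa, n_sites) state matrix to unique patterns."""
    cols, inverse, counts = np.unique(
        encoded.T, axis=0, return_inverse=True, return_counts=True
    )
    return PatternSet(
        codes=np.ascontiguousarray(cols.T),
        weights=counts.astype(float),
        site_to_pattern=inverse.reshape(-1),
    )


def spectral_decomposition(Q: np.ndarray, pi: np.ndarray):
    """Eigendecompose a reversible generator via the symmetrizing similarity.

    Returns (eigvals, left, right) such that P(t) = right @ diag(exp(l t)) @ left.
    """
    sqrt_pi = np.sqrt(pi)
    S = (Q * sqrt_pi[None, :]) / sqrt_pi[:, None]
    eigvals, V = np.linalg.eigh((S + S.T) / 2.0)
    right = V / sqrt_pi[:, None]
    left = V.T * sqrt_pi[None, :]
    return eigvals, left, right


class TransitionCalculator:
    """Transition probability matrices P(t) = exp(Qt) for a reversible Q."""

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        self.Q = Q
        self.pi = pi
        self.eigvals, self._left, self._right = spectral_decomposition(Q, pi)

    def matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError(f"negative branch length {t}")
        P = (self._right * np.exp(self.eigvals * t)[None, :]) @ self._left
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


class PruningEngine:
    """Felsenstein pruning on a fixed tree, reusable across parameter values.

    Nodes are addressed by their deterministic post-order ids. Transition
    matrices are supplied per non-root node (the matrix for the edge above
    that node), which lets mixture models vary matrices per branch.
    """

    def __init__(self, tree: PhyloTree, n_states: int, taxa: list[str]):
        self.tree = tree
        self.n_states = n_states
        missing = [t for t in tree.leaf_labels if t not in taxa]
        if missing:
            raise ValueError(f"alignment lacks taxa present in tree: {missing}")
        self.taxon_row = {t: i for i, t in enumerate(taxa)}
        self.postorder_ids = [n.node_id for n in tree.nodes]
        self.root_id = tree.root.node_id
        self.children = {n.node_id: [c.node_id for c in n.children] for n in tree.nodes}
        self.leaf_row = {
            n.node_id: self.taxon_row[n.label] for n in tree.leaves
        }
        self.internal_ids = [n.node_id for n in tree.nodes if not n.is_leaf]
        self._leaf_cache: tuple[int, dict[int, np.ndarray]] | None = None

    def _leaf_partials(self, patterns: PatternSet) -> dict[int, np.ndarray]:
        """Tip indicator partials, cached per pattern set (reused across the
        many likelihood evaluations of one optimisation / BEB grid)."""
        if self._leaf_cache is not None and self._leaf_cache[0] == id(patterns):
            return self._leaf_cache[1]
        k, m = self.n_states, patterns.n_patterns
        cache: dict[int, np.ndarray] = {}
        for v, row in self.leaf_row.items():
            codes = patterns.codes[row]
            arr = np.zeros((k, m))
            obs = codes >= 0
            arr[codes[obs], np.nonzero(obs)[0]] = 1.0
            arr[:, ~obs] = 1.0
            cache[v] = arr
        self._leaf_cache = (id(patterns), cache)
        return cache

    # -- down pass --------------------------------------------------------

    def partials(self, patterns: PatternSet, P: dict[int, np.ndarray]):
        """Post-order partial likelihoods with per-pattern scaling.

        Returns (partial, scale_log, down) where ``partial[v]`` is
        (n_states, n_patterns) scaled, ``scale_log[v]`` the cumulative log
        scale of the subtree at v, and ``down[v] = P_v @ partial_v`` the
        scaled message sent to v's parent.
        """
        k, m = self.n_states, patterns.n_patterns
        leaf_partials = self._leaf_partials(patterns)
        partial: dict[int, np.ndarray] = {}
        scale_log: dict[int, np.ndarray] = {}
        down: dict[int, np.ndarray] = {}
        for v in self.postorder_ids:
            kids = self.children[v]
            if not kids:
                partial[v] = leaf_partials[v]
                scale_log[v] = np.zeros(m)
            else:
                arr = np.ones((k, m))
                sc = np.zeros(m)
                for c in kids:
                    down[c] = P[c] @ partial[c]
                    arr = arr * down[c]
                    sc = sc + scale_log[c]
                mx = arr.max(axis=0)
                mx[mx == 0.0] = 1.0
                arr /= mx[None, :]
                partial[v] = arr
                scale_log[v] = sc + np.log(mx)
        return partial, scale_log, down

    def site_log_likelihood(
        self, patterns: PatternSet, P: dict[int, np.ndarray], pi: np.ndarray
    ) -> np.ndarray:
        """Per-pattern log-likelihood (natural log)."""
        partial, scale_log, _ = self.partials(patterns, P)
        root = self.root_id
        lik = pi @ partial[root]
        # floor avoids -inf when an optimizer probes a zero-length branch
        # against an incompatible pattern
        return np.log(np.maximum(lik, 1e-300)) + scale_log[root]

    def log_likelihood(
        self, patterns: PatternSet, P: dict[int, np.ndarray], pi: np.ndarray
    ) -> float:
        return float(self.site_log_likelihood(patterns, P, pi) @ patterns.weights)

    def site_log_likelihood_batch(
        self, patterns: PatternSet, P: dict[int, np.ndarray], pi: np.ndarray
    ) -> np.ndarray:
        """Batched pruning: ``P[node]`` is (B, k, k) — one transition matrix
        per mixture class — and the result is (B, n_patterns) log-likelihoods.
        One batched matmul per edge replaces B separate passes."""
        k, m = self.n_states, patterns.n_patterns
        B = next(iter(P.values())).shape[0]
        leaf_partials = self._leaf_partials(patterns)
        partial: dict[int, np.ndarray] = {}
        scale_log: dict[int, np.ndarray] = {}
        for v in self.postorder_ids:
            kids = self.children[v]
            if not kids:
                partial[v] = np.broadcast_to(leaf_partials[v], (B, k, m))
                scale_log[v] = np.zeros((B, m))
            else:
                arr = None
                sc = np.zeros((B, m))
                for c in kids:
                    msg = P[c] @ partial[c]
                    arr = msg if arr is None else arr * msg
                    sc = sc + scale_log[c]
                mx = arr.max(axis=1)
                mx[mx == 0.0] = 1.0
                arr = arr / mx[:, None, :]
                partial[v] = arr
                scale_log[v] = sc + np.log(mx)
        lik = np.einsum("s,bsm->bm", pi, partial[self.root_id])
        return np.log(np.maximum(lik, 1e-300)) + scale_log[self.root_id]

    # -- up pass ----------------------------------------------------------

    def marginal_posteriors(
        self, patterns: PatternSet, P: dict[int, np.ndarray], pi: np.ndarray
    ) -> dict[int, np.ndarray]:
        """Marginal posterior state distributions at every internal node.

        Returns node_id -> (n_patterns, n_states) posterior matrices
        (rows sum to 1).
        """
        partial, scale_log, down = self.partials(patterns, P)
        m = patterns.n_patterns
        up: dict[int, np.ndarray] = {self.root_id: np.tile(pi[:, None], (1, m))}
        posteriors: dict[int, np.ndarray] = {}
        # preorder = reversed postorder
        for v in reversed(self.postorder_ids):
            kids = self.children[v]
            if not kids:
                continue
            joint = up[v] * partial[v]
            total = joint.sum(axis=0)
            posteriors[v] = (joint / total[None, :]).T
            for c in kids:
                msg = up[v].copy()
                for s in kids:
                    if s != c:
                        msg = msg * down[s]
                u = P[c].T @ msg
                mx = u.max(axis=0)
                mx[mx == 0.0] = 1.0
                up[c] = u / mx[None, :]
        return posteriors

    def marginal_consistency_gap(
        self, patterns: PatternSet, P: dict[int, np.ndarray], pi: np.ndarray
    ) -> float:
        """Max |site loglik reassembled at a node - pruned site loglik|.

        Diagnostic for the up/down passes: at every internal node,
        sum_states up*partial (rescaled) must equal the site likelihood.
        """
        partial, scale_log, down = self.partials(patterns, P)
        m = patterns.n_patterns
        site_ll = np.log(pi @ partial[self.root_id]) + scale_log[self.root_id]
        up: dict[int, np.ndarray] = {self.root_id: np.tile(pi[:, None], (1, m))}
        up_scale: dict[int, np.ndarray] = {self.root_id: np.zeros(m)}
        worst = 0.0
        for v in reversed(self.postorder_ids):
            kids = self.children[v]
            if not kids:
                continue
            reassembled = np.log((up[v] * partial[v]).sum(axis=0)) + up_scale[v] + scale_log[v]
            worst = max(worst, float(np.max(np.abs(reassembled - site_ll))))
            for c in kids:
                msg = up[v].copy()
                extra = np.zeros(m)
                for s in kids:
                    if s != c:
                        msg = msg * down[s]
                        extra = extra + scale_log[s]
                u = P[c].T @ msg
                mx = u.max(axis=0)
                mx[mx == 0.0] = 1.0
                up[c] = u / mx[None, :]
                up_scale[c] = up_scale[v] + extra + np.log(mx)
        return worst


def encode_protein(sequences: list[str], alphabet: str) -> np.ndarray:
    """Encode rows of residues to int states; anything outside the alphabet
    (gap, ambiguity) becomes -1."""
    lookup = np.full(128, -1, dtype=np.int64)
    for i, ch in enumerate(alphabet):
        lookup[ord(ch)] = i
    mat = np.frombuffer("".join(sequences).encode(), dtype=np.uint8)
    return lookup[mat].reshape(len(sequences), -1)
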