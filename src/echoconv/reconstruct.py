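"""Marginal empirical-Bayes ancestral reconstruction of amino-acid states.

Workflow per gene: fix the tree topology, estimate branch lengths by
maximum likelihood under the replacement model, then compute for every
internal node and site the marginal posterior over the 20 states with the
model parameters held at their estimates. Ties in the argmax state are
broken by fixed alphabetical order and flagged, never hidden.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from echoconv.aamodel import AAModel, observed_frequencies
from echoconv.align import ProteinAlignment
from echoconv.codons import AMINO_ACIDS, GAP_AA, AMBIG_AA
from echoconv.likelihood import (
    PatternSet,
    PruningEngine,
    TransitionCalculator,
    compress_columns,
    encode_protein,
)
from echoconv.phylo import PhyloTree

MAX_BRANCH_LENGTH = 20.0


def default_model(aln: ProteinAlignment) -> AAModel:
    """Poisson exchangeabilities with observed residue frequencies."""
    return AAModel(name="POISSON", frequencies=observed_frequencies(list(aln.sequences)))


def _prepare(aln: ProteinAlignment, tree: PhyloTree):
    missing = [t for t in tree.leaf_labels if t not in aln.taxa]
    if missing:
        raise ValueError(f"alignment {aln.gene_id} lacks tree taxa: {missing}")
    encoded = encode_protein(list(aln.sequences), AMINO_ACIDS)
    patterns = compress_columns(encoded)
    engine = PruningEngine(tree, n_states=20, taxa=list(aln.taxa))
    return engine, patterns


def _edge_nodes(tree: PhyloTree):
    return [n for n in tree.nodes if n.parent is not None]


def _transition_sets(tree: PhyloTree, model: AAModel):
    """Per rate category, node_id -> P(rate * length)."""
    Q = model.generator()
    pi = model.frequencies
    calc = TransitionCalculator(Q, pi)
    rates, weights = model.rate_categories()
    out = []
    for r in rates:
        out.append({n.node_id: calc.matrix(r * (n.length or 0.0)) for n in _edge_nodes(tree)})
    return out, weights, pi


def compute_log_likelihood(aln: ProteinAlignment, tree: PhyloTree, model: AAModel) -> float:
    """Pruning log-likelihood (nats); gaps/ambiguities are uninformative."""
    engine, patterns = _prepare(aln, tree)
    return _log_likelihood(engine, patterns, tree, model)


def _log_likelihood(engine: PruningEngine, patterns: PatternSet,
                    tree: PhyloTree, model: AAModel) -> float:
    P_sets, weights, pi = _transition_sets(tree, model)
    if len(P_sets) == 1:
        return engine.log_likelihood(patterns, P_sets[0], pi)
    site_ll = np.stack([engine.site_log_likelihood(patterns, P, pi) for P in P_sets])
    mixed = logsumexp(site_ll, axis=0, b=weights[:, None])
    return float(mixed @ patterns.weights)


@dataclass(frozen=True)
class BranchLengthFit:
    tree: PhyloTree
    log_likelihood: float
    converged: bool
    n_restarts: int


def fit_branch_lengths(
    aln: ProteinAlignment,
    tree: PhyloTree,
    model: AAModel,
    max_restarts: int = 3,
    tol: float = 1e-8,
) -> BranchLengthFit:
    """ML branch lengths on the fixed topology (bounded L-BFGS-B).

    The returned likelihood never falls below the starting likelihood; a fit
    that fails to converge within the restart budget is flagged, not hidden.
    """
    engine, patterns = _prepare(aln, tree)
    work = tree.copy()
    edges = _edge_nodes(work)
    Q = model.generator()
    pi = model.frequencies
    calc = TransitionCalculator(Q, pi)
    rates, weights = model.rate_categories()

    def neg_ll(lengths: np.ndarray) -> float:
        if len(rates) == 1:
            P = {n.node_id: calc.matrix(rates[0] * t) for n, t in zip(edges, lengths)}
            return -engine.log_likelihood(patterns, P, pi)
        site_ll = []
        for r in rates:
            P = {n.node_id: calc.matrix(r * t) for n, t in zip(edges, lengths)}
            site_ll.append(engine.site_log_likelihood(patterns, P, pi))
        mixed = logsumexp(np.stack(site_ll), axis=0, b=weights[:, None])
        return -float(mixed @ patterns.weights)

    x0 = np.array([n.length if n.length is not None else 0.1 for n in edges])
    x0 = np.clip(x0, 1e-6, MAX_BRANCH_LENGTH)
    start_ll = -neg_ll(x0)
    best_x, best_ll, converged, attempt = x0, start_ll, False, 0
    rng = np.random.default_rng(0)
    x_init = x0
    while attempt <= max_restarts:
        res = minimize(
            neg_ll, x_init, method="L-BFGS-B",
            bounds=[(0.0, MAX_BRANCH_LENGTH)] * len(edges),
            options={"ftol": tol, "maxiter": 500},
        )
        if -res.fun > best_ll:
            best_ll, best_x = -res.fun, res.x
        if res.success and -res.fun >= start_ll - 1e-9:
            converged = True
            break
        attempt += 1
        x_init = np.clip(best_x * rng.uniform(0.5, 2.0, size=len(edges)), 1e-6, 5.0)

    for node, t in zip(edges, best_x):
        node.length = float(t)
    return BranchLengthFit(tree=work, log_likelihood=float(best_ll),
                           converged=converged, n_restarts=attempt)


@dataclass(frozen=True)
class AncestralReconstruction:
    """Posterior state distributions at every internal node and site.

    posterior: (n_internal, n_sites, 20), rows summing to 1;
    argmax_state / argmax_posterior: the maximum-posterior call per
    node x site; tie_flag marks argmax ties (broken alphabetically);
    missing_flag marks node x site cells whose entire subtree is gap/ambiguous.
    Leaf states are exposed from the alignment for downstream comparisons.
    """

    gene_id: str
    tree: PhyloTree
    alignment: ProteinAlignment
    internal_ids: tuple[int, ...]
    posterior: np.ndarray
    argmax_state: np.ndarray        # (n_internal, n_sites) int state indices
    argmax_posterior: np.ndarray
    tie_flag: np.ndarray
    missing_flag: np.ndarray

    @property
    def n_sites(self) -> int:
        return self.alignment.n_sites

    def _row(self, node_id: int) -> int:
        return self.internal_ids.index(node_id)

    def posterior_at(self, node_id: int, site: int) -> np.ndarray:
        return self.posterior[self._row(node_id), site - 1]

    def state_at(self, node_id: int, site: int) -> str | None:
        """Maximum-posterior residue at an internal node (1-based site);
        None where the node's subtree carries no data at the site."""
        r = self._row(node_id)
        if self.missing_flag[r, site - 1]:
            return None
        return AMINO_ACIDS[self.argmax_state[r, site - 1]]

    def leaf_state(self, taxon: str, site: int) -> str | None:
        ch = self.alignment.row(taxon)[site - 1]
        return None if ch in (GAP_AA, AMBIG_AA) else ch


def reconstruct_marginal(
    aln: ProteinAlignment, tree: PhyloTree, model: AAModel | None = None
) -> AncestralReconstruction:
    """Marginal posteriors P(state | leaf data) at each internal node/site,
    model parameters fixed (empirical Bayes)."""
    if model is None:
        model = default_model(aln)
    engine, patterns = _prepare(aln, tree)
    P_sets, weights, pi = _transition_sets(tree, model)

    if len(P_sets) == 1:
        node_post = engine.marginal_posteriors(patterns, P_sets[0], pi)
    else:
        # mix category posteriors by the per-site category responsibility
        site_ll = np.stack([engine.site_log_likelihood(patterns, P, pi) for P in P_sets])
        log_resp = np.log(weights)[:, None] + site_ll
        log_resp -= logsumexp(log_resp, axis=0, keepdims=True)
        resp = np.exp(log_resp)  # (k, n_patterns)
        per_cat = [engine.marginal_posteriors(patterns, P, pi) for P in P_sets]
        node_post = {}
        for v in per_cat[0]:
            node_post[v] = sum(
                resp[c][:, None] * per_cat[c][v] for c in range(len(P_sets))
            )

    internal_ids = tuple(sorted(node_post))
    expand = patterns.site_to_pattern
    n_sites = aln.n_sites
    post = np.stack([node_post[v][expand] for v in internal_ids])  # (I, sites, 20)

    argmax = post.argmax(axis=2)
    amax_p = np.take_along_axis(post, argmax[..., None], axis=2)[..., 0]
    near = np.isclose(post, amax_p[..., None], rtol=0.0, atol=1e-12)
    ties = near.sum(axis=2) > 1
    # alphabetical tie-break: first index attaining the max
    argmax = near.argmax(axis=2)

    encoded = encode_protein(list(aln.sequences), AMINO_ACIDS)
    leaf_missing = encoded < 0  # (n_taxa, n_sites)
    row_of = {t: i for i, t in enumerate(aln.taxa)}
    missing = np.zeros((len(internal_ids), n_sites), dtype=bool)
    for i, v in enumerate(internal_ids):
        node = tree.node(v)
        rows = [row_of[leaf.label] for leaf in node.postorder() if leaf.is_leaf]
        missing[i] = leaf_missing[rows].all(axis=0)

    return AncestralReconstruction(
        gene_id=aln.gene_id,
        tree=tree,
        alignment=aln,
        internal_ids=internal_ids,
        posterior=post,
        argmax_state=argmax,
        argmax_posterior=amax_p,
        tie_flag=ties,
        missing_flag=missing,
    )


def reconstruction_rows(recon: AncestralReconstruction) -> list[dict]:
    """TSV-ready rows: gene, node id, site, argmax state, posterior."""
    rows = []
    for i, v in enumerate(recon.internal_ids):
        for s in range(recon.n_sites):
            if recon.missing_flag[i, s]:
                continue
            rows.append({
                "gene": recon.gene_id,
                "node": v,
                "site": s + 1,
                "state": AMINO_ACIDS[recon.argmax_state[i, s]],
                "posterior": round(float(recon.argmax_posterior[i, s]), 6),
                "tie": int(recon.tie_flag[i, s]),
            })
    return rows
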