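"""Parallel/convergent amino-acid substitution detection between lineage pairs.

A site is called between two tested branches when (1) the extant residues at
the two tested nodes are identical, and (2) each differs from the residue at
its own most recent ancestor. The call is *parallel* when the two ancestral
residues are equal and *convergent* when they differ. The excess test asks
whether the number of such coincidences exceeds what independent fixation of
the observed substitutions would produce by chance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from echoconv.aamodel import AAModel
from echoconv.codons import AMINO_ACIDS
from echoconv.reconstruct import AncestralReconstruction


@dataclass(frozen=True)
class Substitution:
    site: int          # 1-based, coordinates of the reconstruction's alignment
    parent_state: str
    child_state: str


@dataclass(frozen=True)
class ConvergenceCall:
    gene_id: str
    site: int
    branch_pair: tuple[str, str]   # child-node identifiers of the two branches
    derived: str
    parent_a: str
    parent_b: str
    type: str                      # "parallel" | "convergent"


@dataclass(frozen=True)
class ConvergenceTestResult:
    gene_id: str
    branch_pair: tuple[str, str]
    observed_parallel: int
    observed_convergent: int
    expected_parallel: float
    expected_convergent: float
    p_parallel: float
    p_convergent: float


def classify_site(parent_a: str, parent_b: str, extant_a: str, extant_b: str) -> str | None:
    """Apply the three call criteria to one site; returns the call type or None."""
    if extant_a != extant_b:
        return None
    if extant_a == parent_a or extant_b == parent_b:
        return None
    return "parallel" if parent_a == parent_b else "convergent"


def _branch_nodes(recon: AncestralReconstruction, branch: str | int):
    child = recon.tree.node(branch)
    if child.parent is None:
        raise ValueError(f"branch {branch!r} has no parent edge (root)")
    return child, child.parent


def call_substitutions(
    recon: AncestralReconstruction,
    branch: str | int,
    min_ancestral_posterior: float = 0.0,
) -> list[Substitution]:
    """All sites where the branch's parent (argmax) state differs from the
    child state. Sites with missing data, argmax ties, or ancestral posterior
    below the cut-off are skipped, never guessed."""
    child, parent = _branch_nodes(recon, branch)
    row = recon.internal_ids.index(parent.node_id)
    out: list[Substitution] = []
    for site in range(1, recon.n_sites + 1):
        if recon.missing_flag[row, site - 1] or recon.tie_flag[row, site - 1]:
            continue
        if recon.argmax_posterior[row, site - 1] < min_ancestral_posterior:
            continue
        parent_state = AMINO_ACIDS[recon.argmax_state[row, site - 1]]
        if child.is_leaf:
            child_state = recon.leaf_state(child.label, site)
        else:
            child_state = recon.state_at(child.node_id, site)
        if child_state is None:
            continue
        if child_state != parent_state:
            out.append(Substitution(site=site, parent_state=parent_state, child_state=child_state))
    return out


def _check_paraphyletic(recon: AncestralReconstruction, branch_a, branch_b):
    a = recon.tree.node(branch_a)
    b = recon.tree.node(branch_b)
    if recon.tree.is_ancestor(a, b) or recon.tree.is_ancestor(b, a):
        raise ValueError(f"branch pair ({branch_a!r}, {branch_b!r}) not paraphyletic")


def classify_pair(
    recon: AncestralReconstruction,
    branch_a: str | int,
    branch_b: str | int,
    min_ancestral_posterior: float = 0.0,
) -> list[ConvergenceCall]:
    """Parallel/convergent calls between two paraphyletic branches."""
    _check_paraphyletic(recon, branch_a, branch_b)
    subs_a = {s.site: s for s in call_substitutions(recon, branch_a, min_ancestral_posterior)}
    subs_b = {s.site: s for s in call_substitutions(recon, branch_b, min_ancestral_posterior)}
    calls: list[ConvergenceCall] = []
    for site in sorted(set(subs_a) & set(subs_b)):
        sa, sb = subs_a[site], subs_b[site]
        kind = classify_site(sa.parent_state, sb.parent_state, sa.child_state, sb.child_state)
        if kind is None:
            continue
        calls.append(ConvergenceCall(
            gene_id=recon.gene_id, site=site,
            branch_pair=(str(branch_a), str(branch_b)),
            derived=sa.child_state,
            parent_a=sa.parent_state, parent_b=sb.parent_state, type=kind,
        ))
    return calls


def replacement_distribution(model: AAModel, parent: str) -> np.ndarray:
    """P(derived = x | a replacement happened from ``parent``) under the
    model: proportional to the rate parent->x, zero at the parent itself."""
    Q = model.generator()
    i = AMINO_ACIDS.index(parent)
    row = Q[i].copy()
    row[i] = 0.0
    total = row.sum()
    if total <= 0:
        raise ValueError(f"no replacements possible from state {parent!r}")
    return row / total


def convergence_excess_test(
    recon: AncestralReconstruction,
    branch_a: str | int,
    branch_b: str | int,
    model: AAModel,
    min_ancestral_posterior: float = 0.0,
) -> ConvergenceTestResult:
    """Test observed parallel/convergent counts against the neutral null.

    Null: ancestral states are fixed at their reconstructed values and each
    observed substitution redraws its derived state from the model's
    replacement distribution, independently across branches. Per-site match
    probabilities are summed into expected counts; one-sided P-values come
    from the Poisson upper tail of the expected count at the observed count.
    Zero substitutions on a branch yield the degenerate (expected 0, P = 1).
    """
    _check_paraphyletic(recon, branch_a, branch_b)
    subs_a = {s.site: s for s in call_substitutions(recon, branch_a, min_ancestral_posterior)}
    subs_b = {s.site: s for s in call_substitutions(recon, branch_b, min_ancestral_posterior)}
    calls = classify_pair(recon, branch_a, branch_b, min_ancestral_posterior)
    obs_par = sum(1 for c in calls if c.type == "parallel")
    obs_con = sum(1 for c in calls if c.type == "convergent")

    exp_par = exp_con = 0.0
    for site in set(subs_a) & set(subs_b):
        pa, pb = subs_a[site].parent_state, subs_b[site].parent_state
        da = replacement_distribution(model, pa)
        db = replacement_distribution(model, pb)
        match = float(da @ db)
        if pa == pb:
            exp_par += match
        else:
            exp_con += match

    def poisson_tail(observed: int, mean: float) -> float:
        if observed == 0:
            return 1.0
        if mean == 0.0:
            return 0.0
        return float(stats.poisson.sf(observed - 1, mean))

    return ConvergenceTestResult(
        gene_id=recon.gene_id,
        branch_pair=(str(branch_a), str(branch_b)),
        observed_parallel=obs_par, observed_convergent=obs_con,
        expected_parallel=exp_par, expected_convergent=exp_con,
        p_parallel=poisson_tail(obs_par, exp_par),
        p_convergent=poisson_tail(obs_con, exp_con),
    )


@dataclass(frozen=True)
class PairSummary:
    pair: tuple[str, str]
    parallel_genes: int
    parallel_sites: int
    convergent_genes: int
    convergent_sites: int


def summarize_pairs(
    calls: Mapping[tuple[str, str], Mapping[str, Sequence[ConvergenceCall]]],
    design: Sequence[tuple[str, str]],
) -> tuple[list[PairSummary], set[str]]:
    """Per-pair gene/site counts plus the core parallel gene set.

    ``calls`` maps each comparison pair to {gene -> its calls}. A gene counts
    once per pair however many sites it carries; site counts sum call sites.
    The core set holds genes with at least one parallel call in *every*
    designed comparison (jointly covering all four echolocating lineages).
    """
    missing = [p for p in design if p not in calls]
    if missing:
        raise ValueError(f"design comparisons missing from calls: {missing}")

    summaries: list[PairSummary] = []
    parallel_genes_by_pair: list[set[str]] = []
    for pair in design:
        by_gene = calls[pair]
        par_genes = {g for g, cs in by_gene.items() if any(c.type == "parallel" for c in cs)}
        con_genes = {g for g, cs in by_gene.items() if any(c.type == "convergent" for c in cs)}
        summaries.append(PairSummary(
            pair=pair,
            parallel_genes=len(par_genes),
            parallel_sites=sum(1 for cs in by_gene.values() for c in cs if c.type == "parallel"),
            convergent_genes=len(con_genes),
            convergent_sites=sum(1 for cs in by_gene.values() for c in cs if c.type == "convergent"),
        ))
        parallel_genes_by_pair.append(par_genes)

    core = set.intersection(*parallel_genes_by_pair) if parallel_genes_by_pair else set()
    return summaries, core


def calls_rows(calls: Sequence[ConvergenceCall]) -> list[dict]:
    """TSV-ready rows (gene, site, pair, type, residues)."""
    return [
        {
            "gene": c.gene_id, "site": c.site,
            "pair": f"{c.branch_pair[0]}|{c.branch_pair[1]}",
            "type": c.type, "derived": c.derived,
            "parent_a": c.parent_a, "parent_b": c.parent_b,
        }
        for c in calls
    ]
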