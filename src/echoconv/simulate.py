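"""Synthetic ortholog alignments with known ground truth.

Sequences are evolved by exact stochastic (Gillespie) simulation per branch
and site, so the full substitution history — every (time, from, to) event on
every branch — is available as a test oracle. Codon simulation follows the
branch-site mixture: each site draws one of four classes (0, 1, 2a, 2b) and
foreground-tagged branches use the selection omega for classes 2a/2b.

Defaults (p0=0.45, p1=0.45, omega0=0.1, kappa=2, uniform codon frequencies)
are configuration values chosen for testability, not estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from echoconv.aamodel import AAModel
from echoconv.align import CodonAlignment, ProteinAlignment
from echoconv.codons import AMINO_ACIDS, CODON_SYNONYMOUS, N_AA, N_CODONS, SENSE_CODONS
from echoconv.codonmodel import GY94Params, build_gy94_neutral_scaled, uniform_codon_frequencies
from echoconv.phylo import FOREGROUND, Node, PhyloTree, parse_newick
from echoconv.study import STUDY_TOPOLOGY

CLASS_NAMES = ("0", "1", "2a", "2b")


@dataclass(frozen=True)
class SiteClassParams:
    """Branch-site mixture parameters.

    Site-class proportions are (p0, p1, p2a, p2b) with the positive-selection
    classes 2a/2b sharing 1 - p0 - p1 in ratio p0:p1. omega0 is the purifying
    ratio (background classes 0/2a), omega2 the foreground ratio of classes
    2a/2b; class 1 is neutral (omega = 1).
    """

    p0: float = 0.45
    p1: float = 0.45
    omega0: float = 0.1
    omega2: float = 1.0
    kappa: float = 2.0
    pi: np.ndarray = field(default_factory=uniform_codon_frequencies)

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=float)
        object.__setattr__(self, "pi", pi)
        if not (0.0 <= self.p0 <= 1.0 and 0.0 <= self.p1 <= 1.0 and self.p0 + self.p1 <= 1.0):
            raise ValueError("require p0, p1 in [0,1] with p0 + p1 <= 1")
        if self.p0 + self.p1 == 0.0:
            raise ValueError("p0 + p1 must be positive (classes 2a/2b split in ratio p0:p1)")
        if not (0.0 < self.omega0 < 1.0):
            raise ValueError("omega0 must lie in (0, 1)")
        if self.omega2 < 1.0:
            raise ValueError("omega2 must be >= 1")
        if self.kappa <= 0.0:
            raise ValueError("kappa must be positive")
        if pi.shape != (N_CODONS,) or not np.isclose(pi.sum(), 1.0, atol=1e-8):
            raise ValueError("pi must be a 61-vector summing to 1")

    def class_weights(self) -> np.ndarray:
        rest = 1.0 - self.p0 - self.p1
        share = self.p0 + self.p1
        return np.array([
            self.p0, self.p1, rest * self.p0 / share, rest * self.p1 / share,
        ])


@dataclass
class SubstitutionHistory:
    """Ground-truth record of a simulation.

    node_states[node_id] is the (n_sites,) state vector at that node;
    events[node_id][site] lists (time, from_state, to_state) on the branch
    above node_id at the 1-based site, in time order; site_class holds the
    drawn mixture class per site for codon simulations (else None).
    """

    n_sites: int
    n_states: int
    node_states: dict[int, np.ndarray]
    events: dict[int, dict[int, list[tuple[float, int, int]]]]
    site_class: np.ndarray | None = None

    def branch_events(self, node_id: int) -> dict[int, list[tuple[float, int, int]]]:
        return self.events.get(node_id, {})

    def replay_is_consistent(self, tree: PhyloTree) -> bool:
        """Replaying every event chain from the parent state must land on the
        recorded child state, and chains must be link-consistent."""
        for node in tree.nodes:
            if node.parent is None:
                continue
            parent_states = self.node_states[node.parent.node_id]
            child_states = self.node_states[node.node_id]
            site_events = self.events.get(node.node_id, {})
            for site in range(1, self.n_sites + 1):
                state = parent_states[site - 1]
                for _, frm, to in site_events.get(site, ()):
                    if frm != state:
                        return False
                    state = to
                if state != child_states[site - 1]:
                    return False
        return True

    def substitutions_on(self, node_id: int) -> dict[int, tuple[int, int]]:
        """Net parent->child changes per site on one branch (1-based sites)."""
        return {
            site: (chain[0][1], chain[-1][2])
            for site, chain in self.events.get(node_id, {}).items()
            if chain and chain[0][1] != chain[-1][2]
        }


def _jump_tables(Q: np.ndarray):
    rates = -np.diag(Q).copy()
    jump = Q.copy()
    np.fill_diagonal(jump, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        jump = jump / rates[:, None]
    jump[rates <= 0] = 0.0
    return rates, np.cumsum(jump, axis=1)


def _evolve(state: int, length: float, rates: np.ndarray, jump_cum: np.ndarray,
            rng: np.random.Generator, out_events: list) -> int:
    t = 0.0
    while True:
        r = rates[state]
        if r <= 0.0:
            return state
        t += rng.exponential(1.0 / r)
        if t >= length:
            return state
        new = int(np.searchsorted(jump_cum[state], rng.random() * jump_cum[state, -1]))
        out_events.append((t, state, new))
        state = new


def make_study_fixture(seed: int) -> PhyloTree:
    """The 19-taxon study tree with reproducible, plausible branch lengths.

    Topology is fixed (see :mod:`echoconv.study`); lengths are drawn from the
    seed — terminal branches uniform(0.04, 0.10), internal uniform(0.01, 0.05)
    — giving a tree height of roughly 0.15-0.3 replacements per site.
    """
    tree = parse_newick(STUDY_TOPOLOGY)
    rng = np.random.default_rng([int(seed) % (2 ** 31), 19])
    # draw in post-order so the shape is stable across calls
    for node in tree.nodes:
        if node.parent is None:
            node.length = None
        elif node.is_leaf:
            node.length = float(rng.uniform(0.04, 0.10))
        else:
            node.length = float(rng.uniform(0.01, 0.05))
    return tree


def _simulate_markov(
    tree: PhyloTree,
    n_sites: int,
    n_states: int,
    root_pi: np.ndarray,
    tables_for_branch_site,  # (node, site) -> (rates, jump_cum)
    rng: np.random.Generator,
    site_class: np.ndarray | None,
) -> SubstitutionHistory:
    root_states = rng.choice(n_states, size=n_sites, p=root_pi)
    node_states = {tree.root.node_id: root_states}
    events: dict[int, dict[int, list]] = {}

    def descend(node: Node):
        for child in node.children:
            parent_states = node_states[node.node_id]
            child_states = parent_states.copy()
            branch_events: dict[int, list] = {}
            length = child.length or 0.0
            if length > 0.0:
                for site in range(n_sites):
                    rates, jump_cum = tables_for_branch_site(child, site)
                    chain: list = []
                    child_states[site] = _evolve(
                        int(parent_states[site]), length, rates, jump_cum, rng, chain
                    )
                    if chain:
                        branch_events[site + 1] = chain
            node_states[child.node_id] = child_states
            events[child.node_id] = branch_events
            descend(child)

    descend(tree.root)
    return SubstitutionHistory(
        n_sites=n_sites, n_states=n_states,
        node_states=node_states, events=events, site_class=site_class,
    )


def simulate_codon_alignment(
    tree: PhyloTree,
    params: SiteClassParams,
    n_sites: int,
    seed: int,
    gene_id: str = "sim",
) -> tuple[CodonAlignment, SubstitutionHistory]:
    """Evolve a codon alignment under the branch-site mixture process.

    Foreground-tagged branches use omega2 for classes 2a/2b; background
    branches use omega0 (class 2a) or 1 (class 2b).
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng([int(seed) % (2 ** 31), 61])
    site_class = rng.choice(4, size=n_sites, p=params.class_weights())

    # all classes share the neutral-rate normalisation (see selection module):
    # branch lengths are neutral-equivalent substitutions per codon site
    tables = {
        omega: _jump_tables(
            build_gy94_neutral_scaled(GY94Params(kappa=params.kappa, omega=omega, pi=params.pi))
        )
        for omega in {params.omega0, 1.0, params.omega2}
    }
    fg = {n.node_id for n in tree.nodes if FOREGROUND in n.tags}
    # omega by (class, is_foreground)
    omega_of = {
        (0, False): params.omega0, (0, True): params.omega0,
        (1, False): 1.0, (1, True): 1.0,
        (2, False): params.omega0, (2, True): params.omega2,
        (3, False): 1.0, (3, True): params.omega2,
    }

    def branch_site_tables(child: Node, site: int):
        return tables[omega_of[(int(site_class[site]), child.node_id in fg)]]

    history = _simulate_markov(
        tree, n_sites, N_CODONS, params.pi, branch_site_tables, rng, site_class
    )
    sequences = tuple(
        "".join(SENSE_CODONS[s] for s in history.node_states[leaf.node_id])
        for leaf in tree.leaves
    )
    aln = CodonAlignment(gene_id=gene_id, taxa=tuple(tree.leaf_labels), sequences=sequences)
    return aln, history


def simulate_protein_alignment(
    tree: PhyloTree,
    model: AAModel,
    n_sites: int,
    seed: int,
    gene_id: str = "sim",
) -> tuple[ProteinAlignment, SubstitutionHistory]:
    """Evolve an amino-acid alignment under the replacement model, with
    optional discrete-gamma rate variation drawn per site."""
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng([int(seed) % (2 ** 31), 20])
    Q = model.generator()
    rates_cat, weights = model.rate_categories()
    site_rate_idx = rng.choice(len(rates_cat), size=n_sites, p=weights)
    tables = [_jump_tables(Q * r) for r in rates_cat]

    def branch_site_tables(child: Node, site: int):
        return tables[site_rate_idx[site]]

    history = _simulate_markov(
        tree, n_sites, N_AA, model.frequencies, branch_site_tables, rng, None
    )
    sequences = tuple(
        "".join(AMINO_ACIDS[s] for s in history.node_states[leaf.node_id])
        for leaf in tree.leaves
    )
    aln = ProteinAlignment(gene_id=gene_id, taxa=tuple(tree.leaf_labels), sequences=sequences)
    return aln, history


def protein_view(history: SubstitutionHistory) -> SubstitutionHistory:
    """Project a codon-state history onto amino-acid states.

    Node states map through the genetic code; synonymous events vanish from
    the event chains (the projection of a consistent codon chain is a
    consistent amino-acid chain).
    """
    from echoconv.codons import CODON_AA_INDEX

    if history.n_states != N_CODONS:
        raise ValueError("protein_view expects a codon-state history")
    node_states = {k: CODON_AA_INDEX[v] for k, v in history.node_states.items()}
    events: dict[int, dict[int, list]] = {}
    for nid, per_site in history.events.items():
        mapped: dict[int, list] = {}
        for site, chain in per_site.items():
            aa_chain = [
                (t, int(CODON_AA_INDEX[f]), int(CODON_AA_INDEX[to]))
                for t, f, to in chain
                if CODON_AA_INDEX[f] != CODON_AA_INDEX[to]
            ]
            if aa_chain:
                mapped[site] = aa_chain
        events[nid] = mapped
    return SubstitutionHistory(
        n_sites=history.n_sites, n_states=N_AA,
        node_states=node_states, events=events, site_class=history.site_class,
    )


def count_codon_events(history: SubstitutionHistory) -> tuple[int, int]:
    """(nonsynonymous, synonymous) event totals over all branches/sites."""
    n = s = 0
    for branch in history.events.values():
        for chain in branch.values():
            for _, frm, to in chain:
                if CODON_SYNONYMOUS[frm, to]:
                    s += 1
                else:
                    n += 1
    return n, s


# -- convergence injection -------------------------------------------------

class InjectionError(ValueError):
    pass


def inject_convergence(
    aln: ProteinAlignment,
    history: SubstitutionHistory,
    tree: PhyloTree,
    branch_pair: tuple[str, str],
    n_parallel: int,
    n_convergent: int,
    seed: int,
    preferred_sites: list[int] | None = None,
) -> tuple[ProteinAlignment, SubstitutionHistory, list[tuple[int, str]]]:
    """Force parallel/convergent substitutions onto two paraphyletic branches.

    Eligible sites are those whose two parent (ancestor) states already agree
    (parallel) or differ (convergent) in the simulated history; the two
    branches are then rewritten to substitute to a common derived residue,
    and the edit is propagated to all descendant leaves so the history stays
    replay-consistent. ``preferred_sites`` (1-based) are drawn first when
    eligible. Returns the edited alignment/history plus the truth table
    [(site, "parallel"|"convergent"), ...].
    """
    rng = np.random.default_rng([int(seed) % (2 ** 31), 7])
    a, b = (tree.node(k) for k in branch_pair)
    if tree.is_ancestor(a, b) or tree.is_ancestor(b, a):
        raise InjectionError(f"branch pair {branch_pair} is not paraphyletic")

    node_states = {k: v.copy() for k, v in history.node_states.items()}
    events = {k: {s: list(ch) for s, ch in v.items()} for k, v in history.events.items()}
    pa = node_states[a.parent.node_id]
    pb = node_states[b.parent.node_id]

    preferred = {s - 1 for s in preferred_sites} if preferred_sites else set()

    def ordered(sites: list[int]) -> list[int]:
        return sorted(sites, key=lambda s: (s not in preferred, s))

    eligible_parallel = ordered([s for s in range(history.n_sites) if pa[s] == pb[s]])
    eligible_convergent = ordered([s for s in range(history.n_sites) if pa[s] != pb[s]])
    if len(eligible_parallel) < n_parallel:
        raise InjectionError(
            f"need {n_parallel} parallel-eligible sites, only {len(eligible_parallel)} available"
        )
    if len(eligible_convergent) < n_convergent:
        raise InjectionError(
            f"need {n_convergent} convergent-eligible sites, only {len(eligible_convergent)} available"
        )

    def choose(eligible: list[int], n: int) -> list[int]:
        if not n:
            return []
        front = [s for s in eligible if s in preferred]
        if len(front) >= n:
            return list(rng.choice(front, size=n, replace=False))
        rest = [s for s in eligible if s not in preferred]
        extra = list(rng.choice(rest, size=n - len(front), replace=False))
        return front + extra

    chosen_par = choose(eligible_parallel, n_parallel)
    chosen_con = choose(eligible_convergent, n_convergent)

    def overwrite_below(node: Node, site0: int, state: int) -> None:
        """Set the site's state at node and its whole subtree; clear events
        on branches strictly inside the subtree."""
        node_states[node.node_id][site0] = state
        for child in node.children:
            events.setdefault(child.node_id, {}).pop(site0 + 1, None)
            overwrite_below(child, site0, state)

    def force(branch_child: Node, site0: int, derived: int) -> None:
        parent_state = int(node_states[branch_child.parent.node_id][site0])
        t = 0.5 * (branch_child.length or 1.0)
        events.setdefault(branch_child.node_id, {})[site0 + 1] = [(t, parent_state, derived)]
        overwrite_below(branch_child, site0, derived)

    truth: list[tuple[int, str]] = []
    for site0 in chosen_par:
        parent_state = int(pa[site0])
        derived = int(rng.choice([x for x in range(history.n_states) if x != parent_state]))
        force(a, site0, derived)
        force(b, site0, derived)
        truth.append((site0 + 1, "parallel"))
    for site0 in chosen_con:
        banned = {int(pa[site0]), int(pb[site0])}
        derived = int(rng.choice([x for x in range(history.n_states) if x not in banned]))
        force(a, site0, derived)
        force(b, site0, derived)
        truth.append((site0 + 1, "convergent"))

    sequences = tuple(
        "".join(AMINO_ACIDS[s] for s in node_states[leaf.node_id])
        for leaf in tree.leaves
    )
    new_aln = ProteinAlignment(gene_id=aln.gene_id, taxa=tuple(tree.leaf_labels),
                               sequences=sequences)
    new_history = SubstitutionHistory(
        n_sites=history.n_sites, n_states=history.n_states,
        node_states=node_states, events=events, site_class=history.site_class,
    )
    return new_aln, new_history, sorted(truth)


def inject_gap_columns(aln: CodonAlignment, sites: list[int], taxon: str | None = None) -> CodonAlignment:
    """Replace the codon at the given 1-based sites with '---' (first taxon
    by default) — a trivial utility for exercising the column filter."""
    taxon = taxon or aln.taxa[0]
    rows = []
    for t, seq in zip(aln.taxa, aln.sequences):
        if t == taxon:
            chars = list(seq)
            for s in sites:
                chars[3 * (s - 1):3 * (s - 1) + 3] = "---"
            seq = "".join(chars)
        rows.append(seq)
    return CodonAlignment(gene_id=aln.gene_id, taxa=aln.taxa, sequences=tuple(rows))
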