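"""Pruning likelihoods, branch-length fitting and marginal reconstruction."""

import itertools

import numpy as np
import pytest

from echoconv.aamodel import AAModel, observed_frequencies
from echoconv.align import ProteinAlignment
from echoconv.codons import AMINO_ACIDS
from echoconv.likelihood import TransitionCalculator, compress_columns, encode_protein, PruningEngine
from echoconv.phylo import parse_newick
from echoconv.reconstruct import (
    compute_log_likelihood,
    fit_branch_lengths,
    reconstruct_marginal,
)
from echoconv.simulate import simulate_protein_alignment


def brute_force_loglik(aln, tree, model):
    """Exhaustive sum over all internal-node state assignments."""
    pi = model.frequencies
    calc = TransitionCalculator(model.generator(), pi)
    P = {n.node_id: calc.matrix(n.length) for n in tree.nodes if n.parent is not None}
    internals = [n for n in tree.nodes if not n.is_leaf]
    total = 0.0
    for site in range(1, aln.n_sites + 1):
        leaf_state = {n.node_id: AMINO_ACIDS.index(aln.row(n.label)[site - 1])
                      for n in tree.leaves}
        site_lik = 0.0
        for assignment in itertools.product(range(20), repeat=len(internals)):
            states = dict(leaf_state)
            states.update({n.node_id: s for n, s in zip(internals, assignment)})
            lik = pi[states[tree.root.node_id]]
            for n in tree.nodes:
                if n.parent is not None:
                    lik *= P[n.node_id][states[n.parent.node_id], states[n.node_id]]
            site_lik += lik
        total += np.log(site_lik)
    return total


class TestLikelihood:
    def test_matches_exhaustive_enumeration(self, quartet):
        aln = ProteinAlignment("g", ("A", "B", "C", "D"), ("AC", "AD", "SC", "TC"))
        model = AAModel()
        assert compute_log_likelihood(aln, quartet, model) == pytest.approx(
            brute_force_loglik(aln, quartet, model), abs=1e-8)

    def test_zero_length_limit_is_log_pi(self):
        tree = parse_newick("(A:0,B:0);")
        freqs = observed_frequencies(["ACDE"])
        model = AAModel(frequencies=freqs)
        aln = ProteinAlignment("g", ("A", "B"), ("ACDE", "ACDE"))
        expected = sum(np.log(freqs[AMINO_ACIDS.index(ch)]) for ch in "ACDE")
        assert compute_log_likelihood(aln, tree, model) == pytest.approx(expected, abs=1e-10)

    def test_rerooting_invariance(self):
        """Pulley principle: sliding the root along the central edge leaves
        the likelihood unchanged under a reversible model."""
        aln = ProteinAlignment("g", ("A", "B", "C", "D"), ("ACD", "ADD", "SCA", "TCA"))
        model = AAModel()
        values = [
            compute_log_likelihood(aln, parse_newick(text), model)
            for text in (
                "((A:0.1,B:0.2):0.05,(C:0.15,D:0.3):0.07);",
                "((A:0.1,B:0.2):0.12,(C:0.15,D:0.3):0.0);",
                "((A:0.1,B:0.2):0.0,(C:0.15,D:0.3):0.12);",
            )
        ]
        assert max(values) - min(values) < 1e-8

    def test_gaps_are_uninformative(self, quartet):
        model = AAModel()
        with_gap = ProteinAlignment("g", ("A", "B", "C", "D"), ("A-", "AD", "SC", "TC"))
        ll = compute_log_likelihood(with_gap, quartet, model)
        # site 2 with B's residue gapped must integrate B out
        assert np.isfinite(ll)
        full = ProteinAlignment("g", ("A", "B", "C", "D"), ("A", "A", "S", "T"))
        part = ProteinAlignment("g", ("A", "B", "C", "D"), ("A", "-", "S", "T"))
        marg = sum(
            np.exp(compute_log_likelihood(
                ProteinAlignment("g", ("A", "B", "C", "D"), ("A", aa, "S", "T")),
                quartet, model))
            for aa in AMINO_ACIDS
        )
        assert np.exp(compute_log_likelihood(part, quartet, model)) == pytest.approx(marg, rel=1e-10)

    def test_taxon_mismatch_error(self, quartet):
        aln = ProteinAlignment("g", ("A", "B", "C"), ("A", "A", "S"))
        with pytest.raises(ValueError, match="lacks tree taxa|lacks taxa"):
            compute_log_likelihood(aln, quartet, AAModel())

    def test_no_underflow_on_large_alignment(self, fixture_tree):
        aln, _ = simulate_protein_alignment(fixture_tree, AAModel(), 2000, seed=3)
        tall = fixture_tree.scaled(10.0)
        ll = compute_log_likelihood(aln, tall, AAModel())
        assert np.isfinite(ll)


class TestBranchLengths:
    def test_identical_sequences_collapse(self, quartet):
        aln = ProteinAlignment("g", ("A", "B", "C", "D"), ("ACDEFG",) * 4)
        fit = fit_branch_lengths(aln, quartet, AAModel())
        assert max(n.length for n in fit.tree.nodes if n.parent is not None) <= 1e-6

    def test_monotonicity_contract(self, subtree8):
        model = AAModel()
        for seed in (1, 2):
            aln, _ = simulate_protein_alignment(subtree8, model, 300, seed=seed)
            before = compute_log_likelihood(aln, subtree8, model)
            fit = fit_branch_lengths(aln, subtree8, model)
            assert fit.log_likelihood >= before - 1e-9
            assert fit.converged

    def test_length_recovery_simulation(self, subtree8):
        """ML lengths on long simulated genes land near the truth (mean
        relative error <= 10%); scaled down from 50 genes for runtime."""
        model = AAModel()
        rel_errors = []
        truth = np.array([n.length for n in subtree8.nodes if n.parent is not None])
        for seed in range(12):
            aln, _ = simulate_protein_alignment(subtree8, model, 2000, seed=40 + seed)
            fit = fit_branch_lengths(aln, subtree8, model)
            est = np.array([n.length for n in fit.tree.nodes if n.parent is not None])
            rel_errors.append(np.abs(est - truth) / truth)
        assert float(np.mean(rel_errors)) <= 0.10


class TestMarginalReconstruction:
    def test_constant_column_reconstructed_with_high_posterior(self, quartet):
        aln = ProteinAlignment("g", ("A", "B", "C", "D"), ("W", "W", "W", "W"))
        recon = reconstruct_marginal(aln, quartet, AAModel())
        for node_id in recon.internal_ids:
            assert recon.state_at(node_id, 1) == "W"
            assert recon.posterior_at(node_id, 1)[AMINO_ACIDS.index("W")] >= 0.99

    def test_three_leaf_brute_force_bayes(self):
        tree = parse_newick("(A:0.1,B:0.2,C:0.15);")
        aln = ProteinAlignment("g", ("A", "B", "C"), ("AK", "SK", "AR"))
        model = AAModel()
        recon = reconstruct_marginal(aln, tree, model)
        pi = model.frequencies
        calc = TransitionCalculator(model.generator(), pi)
        P = {lab: calc.matrix(tree.node(lab).length) for lab in "ABC"}
        for site in (1, 2):
            joint = np.array([
                pi[r] * np.prod([P[lab][r, AMINO_ACIDS.index(aln.row(lab)[site - 1])]
                                 for lab in "ABC"])
                for r in range(20)
            ])
            expected = joint / joint.sum()
            got = recon.posterior_at(tree.root.node_id, site)
            assert np.max(np.abs(got - expected)) < 1e-10

    def test_posteriors_normalised(self, fixture_tree):
        aln, _ = simulate_protein_alignment(fixture_tree, AAModel(), 100, seed=5)
        recon = reconstruct_marginal(aln, fixture_tree, AAModel())
        sums = recon.posterior.sum(axis=2)
        assert np.max(np.abs(sums - 1.0)) < 1e-9

    def test_marginal_consistency_with_site_likelihood(self, fixture_tree):
        """Reassembling up-messages x partials at any node reproduces the
        site likelihood (within 1e-8)."""
        aln, _ = simulate_protein_alignment(fixture_tree, AAModel(), 60, seed=6)
        model = AAModel()
        engine = PruningEngine(fixture_tree, 20, list(aln.taxa))
        patterns = compress_columns(encode_protein(list(aln.sequences), AMINO_ACIDS))
        calc = TransitionCalculator(model.generator(), model.frequencies)
        P = {n.node_id: calc.matrix(n.length) for n in fixture_tree.nodes if n.parent is not None}
        gap = engine.marginal_consistency_gap(patterns, P, model.frequencies)
        assert gap < 1e-8

    def test_accuracy_against_true_history(self, fixture_tree):
        """At tree height ~0.24, >= 95% of argmax states match the simulated
        ancestral truth (20 replicates x 1000 sites)."""
        assert fixture_tree.height <= 0.3
        model = AAModel()
        correct = total = 0
        for seed in range(20):
            aln, hist = simulate_protein_alignment(fixture_tree, model, 1000, seed=60 + seed)
            recon = reconstruct_marginal(aln, fixture_tree, model)
            for i, node_id in enumerate(recon.internal_ids):
                truth = hist.node_states[node_id]
                correct += int(np.sum(recon.argmax_state[i] == truth))
                total += len(truth)
        assert correct / total >= 0.95

    def test_accuracy_degrades_with_tree_height(self, fixture_tree):
        model = AAModel()
        accuracies = []
        base_height = fixture_tree.height
        for height in (0.1, 0.5, 1.5):
            tree = fixture_tree.scaled(height / base_height)
            acc = []
            for seed in range(10):
                aln, hist = simulate_protein_alignment(tree, model, 300, seed=80 + seed)
                recon = reconstruct_marginal(aln, tree, model)
                hits = sum(
                    int(np.sum(recon.argmax_state[i] == hist.node_states[node_id]))
                    for i, node_id in enumerate(recon.internal_ids)
                )
                acc.append(hits / (len(recon.internal_ids) * 300))
            accuracies.append(np.mean(acc))
        assert accuracies[0] >= accuracies[1] >= accuracies[2]

    def test_missing_subtree_flagged(self):
        tree = parse_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        aln = ProteinAlignment("g", ("A", "B", "C", "D"), ("-", "-", "K", "K"))
        recon = reconstruct_marginal(aln, tree, AAModel())
        ab = tree.mrca(["A", "B"]).node_id
        cd = tree.mrca(["C", "D"]).node_id
        assert recon.state_at(ab, 1) is None
        assert recon.state_at(cd, 1) == "K"

    def test_gamma_rates_supported(self, quartet):
        aln = ProteinAlignment("g", ("A", "B", "C", "D"), ("AKW", "SKW", "ARW", "ARW"))
        model = AAModel(gamma_shape=0.5)
        recon = reconstruct_marginal(aln, quartet, model)
        assert np.max(np.abs(recon.posterior.sum(axis=2) - 1.0)) < 1e-9
        rates, weights = model.rate_categories()
        assert rates.mean() == pytest.approx(1.0)
        assert len(rates) == 4
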