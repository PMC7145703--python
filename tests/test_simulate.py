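"""The Gillespie simulators and their ground-truth histories."""

import numpy as np
import pytest
from scipy import stats

from echoconv.aamodel import AAModel
from echoconv.codons import AMINO_ACIDS, CODON_SINGLE_STEP, CODON_SYNONYMOUS, CODON_TRANSITION
from echoconv.codonmodel import uniform_codon_frequencies
from echoconv.phylo import mark_foreground, parse_newick
from echoconv.simulate import (
    InjectionError,
    SiteClassParams,
    count_codon_events,
    inject_convergence,
    inject_gap_columns,
    simulate_codon_alignment,
    simulate_protein_alignment,
)


class TestSiteClassParams:
    def test_class_weights_sum_to_one(self):
        p = SiteClassParams(p0=0.5, p1=0.3)
        w = p.class_weights()
        assert w.sum() == pytest.approx(1.0)
        assert np.all(w >= 0)
        # 2a:2b split in ratio p0:p1
        assert w[2] / w[3] == pytest.approx(0.5 / 0.3)

    @pytest.mark.parametrize("kwargs", [
        {"p0": 0.7, "p1": 0.5}, {"omega0": 1.2}, {"omega2": 0.5},
        {"kappa": -1.0}, {"p0": 1.1},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SiteClassParams(**kwargs)


class TestCodonSimulator:
    def test_zero_lengths_give_constant_leaves(self):
        tree = parse_newick("((A:0,B:0):0,C:0);")
        aln, hist = simulate_codon_alignment(tree, SiteClassParams(), 30, seed=4)
        assert len(set(aln.sequences)) == 1
        assert all(not ev for ev in hist.events.values())

    def test_seed_determinism(self, subtree8):
        a1, h1 = simulate_codon_alignment(subtree8, SiteClassParams(), 40, seed=9)
        a2, h2 = simulate_codon_alignment(subtree8, SiteClassParams(), 40, seed=9)
        a3, _ = simulate_codon_alignment(subtree8, SiteClassParams(), 40, seed=10)
        assert a1.sequences == a2.sequences
        assert h1.node_states.keys() == h2.node_states.keys()
        assert a1.sequences != a3.sequences

    def test_history_replays_to_leaves(self, subtree8):
        for seed in (1, 2, 3):
            _, hist = simulate_codon_alignment(subtree8, SiteClassParams(), 60, seed=seed)
            assert hist.replay_is_consistent(subtree8)

    def test_class_proportions_recovered(self, subtree8):
        params = SiteClassParams(p0=0.45, p1=0.45)
        n = 5000
        _, hist = simulate_codon_alignment(subtree8, params, n, seed=8)
        frac0 = float(np.mean(hist.site_class == 0))
        se = np.sqrt(0.45 * 0.55 / n)
        assert abs(frac0 - 0.45) <= 3 * se

    def test_event_count_omega_oracle(self):
        """All-neutral simulation with kappa=1: normalised N/S event counts
        recover omega ~= 1 within 3 Monte-Carlo SE at ~50,000 events."""
        tree = parse_newick("(A:5,B:5);")
        params = SiteClassParams(p0=0.0, p1=1.0, kappa=1.0)  # class 1 only: omega=1
        _, hist = simulate_codon_alignment(tree, params, 5000, seed=3)
        n_events, s_events = count_codon_events(hist)
        assert n_events + s_events > 30000
        pi = uniform_codon_frequencies()
        # expected N:S rate proportions under the neutral generator
        rate = pi[:, None] * pi[None, :] * np.where(CODON_SINGLE_STEP, 1.0, 0.0)
        exp_n = float(rate[CODON_SINGLE_STEP & ~CODON_SYNONYMOUS].sum())
        exp_s = float(rate[CODON_SINGLE_STEP & CODON_SYNONYMOUS].sum())
        omega_hat = (n_events / s_events) / (exp_n / exp_s)
        se = omega_hat * np.sqrt(1 / n_events + 1 / s_events)
        assert abs(omega_hat - 1.0) <= 3 * se

    def test_foreground_branches_accumulate_nonsynonymous_excess(self, fixture_tree):
        tagged = mark_foreground(fixture_tree, "CF+FM+CLICK+TW")
        _, hist = simulate_codon_alignment(tagged, SiteClassParams(omega2=8.0), 400, seed=5)
        fg = {n.node_id for n in tagged.nodes if "FOREGROUND" in n.tags}
        n_fg = n_bg = s_fg = s_bg = 0
        for nid, per_site in hist.events.items():
            for site, chain in per_site.items():
                if hist.site_class[site - 1] < 2:
                    continue
                for _, f, t in chain:
                    if CODON_SYNONYMOUS[f, t]:
                        if nid in fg: s_fg += 1
                        else: s_bg += 1
                    else:
                        if nid in fg: n_fg += 1
                        else: n_bg += 1
        assert n_fg / max(s_fg, 1) > n_bg / max(s_bg, 1)


class TestProteinSimulator:
    def test_zero_lengths_constant_columns(self):
        tree = parse_newick("((A:0,B:0):0,C:0);")
        aln, _ = simulate_protein_alignment(tree, AAModel(), 50, seed=1)
        assert len(set(aln.sequences)) == 1

    def test_seed_determinism(self, fixture_tree):
        a1, _ = simulate_protein_alignment(fixture_tree, AAModel(), 30, seed=2)
        a2, _ = simulate_protein_alignment(fixture_tree, AAModel(), 30, seed=2)
        assert a1.sequences == a2.sequences

    def test_equilibrium_frequencies(self):
        """Empirical state frequencies over a long simulation match the
        model equilibrium within 3 multinomial SE."""
        tree = parse_newick("(A:0.5,B:0.5);")
        rng = np.random.default_rng(0)
        freqs = rng.dirichlet(np.full(20, 10.0))
        model = AAModel(frequencies=freqs)
        n = 100_000
        aln, _ = simulate_protein_alignment(tree, model, n, seed=6)
        counts = np.zeros(20)
        for ch in aln.sequences[0]:
            counts[AMINO_ACIDS.index(ch)] += 1
        emp = counts / n
        se = np.sqrt(freqs * (1 - freqs) / n)
        assert np.all(np.abs(emp - freqs) <= 3.5 * se + 1e-12)

    def test_stationarity_on_long_branch(self):
        """Simulating from equilibrium leaves frequencies at equilibrium:
        chi-square GOF not rejected at alpha=0.01 in >= 95% of 100 runs."""
        tree = parse_newick("(A:5,B:5);")
        model = AAModel()  # uniform equilibrium
        ok = 0
        for run in range(100):
            aln, _ = simulate_protein_alignment(tree, model, 200, seed=1000 + run)
            counts = np.zeros(20)
            for ch in aln.sequences[1]:
                counts[AMINO_ACIDS.index(ch)] += 1
            _, p = stats.chisquare(counts)
            ok += p > 0.01
        assert ok >= 95


class TestInjection:
    @pytest.fixture
    def protein_sim(self, fixture_tree):
        return simulate_protein_alignment(fixture_tree, AAModel(), 80, seed=12), fixture_tree

    def test_zero_injection_is_identity(self, protein_sim):
        (aln, hist), tree = protein_sim
        out, _, truth = inject_convergence(
            aln, hist, tree, ("Aselliscus_stoliczkanus", "Taphozous_melanopogon"),
            n_parallel=0, n_convergent=0, seed=1)
        assert out.sequences == aln.sequences and truth == []

    def test_injected_truth_forced_on_true_ancestors(self, protein_sim):
        """Classifying at the TRUE ancestral states recovers the truth table."""
        from echoconv.convergence import classify_site

        (aln, hist), tree = protein_sim
        pair = ("Aselliscus_stoliczkanus", "Taphozous_melanopogon")
        out, hist2, truth = inject_convergence(aln, hist, tree, pair,
                                               n_parallel=4, n_convergent=3, seed=2)
        assert hist2.replay_is_consistent(tree)
        a, b = tree.node(pair[0]), tree.node(pair[1])
        for site, kind in truth:
            pa = AMINO_ACIDS[hist2.node_states[a.parent.node_id][site - 1]]
            pb = AMINO_ACIDS[hist2.node_states[b.parent.node_id][site - 1]]
            ea = out.row(pair[0])[site - 1]
            eb = out.row(pair[1])[site - 1]
            assert classify_site(pa, pb, ea, eb) == kind
        assert sorted(t for _, t in truth) == ["convergent"] * 3 + ["parallel"] * 4

    def test_not_paraphyletic_rejected(self, protein_sim):
        (aln, hist), tree = protein_sim
        anc = tree.node("Orcinus_orca").parent
        with pytest.raises(InjectionError, match="not paraphyletic"):
            inject_convergence(aln, hist, tree, ("Orcinus_orca", anc.node_id),
                               n_parallel=1, n_convergent=0, seed=1)

    def test_insufficient_sites_error_states_deficit(self, fixture_tree):
        aln, hist = simulate_protein_alignment(fixture_tree, AAModel(), 5, seed=3)
        with pytest.raises(InjectionError, match="only"):
            inject_convergence(aln, hist, fixture_tree,
                               ("Aselliscus_stoliczkanus", "Taphozous_melanopogon"),
                               n_parallel=0, n_convergent=6, seed=1)

    def test_gap_utility(self):
        from echoconv.align import CodonAlignment
        aln = CodonAlignment("g", ("a", "b"), ("ATGAAATTT", "ATGAAGTTC"))
        gapped = inject_gap_columns(aln, [2])
        assert gapped.row("a") == "ATG---TTT"
        assert gapped.row("b") == "ATGAAGTTC"
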