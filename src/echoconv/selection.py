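"""Branch-site positive-selection machinery (model A on GY94).

The mixture has four site classes: 0 (omega0 everywhere), 1 (neutral
everywhere), 2a (omega0 on background, omega2 on foreground branches) and
2b (neutral background, omega2 foreground), with proportions
(p0, p1, (1-p0-p1) p0/(p0+p1), (1-p0-p1) p1/(p0+p1)). The null fixes
omega2 = 1; the alternative frees omega2 >= 1 and is initialised at the
null optimum so the likelihood-ratio statistic is never negative. Branch
lengths are re-estimated per gene under a single-omega (M0) fit — by
default a proportional rescaling of the input tree — and then held fixed.

Positively selected sites are ranked by Bayes-empirical-Bayes posteriors of
membership in classes 2a/2b, averaging over a discrete prior grid on
(p0, p1, omega0, omega2) with the other parameters at their estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import minimize
from scipy.special import logsumexp

from echoconv.align import CodonAlignment
from echoconv.codonmodel import (
    GY94Params,
    build_gy94_neutral_scaled,
    empirical61_frequencies,
    encode_codon_alignment,
    f3x4_frequencies,
)
from echoconv.likelihood import PruningEngine, TransitionCalculator, compress_columns
from echoconv.phylo import FOREGROUND, PhyloTree

BEB_GRID_POINTS = 10
BEB_OMEGA2_MAX = 11.0
DEFAULT_STARTS = 5

#: deterministic multi-start values (kappa, omega0, s=p0+p1, r=p0/(p0+p1), omega2)
_START_TABLE = (
    (2.0, 0.10, 0.85, 0.50, 2.0),
    (1.0, 0.50, 0.60, 0.50, 1.5),
    (3.0, 0.05, 0.95, 0.70, 4.0),
    (2.0, 0.20, 0.70, 0.30, 8.0),
    (1.5, 0.30, 0.90, 0.50, 1.2),
)


def class_proportions(p0: float, p1: float) -> np.ndarray:
    share = p0 + p1
    rest = 1.0 - share
    return np.array([p0, p1, rest * p0 / share, rest * p1 / share])


class CodonLikelihood:
    """Per-gene branch-site likelihood evaluator on a fixed tree.

    Holds the compressed patterns, codon frequencies and foreground flags;
    branch lengths are set once (after the M0 fit) and reused across every
    mixture evaluation and across the BEB grid.
    """

    def __init__(self, aln: CodonAlignment, tree: PhyloTree,
                 frequencies: str | np.ndarray = "F3x4"):
        self.aln = aln
        self.tree = tree
        if isinstance(frequencies, str):
            if frequencies == "F3x4":
                self.pi = f3x4_frequencies(aln)
            elif frequencies == "empirical61":
                self.pi = empirical61_frequencies(aln)
            else:
                raise ValueError(f"unknown frequency mode {frequencies!r}")
        else:
            self.pi = np.asarray(frequencies, dtype=float)
        self.patterns = compress_columns(encode_codon_alignment(aln))
        self.engine = PruningEngine(tree, n_states=61, taxa=list(aln.taxa))
        self.edges = [n for n in tree.nodes if n.parent is not None]
        self.fg = np.array([FOREGROUND in n.tags for n in self.edges], dtype=bool)
        self.lengths = np.array([n.length if n.length is not None else 0.1
                                 for n in self.edges], dtype=float)

    @property
    def n_sites(self) -> int:
        return self.aln.n_codons

    def _transition_set(self, kappa: float, omega: float, scale: float = 1.0):
        # neutral-rate normalisation: shared by the mixture classes so that
        # omega > 1 classes evolve genuinely faster, not just differently
        Q = build_gy94_neutral_scaled(GY94Params(kappa=kappa, omega=omega, pi=self.pi))
        calc = TransitionCalculator(Q, self.pi)
        return {n.node_id: calc.matrix(scale * t) for n, t in zip(self.edges, self.lengths)}

    # -- M0 ---------------------------------------------------------------

    def m0_site_loglik(self, kappa: float, omega: float, scale: float) -> np.ndarray:
        P = self._transition_set(kappa, omega, scale)
        return self.engine.site_log_likelihood(self.patterns, P, self.pi)

    def fit_m0_scale(self) -> tuple[float, float, float, float]:
        """ML (scale, kappa, omega) rescaling the input tree proportionally.

        Returns (scale, kappa, omega, log-likelihood) and leaves
        ``self.lengths`` multiplied by the fitted scale.
        """
        def neg(x):
            scale, kappa, omega = np.exp(x)
            return -float(self.m0_site_loglik(kappa, omega, scale) @ self.patterns.weights)

        res = minimize(neg, np.log([1.0, 2.0, 0.3]), method="L-BFGS-B",
                       bounds=[(-6, 5), (-3, 4), (-8, 3)], options={"ftol": 1e-10})
        scale, kappa, omega = np.exp(res.x)
        self.lengths = self.lengths * scale
        return float(scale), float(kappa), float(omega), -float(res.fun)

    def fit_m0_full(self) -> tuple[float, float, float]:
        """ML per-branch lengths plus (kappa, omega); slower config option."""
        n = len(self.edges)

        def neg(x):
            kappa, omega = np.exp(x[:2])
            self.lengths = x[2:]
            return -float(self.m0_site_loglik(kappa, omega, 1.0) @ self.patterns.weights)

        x0 = np.concatenate([np.log([2.0, 0.3]), np.clip(self.lengths, 1e-4, None)])
        res = minimize(neg, x0, method="L-BFGS-B",
                       bounds=[(-3, 4), (-8, 3)] + [(1e-8, 20.0)] * n,
                       options={"ftol": 1e-10, "maxiter": 1000})
        kappa, omega = np.exp(res.x[:2])
        self.lengths = res.x[2:]
        return float(kappa), float(omega), -float(res.fun)

    # -- model A mixture ---------------------------------------------------

    def class_site_logliks(self, kappa: float, omega0: float, omega2: float) -> np.ndarray:
        """(4, n_patterns) per-class site log-likelihoods, one batched pass.

        Background omegas per class are (omega0, 1, omega0, 1); foreground
        branches use omega2 in classes 2a/2b. All generators share the
        neutral-rate normalisation.
        """
        calcs = {
            omega: TransitionCalculator(
                build_gy94_neutral_scaled(GY94Params(kappa=kappa, omega=omega, pi=self.pi)),
                self.pi,
            )
            for omega in {omega0, 1.0, omega2}
        }
        bg_omegas = (omega0, 1.0, omega0, 1.0)
        fg_omegas = (omega0, 1.0, omega2, omega2)
        P: dict[int, np.ndarray] = {}
        for node, is_fg, t in zip(self.edges, self.fg, self.lengths):
            omegas = fg_omegas if is_fg else bg_omegas
            mats = {w: calcs[w].matrix(t) for w in set(omegas)}
            P[node.node_id] = np.stack([mats[w] for w in omegas])
        return self.engine.site_log_likelihood_batch(self.patterns, P, self.pi)

    def mixture_loglik(self, params: np.ndarray, null: bool) -> float:
        kappa, omega0, s, r, omega2 = _decode(params, null)
        class_ll = self.class_site_logliks(kappa, omega0, omega2)
        w = class_proportions(s * r, s * (1.0 - r))
        site_ll = logsumexp(class_ll, axis=0, b=w[:, None])
        return float(site_ll @ self.patterns.weights)


def _encode(kappa, omega0, s, r, omega2, null: bool) -> np.ndarray:
    x = [np.log(kappa), _logit(omega0), _logit(s), _logit(r)]
    if not null:
        x.append(np.log(max(omega2 - 1.0, 1e-6)))
    return np.array(x)


def _decode(x: np.ndarray, null: bool):
    kappa = float(np.exp(np.clip(x[0], -4, 5)))
    omega0 = _sigmoid(x[1])
    s = _sigmoid(x[2])
    r = _sigmoid(x[3])
    omega2 = 1.0 if null else 1.0 + float(np.exp(np.clip(x[4], -20, 6)))
    return kappa, omega0, s, r, omega2


def _logit(p: float) -> float:
    p = min(max(p, 1e-9), 1 - 1e-9)
    return float(np.log(p / (1 - p)))


def _sigmoid(x: float) -> float:
    x = float(np.clip(x, -30, 30))
    return 1.0 / (1.0 + np.exp(-x)) * (1 - 2e-9) + 1e-9


@dataclass(frozen=True)
class BranchSiteFit:
    """One converged (or flagged) branch-site optimisation."""

    gene_id: str
    null: bool
    log_likelihood: float
    kappa: float
    p0: float
    p1: float
    omega0: float
    omega2: float
    converged: bool
    n_starts: int
    degenerate: bool
    site_class_posterior: np.ndarray  # (n_sites, 4) at the MLE
    config: str = ""

    @property
    def class_weights(self) -> np.ndarray:
        return class_proportions(self.p0, self.p1)


def fit_branch_site(
    aln: CodonAlignment,
    tree: PhyloTree,
    null: bool,
    frequencies: str | np.ndarray = "F3x4",
    n_starts: int = DEFAULT_STARTS,
    init: BranchSiteFit | None = None,
    likelihood: CodonLikelihood | None = None,
    fit_lengths: str = "scale",
    config: str = "",
) -> BranchSiteFit:
    """Maximise the model A mixture likelihood (null: omega2 fixed at 1).

    ``init`` seeds the first start (used to start the alternative at the
    null optimum); ``likelihood`` reuses a prepared evaluator whose branch
    lengths have already been fitted, avoiding a second M0 pass.
    """
    if not any(FOREGROUND in n.tags for n in tree.nodes if n.parent is not None):
        raise ValueError("tree has no FOREGROUND-tagged branch")
    lik = likelihood
    if lik is None:
        lik = CodonLikelihood(aln, tree, frequencies)
        if fit_lengths == "scale":
            lik.fit_m0_scale()
        elif fit_lengths == "full":
            lik.fit_m0_full()
        elif fit_lengths != "fixed":
            raise ValueError(f"unknown fit_lengths mode {fit_lengths!r}")

    degenerate = len(set(aln.sequences)) <= 1

    starts: list[np.ndarray] = []
    if init is not None:
        # start the alternative from the null optimum with omega2 pushed off
        # the boundary (the log(omega2-1) transform has a vanishing gradient
        # exactly at omega2 = 1)
        s_init = init.p0 + init.p1
        r_init = init.p0 / s_init
        starts.append(_encode(init.kappa, init.omega0, s_init, r_init, 2.5, null))
        starts.append(_encode(init.kappa, init.omega0, s_init, r_init, 1.0 + 1e-3, null))
    for row in _START_TABLE:
        if len(starts) >= n_starts + (2 if init is not None else 0):
            break
        starts.append(_encode(*row[:4], row[4], null))

    def neg(x):
        return -lik.mixture_loglik(x, null)

    best = None
    converged = False
    for x0 in starts[: n_starts + (1 if init is not None else 0)]:
        res = minimize(neg, x0, method="L-BFGS-B",
                       options={"ftol": 1e-10, "gtol": 1e-3, "maxiter": 300})
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)

    kappa, omega0, s, r, omega2 = _decode(best.x, null)
    if init is not None and not null and -best.fun < init.log_likelihood:
        # the null is nested in the alternative: never report a lower optimum
        class _Res:
            fun = -init.log_likelihood
            x = _encode(init.kappa, init.omega0, s_init, r_init, 1.0 + 1e-9, null)
        best = _Res()
        kappa, omega0, s, r, omega2 = init.kappa, init.omega0, s_init, r_init, 1.0
    p0, p1 = s * r, s * (1.0 - r)
    class_ll = lik.class_site_logliks(kappa, omega0, omega2)
    w = class_proportions(p0, p1)
    log_joint = np.log(w)[:, None] + class_ll
    post = np.exp(log_joint - logsumexp(log_joint, axis=0, keepdims=True))
    site_post = post.T[lik.patterns.site_to_pattern]

    return BranchSiteFit(
        gene_id=aln.gene_id, null=null,
        log_likelihood=-float(best.fun),
        kappa=kappa, p0=p0, p1=p1, omega0=omega0, omega2=omega2,
        converged=converged, n_starts=len(starts), degenerate=degenerate,
        site_class_posterior=site_post, config=config,
    )


def fit_gene(
    aln: CodonAlignment,
    tree: PhyloTree,
    frequencies: str | np.ndarray = "F3x4",
    n_starts: int = DEFAULT_STARTS,
    fit_lengths: str = "scale",
    config: str = "",
) -> tuple[BranchSiteFit, BranchSiteFit, CodonLikelihood]:
    """Null and alternative fits sharing one M0 branch-length pass; the
    alternative starts at the null optimum, guaranteeing lnL_alt >= lnL_null."""
    lik = CodonLikelihood(aln, tree, frequencies)
    if fit_lengths == "scale":
        lik.fit_m0_scale()
    elif fit_lengths == "full":
        lik.fit_m0_full()
    fit_null = fit_branch_site(aln, tree, null=True, n_starts=n_starts,
                               likelihood=lik, config=config)
    fit_alt = fit_branch_site(aln, tree, null=False, n_starts=n_starts,
                              likelihood=lik, init=fit_null, config=config)
    return fit_null, fit_alt, lik


def lrt(fit_alt: BranchSiteFit, fit_null: BranchSiteFit,
        mixture_null: bool = False) -> tuple[float, float]:
    """2*(lnL_alt - lnL_null) clamped at 0, against chi-square df=1 (the
    conservative reference); ``mixture_null`` switches to the 50:50
    point-mass/chi2_1 mixture."""
    if fit_alt.gene_id != fit_null.gene_id or fit_alt.config != fit_null.config:
        raise ValueError("fits are from different genes or configurations")
    if fit_alt.null or not fit_null.null:
        raise ValueError("pass (alternative, null) fits in that order")
    stat = max(0.0, 2.0 * (fit_alt.log_likelihood - fit_null.log_likelihood))
    p = float(stats.chi2.sf(stat, df=1))
    if mixture_null:
        p = 0.5 * p if stat > 0 else 1.0
    return stat, p


# -- BEB ------------------------------------------------------------------

def beb_sites(
    fit_alt: BranchSiteFit,
    likelihood: CodonLikelihood,
    grid_points: int = BEB_GRID_POINTS,
    threshold: float = 0.90,
) -> list[tuple[int, float]]:
    """Per-site Bayes-empirical-Bayes posterior of the positive-selection
    classes (2a u 2b), averaging over a uniform prior grid on
    (p0, p1, omega0, omega2); kappa and branch lengths stay at their MLEs.

    Returns [(site, posterior), ...] for all sites; callers flag
    posterior > ``threshold`` as positively selected.
    """
    if fit_alt.null:
        raise ValueError("BEB needs the alternative fit")
    if not fit_alt.converged:
        raise ValueError(
            f"refusing BEB on non-converged fit for {fit_alt.gene_id} "
            f"({fit_alt.n_starts} starts exhausted)"
        )
    d = grid_points
    mids = (2 * np.arange(d) + 1) / (2 * d)
    omega0_grid = mids                          # U(0,1)
    omega2_grid = 1.0 + mids * (BEB_OMEGA2_MAX - 1.0)  # U(1, 11)
    # (p0, p1) uniform over the simplex triangle, gridded at cell centres
    p_combos = [(a, b) for a in mids for b in mids if a + b < 1.0]
    W = np.stack([class_proportions(a, b) for a, b in p_combos])  # (n_p, 4)

    kappa = fit_alt.kappa
    patterns = likelihood.patterns
    npat = patterns.n_patterns

    # cache class site logliks: class 0 by omega0, class 1 fixed, 2b by omega2
    base = likelihood.class_site_logliks(kappa, float(omega0_grid[0]), float(omega2_grid[0]))
    ll1 = base[1]
    ll0 = np.empty((d, npat))
    ll2b = np.empty((d, npat))
    ll2a = np.empty((d, d, npat))
    for i, w0 in enumerate(omega0_grid):
        for j, w2 in enumerate(omega2_grid):
            cl = likelihood.class_site_logliks(kappa, float(w0), float(w2))
            if j == 0:
                ll0[i] = cl[0]
            if i == 0:
                ll2b[j] = cl[3]
            ll2a[i, j] = cl[2]

    log_weights = []   # per grid theta: log integrated likelihood
    posteriors = []    # per grid theta: per-pattern P(class 2a u 2b)
    for i in range(d):
        for j in range(d):
            cl = np.stack([ll0[i], ll1, ll2a[i, j], ll2b[j]])  # (4, npat)
            mx = cl.max(axis=0)
            rel = np.exp(cl - mx[None, :])
            mix = W @ rel                                   # (n_p, npat)
            log_mix = np.log(mix) + mx[None, :]
            log_weights.append(log_mix @ patterns.weights)  # (n_p,)
            posteriors.append((W[:, 2:3] * rel[2][None, :] + W[:, 3:4] * rel[3][None, :]) / mix)

    logw = np.concatenate(log_weights)
    post = np.concatenate(posteriors, axis=0)  # (n_theta, npat)
    logw -= logsumexp(logw)
    beb_pat = np.exp(logw) @ post
    beb_site = beb_pat[patterns.site_to_pattern]
    return [(s + 1, float(beb_site[s])) for s in range(len(beb_site))]


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with input."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D list of P-values")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("P-values must lie in [0, 1]")
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / (np.arange(n) + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass(frozen=True)
class LRTResult:
    """One gene x foreground-configuration test."""

    gene_id: str
    config: str
    lnl_alt: float
    lnl_null: float
    statistic: float
    p_value: float
    q_value: float
    beb: tuple[tuple[int, float], ...] = ()
    beb_threshold: float = 0.90

    @property
    def selected_sites(self) -> tuple[int, ...]:
        return tuple(s for s, post in self.beb if post > self.beb_threshold)


def scan_genes(
    alignments: list[CodonAlignment],
    tagged_tree: PhyloTree,
    config: str,
    n_starts: int = DEFAULT_STARTS,
    beb_threshold: float = 0.90,
    run_beb: bool = True,
) -> list[LRTResult]:
    """Branch-site LRT over genes for one foreground configuration, with
    Benjamini-Hochberg correction across genes (within the configuration)."""
    raw: list[tuple] = []
    for aln in alignments:
        fit_null, fit_alt, lik = fit_gene(aln, tagged_tree, n_starts=n_starts, config=config)
        stat, p = lrt(fit_alt, fit_null)
        beb = tuple(beb_sites(fit_alt, lik)) if (run_beb and fit_alt.converged) else ()
        raw.append((aln.gene_id, fit_alt, fit_null, stat, p, beb))
    q = fdr_adjust([r[4] for r in raw]) if raw else np.array([])
    return [
        LRTResult(
            gene_id=g, config=config,
            lnl_alt=fa.log_likelihood, lnl_null=fn.log_likelihood,
            statistic=stat, p_value=p, q_value=float(qv),
            beb=beb, beb_threshold=beb_threshold,
        )
        for (g, fa, fn, stat, p, beb), qv in zip(raw, q)
    ]


def results_rows(results: list[LRTResult]) -> list[dict]:
    """TSV-ready rows (gene, configuration, lnL0, lnL1, 2dl, P, q, BEB sites)."""
    return [
        {
            "gene": r.gene_id, "configuration": r.config,
            "lnL0": round(r.lnl_null, 6), "lnL1": round(r.lnl_alt, 6),
            "statistic": round(r.statistic, 6),
            "P": r.p_value, "q": r.q_value,
            "beb_sites": ";".join(f"{s}:{post:.4f}" for s, post in r.beb if post > r.beb_threshold),
        }
        for r in results
    ]
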