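# Methods

## Scope and data model

The package operates on per-gene in-frame codon alignments (FASTA), a rooted
species tree with branch lengths (Newick, with optional PAML-style `#1`
foreground marks or `[&tags=...]` tag sets), and a comparison design naming
focal lineage pairs and their phylogenetically matched controls. Site
coordinates are 1-based codon positions everywhere, so codon index equals
amino-acid index, and filtered analyses report sites in the original
coordinates via an explicit coordinate map.

The packaged 19-taxon design covers three CF bats, four FM bats, two click
bats, two non-echolocating fruit bats, two toothed whales, one baleen whale
and five other mammals, arranged on the accepted mammal topology
(rhinolophoid CF bats sister to the pteropodids within Yinpterochiroptera;
FM bats as Yangochiroptera; whales with Bos in Cetartiodactyla; Homo/Mus as
outgroup). No branch lengths are published for this tree, so the fixture
draws them reproducibly from the seed: terminal branches uniform(0.04, 0.10)
and internal branches uniform(0.01, 0.05) expected replacements per site,
giving a tree height near 0.24 — comfortably inside the low-divergence
regime in which ancestral reconstruction is reliable (see below).

## Alignment hygiene

Two filters precede every analysis: any codon column containing a gap
(`---`/`-`) or ambiguity (`NNN`/`X`) in any taxon is removed, and genes
whose filtered length falls below 150 nt are discarded. The column rule is
the strictest defensible reading of a codon-level block filter: downstream
site classification needs fully resolved columns, and a stricter filter can
only lose sites, never fabricate calls. Unknown symbols are errors, never
silently treated as missing.

## Likelihood machinery

All likelihoods use Felsenstein pruning with per-pattern scaling after
collapsing alignments to unique site patterns; alignments up to 10,000
sites x 50 taxa run without underflow. Reversible generators are
eigendecomposed once per parameter value through the pi^(1/2) symmetrising
similarity, so transition matrices for all branch lengths are two matrix
products each. Mixture models evaluate their four site classes in one
batched pruning pass.

### Amino-acid models

Default: Poisson exchangeabilities with frequencies observed from the gene's
alignment (plus a pseudocount of 1 so no state is impossible). Any symmetric
20x20 exchangeability matrix can be supplied; none is bundled. Discrete-gamma
rate heterogeneity (k = 4 categories at quantile midpoints, normalised to
mean 1) is available but off by default — the ancestral states consumed
downstream are argmax calls, which a shared rate multiplier perturbs little
at this divergence.

The reconstruction step is defined on the protein alphabet because the
convergence criteria are defined on amino-acid residues; the source protocol
named a nucleotide program for this step, which cannot emit amino-acid
ancestors as written, so the package reconstructs on the 20-state alphabet
directly.

### Codon model

GY94 over the 61 sense codons: single-nucleotide changes have rate
pi_j x {1, kappa, omega, omega*kappa} for synonymous
transversions/transitions and nonsynonymous transversions/transitions;
multi-step changes and changes through stops are forbidden. Codon
frequencies default to F3x4 estimated from the gene (empirical-61
optional). `build_gy94` scales its generator to mean rate 1 at equilibrium
(the single-class convention). Inside the branch-site mixture — and in the
simulator — every class generator is instead divided by one **common**
normaliser, the mean rate of the neutral (omega = 1) generator at the same
kappa and pi. A shared normaliser is essential: scaling each class to rate 1
would equalise total substitution rates across classes and erase the excess
of amino-acid change that makes omega2 > 1 detectable, leaving only
composition differences. Branch lengths are therefore measured in
neutral-equivalent substitutions per codon site.

## Branch-site test

Model A: classes 0 (omega0 everywhere), 1 (neutral), 2a (omega0 background /
omega2 foreground) and 2b (neutral background / omega2 foreground), with
proportions (p0, p1, (1-p0-p1)p0/(p0+p1), (1-p0-p1)p1/(p0+p1)). The null
fixes omega2 = 1. Parameters are optimised by bounded quasi-Newton
(L-BFGS-B) on transformed coordinates (log kappa, logit omega0, logit
(p0+p1), logit p0/(p0+p1), log(omega2-1)) from a deterministic start table
(up to five starts; simulation studies use one). The alternative starts from
the null optimum with omega2 pushed to 2.5 — starting exactly at the
boundary kills the gradient of the log(omega2-1) transform — and the
reported alternative likelihood is clamped to be at least the null's, which
the nesting guarantees mathematically. Convergence uses a relative
likelihood tolerance of 1e-10 (about 1e-6 log-units at typical gene sizes)
plus a projected-gradient threshold of 1e-3; exhausting all starts without
optimizer success flags the fit rather than hiding it.

Branch lengths are re-estimated once per gene under a single-omega (M0) fit
and then fixed for both mixture fits. By default the M0 step estimates one
proportional scale of the input tree together with kappa and omega, rather
than every branch length: per-gene rate variation is overwhelmingly a
shared-scale effect, the scale-only fit is stable on short genes where 2n-2
free lengths are barely identifiable, and it is several-fold faster. Full
per-branch M0 estimation remains available (`fit_lengths="full"`).

The LRT statistic 2(lnL_alt - lnL_null), clamped at zero, is referred to
chi-square with df = 1 — conservative for a boundary null; the 50:50
point-mass/chi-square mixture is available by flag. Benjamini-Hochberg
correction is applied across genes within each foreground configuration
(the narrowest defensible family; a global family is a one-line change).

### BEB site posteriors

Site posteriors for class 2a u 2b average over a uniform prior grid with
kappa and branch lengths fixed at their estimates: (p0, p1) at the centres
of a 10x10 grid on the simplex triangle, omega0 ~ U(0,1) and
omega2 ~ U(1,11), each at 10 interval midpoints. Grid weights are the
integrated data likelihoods (computed in log space); sites with posterior
above 0.90 are flagged. Because the neutral-rate normaliser depends only on
kappa and pi, the per-class site likelihood cache stays valid across the
entire grid.

## Ancestral reconstruction and convergence calls

Marginal posteriors at every internal node come from one down (pruning) and
one up pass; at each node x site the maximum-posterior state is recorded,
ties broken by fixed alphabetical order and flagged. A node x site whose
entire subtree is gap/ambiguous is flagged missing and excluded from calls
rather than guessed; `min_ancestral_posterior` (default 0, i.e. no cutoff)
optionally drops low-confidence ancestors too.

A substitution is called on a branch wherever the parent's argmax state
differs from the child state (leaf residues for terminal branches; flagged
sites skipped). For a paraphyletic branch pair, a site is called when both
branches substituted, the derived residues are identical, and each differs
from its own ancestor; ancestral equality separates parallel from
convergent. Calls on branches whose parent is weakly constrained — for
instance an ancestor adjacent to the root with a single long sibling branch
— carry more false positives (argmax posteriors near 0.4 instead of 0.95);
the packaged study design only calls on branches with well-constrained
parents, and the posterior cutoff exists for designs that do not.

### Convergence-excess (neutrality) test

Null model: ancestral states are fixed at their reconstructed values, and
each observed substitution independently redraws its derived state with
probability proportional to the replacement rate from its parent (parent
excluded). Summing per-site match probabilities over sites substituted on
both branches gives expected parallel and convergent counts; one-sided
P-values come from the Poisson upper tail with that mean (degenerate inputs
— no substitutions — give expected 0 and P = 1). The exact construction of
the historical tool this emulates is not published; this package's null is
pinned instead by a Monte-Carlo resampling oracle in the test suite. With
small expected counts the Poisson tail is conservative, which the null
calibration test confirms (empirical rejection below nominal).

## Matched-control statistics

The seven-row paired design contrasts each echolocator comparison with a
control at the same phylogenetic distance (the click-bat vs toothed-whale
row appears twice, matched once to a bat control and once to a whale
control). The paired-sample t-test runs on (echolocating - control)
differences with df = 6, two-sided — the sidedness reproduces the published
P-values exactly, and all seven rows are used for every metric (the
published "except" clause describes two rows whose direction reverses, not
an exclusion). P-values are rounded to two decimals only in reports; full
precision is kept internally. The adaptive overlap is an exact site-level
intersection of BEB-flagged sites and parallel/convergent calls per gene,
annotated with the supporting foreground configurations and comparisons.

## Simulator and what a green test establishes

Codon and protein sequences evolve by exact stochastic (Gillespie)
simulation per branch and site — not endpoint sampling — because the full
event history is the test oracle: replaying every chain must reproduce the
emitted alignment, event counts calibrate omega recovery, and true ancestral
states ground the reconstruction-accuracy and convergence-recall studies.
Injected parallel/convergent substitutions rewrite two focal branches toward
a common derived residue at sites whose simulated ancestors already satisfy
the required equality/inequality, then propagate the edit through the
subtree so consistency is preserved.

Default mixture parameters (p0 = p1 = 0.45, omega0 = 0.1, kappa = 2, uniform
codon frequencies) are configuration values chosen for testability.
Alignments are generated gap-free; gaps for filter tests are injected by a
separate utility; no indel process, assembly artifacts or alignment error
are emulated. A green suite therefore establishes internal correctness and
calibration of the inference machinery under its own generating model — it
does not certify behaviour under model misspecification (saturation,
heterotachy, alignment error), which real transcriptome-derived orthologs
can exhibit.

## Randomness and reproducibility

Every stage takes an explicit integer seed; the pipeline derives per-gene
streams as `default_rng([seed, gene_index])` so genes are reproducible
independently of batch order, and reruns with one config produce
byte-identical TSVs (checksummed in the run manifest).

## Known limitations

- The branch-site optimisation is local; multi-start (default table of five)
  mitigates but cannot guarantee the global optimum on pathological genes.
- The scale-only M0 default biases per-gene branch lengths when true
  per-branch deviation from the input tree is large; use `fit_lengths="full"`.
- BEB power is limited on short foreground configurations (few, short
  branches): with three CF terminal branches and omega2 = 4, site posteriors
  rarely exceed 0.90 even when the gene-level LRT fires — consistent with
  the method's known behaviour, not a defect.
- The excess test conditions on reconstructed ancestors; reconstruction
  error at weakly constrained nodes propagates into both observed and
  expected counts.
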