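# Methods

This note documents the models implemented in phylomix, the estimation
procedures, the numerical choices that affect results, what the
synthetic-data experiments do and do not demonstrate, and the design
decisions made where more than one reasonable choice existed.

## Substitution models and likelihood

All models are continuous-time Markov chains on the DNA (4-state) or
amino-acid (20-state) alphabet, normalized to one expected substitution
per site per unit branch length (−Σ πᵢqᵢᵢ = 1), so branch lengths are
comparable across models. Reversible models use exchangeabilities and
frequencies (Q ∝ R·diag(π)); the nonreversible UNREST model carries all
12 off-diagonal DNA rates, its stationary distribution is computed from
Q and used as the default root frequency. Custom matrices load from
plain text: PAML-style lower-triangle + frequencies for reversible
matrices (the bundled, published LG/WAG/JTT tables use this format) and
full off-diagonal row-major for nonreversible ones.

Transition probabilities use an eigendecomposition of the
π^{1/2}-symmetrized rate matrix for reversible models (exact, cached
per model) and scipy's scaling-and-squaring matrix exponential for
nonreversible ones. Rows are clamped to [0, 1] and renormalized to
absorb round-off at the 1e-16 level.

Site likelihoods follow the pruning algorithm over weighted site
patterns (identical columns are collapsed; real-valued pattern weights
are allowed, which the EM M-steps exploit). Every internal node is
rescaled by its per-pattern maximum with the log of the factor
accumulated separately, so alignments with hundreds of taxa stay
finite. Mixture likelihoods combine class-conditional pattern
log-likelihoods by log-sum-exp; rate heterogeneity (discrete gamma with
mean-of-slice category rates, free rates, an optional rate-0 invariant
category) enters as extra weighted components per class. IUPAC
ambiguity codes and gaps become 0/1 compatibility vectors at the
leaves.

Unrooted trees are stored rooted at an arbitrary trifurcating node; for
reversible models all results are invariant to that choice (the pulley
principle, asserted to 1e-8 in the tests). Nonreversible likelihoods
legitimately depend on the rooting, and the test suite asserts that
asymmetry too.

## Optimization

Branch lengths are optimized coordinate-wise: for one edge the
likelihood factorizes as L_i(t) = Σ_{a,b} U_i(a) P_{ab}(t) D_i(b) with
"up" and "down" partial tables, so the 1-D problem is solved by bounded
Brent search on [1e-6, 10] (xatol 1e-10) with tables refreshed before
each edge; sweeps repeat until the gain falls below the tolerance
(default 1e-4 log-likelihood units). Model fitting alternates three
individually monotone steps — EM on mixture class weights, L-BFGS-B on
the continuous parameters (log-scale rates and shape parameters,
logit-scale frequencies and weights), and branch-length sweeps — and
reports an unconverged flag rather than raising when the round budget
(default 100) is exhausted. Fitted mixtures are reported with classes
sorted by weight (ties by model name).

Free parameters counted for information criteria: optimized matrix and
rate parameters, frequency parameters (empirical counts are counted as
s−1 estimated quantities, the standard convention), k−1 mixture
weights, and branch lengths when optimized.

The branch-length gradient is analytic (substituting dP/dt = QP on one
edge of the up/down factorization; mixture components are combined by
their per-site posteriors), and the Hessian is a central finite
difference of the analytic gradient (step 1e-5, symmetrized). The
dating export file is plain text: taxon count, Newick, branch-length
vector, gradient, Hessian rows, all at %.17g so the reader round-trips
bit-identically. The exact byte layout expected by external Bayesian
dating tools is not standardized here; the documented layout above is
this package's own.

## Search, selection, rooting

Pairwise ML distances maximize the two-sequence likelihood (closed form
under equal-rates models, bounded Brent otherwise; saturated pairs are
capped at 10 with a warning) and feed Saitou–Nei Neighbor-Joining with
the classic Q-criterion, deterministic lowest-index tie-breaking and
negative branch-length clamping. Topology search is NNI hill-climbing:
both rearrangements of every internal branch are scored with the
central branch re-optimized, the best branch-disjoint improving set is
applied, branch lengths are re-swept, and the gain is re-verified (with
fallback to the single best move if simultaneous moves interfere).

MixtureFinder-style class selection is stepwise: pick the best
single-class model among the candidates by the criterion (default BIC),
then repeatedly propose one extra class seeded from the 25% of sites
with the lowest current site likelihood (initial weight 0.1), choose
the new class's matrix family on that worst-site subalignment,
re-optimize the full mixture, and accept only if the criterion
improves. Within the selection loop all classes use ML-optimized
("+FO") frequencies: this costs the same parameter count as empirical
counts but lets classes separate in base composition, which matters
precisely when a mixture is needed. The default candidate ladder is
{JC, K2P, HKY, GTR} × {none, +G4}, the default class cap 10; both are
package choices, documented, not claims of parity with any other tool.
Selection is restricted to DNA data.

Rooting under a nonreversible model evaluates every branch of the fixed
unrooted topology as a root position, optimizing the split of the
branch length around the root in one dimension. Rootstrap support of a
branch is the fraction of B site-bootstrap replicates whose ML root
lies on it. By default the model parameters and branch lengths are
fitted once on the full data and held fixed per replicate (only the
root is re-placed; `refit="brlen"` enables per-replicate branch-length
refits). This keeps B=100 replicates tractable on one CPU and targets
the same estimand; with per-replicate refits the supports would be
slightly more dispersed.

## MAST and QMaker

The tree mixture is fitted by EM: the E-step computes per-site tree
posteriors, the weight M-step is closed-form (iterated to convergence
at fixed conditional likelihoods, itself a monotone EM), branch lengths
are improved per tree on posterior-weighted patterns (a generalized
M-step), and linked model parameters are refreshed every third round
with L-BFGS-B on the full mixture objective. Input branch lengths,
when present, are the starting point — refitting every topology on the
pooled data first would collapse the distinguishing internal branches
and strand EM at the uninformative symmetric point. Identical input
trees (the GHOST branch-length-mixture case) are deliberately
desymmetrized by scaling the duplicates' starting lengths, and
isomorphic topologies are flagged with only their summed weight
reported as identifiable.

QMaker-style matrix estimation is block-coordinate ascent over (i)
per-alignment branch lengths (and root positions, in the nonreversible
variant) and (ii) the shared exchangeabilities, optimized on the log
scale with the last entry fixed at 1 to remove the scale redundancy;
reversible estimation pools empirical frequencies across alignments.
The outer loop stops when the summed log-likelihood gains less than 0.1
units. The output is PAML-format text directly reloadable through the
model-string `Q.<file>` mechanism.

## The simulator

Sequences evolve root-to-tips. Site class and rate-category labels are
drawn once at the root and inherited, matching the data-generating
process the mixture likelihood assumes (sites do not switch class along
the tree). Two per-branch algorithms share one sampling law: matrix
sampling from the rows of P(t), and per-site Gillespie events
(exponential waits at rate −q_aa, jumps proportional to off-diagonal
rates). The adaptive mode uses events below θ = 0.1 expected
substitutions per site per branch and matrix above; θ is an engineering
choice (the event algorithm wins when substitutions are rare) and every
decision is logged per branch. RNG streams derive from (seed, branch
identifier) so simulations are bit-reproducible and local tree edits do
not perturb unrelated branches. Indel simulation is out of scope.

## Concordance factors

For each internal branch of a binary reference tree with adjacent
clades A, B | C, D: a gene tree is decisive if it carries at least one
taxon of each clade, and concordant if its induced split matches AB|CD
(the two NNI alternatives and a paraphyly remainder are tallied
separately; gCF + gDF1 + gDF2 + gDFP = 100 wherever defined). The
parsimony sCF samples quartets (one leaf per clade, with replacement
across quartets, seeded); a site is decisive for a quartet only when
all four characters are unambiguous and form a 2+2 two-state pattern —
any IUPAC ambiguity makes the site non-decisive, a deliberately
conservative choice. The likelihood sCF fits branch lengths of the
three quartet resolutions and assigns each site to the resolution with
the highest site log-likelihood, excluding near-ties (1e-9); averaging
argmax assignments (rather than assignment probabilities) is the
documented choice here. Branches are identified across trees by their
leaf-set bipartitions, so rotations and rootings do not matter.

## Synthetic-data conditions and what the tests show

All validation data are generated by the package's own simulator under
stated conditions: random topologies with branch lengths uniform on
[0.05, 0.3] (terminal 0.1 / internal 0.3 for the tree-mixture
experiments, following the convention that the distinguishing signal
lives on internal branches), HKY transition/transversion ratio 3, a
"strongly nonreversible" cyclic UNREST matrix (rates 3.0/0.5/0.2) for
rooting experiments, gamma shape 0.5 for rate-heterogeneity recovery,
and a 70/30 two-topology concatenation for MAST. Problem sizes used by
the acceptance tests are the package's own: 200 oracle instances (≤5
taxa, ≤12 sites), one 50,000-site matrix-recovery fit plus ten
20,000-site topology-recovery replicates, ten seeds per MixtureFinder
condition at 10,000 sites with the no-gamma candidate ladder (the
generating processes are rate-homogeneous), twenty 10,000-site MAST
seeds, a 10×5,000-site matrix-estimation set, and twenty rootstrap
seeds at 20,000 sites with B = 100. The acceptance script runs the same
experiments at reduced seed counts and records the measured quantities.

These experiments show internal correctness and statistical
consistency under the assumed generating processes. Real data violate
those assumptions in ways the generator does not emulate — indels and
alignment error, compositional drift across lineages, site-specific
selective constraints, linkage between sites, model misspecification of
every kind — so passing tests certify the estimators and their
implementation, not robustness of inferences on empirical alignments.

## Numerical choices and degenerate inputs

Branch lengths live in [1e-6, 10]; zero-length branches are evaluated
at the lower bound with a warning in curvature calculations. Partial
likelihoods are rescaled at every internal node; patterns with zero
likelihood propagate −inf cleanly. Mixture weights are floored at 1e-8
during EM to avoid log(0) while still allowing effectively degenerate
classes. Model-string parsing is case-insensitive for bases and
suffixes; `+G` means `+G4`. Two-leaf trees, constant alignments
(concordance returns NA), saturated distance pairs (capped, warned) and
alignments with taxa missing from the tree (error naming the taxon) are
all handled explicitly.

## Known limitations

No codon or covarion models; no partition merging; no ultrafast
bootstrap or stochastic SPR search (NNI hill-climbing only); MAST
requires user-provided topologies and shares one rate distribution
across trees; the likelihood sCF refits only branch lengths per
quartet; protein profile mixtures are supported only as user-loaded
frequency classes; rootstrap defaults to a fixed topology per
replicate. The published clade-specific matrices are loadable from
files but not re-derived here.
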