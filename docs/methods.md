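# Methods

## Model

`phylofunc` models the presence/absence of one gene function as a
two-state Markov process running from the root of a rooted, reconciled
gene tree toward its leaves.  The tree's internal nodes carry an event
class — duplication or speciation — and the branch *below* an event
node uses that class's gain/loss pair: (μ01d, μ10d) after a
duplication, (μ01s, μ10s) after a speciation.  The root state is
Bernoulli(π); π is not event-class dependent.  Transition probabilities
are per-branch and deliberately independent of branch length,
reflecting the view that functional change clusters immediately after
duplications rather than accruing gradually with time.  A continuous-
time extension in which μ becomes a rate scaled by branch length would
be conceptually straightforward but is out of scope here.

Observed annotations exist only at a (usually small) subset of leaves
and pass through an error layer: a true absence is recorded as presence
with probability ψ01, a true presence as absence with probability ψ10.
Unannotated leaves are *missing*, never a third state.

Multiple tree+function pairs may be pooled under one shared parameter
vector; their log-likelihoods add.  A tree annotated with several
functions is expanded into one pair per function (functions are treated
as independent).  The 5-parameter "baseline" variant ties
μ01d = μ01s and μ10d = μ10s.

All seven parameters live in [0, 1], and the boundary values are legal:
real estimates do hit 0 and 1 (e.g. loss-free speciation branches), so
every log is guarded and an impossible observation pattern yields a
log-likelihood of −∞, which the sampler treats as an automatic
rejection.

## Likelihood

The likelihood of the observed annotations given parameters is computed
by the classic post-order pruning recursion for discrete characters.
Each node carries the pair L_n(s) = P(subtree data below n | x_n = s);
an annotated leaf initializes its pair from the error layer,
(P(z | x=0), P(z | x=1)); an internal node multiplies, over its
offspring, the transition-weighted sums of its offspring pairs; the
tree likelihood is π·L_root(1) + (1−π)·L_root(0).  Polytomies are
supported (the offspring product is over arbitrary sets).

Two implementation details matter at scale:

* **Reduced pruning order.** A subtree with no annotated leaf
  contributes a factor of exactly one, so only nodes with at least one
  annotated descendant are visited.  With sparse annotation this prunes
  most of the tree.  Equivalently, unannotated leaves could carry unit
  partials; the full-order form is used by the prediction pass, and the
  two agree to machine precision (tested).
* **Per-node rescaling.** Each node's pair is divided by its maximum
  and the log of the discarded factor accumulated, so pooled sets with
  hundreds of leaves per tree cannot underflow.

Trees are flattened to parallel post-order arrays (parent index, branch
event class, observed leaf state) and the hot loop is compiled with
numba; a pooled set is concatenated into a single forest pass.  One
evaluation over 200 trees of 500 leaves takes a few milliseconds, which
is what makes MCMC at that scale routine.

A brute-force oracle (`brute_force_loglik`, ≤ 12 nodes) sums the exact
probability over all 2^|N| state assignments and is the reference for
the pruning implementation in the test suite (agreement < 1e-10 over
randomized instances).

## Posterior decoding

The posterior P(x_n | data) for *every* node is obtained by a downward
pass over the full post-order arrays.  At the root the closed form
π·L(1) / [π·L(1) + (1−π)·L(0)] applies.  For any other node n with
parent p, the joint P(data, x_n = s) factorizes into the subtree term
L_n(s) and a complement term obtained from the parent's joint by
dividing out n's own parent-conditional subtree contribution and
applying the branch's transition probabilities, summed over the
parent's state.  The derivation follows directly from the Markov
factorization; the implementation is validated against the enumeration
oracle rather than against any particular typeset rearrangement of the
recursion.  The branch transition pair is always the event class of the
parent node, exactly as in the likelihood.

Because the upward pass stores max-normalized partials, every joint in
the downward pass shares one arbitrary scale factor that cancels in the
posterior ratio; a 0/0 (an impossible parent state) is guarded by
dropping that term.  With no annotations at all the decoding reduces to
prior propagation: π at the root and chained transition marginals
elsewhere (tested exactly).

Leave-one-out predictions recompute the decoding once per annotated
leaf with that annotation removed — a deliberate, naive quadratic
strategy that is simple, obviously correct, and fast enough at desk
scale.  Predictions for unannotated leaves always use all available
information.

Credible intervals propagate parameter uncertainty: parameter vectors
are resampled with replacement from the kept MCMC draws, the decoding
is repeated per draw, and per-node equal-tailed empirical percentiles
form the interval, with the point estimate computed at the trace mean.
A `high_confidence` filter retains nodes whose interval lies entirely
below 0.1 or entirely above 0.9.

## Estimation

**MCMC.** Random-walk Metropolis on the unit hypercube.  The proposal
is isotropic Gaussian (sd 0.05) for the first `adapt_start = 500`
iterations, after which the covariance adapts to the running empirical
covariance of the chain scaled by 2.38²/d plus 1e-6·I (recomputed every
50 iterations).  Proposals outside [0, 1] are folded back by repeated
reflection (x < 0 → −x, x > 1 → 2 − x); reflection is an involution
that preserves proposal symmetry, so the acceptance ratio uses the
posterior only.  Defaults follow the protocol this model family is
estimated with in practice: 4 chains, burn-in of half the sample,
thinning of 10, point estimate = mean of all kept draws.  Convergence
is monitored by the classical between/within-chain Gelman-Rubin PSRF
with the usual < 1.1 rule.  Chains are seeded from a single master seed
via `numpy.random.SeedSequence.spawn`, making runs bit-reproducible.
Adaptation start, jitter, initial values (prior means; 0.5 under a
uniform prior) and all counts are configuration options because no
single setting suits both a 3-second smoke fit and a pooled study.

On an empty dataset the likelihood is constant and the sampler must
reproduce each parameter's Beta prior; the test suite checks the means
of Beta(2, 9) and Beta(9, 2) targets (0.1818 and 0.8182) within Monte
Carlo error, which simultaneously validates that reflection preserves
detailed balance.

**MLE / MAP.** Multi-start (default 10) L-BFGS-B on logit-transformed
coordinates, which removes the box constraints; boundary optima are
reachable in the limit and reported as values numerically at 0 or 1.
MAP maximizes the same objective plus the Beta log-prior (the mode in
probability space, not in the transformed space).  Likelihood surfaces
under sparse annotation are ridged, so a flatness flag is set when
distinct starts reach the same objective (within 1e-6) at points more
than 0.05 apart — e.g. a single annotated leaf, or π under μ = 0.5.
Parameters may be fixed (`fix={"psi01": 0, ...}`) and the baseline tie
is available inside the same machinery.

**Priors.** Independent Beta(α, β) per parameter; uniform is
Beta(1, 1).  The stock informative set encodes the biological
expectation that change is likely after duplication (Beta(9, 2) on μ·d)
and rare otherwise (Beta(2, 9) on π, μ·s, ψ).

## Simulator

`simulate_tree` builds random rooted bifurcating topologies by
sequential random joins and classes each internal node as a duplication
independently with probability 0.2 — the duplication prevalence typical
of reconciled gene-family trees — standing in for real PANTHER
topologies, which are not redistributable here.  `simulate_states`
realizes the evolutionary process; `observe_states` applies the error
layer at leaves; `drop_annotations` removes a uniformly random subset.

What the simulator does **not** emulate: the size and depth imbalance
of real families, branch lengths, correlated functions, taxonomic
structure, and — importantly — the non-random placement of experimental
annotations (model organisms cluster in real trees) and the extreme
scarcity of negative annotations in curated data.  Passing recovery
tests on simulated data therefore demonstrates internal consistency of
model + estimator, not performance on curated annotation databases.

`run_scenario` drives the Monte Carlo study.  Generating parameters are
drawn per replicate from the study shapes — μ01d ~ Beta(38, 2),
μ10d ~ Beta(10, 10), μ01s, μ10s, π ~ Beta(2, 38) — under three
scenarios: fully annotated (no mislabeling), partially annotated
(missing proportion m ~ Uniform(0.1, 0.9), no mislabeling), and
partially annotated with mislabeling (ψ ~ Beta(2, 38)).  Note these
generating shapes are a distinct object from the estimation priors
above.  Each replicate is refit under the generating ("correct") prior
and/or a biased prior with α doubled, and records truth, estimates,
bias (truth − estimate), and LOO MAE/AUC.  In the scenarios that
exclude mislabeling, ψ is fixed at its generating value of zero during
estimation rather than estimated.  Fit failures are recorded per
replicate, not raised.

## Evaluation

MAE = mean |z − x̂| over scored annotations: 0 perfect, 0.5 coin toss,
1 perfectly wrong; threshold-free and robust to class imbalance, which
is why it is the primary score.  AUC uses the rank (Mann-Whitney)
formulation with midranks for ties — chosen for estimator unbiasedness,
as tie handling is otherwise a free choice.  `sensitivity_sweep` varies
one parameter over a grid, rescoring LOO predictions of annotated
leaves, to show which parameters the prediction error actually depends
on (μ·s strongly; π barely, since it only shifts the root prior of a
deep tree).

## Validation problem sizes

The statistical checks in `tests/test_acceptance.py` run at deliberate
desk scale, chosen once as the smallest designs whose Monte Carlo error
is well below the effects being asserted: oracle equivalence on 100+
random trees of ≤ 12 nodes; prior recovery with 4 chains × 20,000
iterations; parameter recovery over 200 replicates of fully annotated
500-leaf trees (20 distinct topologies, 2 chains × 2,500 iterations per
fit), asserting |median bias| < 0.05 for the four μ parameters; and the
missingness trend over bins {0.1, 0.5, 0.9} with 20 replicates per bin
on 200-leaf trees.  π is excluded from the recovery assertion: with one
root realization per tree it is weakly identified and tends to be
over-estimated, and that behaviour is expected rather than a defect.

## Known limitations

* π is near-unidentifiable from single trees; pooled fits help little
  because each tree still contributes one root.
* Under heavily one-sided annotation data (few or no negatives), ψ01
  and the μ parameters trade off; estimates of ψ01 can absorb
  annotation sparsity artefacts.  Informative priors mitigate this for
  one-tree-at-a-time fits.
* No branch lengths, no correlated functions, no taxon constraints, no
  ontology structure over function terms: each function is an
  independent binary character on a known, fixed tree.
* LOO recomputation is quadratic in the number of annotated leaves per
  tree; fine at desk scale, and a shared-cache optimization would not
  change any result.
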