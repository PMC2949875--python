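# Methods

This note records the models implemented in `crabrange`, the numerical
choices behind them, what the synthetic-data generators do and do not
emulate, and the known limitations. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Areas, adjacency and range states

Four areas are coded A (Indian Subcontinent), B (Southeast Asia including
the Sunda shelf), C (Philippines), D (east of the Wallace Line). Range
states are nonempty subsets of these areas that are connected in an
adjacency graph; the default graph has edges A–B, B–C, B–D, C–D. This is
the minimal graph consistent with the study design's restriction — India
borders only Southeast Asia, while the Philippine and Wallacean ranges are
mutually reachable — and it excludes {A,C}, {A,D} and {A,C,D}, leaving 12
allowed ranges plus an absorbing null (globally extinct) state. A fully
connected graph (15 ranges) is available for analyses without the
restriction. Ranges are bitmasks ordered by size then bit pattern, null
last.

## DEC likelihood

Anagenetic evolution is a CTMC over the range states. Range R gains area
a ∉ R at rate `d · Σ_{b∈R} D[b,a]` when R∪{a} is an allowed state, and
loses any of its areas at rate `e` (the last loss enters the null state,
which is absorbing). `D` is a fixed 0/1 multiplier matrix: all ones off
the diagonal for `H0`; column A zeroed for `HIA` (range expansion into
India disabled, i.e. dispersal only out of India); row A zeroed for `HAI`.
Because `D` is fixed, all three hypotheses have exactly k = 2 free
parameters and are *not* nested — the constrained models can and sometimes
do attain higher likelihoods than `H0` (the published dispersal-model
table shows the same inversion), so comparison is by AIC/Akaike weight
rather than likelihood-ratio tests.

Cladogenesis: a single-area range splits sympatrically (R, R); a
widespread range splits by peripheral-isolate sympatry ({a}, R) and
(R, {a}) for each a ∈ R, plus vicariance into a singleton and its
complement (both orders) whenever the complement is itself an allowed
state. Outcomes are equally weighted; widespread-identity inheritance is
excluded, following the classic DEC convention. Cladogenesis applies at
every internal node *including the root*; the root likelihood is the
unweighted sum of conditional likelihoods over all nonempty allowed root
ranges (no range-size prior, no conditioning on survival). A fixed-root
variant is exposed for validation. With cladogenesis at the root, a
two-tip tree with tips {A} and {B} has likelihood 1/6 even at d = e = 0
(root {A,B} vicariance); impossible data (e.g. the same tips with the
root fixed to {A}) yield a −inf log-likelihood sentinel that is
propagated, never dropped.

Branch transition probabilities are matrix exponentials, computed through
an eigendecomposition fast path (all unique branch lengths in one batched
product) with `scipy.linalg.expm` as fallback whenever the row-sum check
(|row − 1| < 1e-9) fails. Entries that are structurally zero — target
unreachable from source in the rate graph, found by transitive closure —
are clipped to exactly zero, and t = 0 returns the exact identity;
otherwise ~1e-16 eigensolver noise can turn an impossible dataset into a
spurious finite log-likelihood. Partial likelihoods are rescaled per node
(log-scale accumulators), so 100-tip trees pose no underflow risk.

Fitting maximizes the log-likelihood over (ln d, ln e) with L-BFGS-B,
bounds 1e-8–10 per Ma on both rates, from three fixed starting points
((1e-2, 1e-2), (1e-3, 1e-4), (1e-1, 1e-2)); non-finite evaluations are
penalized. Ancestral-split reconstruction decomposes the global likelihood
at each internal node over (ancestor, left, right) scenarios by an
inside–outside pass; scenarios within 2 log-units of the node's best are
reported with relative probability = scenario likelihood / node total
(the node total equals the global likelihood, which the tests assert).

## DIVA parsimony

Exact dynamic programming over all 2^k − 1 subsets at every node (no
adjacency restriction — the restriction is a DEC-side device): vicariance
(any ordered disjoint bipartition of a widespread ancestor) and
within-area duplication are free; each area gained along a branch costs 1
dispersal and each area lost costs 1 extinction, counted by set
differences between a daughter's inherited start set and its own
distribution. An outside pass recovers, per node, every distribution
participating in at least one globally optimal reconstruction, reported in
(size, bitmask) order and capped at `max_alternatives` (default 1000)
after optimality filtering. `max_areas` caps ancestral distribution sizes;
tip distributions are data and are never capped. Exhaustive enumeration on
small trees is the test oracle.

## Bayesian multistate ancestral areas

Single-area tips evolve under a fully asymmetric 4-state Mk model (12 free
rates, uniform root frequencies) — the BayesTraits-style multistate
default, since the study design names no rate restriction. Priors are
hierarchical: hyperprior mean m ~ uniform(0, 80) and each rate
q_ij ~ exponential(mean m), a literal reading of the seeded exponential
hyperprior. Proposals: one uniformly chosen rate per generation updated by
a sliding window of width `rate_deviation` (default 0.1) reflected at 0,
or (with probability 1/13) an independent uniform redraw of m over its
range; acceptance rates are reported as a diagnostic (the historical
operating point for this proposal width was a ~33% mean acceptance rate).
Ancestral states are drawn jointly at each sampled generation from the
pruning partials, root downward. Fossilizing a node zeroes its partial
likelihoods for all other states, which can only lower the attainable
likelihood (tested on fixed-rate grids).

Desk-scale defaults are 1e5 generations, sampling every 100, 100 samples
of burn-in; the historical large-scale settings (5e7 generations etc.)
remain valid configuration values. Chains are initialized at the tree's
natural rate scale (mean rate = 1 / total tree length) rather than from
the diffuse seeded prior: the stationary distribution is unchanged, but
short chains would otherwise spend their entire run walking in from the
prior's far tail and contaminate the harmonic-mean estimate with
transient samples. "sampling 5 × 10^4 generations" in the source design
is ambiguous (an interval vs a total); the configuration makes the
interval explicit and claims no equivalence.

Node support compares, for each candidate area, the marginal likelihood
of the model with the node fossilized to that area: each constrained
model's ln marginal likelihood is the mean of `repeats` (default 5)
independent harmonic-mean runs, and the node is *supported* for the best
area only when its log10 Bayes factor against every alternative exceeds
0.48; otherwise the verdict is equivocal.

## Marginal likelihoods and Bayes factors

The harmonic-mean estimator is lnML = −(logsumexp(−lnL) − ln n) over
post-burn-in samples, implemented as specified despite its known
instability, because it is the Tracer-style procedure this package
mirrors; a top-fraction truncation variant exists behind a flag, off by
default. Its standard error is a moving-block bootstrap (block length
⌈√n⌉, 1000 resamples, fixed seed) since traces are autocorrelated.
Pairwise log10 Bayes factors are (lnML_a − lnML_b)/ln 10 with
Kass–Raftery-style categories >0.48 substantial (*), >1.00 strong (**),
>1.48 very strong (***); categories are computed on unrounded values,
tables print half-up to two decimals. AIC = 2k − 2 lnL with Akaike
weights w_i ∝ exp(−Δ_i/2). The published dispersal-model table's printed
AIC and weight columns are not reproducible from its own printed
log-likelihoods under the standard definitions (2·2 − 2·(−48.88) = 101.76,
not the printed 111.76); the implementation computes the standard
definitions and sets no expectation on those printed cells. Likewise one
cell of the published temporal-model matrix (±0.78 between the 45/35 and
35/35 models) disagrees with its own printed ln marginal likelihoods
(which give 0.28); the other 20 pairs and all star marks are reproduced.
HPD intervals are the shortest window of ⌈level·n⌉ sorted samples,
ties broken toward the lowest lower bound.

## Dating priors

Fossil calibrations are offset gamma densities: zero below the fossil's
minimum age, gamma(shape, scale) above it. The shipped design uses offsets
16.5, 6 and 2.5 Ma with shapes 4, 2, 3 and scale 1 — larger shapes encode
more uncertainty about how far the node predates the fossil. Temporal
node-age hypotheses are normal densities at 45/35/25 Ma with sd fixed at
20% of the mean (the design states only "a standard deviation of 20%";
normal is the simplest shape consistent with that, and the choice is
documented rather than claimed). The clock-rate prior is normal
(0.88 %/Ma, 10% sd) truncated at zero and renormalized, rates being
positive. These priors parameterize fixtures and document the dating
design; full tree-dating MCMC over topologies is out of scope.

## Synthetic data

All generators are seeded and bit-reproducible. Yule trees come from
dendropy's constant-rate birth–death simulator (death rate 0) with one
extra exponential epoch appended after the n-th speciation so the youngest
divergence sits strictly before the present; trees can be rescaled to a
target root age (Yule shapes are scale-free). The DEC simulator uses the
same rate matrix and cladogenesis weights as the likelihood (Gillespie
along branches, a scenario drawn at each node); branches that reach the
null range are redrawn, holding tip count fixed. This conditions the
simulation on survival while the fitted likelihood does not condition —
at the extinction rates used (e ~ 1e-4–1e-3 per Ma) the null state is
rarely reached and the mismatch is negligible, but it is a real asymmetry
at high e. The Mk simulator is a plain CTMC. Likelihood traces come from
a conjugate normal–normal model (latent mean, known variances) whose
exact ln marginal likelihood is a multivariate normal density; the
defaults (5 observations, likelihood sd 1, prior sd 0.3) keep
prior_sd² < like_sd²/n with a factor-2 margin, the condition for the
harmonic-mean estimator to have finite variance, so the estimator's
calibration test is well-posed.

The study-scale fixture is a 57-tip Yule tree rescaled to root age
47.23 Ma with ranges simulated under `HIA` from an Indian root at
d = 3.9e-3, e = 3.2e-4 per Ma (the study's fitted rates, used as
qualitative anchors — its own tree is unpublished, so its exact likelihood
and rate values are not reproducible targets). The fixture ships as
versioned text files regenerable bit-for-bit from its recorded seed. What
passing tests on these data do show: the estimators recover the generating
process of the models they implement. What they do not show: robustness to
phylogenetic error, non-Yule tree shape, rate heterogeneity across
lineages, or area miscoding, none of which the generators emulate.

## Problem sizes and test design

Oracle tests enumerate joint assignments exhaustively on trees of 2–5 tips
with 2–3 areas, where enumeration is exact and fast. The parameter-recovery
study uses 20 replicates of 100-tip chronograms at root age 47.23 Ma with
d = 5e-3, e = 5e-4 per Ma; at those rates a tree carries only a handful of
dispersal events, which is enough to pin d to within a factor of two but
leaves the directional hypotheses (`H0` vs `HIA`) separated by less than
~0.02 log-units in most replicates — the direction test is
data-starved at this scale, and the test suite documents the measured
identification rate rather than papering over it. MCMC validation runs use
4k–20k generations on 3–10-tip trees, sized so exact conditionals and
harmonic-mean calibration are checkable in seconds to minutes.

## Known limitations

Time-stratified dispersal matrices, >2 DEC rate parameters, Bayesian DEC,
statistical (tree-averaged) DIVA, reversible-jump rate-class models and
integration over posterior tree sets are all out of scope. The
harmonic-mean estimator is used deliberately for fidelity to the mirrored
workflow; for new analyses, path-sampling estimators would be preferable
and are not provided here.
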