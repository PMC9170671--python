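# Methods

## Problem

A pairwise forced-choice questionnaire (FCQ) presents statements in blocks of
two; the respondent picks the statement they agree with more. The format
suppresses acquiescence and (with matched social desirability) faking, but a
given single-statement pool can yield questionnaires of very different
precision depending on how the statements are paired. Pairing `N` items into
`J` blocks is a combinatorial problem with

    N! / (J! (N - JV)! V!^J)

candidates for blocks of size `V`; at `N = 60, J = 30, V = 2` that is about
2.92e40, far beyond exhaustive search, and the multidimensional information
structure rules out direct linear-programming formulations. `fcassembly`
implements a heuristic optimizer for this assembly problem together with the
measurement model, a budget-matched random-search baseline, and a
trait-recovery simulation harness.

## Measurement model (MUPP-2PL)

Each statement is a dominance 2PL item: agreement probability
`expit(a*theta_d + c)` with `c = -a*b`, loading a single trait `d`. Under the
multi-unidimensional pairwise-preference framework, the probability of
endorsing the first statement of block `j` reduces to a multidimensional
compensatory logistic:

    P(y_j = 1 | theta) = expit(s_j' theta + c_j)

with scale vector `s_j` holding `+a_1` at the first item's trait and `-a_2`
at the second item's trait, and `c_j = c_1 - c_2`. Responses are coded 1/2
for first/second statement. The block Fisher information is the rank-one
matrix `I_j(theta) = s_j s_j' P_j Q_j` and, assuming conditional independence
(each item used in at most one block), questionnaire information is the sum
over blocks.

## Assembly objective

The objective is the average over traits of the posterior marginal
reliability: at each node `theta_l` of a full-factorial grid with points
{-2, 0, +2} per trait (243 nodes for five traits), the posterior information
matrix `M_l = I(theta_l) + Phi^{-1}` is inverted and its d-th diagonal
element taken as the conditional posterior error variance of trait `d`;
these are averaged over the grid with MVN(0, Phi) density weights, and
`rho2_d = 1 - var_bar_d`. The prior precision term makes the criterion
appropriate for Bayesian (MAP) scoring and keeps `M_l` invertible for any
questionnaire, including the empty one.

Numerical choices: the grid weights are *normalized to sum to one* (raw MVN
densities over a coarse grid do not integrate to 1; without normalization
the "reliabilities" would not live on the 0-1 scale). All logistic
evaluations go through `scipy.special.expit`; whole candidate populations
are scored in one vectorized pass (einsum over blocks/nodes, batched 5x5
inverses).

## Optimizer: node-histogram sampling GA

Genotypes are involutive permutations `delta` of the pool indices:
`delta[i] = u` pairs items i and u, `delta[i] = i` leaves item i out
(`N - 2J` fixed points). An estimation-of-distribution scheme replaces
crossover/mutation:

- **Node histogram** `Dt[i, u]`: number of population members pairing i with
  u (rows sum to the population size K).
- **Sampling distribution** for position i: proportional to
  `C*[i, u] * (Dt[i, u] + eps_i)` over the currently feasible partners,
  where `eps_i = (K / sum_u C[i, u]) * B_ratio` is the mutation constant.
  Large `B_ratio` pushes sampling toward uniform; `B_ratio = 2^-4` is the
  default, with `K = N` as in the study conditions.
- **Sampling operator**: two cut points `m1 <= m2` are drawn uniformly; the
  parent's entries in `[m1, m2]` are copied together with their mirror
  positions (preserving the involution; copied fixed points stay out of the
  questionnaire). Remaining positions are filled in ascending index order by
  multinomial draws; after each accepted pair the rows/columns of both items
  are retired, and when a dimension pair reaches its quota `h_max` all
  pairs of those two traits are closed. A position with no remaining
  feasible partner self-pairs.
- **Selection**: parents and offspring are pooled and the K best kept
  (elitist; best objective is non-decreasing). Ties break in stable union
  order so runs are reproducible from the seed.
- **Convergence**: all K genotypes identical; a `max_generations` cap
  (default 10,000) bounds runtime.

Questionnaire-level constraints: blocks are hetero-dimensional (same-trait
pairs are zeroed in C); with `h_max = J / (D choose 2)` every trait pair
receives the same number of blocks. An optional polarity quota fixes the
numbers of homo-polar and hetero-polar blocks.

**Dead-end policy** (the published description leaves this open): sequential
quota-constrained sampling can strand items whose partners' quotas are
filled. A build that ends with fewer than J blocks restarts with fresh cut
points, up to 25 times; a GA offspring then falls back to its parent
(counted and reported). Under a polarity quota an additional counting filter
is applied while sampling: a partner is masked if forming that block kind
would leave the remaining positive/negative item counts unable to complete
the homo/hetero quotas (e.g. with exactly N/4 negative items, a
negative-negative block can never complete the half-hetero design). The
filter is a necessary condition only; residual dead-ends are handled by the
restarts.

Within-block order is lower pool index first. The order only negates
`(s_j, c_j)`, which leaves information and the objective invariant (a test
asserts this); it matters only for interpreting the 1/2 response coding.

## Brute-force baseline

The same sampling machinery with an empty template and uniform probabilities
yields independent feasible questionnaires ("quasi-brute-force"). The search
runs under a budget in candidate evaluations — matched by default to the
number of evaluations the GA consumed, a hardware-independent proxy for the
wall-clock matching used in the original protocol — and reports the best and
mean objective plus a uniform reservoir subsample of candidates for scoring
the average-candidate benchmark.

## Simulation harness

Pools emulate a five-trait (Big-Five-like) instrument: equal items per
trait, `a ~ N(1.5, 0.5)`, `b ~ U(-2, 2)`, trait correlations `Phi` either
identity or the NEO PI-R matrix. In all-positive mode raw discrimination
draws are kept (a negative draw is a ~3-sigma event; none appear at study
pool sizes). In half-negative mode a quarter of the pool (balanced across
traits) is negatively keyed with `a ~ N(-1.5, 0.5)`; a draw whose sign
contradicts the designated key is redrawn (~0.13% of draws), because the
exact quarter-negative composition is a design property without which the
half-homo/half-hetero-polar questionnaire is infeasible.

True scores are `MVN(0, Phi)` (default 1000 simulees); responses are
Bernoulli draws from the block probabilities. Scoring is MAP with block
parameters fixed at truth: vectorized Newton ascent on the log-posterior
from the prior mode, gradient tolerance 1e-6. The posterior is globally
concave (logistic likelihood, Gaussian prior), so Newton converges in a few
iterations for all simulees simultaneously.

Recovery metrics per questionnaire: mean squared true-estimate correlation
(true reliability), RMSE, and trait-correlation bias — the correlation
matrix of the MAP estimates (Pearson; the estimator is not specified in the
source protocol) compared with `Phi` by averaging Fisher-Z differences over
the 10 off-diagonal cells and back-transforming. Conditional error curves
bin RMSE/bias/SE of the estimates by true score, pooled across traits, in 15
equal-width bins on [-3, 3] (binning is an implementation choice).
`run_condition` chains pool generation, GA assembly, budget-matched BF, a
shared simulee sample, and scoring of the GA, best-BF and a 10-candidate BF
subsample (the average-candidate benchmark: scoring every BF candidate would
be disproportionate) per replication; all randomness flows from one seeded
`SeedSequence` per condition, so a fixed seed reproduces tables bitwise.

## Problem sizes used in the checks

The end-to-end checks run the smallest published conditions at desk scale:
`J = 30, N:J = 2:1` (all three variants: identity Phi, NEO Phi, and the
half-hetero-polar design), five replications of 1000 simulees each. The
longer `J = 60` and `8:1` conditions scale the same code but are checked
qualitatively (method ordering at reduced size) only. The enumerable-pool
optimality check uses 6- and 8-item pools at `K = 60`: holding the
population at the smallest study size rather than shrinking it with the pool
keeps the node histogram informative (at `K = N = 6` the population is
degenerate and frequently collapses before sampling the optimum).

## What the synthetic data does and does not show

The generator matches the published study conditions, not field data: item
parameters are drawn independently of content, social desirability is not
modeled, response biases (faking, careless responding) are absent, and block
parameters are assumed invariant between single-statement calibration and
forced-choice administration. Passing recovery checks therefore validates
the assembly machinery and scoring pipeline under the model, not the
behavioral claims of forced-choice measurement. Known limitations: blocks
are pairs only (`V = 2`); the MIP/linear-programming route is out of scope;
`BF_avg` is computed on a candidate subsample (configurable) rather than all
candidates.
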