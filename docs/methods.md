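# Methods

## Conditional-independence tests

A test of X ⊥ Y | **Z** is built from two nested regressions of an
*outcome* variable: a reduced model on **Z** and a full model on the
other variable plus **Z**. Categorical predictors (nominal and ordinal
alike) enter through d − 1 indicator columns against the first declared
level; every model carries an intercept and only linear terms. The
family follows the outcome's type:

- **continuous** — ordinary least squares; the models are compared with
  the exact F statistic
  F = (RSS₀ − RSS₁)(n − Par₁) / (RSS₁ (Par₁ − Par₀)) on
  (Par₁ − Par₀, n − Par₁) degrees of freedom.
- **binary / nominal** — binary or multinomial (softmax) logistic
  regression, compared with the likelihood-ratio statistic
  T = 2(LL₁ − LL₀) against χ² with Par₁ − Par₀ degrees of freedom,
  where Par(M) = (d − 1)(Dof(predictors) + 1).
- **ordinal** — the generalized ordered logit (no proportional-odds
  constraint), fit Williams-style as d − 1 independent binary logistic
  regressions of 1{Y > level_j}. The model is *scored* on the category
  scale: with Ĝⱼ(x) = P(Y > level_j | x) from the split fits, the
  likelihood uses P(Y = level_j) = Ĝⱼ₋₁ − Ĝⱼ. Scoring the categorical
  likelihood (rather than summing the d − 1 binomial likelihoods) is
  essential: the sum of correlated split statistics is not χ²
  distributed, and in simulation the summed version leaves a persistent
  ~0.13 gap between the two directional p values even at n = 10⁴,
  whereas the categorical scoring drives the gap to zero. Because the
  split fits are unconstrained, reconstructed probabilities can cross
  below zero for a few observations (about 1% of replicates at n = 200
  in the hardest settings); such fits are flagged not-converged and the
  symmetric wrapper falls back to the opposite direction.

Likelihood models are maximized by damped Newton iterations (step
halving; at most 100 iterations; stop when the log-likelihood moves by
less than 1e−8). Separation and collinearity are never patched by
regularization — the fit is flagged and the caller decides. A
numerically negative LR statistic is clamped at zero (a warning is
emitted when both fits converged and the deficit exceeds 1e−6, which for
the ordered-logit family can happen because the categorical score is not
the objective the splits maximize).

## Symmetric tests

The directional test is asymmetric: regressing on X need not give the
p value of regressing on Y. Four symmetric wrappers are provided. *mm*
combines the two dependent p values as min{2 min(p₁,p₂), max(p₁,p₂)};
*min* and *max* take the obvious envelope (disjunction / conjunction of
the two rejections); *fast* performs a single test, choosing the outcome
by the priority continuous > nominal > ordinal and, between two
same-kind categoricals, the one with fewer levels — a smaller model is
estimated more accurately from the same data. Exact ties fall back to
the lexicographically smaller variable name, so the choice (and hence
every result) is invariant to argument order. When both variables are
continuous the two directions provably coincide and only one is
computed. If one direction's fit is unreliable the other direction's
p value is used; if both fail the test returns p = 1 (biasing PC toward
deleting the edge rather than crashing), always logged.

## PC-stable learner

Skeleton search is the order-independent variant: at level k, candidate
separating sets are drawn from the adjacency sets frozen at the start of
the level, enumerated in sorted-name order over the neighbors of either
endpoint, and all deletions are applied at the level's end. The first
set with p > α is recorded as the pair's separating set. Unshielded
triples X–Z–Y with Z outside sepset(X, Y) become colliders; conflicting
arrowhead claims leave the edge undirected (logged). Meek rules R1–R4
then propagate orientations to a fixpoint. Defaults: α = 0.01,
conditioning-set size unbounded (max_k = p − 2). The whole chain is
verified exact against a d-separation oracle on random 30–50-node DAGs,
and DAG→CPDAG conversion against exhaustive enumeration of Markov
equivalence classes on all DAGs with up to four nodes.

## Synthetic-data generator

The generator is the package's only data source and fixes the study
conditions:

- DAG topology: a random topological order over p nodes; each
  order-respecting pair is an edge with probability avg_degree/(p − 1).
- Types: drawn per node from the requested mixture (default: continuous
  and ordinal, half each); categorical level counts uniform on {2, 3, 4}.
- Coefficients (including intercepts): uniform on [−1, −0.1] ∪ [0.1, 1],
  so no effect is exactly zero but many are weak.
- Roots: standard normal (continuous), uniform over levels (nominal),
  discretized standard normal (ordinal).
- Continuous children: linear predictor + N(0, 1) noise. Nominal
  children: a multinomial-logit link with an independent coefficient
  vector per non-reference category. Ordinal children: a continuous
  latent child, discretized.
- Discretization: category proportions are 15% plus a flat-Dirichlet
  split of the remaining mass; observations are assigned to categories
  by rank of the latent value, so the ordering is preserved exactly and
  every category keeps at least ⌊0.15 n⌋ observations.
- Ordinal *parents* enter structural equations as integer scores
  0..d − 1 with a single coefficient (in the tests themselves they are
  dummy-coded like nominal predictors).

The small calibration structures use five type pairs — continuous-binary,
continuous-multinomial, continuous-ordinal, binary-ordinal,
multinomial-ordinal — in four arrangements: independent, one causing the
other (both directions), a collider X → Z ← Y, and a common cause
X ← Z → Y, with Z always continuous. Multinomial and ordinal variables
in these pairs carry four levels, the most parameter-hungry setting (the
multinomial-ordinal conditional test fits 15-parameter models on either
side).

What the generator does *not* emulate: missing data, non-Gaussian
continuous noise, interactions or nonlinearities, selection bias, latent
confounding. Passing tests therefore show correct behavior under
faithful, causally sufficient, linear-link data — not robustness to
real-data violations of those assumptions.

## Evaluation

Learned PDAGs are scored against the CPDAG of the generating DAG.
Skeleton precision/recall ignore edge marks. Orientation
precision/recall by default require the identical mark (same direction,
or undirected on both sides); an alternative arrowhead-wise convention
(an edge is credited when every arrowhead it asserts exists in the other
graph) is available via `graph_metrics(..., orientation="arrowhead")`.
With no predicted edges, precision is defined as 1 (logged). SHD counts
one unit per pair that is missing, extra, or carries the wrong mark.

## Numerical and scale choices

- The calibration harness uses 1000 replicates per condition; the
  acceptance suite checks type-I error and power at n = 1000 and
  directional agreement at n = 200.
- The network benchmark in the acceptance suite uses 10 random networks
  with 50 variables and average degree 3 at n ∈ {500, 1000} — large
  enough that the per-network standard error of each proportion metric
  is ≈ 0.01–0.03; reference-value comparisons use a 20% relative band.
- Random-number streams derive from `numpy.random.SeedSequence` so every
  harness is exactly reproducible from its integer seed and identical
  seeds give byte-identical datasets.

## Known limitations

- Power at n = 1000 is *not* uniformly high: because effect sizes are
  resampled every replicate from |b| ∈ [0.1, 1], draws near 0.1 leave
  conditional (collider-induced) dependencies genuinely hard to detect;
  measured rejection rates in the collider conditions plateau around
  0.7–0.9 for every method.
- PC orientations degrade when a weak transitive dependence (the product
  of two detectable edge effects) falls below the detection threshold:
  the pair is separated by the empty set, and the triple is wrongly
  oriented as a collider. At the benchmark's coefficient law this caps
  exact-mark orientation precision near 0.56 regardless of the test
  method — an intrinsic limit of sepset-based orientation under weak
  effects, not of the tests.
- The generalized ordered logit is fit split-wise, not by joint maximum
  likelihood; its likelihood-ratio statistics are asymptotically but not
  exactly χ², and its monotonicity in nested designs holds only up to a
  small tolerance.
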