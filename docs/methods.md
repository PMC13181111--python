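# Methods

## Model

`symptomnet` analyses co-occurrence networks of binary symptoms. The
joint distribution of a symptom vector `x ∈ {0,1}^p` is a pairwise
Markov random field — an Ising model in {0,1} coding:

    P(x) ∝ exp( Σ_i τ_i x_i + Σ_{i<j} W_ij x_i x_j )

`τ_i` is the threshold (baseline log-odds scale) of symptom *i* and
`W_ij` the pairwise interaction; a positive edge means the two symptoms
reinforce each other's presence. The conditional distribution of one
node given the rest is logistic, `P(x_i=1 | x_−i) = σ(τ_i + Σ_j W_ij
x_j)`, which is what makes nodewise logistic regression a consistent
estimation strategy.

We use the {0,1} coding (not {−1,+1}) throughout because the data are
presence/absence recodings of ordinal questionnaire items (a score of 0
is absence, 1–3 presence) and because the nodewise-logistic
parameterization is the one the estimator works in. Conversion between
codings is deliberately not provided.

## Estimation (eLASSO)

Each node is regressed on the remaining `p−1` nodes with an
L1-penalized logistic regression along a 100-point log-spaced penalty
path running from `λ_max` (the smallest penalty with an all-zero
solution, `max_j |X_jᵀ(y−ȳ)|/n`) down to `λ_max/100`. Per node, the
Extended Bayesian Information Criterion selects one model:

    EBIC(λ) = −2·ℓ(β̂_λ) + k·log n + 2γ·k·log(p−1)

with `k` the number of active coefficients, `γ = 0.25` by default, and
`ℓ` the *unpenalized* log-likelihood of the penalized solution
(plug-in convention). Ties in EBIC resolve toward the sparser,
larger-penalty end of the path. The two directed coefficients of each
pair are combined under the AND rule by default: the edge is their
arithmetic mean if both are nonzero and exactly zero otherwise (under
OR, the mean — including the zero — whenever either is nonzero).
Thresholds are the selected intercepts. Whether the AND or OR rule and
which γ the canonical defaults correspond to is configurable and
logged, since published analyses often state only that defaults were
retained.

### Solver

The path is solved by proximal Newton: an outer
iteratively-reweighted-least-squares approximation with an inner cyclic
coordinate descent and soft thresholding, warm-started across the path
(glmnet-style), compiled with numba. The contract is the optimum, not
the algorithm: the convergence target is 1e-7 on the objective, and the
parameter-level stopping thresholds are derived from it using the fact
that the logistic curvature is at most 1/4. Coefficients below 1e-8 in
magnitude are snapped to exact zero when a path point is stored; this
matters at the path start, where the KKT condition holds with equality
and float rounding would otherwise leave an `ε`-sized coefficient that
removes the exact null model from the EBIC comparison.

Binary rows are collapsed to unique patterns with multiplicities once
per dataset (at most `2^p` patterns, usually far fewer than `n`); the
weighted likelihood is exactly that of the expanded data, and the same
collapse serves all `p` nodewise regressions. |coefficients| are capped
at 15 as a guard against perfect separation inside resamples.

### Degenerate inputs

An item that is constant in a (re)sample makes its nodewise regression
ill-posed. The policy is *isolated node*: no incident edges, threshold
set to the cap (±15), the event logged. Resampling procedures
(bootstrap, permutation, power replications) therefore never discard or
crash on degenerate resamples, which avoids biasing their
distributions toward well-behaved samples.

## Centrality

Node strength `s_i = Σ_j |W_ij|` and global strength `Σ_{i<j} |W_ij|`
(= half the strength total) are the only indices computed.
Shortest-path centralities are omitted on purpose: they are known to be
unstable under bootstrap in symptom networks. Both raw and
z-standardized strengths are reported; their rank order is identical.

## Stability

*Edge-weight bootstrap*: `B` resamples of subjects with replacement,
full re-estimation each time, percentile 95% intervals per edge
(linear-interpolation quantiles — the numpy default — documented so
results are bit-reproducible under a fixed seed).

*Case-dropping bootstrap*: for each drop proportion `q` on a grid
(default 0.05 to 0.75 in steps of 0.10), subsamples of size
`round((1−q)·n)` are drawn without replacement and the Pearson
correlation between subsample and full-sample strength vectors
recorded; `B` subsamples are split evenly across the grid. The
CS-coefficient is the largest `q` such that at every grid point up to
`q` at least 95% of correlations reach 0.7; above 0.25 is conventionally
acceptable, above 0.5 ideal. The grid is configurable because published
CS values often fall between default grid points, indicating finer
grids in the original software. A constant strength vector in a
degenerate subsample contributes correlation 0 (conservative).

## Network comparison test

Observed statistics: `M = max_{i<j} |W^A_ij − W^B_ij|` (structure) and
`S = |GS_A − GS_B|` (global strength). Subjects are pooled and group
labels reassigned uniformly at random `P` times preserving group
sizes; both networks are re-estimated *from scratch* on every
permutation — no surrogate statistics — and p-values use the add-one
convention `(1 + #{permuted ≥ observed}) / (1 + P)`, which is valid
(type-I error ≤ α) for any `P`. The observed labeling is one of the
equally likely assignments under exchangeability, so the test is exact
up to Monte-Carlo error; the calibration suite verifies 0.05 ± 0.03
empirically over 500 null runs.

## Power simulation

Given two generating networks, each replication samples `n_A` subjects
from the first and `n_B` from the second (exact sampler), runs the NCT
with `P` permutations, and records both p-values; power is the
proportion of replications with `p < α` (strict), with Monte-Carlo
standard error `sqrt(power·(1−power)/R)`. Defaults `R = 300`, `P =
250`, `n_A = 1111`, `n_B ∈ {160, 250, 350}` mirror the headline
analysis design; `n_A` is held at the first group's size, an explicit
assumption. Thresholds are taken from the fitted/specified networks as
given (not re-calibrated per replication); both choices are
configuration fields. Every replication's seeds derive from the master
seed via `SeedSequence.spawn`, so results are identical for any degree
of parallelism.

## Synthetic cohorts

The generator emulates a two-group design: 9 binary symptoms, group
sizes 1,111 and 160, group-specific marginal presence prevalences fixed
to the published prevalence columns, and pairwise dependence
concentrated on a few strong positive edges whose rank order matches
the published description (largest group: guilt–suicidal ideation,
then guilt–depressed mood, then suicidal ideation–sleep, with suicidal
ideation the most central node; smaller group: depressed mood–energy,
then depressed mood–anhedonia, with guilt most central). Edge
*magnitudes* are a structural emulation, not fitted values — the
original adjacency matrices live in an unavailable supplement. Two
scale properties are anchored to the published results: the generating
global strengths are 25.0 (larger group) and 18.5 (smaller group),
matching the printed estimates 25.01 and 18.11, and the node-strength
profiles have substantial contrast (strengths ranging roughly 3.5–9,
SD ≈ 1.9 across nodes), without which subsample centrality orderings
would be dominated by estimation noise and the case-dropping stability
analysis would be degenerate — the published CS values (0.59/0.57)
show the real networks had estimable centrality orderings. Individual
weights lie between 0.27 and 2.74 on the log-odds interaction scale.
Anyone holding the original matrices can build a `ScenarioSpec` from
them directly and bypass the presets.

One consequence of realistic margins is differential shrinkage: the
rarest symptom (suicidal ideation, 8.2% prevalence in the larger
group) contributes few present cases, so its estimated edges shrink
more than those of common symptoms. At study-size samples the
*estimated* strength ranking can therefore swap nearly tied nodes even
when the generating ranking is strict; the estimated strongest *edge*
orderings are much more stable and are what the recovery tests assert.

Thresholds are *calibrated*: Newton iteration on the exact enumerated
marginals (the Jacobian of `τ ↦ E[x]` is the state covariance matrix),
damped to steps of max-norm ≤ 2, converging to the targets within 1e-4
in a handful of iterations for p = 9. Present entries are expanded to
ordinal severities 1/2/3 with probabilities (0.5, 0.3, 0.2) — arbitrary
but fixed, since only the dichotomized data enter the analysis — so
dichotomizing a generated cohort recovers the generating binary matrix
exactly.

What the generator does *not* emulate: covariates (age, gender,
income), missingness, longitudinal dynamics, and any marginal/ordinal
structure beyond the calibrated presence prevalences. Passing tests
therefore demonstrate correctness of the machinery and calibration
under the stated model, not robustness to real-data violations of it.

## Problem sizes in the test and reproduction suites

Simulation-heavy suites use penalty paths of 30 values (the default
100 is kept for headline fits; EBIC selection is essentially unchanged
on these small networks) and these scales: sampler-vs-enumeration
checks at p = 5 with 200,000 draws (TV < 0.01); support recovery on a
4-node chain, n = 4,000, 50 seeds (≥ 90% exact recovery); NCT null
calibration with 500 runs at P = 100, n = 400 per group, p = 6; power
null calibration at R = 200, P = 99; power monotonicity at R = 100,
P = 49. The reproduction script runs the full cohort pipeline at the
design sizes (1,111/160, P = 1,000 permutations, B = 1,000 case-drop
subsamples) and the power stage at R = 60, P = 60.

## Known limitations

- Binary (dichotomized) modeling only; ordinal/polychoric network
  estimation is out of scope, and dichotomization loses severity
  information by design.
- Exact sampling and threshold calibration require p ≤ 20 (2^p
  enumeration); beyond that only the Gibbs sampler is available and
  calibration is not implemented.
- The CS-coefficient resolution is bounded by the drop-proportion grid.
- EBIC-selected lasso estimates are shrunk toward zero; recovered edge
  weights are biased low relative to the generating values, which is
  the standard trade-off of this estimator, not a defect of the
  implementation.
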