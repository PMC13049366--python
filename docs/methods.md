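# Methods

## The age-dependent branching model

`adbphylo` models a population (cells, in the motivating applications) in
which each individual lives for a random lifetime drawn i.i.d. from a
Gamma distribution with shape `k >= 1` and scale `theta`, then either dies
with probability `d` or divides into two newborn daughters.  The mean
lifetime is `ell = k * theta`; `k` and `ell` are the natural user-facing
parameterization and `theta` is derived.  For integer `k` the lifetime is
Erlang — the sum of `k` exponential stages — which interpolates between
the memoryless constant-rate birth–death model (`k = 1`, birth rate
`lambda = (1-d)/theta`, death rate `mu = d/theta`) and near-deterministic,
synchronous division times (`k` large).  At the present, extant
individuals are sampled independently with probability `rho`; the data
are the time-scaled, rooted, binary, ultrametric phylogenies of those
samples (reconstructed trees), possibly several per analysis under one
shared process.

We require `d < 1/2` (supercritical process) and `k >= 1`.  `k` is
treated as a real number throughout: every formula used, including the
edge-density series below, is well defined through the Gamma
distribution, and the continuous priors used for inference make a hard
integer restriction unnatural (an integer random-walk proposal mode is
available).

Time runs backward from the present (`t = 0`); `t_or` is the process
origin and `t_root` the first division ancestral to the sample.

## Governing equations and the grid solver

Three quantities drive the likelihood, each defined by a Volterra-type
integral equation obtained by conditioning on the founder's first event:

- `P0(t)`: probability a lineage born at time `t` leaves no sampled
  descendant:
  `P0(t) = (1-rho)(1-F(t)) + d F(t) + (1-d) \int_0^t f(t-w) P0(w)^2 dw`.
- `P1(t)`: probability of exactly one sampled descendant:
  `P1(t) = rho (1-F(t)) + 2(1-d) \int_0^t f(t-w) P0(w) P1(w) dw`.
- `b(s, t)`: density that a lineage born at `t` has exactly one
  ancestral-to-the-sample descendant at `s` (its next observed division):
  `b(s,t) = (1-d) f(t-s) + 2(1-d) \int_s^t f(t-w) P0(w) b(s,w) dw`.

These have no closed form for `k != 1` and are solved by Picard
(fixed-point) iteration on a uniform grid over `[0, 1.05 x conditioning
time]` with, by default, `m = 2048` nodes.  Each iteration evaluates the
convolution with trapezoidal weights via a zero-padded real FFT plus
explicit end corrections, so an iteration costs `O(m log m)`; iterates of
`P0`/`P1` are clipped to `[0, 1]` to guard against quadrature overshoot
near `t = 0`.  Iteration stops when the sup-norm change drops below
`tol = 1e-10` (the map is a strong contraction for `d < 1/2`; typical
counts are 10–40 iterations), and raises an error carrying the last
residual after 500 iterations.  The quadrature is second order: halving
the step shrinks the solution change by about 4x, which the test suite
checks at `k in {1, 5, 30}`.

Values at arbitrary tree times are obtained by evaluating the closed-form
source term exactly and linearly interpolating only the smooth
convolution remainder between grid nodes.  This keeps degenerate cases
exact (for `rho = 1, d = 0`, `P0 = 0` and `P1 = 1 - F` hold to machine
precision) and removes the dominant interpolation error elsewhere.

Per-edge solves of `b(s, ·)` use a sub-grid on `[s, t]` aligned with the
edge (at least 128 nodes, spacing no coarser than the main grid), with
`P0` interpolated from the main grid.

## The edge-density series approximation

Solving one integral equation per internal edge does not scale, so the
default backend replaces `b(s, t)` by the series

    b(s,t) ~= sum_{n=0}^{n_u} 2^n (1-d)^{n+1} f(t-s; (n+1)k, theta) P0bar^n,

where `n` counts hidden divisions along the edge whose side-subtrees left
no sampled descendants: the total waiting time across `n+1` lifetimes is
Gamma((n+1)k, theta), each hidden division contributes a factor 2 (which
daughter continues), survival `(1-d)`, and one unobserved subtree priced
at `P0bar`, the trapezoidal average of `P0` over `[s, t]`.  Terms are
computed in log space ((n+1)k can exceed 1000, overflowing linear-scale
Gamma normalizers) and accumulated with `logaddexp`.  Truncation: stop at
the first `n` whose term falls below `eps = 1e-8` times the running sum,
with a hard cap of 100 terms; both are configurable.  When many edges are
evaluated at once the stopping rule is applied jointly (terms are added
until every edge has converged), which vectorizes the computation.

Pricing hidden subtrees at the edge-averaged `P0bar` rather than at their
actual branching times is the approximation's only error source.  It is
exact when `P0` is constant over the edge (in particular `P0 = 0`), and
it degrades as `P0` becomes large and strongly varying — empirically the
worst errors occur at low `d` with incomplete sampling, where per-edge
relative errors on long edges reach a few percent while short edges are
essentially exact.  Whole-tree log-likelihood differences between the
exact and series backends stay below 0.5 on 20-tip trees across
`d in [0.05, 0.4]`, and the direction of the error is a slight
underestimate of the death probability in inference.

## Tree likelihood

Conditioned on the origin and on survival of the process,

    P(Tr | t_or) = 1/(1 - P0(t_or)) * prod_{e in E} P1(t_e)
                                     * prod_{e in I} b(s_e, t_e),

with `E` the external edges (terminus at the parent of each tip) and `I`
the internal edges including the origin-to-root stem.  Conditioning on
the root multiplies the two subtree densities each origin-conditioned at
`t_root`; with shared edge sets this is the same product with the stem
edge dropped and the survival factor squared.  Each subtree keeps its own
`1/(1 - P0(t_root))` factor — the literal reading of the root-conditioned
product.  A labelled-tree factor `2^{n-1}/n!` is applied by default; it
is constant in the parameters and only matters for cross-model
comparisons.  All products are accumulated in log space.  Forests sum
per-tree log-likelihoods; trees may carry individual fixed `rho` values
(e.g. observed per-colony sampling fractions), and trees sharing a `rho`
share one solved grid (P0/P1 do not depend on the grid horizon, so a
single grid to the largest conditioning time serves every tree).

For `k = 1` the model is the constant-rate birth–death-sampling model,
whose `p0`/`p1` have closed forms; along an edge the propagator with
unsampled side branches is `p1(t)/p1(s)` and every division contributes a
rate factor `lambda`, so the edge products telescope to
`lambda^{n-1} p1(t_or) prod_x p1(x)` over internal node times `x` (origin
conditioning).  This closed form is implemented as an independent oracle
and the grid solver is required to match it to a relative log-likelihood
error of 1e-3 on simulated 20-tip trees, improving as the step size
shrinks.

## Simulation

The simulator is event-driven: a priority queue of cell-termination
times, no time discretization.  Two stopping modes exist: a fixed origin
time, and a fixed tip count where the process runs until
`ceil(n / rho)` cells are first alive so the rho-sampled reconstructed
tree has about `n` tips (tip counts are binomial around `n`, not exact).
The first-passage rule is the simple sampling approach (SSA); it biases
the origin-time distribution when later periods with the same cell count
are likely, which matters for `d` around 0.4 and above.  The general
sampling approach (GSA) is provided for that regime: the trajectory is
continued (to three times the target count by default), all periods
during which the living count equals the target are enumerated, one is
chosen with probability proportional to its duration, and the present is
placed uniformly inside it.  Fixed-origin simulations are conditioned on
survival by rejection (up to 1000 retries, configurable), matching the
likelihood's survival conditioning; the unconditioned mode used in
moment-validation tests keeps extinct runs.

The complete tree records division, death and censored-extant events
plus per-cell sampling flags; pruning death lineages and unsampled
extant cells and suppressing single-child nodes yields the reconstructed
tree.  Deaths and dropouts are a single "death" category.

What the generator does *not* emulate about real lineage-tracing data:
imaging-frame time quantization (e.g. 15-minute windows), barcode
editing/readout noise, missing links in tracked lineages, and any cell
heterogeneity (the process is single-type).  Passing recovery tests on
simulated trees therefore demonstrates correctness of the inference
machinery under the model, not robustness to those artefacts.

## Expected lineages through time

The expected number of lineages at time `t` descending from a founder at
`tau` satisfies the renewal equation

    mu(t,tau) = 1 - F(tau-t) + 2(1-d) \int_t^tau f(tau-w) mu(t,w) dw

for the complete tree; the reconstructed variant multiplies the
first (no-division) term by `1 - P0(tau)` so only sample-ancestral
lineages count.  The complete curve depends on `tau - t` only and needs a
single Volterra solve; the reconstructed variant couples `t` and `tau`
through `P0` and is solved per requested time point.  The simulator is
validated against the reconstructed curve: over 1000 unconditioned
fixed-origin simulations the mean empirical sample-ancestral lineage
count matches the curve within three Monte-Carlo standard errors at ten
checkpoints (extinct or unsampled runs contribute zero lineages, so the
unconditioned mean is the right comparison).

## Empirical estimators and their bias

From complete population trees the package computes `ell_hat`, the mean
of fully observed lifetimes (branches ending in a division or a death),
and `d_hat = #death / (#division + #death)`.  `d_hat` is consistent for
`d` — a lifetime's fate is independent of its length.  `ell_hat` is
*not* consistent for `ell` under fixed-horizon observation: lifetimes
completed by the horizon are exponentially length-biased.  In the stable
age distribution of the supercritical process, births arrive at rate
proportional to `e^{alpha t}` with Malthusian parameter `alpha` solving
`2(1-d)(1 + alpha theta)^{-k} = 1`, so observed completed lifetimes have
density proportional to `f(L) e^{-alpha L}` and mean
`k theta / (1 + alpha theta)`.  At `(k=5, ell=10, d=0.1)` this limit is
8.89, which the simulator reproduces to four digits; the test suite
asserts convergence to this tilted limit rather than to `ell`.  On short
empirical recordings (a handful of generations from a single founder)
the bias is much smaller, which is why such estimators remain useful
reference values there.

## Bayesian inference

The posterior `P(k, ell, d, rho | T) \propto P(k)P(ell)P(d)P(rho) P(T | ...)`
is sampled by random-scan componentwise random-walk Metropolis on the
natural parameter scales: one randomly chosen parameter is perturbed per
step by a Gaussian whose width is adapted (toward 44% acceptance, in
batches of 50) during burn-in only, preserving the correct stationary
distribution afterwards.  Proposals outside a prior's support or the
model domain (`k >= 1`, `d < 1/2`, `rho in (0, 1]`) are rejected, as are
states where the solver fails (failures are counted and reported).
Natural-scale proposals with support rejection were chosen over
transformed scales because the boundary `k = 1` is interior to common
priors (e.g. Uniform(1, 100)), making log/logit transforms awkward, and
because they need no Jacobians; mixing is adequate for these
four-dimensional posteriors.  Priors available: Uniform, LogNormal,
Exponential, Beta, and Fixed (pinning a parameter, e.g. a known
per-colony sampling fraction).

Convergence diagnostics: effective sample size uses FFT autocorrelation
with Geyer's initial-positive-sequence truncation; the Gelman–Rubin
statistic is the split-chain potential scale reduction factor (each
chain halved, between/within variance ratio).  The split-chain form was
chosen over the lugsail/stable variants as the widely understood
default; the operative pass line is `R_hat < 1.01` together with
`ESS >= 200`, and runs failing it are flagged non-converged.  Posterior
summaries are medians and 95% highest-posterior-density intervals
(shortest interval by a sliding window over sorted samples).

The default chain protocol mirrors common practice for this model class:
1e6 steps, sampling every 1000, 10% burn-in, multiple chains combined
after burn-in.  Validation runs in this repository use deliberately
smaller problem sizes chosen to exercise the same code paths: MCMC grids
of 512 nodes with `tol = 1e-9` (whole-tree log-likelihood within ~0.02 of
the 4096-node reference on a 100-tip tree), chains of 3k–200k steps, and
20-tip trees in the smoke-scale coverage study (with relaxed convergence
thresholds, since coverage bands are only meaningful at full scale).

## Simulation-study harness

`simulation_study` draws true parameters per simulation from a prior set
(redrawing `d >= 1/2` and truncating `rho` below 0.01, where the grid is
unreliable at small `k`) or holds them fixed, simulates a fixed-tip-count
tree, infers with a second prior set conditioning on the known origin,
and reports per-parameter relative bias `(median - true)/true`, relative
error `|median - true|/true`, relative 95% HPD width
`(upper - lower)/true`, and the count of intervals covering the truth.
Non-converged runs are excluded from the metrics but counted and listed.
At full scale (100 simulations, 100-tip trees) the coverage count per
parameter is expected in `[90, 99]`.

## Known limitations

- Single-type process: no cell differentiation, no parameter variation
  across lineages or time.
- Extant ultrametric sampling only: no serial sampling, no sampled
  ancestors.
- `k < 1` (heavy-tailed, anti-synchronous lifetimes) is outside the
  series approximation's validity and rejected.
- Numerically fragile regimes, flagged by warnings: `rho < 0.01` with
  `k < 20` (grid accuracy; recoverable by decreasing the step size) and
  `d > 0.4` (slow contraction and error accumulation).
- The tree is fixed data; joint inference of tree and parameters is out
  of scope.
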