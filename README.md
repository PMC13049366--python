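# adbphylo

Phylodynamic inference for time-scaled phylogenies generated by an
**age-dependent branching (ADB) process**: individuals (typically cells)
live for a Gamma/Erlang-distributed lifetime with shape `k` and mean
`ℓ = k·θ`, then die with probability `d` or divide into two daughters;
extant individuals at the present are sampled with probability `ρ`.  The
classical constant-rate birth–death-sampling model is the `k = 1` special
case (`λ = (1−d)/θ`, `μ = d/θ`).  Increasing `k` makes divisions more
regular and synchronous — a hallmark of developmental cell lineages that
memoryless birth–death priors cannot reproduce.

The package is aimed at researchers analysing single-cell lineage-tracing
or developmental phylogenies (and any other setting where waiting times
are visibly non-exponential) who want to estimate the population-dynamic
parameters `(k, ℓ, d, ρ)` from reconstructed trees.

## What it computes

The tree density conditioned on the origin time is

    P(Tr | t_or) = 1/(1 − P0(t_or)) · ∏_{e∈E} P1(t_e) · ∏_{e∈I} b(s_e, t_e),

where `P0`/`P1` are the probabilities of zero / exactly one sampled
descendant and `b(s,t)` is the density of an internal edge.  These solve
Volterra integral equations with no closed form for `k ≠ 1`; `adbphylo`
solves them by fixed-point iteration with FFT-accelerated trapezoidal
convolution, and replaces the per-edge integral equation by a closed-form
series over hidden divisions,

    b(s,t) ≈ Σ_{n=0}^{n_u} 2ⁿ (1−d)^{n+1} f(t−s; (n+1)k, θ) · P̄0ⁿ,

which makes likelihood evaluation scale to large trees.  On top of the
likelihood the package provides:

- `trees` — Newick/NEXUS I/O, backward-time edge intervals, B1 balance
  index, internal branch lengths, and direct estimators (ℓ̂, d̂) from
  complete population trees;
- `densities` / `edge_approx` — the grid solvers and the series
  approximation, with an exact-vs-approximate comparison harness;
- `likelihood` — tree and forest log-likelihoods (origin or root
  conditioning, labelled-tree factor, exact or series backend) and the
  analytic `k = 1` birth–death oracle;
- `simulator` — event-driven simulation of complete and reconstructed
  trees (fixed tip count via SSA or GSA, or fixed origin) and expected
  lineages-through-time curves;
- `inference` — adaptive random-walk Metropolis over `(k, ℓ, d, ρ)` with
  configurable priors, ESS / Gelman–Rubin diagnostics, HPD summaries,
  and a simulation-study harness (bias, error, HPD width, coverage).

See `docs/methods.md` for the model, numerical choices and limitations.

## Worked example

Simulate a 100-tip tree at `(k=5, ℓ=10, d=0.1, ρ=0.1)` and re-infer the
parameters from it:

```sh
adbphylo simulate --n-tips 100 --k 5 --lifetime 10 --death 0.1 --rho 0.1 \
    --seed 1 --out sim
adbphylo infer --trees sim/trees.nwk --conditioning origin \
    --prior-k "lognormal(2,1)" --prior-lifetime "uniform(1,100)" \
    --prior-death "beta(2,5)" --prior-rho "beta(2,5)" \
    --length 50000 --thin 50 --grid-m 512 --seed 1 --out run
```

which prints (posterior median, 95% HPD bounds, ESS and split-chain R̂
per parameter):

```
       median  hpd_lower  hpd_upper         ess      rhat
k    7.480194   4.590168  10.963946  549.993368  0.999434
ell  9.185413   7.758882  10.802186  171.133779  1.001467
d    0.090394   0.020292   0.179602  176.705380  1.005238
rho  0.074245   0.043615   0.111076  406.878071  0.998901
```

The true values (5, 10, 0.1, 0.1) all fall inside their 95% HPD
intervals; the mean lifetime is the best-recovered parameter, as expected
from the synchronous branching signal in the tree.  `run/trace.log` is a
Tracer-compatible sample log and `run/summary.json` the same summary in
machine-readable form; every output directory carries a `manifest.json`
(configuration + package version + seed) sufficient to reproduce it.

The same pipeline is available in Python:

```python
import adbphylo as ap

params = ap.ADBParams(k=5, ell=10.0, d=0.1, rho=0.1)
tree = ap.simulate_reconstructed_tree(ap.SimConfig(params=params, n_tips=100), seed=1)
ll = ap.tree_log_likelihood(tree, params, ap.LikelihoodConfig(conditioning="origin"))
trace = ap.run_mcmc(tree, ap.STUDY2_PRIORS,
                    ap.MCMCSettings(chain_length=50_000, sample_every=50, seed=1),
                    ap.LikelihoodConfig(conditioning="origin", grid_m=512))
print(trace.summary())
```

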