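"""Bayesian MCMC inference of age-dependent branching parameters.

The posterior over (k, ell, d, rho) given one or more reconstructed trees
is proportional to P(k) P(ell) P(d) P(rho) P(T | k, ell, d, rho), with
the phylodynamic likelihood from :mod:`adbphylo.likelihood`.  Sampling
uses random-scan componentwise random-walk Metropolis on the natural
parameter scales with proposal widths adapted during burn-in; proposals
outside a prior's support (or in the supercritical-violating region
d >= 1/2) are rejected.  Convergence is summarized by autocorrelation
based effective sample sizes and the (split-chain) Gelman--Rubin
statistic, with posterior medians and highest-posterior-density
intervals per parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .densities import SolverError, check_fragile_regime
from .lifetime import ADBParams
from .likelihood import LikelihoodConfig, forest_log_likelihood
from .simulator import SimConfig, simulate_reconstructed_tree
from .trees import Forest, TimeTree

__all__ = [
    "Uniform", "LogNormal", "Exponential", "Beta", "Fixed",
    "PriorSpec", "MCMCSettings", "Trace", "StudyReport",
    "run_mcmc", "hpd_interval", "ess", "gelman_rubin", "simulation_study",
    "STUDY1_PRIORS", "STUDY2_PRIORS", "STUDY2_TRUE_PARAMS",
]

PARAM_NAMES = ("k", "ell", "d", "rho")


# -- priors -------------------------------------------------------------


class _Prior:
    lo: float = -np.inf
    hi: float = np.inf

    def _make_dist(self):
        raise NotImplementedError

    @property
    def dist(self):
        # frozen scipy dists are expensive to build; cache per instance
        d = self.__dict__.get("_dist")
        if d is None:
            d = self._make_dist()
            object.__setattr__(self, "_dist", d)
        return d

    def logpdf(self, x: float) -> float:
        if not (self.lo <= x <= self.hi):
            return -np.inf
        return float(self.dist.logpdf(x))

    def sample(self, rng) -> float:
        return float(self.dist.rvs(random_state=rng))

    @property
    def fixed(self) -> bool:
        return False


@dataclass(frozen=True, eq=False)
class Uniform(_Prior):
    a: float
    b: float

    def _make_dist(self):
        return stats.uniform(self.a, self.b - self.a)

    @property
    def lo(self):
        return self.a

    @property
    def hi(self):
        return self.b

    def logpdf(self, x: float) -> float:
        if not self.a <= x <= self.b:
            return -np.inf
        return -np.log(self.b - self.a)


@dataclass(frozen=True, eq=False)
class LogNormal(_Prior):
    """Log-normal with log-scale mean ``m`` and standard deviation ``s``."""

    m: float
    s: float
    lo: float = 0.0

    def _make_dist(self):
        return stats.lognorm(self.s, scale=np.exp(self.m))

    def logpdf(self, x: float) -> float:
        if x <= 0:
            return -np.inf
        lx = np.log(x)
        return float(-lx - np.log(self.s) - 0.5 * np.log(2 * np.pi)
                     - 0.5 * ((lx - self.m) / self.s) ** 2)


@dataclass(frozen=True, eq=False)
class Exponential(_Prior):
    rate: float
    lo: float = 0.0

    def _make_dist(self):
        return stats.expon(scale=1.0 / self.rate)

    def logpdf(self, x: float) -> float:
        if x < 0:
            return -np.inf
        return float(np.log(self.rate) - self.rate * x)


@dataclass(frozen=True, eq=False)
class Beta(_Prior):
    a: float
    b: float
    lo: float = 0.0
    hi: float = 1.0

    def _make_dist(self):
        return stats.beta(self.a, self.b)

    def logpdf(self, x: float) -> float:
        if not 0 <= x <= 1:
            return -np.inf
        from scipy.special import betaln
        with np.errstate(divide="ignore"):
            return float((self.a - 1) * np.log(x) + (self.b - 1) * np.log1p(-x)
                         - betaln(self.a, self.b))


@dataclass(frozen=True)
class Fixed:
    value: float

    def logpdf(self, x: float) -> float:
        return 0.0

    def sample(self, rng) -> float:
        return self.value

    @property
    def fixed(self) -> bool:
        return True


@dataclass(frozen=True)
class PriorSpec:
    """Per-parameter prior distributions (or Fixed values).

    Parameter domains are enforced on top of each prior's own support:
    k >= 1, ell > 0, d in [0, 1/2), rho in (0, 1].
    """

    k: object
    ell: object
    d: object
    rho: object

    def __getitem__(self, name):
        return getattr(self, name)

    @property
    def free_names(self) -> tuple:
        return tuple(n for n in PARAM_NAMES if not self[n].fixed)

    def log_density(self, values: dict) -> float:
        return sum(self[n].logpdf(values[n]) for n in self.free_names)

    def sample(self, rng) -> dict:
        return {n: self[n].sample(rng) for n in PARAM_NAMES}


# the two simulation-study prior sets
STUDY1_PRIORS = PriorSpec(k=Uniform(1, 100), ell=LogNormal(2, 1),
                          d=Exponential(10), rho=Beta(2, 5))
STUDY2_PRIORS = PriorSpec(k=LogNormal(2, 1), ell=Uniform(1, 100),
                          d=Beta(2, 5), rho=Beta(2, 5))
STUDY2_TRUE_PARAMS = ADBParams(k=5, ell=10.0, d=0.1, rho=0.1)

_DOMAIN = {"k": (1.0, np.inf), "ell": (1e-12, np.inf),
           "d": (0.0, np.nextafter(0.5, 0)), "rho": (1e-12, 1.0)}


# -- settings and trace -------------------------------------------------


@dataclass(frozen=True)
class MCMCSettings:
    chain_length: int = 1_000_000
    n_chains: int = 1
    sample_every: int = 1_000
    burn_in: float = 0.10
    seed: int = 0
    ess_threshold: float = 200.0
    gr_threshold: float = 1.01
    integer_k: bool = False
    adapt_target: float = 0.44

    def __post_init__(self):
        if not 0 <= self.burn_in < 1:
            raise ValueError("burn-in fraction must lie in [0, 1)")
        if self.chain_length < 10 * self.sample_every:
            raise ValueError("chain length must be at least 10x the sampling frequency")


@dataclass
class Trace:
    """MCMC output: thinned samples per chain plus posterior summaries."""

    chains: list  # list of DataFrames: state, posterior, likelihood, prior, k, ell, d, rho
    settings: MCMCSettings
    priors: PriorSpec
    n_likelihood_failures: int = 0
    log: list = field(default_factory=list)

    def combined(self) -> pd.DataFrame:
        """Post-burn-in samples pooled over chains."""
        parts = []
        for c in self.chains:
            cut = int(np.floor(self.settings.burn_in * len(c)))
            parts.append(c.iloc[cut:])
        return pd.concat(parts, ignore_index=True)

    def summary(self) -> pd.DataFrame:
        pooled = self.combined()
        rows = {}
        post_burn = [c.iloc[int(np.floor(self.settings.burn_in * len(c))):]
                     for c in self.chains]
        for name in PARAM_NAMES:
            x = pooled[name].to_numpy()
            lo, hi = hpd_interval(x, 0.95)
            if self.priors[name].fixed:
                rows[name] = dict(median=float(np.median(x)), hpd_lower=lo,
                                  hpd_upper=hi, ess=np.nan, rhat=np.nan)
                continue
            ess_total = float(sum(ess(c[name].to_numpy()) for c in post_burn))
            rhat = gelman_rubin([c[name].to_numpy() for c in post_burn]) \
                if len(post_burn) >= 1 else np.nan
            rows[name] = dict(median=float(np.median(x)), hpd_lower=lo,
                              hpd_upper=hi, ess=ess_total, rhat=rhat)
        return pd.DataFrame(rows).T

    def converged(self) -> bool:
        s = self.summary()
        free = list(self.priors.free_names)
        return bool((s.loc[free, "ess"] >= self.settings.ess_threshold).all()
                    and (s.loc[free, "rhat"] <= self.settings.gr_threshold).all())

    def to_tracer_log(self, path) -> None:
        """Write a Tracer-compatible tab-separated .log file."""
        df = pd.concat(self.chains, ignore_index=True)
        out = df.rename(columns={"ell": "lifetime", "d": "death"})
        cols = ["state", "posterior", "likelihood", "prior",
                "k", "lifetime", "death", "rho"]
        out[cols].to_csv(path, sep="\t", index=False)


# -- posterior summaries and diagnostics --------------------------------


def hpd_interval(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``mass`` of the empirical distribution."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n == 0:
        raise ValueError("no samples")
    n_in = max(int(np.ceil(mass * n)), 2)
    if n_in >= n:
        return float(x[0]), float(x[-1])
    widths = x[n_in - 1:] - x[:n - n_in + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + n_in - 1])


def ess(samples) -> float:
    """Autocorrelation-based effective sample size of one chain.

    Uses the FFT autocorrelation with Geyer's initial-positive-sequence
    truncation: lag pairs are summed and accumulation stops at the first
    negative pair sum.  A constant chain is degenerate and reports 0.
    """
    x = np.asarray(samples, dtype=float)
    n = len(x)
    if n < 4:
        return 0.0
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var == 0:
        return 0.0
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    acov = np.fft.irfft(np.abs(np.fft.rfft(x, nfft)) ** 2, nfft)[:n] / n
    rho = acov / acov[0]
    tau = 1.0
    for m in range(1, (n - 1) // 2):
        pair = rho[2 * m - 1] + rho[2 * m]
        if pair < 0:
            break
        tau += 2.0 * pair
    return float(min(n, n / tau))


def gelman_rubin(chains) -> float:
    """Split-chain Gelman--Rubin potential scale reduction statistic.

    Each chain is split in half; the statistic compares between- and
    within-half variances and approaches 1 as chains mix over the same
    distribution.  Chains of unequal length are truncated to the
    shortest (with a warning).
    """
    arrays = [np.asarray(c, dtype=float) for c in chains]
    n_min = min(len(a) for a in arrays)
    if any(len(a) != n_min for a in arrays):
        warnings.warn("unequal chain lengths: truncating to shortest", stacklevel=2)
        arrays = [a[:n_min] for a in arrays]
    half = n_min // 2
    if half < 2:
        return np.nan
    splits = []
    for a in arrays:
        splits.append(a[:half])
        splits.append(a[half:2 * half])
    mat = np.vstack(splits)          # m chains x n samples
    m, n = mat.shape
    within = mat.var(axis=1, ddof=1)
    w = within.mean()
    b_over_n = mat.mean(axis=1).var(ddof=1)
    if w == 0:
        return 1.0 if b_over_n == 0 else np.inf
    var_plus = (n - 1) / n * w + b_over_n
    return float(np.sqrt(var_plus / w))


# -- the sampler --------------------------------------------------------


def _log_likelihood(forest, values: dict, lik_cfg: LikelihoodConfig,
                    failures: list) -> float:
    if forest is None:
        return 0.0
    try:
        params = ADBParams(k=values["k"], ell=values["ell"],
                           d=values["d"], rho=values["rho"])
    except ValueError:
        return -np.inf
    try:
        return forest_log_likelihood(forest, params, lik_cfg)
    except (SolverError, ValueError, FloatingPointError) as exc:
        failures.append(str(exc))
        return -np.inf


def _in_domain(name: str, x: float) -> bool:
    lo, hi = _DOMAIN[name]
    return lo <= x <= hi


def _run_single_chain(forest, priors: PriorSpec, settings: MCMCSettings,
                      lik_cfg: LikelihoodConfig, rng, failures: list,
                      init: dict | None = None) -> pd.DataFrame:
    free = list(priors.free_names)
    values = None
    if init is not None:
        values = dict(init)
        log_prior = priors.log_density(values)
        log_lik = _log_likelihood(forest, values, lik_cfg, failures)
        if not np.isfinite(log_prior + log_lik):
            values = None
    if values is None:
        # start from the best of several finite prior draws; a single bad
        # draw can land in a numerically erroneous regime and stick
        best = None
        n_finite = 0
        for _ in range(200):
            cand = priors.sample(rng)
            if not all(_in_domain(n, cand[n]) for n in PARAM_NAMES):
                continue
            lp = priors.log_density(cand)
            ll = _log_likelihood(forest, cand, lik_cfg, failures)
            if np.isfinite(lp + ll):
                n_finite += 1
                if best is None or lp + ll > best[0]:
                    best = (lp + ll, cand, lp, ll)
                if n_finite >= 10:
                    break
        if best is None:
            raise RuntimeError(
                "likelihood not finite at any prior draw; try different "
                "initialization or priors")
        _, values, log_prior, log_lik = best

    if settings.integer_k and not priors["k"].fixed:
        values["k"] = float(max(1, round(values["k"])))
        log_prior = priors.log_density(values)
        log_lik = _log_likelihood(forest, values, lik_cfg, failures)

    scales = {n: _initial_scale(priors[n]) for n in free}
    acc = {n: 0 for n in free}
    tries = {n: 0 for n in free}
    burn_end = int(settings.burn_in * settings.chain_length)
    rows = []
    log_post = log_prior + log_lik
    for step in range(settings.chain_length + 1):
        if step % settings.sample_every == 0:
            rows.append((step, log_post, log_lik, log_prior,
                         values["k"], values["ell"], values["d"], values["rho"]))
        if step == settings.chain_length:
            break
        name = free[rng.integers(len(free))]
        if name == "k" and settings.integer_k:
            prop = values[name] + float(rng.choice([-2, -1, 1, 2]))
        else:
            prop = values[name] + scales[name] * rng.standard_normal()
        tries[name] += 1
        if _in_domain(name, prop):
            # only the moved parameter's prior term changes
            d_prior = priors[name].logpdf(prop) - priors[name].logpdf(values[name])
            if np.isfinite(d_prior):
                cand = dict(values)
                cand[name] = prop
                cand_lik = _log_likelihood(forest, cand, lik_cfg, failures)
                log_alpha = d_prior + cand_lik - log_lik
                if np.log(rng.random()) < log_alpha:
                    values = cand
                    log_prior += d_prior
                    log_lik = cand_lik
                    log_post = log_prior + log_lik
                    acc[name] += 1
        # adapt proposal widths during burn-in only
        if step < burn_end and tries[name] % 50 == 0:
            rate = acc[name] / tries[name]
            scales[name] *= float(np.exp(np.clip(rate - settings.adapt_target, -0.5, 0.5)))
    return pd.DataFrame(rows, columns=["state", "posterior", "likelihood",
                                       "prior", "k", "ell", "d", "rho"])


def _initial_scale(prior) -> float:
    try:
        sd = float(prior.dist.std())
    except Exception:
        sd = 1.0
    if not np.isfinite(sd) or sd <= 0:
        sd = 1.0
    return 0.3 * sd


def run_mcmc(data, priors: PriorSpec, settings: MCMCSettings | None = None,
             lik_cfg: LikelihoodConfig | None = None,
             init: dict | None = None) -> Trace:
    """Sample the posterior of (k, ell, d, rho) for a tree or forest.

    ``data`` may be a TimeTree, a Forest, or None (prior-only sampling,
    useful for validating the sampler).  Fixed priors pin parameters;
    per-tree fixed sampling probabilities on the forest override rho.
    Reproducible given ``settings.seed``.
    """
    settings = settings or MCMCSettings()
    lik_cfg = lik_cfg or LikelihoodConfig()
    if isinstance(data, TimeTree):
        data = Forest([data], conditioning=lik_cfg.conditioning)
    if data is not None and lik_cfg.warn_fragile:
        lik_cfg = replace(lik_cfg, warn_fragile=False)  # warn once, below

    failures: list = []
    chains = []
    root = np.random.SeedSequence(settings.seed)
    for child in root.spawn(settings.n_chains):
        rng = np.random.default_rng(child)
        chains.append(_run_single_chain(data, priors, settings, lik_cfg,
                                        rng, failures, init=init))
    trace = Trace(chains=chains, settings=settings, priors=priors,
                  n_likelihood_failures=len(failures))
    if data is not None:
        med = {n: float(np.median(trace.combined()[n])) for n in PARAM_NAMES}
        try:
            trace.log.extend(check_fragile_regime(ADBParams(**{
                "k": med["k"], "ell": med["ell"], "d": med["d"], "rho": med["rho"]})))
        except ValueError:
            pass
    if failures:
        trace.log.append(f"{len(failures)} likelihood evaluations failed and were rejected")
    return trace


# -- simulation-study harness -------------------------------------------


@dataclass
class StudyReport:
    """Per-simulation truths, posterior summaries and accuracy metrics."""

    table: pd.DataFrame          # one row per (simulation, parameter)
    n_simulations: int
    n_converged: int
    failed_runs: list

    def metrics(self) -> pd.DataFrame:
        """Relative bias, error and HPD width (medians over converged
        simulations) plus 95% HPD coverage counts per parameter."""
        conv = self.table[self.table.converged]
        rows = {}
        for name, g in conv.groupby("parameter"):
            rel = (g["median"] - g["truth"]) / g["truth"]
            rows[name] = dict(
                rel_bias=float(rel.median()),
                rel_error=float(rel.abs().median()),
                rel_hpd_width=float(((g.hpd_upper - g.hpd_lower) / g.truth).median()),
                coverage=int(((g.hpd_lower <= g.truth) & (g.truth <= g.hpd_upper)).sum()),
                n=len(g),
            )
        return pd.DataFrame(rows).T


def simulation_study(n_sims: int, n_tips: int,
                     inference_priors: PriorSpec,
                     simulation_priors: PriorSpec | None = None,
                     true_params: ADBParams | None = None,
                     settings: MCMCSettings | None = None,
                     lik_cfg: LikelihoodConfig | None = None,
                     seed: int = 0,
                     min_rho: float = 0.01) -> StudyReport:
    """Simulate trees, infer parameters, and score the recovery.

    Truths are drawn per simulation from ``simulation_priors`` (draws
    with d >= 1/2 or rho below ``min_rho`` are redrawn) or held at
    ``true_params``.  Each tree is simulated with a fixed tip count,
    inference conditions on its (known) origin, and non-converged runs
    are excluded from the metrics but counted.
    """
    if (simulation_priors is None) == (true_params is None):
        raise ValueError("provide exactly one of simulation_priors or true_params")
    settings = settings or MCMCSettings()
    lik_cfg = lik_cfg or LikelihoodConfig(conditioning="origin")
    root = np.random.SeedSequence(seed)
    rows, failed = [], []
    n_converged = 0
    for i, child in enumerate(root.spawn(n_sims)):
        rng = np.random.default_rng(child)
        if true_params is not None:
            truth = true_params
        else:
            while True:
                draw = simulation_priors.sample(rng)
                try:
                    truth = ADBParams(k=max(draw["k"], 1.0), ell=draw["ell"],
                                      d=draw["d"], rho=draw["rho"])
                except ValueError:
                    continue
                if truth.rho >= min_rho:
                    break
        try:
            tree = simulate_reconstructed_tree(
                SimConfig(params=truth, n_tips=n_tips), seed=rng)
            chain_settings = replace(settings, seed=int(rng.integers(2 ** 31)))
            trace = run_mcmc(tree, inference_priors, chain_settings, lik_cfg)
        except Exception as exc:  # failures recorded, not raised
            failed.append((i, str(exc)))
            continue
        summ = trace.summary()
        converged = trace.converged()
        n_converged += converged
        for name in PARAM_NAMES:
            rows.append(dict(
                simulation=i, parameter=name, truth=getattr(truth, name),
                median=summ.loc[name, "median"],
                hpd_lower=summ.loc[name, "hpd_lower"],
                hpd_upper=summ.loc[name, "hpd_upper"],
                ess=summ.loc[name, "ess"], rhat=summ.loc[name, "rhat"],
                converged=converged))
    return StudyReport(table=pd.DataFrame(rows), n_simulations=n_sims,
                       n_converged=n_converged, failed_runs=failed)
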