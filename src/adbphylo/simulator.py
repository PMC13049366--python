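"""Forward-time simulation of trees under age-dependent branching.

Starting from a single cell, lifetimes are drawn i.i.d. from
Gamma(k, theta); at the end of its lifetime a cell dies with probability
``d`` and divides into two daughters otherwise.  Simulation is
event-driven (a priority queue of cell-termination times, no time
discretization) and stops either at a fixed origin time or, in
fixed-tip-count mode, when the number of living cells reaches the target
``ceil(n / rho)`` so the rho-sampled reconstructed tree has about n tips.
The simple sampling approach (SSA) stops the first time the target count
is reached; the general sampling approach (GSA) samples the stopping time
uniformly (weighted by duration) among all periods during which the count
equals the target, which removes the origin-time bias SSA incurs at high
death probabilities.

Also provided are the expected lineages-through-time curves: the expected
number of lineages ``mu(t, tau)`` descending from a cell that originated
at time ``tau`` satisfies the renewal equation

    mu(t, tau) = 1 - F(tau - t) + 2 (1-d) Int_t^tau f(tau - w) mu(t, w) dw

for the complete tree, and the reconstructed-tree variant replaces the
first term by ``(1 - P0(tau)) (1 - F(tau - t))`` so only lineages with
sampled descendants are counted.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from .densities import solve_p0, volterra_fixed_point
from .lifetime import ADBParams, lifetime_cdf, lifetime_pdf
from .trees import CompleteTree, TimeTree, extract_subtree

__all__ = [
    "SimConfig",
    "LTTCurve",
    "UnobservableTreeError",
    "simulate_complete_tree",
    "simulate_reconstructed_tree",
    "prune_and_sample",
    "expected_ltt",
    "sample_ltt",
]

MAX_EVENTS = 2_000_000


class UnobservableTreeError(RuntimeError):
    """Fewer than two tips survive sampling; no reconstructed tree exists."""


@dataclass(frozen=True)
class SimConfig:
    """Stopping mode, sampling approach and parameters of one simulation.

    Exactly one of ``n_tips`` (fixed tip count of the reconstructed tree)
    or ``t_or`` (fixed origin time) must be set.  ``method`` is "ssa" or
    "gsa" (fixed-tips mode only).  ``condition_on_survival`` retries
    fixed-origin simulations in which the population dies out or leaves
    no sampled cell.
    """

    params: ADBParams
    n_tips: int | None = None
    t_or: float | None = None
    method: str = "ssa"
    condition_on_survival: bool = True
    retry_cap: int = 1000
    gsa_growth_factor: float = 3.0

    def __post_init__(self):
        if (self.n_tips is None) == (self.t_or is None):
            raise ValueError("set exactly one of n_tips or t_or")
        if self.n_tips is not None and self.n_tips < 2:
            raise ValueError("n_tips must be at least 2")
        if self.t_or is not None and self.t_or <= 0:
            raise ValueError("t_or must be positive")
        if self.method not in ("ssa", "gsa"):
            raise ValueError(f"unknown sampling approach {self.method!r}")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _simulate_history(cfg: SimConfig, rng: np.random.Generator):
    """Run the event queue; return (cells, T_end) or None if unusable.

    ``cells`` is a list of records [birth, term, fate, parent] in forward
    time; ``fate`` is "division", "death", or None (still alive when the
    simulation stopped).  T_end is the forward time of the present.
    """
    p = cfg.params
    k, theta, d = p.k, p.theta, p.d
    birth = [0.0]
    term = [rng.gamma(k, theta)]
    fate: list = [None]
    parent = [-1]
    heap = [(term[0], 0)]
    alive = 1

    if cfg.t_or is not None:
        t_end = cfg.t_or
        while heap and heap[0][0] <= t_end:
            if len(birth) > MAX_EVENTS:
                raise RuntimeError("simulation exceeded the event cap")
            t_ev, i = heapq.heappop(heap)
            if rng.random() < d:
                fate[i] = "death"
                alive -= 1
            else:
                fate[i] = "division"
                alive += 1
                for _ in range(2):
                    j = len(birth)
                    birth.append(t_ev)
                    term.append(t_ev + rng.gamma(k, theta))
                    fate.append(None)
                    parent.append(i)
                    heapq.heappush(heap, (term[j], j))
        if alive == 0 and cfg.condition_on_survival:
            return None
        return (birth, term, fate, parent), t_end

    target = int(np.ceil(cfg.n_tips / p.rho))
    stop_count = (target if cfg.method == "ssa"
                  else max(int(np.ceil(cfg.gsa_growth_factor * target)), target + 20))
    # trajectory of (event time, alive count after the event) for GSA
    traj = [(0.0, 1)]
    t_end = None
    while heap:
        if len(birth) > MAX_EVENTS:
            raise RuntimeError("simulation exceeded the event cap")
        t_ev, i = heapq.heappop(heap)
        if rng.random() < d:
            fate[i] = "death"
            alive -= 1
        else:
            fate[i] = "division"
            alive += 1
            for _ in range(2):
                j = len(birth)
                birth.append(t_ev)
                term.append(t_ev + rng.gamma(k, theta))
                fate.append(None)
                parent.append(i)
                heapq.heappush(heap, (term[j], j))
        traj.append((t_ev, alive))
        if alive == 0:
            return None
        if alive >= stop_count:
            t_end = t_ev
            break
    if t_end is None:
        return None

    if cfg.method == "ssa":
        return (birth, term, fate, parent), t_end

    # GSA: choose among all periods with exactly `target` living cells,
    # weighted by duration, then a uniform time within the chosen period.
    starts, durations = [], []
    for (t0, a0), (t1, _) in zip(traj[:-1], traj[1:]):
        if a0 == target and t1 > t0:
            starts.append(t0)
            durations.append(t1 - t0)
    if not starts:
        return None
    durations = np.asarray(durations)
    idx = rng.choice(len(starts), p=durations / durations.sum())
    t_present = starts[idx] + rng.random() * durations[idx]
    return (birth, term, fate, parent), t_present


def _build_complete_tree(history, t_end: float, rho: float,
                         rng: np.random.Generator) -> CompleteTree:
    birth, term, fate, parent = history
    keep = [i for i in range(len(birth)) if birth[i] <= t_end]
    index = {c: j for j, c in enumerate(keep)}
    n = len(keep)
    new_parent = np.full(n, -1, dtype=int)
    children: list[list[int]] = [[] for _ in range(n)]
    times = np.zeros(n)
    events: list[str] = [""] * n
    sampled = np.zeros(n, dtype=bool)
    for j, c in enumerate(keep):
        p = parent[c]
        if p >= 0:
            new_parent[j] = index[p]
            children[index[p]].append(j)
        if term[c] <= t_end and fate[c] == "division":
            times[j] = t_end - term[c]
            events[j] = "division"
        elif term[c] <= t_end and fate[c] == "death":
            times[j] = t_end - term[c]
            events[j] = "death"
        else:
            times[j] = 0.0
            events[j] = "extant"
            sampled[j] = rng.random() < rho
    tree = CompleteTree(new_parent, [tuple(c) for c in children], times,
                        events, sampled=sampled, t_or=t_end - birth[0])
    return tree


def simulate_complete_tree(cfg: SimConfig, seed=None) -> CompleteTree:
    """Simulate one complete population tree (divisions, deaths, censored
    extant cells with rho-sampling flags).  Deterministic given a seed."""
    rng = _as_rng(seed)
    for _ in range(cfg.retry_cap):
        out = _simulate_history(cfg, rng)
        if out is None:
            continue
        history, t_end = out
        tree = _build_complete_tree(history, t_end, cfg.params.rho, rng)
        if cfg.t_or is not None and cfg.condition_on_survival \
                and len(tree.extant_tip_indices) == 0:
            continue
        return tree
    raise RuntimeError(f"no usable simulation in {cfg.retry_cap} attempts "
                       "(population went extinct every time)")


def prune_and_sample(tree: CompleteTree, rho: float | None = None,
                     seed=None, resample: bool = False,
                     retry_cap: int = 1000) -> TimeTree:
    """Reconstructed tree: prune dead cells and keep each extant cell
    independently with probability rho.

    With ``rho=None`` the sampling flags already on the tree are used.
    Fewer than 2 sampled tips raises :class:`UnobservableTreeError`
    unless ``resample`` re-draws the sample (requires ``rho``).
    """
    rng = _as_rng(seed)
    extant = tree.extant_tip_indices
    attempts = retry_cap if (resample and rho is not None) else 1
    for _ in range(attempts):
        if rho is None:
            keep = extant[tree.sampled[extant]]
        else:
            keep = extant[rng.random(len(extant)) < rho]
        if len(keep) >= 2:
            return extract_subtree(tree, keep)
    raise UnobservableTreeError(
        f"only {len(keep)} of {len(extant)} extant tips sampled; "
        "a reconstructed tree needs at least 2")


def simulate_reconstructed_tree(cfg: SimConfig, seed=None) -> TimeTree:
    """Simulate a complete tree and return its rho-sampled reconstruction,
    retrying until at least two tips are sampled."""
    rng = _as_rng(seed)
    for _ in range(cfg.retry_cap):
        tree = simulate_complete_tree(cfg, rng)
        try:
            return prune_and_sample(tree, rho=None)
        except UnobservableTreeError:
            continue
    raise RuntimeError(f"no observable tree in {cfg.retry_cap} attempts")


# -- expected lineages through time -------------------------------------


@dataclass
class LTTCurve:
    """Expected lineage counts mu(t, tau) on a grid of times t."""

    times: np.ndarray        # backward times, ascending, in [0, tau]
    values: np.ndarray
    tau: float
    variant: str             # "complete" or "reconstructed"
    params: ADBParams

    def at(self, t):
        return np.interp(t, self.times, self.values)


def expected_ltt(params: ADBParams, tau: float, variant: str = "reconstructed",
                 t_eval=None, m: int = 1024, tol: float = 1e-10,
                 max_iter: int = 500) -> LTTCurve:
    """Solve the renewal equation for the expected LTT curve.

    For the complete tree the curve depends on ``tau - t`` only, so a
    single Volterra solve suffices; the reconstructed variant couples
    ``t`` and ``tau`` through P0 and is solved per requested time point.
    The expected final population (or sample-ancestral lineage) size is
    the value at t = 0.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if variant not in ("complete", "reconstructed"):
        raise ValueError(f"unknown variant {variant!r}")
    k, theta, d = params.k, params.theta, params.d

    if variant == "complete":
        v = np.linspace(0.0, tau, m)
        f_vals = lifetime_pdf(v, k, theta)
        source = 1.0 - lifetime_cdf(v, k, theta)
        nu, _, _ = volterra_fixed_point(source, f_vals, v[1] - v[0],
                                        lambda x: 2.0 * (1.0 - d) * x,
                                        tol=tol, max_iter=max_iter)
        if t_eval is None:
            times = tau - v[::-1]
            values = nu[::-1]
        else:
            times = np.asarray(t_eval, dtype=float)
            values = np.interp(tau - times, v, nu)
        return LTTCurve(np.asarray(times), np.asarray(values), tau, variant, params)

    grid = solve_p0(params, tau, m=max(m, 256), warn_fragile=False)
    if t_eval is None:
        t_eval = np.linspace(0.0, tau, 101)
    times = np.asarray(t_eval, dtype=float)
    values = np.empty_like(times)
    for j, t in enumerate(times):
        span = tau - t
        if span <= 0:
            values[j] = 1.0 - float(grid.p0_at(tau))
            continue
        m_sub = max(128, int(np.ceil(span / grid.h)) + 1)
        u = np.linspace(0.0, span, m_sub)
        f_vals = lifetime_pdf(u, k, theta)
        source = (1.0 - grid.p0_at(t + u)) * (1.0 - lifetime_cdf(u, k, theta))
        mu, _, _ = volterra_fixed_point(source, f_vals, u[1] - u[0],
                                        lambda x: 2.0 * (1.0 - d) * x,
                                        tol=tol, max_iter=max_iter)
        values[j] = mu[-1]
    return LTTCurve(times, values, tau, variant, params)


def sample_ltt(tree: CompleteTree, times) -> np.ndarray:
    """Number of ancestral lineages of the sampled tips at given backward
    times (the empirical reconstructed LTT; 0 everywhere if nothing was
    sampled)."""
    times = np.asarray(times, dtype=float)
    n_desc = np.zeros(tree.n_nodes, dtype=int)
    for i in tree.postorder():
        if tree.children[i]:
            n_desc[i] = sum(n_desc[c] for c in tree.children[i])
        else:
            n_desc[i] = int(tree.events[i] == "extant" and tree.sampled[i])
    counts = np.zeros(len(times), dtype=int)
    for i in range(tree.n_nodes):
        if n_desc[i] == 0:
            continue
        lo = tree.times[i]
        hi = tree.t_or if tree.parent[i] < 0 else tree.times[tree.parent[i]]
        # lineage occupies (lo, hi]; count t in [lo, hi)
        counts += (times >= lo) & (times < hi)
    return counts
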