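"""Phylodynamic tree and forest log-likelihoods.

Conditioned on the origin time, the density of a reconstructed tree is

    P(Tr | t_or) = 1 / (1 - P0(t_or)) * prod_{e in E} P1(t_e)
                                      * prod_{e in I} b(s_e, t_e),

where E are the external edges, I the internal edges including the
origin-to-root stem, P1 the single-sampled-descendant probability and b
the internal-edge density.  Conditioning on the root instead multiplies
the two origin-conditioned subtree densities with ``t_or = t_root``; with
the shared edge sets this amounts to squaring the survival factor and
dropping the stem edge.  For a labelled (tip-exchangeable) tree the
density is multiplied by ``2^(n-1) / n!``.

With exponential lifetimes (k = 1) the model collapses to the
constant-rate birth--death model with extant rho-sampling, whose
likelihood has a closed form; it is provided here as an independent
oracle for validating the grid solvers.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .densities import (DEFAULT_GRID_NODES, DEFAULT_MAX_ITER, DEFAULT_TOL,
                        DensityGrid, mean_p0_over_interval, solve_edge_density_exact,
                        solve_p0, solve_p1)
from .edge_approx import ApproxConfig, approx_edge_log_densities
from .lifetime import ADBParams
from .trees import Forest, TimeTree, edge_intervals

__all__ = [
    "LikelihoodConfig",
    "BDParams",
    "tree_log_likelihood",
    "forest_log_likelihood",
    "bd_log_likelihood_analytic",
    "bd_p0",
    "bd_p1",
    "clear_grid_cache",
]

HORIZON_PAD = 1.05


@dataclass(frozen=True)
class LikelihoodConfig:
    """Settings for likelihood evaluation.

    conditioning : "origin" (requires an origin time on the tree or in
        ``origin_time``) or "root" (first division).
    backend : "approx" uses the scalable series approximation for internal
        edges; "exact" solves the per-edge integral equation.
    labelled : include the ``2^(n-1)/n!`` labelled-tree factor.
    """

    conditioning: str = "origin"
    backend: str = "approx"
    labelled: bool = True
    origin_time: float | None = None
    approx: ApproxConfig = field(default_factory=ApproxConfig)
    grid_m: int = DEFAULT_GRID_NODES
    grid_h: float | None = None
    tol: float = DEFAULT_TOL
    max_iter: int = DEFAULT_MAX_ITER
    warn_fragile: bool = True

    def __post_init__(self):
        if self.conditioning not in ("origin", "root"):
            raise ValueError(f"unknown conditioning {self.conditioning!r}")
        if self.backend not in ("exact", "approx"):
            raise ValueError(f"unknown backend {self.backend!r}")


@dataclass(frozen=True)
class BDParams:
    """Constant-rate birth--death parameters for the k = 1 oracle."""

    lam: float
    mu: float
    rho: float

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("birth rate must be positive")
        if self.mu < 0:
            raise ValueError("death rate must be non-negative")
        if not 0 < self.rho <= 1:
            raise ValueError("sampling probability must lie in (0, 1]")


# -- grid cache ---------------------------------------------------------

_GRID_CACHE: OrderedDict = OrderedDict()
_GRID_CACHE_SIZE = 32


def clear_grid_cache() -> None:
    _GRID_CACHE.clear()


def _get_grid(params: ADBParams, horizon: float, cfg: LikelihoodConfig) -> DensityGrid:
    key = (params.k, params.ell, params.d, params.rho, round(horizon, 12),
           cfg.grid_m, cfg.grid_h)
    grid = _GRID_CACHE.get(key)
    if grid is None:
        grid = solve_p0(params, horizon, h=cfg.grid_h, m=cfg.grid_m,
                        tol=cfg.tol, max_iter=cfg.max_iter,
                        warn_fragile=cfg.warn_fragile)
        solve_p1(params, grid, tol=cfg.tol, max_iter=cfg.max_iter)
        _GRID_CACHE[key] = grid
        if len(_GRID_CACHE) > _GRID_CACHE_SIZE:
            _GRID_CACHE.popitem(last=False)
    return grid


# -- ADB likelihood -----------------------------------------------------


def _conditioning_time(tree: TimeTree, cfg: LikelihoodConfig) -> float:
    if cfg.conditioning == "root":
        return tree.t_root
    t_or = cfg.origin_time if cfg.origin_time is not None else tree.t_or
    if t_or is None:
        raise ValueError("origin conditioning requires an origin time "
                         "(stem edge in the Newick or cfg.origin_time)")
    if t_or < tree.t_root:
        raise ValueError("origin time precedes root time")
    return float(t_or)


def _internal_log_densities(params: ADBParams, internal: list[tuple],
                            grid: DensityGrid, cfg: LikelihoodConfig) -> float:
    if not internal:
        return 0.0
    if cfg.backend == "exact":
        total = 0.0
        for s, t in internal:
            b = solve_edge_density_exact(params, s, t, grid,
                                         tol=cfg.tol, max_iter=cfg.max_iter)
            if b <= 0:
                return -np.inf
            total += np.log(b)
        return float(total)
    s = np.array([e[0] for e in internal])
    t = np.array([e[1] for e in internal])
    p0bar = mean_p0_over_interval(grid, s, t)
    return float(np.sum(approx_edge_log_densities(params, s, t, p0bar, cfg.approx)))


def tree_log_likelihood(tree: TimeTree, params: ADBParams,
                        cfg: LikelihoodConfig | None = None,
                        grid: DensityGrid | None = None) -> float:
    """Log-likelihood of a reconstructed tree under the ADB process."""
    cfg = cfg or LikelihoodConfig()
    t_cond = _conditioning_time(tree, cfg)
    if grid is None:
        grid = _get_grid(params, HORIZON_PAD * t_cond, cfg)
    cached = getattr(tree, "_edge_cache", None)
    if cached is None:
        cached = edge_intervals(tree)
        tree._edge_cache = cached
    external, internal = cached
    if cfg.conditioning == "origin":
        internal = internal + [(tree.t_root, t_cond)]
        n_survival_factors = 1
    else:
        n_survival_factors = 2

    p0_cond = float(grid.p0_at(t_cond))
    if p0_cond >= 1.0 - 1e-14:
        raise ValueError("conditioning on survival impossible: P0 at the "
                         f"conditioning time is {p0_cond}")
    log_l = -n_survival_factors * np.log1p(-p0_cond)

    t_ext = np.array([e[1] for e in external])
    p1 = grid.p1_at(t_ext)
    with np.errstate(divide="ignore"):
        log_l += float(np.sum(np.log(p1)))
    log_l += _internal_log_densities(params, internal, grid, cfg)

    if cfg.labelled:
        n = tree.n_tips
        log_l += (n - 1) * np.log(2.0) - gammaln(n + 1)
    return float(log_l)


def forest_log_likelihood(forest: Forest, params: ADBParams,
                          cfg: LikelihoodConfig | None = None) -> float:
    """Joint log-likelihood of a forest sharing one parameter set.

    Trees are independent draws from the same process, so the forest
    log-likelihood is the sum of per-tree terms.  Per-tree fixed sampling
    probabilities (e.g. observed per-colony sampling fractions) override
    the shared rho; trees sharing a rho also share one solved grid.
    """
    cfg = cfg or LikelihoodConfig()
    base_cfg = cfg
    if cfg.conditioning != forest.conditioning:
        base_cfg = LikelihoodConfig(**{**cfg.__dict__, "conditioning": forest.conditioning})

    groups: dict[float, list[int]] = {}
    for i, tree in enumerate(forest.trees):
        rho = params.rho
        if forest.rho_per_tree is not None and forest.rho_per_tree[i] is not None:
            rho = float(forest.rho_per_tree[i])
        groups.setdefault(rho, []).append(i)

    total = 0.0
    for rho, indices in groups.items():
        p = params.with_(rho=rho)
        horizon = HORIZON_PAD * max(
            _conditioning_time(forest.trees[i], base_cfg) for i in indices)
        grid = _get_grid(p, horizon, base_cfg)
        for i in indices:
            total += tree_log_likelihood(forest.trees[i], p, base_cfg, grid=grid)
    return float(total)


# -- analytic birth-death oracle (k = 1) --------------------------------


def _bd_denominator(bd: BDParams, t):
    r = bd.lam - bd.mu
    return bd.rho * bd.lam + (bd.lam * (1.0 - bd.rho) - bd.mu) * np.exp(-r * np.asarray(t, dtype=float))


def bd_p0(bd: BDParams, t):
    """Probability of no sampled descendants under constant-rate
    birth--death with extant rho-sampling."""
    r = bd.lam - bd.mu
    return 1.0 - bd.rho * r / _bd_denominator(bd, t)


def bd_p1(bd: BDParams, t):
    """Probability of exactly one sampled descendant under the same model."""
    r = bd.lam - bd.mu
    t = np.asarray(t, dtype=float)
    return bd.rho * r * r * np.exp(-r * t) / _bd_denominator(bd, t) ** 2


def bd_log_likelihood_analytic(tree: TimeTree, bd: BDParams,
                               cfg: LikelihoodConfig | None = None) -> float:
    """Closed-form constant-rate birth--death-sampling log-likelihood.

    Along an edge the propagator with unsampled side branches is
    ``p1(t) / p1(s)`` and each division contributes a rate factor, so the
    edge products telescope into a product of ``p1`` at the internal node
    times.  Conditioning and labelling conventions match
    :func:`tree_log_likelihood`.
    """
    cfg = cfg or LikelihoodConfig()
    t_cond = _conditioning_time(tree, cfg)
    node_times = np.array([tree.times[i] for i in range(tree.n_nodes)
                           if tree.children[i]])
    n = tree.n_tips
    if cfg.conditioning == "origin":
        log_l = (-np.log1p(-bd_p0(bd, t_cond))
                 + (n - 1) * np.log(bd.lam)
                 + np.log(bd_p1(bd, t_cond))
                 + float(np.sum(np.log(bd_p1(bd, node_times)))))
    else:
        non_root = np.array([tree.times[i] for i in range(tree.n_nodes)
                             if tree.children[i] and i != tree.root])
        log_l = (-2.0 * np.log1p(-bd_p0(bd, t_cond))
                 + (n - 2) * np.log(bd.lam)
                 + 2.0 * np.log(bd_p1(bd, tree.t_root))
                 + float(np.sum(np.log(bd_p1(bd, non_root)))))
    if cfg.labelled:
        log_l += (n - 1) * np.log(2.0) - gammaln(n + 1)
    return float(log_l)
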