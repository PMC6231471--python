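"""Composite-likelihood fitting of IM models and model comparison.

The optimizer is a multi-start cycle of conditional one-dimensional
maximizations (bounded Brent searches) over log10-scaled parameters.
Within a run, every expected-SFS evaluation reuses the same Monte-Carlo
seed (common random numbers), which makes the objective deterministic in
the parameters and the cycle's best likelihood monotone non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import optimize

from ..core import GenotypeMatrix
from .model import IMParams, ModelSpec
from .sfs import FoldedSFS, composite_loglik, expected_sfs


@dataclass
class IMFit:
    """Result of one model fit."""

    model: ModelSpec
    params: IMParams
    loglik: float
    trace: list[float] = field(default_factory=list)
    n_free: int = 0
    converged: bool = True
    aic: float = float("nan")
    akaike_weight: float = float("nan")
    ci: dict[str, tuple[float, float]] | None = None

    def free_values(self) -> dict[str, float]:
        out = {}
        for name, _ in self.model.free:
            if name == "migrants":
                off = ~np.eye(3, dtype=bool)
                out[name] = float(self.params.migrants[off].mean())
            else:
                out[name] = float(getattr(self.params, name))
        return out


def _apply_free(base: IMParams, model: ModelSpec, theta_log10: np.ndarray) -> IMParams:
    kw: dict = {}
    for (name, _), v in zip(model.free, 10.0 ** np.asarray(theta_log10)):
        if name == "migrants":
            m = np.full((3, 3), v)
            np.fill_diagonal(m, 0.0)
            kw["migrants"] = m
        else:
            kw[name] = v
    kw.setdefault("growth_mode", model.growth_mode)
    return base.replace(**kw)


def fit_im(
    obs: FoldedSFS,
    model: ModelSpec,
    base_params: IMParams,
    n_runs: int = 50,
    cycles: int = 10,
    n_sims: int = 10_000,
    seed: int = 0,
    brent_iters: int = 10,
    init: Sequence[float] | None = None,
) -> IMFit:
    """Maximize the composite likelihood of ``obs`` under one IM model.

    ``base_params`` supplies the fixed parameters; entries of ``model.free``
    are optimized within their log10 bounds from ``n_runs`` random
    log-uniform starts (``init`` warm-starts the first run with the given
    log10 values). With zero free parameters the fit evaluates and returns
    the base parameterization.
    """
    if obs.n_snps <= 0:
        raise ValueError("observed SFS is empty")
    sizes = list(obs.sizes)
    rng = np.random.default_rng(seed)
    order = model.branching_order

    if model.n_free == 0:
        p = base_params.replace(growth_mode=model.growth_mode)
        exp = expected_sfs(p, sizes, n_sims, int(rng.integers(2**31 - 1)), order)
        ll = composite_loglik(obs, exp)
        return IMFit(model, p, ll, [ll], 0, True)

    bounds = np.array([b for _, b in model.free], dtype=float)
    best_ll = -np.inf
    best_theta = None
    best_trace: list[float] = []
    improved = False
    for run in range(n_runs):
        run_seed = int(rng.integers(2**31 - 1))
        if run == 0 and init is not None:
            theta = np.clip(np.asarray(init, dtype=float),
                            bounds[:, 0], bounds[:, 1])
        else:
            theta = rng.uniform(bounds[:, 0], bounds[:, 1])

        def objective(th: np.ndarray) -> float:
            try:
                p = _apply_free(base_params, model, th)
            except ValueError:  # e.g. proposed t_recent >= t_root
                return -1e12
            exp = expected_sfs(p, sizes, n_sims, run_seed, order)
            return composite_loglik(obs, exp)

        for _ in range(100):
            if objective(theta) > -1e12:
                break
            theta = rng.uniform(bounds[:, 0], bounds[:, 1])
        ll = objective(theta)
        ll0 = ll
        trace = [ll]
        # sizes and times are strongly correlated through the coalescent
        # timescale; a joint log-scale direction over them (migration in
        # migrants/generation is scale-free) lets each cycle slide along
        # the ridge instead of inching one coordinate at a time
        scale_idx = np.array([j for j, (name, _) in enumerate(model.free)
                              if name.startswith(("ne_", "t_"))])
        for _cycle in range(cycles):
            moved = False
            for j in range(len(theta)):

                def neg1d(x: float, j=j) -> float:
                    th = theta.copy()
                    th[j] = x
                    return -objective(th)

                res = optimize.minimize_scalar(
                    neg1d, bounds=tuple(bounds[j]), method="bounded",
                    options={"maxiter": brent_iters, "xatol": 0.02})
                if -res.fun > ll + 1e-9:
                    theta[j] = res.x
                    ll = -res.fun
                    moved = True
            if scale_idx.size >= 2:

                def neg_scale(c: float) -> float:
                    th = theta.copy()
                    th[scale_idx] = np.clip(th[scale_idx] + c,
                                            bounds[scale_idx, 0],
                                            bounds[scale_idx, 1])
                    return -objective(th)

                res = optimize.minimize_scalar(
                    neg_scale, bounds=(-0.6, 0.6), method="bounded",
                    options={"maxiter": brent_iters, "xatol": 0.01})
                if -res.fun > ll + 1e-9:
                    theta[scale_idx] = np.clip(theta[scale_idx] + res.x,
                                               bounds[scale_idx, 0],
                                               bounds[scale_idx, 1])
                    ll = -res.fun
                    moved = True
            trace.append(ll)
            if not moved:
                break
        if ll > ll0 + 1e-9:
            improved = True
        if ll > best_ll:
            best_ll, best_theta, best_trace = ll, theta.copy(), trace
    params = _apply_free(base_params, model, best_theta)
    fit = IMFit(model, params, best_ll, best_trace, model.n_free,
                converged=improved)
    fit.aic = 2.0 * model.n_free - 2.0 * best_ll
    return fit


def akaike_weights(fits: Sequence[tuple[float, int]] | Sequence[IMFit]) -> np.ndarray:
    """Akaike weights w_i = exp(-dAIC_i/2) / sum_j exp(-dAIC_j/2)."""
    if len(fits) < 2:
        raise ValueError("need at least two models to compare")
    if isinstance(fits[0], IMFit):
        aic = np.array([2.0 * f.n_free - 2.0 * f.loglik for f in fits])
    else:
        aic = np.array([2.0 * k - 2.0 * ll for ll, k in fits])
    delta = aic - aic.min()
    w = np.exp(-delta / 2.0)
    w = w / w.sum()
    if isinstance(fits[0], IMFit):
        for f, (a, wi) in zip(fits, zip(aic, w)):
            f.aic = float(a)
            f.akaike_weight = float(wi)
    return w


def block_bootstrap_ci(
    G: GenotypeMatrix,
    estimator: Callable[[GenotypeMatrix], Mapping[str, float]],
    n_boot: int = 100,
    level: float = 0.95,
    seed: int = 0,
) -> dict[str, tuple[float, float]]:
    """Percentile CIs from fragment-level (block) bootstrap of the loci.

    Fragments (``G.fragments``) are the independent genomic blocks; each
    bootstrap dataset resamples fragments with replacement and re-runs
    ``estimator``, which returns a name -> value mapping.
    """
    if G.fragments is None:
        raise ValueError("genotype matrix carries no fragment labels")
    frags = np.asarray(G.fragments)
    uniq = np.unique(frags)
    if uniq.size < 2:
        raise ValueError("need at least two fragments to bootstrap")
    members = {f: np.flatnonzero(frags == f) for f in uniq}
    rng = np.random.default_rng(seed)
    draws: dict[str, list[float]] = {}
    for _ in range(n_boot):
        chosen = rng.choice(uniq, size=uniq.size, replace=True)
        idx = np.concatenate([members[f] for f in chosen])
        est = estimator(G.take_loci(idx))
        for k, v in est.items():
            draws.setdefault(k, []).append(float(v))
    lo = (1.0 - level) / 2.0
    return {
        k: (float(np.quantile(v, lo)), float(np.quantile(v, 1.0 - lo)))
        for k, v in draws.items()
    }
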