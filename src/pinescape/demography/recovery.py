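"""Simulation-study harness: parameter recovery and model-selection trials.

One trial simulates a SNP panel under a known IM truth, builds the folded
joint SFS, fits candidate branching orders, compares them by Akaike weight,
and computes fragment-bootstrap percentile CIs for the free parameters of
the generating model (each bootstrap dataset refits from a warm start with
its own Monte-Carlo seed, so CI width reflects both data resampling and
simulation noise). The scale of the conditional SFS is anchored by keeping
one effective size fixed at its true value — with segregating-sites-only
data the spectrum identifies parameter ratios, so one parameter must be
pinned, as is standard for SNP-only SFS inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fit import IMFit, akaike_weights, fit_im
from .model import BRANCHING_ORDERS, IMParams, ModelSpec
from .sfs import FoldedSFS, composite_loglik, expected_sfs, project_folded_sfs
from .simulate import simulate_im

#: default free-parameter bounds (log10) with ne_north anchoring the scale
DEFAULT_FREE: tuple[tuple[str, tuple[float, float]], ...] = (
    ("ne_south", (3.0, 5.0)),
    ("ne_west", (3.0, 5.0)),
    ("t_root", (3.8, 5.3)),
    ("t_recent", (3.0, 4.6)),
    ("migrants", (-0.7, 1.3)),
)


def default_truth() -> IMParams:
    """Desk-scale generating model: south-first, constant sizes.

    A 10:1 split-time ratio and one migrant per generation keep the
    branching order identifiable from a few thousand SNPs while preserving
    the qualitative shape of the inferred history (old outgroup split,
    young sister split, ongoing gene flow).
    """
    m = np.full((3, 3), 1.0)
    np.fill_diagonal(m, 0.0)
    return IMParams(ne_south=8_000, ne_north=12_000, ne_west=10_000,
                    ne_anc1=10_000, ne_anc2=10_000,
                    t_root=60_000, t_recent=6_000, migrants=m)


@dataclass
class RecoveryTrial:
    best_order: str
    weights: dict[str, float]
    fit: IMFit
    ci: dict[str, tuple[float, float]]
    truth_values: dict[str, float]
    covered: dict[str, bool]

    @property
    def selected_truth(self) -> bool:
        return self.best_order == "south_first"

    @property
    def coverage(self) -> float:
        return float(np.mean(list(self.covered.values())))


def _truth_value(truth: IMParams, name: str) -> float:
    if name == "migrants":
        off = ~np.eye(3, dtype=bool)
        return float(truth.migrants[off].mean())
    return float(getattr(truth, name))


def recovery_trial(
    seed: int,
    truth: IMParams | None = None,
    n_loci: int = 4000,
    samples_per_pop: Sequence[int] = (6, 6, 6),
    projection: int = 12,
    free: Sequence[tuple[str, tuple[float, float]]] = DEFAULT_FREE,
    orders: Sequence[str] = BRANCHING_ORDERS,
    n_runs: int = 1,
    cycles: int = 3,
    n_sims: int = 1500,
    n_boot: int = 10,
    boot_n_sims: int = 800,
    eval_n_sims: int = 20_000,
) -> RecoveryTrial:
    """Run one simulate/fit/compare/bootstrap trial under the given seed."""
    truth = truth or default_truth()
    rng = np.random.default_rng(seed)
    G = simulate_im(truth, n_loci, list(samples_per_pop),
                    seed=int(rng.integers(2**31 - 1)))
    popmap = {i: i.split("_")[0] for i in G.individual_ids}
    proj = [projection] * 3
    obs = project_folded_sfs(G, popmap, proj)
    fits = []
    eval_seed = int(rng.integers(2**31 - 1))
    for order in orders:
        f = fit_im(obs, ModelSpec(order, "constant", tuple(free)),
                   truth, n_runs=n_runs, cycles=cycles, n_sims=n_sims,
                   seed=int(rng.integers(2**31 - 1)), brent_iters=8)
        # precise re-evaluation at common random numbers: the model
        # comparison should not hinge on per-fit Monte-Carlo noise
        exp = expected_sfs(f.params, proj, eval_n_sims, eval_seed,
                           f.model.branching_order)
        f.loglik = composite_loglik(obs, exp)
        fits.append(f)
    w = akaike_weights(fits)
    best_i = int(np.argmax(w))
    gen_fit = fits[list(orders).index("south_first")]
    spec = ModelSpec("south_first", "constant", tuple(free))
    draws: dict[str, list[float]] = {name: [] for name, _ in free}
    counts = obs.counts
    flat = counts.ravel()
    total = flat.sum()
    for _ in range(n_boot):
        # multinomial resample of unlinked sites = fragment bootstrap (each
        # locus is its own fragment); refits restart from scratch so the CI
        # reflects the estimator's full error, optimization noise included
        resampled = rng.multinomial(int(round(total)), flat / total).astype(float)
        boot_obs = FoldedSFS(resampled.reshape(counts.shape), obs.sizes,
                             obs.folded)
        bfit = fit_im(boot_obs, spec, truth, n_runs=1, cycles=2,
                      n_sims=boot_n_sims, seed=int(rng.integers(2**31 - 1)),
                      brent_iters=8)
        for name, val in bfit.free_values().items():
            draws[name].append(val)
    ci = {k: (float(np.quantile(v, 0.025)), float(np.quantile(v, 0.975)))
          for k, v in draws.items()}
    gen_fit.ci = ci
    truth_vals = {name: _truth_value(truth, name) for name, _ in free}
    covered = {k: ci[k][0] <= truth_vals[k] <= ci[k][1] for k in ci}
    return RecoveryTrial(
        best_order=list(orders)[best_i],
        weights={o: float(wi) for o, wi in zip(orders, w)},
        fit=gen_fit,
        ci=ci,
        truth_values=truth_vals,
        covered=covered,
    )
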