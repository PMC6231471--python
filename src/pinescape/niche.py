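"""Niche divergence statistics in PCA-reduced environmental space.

Covers the correlation-matrix PCA of the environmental variables
(Kaiser rule, eigenvalue > 1), the per-axis dn/db background-divergence
resampling test with a permutation t-test, Schoener's D and Warren's I
overlap between suitability surfaces, and the pseudoniche background test.

The dn/db logic: on each retained axis, dn is the absolute difference in
mean occurrence scores between two groups (over 1,000 resamples of 75% of
the occurrences) and db the same quantity over resamples of the two
background clouds. Divergence on an axis requires the mean dn to exceed
the db 95% null interval *and* a significant occurrence-score permutation
t-test; db above dn indicates niche conservatism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthdata import NicheSample, SuitabilityGrid, kde_suitability


@dataclass
class NicheAxes:
    """Retained PCA axes of the pooled environmental space."""

    loadings: pd.DataFrame      # variables x axes
    eigenvalues: np.ndarray     # all eigenvalues
    var_frac: np.ndarray
    mean: np.ndarray
    scale: np.ndarray
    columns: list[str]

    @property
    def n_axes(self) -> int:
        return self.loadings.shape[1]

    def transform(self, env: pd.DataFrame) -> np.ndarray:
        Z = (env[self.columns].to_numpy(dtype=float) - self.mean) / self.scale
        return Z @ self.loadings.to_numpy()


def niche_axes(samples: Sequence[NicheSample], eig_min: float = 1.0) -> NicheAxes:
    """Correlation-matrix PCA over pooled occurrence + background points.

    Axes with eigenvalue > ``eig_min`` are retained (at least one);
    constant variables are dropped with a warning.
    """
    frames = []
    for s in samples:
        frames.append(s.occurrences[s.env_columns])
        frames.append(s.background[s.env_columns])
    pooled = pd.concat(frames, axis=0)
    sd = pooled.std(axis=0, ddof=1)
    const = sd == 0
    if const.any():
        import warnings

        warnings.warn(f"dropping constant variables: {list(pooled.columns[const])}")
        pooled = pooled.loc[:, ~const]
        sd = sd[~const]
    cols = list(pooled.columns)
    mean = pooled.mean(axis=0).to_numpy()
    scale = sd.to_numpy()
    Z = (pooled.to_numpy(dtype=float) - mean) / scale
    corr = np.corrcoef(Z.T)
    eig, vec = np.linalg.eigh(corr)
    order = np.argsort(eig)[::-1]
    eig = eig[order]
    vec = vec[:, order]
    n_keep = max(int((eig > eig_min).sum()), 1)
    loadings = pd.DataFrame(vec[:, :n_keep], index=cols,
                            columns=[f"PC{i + 1}" for i in range(n_keep)])
    return NicheAxes(loadings, eig, eig / eig.sum(), mean, scale, cols)


def perm_t_test(a: Sequence[float], b: Sequence[float], n_perm: int = 999,
                seed: int = 0) -> float:
    """Two-sided permutation t-test: p = (1 + #{|t*| >= |t|}) / (1 + n_perm)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0

    def tstat(x: np.ndarray, y: np.ndarray) -> float:
        vx = x.var(ddof=1) if x.size > 1 else 0.0
        vy = y.var(ddof=1) if y.size > 1 else 0.0
        se = np.sqrt(vx / x.size + vy / y.size)
        if se == 0:
            return np.inf if x.mean() != y.mean() else 0.0
        return (x.mean() - y.mean()) / se

    obs = abs(tstat(a, b))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(tstat(perm[: a.size], perm[a.size:])) >= obs - 1e-12:
            count += 1
    return (1.0 + count) / (1.0 + n_perm)


@dataclass
class DivergenceAxisReport:
    axis: str
    dn_mean: float
    dn_interval: tuple[float, float]
    db_interval: tuple[float, float]
    p_value: float
    verdict: str                      # divergence | conservatism | inconclusive
    var_frac: float
    top_loadings: list[tuple[str, float]]


def dn_db_test(
    A: NicheSample,
    B: NicheSample,
    axes: NicheAxes,
    n_resample: int = 1000,
    frac: float = 0.75,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> list[DivergenceAxisReport]:
    """Per-axis dn/db background-divergence test between two groups."""
    for s in (A, B):
        if len(s.occurrences) < 4:
            raise ValueError(f"group {s.group} has fewer than 4 occurrences")
    rng = np.random.default_rng(seed)
    occ_a = axes.transform(A.occurrences)
    occ_b = axes.transform(B.occurrences)
    bg_a = axes.transform(A.background)
    bg_b = axes.transform(B.background)
    reports = []
    for j in range(axes.n_axes):
        name = axes.loadings.columns[j]
        sa, sb = occ_a[:, j], occ_b[:, j]
        ga, gb = bg_a[:, j], bg_b[:, j]
        if np.ptp(np.concatenate([sa, sb])) == 0 and np.ptp(
                np.concatenate([ga, gb])) == 0:
            continue  # degenerate axis: no variation, skip with no report
        dn = _resampled_diff(sa, sb, frac, n_resample, rng)
        db = _resampled_diff(ga, gb, frac, n_resample, rng)
        dn_mean = float(dn.mean())
        db_lo, db_hi = np.quantile(db, [0.025, 0.975])
        p = perm_t_test(sa, sb, n_perm=n_perm,
                        seed=int(rng.integers(2**31 - 1)))
        if dn_mean > db_hi and p < alpha:
            verdict = "divergence"
        elif dn_mean < db_lo:
            verdict = "conservatism"
        else:
            verdict = "inconclusive"
        lo = axes.loadings[name].abs().sort_values(ascending=False)
        top = [(v, float(axes.loadings.loc[v, name])) for v in lo.index[:3]]
        reports.append(DivergenceAxisReport(
            axis=name,
            dn_mean=dn_mean,
            dn_interval=tuple(np.quantile(dn, [0.025, 0.975])),
            db_interval=(float(db_lo), float(db_hi)),
            p_value=p,
            verdict=verdict,
            var_frac=float(axes.var_frac[j]),
            top_loadings=top,
        ))
    return reports


def _resampled_diff(a: np.ndarray, b: np.ndarray, frac: float,
                    n_resample: int, rng: np.random.Generator) -> np.ndarray:
    na = max(int(round(frac * a.size)), 1)
    nb = max(int(round(frac * b.size)), 1)
    ia = rng.integers(0, a.size, size=(n_resample, na))
    ib = rng.integers(0, b.size, size=(n_resample, nb))
    return np.abs(a[ia].mean(axis=1) - b[ib].mean(axis=1))


def reports_frame(reports: Sequence[DivergenceAxisReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        rows.append({
            "axis": r.axis, "dn": r.dn_mean,
            "db_lo": r.db_interval[0], "db_hi": r.db_interval[1],
            "p": r.p_value, "verdict": r.verdict,
            "pct_variance": 100 * r.var_frac,
            "top_loadings": "; ".join(f"{v}:{w:+.2f}" for v, w in r.top_loadings),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# overlap statistics

def _normalized(P: SuitabilityGrid | np.ndarray) -> np.ndarray:
    vals = P.values if isinstance(P, SuitabilityGrid) else np.asarray(P, float)
    tot = vals.sum()
    if tot <= 0:
        raise ValueError("grid has no mass")
    return vals / tot


def schoener_d(P: SuitabilityGrid | np.ndarray, Q: SuitabilityGrid | np.ndarray) -> float:
    """Schoener's D = 1 - 0.5 sum|p - q| over normalized surfaces."""
    p, q = _normalized(P), _normalized(Q)
    if p.shape != q.shape:
        raise ValueError("grids must have identical shape")
    return float(1.0 - 0.5 * np.abs(p - q).sum())


def warren_i(P: SuitabilityGrid | np.ndarray, Q: SuitabilityGrid | np.ndarray) -> float:
    """Warren's I = 1 - 0.5 sum(sqrt(p) - sqrt(q))^2 (Hellinger-based)."""
    p, q = _normalized(P), _normalized(Q)
    if p.shape != q.shape:
        raise ValueError("grids must have identical shape")
    return float(1.0 - 0.5 * ((np.sqrt(p) - np.sqrt(q)) ** 2).sum())


# ---------------------------------------------------------------------------
# background (pseudoniche) test

@dataclass
class BackgroundTestResult:
    observed_d: float
    observed_i: float
    null_d: np.ndarray
    null_i: np.ndarray
    verdict_d: str
    verdict_i: str
    n_failed: int = 0


def background_test(
    observed_d: float,
    observed_i: float,
    occ_A: pd.DataFrame,
    bg_B: pd.DataFrame,
    grid_A: SuitabilityGrid,
    grid_shape: tuple[int, int] | None = None,
    n_reps: int = 100,
    seed: int = 0,
    model: Callable[[np.ndarray, tuple, tuple], SuitabilityGrid] | None = None,
) -> BackgroundTestResult:
    """Pseudoniche background test in one direction (A vs B's background).

    ``observed_d`` / ``observed_i`` are the actual A-vs-B overlaps. Each of
    ``n_reps`` repetitions draws |occ_A| pseudo-occurrence points from B's
    background, fits the stand-in suitability model (default normalized
    Gaussian KDE on A's extent) and records its overlap with A's surface.
    Observed overlap below the null 2.5th percentile supports divergence,
    above the 97.5th conservatism.
    """
    n_occ = len(occ_A)
    if len(bg_B) < n_occ:
        raise ValueError("background of B smaller than A's occurrence set")
    if model is None:
        model = kde_suitability
    shape = grid_shape or grid_A.values.shape
    rng = np.random.default_rng(seed)
    xy = bg_B[["lon", "lat"]].to_numpy(dtype=float)
    null_d, null_i = [], []
    failed = 0
    for _ in range(n_reps):
        idx = rng.choice(len(xy), size=n_occ, replace=False)
        try:
            pseudo = model(xy[idx], grid_A.extent, shape)
        except np.linalg.LinAlgError:
            failed += 1
            continue
        null_d.append(schoener_d(grid_A, pseudo))
        null_i.append(warren_i(grid_A, pseudo))
    null_d = np.asarray(null_d)
    null_i = np.asarray(null_i)

    def verdict(obs: float, null: np.ndarray) -> str:
        lo, hi = np.quantile(null, [0.025, 0.975])
        if obs < lo:
            return "divergence"
        if obs > hi:
            return "conservatism"
        return "inconclusive"

    return BackgroundTestResult(observed_d, observed_i, null_d, null_i,
                                verdict(observed_d, null_d),
                                verdict(observed_i, null_i), failed)


def reciprocal_background_tests(
    samples: dict[str, NicheSample],
    grids: dict[str, SuitabilityGrid],
    pair: tuple[str, str],
    n_reps: int = 100,
    seed: int = 0,
) -> dict[str, BackgroundTestResult]:
    """Run the background test in both directions for a pair of groups."""
    a, b = pair
    obs_d = schoener_d(grids[a], grids[b])
    obs_i = warren_i(grids[a], grids[b])
    rng = np.random.default_rng(seed)
    return {
        f"{a}_vs_{b}_background": background_test(
            obs_d, obs_i, samples[a].occurrences, samples[b].background,
            grids[a], n_reps=n_reps, seed=int(rng.integers(2**31 - 1))),
        f"{b}_vs_{a}_background": background_test(
            obs_d, obs_i, samples[b].occurrences, samples[a].background,
            grids[b], n_reps=n_reps, seed=int(rng.integers(2**31 - 1))),
    }
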