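"""Redundancy analysis and the IBE/IBD/IBC variance-partition ledger.

The dependent matrix is populations x loci allele frequencies (centered per
locus); predictor matrices are environmental PCs, a trend surface of the
sampling coordinates, and PCs of the mitotype frequency table. RDA is a
multivariate regression followed by an eigen-decomposition of the fitted
values; partial RDA residualizes both sides on a conditioning matrix first.
Explained fractions are Ezekiel-adjusted R^2 values; conditional fractions
come from subtraction of nested adjusted R^2 (so the ledger identity
env|geog + geog|env + joint = total holds exactly at full precision).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class ConstraintMatrix:
    """Populations x predictors design matrix with provenance."""

    data: pd.DataFrame
    role: str = "env"       # env | geog | mito | custom
    provenance: str = ""

    def __post_init__(self) -> None:
        drop = [c for c in self.data.columns if self.data[c].nunique() <= 1]
        if drop:
            warnings.warn(f"dropping constant predictor columns: {drop}")
            self.data = self.data.drop(columns=drop)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def aligned(self, index: Sequence[str]) -> np.ndarray:
        return self.data.loc[list(index)].to_numpy(dtype=float)


def trend_surface(coords: pd.DataFrame) -> ConstraintMatrix:
    """Second-order trend surface x, y, xy, x^2, y^2 of centered coordinates.

    Degenerate geometries (e.g. all populations on one meridian) drop the
    linearly dependent columns with a warning.
    """
    if coords.shape[0] < 3:
        raise ValueError("need at least three populations for a trend surface")
    x = coords.iloc[:, 0].to_numpy(dtype=float)
    y = coords.iloc[:, 1].to_numpy(dtype=float)
    x = x - x.mean()
    y = y - y.mean()
    M = pd.DataFrame(
        {"x": x, "y": y, "xy": x * y, "x2": x**2, "y2": y**2},
        index=coords.index,
    )
    degenerate = list(M.columns[M.nunique() <= 1])
    if degenerate:
        warnings.warn(f"degenerate trend-surface terms dropped: {degenerate}")
    M = M.loc[:, M.nunique() > 1]
    # drop columns that are linear combinations of earlier ones
    keep: list[str] = []
    for c in M.columns:
        trial = M[keep + [c]].to_numpy()
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(c)
    if len(keep) < M.shape[1]:
        warnings.warn("collinear trend-surface terms dropped: "
                      f"{sorted(set(M.columns) - set(keep))}")
    return ConstraintMatrix(M[keep], role="geog",
                            provenance="trend surface (x, y, xy, x2, y2)")


def pca_reduce(
    M: pd.DataFrame,
    criterion: str = "cum_var",
    cum_var: float = 0.75,
    k: int | None = None,
    role: str = "env",
) -> tuple[ConstraintMatrix, np.ndarray]:
    """Correlation-matrix PCA reduction of a predictor table.

    ``criterion`` is one of ``"cum_var"`` (keep axes until cumulative
    variance >= ``cum_var``), ``"eigenvalue"`` (Kaiser: eigenvalue > 1, with
    fall-back to PC1 if none qualifies), or ``"fixed"`` (exactly ``k`` axes).
    Returns the retained scores and the fraction of variance per axis.
    """
    if M.shape[1] < 2:
        raise ValueError("need at least two columns to reduce")
    X = M.to_numpy(dtype=float)
    sd = X.std(axis=0)
    const = sd == 0
    if const.any():
        warnings.warn(f"dropping constant columns: {list(M.columns[const])}")
        X = X[:, ~const]
        sd = sd[~const]
    Z = (X - X.mean(axis=0)) / sd
    u, s, _ = np.linalg.svd(Z, full_matrices=False)
    eig = s**2 / (Z.shape[0] - 1)
    var_frac = eig / eig.sum()
    if criterion == "cum_var":
        n_keep = int(np.searchsorted(np.cumsum(var_frac), cum_var) + 1)
    elif criterion == "eigenvalue":
        n_keep = int((eig > 1.0).sum())
        if n_keep == 0:
            n_keep = 1  # isotropic edge case: keep PC1
    elif criterion == "fixed":
        if k is None:
            raise ValueError("criterion 'fixed' needs k")
        n_keep = int(k)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    n_keep = min(n_keep, len(eig))
    scores = u[:, :n_keep] * s[:n_keep]
    out = pd.DataFrame(scores, index=M.index,
                       columns=[f"PC{i + 1}" for i in range(n_keep)])
    prov = f"correlation PCA, {criterion}, {n_keep} axes, " \
           f"{100 * var_frac[:n_keep].sum():.1f}% variance"
    return ConstraintMatrix(out, role=role, provenance=prov), var_frac


@dataclass
class RdaResult:
    r2: float
    adj_r2: float
    n: int
    p: int
    axes: np.ndarray | None = None
    perm_p: float | None = None
    residuals: np.ndarray | None = None


def _center(F: np.ndarray) -> np.ndarray:
    return F - F.mean(axis=0)


def _residualize(A: np.ndarray, Z: np.ndarray) -> np.ndarray:
    Z1 = np.column_stack([np.ones(Z.shape[0]), Z])
    beta, *_ = np.linalg.lstsq(Z1, A, rcond=None)
    return A - Z1 @ beta


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel adjustment 1 - (1-R^2)(n-1)/(n-p-1)."""
    if p == 0:
        return float(r2)
    if n <= p + 1:
        raise ValueError(f"adjusted R^2 undefined for n={n}, p={p}")
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - p - 1))


def rda(
    F: np.ndarray | pd.DataFrame,
    X: ConstraintMatrix | np.ndarray,
    Z: ConstraintMatrix | np.ndarray | None = None,
) -> RdaResult:
    """(Partial) redundancy analysis of F on X, conditioning on Z.

    F is populations x loci (centered internally); R^2 is the fraction of
    the total sum of squares captured by the fitted values. When Z is given
    both F and X are residualized on Z first and R^2 is relative to the
    residual total.
    """
    F = np.asarray(F, dtype=float) if not isinstance(F, pd.DataFrame) else F.to_numpy(dtype=float)
    Xv = X.values if isinstance(X, ConstraintMatrix) else np.asarray(X, dtype=float)
    if Xv.ndim == 1:
        Xv = Xv[:, None]
    n = F.shape[0]
    if Xv.shape[0] != n:
        raise ValueError("rows of F and X differ")
    Fc = _center(F)
    if Z is not None:
        Zv = Z.values if isinstance(Z, ConstraintMatrix) else np.asarray(Z, dtype=float)
        if Zv.ndim == 1:
            Zv = Zv[:, None]
        Fc = _residualize(Fc, Zv)
        Xv = _residualize(Xv, Zv)
    p = int(np.linalg.matrix_rank(Xv)) if Xv.size else 0
    if p >= n:
        raise ValueError(f"predictor rank {p} must be below n populations {n}")
    total = float((Fc**2).sum())
    if total == 0:
        raise ValueError("dependent matrix has no variance")
    if p == 0:
        return RdaResult(0.0, 0.0, n, 0, residuals=Fc)
    X1 = np.column_stack([np.ones(n), Xv])
    beta, *_ = np.linalg.lstsq(X1, Fc, rcond=None)
    fitted = X1 @ beta
    r2 = float((fitted**2).sum() / total)
    adj = adjusted_r2(r2, n, p) if n > p + 1 else np.nan
    u, s, _ = np.linalg.svd(fitted, full_matrices=False)
    axes = u[:, : min(p, len(s))] * s[: min(p, len(s))]
    return RdaResult(r2, adj, n, p, axes=axes, residuals=Fc - fitted)


def permutation_test(
    F: np.ndarray | pd.DataFrame,
    X: ConstraintMatrix | np.ndarray,
    Z: ConstraintMatrix | np.ndarray | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """Permutation p-value for the (partial) RDA pseudo-F.

    Rows of (residualized) F are freely permuted; p = (1 + #{F* >= F}) /
    (1 + n_perm).
    """
    F = np.asarray(F, dtype=float) if not isinstance(F, pd.DataFrame) else F.to_numpy(dtype=float)
    Xv = X.values if isinstance(X, ConstraintMatrix) else np.asarray(X, dtype=float)
    if Xv.ndim == 1:
        Xv = Xv[:, None]
    Fc = _center(F)
    if Z is not None:
        Zv = Z.values if isinstance(Z, ConstraintMatrix) else np.asarray(Z, dtype=float)
        if Zv.ndim == 1:
            Zv = Zv[:, None]
        Fc = _residualize(Fc, Zv)
        Xv = _residualize(Xv, Zv)
    n = Fc.shape[0]
    p = max(int(np.linalg.matrix_rank(Xv)), 1)

    def pseudo_f(Fm: np.ndarray) -> float:
        X1 = np.column_stack([np.ones(n), Xv])
        beta, *_ = np.linalg.lstsq(X1, Fm, rcond=None)
        fitted = X1 @ beta
        ss_fit = (fitted**2).sum()
        ss_res = ((Fm - fitted) ** 2).sum()
        dof_res = max(n - p - 1, 1)
        return (ss_fit / p) / (ss_res / dof_res) if ss_res > 0 else np.inf

    obs = pseudo_f(Fc)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if pseudo_f(Fc[perm]) >= obs:
            count += 1
    return (1.0 + count) / (1.0 + n_perm)


def forward_select(
    F: np.ndarray | pd.DataFrame,
    candidates: ConstraintMatrix,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
) -> ConstraintMatrix:
    """Forward selection of predictor columns by permutation significance.

    A global permutation test of the full candidate matrix gates the
    procedure (no selection when the global model is not significant —
    the standard guard against stepwise overfitting); then candidates are
    added one at a time, requiring permutation p < alpha and an improving
    adjusted R^2. May select nothing.
    """
    if candidates.data.shape[1] == 0:
        raise ValueError("no candidate predictors")
    rng = np.random.default_rng(seed)
    global_p = permutation_test(F, candidates, n_perm=n_perm,
                                seed=int(rng.integers(2**31 - 1)))
    if global_p >= alpha:
        return ConstraintMatrix(candidates.data[[]], candidates.role,
                                provenance=f"forward selection alpha={alpha}, "
                                           f"global p={global_p:.3f} n.s.")
    selected: list[str] = []
    remaining = list(candidates.data.columns)
    best_adj = 0.0
    while remaining:
        scores = []
        for c in remaining:
            cols = selected + [c]
            sub = ConstraintMatrix(candidates.data[cols], candidates.role)
            Z = (ConstraintMatrix(candidates.data[selected], candidates.role)
                 if selected else None)
            pval = permutation_test(F, ConstraintMatrix(candidates.data[[c]]),
                                    Z=Z, n_perm=n_perm,
                                    seed=int(rng.integers(2**31 - 1)))
            try:
                adj = rda(F, sub).adj_r2
            except ValueError:
                adj = -np.inf
            scores.append((pval, -adj, c, adj))
        scores.sort()
        pval, _, c, adj = scores[0]
        if pval < alpha and adj > best_adj:
            selected.append(c)
            remaining.remove(c)
            best_adj = adj
        else:
            break
    return ConstraintMatrix(candidates.data[selected], candidates.role,
                            provenance=f"forward selection alpha={alpha}")


@dataclass
class PartitionTable:
    """Adjusted-R^2 ledger of combined/individual/joint/total fractions."""

    combined: dict[str, float]          # marginal adj R^2 per role
    individual: dict[str, float]        # env|geog, geog|env
    joint: float
    total_explained: float
    total_unexplained: float
    pvalues: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("F~env.", self.combined.get("env", np.nan), self.pvalues.get("env")),
            ("F~geog.", self.combined.get("geog", np.nan), self.pvalues.get("geog")),
            ("F~mito.", self.combined.get("mito", np.nan), self.pvalues.get("mito")),
            ("F~env.|geog.", self.individual.get("env|geog", np.nan),
             self.pvalues.get("env|geog")),
            ("F~geog.|env.", self.individual.get("geog|env", np.nan),
             self.pvalues.get("geog|env")),
            ("F~env.+geog.", self.joint, None),
            ("Total explained", self.total_explained, None),
            ("Total unexplained", self.total_unexplained, None),
        ]
        return pd.DataFrame(rows, columns=["fraction", "adj_r2", "p"]).set_index("fraction")


def partition_from_adjusted(adj_env: float, adj_geog: float,
                            adj_both: float) -> dict[str, float]:
    """Conditional and joint fractions from the three marginal adjusted R^2.

    env|geog = both - geog; geog|env = both - env; joint = env + geog - both;
    the three sum to ``both`` exactly.
    """
    return {
        "env|geog": adj_both - adj_geog,
        "geog|env": adj_both - adj_env,
        "joint": adj_env + adj_geog - adj_both,
        "total_explained": adj_both,
        "total_unexplained": 1.0 - adj_both,
    }


def variance_partition(
    F: np.ndarray | pd.DataFrame,
    env: ConstraintMatrix,
    geog: ConstraintMatrix,
    mito: ConstraintMatrix | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> PartitionTable:
    """Partition among-population variance into environment/geography(/mito).

    Combined fractions are marginal adjusted R^2 per predictor matrix;
    individual and joint fractions come from nested-model subtraction. The
    mitotype matrix is reported marginally only; the confounded joint
    fraction carries no significance test.
    """
    Fm = F.to_numpy(dtype=float) if isinstance(F, pd.DataFrame) else np.asarray(F, float)
    rng = np.random.default_rng(seed)
    adj_env = rda(Fm, env).adj_r2
    adj_geog = rda(Fm, geog).adj_r2
    both = ConstraintMatrix(
        pd.concat([env.data.add_prefix("env_"), geog.data.add_prefix("geog_")],
                  axis=1), role="env+geog")
    adj_both = rda(Fm, both).adj_r2
    parts = partition_from_adjusted(adj_env, adj_geog, adj_both)
    combined = {"env": adj_env, "geog": adj_geog}
    pvals = {
        "env": permutation_test(Fm, env, n_perm=n_perm,
                                seed=int(rng.integers(2**31 - 1))),
        "geog": permutation_test(Fm, geog, n_perm=n_perm,
                                 seed=int(rng.integers(2**31 - 1))),
        "env|geog": permutation_test(Fm, env, Z=geog, n_perm=n_perm,
                                     seed=int(rng.integers(2**31 - 1))),
        "geog|env": permutation_test(Fm, geog, Z=env, n_perm=n_perm,
                                     seed=int(rng.integers(2**31 - 1))),
    }
    if mito is not None and mito.data.shape[1] > 0:
        combined["mito"] = rda(Fm, mito).adj_r2
        pvals["mito"] = permutation_test(Fm, mito, n_perm=n_perm,
                                         seed=int(rng.integers(2**31 - 1)))
    return PartitionTable(
        combined=combined,
        individual={"env|geog": parts["env|geog"], "geog|env": parts["geog|env"]},
        joint=parts["joint"],
        total_explained=parts["total_explained"],
        total_unexplained=parts["total_unexplained"],
        pvalues=pvals,
    )


def mito_constraint(
    mitotypes: Mapping[str, str],
    popmap: Mapping[str, str],
    populations: Sequence[str],
    cum_var: float = 0.75,
) -> ConstraintMatrix:
    """Mitotype predictor matrix: PCA of per-population mitotype frequencies.

    Singleton mitotypes (carried by one individual overall) are removed
    before the frequency table is built; PCs are retained to >= ``cum_var``
    cumulative variance.
    """
    haps = pd.Series(mitotypes)
    hap_counts = haps.value_counts()
    keep_haps = hap_counts[hap_counts > 1].index
    rows = []
    for pop in populations:
        members = [i for i, p in popmap.items() if p == pop and i in mitotypes]
        sub = haps.loc[members]
        total = len(sub)
        rows.append([float((sub == h).sum()) / total if total else 0.0
                     for h in keep_haps])
    table = pd.DataFrame(rows, index=list(populations), columns=list(keep_haps))
    cm, _ = pca_reduce(table, criterion="cum_var", cum_var=cum_var, role="mito")
    cm.provenance = "PCA of mitotype frequencies, " + cm.provenance
    return cm
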