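"""Joint folded site-frequency spectra: projection, expectation, likelihood.

The joint SFS over 2-3 populations is held as a dense array indexed by
derived/alt allele counts per population (shape ``(n1+1, n2+1, ...)`` for
haploid sample sizes ``n``). Folding maps each cell onto its
minor-configuration equivalence class: the representative of ``{c, n - c}``
with the smaller total allele count (lexicographic tie-break at exactly
half frequency, where the class has a single member and keeps its own mass
once — the half-weight convention).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from ..core import MISSING, GenotypeMatrix, membership_indices
from . import _engine
from .model import Demography, IMParams, im_demography


@dataclass
class FoldedSFS:
    """A (possibly folded) joint SFS with the monomorphic class excluded.

    ``counts`` may hold integer site counts (observed spectra), fractional
    expected counts (projection) or probabilities (normalized expectation).
    Non-canonical cells are zero after folding. ``excluded_monomorphic`` is
    the mass removed from the monomorphic class; ``n_sims`` records the
    Monte-Carlo effort behind an expected spectrum (None for observed data).
    """

    counts: np.ndarray
    sizes: tuple[int, ...]
    folded: bool = True
    excluded_monomorphic: float = 0.0
    skipped_sites: int = 0
    n_sims: int | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.sizes = tuple(int(s) for s in self.sizes)
        if self.counts.shape != tuple(s + 1 for s in self.sizes):
            raise ValueError("counts shape must be sizes + 1 per population")
        if (self.counts < 0).any():
            raise ValueError("SFS entries must be >= 0")

    @property
    def n_snps(self) -> float:
        return float(self.counts.sum())

    def normalized(self) -> "FoldedSFS":
        tot = self.counts.sum()
        if tot == 0:
            raise ValueError("cannot normalize an empty spectrum")
        return FoldedSFS(self.counts / tot, self.sizes, self.folded,
                         self.excluded_monomorphic, self.skipped_sites, self.n_sims)

    def without_singletons(self) -> "FoldedSFS":
        """Drop cells whose joint minor-allele count is exactly 1."""
        out = self.counts.copy()
        dropped = 0.0
        for cell in zip(*np.nonzero(out)):
            if sum(cell) == 1:
                dropped += out[cell]
                out[cell] = 0.0
        return FoldedSFS(out, self.sizes, self.folded,
                         self.excluded_monomorphic + dropped,
                         self.skipped_sites, self.n_sims)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f"# sizes: {' '.join(map(str, self.sizes))}\n")
            fh.write(f"# folded: {int(self.folded)} "
                     f"excluded_monomorphic: {float(self.excluded_monomorphic)!r} "
                     f"skipped_sites: {self.skipped_sites}\n")
            fh.write(" ".join(repr(float(v)) for v in self.counts.ravel()) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "FoldedSFS":
        lines = Path(path).read_text().splitlines()
        sizes = tuple(int(v) for v in lines[0].split(":")[1].split())
        meta = lines[1].lstrip("# ").split()
        folded = bool(int(meta[1]))
        excl = float(meta[3])
        skipped = int(meta[5])
        flat = np.array([float(v) for v in lines[2].split()])
        return cls(flat.reshape(tuple(s + 1 for s in sizes)), sizes, folded,
                   excl, skipped)


def _canonical(cell: tuple[int, ...], sizes: tuple[int, ...]) -> tuple[int, ...]:
    comp = tuple(s - c for s, c in zip(sizes, cell))
    tot, tot_c = sum(cell), sum(comp)
    if (tot, cell) <= (tot_c, comp):
        return cell
    return comp


def fold_joint(arr: np.ndarray, sizes: Sequence[int]) -> np.ndarray:
    """Fold an unfolded joint spectrum onto minor-configuration classes."""
    sizes = tuple(int(s) for s in sizes)
    out = np.zeros_like(np.asarray(arr, dtype=float))
    for cell in np.ndindex(*[s + 1 for s in sizes]):
        out[_canonical(cell, sizes)] += arr[cell]
    return out


def _strip_monomorphic(arr: np.ndarray, sizes: tuple[int, ...]) -> tuple[np.ndarray, float]:
    out = arr.copy()
    zero = tuple(0 for _ in sizes)
    full = tuple(sizes)
    excluded = out[zero] + (out[full] if full != zero else 0.0)
    out[zero] = 0.0
    out[full] = 0.0
    return out, float(excluded)


def project_folded_sfs(
    G: GenotypeMatrix,
    popmap: Mapping[str, str],
    target_haploid_sizes: Mapping[str, int] | Sequence[int],
) -> FoldedSFS:
    """Down-sampling projection of genotype data onto a folded joint SFS.

    Each site contributes its exact hypergeometric expectation: alt alleles
    among ``m`` observed alleles in a population are projected without
    replacement onto ``s`` alleles. Sites where any population has fewer
    than ``s`` non-missing alleles are skipped (and counted); the
    monomorphic-after-projection mass is excluded and reported.
    """
    pops, groups = membership_indices(G.individual_ids, popmap)
    if isinstance(target_haploid_sizes, Mapping):
        sizes = tuple(int(target_haploid_sizes[p]) for p in pops)
    else:
        sizes = tuple(int(s) for s in target_haploid_sizes)
    if len(sizes) != len(pops):
        raise ValueError("one target size per population required")
    if any(s <= 0 for s in sizes):
        raise ValueError("target sizes must be positive")
    n_cells = float(np.prod([s + 1.0 for s in sizes]))
    if n_cells > 5e7:
        raise ValueError(
            f"joint spectrum over {len(pops)} populations would need "
            f"{n_cells:.2g} cells; project over grouped populations instead")
    n_pops = len(pops)
    alt = np.stack([np.where(G.calls[idx] != MISSING, G.calls[idx], 0).sum(axis=0)
                    for idx in groups])
    m = np.stack([2 * (G.calls[idx] != MISSING).sum(axis=0) for idx in groups])
    usable = (m >= np.array(sizes)[:, None]).all(axis=0)
    skipped = int((~usable).sum())
    unfolded = np.zeros(tuple(s + 1 for s in sizes))
    # per-population projection weight matrices, one (s+1, L) block per pop
    vecs = []
    for p in range(n_pops):
        x = np.arange(sizes[p] + 1)[:, None]
        with np.errstate(invalid="ignore"):
            w = stats.hypergeom.pmf(x, m[p][None, :], alt[p][None, :], sizes[p])
        vecs.append(np.nan_to_num(w))
    for j in np.flatnonzero(usable):
        contrib = functools.reduce(np.multiply.outer, [v[:, j] for v in vecs])
        unfolded += contrib
    folded = fold_joint(unfolded, sizes)
    folded, excluded = _strip_monomorphic(folded, sizes)
    return FoldedSFS(folded, sizes, folded=True,
                     excluded_monomorphic=excluded, skipped_sites=skipped)


def branch_sfs(
    dem: Demography,
    haploids_per_deme: Sequence[int],
    n_sims: int,
    seed: int,
    pop_of_deme: Sequence[int] | None = None,
) -> np.ndarray:
    """Monte-Carlo expected branch length per unfolded joint count cell."""
    haploids_per_deme = np.asarray(haploids_per_deme, dtype=np.int64)
    if pop_of_deme is None:
        pop_of_deme = np.arange(dem.n_demes, dtype=np.int64)
    pop_of_deme = np.asarray(pop_of_deme, dtype=np.int64)
    sample_deme = np.repeat(np.arange(dem.n_demes), haploids_per_deme)
    sample_pop = pop_of_deme[sample_deme]
    n_pops = int(sample_pop.max()) + 1
    sizes = np.array([(sample_pop == p).sum() for p in range(n_pops)])
    shape = tuple(int(s) + 1 for s in sizes)
    strides = np.ones(n_pops, dtype=np.int64)
    for p in range(n_pops - 2, -1, -1):
        strides[p] = strides[p + 1] * shape[p + 1]
    n0, alpha, t_end, mig, ev_t, ev_s, ev_d = dem.engine_arrays()
    acc = _engine.sim_branch_sfs(
        int(seed) % (2**31 - 1), int(n_sims), sample_deme, sample_pop, n_pops,
        strides, int(np.prod(shape)), n0, alpha, t_end, mig, ev_t, ev_s, ev_d)
    return acc.reshape(shape)


def expected_sfs(
    params: IMParams,
    haploids_per_pop: Sequence[int],
    n_sims: int,
    seed: int,
    branching_order: str = "south_first",
    fold: bool = True,
) -> FoldedSFS:
    """Normalized expected SFS of an IM model, conditional on segregating.

    Estimated from the expected genealogy branch lengths of ``n_sims``
    simulated trees; the monomorphic class has expectation zero by
    construction and the spectrum is normalized to sum to one.
    """
    if n_sims < 10:
        raise ValueError("n_sims too small for a meaningful expectation")
    haploids_per_pop = list(haploids_per_pop)
    if len(haploids_per_pop) != 3:
        raise ValueError("haploids_per_pop must list the three extant groups")
    dem = im_demography(params, branching_order)
    arr = branch_sfs(dem, haploids_per_pop + [0, 0], n_sims, seed,
                     pop_of_deme=[0, 1, 2, 0, 0])
    sizes = tuple(haploids_per_pop)
    if fold:
        arr = fold_joint(arr, sizes)
    arr, _ = _strip_monomorphic(arr, sizes)
    out = FoldedSFS(arr, sizes, folded=fold, n_sims=int(n_sims))
    return out.normalized()


def composite_loglik(obs: FoldedSFS, exp: FoldedSFS,
                     floor: float | None = None) -> float:
    """Multinomial composite log-likelihood sum(obs * log(p)) over SFS cells.

    ``exp`` must be normalized; zero-probability cells are floored (default
    ``1/(10 * n_sims)``, one tenth of a Monte-Carlo count) to avoid -inf.
    """
    if obs.sizes != exp.sizes:
        raise ValueError("observed and expected SFS dimensions differ")
    if obs.folded != exp.folded:
        raise ValueError("folding convention differs between spectra")
    p = exp.counts
    tot = p.sum()
    if not np.isclose(tot, 1.0, atol=1e-6):
        raise ValueError("expected SFS must be normalized")
    if floor is None:
        floor = 1.0 / (10.0 * (exp.n_sims or 1000))
    p = np.where(p > 0, p, floor)
    mask = obs.counts > 0
    return float((obs.counts[mask] * np.log(p[mask])).sum())
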