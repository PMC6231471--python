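"""Ground-truthed synthetic datasets emulating a range-wide conifer GBS study.

The default configuration mirrors the emulation target: 17 populations in
three geographic clusters (a large northern cluster, a western cluster on
high ground, a small southern cluster), ~4,077 biallelic SNPs with ~7%
missingness, hierarchical divergence with migration (an old split of the
southern cluster, a younger north/west split), environmental gradients
that follow the sampling coordinates, a minority of environment-associated
loci, and strongly structured maternally inherited mitotypes.

One global seed fans out to independent per-stage streams
(:func:`stage_rng`) so each stage can be regenerated on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import gaussian_kde

from .core import MISSING, GenotypeMatrix
from .demography import Demography, IMParams, simulate_demography

# population name, Table-style diploid sample size, cluster, lon, lat
_DEFAULT_POPS: tuple[tuple[str, int, str, float, float], ...] = (
    ("JL", 10, "north", 126.60, 42.08),
    ("NC", 11, "north", 118.97, 42.27),
    ("SS", 12, "north", 115.95, 40.45),
    ("WT", 11, "north", 113.65, 38.88),
    ("LK", 12, "north", 112.03, 36.60),
    ("FS", 12, "north", 111.55, 37.93),
    ("DS", 12, "north", 110.30, 40.78),
    ("TB", 9, "north", 107.17, 34.03),
    ("LS", 12, "north", 110.82, 33.73),
    ("JZ", 12, "west", 103.78, 33.28),
    ("QL", 8, "west", 103.43, 37.43),
    ("RG", 12, "west", 103.35, 33.70),
    ("HZ", 12, "west", 102.45, 36.95),
    ("GY", 12, "south", 106.10, 32.62),
    ("NS", 12, "south", 108.38, 33.47),
    ("HL", 10, "west", 105.92, 38.73),
    ("ZW", 12, "north", 108.72, 35.63),
)

_STAGES = {"genotypes": 0, "missing": 1, "env": 2, "mito": 3, "spike": 4,
           "niche": 5, "coords": 6}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Child RNG for a named pipeline stage derived from the global seed."""
    return np.random.default_rng(np.random.SeedSequence((int(seed), _STAGES[stage])))


def default_im_params() -> IMParams:
    """Three-cluster IM truth at the scale of a widespread conifer.

    Extant sizes and split times follow the landscape inference for this
    system (Ne ~1e5, splits at 73,400 and 11,600 generations); ancestral
    sizes and the south-north migration rate are not pinned down by the
    point estimates and are set to round intermediate values.
    """
    mig = np.array([
        [0.0, 5.0, 19.0],   # into south: from north, west
        [5.0, 0.0, 14.5],   # into north
        [19.0, 14.5, 0.0],  # into west
    ])
    return IMParams(
        ne_south=1.09e5, ne_north=2.10e5, ne_west=1.27e5,
        ne_anc1=1.5e5, ne_anc2=2.0e5,
        t_root=73_400.0, t_recent=11_600.0,
        migrants=mig,
    )


@dataclass
class EnvGradient:
    """Linear environmental field over the sampling coordinates.

    Each variable is ``slope * (directional trend in standardized lon/lat)
    + N(0, noise_sd)``; the first variable runs along latitude so that it
    tracks cluster membership.
    """

    slope: float = 1.0
    noise_sd: float = 0.3
    n_vars: int = 14


@dataclass
class SynthConfig:
    """Generator configuration; defaults are the full study conditions."""

    pop_sizes: dict[str, int] = field(
        default_factory=lambda: {p: n for p, n, *_ in _DEFAULT_POPS})
    cluster_assignment: dict[str, str] = field(
        default_factory=lambda: {p: g for p, _, g, *_ in _DEFAULT_POPS})
    coords: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {p: (x, y) for p, _, _, x, y in _DEFAULT_POPS})
    im_params: IMParams = field(default_factory=default_im_params)
    branching_order: str = "south_first"
    n_loci: int = 4077
    # the emulated panel is the post-QC SNP set, which passed a MAF >= 0.05
    # filter during discovery; ascertain the simulated panel the same way
    ascertain_maf: float = 0.05
    missing_rate: float = 0.072
    env_gradient: EnvGradient = field(default_factory=EnvGradient)
    n_adaptive: int = 46
    adaptive_beta: float = 3.0
    # frozen from a (theta, share) grid targeting among-group mitotype
    # differentiation ~0.8 with the smallest seed-to-seed spread
    mito_theta: float = 0.03
    mito_share: float = 0.05
    within_group_migrants: float = 5.0
    pop_scatter_time: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.pop_sizes:
            raise ValueError("pop_sizes: need at least one population")
        for name, n in self.pop_sizes.items():
            if n <= 0:
                raise ValueError(f"pop_sizes[{name}] must be positive")
        if not set(self.pop_sizes) <= set(self.cluster_assignment):
            raise ValueError("cluster_assignment must cover every population")
        if not set(self.pop_sizes) <= set(self.coords):
            raise ValueError("coords must cover every population")
        if self.n_loci <= 0:
            raise ValueError("n_loci must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_adaptive < 0 or self.n_adaptive > self.n_loci:
            raise ValueError("n_adaptive must lie in [0, n_loci]")
        if self.pop_scatter_time >= self.im_params.t_recent:
            raise ValueError("pop_scatter_time must predate the youngest split")

    @property
    def n_pops(self) -> int:
        return len(self.pop_sizes)

    @property
    def populations(self) -> list[str]:
        return list(self.pop_sizes)

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for p in self.populations:
            g = self.cluster_assignment[p]
            if g not in seen:
                seen.append(g)
        return seen


@dataclass
class SynthBundle:
    """A generated dataset plus its ground truth."""

    genotypes: GenotypeMatrix
    popmap: dict[str, str]
    coords: pd.DataFrame          # population x (lon, lat)
    env: pd.DataFrame             # population x variable
    mitotypes: dict[str, str]
    truth: dict

    def __post_init__(self) -> None:
        pops = set(self.coords.index)
        for ind, pop in self.popmap.items():
            if pop not in pops:
                raise ValueError(f"popmap assigns {ind} to unknown population {pop}")
        bad = [i for i in self.truth.get("adaptive_loci", [])
               if not 0 <= i < self.genotypes.n_loci]
        if bad:
            raise ValueError(f"truth.adaptive_loci out of range: {bad[:5]}")

    def group_of_individual(self) -> dict[str, str]:
        groups = self.truth["group_labels"]
        return {ind: groups[pop] for ind, pop in self.popmap.items()}


def _scatter_demography(config: SynthConfig) -> tuple[Demography, list[int]]:
    """Deme graph: one deme per population nested inside the 3-cluster IM."""
    pops = config.populations
    groups = config.groups
    if len(groups) != 3:
        raise ValueError("cluster_assignment must define exactly three clusters "
                         "(the IM model has three extant branches)")
    p = config.im_params
    group_ne = {groups[0]: None, groups[1]: None, groups[2]: None}
    # groups are mapped onto IM branches in order (south, north, west) by
    # sorting: the caller's cluster labels are free-form, so map by name when
    # the canonical names are used, else by first appearance
    canon = {"south": p.ne_south, "north": p.ne_north, "west": p.ne_west}
    if set(groups) == set(canon):
        group_ne = {g: canon[g] for g in groups}
        im_index = {"south": 0, "north": 1, "west": 2}
    else:
        sizes3 = [p.ne_south, p.ne_north, p.ne_west]
        group_ne = {g: sizes3[i] for i, g in enumerate(groups)}
        im_index = {g: i for i, g in enumerate(groups)}
    members = {g: [q for q in pops if config.cluster_assignment[q] == g]
               for g in groups}
    n_demes = len(pops) + 5  # pop demes + 3 group ancestors + anc1 + root
    sizes = np.empty(n_demes)
    migr = np.zeros((n_demes, n_demes))
    for i, q in enumerate(pops):
        g = config.cluster_assignment[q]
        sizes[i] = group_ne[g] / len(members[g])
    anc_of_group = {g: len(pops) + im_index[g] for g in groups}
    sizes[len(pops):len(pops) + 3] = [group_ne[g] for g in sorted(groups, key=lambda g: im_index[g])]
    sizes[len(pops) + 3] = p.ne_anc1
    sizes[len(pops) + 4] = p.ne_anc2
    # within-group island migration between population demes
    for g in groups:
        for a in members[g]:
            for b in members[g]:
                if a != b:
                    migr[pops.index(a), pops.index(b)] = config.within_group_migrants
    # between-group migration spread over deme pairs
    for gi in groups:
        for gj in groups:
            if gi == gj:
                continue
            m = p.migrants[im_index[gi], im_index[gj]]
            for a in members[gi]:
                for b in members[gj]:
                    migr[pops.index(a), pops.index(b)] = m / (
                        len(members[gi]) * len(members[gj]))
            migr[anc_of_group[gi], anc_of_group[gj]] = m
    merges = [(config.pop_scatter_time, pops.index(q),
               anc_of_group[config.cluster_assignment[q]]) for q in pops]
    out = {"south_first": 0, "north_first": 1, "west_first": 2}[config.branching_order]
    pair = [i for i in range(3) if i != out]
    merges.append((p.t_recent, len(pops) + pair[0], len(pops) + 3))
    merges.append((p.t_recent, len(pops) + pair[1], len(pops) + 3))
    merges.append((p.t_root, len(pops) + out, len(pops) + 4))
    merges.append((p.t_root, len(pops) + 3, len(pops) + 4))
    dem = Demography(sizes=sizes, migrants=migr, merges=merges)
    samples = [config.pop_sizes[q] for q in pops] + [0] * 5
    return dem, samples


def gen_env(config: SynthConfig) -> pd.DataFrame:
    """Population x variable environmental table (linear field + noise)."""
    rng = stage_rng(config.seed, "env")
    grad = config.env_gradient
    pops = config.populations
    xy = np.array([config.coords[p] for p in pops])
    z = (xy - xy.mean(axis=0)) / xy.std(axis=0)
    cols = {}
    for k in range(grad.n_vars):
        if k == 0:
            direction = np.array([0.0, 1.0])  # latitude axis
        else:
            a = rng.uniform(0, 2 * np.pi)
            direction = np.array([np.cos(a), np.sin(a)])
        cols[f"env{k + 1}"] = grad.slope * z @ direction + rng.normal(
            0.0, grad.noise_sd, size=len(pops))
    return pd.DataFrame(cols, index=pops)


def gen_im_dataset(config: SynthConfig) -> SynthBundle:
    """Generate the full bundle: genotypes, popmap, coords, env, mitotypes.

    Genotypes come from the structured-coalescent simulator under the
    configured IM truth with one deme per population; missingness is applied
    uniformly at random; adaptive loci are spiked afterwards when
    ``config.n_adaptive > 0``.
    """
    dem, samples = _scatter_demography(config)
    pops = config.populations
    geno_seed = int(stage_rng(config.seed, "genotypes").integers(2**31 - 1))
    G = simulate_demography(dem, samples, config.n_loci, geno_seed,
                            mutation="snp", min_maf=config.ascertain_maf)
    # rename individuals to <pop>_<k>
    ids = []
    popmap = {}
    k = 0
    for d, q in enumerate(pops):
        for i in range(config.pop_sizes[q]):
            name = f"{q}_{i}"
            ids.append(name)
            popmap[name] = q
            k += 1
    G = GenotypeMatrix(G.calls, ids, list(G.locus_ids), fragments=G.fragments)
    if config.missing_rate > 0:
        rng = stage_rng(config.seed, "missing")
        mask = rng.random(G.calls.shape) < config.missing_rate
        G.calls[mask] = MISSING
    env = gen_env(config)
    coords = pd.DataFrame(
        [config.coords[p] for p in pops], index=pops, columns=["lon", "lat"])
    mitotypes = gen_mitotypes(
        popmap,
        {g: [f"{g}_h{j}" for j in range(3)] for g in config.groups},
        theta=config.mito_theta,
        groups={p: config.cluster_assignment[p] for p in pops},
        share=config.mito_share,
        seed=int(stage_rng(config.seed, "mito").integers(2**31 - 1)),
    )
    truth = {
        "adaptive_loci": [],
        "adaptive_beta": 0.0,
        "group_labels": dict(config.cluster_assignment),
        "im_params": config.im_params,
        "branching_order": config.branching_order,
        "seed": config.seed,
    }
    bundle = SynthBundle(G, popmap, coords, env, mitotypes, truth)
    if config.n_adaptive > 0:
        bundle = spike_adaptive_loci(
            bundle, config.adaptive_beta, config.n_adaptive,
            seed=int(stage_rng(config.seed, "spike").integers(2**31 - 1)))
    return bundle


def spike_adaptive_loci(
    bundle: SynthBundle, beta: float, n: int, seed: int = 0
) -> SynthBundle:
    """Overwrite ``n`` loci with an environmental cline in allele frequency.

    Population allele frequencies at the chosen loci become
    ``logistic(a0 + beta * z)`` where ``z`` is the standardized first
    environmental variable and ``a0`` preserves each locus's baseline
    frequency; individual genotypes are redrawn binomially from the new
    frequencies (missing calls stay missing).
    """
    G = bundle.genotypes
    if n > G.n_loci:
        raise ValueError(f"cannot spike {n} loci: only {G.n_loci} available")
    if bundle.env.shape[1] < 1:
        raise ValueError("bundle has no environmental variables")
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(G.n_loci, size=n, replace=False))
    zvals = bundle.env.iloc[:, 0]
    z = (zvals - zvals.mean()) / zvals.std()
    out = G.copy()
    pops = list(bundle.coords.index)
    obs = G.calls != MISSING
    for l in chosen:
        col = G.calls[:, l]
        seen = obs[:, l]
        base = col[seen].sum() / (2.0 * max(seen.sum(), 1))
        a0 = logit(np.clip(base, 0.05, 0.95))
        for q in pops:
            p_new = expit(a0 + beta * z[q])
            rows = [i for i, ind in enumerate(G.individual_ids)
                    if bundle.popmap[ind] == q]
            draws = rng.binomial(2, p_new, size=len(rows)).astype(np.int8)
            for r, d in zip(rows, draws):
                if out.calls[r, l] != MISSING:
                    out.calls[r, l] = d
    truth = dict(bundle.truth)
    truth["adaptive_loci"] = sorted(set(truth.get("adaptive_loci", []))
                                    | set(int(c) for c in chosen))
    truth["adaptive_beta"] = float(beta)
    return SynthBundle(out, dict(bundle.popmap), bundle.coords, bundle.env,
                       dict(bundle.mitotypes), truth)


def gen_mitotypes(
    popmap: Mapping[str, str],
    refugium_map: Mapping[str, Sequence[str]],
    theta: float = 0.08,
    groups: Mapping[str, str] | None = None,
    share: float = 0.0,
    seed: int = 0,
) -> dict[str, str]:
    """Draw maternally inherited haplotype labels with refugial structure.

    Each group (refugium lineage) owns a haplotype pool whose frequencies
    are a symmetric Dirichlet(``theta``) draw — small ``theta`` gives one
    dominant haplotype per refugium, hence high among-group differentiation.
    With probability ``share`` an individual instead draws uniformly from
    the union of all pools (rare seed exchange between regions).

    ``groups`` maps population -> group; when omitted, populations are
    assumed to be named directly by the ``refugium_map`` keys.
    """
    for g, pool in refugium_map.items():
        if len(pool) == 0:
            raise ValueError(f"refugium {g} has an empty haplotype pool")
    rng = np.random.default_rng(seed)
    # identical pools share one frequency draw: a single global pool means
    # panmixia, not independently drifted copies of the same pool
    pool_freqs: dict[tuple[str, ...], np.ndarray] = {}
    group_freqs = {}
    for g in sorted(refugium_map):
        pool = tuple(refugium_map[g])
        if pool not in pool_freqs:
            pool_freqs[pool] = (rng.dirichlet(np.full(len(pool), theta))
                                if len(pool) > 1 else np.ones(1))
        group_freqs[g] = (list(pool), pool_freqs[pool])
    union = sorted({h for pool in refugium_map.values() for h in pool})
    out = {}
    for ind in popmap:
        pop = popmap[ind]
        g = groups[pop] if groups is not None else pop
        if g not in group_freqs:
            raise KeyError(f"no haplotype pool for group {g}")
        if share > 0 and rng.random() < share:
            out[ind] = union[rng.integers(len(union))]
        else:
            pool, freqs = group_freqs[g]
            out[ind] = pool[rng.choice(len(pool), p=freqs)]
    return out


@dataclass
class NicheSample:
    """Occurrence and background points of one group with env vectors."""

    group: str
    occurrences: pd.DataFrame  # columns lon, lat, env1..envK
    background: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.occurrences.columns) != list(self.background.columns):
            raise ValueError("occurrence/background columns differ")

    @property
    def env_columns(self) -> list[str]:
        return [c for c in self.occurrences.columns if c not in ("lon", "lat")]


@dataclass
class SuitabilityGrid:
    """Normalized habitat-suitability surface on a lon/lat raster."""

    values: np.ndarray
    extent: tuple[float, float, float, float]  # lon0, lon1, lat0, lat1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("suitability values must be >= 0")

    def normalized(self) -> "SuitabilityGrid":
        tot = self.values.sum()
        if tot <= 0:
            raise ValueError("cannot normalize an all-zero grid")
        return SuitabilityGrid(self.values / tot, self.extent)


def kde_suitability(points_xy: np.ndarray,
                    extent: tuple[float, float, float, float],
                    grid_shape: tuple[int, int]) -> SuitabilityGrid:
    """Normalized Gaussian-KDE suitability surface from occurrence points."""
    kde = gaussian_kde(points_xy.T)
    gx = np.linspace(extent[0], extent[1], grid_shape[1])
    gy = np.linspace(extent[2], extent[3], grid_shape[0])
    xx, yy = np.meshgrid(gx, gy)
    vals = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(grid_shape)
    return SuitabilityGrid(vals, extent).normalized()


def gen_niche_points(
    centers: Mapping[str, Sequence[float]],
    spread: float = 1.0,
    n_occ: int = 55,
    n_bg: int = 1000,
    grid_shape: tuple[int, int] = (60, 60),
    n_env: int = 14,
    seed: int = 0,
) -> tuple[dict[str, NicheSample], dict[str, SuitabilityGrid]]:
    """Occurrences, backgrounds and suitability grids for each group.

    ``centers`` maps group -> geographic center (lon, lat). Occurrences are
    Gaussian around the center with sd ``spread``; background points are
    uniform over the group's envelope (center +/- 4*spread). Environmental
    vectors are linear responses to the coordinates plus noise, so groups
    with distinct geographic centers occupy distinct environmental niches.
    """
    if n_occ < 4:
        raise ValueError("need at least 4 occurrences per group for resampling")
    if n_env < 2:
        raise ValueError("need at least two environmental variables")
    rng = np.random.default_rng(seed)
    # shared linear env field: direction per variable, var 1 along latitude
    dirs = [np.array([0.0, 1.0])]
    for _ in range(n_env - 1):
        a = rng.uniform(0, 2 * np.pi)
        dirs.append(np.array([np.cos(a), np.sin(a)]))

    def env_of(xy: np.ndarray) -> np.ndarray:
        cols = [xy @ d + rng.normal(0, 0.3 * spread, size=len(xy)) for d in dirs]
        return np.column_stack(cols)

    samples = {}
    grids = {}
    for g in sorted(centers):
        c = np.asarray(centers[g], dtype=float)
        occ_xy = rng.normal(c, spread, size=(n_occ, 2))
        lo, hi = c - 4 * spread, c + 4 * spread
        bg_xy = rng.uniform(lo, hi, size=(n_bg, 2))
        cols = ["lon", "lat"] + [f"env{k + 1}" for k in range(n_env)]
        occ = pd.DataFrame(np.column_stack([occ_xy, env_of(occ_xy)]), columns=cols)
        bg = pd.DataFrame(np.column_stack([bg_xy, env_of(bg_xy)]), columns=cols)
        samples[g] = NicheSample(g, occ, bg)
    all_xy = np.vstack([s.occurrences[["lon", "lat"]].to_numpy()
                        for s in samples.values()])
    pad = 2 * spread
    extent = (all_xy[:, 0].min() - pad, all_xy[:, 0].max() + pad,
              all_xy[:, 1].min() - pad, all_xy[:, 1].max() + pad)
    for g, s in samples.items():
        grids[g] = kde_suitability(s.occurrences[["lon", "lat"]].to_numpy(),
                                   extent, grid_shape)
    return samples, grids
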