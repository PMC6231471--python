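"""Demographic model descriptions: generic deme graphs and the 3-group IM family.

The three-population isolation-with-migration (IM) family covers nine models:
three branching orders (which extant group split off first) crossed with
three size histories in the descendant groups (constant, exponential growth
since the split, recent exponential growth).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

POPS = ("south", "north", "west")
BRANCHING_ORDERS = ("south_first", "north_first", "west_first")
GROWTH_MODES = ("constant", "exponential", "recent_exponential")


@dataclass
class Demography:
    """A deme graph for the structured coalescent.

    ``sizes`` are current diploid effective sizes per deme; ``growth_rate``
    (per generation, >= 0) shrinks a deme backward in time until backward time
    ``growth_end``; ``migrants`` is migrants-per-generation (individuals)
    received by deme *i* from deme *j* forward in time; ``merges`` are
    ``(backward_time, source_deme, dest_deme)`` lineage-movement events.
    """

    sizes: np.ndarray
    migrants: np.ndarray
    merges: list[tuple[float, int, int]] = field(default_factory=list)
    growth_rate: np.ndarray | None = None
    growth_end: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=float)
        nd = self.sizes.shape[0]
        self.migrants = np.asarray(self.migrants, dtype=float)
        if self.migrants.shape != (nd, nd):
            raise ValueError("migrants must be n_demes x n_demes")
        if (self.sizes <= 0).any():
            raise ValueError("deme sizes must be positive")
        if (self.migrants < 0).any():
            raise ValueError("migration must be non-negative")
        if self.growth_rate is None:
            self.growth_rate = np.zeros(nd)
        if self.growth_end is None:
            self.growth_end = np.full(nd, np.inf)
        self.growth_rate = np.asarray(self.growth_rate, dtype=float)
        self.growth_end = np.asarray(self.growth_end, dtype=float)
        if (self.growth_rate < 0).any():
            raise ValueError("growth rates must be >= 0 (forward growth only)")
        for t, s, d in self.merges:
            if t <= 0:
                raise ValueError("merge times must be positive (backward)")
            if not (0 <= s < nd and 0 <= d < nd and s != d):
                raise ValueError("merge demes out of range")

    @property
    def n_demes(self) -> int:
        return self.sizes.shape[0]

    def engine_arrays(self):
        """Arrays consumed by the jitted simulator.

        Forward migrant counts are converted to backward per-lineage rates
        m_ij = M_ij / N_i evaluated at current sizes; the diagonal is zeroed.
        """
        mig = self.migrants / self.sizes[:, None]
        np.fill_diagonal(mig, 0.0)
        order = sorted(self.merges)
        ev_time = np.array([e[0] for e in order], dtype=float)
        ev_src = np.array([e[1] for e in order], dtype=np.int64)
        ev_dst = np.array([e[2] for e in order], dtype=np.int64)
        return (self.sizes.copy(), self.growth_rate.copy(), self.growth_end.copy(),
                np.ascontiguousarray(mig), ev_time, ev_src, ev_dst)


@dataclass
class IMParams:
    """Parameters of the three-group IM models.

    Sizes are diploid effective sizes; times are in generations before
    present with ``t_root > t_recent``: ``t_root`` is the first split
    (outgroup vs the ancestor of the remaining pair) and ``t_recent`` the
    later split of that pair. ``migrants[i, j]`` is migrants per generation
    received by group *i* from group *j*, ordered (south, north, west);
    migration acts between extant groups only.
    """

    ne_south: float
    ne_north: float
    ne_west: float
    ne_anc1: float
    ne_anc2: float
    t_root: float
    t_recent: float
    migrants: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    growth_mode: str = "constant"
    growth_rate: float = 0.0
    growth_onset: float = 0.0

    def __post_init__(self) -> None:
        self.migrants = np.asarray(self.migrants, dtype=float)
        for name in ("ne_south", "ne_north", "ne_west", "ne_anc1", "ne_anc2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.t_root > self.t_recent > 0:
            raise ValueError("need t_root > t_recent > 0")
        if self.migrants.shape != (3, 3) or (self.migrants < 0).any():
            raise ValueError("migrants must be a non-negative 3x3 matrix")
        if self.growth_mode not in GROWTH_MODES:
            raise ValueError(f"growth_mode must be one of {GROWTH_MODES}")
        if self.growth_mode != "constant" and self.growth_rate < 0:
            raise ValueError("growth_rate must be >= 0")
        if self.growth_mode == "recent_exponential" and not (
            0 < self.growth_onset < self.t_recent
        ):
            raise ValueError("growth_onset must lie in (0, t_recent)")

    def extant_sizes(self) -> np.ndarray:
        return np.array([self.ne_south, self.ne_north, self.ne_west])

    def replace(self, **kw) -> "IMParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class ModelSpec:
    """One of the nine IM model variants plus the list of free parameters.

    ``free`` maps an :class:`IMParams` field name (or ``"migrants"``, fitted
    as a single shared symmetric rate) to log10 search bounds.
    """

    branching_order: str = "south_first"
    growth_mode: str = "constant"
    free: tuple[tuple[str, tuple[float, float]], ...] = ()

    def __post_init__(self) -> None:
        if self.branching_order not in BRANCHING_ORDERS:
            raise ValueError(f"branching_order must be one of {BRANCHING_ORDERS}")
        if self.growth_mode not in GROWTH_MODES:
            raise ValueError(f"growth_mode must be one of {GROWTH_MODES}")

    @property
    def n_free(self) -> int:
        return len(self.free)

    @property
    def outgroup(self) -> int:
        return {"south_first": 0, "north_first": 1, "west_first": 2}[
            self.branching_order
        ]


def im_demography(params: IMParams, branching_order: str = "south_first") -> Demography:
    """Build the 5-deme graph of one IM model.

    Demes 0..2 are the extant groups (south, north, west), deme 3 the
    ancestor of the two later-diverging groups (size ``ne_anc1``), deme 4
    the root (size ``ne_anc2``). The outgroup set by ``branching_order``
    joins the root directly at ``t_root``; the other two merge into deme 3
    at ``t_recent``.
    """
    out = {"south_first": 0, "north_first": 1, "west_first": 2}[branching_order]
    pair = [i for i in range(3) if i != out]
    sizes = np.array([params.ne_south, params.ne_north, params.ne_west,
                      params.ne_anc1, params.ne_anc2])
    mig = np.zeros((5, 5))
    mig[:3, :3] = params.migrants
    merges = [
        (params.t_recent, pair[0], 3),
        (params.t_recent, pair[1], 3),
        (params.t_root, out, 4),
        (params.t_root, 3, 4),
    ]
    growth = np.zeros(5)
    g_end = np.full(5, np.inf)
    if params.growth_mode != "constant":
        growth[:3] = params.growth_rate
        if params.growth_mode == "recent_exponential":
            g_end[:3] = params.growth_onset
        else:
            # growth since the split of each branch
            g_end[out] = params.t_root
            g_end[pair] = params.t_recent
    return Demography(sizes=sizes, migrants=mig, merges=merges,
                      growth_rate=growth, growth_end=g_end)
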