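"""Genotype simulation from the structured coalescent.

Each locus is a single biallelic site on an independent genealogy
(unlinked loci, infinite-sites mutation). Two mutation conventions:

``"snp"``
    SNP-ascertained loci: genealogies are drawn in a pool, loci pick a
    genealogy with probability proportional to its total branch length and
    then a branch proportional to length — i.e. sites conditioned on being
    segregating in the sample. Every emitted locus is polymorphic.
``"poisson"``
    One genealogy per locus; the locus carries a mutation with probability
    1 - exp(-mu * L) (at most one site retained). Monomorphic loci are kept
    as all-reference columns, so nucleotide-diversity expectations such as
    pi = 4*Ne*mu hold per locus.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from ..core import GenotypeMatrix
from . import _engine
from .model import Demography, IMParams, im_demography


def simulate_demography(
    dem: Demography,
    samples_per_deme: Sequence[int],
    n_loci: int,
    seed: int,
    mutation: str = "snp",
    mu: float | None = None,
    pop_of_deme: Sequence[int] | None = None,
    min_maf: float = 0.0,
    individual_prefix: str = "ind",
    locus_prefix: str = "L",
) -> GenotypeMatrix:
    """Simulate diploid genotypes for samples drawn from a deme graph.

    ``samples_per_deme[d]`` diploid individuals are sampled from deme *d*;
    each contributes two haploid lineages. ``pop_of_deme`` maps demes to
    output "population" axes (defaults to identity) — it only labels the
    SFS axes and has no dynamical role here. With ``min_maf`` > 0 (snp
    mode only) loci are ascertained to have pooled minor-allele frequency
    at or above the threshold, emulating a quality-filtered SNP panel.
    """
    samples_per_deme = np.asarray(samples_per_deme, dtype=np.int64)
    if (samples_per_deme < 0).any() or samples_per_deme.sum() == 0:
        raise ValueError("need a positive number of sampled individuals")
    if mutation not in ("snp", "poisson"):
        raise ValueError("mutation must be 'snp' or 'poisson'")
    if mutation == "poisson" and (mu is None or mu <= 0):
        raise ValueError("poisson mutation model needs a positive mu")
    if pop_of_deme is None:
        pop_of_deme = np.arange(dem.n_demes, dtype=np.int64)
    pop_of_deme = np.asarray(pop_of_deme, dtype=np.int64)
    sample_deme = np.repeat(np.arange(dem.n_demes), 2 * samples_per_deme)
    sample_pop = pop_of_deme[sample_deme]
    n_pops = int(sample_pop.max()) + 1
    n0, alpha, t_end, mig, ev_t, ev_s, ev_d = dem.engine_arrays()
    rng = np.random.default_rng(seed)
    engine_seed = int(rng.integers(0, 2**31 - 1))

    n_trees = int(n_loci)
    zero_draws = np.zeros(n_trees, dtype=np.int64)
    no_uniforms = np.zeros(0)
    # pass 1: lengths only (no descendant tracking)
    _, lengths = _engine.sim_carriers(
        engine_seed, n_trees, zero_draws, no_uniforms, sample_deme, sample_pop,
        n_pops, n0, alpha, t_end, mig, ev_t, ev_s, ev_d, False)
    n_hap = sample_deme.shape[0]

    def draw_carriers(tree_idx: np.ndarray) -> np.ndarray:
        """Sample one length-weighted branch per requested tree (pass 2)."""
        draws = np.bincount(tree_idx, minlength=n_trees).astype(np.int64)
        uniforms = rng.random(int(draws.sum()))
        carriers, lengths2 = _engine.sim_carriers(
            engine_seed, n_trees, draws, uniforms, sample_deme, sample_pop,
            n_pops, n0, alpha, t_end, mig, ev_t, ev_s, ev_d, True)
        assert np.allclose(lengths, lengths2)
        # carrier rows come grouped by tree; restore the request order
        order = np.argsort(tree_idx, kind="stable")
        out = np.zeros((tree_idx.size, n_hap), dtype=np.uint8)
        out[order] = carriers
        return out

    if mutation == "snp":
        probs = lengths / lengths.sum()
        hap_rows = []
        need = n_loci
        attempts = 0
        while need > 0:
            attempts += 1
            if attempts > 50:
                raise RuntimeError("SNP ascertainment kept rejecting loci; "
                                   "min_maf too high for this demography")
            batch = need if min_maf <= 0 else max(4 * need, 64)
            rows = draw_carriers(rng.choice(n_trees, size=batch, p=probs))
            if min_maf > 0:
                freq = rows.mean(axis=1)
                ok = np.minimum(freq, 1 - freq) >= min_maf
                rows = rows[ok]
            hap_rows.append(rows[:need])
            need -= len(rows[:need])
        hap = np.vstack(hap_rows)
    else:
        if min_maf > 0:
            raise ValueError("min_maf ascertainment applies to snp mode only")
        p_seg = -np.expm1(-mu * lengths)
        segregating = rng.random(n_loci) < p_seg
        hap = np.zeros((n_loci, n_hap), dtype=np.uint8)
        hap[segregating] = draw_carriers(np.flatnonzero(segregating))
    dosage = (hap[:, 0::2] + hap[:, 1::2]).astype(np.int8).T  # individuals x loci
    ind_ids = []
    for d in range(dem.n_demes):
        for i in range(samples_per_deme[d]):
            ind_ids.append(f"{individual_prefix}{d}_{i}")
    locus_ids = [f"{locus_prefix}{i}" for i in range(n_loci)]
    return GenotypeMatrix(
        calls=dosage,
        individual_ids=ind_ids,
        locus_ids=locus_ids,
        fragments=np.arange(n_loci),
    )


def simulate_im(
    params: IMParams,
    n_loci: int,
    samples_per_pop: Sequence[int],
    seed: int,
    branching_order: str = "south_first",
    mutation: str = "snp",
    mu: float | None = None,
    min_maf: float = 0.0,
) -> GenotypeMatrix:
    """Simulate genotypes for the three extant IM groups (south, north, west)."""
    samples_per_pop = list(samples_per_pop)
    if len(samples_per_pop) != 3:
        raise ValueError("samples_per_pop must list the three extant groups")
    dem = im_demography(params, branching_order)
    samples = samples_per_pop + [0, 0]
    return simulate_demography(
        dem, samples, n_loci, seed, mutation=mutation, mu=mu,
        min_maf=min_maf, pop_of_deme=[0, 1, 2, 0, 0])
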