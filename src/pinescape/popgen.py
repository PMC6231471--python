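"""SNP filtering and diversity/differentiation statistics.

Implements the GBS quality-control chain (genotype-level masking, then
locus-level filtering), per-population diversity summaries, the
Weir & Cockerham (1984) variance-component F\\ :sub:`ST` estimator, and
unbiased haplotype (mitotype) diversity.

Filtering semantics follow the printed inequalities of the source pipeline:
loci are dropped when MAF < ``maf_min``, missing rate >= ``missing_rate_max``,
observed heterozygote fraction > ``het_max``, mean depth >= ``mean_depth_max``,
or when genotyped in fewer than ``min_genotyped_per_pop`` individuals in any
population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, PopAlleleFreqs, membership_indices


@dataclass
class FilterSpec:
    """Locus- and genotype-level SNP filter thresholds.

    Defaults mirror a stringent GBS pipeline for a conifer panel: MAF >= 0.05,
    per-locus missing rate < 0.3, observed heterozygosity <= 50%, mean depth
    < 400 reads, and at least 4 genotyped individuals in every population.
    """

    maf_min: float = 0.05
    missing_rate_max: float = 0.3
    het_max: float = 0.5
    mean_depth_max: float | None = 400.0
    min_genotyped_per_pop: int = 4
    gq_min: float = 20.0
    dp_min: float = 5.0

    def __post_init__(self) -> None:
        for name in ("maf_min", "missing_rate_max", "het_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a fraction in [0, 1], got {v}")
        if self.min_genotyped_per_pop < 0:
            raise ValueError("min_genotyped_per_pop must be >= 0")


def mask_genotypes(
    G: GenotypeMatrix, gq_min: float = 20.0, dp_min: float = 5.0
) -> GenotypeMatrix:
    """Mask genotype calls below quality/depth thresholds as missing.

    Calls with GQ < ``gq_min`` or depth < ``dp_min`` become missing; no locus
    is removed. If the matrix carries no quality layers the operation is the
    identity (with a warning).
    """
    if G.gq is None and G.depth is None:
        warnings.warn("no GQ/DP layers present; mask_genotypes is a no-op")
        return G
    out = G.copy()
    bad = np.zeros(out.calls.shape, dtype=bool)
    if out.gq is not None:
        bad |= out.gq < gq_min
    if out.depth is not None:
        bad |= out.depth < dp_min
    out.calls[bad] = MISSING
    return out


def _locus_stats(calls: np.ndarray) -> dict[str, np.ndarray]:
    """Pooled per-locus allele/genotype summaries used by the filters."""
    obs = calls != MISSING
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt = np.where(obs, calls, 0).sum(axis=0)
        p_alt = alt / (2.0 * n_obs)
        maf = np.minimum(p_alt, 1.0 - p_alt)
        het = np.where(obs, calls == 1, False).sum(axis=0) / n_obs
    miss_rate = 1.0 - n_obs / calls.shape[0]
    return {"n_obs": n_obs, "maf": maf, "het": het, "missing": miss_rate}


def filter_loci(
    G: GenotypeMatrix,
    spec: FilterSpec,
    popmap: Mapping[str, str],
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply locus-level filters; return survivors and a rejection report.

    The report has one row per dropped locus with the *first* failing rule
    in the fixed order maf, missing, het, depth, per_pop_n.
    """
    missing_pm = [i for i in G.individual_ids if i not in popmap]
    if missing_pm:
        raise KeyError(f"popmap does not cover individuals: {missing_pm[:5]}")
    stats = _locus_stats(G.calls)
    rules: list[tuple[str, np.ndarray]] = []
    with np.errstate(invalid="ignore"):
        rules.append(("maf", stats["maf"] < spec.maf_min))
        rules.append(("missing", stats["missing"] >= spec.missing_rate_max))
        rules.append(("het", stats["het"] > spec.het_max))
    if spec.mean_depth_max is not None and G.depth is not None:
        mean_dp = np.where(G.calls != MISSING, G.depth, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_dp = np.nanmean(mean_dp, axis=0)
        rules.append(("depth", mean_dp >= spec.mean_depth_max))
    _, groups = membership_indices(G.individual_ids, popmap)
    per_pop_n = np.stack([(G.calls[idx] != MISSING).sum(axis=0) for idx in groups])
    rules.append(("per_pop_n", (per_pop_n < spec.min_genotyped_per_pop).any(axis=0)))
    # loci where nothing was observed at all fail "missing" (rate 1.0) already
    drop = np.zeros(G.n_loci, dtype=bool)
    reason = np.full(G.n_loci, "", dtype=object)
    for name, bad in rules:
        bad = np.asarray(bad, dtype=bool)
        newly = bad & ~drop
        reason[newly] = name
        drop |= bad
    report = pd.DataFrame(
        {"locus_id": [G.locus_ids[i] for i in np.flatnonzero(drop)],
         "rule": reason[drop]}
    )
    keep = np.flatnonzero(~drop)
    if keep.size == 0:
        warnings.warn("all loci removed by filters")
    return G.take_loci(keep), report


def pop_allele_freqs(G: GenotypeMatrix, popmap: Mapping[str, str]) -> PopAlleleFreqs:
    """Alt-allele frequency per population x locus with allele sample sizes."""
    pops, groups = membership_indices(G.individual_ids, popmap)
    freqs = np.full((len(pops), G.n_loci), np.nan)
    n_alleles = np.zeros((len(pops), G.n_loci), dtype=np.int64)
    for k, idx in enumerate(groups):
        sub = G.calls[idx]
        obs = sub != MISSING
        n = 2 * obs.sum(axis=0)
        alt = np.where(obs, sub, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[k] = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
        n_alleles[k] = n
    return PopAlleleFreqs(freqs, n_alleles, pops, list(G.locus_ids))


def diversity_summary(G: GenotypeMatrix, popmap: Mapping[str, str]) -> pd.DataFrame:
    """Per-population %polymorphic loci and mean observed heterozygosity.

    %Poly counts loci at which both alleles are observed within the
    population; Het averages, over loci with any data, the heterozygote
    fraction among non-missing individuals.
    """
    pops, groups = membership_indices(G.individual_ids, popmap)
    rows = []
    for pop, idx in zip(pops, groups):
        sub = G.calls[idx]
        obs = sub != MISSING
        n_obs = obs.sum(axis=0)
        alt = np.where(obs, sub, 0).sum(axis=0)
        seen = n_obs > 0
        poly = (alt > 0) & (alt < 2 * n_obs)
        with np.errstate(invalid="ignore", divide="ignore"):
            het_locus = np.where(obs, sub == 1, False).sum(axis=0) / n_obs
        rows.append(
            {
                "population": pop,
                "n": len(idx),
                "pct_polymorphic": 100.0 * poly[seen].mean() if seen.any() else np.nan,
                "heterozygosity": float(np.nanmean(het_locus[seen])) if seen.any() else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("population")


def wc_fst_components(
    G: GenotypeMatrix, popmap: Mapping[str, str], grouping: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Per-locus Weir & Cockerham (1984) variance components a, b, c.

    ``grouping`` optionally collapses populations into higher-level groups
    (the differentiation units); by default each population is its own unit.
    Returns one row per locus (NaN components where fewer than two units
    have data).
    """
    units: Mapping[str, str]
    if grouping is None:
        units = dict(popmap)
    else:
        units = {ind: grouping[pop] for ind, pop in popmap.items()}
    labels, groups = membership_indices(G.individual_ids, units)
    if len(labels) < 2:
        raise ValueError("need at least two groups for FST")
    L = G.n_loci
    # per-unit per-locus: sample size (individuals), alt freq, het fraction
    n_i = np.stack([(G.calls[idx] != MISSING).sum(axis=0) for idx in groups]).astype(float)
    alt_i = np.stack([np.where(G.calls[idx] != MISSING, G.calls[idx], 0).sum(axis=0)
                      for idx in groups]).astype(float)
    het_i = np.stack([np.where(G.calls[idx] != MISSING, G.calls[idx] == 1, False).sum(axis=0)
                      for idx in groups]).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_i = alt_i / (2.0 * n_i)
        h_i = het_i / n_i
    have = n_i > 0
    r = have.sum(axis=0).astype(float)  # units with data, per locus
    a = np.full(L, np.nan)
    b = np.full(L, np.nan)
    c = np.full(L, np.nan)
    ok = r >= 2
    n_sum = np.where(have, n_i, 0.0).sum(axis=0)
    n_bar = n_sum / np.maximum(r, 1.0)
    n_sq = np.where(have, n_i**2, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (n_sum - n_sq / n_sum) / (r - 1.0)
        p_bar = np.where(have, n_i * np.nan_to_num(p_i), 0.0).sum(axis=0) / n_sum
        s2 = np.where(have, n_i * (np.nan_to_num(p_i) - p_bar) ** 2, 0.0).sum(axis=0) / (
            (r - 1.0) * n_bar
        )
        h_bar = np.where(have, n_i * np.nan_to_num(h_i), 0.0).sum(axis=0) / n_sum
        a_ = (n_bar / n_c) * (
            s2
            - (1.0 / (n_bar - 1.0))
            * (p_bar * (1 - p_bar) - ((r - 1.0) / r) * s2 - h_bar / 4.0)
        )
        b_ = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1 - p_bar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * n_bar - 1.0) / (4.0 * n_bar)) * h_bar
        )
        c_ = h_bar / 2.0
    a[ok], b[ok], c[ok] = a_[ok], b_[ok], c_[ok]
    return pd.DataFrame({"a": a, "b": b, "c": c}, index=G.locus_ids)


def wc_fst(
    G: GenotypeMatrix,
    popmap: Mapping[str, str],
    grouping: Mapping[str, str] | None = None,
) -> tuple[pd.Series, float, int]:
    """Per-locus theta and the multilocus ratio-of-sums estimate.

    Returns ``(per_locus_theta, multilocus_theta, n_undefined)`` where
    undefined loci (a+b+c == 0 or no data) are excluded from both the
    per-locus series denominator handling and the multilocus sums.
    """
    comp = wc_fst_components(G, popmap, grouping)
    denom = comp["a"] + comp["b"] + comp["c"]
    defined = np.isfinite(denom) & (denom != 0)
    theta = pd.Series(np.nan, index=comp.index, name="theta")
    theta[defined] = comp["a"][defined] / denom[defined]
    multi = float(comp["a"][defined].sum() / denom[defined].sum())
    return theta, multi, int((~defined).sum())


def haplotype_diversity(counts: Sequence[int], ndigits: int | None = 3) -> float:
    """Unbiased haplotype diversity He = n/(n-1) (1 - sum p_i^2).

    ``counts`` are haplotype counts in one population; ``n`` is their sum.
    Rounded to ``ndigits`` decimals (pass None for full precision).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0 or (counts <= 0).any() or not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be positive integers")
    n = counts.sum()
    if n < 2:
        raise ValueError("need at least two sampled haplotypes")
    he = n / (n - 1.0) * (1.0 - ((counts / n) ** 2).sum())
    return round(float(he), ndigits) if ndigits is not None else float(he)


def mitotype_fst(mitotypes: Mapping[str, str], groups: Mapping[str, str]) -> float:
    """Among-group haplotype differentiation G\\ :sub:`ST` = (Ht - Hs) / Ht.

    ``mitotypes`` maps individual -> haplotype label; ``groups`` maps
    individual -> group. Uses unweighted Nei diversities over groups.
    """
    inds = list(mitotypes)
    labs = sorted(set(groups[i] for i in inds))
    haps = sorted(set(mitotypes.values()))
    hap_idx = {h: k for k, h in enumerate(haps)}
    freqs = []
    for g in labs:
        members = [i for i in inds if groups[i] == g]
        cnt = np.zeros(len(haps))
        for i in members:
            cnt[hap_idx[mitotypes[i]]] += 1
        freqs.append(cnt / cnt.sum())
    freqs = np.stack(freqs)
    hs = float(np.mean(1.0 - (freqs**2).sum(axis=1)))
    pbar = freqs.mean(axis=0)
    ht = float(1.0 - (pbar**2).sum())
    if ht == 0:
        return 0.0
    return (ht - hs) / ht
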