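"""Filtering, diversity and differentiation statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pinescape.core import MISSING, GenotypeMatrix
from pinescape.popgen import (FilterSpec, diversity_summary, filter_loci,
                              haplotype_diversity, mask_genotypes,
                              mitotype_fst, pop_allele_freqs, wc_fst,
                              wc_fst_components)


def _matrix(calls, depth=None, gq=None):
    calls = np.asarray(calls, dtype=np.int8)
    n, L = calls.shape
    return GenotypeMatrix(calls, [f"i{k}" for k in range(n)],
                          [f"L{k}" for k in range(L)],
                          depth=None if depth is None else np.asarray(depth),
                          gq=None if gq is None else np.asarray(gq))


class TestMasking:
    def test_all_above_thresholds_is_identity(self):
        G = _matrix([[0, 1], [2, 1]], depth=[[10, 10], [10, 10]],
                    gq=[[30, 30], [30, 30]])
        out = mask_genotypes(G)
        assert np.array_equal(out.calls, G.calls)

    def test_single_low_depth_cell_masked(self):
        G = _matrix([[0, 1], [2, 1]], depth=[[10, 4], [10, 10]],
                    gq=[[30, 30], [30, 30]])
        out = mask_genotypes(G)
        assert out.calls[0, 1] == MISSING
        assert (out.calls != MISSING).sum() == 3

    def test_no_layers_is_identity_with_warning(self):
        G = _matrix([[0, 1], [2, 1]])
        with pytest.warns(UserWarning):
            out = mask_genotypes(G)
        assert np.array_equal(out.calls, G.calls)

    def test_mask_matches_cellwise_oracle(self):
        rng = np.random.default_rng(7)
        calls = rng.integers(0, 3, (5, 5)).astype(np.int8)
        depth = rng.integers(0, 20, (5, 5))
        gq = rng.integers(0, 40, (5, 5))
        out = mask_genotypes(_matrix(calls, depth, gq), gq_min=20, dp_min=5)
        for i in range(5):
            for j in range(5):
                expect = MISSING if (gq[i, j] < 20 or depth[i, j] < 5) else calls[i, j]
                assert out.calls[i, j] == expect


class TestFilterLoci:
    def _brute_force_keep(self, G, spec, popmap):
        keep = []
        pops = sorted(set(popmap.values()))
        for j in range(G.n_loci):
            col = G.calls[:, j]
            obs = col != MISSING
            if not obs.any():
                continue
            p = col[obs].sum() / (2 * obs.sum())
            if min(p, 1 - p) < spec.maf_min:
                continue
            if 1 - obs.mean() >= spec.missing_rate_max:
                continue
            if (col[obs] == 1).mean() > spec.het_max:
                continue
            ok = True
            for pop in pops:
                rows = [i for i, ind in enumerate(G.individual_ids)
                        if popmap[ind] == pop]
                if (col[rows] != MISSING).sum() < spec.min_genotyped_per_pop:
                    ok = False
            if ok:
                keep.append(G.locus_ids[j])
        return keep

    def test_maf_dropped_with_reason(self):
        # one locus at MAF 0.04 (2 alt alleles in 25 diploids), one common
        calls = np.zeros((25, 2), dtype=np.int8)
        calls[0, 0] = 2
        calls[:12, 1] = 1
        G = _matrix(calls)
        popmap = {f"i{k}": "A" for k in range(25)}
        out, report = filter_loci(G, FilterSpec(min_genotyped_per_pop=0), popmap)
        assert out.locus_ids == ["L1"]
        assert report.set_index("locus_id").loc["L0", "rule"] == "maf"

    def test_underfilled_population_dropped(self):
        calls = np.tile([0, 1, 2, 1, 0, 1, 2, 1], (3, 1)).T.astype(np.int8)
        calls[4:, 0] = MISSING  # pop B genotyped in 0 < 4 at locus 0
        calls[4, 0] = 1  # 1 genotyped individual only
        G = _matrix(calls)
        popmap = {f"i{k}": ("A" if k < 4 else "B") for k in range(8)}
        out, report = filter_loci(
            G, FilterSpec(maf_min=0, missing_rate_max=1.0, het_max=1.0), popmap)
        assert "L0" not in out.locus_ids
        assert report.set_index("locus_id").loc["L0", "rule"] == "per_pop_n"

    def test_survivors_match_brute_force(self, toy_matrix):
        G, popmap = toy_matrix
        spec = FilterSpec(maf_min=0.1, missing_rate_max=0.3, het_max=0.6,
                          min_genotyped_per_pop=3)
        out, _ = filter_loci(G, spec, popmap)
        assert out.locus_ids == self._brute_force_keep(G, spec, popmap)

    def test_idempotent(self, toy_matrix):
        G, popmap = toy_matrix
        spec = FilterSpec(maf_min=0.1, min_genotyped_per_pop=2)
        once, _ = filter_loci(G, spec, popmap)
        twice, report = filter_loci(once, spec, popmap)
        assert twice.locus_ids == once.locus_ids
        assert report.empty


class TestAlleleFreqs:
    def test_two_individuals_half(self):
        G = _matrix([[0], [2]])
        freqs = pop_allele_freqs(G, {"i0": "A", "i1": "A"})
        assert freqs.freqs[0, 0] == 0.5
        assert freqs.n_alleles[0, 0] == 4

    def test_all_missing_cell_flagged(self):
        G = _matrix([[MISSING], [MISSING]])
        freqs = pop_allele_freqs(G, {"i0": "A", "i1": "A"})
        assert freqs.empty[0, 0]
        assert np.isnan(freqs.freqs[0, 0])

    def test_matches_counting_oracle(self, toy_matrix):
        G, popmap = toy_matrix
        freqs = pop_allele_freqs(G, popmap)
        for pi, pop in enumerate(freqs.populations):
            rows = [i for i, ind in enumerate(G.individual_ids)
                    if popmap[ind] == pop]
            for j in range(G.n_loci):
                vals = [G.calls[i, j] for i in rows if G.calls[i, j] != MISSING]
                if vals:
                    assert freqs.freqs[pi, j] == pytest.approx(
                        sum(vals) / (2 * len(vals)))
                else:
                    assert freqs.empty[pi, j]


class TestDiversity:
    def test_monomorphic_population(self):
        G = _matrix(np.zeros((4, 5)))
        df = diversity_summary(G, {f"i{k}": "A" for k in range(4)})
        assert df.loc["A", "pct_polymorphic"] == 0
        assert df.loc["A", "heterozygosity"] == 0

    def test_all_heterozygous(self):
        G = _matrix(np.ones((4, 5)))
        df = diversity_summary(G, {f"i{k}": "A" for k in range(4)})
        assert df.loc["A", "heterozygosity"] == 1.0

    def test_matches_enumeration(self, toy_matrix):
        G, popmap = toy_matrix
        df = diversity_summary(G, popmap)
        rows = [i for i, ind in enumerate(G.individual_ids) if popmap[ind] == "A"]
        polys, hets = [], []
        for j in range(G.n_loci):
            vals = [G.calls[i, j] for i in rows if G.calls[i, j] != MISSING]
            if not vals:
                continue
            alt = sum(vals)
            polys.append(0 < alt < 2 * len(vals))
            hets.append(np.mean([v == 1 for v in vals]))
        assert df.loc["A", "pct_polymorphic"] == pytest.approx(100 * np.mean(polys))
        assert df.loc["A", "heterozygosity"] == pytest.approx(np.mean(hets))


def _wc_oracle(G, popmap):
    """Term-wise Weir & Cockerham (1984) components, straight loops."""
    pops = sorted(set(popmap.values()))
    out = []
    for j in range(G.n_loci):
        n_i, p_i, h_i = [], [], []
        for pop in pops:
            rows = [i for i, ind in enumerate(G.individual_ids)
                    if popmap[ind] == pop]
            vals = [G.calls[i, j] for i in rows if G.calls[i, j] != MISSING]
            if vals:
                n_i.append(len(vals))
                p_i.append(sum(vals) / (2 * len(vals)))
                h_i.append(np.mean([v == 1 for v in vals]))
        r = len(n_i)
        if r < 2:
            out.append((np.nan,) * 3)
            continue
        n_i = np.array(n_i, float)
        p_i = np.array(p_i)
        h_i = np.array(h_i)
        nbar = n_i.mean()
        nc = (n_i.sum() - (n_i**2).sum() / n_i.sum()) / (r - 1)
        pbar = (n_i * p_i).sum() / n_i.sum()
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / n_i.sum()
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                           / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        out.append((a, b, c))
    return out


class TestWcFst:
    def test_fixed_difference_is_one(self):
        calls = np.array([[0] * 3] * 4 + [[2] * 3] * 4, dtype=np.int8)
        G = _matrix(calls)
        popmap = {f"i{k}": ("A" if k < 4 else "B") for k in range(8)}
        theta, multi, _ = wc_fst(G, popmap)
        assert multi == pytest.approx(1.0)
        assert np.allclose(theta.dropna(), 1.0)

    def test_panmixia_theta_near_zero(self):
        rng = np.random.default_rng(0)
        reps = []
        for _ in range(50):
            calls = rng.binomial(2, 0.3, size=(16, 40)).astype(np.int8)
            G = _matrix(calls)
            popmap = {f"i{k}": ("A" if k < 8 else "B") for k in range(16)}
            reps.append(wc_fst(G, popmap)[1])
        reps = np.array(reps)
        assert abs(reps.mean()) < 3 * reps.std() / np.sqrt(len(reps)) + 1e-3

    def test_components_match_termwise_oracle(self, toy_matrix):
        G, popmap = toy_matrix
        comp = wc_fst_components(G, popmap)
        oracle = _wc_oracle(G, popmap)
        for j, (a, b, c) in enumerate(oracle):
            row = comp.iloc[j]
            if np.isnan(a):
                assert np.isnan(row["a"])
            else:
                assert row["a"] == pytest.approx(a)
                assert row["b"] == pytest.approx(b)
                assert row["c"] == pytest.approx(c)

    def test_invariant_to_locus_order_and_allele_swap(self, toy_matrix):
        G, popmap = toy_matrix
        _, multi, _ = wc_fst(G, popmap)
        perm = np.random.default_rng(1).permutation(G.n_loci)
        _, multi_perm, _ = wc_fst(G.take_loci(perm), popmap)
        assert multi_perm == pytest.approx(multi)
        swapped = G.copy()
        obs = swapped.calls != MISSING
        swapped.calls[obs] = 2 - swapped.calls[obs]
        _, multi_swap, _ = wc_fst(swapped, popmap)
        assert multi_swap == pytest.approx(multi)

    def test_single_group_rejected(self):
        G = _matrix([[0, 1], [1, 2]])
        with pytest.raises(ValueError):
            wc_fst(G, {"i0": "A", "i1": "A"})


class TestHaplotypeDiversity:
    @pytest.mark.parametrize("counts, expected", [
        ((7, 1), 0.250),     # two mitotypes, n=8
        ((6, 2), 0.429),
        ((13, 2, 1), 0.342), # three mitotypes, n=16
        ((5,), 0.0),         # monomorphic
    ])
    def test_worked_examples(self, counts, expected):
        assert haplotype_diversity(counts) == pytest.approx(expected)

    def test_rejects_tiny_samples(self):
        with pytest.raises(ValueError):
            haplotype_diversity((1,))
        with pytest.raises(ValueError):
            haplotype_diversity(())

    @settings(max_examples=60, derandomize=True)
    @given(st.lists(st.integers(min_value=1, max_value=30), min_size=1,
                    max_size=6).filter(lambda c: sum(c) >= 2))
    def test_bounded_in_unit_interval(self, counts):
        he = haplotype_diversity(counts, ndigits=None)
        assert 0.0 <= he <= 1.0

    def test_evening_counts_never_decreases_he(self):
        # single evening step (move one from a larger to a smaller count)
        for n in range(4, 13):
            for k in range(2, min(n, 5) + 1):
                for counts in itertools.combinations_with_replacement(
                        range(1, n), k):
                    if sum(counts) != n:
                        continue
                    counts = sorted(counts)
                    if counts[-1] - counts[0] >= 2:
                        evened = sorted([counts[0] + 1] + counts[1:-1]
                                        + [counts[-1] - 1])
                        assert (haplotype_diversity(evened, ndigits=None)
                                >= haplotype_diversity(counts, ndigits=None) - 1e-12)


class TestMitotypeFst:
    def test_fixed_groups_give_one(self):
        mitos = {"a": "h1", "b": "h1", "c": "h2", "d": "h2"}
        groups = {"a": "G1", "b": "G1", "c": "G2", "d": "G2"}
        assert mitotype_fst(mitos, groups) == pytest.approx(1.0)

    def test_identical_groups_give_zero(self):
        mitos = {"a": "h1", "b": "h2", "c": "h1", "d": "h2"}
        groups = {"a": "G1", "b": "G1", "c": "G2", "d": "G2"}
        assert mitotype_fst(mitos, groups) == pytest.approx(0.0)
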