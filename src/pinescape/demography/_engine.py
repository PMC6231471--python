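"""Numba core of the structured-coalescent simulator.

Simulates single-site genealogies for samples spread over demes under a
piecewise demography: per-deme diploid sizes with optional backward-shrinking
exponential growth, a constant backward migration-rate matrix between demes,
and timed merge events that move every lineage of a source deme into a
destination deme (and silence migration involving the source).

Time runs backward in generations from 0 (sampling). Coalescence in deme *d*
at backward time *t* occurs at rate k(k-1)/2 / (2 N_d(t)) with
``N_d(t) = N0_d * exp(-alpha_d * min(t, t_end_d))`` — under forward
exponential growth the deme shrinks into the past, so the rate is
non-decreasing between fixed time points, which lets the time-inhomogeneous
process be simulated exactly by thinning against the rate at the window end.
"""

import numpy as np
from numba import njit

_LN4 = 1.3862943611198906


@njit(cache=True)
def _sim_tree(sample_deme, sample_pop, n_pops, strides, N0, alpha, t_end,
              mig0, ev_time, ev_src, ev_dst, want_desc, sfs_acc, accumulate):
    n = sample_deme.shape[0]
    n_demes = N0.shape[0]
    n_nodes = 2 * n - 1
    birth = np.zeros(n_nodes)
    blen = np.zeros(n_nodes)
    counts = np.zeros((n_nodes, n_pops), dtype=np.int64)
    if want_desc:
        desc = np.zeros((n_nodes, n), dtype=np.bool_)
    else:
        desc = np.zeros((1, 1), dtype=np.bool_)
    lin_node = np.empty(n, dtype=np.int64)
    lin_deme = np.empty(n, dtype=np.int64)
    k = np.zeros(n_demes, dtype=np.int64)
    for i in range(n):
        lin_node[i] = i
        lin_deme[i] = sample_deme[i]
        counts[i, sample_pop[i]] = 1
        if want_desc:
            desc[i, i] = True
        k[sample_deme[i]] += 1
    migw = mig0.copy()
    rowmig = np.zeros(n_demes)
    for d in range(n_demes):
        s = 0.0
        for j in range(n_demes):
            s += migw[d, j]
        rowmig[d] = s
    cur = n
    nxt = n
    t = 0.0
    ev_i = 0
    n_ev = ev_time.shape[0]
    while cur > 1:
        while ev_i < n_ev and ev_time[ev_i] <= t:
            src = ev_src[ev_i]
            dst = ev_dst[ev_i]
            for li in range(cur):
                if lin_deme[li] == src:
                    lin_deme[li] = dst
            k[dst] += k[src]
            k[src] = 0
            for j in range(n_demes):
                migw[src, j] = 0.0
                migw[j, src] = 0.0
            for d in range(n_demes):
                s = 0.0
                for j in range(n_demes):
                    s += migw[d, j]
                rowmig[d] = s
            ev_i += 1
        t_fix = np.inf
        if ev_i < n_ev:
            t_fix = ev_time[ev_i]
        amax = 0.0
        for d in range(n_demes):
            if k[d] >= 2 and alpha[d] > 0.0 and t < t_end[d]:
                if alpha[d] > amax:
                    amax = alpha[d]
        t_hi = t_fix
        if amax > 0.0:
            cap = t + _LN4 / amax
            if cap < t_hi:
                t_hi = cap
        tb = t_hi if t_hi < np.inf else t
        rc_bound = 0.0
        for d in range(n_demes):
            if k[d] >= 2:
                tt = tb if tb < t_end[d] else t_end[d]
                nd = N0[d] * np.exp(-alpha[d] * tt)
                rc_bound += 0.25 * k[d] * (k[d] - 1) / nd
        mtot = 0.0
        for li in range(cur):
            mtot += rowmig[lin_deme[li]]
        rate = rc_bound + mtot
        if rate <= 0.0:
            if t_fix == np.inf:
                raise ValueError("structured coalescent cannot complete: "
                                 "isolated lineages with no pending merge")
            t = t_fix
            continue
        w = np.random.exponential(1.0 / rate)
        if t + w >= t_hi:
            if t_hi == np.inf:
                raise ValueError("structured coalescent cannot complete: "
                                 "no finite event horizon")
            t = t_hi
            continue
        t = t + w
        u = np.random.random() * rate
        acc = 0.0
        chosen = -1
        for d in range(n_demes):
            if k[d] >= 2:
                tt = t if t < t_end[d] else t_end[d]
                nd = N0[d] * np.exp(-alpha[d] * tt)
                acc += 0.25 * k[d] * (k[d] - 1) / nd
                if u < acc:
                    chosen = d
                    break
        if chosen >= 0:
            i1 = int(np.random.random() * k[chosen])
            if i1 >= k[chosen]:
                i1 = k[chosen] - 1
            i2 = int(np.random.random() * (k[chosen] - 1))
            if i2 >= k[chosen] - 1:
                i2 = k[chosen] - 2
            if i2 >= i1:
                i2 += 1
            a = -1
            b = -1
            cnt = 0
            for li in range(cur):
                if lin_deme[li] == chosen:
                    if cnt == i1:
                        a = li
                    if cnt == i2:
                        b = li
                    cnt += 1
            na = lin_node[a]
            nb = lin_node[b]
            blen[na] = t - birth[na]
            blen[nb] = t - birth[nb]
            if accumulate:
                c1 = 0
                c2 = 0
                for p in range(n_pops):
                    c1 += counts[na, p] * strides[p]
                    c2 += counts[nb, p] * strides[p]
                sfs_acc[c1] += blen[na]
                sfs_acc[c2] += blen[nb]
            newn = nxt
            nxt += 1
            birth[newn] = t
            for p in range(n_pops):
                counts[newn, p] = counts[na, p] + counts[nb, p]
            if want_desc:
                for s_ in range(n):
                    desc[newn, s_] = desc[na, s_] or desc[nb, s_]
            lin_node[a] = newn
            lin_node[b] = lin_node[cur - 1]
            lin_deme[b] = lin_deme[cur - 1]
            cur -= 1
            k[chosen] -= 1
        elif u < acc + mtot:
            v = u - acc
            sel = -1
            run = 0.0
            for li in range(cur):
                run += rowmig[lin_deme[li]]
                if v < run:
                    sel = li
                    break
            if sel >= 0:
                d0 = lin_deme[sel]
                v2 = np.random.random() * rowmig[d0]
                run2 = 0.0
                dnew = -1
                for j in range(n_demes):
                    run2 += migw[d0, j]
                    if v2 < run2:
                        dnew = j
                        break
                if dnew >= 0:
                    k[d0] -= 1
                    k[dnew] += 1
                    lin_deme[sel] = dnew
        # otherwise: thinning rejection, no event
    return blen, desc, counts


@njit(cache=True)
def sim_branch_sfs(seed, n_trees, sample_deme, sample_pop, n_pops, strides,
                   n_cells, N0, alpha, t_end, mig0, ev_time, ev_src, ev_dst):
    """Accumulate expected branch length per joint descendant-count cell."""
    np.random.seed(seed)
    acc = np.zeros(n_cells)
    for _ in range(n_trees):
        _sim_tree(sample_deme, sample_pop, n_pops, strides, N0, alpha, t_end,
                  mig0, ev_time, ev_src, ev_dst, False, acc, True)
    return acc


@njit(cache=True)
def sim_carriers(seed, n_trees, draws_per_tree, draw_uniforms, sample_deme,
                 sample_pop, n_pops, N0, alpha, t_end, mig0, ev_time, ev_src,
                 ev_dst, want_desc):
    """Simulate trees; optionally sample mutation-carrier sets on branches.

    ``draws_per_tree[t]`` branches are sampled on tree *t* with probability
    proportional to branch length, using the externally supplied uniforms in
    ``draw_uniforms`` (one per draw, in tree order) so that the internal RNG
    stream — and hence the genealogies — is identical whether or not draws
    are requested. Returns (carrier matrix, per-tree total lengths).
    """
    np.random.seed(seed)
    dummy = np.zeros(1)
    strides = np.ones(n_pops, dtype=np.int64)
    total_draws = 0
    for i in range(n_trees):
        total_draws += draws_per_tree[i]
    n = sample_deme.shape[0]
    carriers = np.zeros((total_draws, n), dtype=np.uint8)
    lengths = np.zeros(n_trees)
    row = 0
    di = 0
    for ti in range(n_trees):
        blen, desc, counts = _sim_tree(
            sample_deme, sample_pop, n_pops, strides, N0, alpha, t_end,
            mig0, ev_time, ev_src, ev_dst, want_desc, dummy, False)
        total = 0.0
        for nd in range(blen.shape[0]):
            total += blen[nd]
        lengths[ti] = total
        for _ in range(draws_per_tree[ti]):
            u = draw_uniforms[di] * total
            di += 1
            run = 0.0
            node = -1
            for nd in range(blen.shape[0]):
                run += blen[nd]
                if u < run:
                    node = nd
                    break
            if node < 0:
                node = blen.shape[0] - 2
            for s_ in range(n):
                carriers[row, s_] = 1 if desc[node, s_] else 0
            row += 1
    return carriers, lengths
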