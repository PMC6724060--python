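"""Numba kernels for the backward coalescent walker.

The walker runs in three phases, from the present backwards:

A. *Stationary phase* (only for collapsed traces): every deme sits at
   carrying capacity K; lineages move under the time-reversal of the forward
   migration kernel (exact on a translation-symmetric lattice, an
   approximation near grid edges) and co-resident lineages coalesce with
   pairwise probability 1/K per generation.
B. *Explicit phase*: lineage relocation follows the recorded migrant counts
   (probability ``immigrants_{j->i}(t) / sizes_t(i)``); co-resident lineages
   coalesce with pairwise probability 1/round(deme size).
C. *Ancestral phase*: lineages older than the expansion onset coalesce
   panmictically in a constant population of ``n_ancestral`` gene copies,
   with geometric waiting times at pairwise rate 1/n_ancestral.

Simultaneous collisions are resolved by sequential random pairing within the
generation: pairs are examined in shuffled order and a merged lineage keeps
coalescing, so multi-mergers at tiny N collapse within one generation.
"""

import numpy as np
from numba import njit

TWO_PI = 2.0 * np.pi


@njit(cache=True)
def _shuffle_inplace(arr, n):
    for a in range(n - 1, 0, -1):
        b = int(np.random.random() * (a + 1))
        tmp = arr[a]
        arr[a] = arr[b]
        arr[b] = tmp


#: sub-generation offset separating chained merges within one generation,
#: keeping node times strictly ordered while perturbing branch lengths by
#: less than 1e-3 of a generation
EV_STEP = 1e-6


@njit(cache=True)
def _coalesce_generation(active_node, active_deme, k, deme_sizes, tau,
                         parent, ntime, ndeme, next_id,
                         head, nxt, mem, removed):
    """One generation of within-deme pairwise coalescence.

    ``head`` (per deme), ``nxt``/``mem``/``removed`` (per lineage) are
    scratch buffers owned by the caller; ``head`` must be all -1 on entry
    and is restored on exit.  Successive merges within the generation get
    times ``tau + j*EV_STEP`` so ancestry stays strictly ordered.  Returns
    the new number of active lineages and the next free node id.
    """
    if k < 2:
        return k, next_id
    ev = 0
    for i in range(k):
        removed[i] = 0
        d = active_deme[i]
        nxt[i] = head[d]
        head[d] = i
    for i in range(k):
        d = active_deme[i]
        if head[d] == -2:
            continue
        cnt = 0
        j = head[d]
        while j != -1:
            mem[cnt] = j
            cnt += 1
            j = nxt[j]
        head[d] = -2
        if cnt < 2:
            continue
        _shuffle_inplace(mem, cnt)
        n_copies = int(round(deme_sizes[d]))
        if n_copies < 1:
            n_copies = 1
        p = 1.0 / n_copies
        mlen = cnt
        a = 0
        while a < mlen - 1:
            b = a + 1
            while b < mlen:
                if np.random.random() < p:
                    new = next_id
                    parent[active_node[mem[a]]] = new
                    parent[active_node[mem[b]]] = new
                    ntime[new] = tau + ev * EV_STEP
                    ev += 1
                    ndeme[new] = d
                    active_node[mem[a]] = new
                    removed[mem[b]] = 1
                    mem[b] = mem[mlen - 1]
                    mlen -= 1
                    next_id += 1
                else:
                    b += 1
            a += 1
    w = 0
    for i in range(k):
        if removed[i] == 0:
            active_node[w] = active_node[i]
            active_deme[w] = active_deme[i]
            w += 1
        head[active_deme[i]] = -1
    return w, next_id


@njit(cache=True)
def _trunc_gamma_scalar(shape, scale, lo, hi):
    for _ in range(1000):
        d = np.random.gamma(shape, scale)
        if lo <= d <= hi:
            return d
    d = np.random.gamma(shape, scale)
    if d < lo:
        return lo
    if d > hi:
        return hi
    return d


@njit(cache=True)
def _stationary_move(d, p_ldd, gshape, gscale, dmin, dmax,
                     deme_rows, deme_cols, cell_to_deme,
                     nbr_indptr, nbr_indices):
    """Mirror of the forward per-individual migration kernel, applied to a
    lineage already chosen to move."""
    if p_ldd > 0.0 and np.random.random() < p_ldd:
        nr, nc = cell_to_deme.shape
        for _ in range(10):
            dist = _trunc_gamma_scalar(gshape, gscale, dmin, dmax)
            theta = np.random.random() * TWO_PI
            rr = int(round(deme_rows[d] + dist * np.sin(theta)))
            cc = int(round(deme_cols[d] + dist * np.cos(theta)))
            if 0 <= rr < nr and 0 <= cc < nc:
                tgt = cell_to_deme[rr, cc]
                if tgt >= 0:
                    return tgt
        return d  # cancelled jump
    lo = nbr_indptr[d]
    hi = nbr_indptr[d + 1]
    if hi > lo:
        return nbr_indices[lo + int(np.random.random() * (hi - lo))]
    return d


@njit(cache=True)
def backward_walk(sample_demes, sizes, gen_ptr, imm_dst, imm_src, imm_cnt,
                  t_onset, stationary, K, m, p_ldd, gshape, gscale,
                  dmin, dmax, deme_rows, deme_cols, cell_to_deme,
                  nbr_indptr, nbr_indices, n_ancestral, seed):
    """Full backward coalescent; returns (parent, node_time, node_deme)."""
    np.random.seed(seed)
    n = sample_demes.size
    total = 2 * n - 1
    parent = np.full(total, -1, np.int64)
    ntime = np.zeros(total, np.float64)
    ndeme = np.full(total, -1, np.int32)
    for i in range(n):
        ndeme[i] = sample_demes[i]

    active_node = np.arange(n).astype(np.int64)
    active_deme = sample_demes.astype(np.int32).copy()
    k = n
    next_id = n
    n_explicit = sizes.shape[0] - 1
    tau = 0.0
    head = np.full(sizes.shape[1], -1, np.int64)
    nxt = np.empty(n, np.int64)
    mem = np.empty(n, np.int64)
    removed = np.zeros(n, np.uint8)

    # ---- phase A: stationary plateau -------------------------------------
    if stationary and k > 1:
        k_sizes = np.full(sizes.shape[1], K)
        s_gens = t_onset - n_explicit
        # mover selection: Binomial(k, m) movers per generation, chosen
        # uniformly without replacement — jointly identical to independent
        # Bernoulli(m) moves per lineage, at a fraction of the draws
        idxbuf = np.empty(n, np.int64)
        k_last = -1
        for _ in range(s_gens):
            if k == 1:
                break
            tau += 1.0
            n_move = np.random.binomial(k, m)
            if n_move > 0:
                if k != k_last:
                    for i in range(k):
                        idxbuf[i] = i
                    k_last = k
                for t in range(n_move):
                    r = t + int(np.random.random() * (k - t))
                    tmp = idxbuf[t]
                    idxbuf[t] = idxbuf[r]
                    idxbuf[r] = tmp
                    i = idxbuf[t]
                    active_deme[i] = _stationary_move(
                        active_deme[i], p_ldd, gshape, gscale, dmin, dmax,
                        deme_rows, deme_cols, cell_to_deme,
                        nbr_indptr, nbr_indices)
            k, next_id = _coalesce_generation(
                active_node, active_deme, k, k_sizes, tau,
                parent, ntime, ndeme, next_id, head, nxt, mem, removed)
            if k != k_last:
                k_last = -1  # force an index refill after coalescence
        tau = float(s_gens)

    # ---- phase B: explicit trace -----------------------------------------
    g = n_explicit
    while g > 0 and k > 1:
        tau += 1.0
        lo_g = gen_ptr[g]
        hi_g = gen_ptr[g + 1]
        for i in range(k):
            d = active_deme[i]
            a = lo_g + np.searchsorted(imm_dst[lo_g:hi_g], d, side='left')
            b = lo_g + np.searchsorted(imm_dst[lo_g:hi_g], d, side='right')
            if b > a:
                tot = 0.0
                for j in range(a, b):
                    tot += imm_cnt[j]
                u = np.random.random() * sizes[g, d]
                if u < tot:
                    acc = 0.0
                    for j in range(a, b):
                        acc += imm_cnt[j]
                        if u < acc:
                            active_deme[i] = imm_src[j]
                            break
        g -= 1
        k, next_id = _coalesce_generation(
            active_node, active_deme, k, sizes[g], tau,
            parent, ntime, ndeme, next_id, head, nxt, mem, removed)
    tau = float(t_onset)

    # ---- phase C: panmictic ancestral population -------------------------
    p_pair = 1.0 / n_ancestral
    while k > 1:
        npairs = k * (k - 1) / 2.0
        p_any = 1.0 - (1.0 - p_pair) ** npairs
        if p_any >= 1.0:
            wait = 1.0
        else:
            u = np.random.random()
            wait = 1.0 + np.floor(np.log(u) / np.log(1.0 - p_any))
        tau += wait
        # choose a uniform pair
        a = int(np.random.random() * k)
        b = int(np.random.random() * (k - 1))
        if b >= a:
            b += 1
        new = next_id
        parent[active_node[a]] = new
        parent[active_node[b]] = new
        ntime[new] = tau
        ndeme[new] = active_deme[a]
        active_node[a] = new
        active_node[b] = active_node[k - 1]
        active_deme[b] = active_deme[k - 1]
        k -= 1
        next_id += 1

    return parent, ntime, ndeme
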