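"""Numba kernel for one forward generation (growth + migration).

The kernel mirrors the reference operations in :mod:`demescape.demography`
(`logistic_step`, `migrate_gdd`, `migrate_ldd`) but fuses them and records
directed migrant counts into caller-provided buffers, which keeps the
per-generation cost low enough for reference-table construction.  The
multinomial split among neighbours is realised as the standard sequence of
conditional binomials; long-distance events are drawn per migrant.
"""

import numpy as np
from numba import njit

TWO_PI = 2.0 * np.pi


@njit(cache=True)
def forward_step(n, r, K, m, p_ldd, gshape, gscale, dmin, dmax,
                 nbr_indptr, nbr_indices, deme_rows, deme_cols, cell_to_deme,
                 out_src, out_dst, out_cnt, seed):
    """Advance densities ``n`` by one generation in place.

    Returns the number of migrant records written to the out buffers.
    Emission reads the post-growth snapshot, so the deme order does not
    matter; the total population is conserved exactly.
    """
    np.random.seed(seed)
    nd = n.size
    nr, nc = cell_to_deme.shape
    # logistic growth
    for d in range(nd):
        v = n[d]
        if v > 0.0:
            v = v + r * v * (1.0 - v / K)
            n[d] = v if v > 0.0 else 0.0
    # emission (from the post-growth snapshot)
    n_rec = 0
    for d in range(nd):
        v = n[d]
        if v < 1.0:
            continue
        x = m * v
        emi = int(x)
        if np.random.random() < x - emi:
            emi += 1
        if emi > int(v):
            emi = int(v)
        if emi == 0:
            continue
        n_ldd = 0
        if p_ldd > 0.0:
            n_ldd = np.random.binomial(emi, p_ldd)
        n_gdd = emi - n_ldd
        lo = nbr_indptr[d]
        deg = nbr_indptr[d + 1] - lo
        if n_rec + deg + n_ldd > out_src.size:
            return -1  # caller re-runs the generation with a larger buffer
        if deg > 0 and n_gdd > 0:
            rem = n_gdd
            for j in range(deg):
                if j == deg - 1:
                    c = rem
                else:
                    c = np.random.binomial(rem, 1.0 / (deg - j))
                    rem -= c
                if c > 0:
                    out_src[n_rec] = d
                    out_dst[n_rec] = nbr_indices[lo + j]
                    out_cnt[n_rec] = c
                    n_rec += 1
        for _e in range(n_ldd):
            for _try in range(10):
                dist = -1.0
                for _g in range(1000):
                    dist = np.random.gamma(gshape, gscale)
                    if dmin <= dist <= dmax:
                        break
                if dist < dmin:
                    dist = dmin
                elif dist > dmax:
                    dist = dmax
                theta = np.random.random() * TWO_PI
                rr = int(round(deme_rows[d] + dist * np.sin(theta)))
                cc = int(round(deme_cols[d] + dist * np.cos(theta)))
                if 0 <= rr < nr and 0 <= cc < nc:
                    tgt = cell_to_deme[rr, cc]
                    if tgt >= 0:
                        out_src[n_rec] = d
                        out_dst[n_rec] = tgt
                        out_cnt[n_rec] = 1.0
                        n_rec += 1
                        break
            # all tries failed: the migrant stays (no record)
    # apply the recorded moves
    for i in range(n_rec):
        n[out_src[i]] -= out_cnt[i]
        n[out_dst[i]] += out_cnt[i]
    return n_rec
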