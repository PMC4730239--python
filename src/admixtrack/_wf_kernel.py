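"""Numba kernel for the forward-time Wright-Fisher admixture simulator.

The population is a pool of haploid chromosomes, each stored as a run of
ancestry segments in a flattened (ends, ancestry, offsets) representation:
chromosome ``c`` owns ``ends[off[c]:off[c+1]]`` (right edges in Morgans,
last one equal to the chromosome length) and the matching ancestry codes.

One generation = migrant replacement at the gamete-pool level followed by a
full round of random mating: a fraction of the parent pool is (virtually)
replaced by single-segment migrant chromosomes, then every chromosome of
the next generation is produced by recombining two distinct, uniformly
chosen parents with a Poisson(chromosome length) number of crossovers at
uniform positions.  The founding generation mates immediately, so a cohort
entering at generation t undergoes exactly T - t + 1 meioses — the
convention the mixture-of-exponentials theory uses for its effective
recombination rates.
"""

import numpy as np
from numba import njit

__all__ = ["run_wright_fisher"]


@njit(cache=True)
def _copy_interval(ends, anc, i, prev, stop, out_ends, out_anc, n_out, child_start):
    """Copy parent segments overlapping (prev, stop] into the child, merging
    adjacent same-ancestry output segments.  Returns (cursor, n_out)."""
    while ends[i] <= prev:
        i += 1
    while True:
        e = ends[i] if ends[i] < stop else stop
        a = anc[i]
        if n_out > child_start and out_anc[n_out - 1] == a:
            out_ends[n_out - 1] = e
        else:
            out_ends[n_out] = e
            out_anc[n_out] = a
            n_out += 1
        if ends[i] >= stop:
            break
        i += 1
    return i, n_out


@njit(cache=True)
def _evolve(mig_counts, L, pool, T, seed, cap):
    """Run T generations; returns (status, ends, anc, off, n_seg).

    status 0 = ok, 1 = segment buffer overflow (caller retries with a
    larger ``cap``).
    """
    np.random.seed(seed)
    K = mig_counts.shape[1]

    ends_a = np.empty(cap, dtype=np.float64)
    anc_a = np.empty(cap, dtype=np.int8)
    off_a = np.empty(pool + 1, dtype=np.int64)
    ends_b = np.empty(cap, dtype=np.float64)
    anc_b = np.empty(cap, dtype=np.int8)
    off_b = np.empty(pool + 1, dtype=np.int64)
    # parent-pool scratch (previous children with migrants spliced in)
    ends_p = np.empty(cap, dtype=np.float64)
    anc_p = np.empty(cap, dtype=np.int8)
    off_p = np.empty(pool + 1, dtype=np.int64)

    n_cur = 0  # segments in current children arrays (ends_a set)
    cur_is_a = True
    xs_buf = np.empty(256, dtype=np.float64)

    for t in range(T):
        n_mig = 0
        for k in range(K):
            n_mig += mig_counts[t, k]

        if cur_is_a:
            c_ends, c_anc, c_off = ends_a, anc_a, off_a
            o_ends, o_anc, o_off = ends_b, anc_b, off_b
        else:
            c_ends, c_anc, c_off = ends_b, anc_b, off_b
            o_ends, o_anc, o_off = ends_a, anc_a, off_a

        # -- parent pool: previous children with the first n_mig chromosomes
        #    replaced by pure migrant chromosomes -------------------------
        if n_mig == 0:
            p_ends, p_anc, p_off = c_ends, c_anc, c_off
        else:
            p_ends, p_anc, p_off = ends_p, anc_p, off_p
            n_p = 0
            p_off[0] = 0
            j = 0
            for k in range(K):
                for _ in range(mig_counts[t, k]):
                    p_ends[n_p] = L
                    p_anc[n_p] = k
                    n_p += 1
                    j += 1
                    p_off[j] = n_p
            for c in range(n_mig, pool):
                lo = c_off[c]
                hi = c_off[c + 1]
                if n_p + (hi - lo) > cap:
                    return 1, ends_a, anc_a, off_a, 0
                for q in range(lo, hi):
                    p_ends[n_p] = c_ends[q]
                    p_anc[n_p] = c_anc[q]
                    n_p += 1
                j += 1
                p_off[j] = n_p

        # -- mating round -------------------------------------------------
        n_out = 0
        o_off[0] = 0
        for c in range(pool):
            a = np.random.randint(pool)
            b = np.random.randint(pool)
            while b == a:
                b = np.random.randint(pool)
            k_x = np.random.poisson(L)
            if k_x > 255:
                k_x = 255
            for q in range(k_x):
                xs_buf[q] = np.random.random() * L
            xs = np.sort(xs_buf[:k_x])
            start_with_a = np.random.randint(2) == 0

            child_start = n_out
            seg_a = p_off[a + 1] - p_off[a]
            seg_b = p_off[b + 1] - p_off[b]
            if n_out + seg_a + seg_b + k_x + 1 > cap:
                return 1, ends_a, anc_a, off_a, 0
            ia = p_off[a]
            ib = p_off[b]
            prev = 0.0
            use_a = start_with_a
            for j in range(k_x + 1):
                stop = xs[j] if j < k_x else L
                if stop > prev:
                    if use_a:
                        ia, n_out = _copy_interval(
                            p_ends, p_anc, ia, prev, stop,
                            o_ends, o_anc, n_out, child_start,
                        )
                    else:
                        ib, n_out = _copy_interval(
                            p_ends, p_anc, ib, prev, stop,
                            o_ends, o_anc, n_out, child_start,
                        )
                    prev = stop
                use_a = not use_a
            o_off[c + 1] = n_out

        n_cur = n_out
        cur_is_a = not cur_is_a

    if cur_is_a:
        return 0, ends_a, anc_a, off_a, n_cur
    return 0, ends_b, anc_b, off_b, n_cur


def run_wright_fisher(mig_counts, length, pool, seed):
    """Drive the jit kernel, growing the segment buffer on overflow.

    Parameters
    ----------
    mig_counts : (T, K) int64
        Migrant chromosome counts per generation; row 0 must sum to ``pool``.
    length : float
        Chromosome length in Morgans.
    pool : int
        Number of haploid chromosomes (2 x diploid population size).
    seed : int
        Kernel RNG seed (< 2**32).

    Returns
    -------
    ends, anc, off : flattened final-generation pool.
    """
    mig_counts = np.ascontiguousarray(mig_counts, dtype=np.int64)
    T = mig_counts.shape[0]
    # expected junctions per chromosome grow ~ linearly with T; start generous
    cap = int(pool * (8 + 3 * length * max(1, T) * 0.6)) + 1024
    for _ in range(8):
        status, ends, anc, off, n_seg = _evolve(
            mig_counts, float(length), int(pool), int(T), int(seed) % (2**32), cap
        )
        if status == 0:
            return ends[:n_seg].copy(), anc[:n_seg].copy(), off.copy()
        cap *= 2
    raise RuntimeError("segment buffer kept overflowing; pathological input?")
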