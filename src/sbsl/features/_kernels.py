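"""Numba kernels for the margin-preserving permutation null.

The permutation scheme randomizes a binary alteration matrix while keeping
every gene (row) and sample (column) margin fixed, via random 2x2
"checkerboard" swaps: a submatrix [[1,0],[0,1]] becomes [[0,1],[1,0]] and
vice versa. A burn-in of swaps decorrelates the chain from the observed
matrix; successive samples are separated by a thinning interval.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["swap_chain_overlaps", "swap_chain_overlaps_multi"]


@njit(cache=True)
def _attempt_swaps(mat, n_attempts, state):
    """Run n_attempts random checkerboard swap attempts in place.

    Returns the number of successful swaps. ``state`` is a length-1 int64
    array holding an xorshift state (numba-safe explicit RNG so the chain is
    reproducible independently of numpy global state).
    """
    n_rows, n_cols = mat.shape
    s = state[0]
    successes = 0
    for _ in range(n_attempts):
        # xorshift64*
        s ^= s >> 12
        s ^= (s << 25) & 0xFFFFFFFFFFFFFFFF
        s ^= s >> 27
        r1 = int(((s * 2685821657736338717) & 0xFFFFFFFFFFFFFFFF) >> 33) % n_rows
        s ^= s >> 12
        s ^= (s << 25) & 0xFFFFFFFFFFFFFFFF
        s ^= s >> 27
        r2 = int(((s * 2685821657736338717) & 0xFFFFFFFFFFFFFFFF) >> 33) % n_rows
        s ^= s >> 12
        s ^= (s << 25) & 0xFFFFFFFFFFFFFFFF
        s ^= s >> 27
        c1 = int(((s * 2685821657736338717) & 0xFFFFFFFFFFFFFFFF) >> 33) % n_cols
        s ^= s >> 12
        s ^= (s << 25) & 0xFFFFFFFFFFFFFFFF
        s ^= s >> 27
        c2 = int(((s * 2685821657736338717) & 0xFFFFFFFFFFFFFFFF) >> 33) % n_cols
        if r1 == r2 or c1 == c2:
            continue
        a = mat[r1, c1]
        b = mat[r1, c2]
        c = mat[r2, c1]
        d = mat[r2, c2]
        if a == 1 and d == 1 and b == 0 and c == 0:
            mat[r1, c1] = 0
            mat[r2, c2] = 0
            mat[r1, c2] = 1
            mat[r2, c1] = 1
            successes += 1
        elif a == 0 and d == 0 and b == 1 and c == 1:
            mat[r1, c1] = 1
            mat[r2, c2] = 1
            mat[r1, c2] = 0
            mat[r2, c1] = 0
            successes += 1
    state[0] = s
    return successes


@njit(cache=True)
def swap_chain_overlaps(mat, row_a, row_b, n_perm, burn_in, thin, seed):
    """Overlap of rows (row_a, row_b) in n_perm margin-preserving samples.

    Returns (overlaps int64[n_perm], total_successful_swaps).
    """
    work = mat.copy()
    state = np.empty(1, dtype=np.int64)
    state[0] = seed * 6364136223846793005 + 1442695040888963407
    if state[0] == 0:
        state[0] = 88172645463325252
    total = _attempt_swaps(work, burn_in, state)
    out = np.empty(n_perm, dtype=np.int64)
    n_cols = work.shape[1]
    for i in range(n_perm):
        total += _attempt_swaps(work, thin, state)
        ov = 0
        for s in range(n_cols):
            if work[row_a, s] == 1 and work[row_b, s] == 1:
                ov += 1
        out[i] = ov
    return out, total


@njit(cache=True)
def swap_chain_overlaps_multi(mat, rows_a, rows_b, n_perm, burn_in, thin, seed):
    """Shared-ensemble variant: one chain, overlaps recorded for many pairs.

    Returns (overlaps int64[n_pairs, n_perm], total_successful_swaps).
    """
    work = mat.copy()
    state = np.empty(1, dtype=np.int64)
    state[0] = seed * 6364136223846793005 + 1442695040888963407
    if state[0] == 0:
        state[0] = 88172645463325252
    total = _attempt_swaps(work, burn_in, state)
    n_pairs = rows_a.shape[0]
    out = np.empty((n_pairs, n_perm), dtype=np.int64)
    n_cols = work.shape[1]
    for i in range(n_perm):
        total += _attempt_swaps(work, thin, state)
        for k in range(n_pairs):
            ra = rows_a[k]
            rb = rows_b[k]
            ov = 0
            for s in range(n_cols):
                if work[ra, s] == 1 and work[rb, s] == 1:
                    ov += 1
            out[k, i] = ov
    return out, total
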