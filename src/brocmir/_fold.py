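"""Numba kernels for the nearest-neighbor folding dynamic program.

The recursion is a single-strand Zuker scheme over three tables:

``V[i, j]``
    minimum energy of the subsequence ``i..j`` given that ``(i, j)`` is a
    base pair (hairpin closing, stack/bulge/internal extension with a bounded
    loop size, or a multiloop closing).
``WM[i, j]``
    minimum energy of ``i..j`` inside a multiloop, containing at least one
    branch; unpaired multiloop bases are free, each branch costs ``Mb``.
``W[k]``
    minimum energy of the prefix ``0..k-1`` with free external bases.

Energies are in the model's kcal/mol scale; ``INF`` marks forbidden states.
Loop penalties are logarithmic in loop size (Jacobson–Stockmayer form).
"""

import numpy as np
from numba import njit

INF = 1e9


@njit(cache=True)
def fill_tables(enc, can_pair, stack, min_loop, max_internal,
                multi_close, multi_branch,
                hp_base, hp_slope, bulge_base, bulge_slope,
                int_base, int_slope, int_asym, int_asym_cap):
    n = enc.shape[0]
    V = np.full((n, n), INF)
    WM = np.full((n, n), INF)
    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            a = enc[i]
            b = enc[j]
            if can_pair[a, b]:
                best = INF
                loop = j - i - 1
                if loop >= min_loop:
                    best = hp_base + hp_slope * np.log(loop / min_loop)
                # stack / bulge / internal loop closed by (i,j), inner pair (p,q)
                for l1 in range(0, max_internal + 1):
                    p = i + 1 + l1
                    if p >= j - 1:
                        break
                    for l2 in range(0, max_internal - l1 + 1):
                        q = j - 1 - l2
                        if q <= p:
                            break
                        if not can_pair[enc[p], enc[q]]:
                            continue
                        v = V[p, q]
                        if v >= INF / 2:
                            continue
                        if l1 == 0 and l2 == 0:
                            e = stack[a * 4 + b, enc[p] * 4 + enc[q]]
                        elif l1 == 0 or l2 == 0:
                            e = bulge_base + bulge_slope * np.log(float(l1 + l2))
                        else:
                            asym = int_asym * abs(l1 - l2)
                            if asym > int_asym_cap:
                                asym = int_asym_cap
                            e = int_base + int_slope * np.log((l1 + l2) / 2.0) + asym
                        if v + e < best:
                            best = v + e
                # multiloop closed by (i,j): at least two inner branches
                for k in range(i + 1, j - 1):
                    wl = WM[i + 1, k]
                    wr = WM[k + 1, j - 1]
                    if wl < INF / 2 and wr < INF / 2:
                        v = multi_close + multi_branch + wl + wr
                        if v < best:
                            best = v
                V[i, j] = best
            # WM
            w = INF
            if V[i, j] < INF / 2:
                w = V[i, j] + multi_branch
            if WM[i + 1, j] < w:
                w = WM[i + 1, j]
            if WM[i, j - 1] < w:
                w = WM[i, j - 1]
            for k in range(i, j):
                wl = WM[i, k]
                wr = WM[k + 1, j]
                if wl < INF / 2 and wr < INF / 2 and wl + wr < w:
                    w = wl + wr
            WM[i, j] = w
    # external prefix table
    W = np.zeros(n + 1)
    for k in range(1, n + 1):
        j = k - 1
        best = W[k - 1]
        for i in range(0, j):
            if V[i, j] < INF / 2:
                t = W[i] + V[i, j]
                if t < best:
                    best = t
        W[k] = best
    return V, WM, W
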