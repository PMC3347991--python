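"""Dynamic-programming kernel for minimum-free-energy folding.

Separated from :mod:`mirkit.folding` so the hot loops can be jit-compiled
with numba when it is available; the pure-Python path is identical but slow.
"""

from __future__ import annotations

import numpy as np

INF = 1e9

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=False)
def fill_matrices(
    enc,
    can,
    stack4,
    hairpin_e,
    bulge_e,
    internal_e,
    ml_close,
    ml_branch,
    ml_unpaired,
    min_hairpin,
    max_interior,
):
    """Fill V (paired), WM (multiloop component) and Wl (exterior suffix).

    V[i, j]   : MFE over [i, j] given (i, j) paired.
    WM[i, j]  : MFE of >=1 multiloop branches in [i, j], unpaired nt cost
                ml_unpaired each, branches cost ml_branch each.
    Wl[i]     : exterior MFE of the suffix [i, n); unpaired free.
    """
    n = enc.shape[0]
    V = np.full((n, n), INF)
    WM = np.full((n, n), INF)
    min_span = min_hairpin + 2  # smallest paired span: i, >=3 loop nt, j
    for span in range(1, n + 1):
        for i in range(0, n - span + 1):
            j = i + span - 1
            if span >= min_span and can[enc[i], enc[j]]:
                best = hairpin_e[j - i - 1]
                # stack / bulge / internal closed by (k, l)
                kmax = min(j - 1, i + max_interior + 1)
                for k in range(i + 1, kmax + 1):
                    s1 = k - i - 1
                    lmin = max(k + min_hairpin + 1, j - 1 - (max_interior - s1))
                    for l in range(lmin, j):
                        if V[k, l] >= INF:
                            continue
                        s2 = j - l - 1
                        if s1 == 0 and s2 == 0:
                            e = stack4[enc[i], enc[j], enc[k], enc[l]]
                        elif s1 == 0 or s2 == 0:
                            e = bulge_e[s1 + s2]
                        else:
                            e = internal_e[s1 + s2]
                        if e + V[k, l] < best:
                            best = e + V[k, l]
                # multiloop: >=2 branches inside [i+1, j-1]
                for k in range(i + 2, j - 2):
                    if WM[i + 1, k] < INF and WM[k + 1, j - 1] < INF:
                        cand = ml_close + ml_branch + WM[i + 1, k] + WM[k + 1, j - 1]
                        if cand < best:
                            best = cand
                V[i, j] = best
            # WM
            wm = INF
            if j > i and WM[i + 1, j] + ml_unpaired < wm:
                wm = WM[i + 1, j] + ml_unpaired
            if j > i and WM[i, j - 1] + ml_unpaired < wm:
                wm = WM[i, j - 1] + ml_unpaired
            if V[i, j] + ml_branch < wm:
                wm = V[i, j] + ml_branch
            for k in range(i + 1, j + 1):
                if WM[i, k - 1] < INF and WM[k, j] < INF:
                    if WM[i, k - 1] + WM[k, j] < wm:
                        wm = WM[i, k - 1] + WM[k, j]
            WM[i, j] = wm
    Wl = np.zeros(n + 1)
    for i in range(n - 1, -1, -1):
        best = Wl[i + 1]
        for k in range(i + min_span - 1, n):
            if V[i, k] < INF and V[i, k] + Wl[k + 1] < best:
                best = V[i, k] + Wl[k + 1]
        Wl[i] = best
    return V, WM, Wl
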