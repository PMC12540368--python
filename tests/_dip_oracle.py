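"""Independent dip oracle: for a fixed mode, the closest unimodal CDF
within a sup-norm band of the empirical CDF is a linear program; the dip
is the minimum over modes (every data point plus a grid inside every
gap).  Exact up to the gap grid.  Assumes no tied observations."""

import numpy as np
from scipy.optimize import linprog


def _dip_lp_fixed_mode(x, mode_kind, k, frac=None):
    x = np.asarray(x, float)
    n = x.size
    nv = n + 3
    iL, iR, irho = n, n + 1, n + 2
    A, b = [], []

    def le(coefs, rhs):
        row = np.zeros(nv)
        for j, c in coefs:
            row[j] += c
        A.append(row)
        b.append(rhs)

    for i in range(n):
        lo_level, hi_level = (i + 1) / n, i / n
        if mode_kind == "point" and i == k:
            hi_level = (i + 1) / n  # an atom at the mode relaxes the cap
        le([(i, -1.0), (irho, -1.0)], -lo_level)
        le([(i, 1.0), (irho, -1.0)], hi_level)

    if mode_kind == "point":
        m = x[k]
        left = list(range(k))
        right = list(range(k, n))
        cR_is = k
    else:
        m = x[k] + frac * (x[k + 1] - x[k]) if 0 <= k < n - 1 else (
            x[0] - 1.0 if k < 0 else x[-1] + 1.0)
        left = list(range(k + 1))
        right = list(range(k + 1, n))
        cR_is = None

    lpts = [(x[i], i) for i in left] + [(m, iL)]
    for (xa, ia), (xb, ib), (xc, ic) in zip(lpts, lpts[1:], lpts[2:]):
        d1, d2 = xb - xa, xc - xb
        le([(ib, d2 + d1), (ia, -d2), (ic, -d1)], 0.0)
    if len(lpts) >= 2:
        (_, ia), (_, ib) = lpts[0], lpts[1]
        le([(ia, 1.0), (ib, -1.0)], 0.0)
    le([(lpts[0][1], -1.0)], 0.0)

    rpts = ([] if cR_is is not None else [(m, iR)]) + [(x[i], i) for i in right]
    for (xa, ia), (xb, ib), (xc, ic) in zip(rpts, rpts[1:], rpts[2:]):
        d1, d2 = xb - xa, xc - xb
        le([(ib, -(d2 + d1)), (ia, d2), (ic, d1)], 0.0)
    if len(rpts) >= 2:
        (_, ia), (_, ib) = rpts[-2], rpts[-1]
        le([(ia, 1.0), (ib, -1.0)], 0.0)
    le([(rpts[-1][1], 1.0)], 1.0)

    level = len(left) / n
    cR_var = cR_is if cR_is is not None else iR
    le([(iL, 1.0), (cR_var, -1.0)], 0.0)
    le([(iL, 1.0), (irho, -1.0)], level)
    if mode_kind == "gap":
        le([(iR, -1.0), (irho, -1.0)], -level)

    c = np.zeros(nv)
    c[irho] = 1.0
    bounds = [(None, None)] * nv
    bounds[irho] = (0.0, None)
    res = linprog(c, A_ub=np.array(A), b_ub=np.array(b), bounds=bounds,
                  method="highs")
    return res.fun if res.status == 0 else np.inf


def dip_lp(x, gap_grid=25):
    x = np.sort(np.asarray(x, float))
    n = x.size
    best = np.inf
    for k in range(n):
        best = min(best, _dip_lp_fixed_mode(x, "point", k))
    fr = np.linspace(0.02, 0.98, gap_grid)
    for k in range(-1, n):
        if 0 <= k < n - 1:
            for f in fr:
                best = min(best, _dip_lp_fixed_mode(x, "gap", k, f))
        else:
            best = min(best, _dip_lp_fixed_mode(x, "gap", k, 0.5))
    return best
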