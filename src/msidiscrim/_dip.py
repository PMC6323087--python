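"""Hartigan's dip statistic of unimodality and a calibrated test.

The statistic is the maximum distance between the empirical CDF and the
closest unimodal CDF, computed by the classic greatest-convex-minorant /
least-concave-majorant iteration.  P-values come either from a frozen
null-quantile table (uniform null, interpolated on the sqrt(n)-scaled
statistic; table generated by ``scripts/make_dip_table.py``) or from an
explicit uniform bootstrap.
"""

from __future__ import annotations

import numpy as np

from ._dip_table import DIP_TABLE_N, DIP_TABLE_PROBS, DIP_TABLE_QUANTILES


def dip_statistic(x: np.ndarray) -> float:
    """Dip statistic of a 1-D sample (>= 1/(2n); 0 for degenerate input)."""
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    if n < 2 or x[0] == x[-1]:
        return 0.0

    # pointer arrays for the convex minorant / concave majorant fits
    mn = np.zeros(n, dtype=int)
    for j in range(1, n):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 0 or (x[j] - x[mnj]) * (mnj - mnmnj) < (x[mnj] - x[mnmnj]) * (j - mnj):
                break
            mn[j] = mnmnj
    mj = np.zeros(n, dtype=int)
    mj[n - 1] = n - 1
    for k in range(n - 2, -1, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            mjmjk = mj[mjk]
            if mjk == n - 1 or (x[k] - x[mjk]) * (mjk - mjmjk) < (x[mjk] - x[mjmjk]) * (k - mjk):
                break
            mj[k] = mjmjk

    low, high = 0, n - 1
    dip = 1.0  # in units of 1/(2n) steps; final value divided by 2n

    while True:
        # GCM change points from high to low, LCM from low to high
        gcm = [high]
        while gcm[-1] > low:
            gcm.append(mn[gcm[-1]])
        l_gcm = len(gcm)
        ix = l_gcm - 2
        lcm = [low]
        while lcm[-1] < high:
            lcm.append(mj[lcm[-1]])
        l_lcm = len(lcm)
        iv = 1

        ig, ih = l_gcm - 1, l_lcm - 1
        # largest distance between the GCM and the LCM on [low, high]
        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            while True:
                gcmix, lcmiv = gcm[ix], lcm[iv]
                if gcmix > lcmiv:
                    gcmi1 = gcm[ix + 1]
                    dd = (lcmiv - gcmi1 + 1) - (x[lcmiv] - x[gcmi1]) * (
                        gcmix - gcmi1
                    ) / (x[gcmix] - x[gcmi1])
                    iv += 1
                    if dd >= d:
                        d = dd
                        ig, ih = ix + 1, iv - 1
                else:
                    lcmiv1 = lcm[iv - 1]
                    dd = (x[gcmix] - x[lcmiv1]) * (lcmiv - lcmiv1) / (
                        x[lcmiv] - x[lcmiv1]
                    ) - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dd >= d:
                        d = dd
                        ig, ih = ix + 1, iv
                if ix < 0:
                    ix = 0
                if iv > l_lcm - 1:
                    iv = l_lcm - 1
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0

        if d < dip:
            break

        # dip within the current minorant / majorant fits
        dip_l = 0.0
        for j in range(ig, l_gcm - 1):
            jb, je = gcm[j + 1], gcm[j]
            max_t = 1.0
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (x[jj] - x[jb]) * c
                    if t > max_t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t
        dip_u = 0.0
        for j in range(ih, l_lcm - 1):
            jb, je = lcm[j], lcm[j + 1]
            max_t = 1.0
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (x[jj] - x[jb]) * c - (jj - jb - 1)
                    if t > max_t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t

        dipnew = max(dip_l, dip_u)
        if dip < dipnew:
            dip = dipnew
        if low == gcm[ig] and high == lcm[ih]:
            break
        low, high = gcm[ig], lcm[ih]

    return dip / (2.0 * n)


def dip_pvalue_bootstrap(
    x: np.ndarray, n_boot: int = 500, rng: np.random.Generator | None = None
) -> float:
    """Monte-Carlo p-value against the uniform null of the same size."""
    rng = rng or np.random.default_rng(0)
    d = dip_statistic(x)
    n = np.asarray(x).size
    null = np.array([dip_statistic(rng.random(n)) for _ in range(n_boot)])
    return float((1 + np.sum(null >= d)) / (1 + n_boot))


def dip_pvalue(x: np.ndarray) -> float:
    """Table-interpolated p-value of the dip statistic.

    Null quantiles were simulated on a grid of sample sizes; interpolation
    follows the usual sqrt(n)-scaling of the statistic.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    d = dip_statistic(x)
    if d <= 0:
        return 1.0
    stat = d * np.sqrt(n)
    n_grid = np.asarray(DIP_TABLE_N, dtype=float)
    q = np.asarray(DIP_TABLE_QUANTILES)  # (len(n_grid), len(probs)) of dip*sqrt(n)
    nn = min(max(n, n_grid[0]), n_grid[-1])
    i = int(np.searchsorted(n_grid, nn, side="right")) - 1
    i = min(i, len(DIP_TABLE_N) - 2)
    f = (np.sqrt(nn) - np.sqrt(n_grid[i])) / (
        np.sqrt(n_grid[i + 1]) - np.sqrt(n_grid[i])
    )
    row = (1 - f) * q[i] + f * q[i + 1]
    probs = np.asarray(DIP_TABLE_PROBS)
    if stat <= row[0]:
        return float(1.0 - probs[0] * stat / row[0])
    if stat >= row[-1]:
        return float(min(1.0, (1.0 - probs[-1]) * (row[-1] / stat) ** 2))
    cdf = np.interp(stat, row, probs)
    return float(1.0 - cdf)
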