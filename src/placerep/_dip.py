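"""Hartigan-Hartigan dip statistic.

The dip of an empirical CDF F_n is the smallest d such that some
unimodal CDF U (convex then concave, with an atom allowed at the mode)
stays within sup-distance d of F_n. At radius d the constraints reduce
to value bands at the sorted unique sample values x_(1..m): the value
just right of x_j must be at least c_j/n - d and the left limit at most
(c_j - k_j)/n + d, with c_j the cumulative count through x_j and k_j
its multiplicity.

A unimodal fit exists iff some sample point can host the mode: a
nondecreasing convex function fits the bands strictly left of it, a
nondecreasing concave one from it rightward, and the two limits at the
mode point are ordered (left limit <= right limit; when the mode sits
strictly between samples the limits coincide and both bands at the
shared point apply). Deciding this exactly requires, per prefix, the
range of achievable endpoint values, which is computed by a forward
dynamic program over the last-slope budget s:

  Fmin_t(s) = min{ U(x_t) : convex config on points 1..t, last slope <= s }
  Fmax_t(s) = max{ ... }

Both are piecewise-linear in s (Fmin nonincreasing convex, Fmax
nondecreasing concave, flat tails) and are updated in O(pieces) per
point; a shared domain cut keeps the lower clip of Fmin honest. The
concave side is the same program on the reflected axis, and the dip is
found by bisection on d. Validated in the test suite against a
brute-force linear-programming oracle over unimodal CDFs. The kernels
are plain Python compiled with numba when available.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except Exception:  # pragma: no cover
    def njit(*args, **kwargs):
        def deco(f):
            return f

        return deco(args[0]) if args and callable(args[0]) else deco


@njit(cache=False)
def _prefix_profiles(x, L, H, floor, cmin, feas, cmin_rel, feas_rel):
    """Forward DP for convex-in-band prefixes (see module docstring).

    Per prefix end t: ``cmin[t]``/``feas[t]`` describe configs whose
    endpoint honors both bands at x_t (mode strictly past x_t);
    ``cmin_rel[t]``/``feas_rel[t]`` describe the endpoint as a left
    limit at x_t with the lower band relaxed (mode atom exactly at
    x_t). ``floor`` is the lower range bound of the CDF values (0 on
    the direct axis, -1 on the reflected one).
    """
    m = len(x)
    a_s = np.empty(m + 2)
    a_g = np.empty(m + 2)
    b_s = np.empty(m + 2)
    b_g = np.empty(m + 2)
    a_s[0] = 0.0
    a_g[0] = L[0]
    Ka = 1
    b_s[0] = 0.0
    b_g[0] = H[0]
    Kb = 1
    ok = L[0] <= H[0]
    cmin[0] = L[0]
    feas[0] = ok
    cmin_rel[0] = floor
    feas_rel[0] = True
    for t in range(1, m):
        if not ok:
            feas[t] = False
            feas_rel[t] = False
            cmin[t] = np.inf
            cmin_rel[t] = np.inf
            continue
        dx = x[t] - x[t - 1]
        Lt = L[t]
        Ht = H[t]
        # --- Fmin <- running min of Fmin(s) + s*dx
        kmin = Ka - 1
        for i in range(Ka - 1):
            if (a_g[i + 1] - a_g[i]) / (a_s[i + 1] - a_s[i]) + dx > 0:
                kmin = i
                break
        for i in range(kmin + 1):
            a_g[i] = a_g[i] + a_s[i] * dx
        Ka = kmin + 1
        # relaxed endpoint (atom at x_t): lower band does not apply
        if a_g[Ka - 1] <= Ht:
            cmin_rel[t] = max(a_g[Ka - 1], floor)
            feas_rel[t] = True
        else:
            cmin_rel[t] = np.inf
            feas_rel[t] = False
        # clip below at Lt (validity ensured by the Fmax domain cut)
        if a_g[Ka - 1] < Lt:
            if a_g[0] <= Lt:
                Ka = 1
                a_g[0] = Lt
            else:
                i = 0
                while i + 1 < Ka and a_g[i + 1] > Lt:
                    i += 1
                frac = (a_g[i] - Lt) / (a_g[i] - a_g[i + 1])
                sc = a_s[i] + frac * (a_s[i + 1] - a_s[i])
                a_s[i + 1] = sc
                a_g[i + 1] = Lt
                Ka = i + 2
        # --- Fmax <- Fmax(s) + s*dx capped at Ht
        for i in range(Kb):
            b_g[i] = b_g[i] + b_s[i] * dx
        if b_g[0] >= Ht:
            Kb = 1
            b_g[0] = Ht
        else:
            i = 0
            while i + 1 < Kb and b_g[i + 1] < Ht:
                i += 1
            if i + 1 < Kb:
                frac = (Ht - b_g[i]) / (b_g[i + 1] - b_g[i])
                sc = b_s[i] + frac * (b_s[i + 1] - b_s[i])
            else:  # crossing on the tail ray of slope dx
                sc = b_s[Kb - 1] + (Ht - b_g[Kb - 1]) / dx
            b_s[i + 1] = sc
            b_g[i + 1] = Ht
            Kb = i + 2
        # --- common domain: need Fmax >= Lt and Fmin <= Ht somewhere
        if b_g[Kb - 1] < Lt or a_g[Ka - 1] > Ht:
            ok = False
            feas[t] = False
            cmin[t] = np.inf
            continue
        s0 = a_s[0]
        if b_s[0] > s0:
            s0 = b_s[0]
        if b_g[0] < Lt:
            i = 0
            while i + 1 < Kb and b_g[i + 1] < Lt:
                i += 1
            if i + 1 < Kb:
                frac = (Lt - b_g[i]) / (b_g[i + 1] - b_g[i])
                sc = b_s[i] + frac * (b_s[i + 1] - b_s[i])
                if sc > s0:
                    s0 = sc
        if a_g[0] > Ht:
            i = 0
            while i + 1 < Ka and a_g[i + 1] > Ht:
                i += 1
            if i + 1 < Ka:
                frac = (a_g[i] - Ht) / (a_g[i] - a_g[i + 1])
                sc = a_s[i] + frac * (a_s[i + 1] - a_s[i])
                if sc > s0:
                    s0 = sc
        Ka = _truncate_left(a_s, a_g, Ka, s0)
        Kb = _truncate_left(b_s, b_g, Kb, s0)
        cmin[t] = a_g[Ka - 1]
        feas[t] = True


@njit(cache=False)
def _truncate_left(vs, vg, K, s0):
    """Restrict a piecewise-linear frontier to s >= s0, in place."""
    if s0 <= vs[0]:
        return K
    i = 0
    while i + 1 < K and vs[i + 1] <= s0:
        i += 1
    if i + 1 < K:
        frac = (s0 - vs[i]) / (vs[i + 1] - vs[i])
        v0 = vg[i] + frac * (vg[i + 1] - vg[i])
        newK = K - i
        for j in range(i + 1, K):
            vs[j - i] = vs[j]
            vg[j - i] = vg[j]
        vs[0] = s0
        vg[0] = v0
        return newK
    vs[0] = s0
    vg[0] = vg[K - 1]
    return 1


@njit(cache=False)
def _band_feasible(x, L, H, d):
    """Does some unimodal CDF fit within sup-distance d of the bands?"""
    m = len(x)
    Ld = L - d
    Hd = H + d
    cP = np.empty(m)
    fP = np.empty(m, np.bool_)
    cPr = np.empty(m)
    fPr = np.empty(m, np.bool_)
    _prefix_profiles(x, Ld, Hd, 0.0, cP, fP, cPr, fPr)
    xr = -x[::-1]
    Lr = -Hd[::-1]
    Hr = -Ld[::-1]
    cR = np.empty(m)
    fR = np.empty(m, np.bool_)
    cRr = np.empty(m)
    fRr = np.empty(m, np.bool_)
    _prefix_profiles(xr, Lr, Hr, -1.0, cR, fR, cRr, fRr)
    for t in range(m):
        tr = m - 1 - t
        # mode strictly between samples: both limits share one value
        if fP[t] and fR[tr] and cP[t] <= -cR[tr]:
            return True
        # mode atom exactly at x_t: left limit <= right limit
        if fPr[t] and fRr[tr]:
            dmax = -cRr[tr]
            if dmax > 1.0:
                dmax = 1.0
            if cPr[t] <= dmax:
                return True
    return False


def dip_statistic(values: np.ndarray) -> float:
    """Dip statistic of a 1-D sample (n >= 2).

    At most 0.25; equals 1/(2n) for maximally 'spread' distinct
    samples and approaches 0 for heavily tied ones.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    if n < 2:
        raise ValueError("dip statistic needs at least 2 observations")
    uniq, counts = np.unique(v, return_counts=True)
    cum = np.cumsum(counts).astype(np.float64)
    L = cum / n
    H = (cum - counts) / n
    lo, hi = -1e-15, 0.5
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _band_feasible(uniq, L, H, mid):
            hi = mid
        else:
            lo = mid
    return float(hi)


def dip_pvalue_montecarlo(
    dip: float, n: int, n_boot: int = 10000, seed: int = 0
) -> float:
    """Monte-Carlo p-value of a dip under the uniform null at matched n."""
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_boot):
        if dip_statistic(rng.uniform(0, 1, n)) >= dip:
            exceed += 1
    return (exceed + 1) / (n_boot + 1)
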