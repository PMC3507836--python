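"""Independent oracles for the test suite.

Equilibria of the activation system admit a one-dimensional semi-analytic
enumeration that shares nothing with the package's grid-seeded Newton or
continuation machinery: at a steady state every zone lies on its own curve

    s_i(x) = x / ((eps + beta * (a_i * x)**2) * (1 - x)),

so the free substrate ``s`` parametrises all solution families.  Splitting
each curve into monotone segments and solving ``s + sum_i a_i x_i(s) = l``
per segment combination by bracketing/bisection yields every equilibrium.
"""

from __future__ import annotations

import itertools
from typing import List

import numpy as np
from scipy.optimize import brentq


def _zone_segments(eps: float, beta: float, ai: float, N: int = 40001):
    """Monotone (s, x) segments of one zone's equilibrium curve."""
    x = np.linspace(1e-9, 1 - 1e-7, N)
    s = x / ((eps + beta * (ai * x) ** 2) * (1 - x))
    ds = np.diff(s)
    brk = list(np.where(np.sign(ds[:-1]) != np.sign(ds[1:]))[0] + 1)
    cuts = [0] + brk + [N - 1]
    segs = []
    for k in range(len(cuts) - 1):
        ss = s[cuts[k]:cuts[k + 1] + 1]
        xx = x[cuts[k]:cuts[k + 1] + 1]
        if ss[0] > ss[-1]:
            ss, xx = ss[::-1], xx[::-1]
        segs.append((ss, xx))
    return segs


def oracle_equilibria(params, l: float, n_s: int = 6000) -> List[np.ndarray]:
    """All equilibria at fixed l via the substrate parametrisation."""
    eps, beta, a = params.epsilon, params.beta, params.a
    n = len(a)
    if eps == 0.0:
        # the inactive state is exact; nontrivial states still found below
        found = [np.zeros(n)]
    else:
        found = []
    segs = [_zone_segments(eps, beta, ai) for ai in a]
    s_hi = min(l, max(float(s[-1][0].max() if len(s) else 0) for s in segs) + l)
    s_grid = np.linspace(1e-8, max(s_hi, 1e-6), n_s)
    for combo in itertools.product(*[range(len(s)) for s in segs]):
        lo = max(segs[i][c][0][0] for i, c in enumerate(combo))
        hi = min(segs[i][c][0][-1] for i, c in enumerate(combo))
        if lo >= hi:
            continue
        sg = s_grid[(s_grid >= lo) & (s_grid <= hi)]
        # refine near the segment endpoints, where folds sit and roots can
        # hug the boundary
        width = hi - lo
        edges = np.geomspace(1e-10, max(width * 0.1, 1e-9), 30)
        sg = np.unique(np.clip(
            np.concatenate([[lo, hi], sg, lo + edges, hi - edges]), lo, hi
        ))

        def h(sv):
            tot = sv - l
            for i, c in enumerate(combo):
                ss, xx = segs[i][c]
                tot += a[i] * np.interp(sv, ss, xx)
            return tot

        hv = np.array([h(sv) for sv in sg])
        sign_change = np.nonzero(np.sign(hv[:-1]) * np.sign(hv[1:]) < 0)[0]
        for k in sign_change:
            s_star = brentq(h, sg[k], sg[k + 1], xtol=1e-13)
            x_star = np.array(
                [np.interp(s_star, *segs[i][c]) for i, c in enumerate(combo)]
            )
            res = _residual(eps, beta, a, l, x_star)
            if res < 1e-7:
                found.append(x_star)
    out: List[np.ndarray] = []
    for p in found:
        if not any(np.max(np.abs(p - q)) < 1e-5 for q in out):
            out.append(p)
    return sorted(out, key=lambda v: tuple(v))


def _residual(eps, beta, a, l, x) -> float:
    a = np.asarray(a)
    s = l - float(a @ x)
    f = (eps + beta * (a * x) ** 2) * s * (1 - x) - x
    return float(np.max(np.abs(f)))


def oracle_stable(params, l: float, x: np.ndarray, h: float = 1e-6) -> bool:
    """Stability via a finite-difference Jacobian (no analytic derivatives)."""
    n = len(x)
    J = np.zeros((n, n))
    eps, beta, a = params.epsilon, params.beta, np.asarray(params.a)

    def f(xx):
        s = l - float(a @ xx)
        return (eps + beta * (a * xx) ** 2) * s * (1 - xx) - xx

    for j in range(n):
        e = np.zeros(n)
        e[j] = h
        J[:, j] = (f(x + e) - f(x - e)) / (2 * h)
    return bool(np.max(np.linalg.eigvals(J).real) < -1e-8)


def fd_jacobian(fun, x: np.ndarray, h: float = 1e-6) -> np.ndarray:
    """Central finite-difference Jacobian of ``fun`` at ``x``."""
    n = len(x)
    f0 = np.asarray(fun(x))
    J = np.zeros((len(f0), n))
    for j in range(n):
        e = np.zeros(n)
        e[j] = h
        J[:, j] = (np.asarray(fun(x + e)) - np.asarray(fun(x - e))) / (2 * h)
    return J
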