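"""Independent numerical oracles used across the test suite.

Restricted AUCs are recomputed by midpoint Riemann quadrature of the
survival curve (step 1e-4, aligned to segment breakpoints so each panel is
smooth), and the time of equal cumulative life years by bisection on the
quadrature — deliberately avoiding the package's exact segment algebra.
"""

from __future__ import annotations

import math

import numpy as np


def rr_time(segments, u):
    """Integral of the relative risk over [0, u] for (duration, rr) pairs."""
    u = np.asarray(u, dtype=float)
    total = np.zeros_like(u)
    start = 0.0
    for dur, rr in segments:
        total += rr * np.clip(u - start, 0.0, dur)
        start += dur
    return total


def riemann_auc(segments, m: float, t: float, step: float = 1e-4) -> float:
    """Midpoint Riemann sum of exp(-m * R(u)) on [0, t], breakpoint-aligned.

    ``segments=None`` integrates the wait-list curve exp(-m*u).
    """
    edges = [0.0]
    if segments is not None:
        s = 0.0
        for dur, _ in segments[:-1]:
            s += dur
            if s < t:
                edges.append(s)
    edges.append(t)
    total = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        nsub = max(1, math.ceil((b - a) / step))
        h = (b - a) / nsub
        mids = a + (np.arange(nsub) + 0.5) * h
        if segments is None:
            vals = np.exp(-m * mids)
        else:
            vals = np.exp(-m * rr_time(segments, mids))
        total += h * float(vals.sum())
    return total


def bisect_equal_auc(segments, m: float, lo: float, hi: float,
                     step: float = 1e-4, iters: int = 60) -> float:
    """Bisection root of AUC_tx(t) - AUC_wait(t) using the Riemann oracle."""
    f = lambda t: riemann_auc(segments, m, t, step) - riemann_auc(None, m, t, step)
    assert f(lo) < 0 < f(hi)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12:
            break
    return 0.5 * (lo + hi)
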