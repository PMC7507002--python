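"""Independent reference implementations used only by the tests.

Each oracle is written in the most transparent form available (exact
rational arithmetic, explicit summation, grid search) and stays independent
of the package code paths it checks.
"""

from fractions import Fraction
from math import comb

import numpy as np


def binom_tail_exact(k: int, n: int, p: float) -> float:
    """P(X >= k), X ~ Binomial(n, p), by exact rational summation.

    ``p`` is converted exactly from its binary float representation so the
    oracle evaluates the same null as a float implementation. The shorter
    tail is summed and complemented when that is cheaper.
    """
    pf = Fraction(p)
    qf = 1 - pf
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    if n - k + 1 <= k:
        total = sum(comb(n, i) * pf**i * qf ** (n - i) for i in range(k, n + 1))
        return float(total)
    lower = sum(comb(n, i) * pf**i * qf ** (n - i) for i in range(0, k))
    return float(1 - lower)


def spearman_d2(x, y) -> float:
    """Tie-free Spearman rho via the classical 1 - 6*sum(d^2)/(n(n^2-1))."""
    x = np.asarray(x)
    y = np.asarray(y)
    rx = np.empty(len(x))
    rx[np.argsort(x)] = np.arange(1, len(x) + 1)
    ry = np.empty(len(y))
    ry[np.argsort(y)] = np.arange(1, len(y) + 1)
    d2 = ((rx - ry) ** 2).sum()
    n = len(x)
    return 1.0 - 6.0 * d2 / (n * (n**2 - 1))


def midranks(v) -> np.ndarray:
    """Mid-ranks computed by explicit tie-group averaging."""
    v = np.asarray(v, dtype=float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v))
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_midrank(x, y) -> float:
    """Tie-corrected Spearman rho as the Pearson correlation of mid-ranks."""
    rx = midranks(x)
    ry = midranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def efron_loglik(beta, x, time, event):
    """Efron partial log-likelihood for one covariate, written out plainly.

    ``beta`` may be a scalar or an array of candidate values (vectorized over
    beta only; the event-time structure is handled with explicit loops).
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    ll = np.zeros_like(beta)
    for t in np.unique(time[event == 1]):
        dead = (time == t) & (event == 1)
        risk = time >= t
        d = int(dead.sum())
        xs_dead = x[dead]
        w_risk = np.exp(np.outer(beta, x[risk]))  # (B, n_risk)
        w_dead = np.exp(np.outer(beta, xs_dead))  # (B, d)
        s_risk = w_risk.sum(axis=1)
        s_dead = w_dead.sum(axis=1)
        ll += beta * xs_dead.sum()
        for el in range(d):
            ll -= np.log(s_risk - (el / d) * s_dead)
    return ll if ll.size > 1 else float(ll[0])


def cox_grid_mle(x, time, event, lo=-5.0, hi=5.0, step=1e-4) -> float:
    """Brute-force maximizer of the Efron partial likelihood over a beta grid."""
    grid = np.arange(lo, hi + step / 2, step)
    ll = efron_loglik(grid, x, time, event)
    return float(grid[int(np.argmax(ll))])


def km_product_limit(time, event):
    """Hand product-limit estimator: (event_times, survival) arrays."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    out_t, out_s = [], []
    s = 1.0
    for t in np.unique(time[event == 1]):
        n_risk = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        s *= 1.0 - d / n_risk
        out_t.append(t)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)


def logrank_two_group(time, event, in_group_a):
    """Two-group log-rank chi-square by term-by-term hypergeometric summation."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    a = np.asarray(in_group_a, dtype=bool)
    obs = exp = var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & a).sum())
        d = int(((time == t) & (event == 1)).sum())
        d1 = int(((time == t) & (event == 1) & a).sum())
        obs += d1
        exp += d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (obs - exp) ** 2 / var
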