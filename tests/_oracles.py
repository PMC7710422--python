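"""Independent brute-force oracles used by the unit and acceptance tests.

Each function re-derives a statistic straight from its textbook
definition, using only plain loops and numpy, so it shares no code path
with the package implementation it checks.
"""

from __future__ import annotations

import numpy as np


def bh_stepup_bruteforce(pvals):
    """BH adjusted p-values from the step-up definition.

    Sort ascending; adjusted_(i) = min_{j >= i} m * p_(j) / j, capped at 1;
    report in the original order.
    """
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted_sorted = [0.0] * m
    for rank_pos in range(m):
        candidates = [
            m * p[order[j]] / (j + 1) for j in range(rank_pos, m)
        ]
        adjusted_sorted[rank_pos] = min(1.0, min(candidates))
    out = [0.0] * m
    for rank_pos, original in enumerate(order):
        out[original] = adjusted_sorted[rank_pos]
    return np.array(out)


def spearman_rank_then_pearson(x, y):
    """Spearman rho as Pearson on ranks; ranks via double argsort
    (valid for distinct values) plus explicit tie averaging."""
    def ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        r = np.empty(len(v), dtype=float)
        r[order] = np.arange(1, len(v) + 1)
        # average ranks over ties
        for val in np.unique(v):
            mask = v == val
            r[mask] = r[mask].mean()
        return r

    rx, ry = ranks(x), ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def logrank_bruteforce(time, event, in_high):
    """Log-rank chi2 and high-group O-E by explicit accumulation over the
    distinct death times, written with plain python loops."""
    time = list(map(float, time))
    event = list(map(int, event))
    in_high = list(map(bool, in_high))
    death_times = sorted({t for t, e in zip(time, event) if e == 1})
    o_minus_e = 0.0
    var = 0.0
    for t in death_times:
        risk = [i for i in range(len(time)) if time[i] >= t]
        n = len(risk)
        n1 = sum(1 for i in risk if in_high[i])
        d = sum(1 for i in risk if time[i] == t and event[i] == 1)
        d1 = sum(1 for i in risk if time[i] == t and event[i] == 1 and in_high[i])
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = 0.0 if var == 0 else o_minus_e**2 / var
    return chi2, o_minus_e


def student_t_bruteforce(a, b):
    """Pooled two-sample t statistic and df from the textbook formula."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    return t, na + nb - 2


def welch_t_bruteforce(a, b):
    """Welch t statistic and Welch-Satterthwaite df."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return t, df
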