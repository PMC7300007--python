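"""Independent reference implementations used only to check the package.

These are deliberately naive (pure-Python loops, textbook formulas) and
share no code with the implementation under test.
"""

from __future__ import annotations

import math


def brute_force_es(ids, scores, members, weight_p):
    """Weighted KS running sum evaluated position by position.

    Hits step up by |score|^p normalized over hits, misses step down by
    1/(N - N_hits); returns the signed maximum deviation, positive winning
    magnitude ties (within 1e-9).
    """
    members = set(members)
    hits = [i in members for i in ids]
    n_hits = sum(hits)
    n = len(ids)
    if n_hits == 0 or n_hits == n:
        raise ValueError("degenerate gene set")
    if weight_p == 0:
        weights = [1.0 if h else 0.0 for h in hits]
    else:
        weights = [
            abs(s) ** weight_p if h else 0.0 for h, s in zip(hits, scores)
        ]
    wsum = sum(weights)
    if wsum == 0:
        weights = [1.0 if h else 0.0 for h in hits]
        wsum = float(n_hits)
    run = 0.0
    highest = 0.0
    lowest = 0.0
    for i in range(n):
        if hits[i]:
            run += weights[i] / wsum
        else:
            run -= 1.0 / (n - n_hits)
        highest = max(highest, run)
        lowest = min(lowest, run)
    return highest if highest + 1e-9 >= -lowest else lowest


def formula_pearson(x, y):
    """Pearson r, r^2 and the two-sided t-test p-value from first principles."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    r = sxy / math.sqrt(sxx * syy)
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * _t_sf(abs(t), n - 2)
    return r, r * r, p


def _t_sf(t, df):
    """Student-t survival function via the regularized incomplete beta."""
    x = df / (df + t * t)
    return 0.5 * _betainc_reg(df / 2.0, 0.5, x)


def _betainc_reg(a, b, x, n_steps=200_000):
    """Regularized incomplete beta by plain numerical integration."""
    if x <= 0:
        return 0.0
    if x >= 1:
        return 1.0
    total = 0.0
    h = x / n_steps
    for i in range(n_steps):
        u = (i + 0.5) * h
        total += u ** (a - 1.0) * (1.0 - u) ** (b - 1.0)
    total *= h
    beta = math.gamma(a) * math.gamma(b) / math.gamma(a + b)
    return total / beta
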