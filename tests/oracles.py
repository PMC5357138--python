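"""Independent brute-force oracles used to pin the statistical routines.

Everything here is deliberately naive: scalar loops, exhaustive
enumeration, and exact rational arithmetic. None of it shares code with
the implementations under test.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np
from scipy.stats import t as t_dist


def pearson_oracle(x, y):
    """Scalar-loop Pearson r and two-sided t-reference p on complete pairs."""
    pairs = [(a, b) for a, b in zip(x, y) if math.isfinite(a) and math.isfinite(b)]
    n = len(pairs)
    mx = sum(a for a, _ in pairs) / n
    my = sum(b for _, b in pairs) / n
    sxy = sum((a - mx) * (b - my) for a, b in pairs)
    sxx = sum((a - mx) ** 2 for a, _ in pairs)
    syy = sum((b - my) ** 2 for _, b in pairs)
    if sxx == 0 or syy == 0:
        return float("nan"), float("nan"), n
    r = sxy / math.sqrt(sxx * syy)
    df = n - 2
    tt = r * math.sqrt(df / max(1.0 - r * r, 1e-300))
    p = 2.0 * float(t_dist.sf(abs(tt), df))
    return r, min(p, 1.0), n


def bh_oracle(p_values):
    """Hand application of the BH step-up rule."""
    p = list(p_values)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        q[i] = val
        prev = val
    return q


def hypergeom_pmf_frac(i, K, n, N) -> Fraction:
    return Fraction(math.comb(K, i) * math.comb(N - K, n - i), math.comb(N, n))


def hypergeom_tail_oracle(k, K, n, N) -> Fraction:
    """Exact rational upper tail P(overlap >= k)."""
    return sum(hypergeom_pmf_frac(i, K, n, N)
               for i in range(k, min(K, n) + 1))


def fisher_two_sided_oracle(table) -> Fraction:
    """Minimum-likelihood two-sided Fisher p by exact enumeration."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    p_obs = hypergeom_pmf_frac(a, col1, row1, n)
    total = Fraction(0)
    for i in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        pi = hypergeom_pmf_frac(i, col1, row1, n)
        if pi <= p_obs:
            total += pi
    return total


def mann_whitney_oracle(x, y, alternative="less") -> Fraction:
    """Exact Mann-Whitney p by enumerating all label assignments (no ties)."""
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    n, m = len(x), len(y)

    def u_of(xs):
        return sum(1 for a in xs for b in pooled if b not in xs and a > b)

    u_obs = sum(1 for a in x for b in y if a > b)
    count_le = count_ge = 0
    total = 0
    for combo in itertools.combinations(pooled, n):
        u = u_of(set(combo))
        total += 1
        count_le += u <= u_obs
        count_ge += u >= u_obs
    if alternative == "less":
        return Fraction(count_le, total)
    if alternative == "greater":
        return Fraction(count_ge, total)
    return min(Fraction(1), 2 * min(Fraction(count_le, total),
                                    Fraction(count_ge, total)))


def binomial_tail_oracle(k, n, p0) -> Fraction:
    """Exact rational P(X >= k) for X ~ Binomial(n, p0) (p0 as an exact
    binary fraction of the float)."""
    p = Fraction(p0)
    return sum(Fraction(math.comb(n, i)) * p ** i * (1 - p) ** (n - i)
               for i in range(k, n + 1))


def delta_oracle(scores, is_loss):
    loss = [s for s, l in zip(scores, is_loss) if l]
    neut = [s for s, l in zip(scores, is_loss) if not l]
    return sum(loss) / len(loss) - sum(neut) / len(neut)


def betabinom_loglik_oracle(k, n, pi, rho):
    """Beta-binomial log-likelihood via scipy's betabinom distribution."""
    from scipy.stats import betabinom as bb
    theta = (1.0 - rho) / rho
    return float(np.sum(bb.logpmf(k, n, pi * theta, (1.0 - pi) * theta)))
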