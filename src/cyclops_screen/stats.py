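"""Shared statistical primitives.

Small wrappers with explicit NA policies around scipy/statsmodels routines,
plus a log-space exact binomial tail that stays finite far below float
underflow (needed for direction-count comparisons with p-values smaller
than 1e-300).
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_adjust",
    "mann_whitney",
    "fisher_exact",
    "hypergeom_test",
    "log_binomial_tail",
    "binomial_tail",
]

#: sample size above which Mann-Whitney switches from exact enumeration to
#: the tie-corrected normal approximation
MANN_WHITNEY_EXACT_MAX_N = 20


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    NaN entries are passed through unchanged and excluded from the family
    size m. Raises ValueError for entries outside [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if np.any((p[mask] < 0) | (p[mask] > 1)):
        bad = p[mask][(p[mask] < 0) | (p[mask] > 1)]
        raise ValueError(f"p-values outside [0, 1]: {bad[:5]}")
    if mask.sum() > 0:
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def mann_whitney(x, y, alternative: str = "two-sided") -> float:
    """Mann-Whitney U test p-value with midranks for ties.

    Exact enumeration for small samples without ties (both sizes at most
    MANN_WHITNEY_EXACT_MAX_N), tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    small = max(x.size, y.size) <= MANN_WHITNEY_EXACT_MAX_N
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (small and not has_ties) else "asymptotic"
    return float(sps.mannwhitneyu(x, y, alternative=alternative, method=method).pvalue)


def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table.

    Uses the minimum-likelihood convention (sum of all tables with
    probability <= that of the observed table at fixed margins).
    Returns (odds_ratio, p).
    """
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("table must be a non-negative 2x2 count table")
    odds, p = sps.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def hypergeom_test(k: int, set_size: int, query_size: int, universe_size: int) -> float:
    """Upper-tail hypergeometric p: P(overlap >= k).

    k successes drawn in a query of size n from a universe of size N
    containing K set members.
    """
    if not (0 <= k <= min(set_size, query_size)):
        raise ValueError("overlap k must satisfy 0 <= k <= min(K, n)")
    return float(sps.hypergeom.sf(k - 1, universe_size, set_size, query_size))


def log_binomial_tail(k: int, n: int, p0: float) -> float:
    """log10 of the exact upper binomial tail P(X >= k), X ~ Binomial(n, p0).

    Computed entirely in log space from log-gamma terms, so the result is
    finite even when the tail probability is far below the smallest positive
    float (e.g. log10 p near -1100 for n ~ 8000). The summation window is
    truncated 12 standard deviations past k, beyond which the omitted mass
    is negligible at double precision.
    """
    if not (0 <= k <= n):
        raise ValueError("require 0 <= k <= n")
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must be in (0, 1)")
    if k == 0:
        return 0.0
    logp, log1mp = math.log(p0), math.log1p(-p0)
    lognorm = gammaln(n + 1)

    def logpmf(i: np.ndarray) -> np.ndarray:
        return lognorm - gammaln(i + 1) - gammaln(n - i + 1) + i * logp + (n - i) * log1mp

    window = int(12.0 * math.sqrt(n * p0 * (1.0 - p0))) + 64
    mode = math.floor((n + 1) * p0)
    if k > mode:
        # terms decrease monotonically from k; a finite window suffices
        i = np.arange(k, min(n, k + window) + 1)
        return float(logsumexp(logpmf(i)) / math.log(10.0))
    # k at or below the mode: tail >= pmf(mode), compute via the lower tail
    i = np.arange(max(0, k - 1 - window), k)
    log_lower = logsumexp(logpmf(i)) if i.size else -np.inf
    return float(math.log1p(-math.exp(log_lower)) / math.log(10.0))


def binomial_tail(k: int, n: int, p0: float) -> float:
    """Exact upper binomial tail P(X >= k) on the probability scale.

    Underflows to 0.0 below ~1e-308; use log_binomial_tail when the
    magnitude itself is the quantity of interest.
    """
    return float(10.0 ** log_binomial_tail(k, n, p0))
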