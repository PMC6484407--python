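"""Independent brute-force oracles used by the test suite.

Each oracle is written from the definition of the statistic it checks,
without reference to the implementation under test.
"""
from __future__ import annotations

import math

import numpy as np


def brute_force_breakpoint(counts: np.ndarray) -> tuple[int, float]:
    """Exhaustive two-segment Poisson ML scan (smallest k on ties).

    Log-likelihood per segment at the ML mean, dropping terms constant
    in k: sum(c) * log(mean(c)) per segment (0 for empty-count segments).
    """
    x = np.asarray(counts, dtype=float)
    n = len(x)

    def seg(xs) -> float:
        c = float(np.sum(xs))
        if c <= 0:
            return 0.0
        return c * math.log(c / len(xs))

    best_k, best_ll = None, -math.inf
    for k in range(1, n):
        ll = seg(x[:k]) + seg(x[k:])
        if ll > best_ll + 1e-12:
            best_ll, best_k = ll, k
    return best_k, best_ll - seg(x)


def brute_force_u(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U of sample a by direct pair counting (0.5 per tie)."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def fisher_enumeration_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by full enumeration over the margin.

    Conditional on the margins, the table count a follows a
    hypergeometric law; the two-sided p sums the probabilities of all
    tables at most as probable as the observed one.
    """
    row1, col1, n = a + b, a + c, a + b + c + d

    def logp(aa: int) -> float:
        return (
            math.lgamma(row1 + 1) - math.lgamma(aa + 1) - math.lgamma(row1 - aa + 1)
            + math.lgamma(n - row1 + 1) - math.lgamma(col1 - aa + 1)
            - math.lgamma(n - row1 - (col1 - aa) + 1)
            - (math.lgamma(n + 1) - math.lgamma(col1 + 1) - math.lgamma(n - col1 + 1))
        )

    lo, hi = max(0, col1 - (n - row1)), min(row1, col1)
    p_obs = math.exp(logp(a))
    total = 0.0
    for aa in range(lo, hi + 1):
        p = math.exp(logp(aa))
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)
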