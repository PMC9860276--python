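"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive: O(nm) dynamic programming, explicit
enumeration, direct Newton optimization of log-likelihoods.  None of it
shares code with the package internals it checks.
"""

from __future__ import annotations

import math

import numpy as np


def sw_affine_score(
    x: str,
    y: str,
    match: float = 1.0,
    mismatch: float = -2.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
) -> float:
    """Smith-Waterman local alignment score with affine gaps (Gotoh).

    gap_open is the score of the first gapped position, gap_extend of each
    further one (matching Bio.Align.PairwiseAligner semantics).
    """
    n, m = len(x), len(y)
    neg = -1e9
    h = np.zeros((n + 1, m + 1))
    e = np.full((n + 1, m + 1), neg)  # gap in x (horizontal)
    f = np.full((n + 1, m + 1), neg)  # gap in y (vertical)
    best = 0.0
    for i in range(1, n + 1):
        xi = x[i - 1]
        for j in range(1, m + 1):
            sub = match if (xi == y[j - 1] and xi != "N") else mismatch
            e[i][j] = max(h[i][j - 1] + gap_open, e[i][j - 1] + gap_extend)
            f[i][j] = max(h[i - 1][j] + gap_open, f[i - 1][j] + gap_extend)
            h[i][j] = max(0.0, h[i - 1][j - 1] + sub, e[i][j], f[i][j])
            if h[i][j] > best:
                best = h[i][j]
    return best


def binom_tail_ge(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p), by direct summation."""
    total = 0.0
    for i in range(k, n + 1):
        total += math.comb(n, i) * p**i * (1 - p) ** (n - i)
    return min(1.0, total)


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p by full hypergeometric enumeration.

    Sums the probabilities of all tables with the observed margins whose
    probability does not exceed the observed table's (with a small relative
    tolerance for float ties).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x: int) -> float:
        # table (x, r1-x, c1-x, r2-c1+x)
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = prob(a)
    total = 0.0
    for x in range(lo, hi + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(1.0, total)


def connected_components(nodes: list[str], edges: list[tuple[str, str]]) -> list[frozenset]:
    """Brute-force components via repeated closure expansion."""
    comps: list[set] = []
    adj: dict[str, set[str]] = {v: set() for v in nodes}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    seen: set[str] = set()
    for v in adj:
        if v in seen:
            continue
        comp = {v}
        changed = True
        while changed:
            changed = False
            for u in list(comp):
                new = adj[u] - comp
                if new:
                    comp |= new
                    changed = True
        seen |= comp
        comps.append(frozenset(comp))
    return comps


def binomial_glm_newton(
    successes: np.ndarray, failures: np.ndarray, exog: np.ndarray, tol: float = 1e-12
) -> tuple[np.ndarray, float]:
    """Direct Newton maximization of the binomial log-likelihood (logit link).

    Returns (coefficients, maximized log-likelihood with binomial constant).
    """
    s = np.asarray(successes, float)
    f = np.asarray(failures, float)
    n = s + f
    X = np.asarray(exog, float)
    beta = np.zeros(X.shape[1])
    for _ in range(200):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (s - n * p)
        w = n * p * (1 - p)
        hess = X.T @ (X * w[:, None])
        step = np.linalg.solve(hess + 1e-12 * np.eye(X.shape[1]), grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    p = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    const = sum(
        math.lgamma(ni + 1) - math.lgamma(si + 1) - math.lgamma(ni - si + 1)
        for ni, si in zip(n, s)
    )
    ll = float(np.sum(s * np.log(p) + f * np.log(1 - p)) + const)
    return beta, ll


def mannwhitney_exact_less(x: list[float], y: list[float]) -> float:
    """Exact one-sided (x stochastically less) rank-sum p by enumeration."""
    from itertools import combinations

    pooled = sorted(x + y)
    ranks = {}
    # average ranks for ties
    i = 0
    while i < len(pooled):
        j = i
        while j < len(pooled) and pooled[j] == pooled[i]:
            j += 1
        r = (i + 1 + j) / 2
        ranks[pooled[i]] = r
        i = j
    obs = sum(ranks[v] for v in x)
    nx = len(x)
    count = 0
    total = 0
    vals = pooled
    for comb in combinations(range(len(vals)), nx):
        total += 1
        if sum(ranks[vals[i]] for i in comb) <= obs:
            count += 1
    return count / total
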