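"""Independent from-definition oracles used to validate the implementation.

Each oracle is deliberately written by the most literal route available
(enumeration, definition-chasing, or a different library), independent of
the code path it checks.
"""

import numpy as np
from scipy.stats import hypergeom


def bh_oracle(p):
    """BH step-up from the definition: q_(i) = min_{j>=i} m * p_(j) / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        q[idx] = min(running, 1.0)
    return q


def fisher_oracle(table):
    """Two-sided Fisher p by full hypergeometric enumeration.

    Margins fixed; sum P(k) over all k whose table probability is <= the
    observed table's probability (point-probability criterion).
    """
    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    rv = hypergeom(n, row1, col1)
    k_min = max(0, col1 - (n - row1))
    k_max = min(col1, row1)
    p_obs = rv.pmf(a)
    total = 0.0
    for k in range(k_min, k_max + 1):
        pk = rv.pmf(k)
        if pk <= p_obs * (1.0 + 1e-12):
            total += pk
    return min(total, 1.0)


def ols_oracle(y, X):
    """OLS beta/se/p for column 1 via statsmodels (independent route)."""
    import statsmodels.api as sm

    fit = sm.OLS(y, X).fit()
    return float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])


def ward_oracle(X):
    """O(n^3) Ward agglomeration from the Lance-Williams definition.

    Returns (merge list, heights, partitions) where ``merges`` holds the
    member-index frozensets joined at each step and ``partitions`` the set
    of clusters after each merge.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    d2 = {}
    for i in range(n):
        for j in range(i + 1, n):
            d2[(i, j)] = float(((X[i] - X[j]) ** 2).sum())

    def key(i, j):
        return (i, j) if i < j else (j, i)

    merges, heights, partitions = [], [], []
    active = set(range(n))
    next_id = n
    while len(active) > 1:
        (i, j), best = min(
            ((pair, v) for pair, v in d2.items()
             if pair[0] in active and pair[1] in active),
            key=lambda kv: kv[1],
        )
        heights.append(np.sqrt(best))
        merged = clusters[i] | clusters[j]
        merges.append((clusters[i], clusters[j]))
        ni, nj = sizes[i], sizes[j]
        new = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            nk = sizes[k]
            dik = d2[key(i, k)]
            djk = d2[key(j, k)]
            dij = d2[key(i, j)]
            d2[key(new, k)] = (
                (ni + nk) * dik + (nj + nk) * djk - nk * dij
            ) / (ni + nj + nk)
        active -= {i, j}
        active.add(new)
        clusters[new] = merged
        sizes[new] = ni + nj
        partitions.append({clusters[k] for k in active})
    return merges, np.asarray(heights), partitions


def scipy_linkage_partitions(link, n):
    """Replay a scipy linkage matrix into per-step partitions of leaves."""
    clusters = {i: frozenset([i]) for i in range(n)}
    active = set(range(n))
    partitions = []
    for step, (a, b, _, _) in enumerate(link):
        a, b = int(a), int(b)
        new = n + step
        clusters[new] = clusters[a] | clusters[b]
        active -= {a, b}
        active.add(new)
        partitions.append({clusters[k] for k in active})
    return partitions


def rank_normal_oracle(x):
    """Inverse-normal transform from the definition via sorting."""
    from scipy.stats import norm, rankdata

    x = np.asarray(x, dtype=float)
    r = rankdata(x, method="average")
    return norm.ppf((r - 0.5) / len(x))
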