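"""Independent brute-force references used by the statistical tests."""

import itertools

import numpy as np
from scipy.stats import rankdata


def exact_mannwhitney_p(x, y) -> float:
    """Two-sided Mann-Whitney p by full enumeration of group assignments.

    Enumerates every C(n+m, n) split of the pooled sample, computes the
    rank-sum U for each, and returns the probability of a U at least as far
    from the null mean as the observed one.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    mu = n * m / 2.0
    count = total = 0
    for idx in itertools.combinations(range(n + m), n):
        u = ranks[list(idx)].sum() - n * (n + 1) / 2
        count += abs(u - mu) >= abs(u_obs - mu) - 1e-9
        total += 1
    return count / total


def holm_reference(pvals, alpha=0.05):
    """Step-down Holm rejections straight from the definition."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    for k, idx in enumerate(order):
        if p[idx] <= alpha / (m - k):
            reject[idx] = True
        else:
            break
    return reject


def holm_adjusted_reference(pvals):
    """Step-down adjusted p-values from the definition (monotone prefix max)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for k, idx in enumerate(order):
        running = max(running, min(1.0, (m - k) * p[idx]))
        adj[idx] = running
    return adj


def bonferroni_reject(pvals, alpha=0.05):
    p = np.asarray(pvals, dtype=float)
    return p <= alpha / len(p)
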