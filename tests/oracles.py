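"""Independent reference implementations used only to check the package.

Everything here is deliberately written the straight-line, textbook way
(explicit loops, no shared code with the package) so agreement is evidence
of correctness rather than of shared bugs.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def irls_quasibinomial(y, X, max_iter=100, tol=1e-12):
    """Textbook IRLS for a logit-link quasi-binomial GLM.

    Returns (coef, se, t, p, dispersion) with Pearson-X2 scale and a t
    reference with n - p degrees of freedom.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    beta = np.zeros(p)
    mu = np.clip(y.mean() * np.ones(n), 1e-6, 1 - 1e-6)
    eta = np.log(mu / (1 - mu))
    for _ in range(max_iter):
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu)
        z = eta + (y - mu) / W
        WX = X * W[:, None]
        beta_new = np.linalg.solve(X.T @ WX, X.T @ (W * z))
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
        eta = X @ beta
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    pearson = np.sum((y - mu) ** 2 / (mu * (1 - mu)))
    phi = pearson / (n - p)
    W = mu * (1 - mu)
    cov = phi * np.linalg.inv(X.T @ (X * W[:, None]))
    se = np.sqrt(np.diag(cov))
    t = beta / se
    pvals = 2 * stats.t.sf(np.abs(t), df=n - p)
    return beta, se, t, pvals, phi


def bh_adjust(pvals):
    """Benjamini-Hochberg step-up adjusted p-values, written longhand."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        val = min(prev, p[idx] * m / rank)
        adj[idx] = val
        prev = val
    return adj


def kruskal_wallis_brute(groups, x):
    """Midrank KW statistic with tie correction, from the formula."""
    x = np.asarray(x, float)
    groups = np.asarray(groups)
    n = len(x)
    ranks = stats.rankdata(x)
    h = 0.0
    for g in np.unique(groups):
        r = ranks[groups == g]
        h += r.sum() ** 2 / len(r)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(x, return_counts=True)
    ties = ((counts ** 3 - counts).sum()) / (n ** 3 - n)
    return h / (1.0 - ties) if ties < 1 else 0.0


def chi_square_brute(table):
    """Pearson chi-square by direct summation over a dense table."""
    O = np.asarray(table, float)
    row = O.sum(axis=1)
    col = O.sum(axis=0)
    total = O.sum()
    stat = 0.0
    for i in range(O.shape[0]):
        for j in range(O.shape[1]):
            E = row[i] * col[j] / total
            if E > 0:
                stat += (O[i, j] - E) ** 2 / E
    return stat


def upgma(D):
    """Average-linkage agglomeration from a dense distance matrix.

    Returns the sorted list of merge heights (the quantity compared against
    the package's dendrogram).
    """
    D = np.asarray(D, float).copy()
    n = D.shape[0]
    sizes = {i: 1 for i in range(n)}
    active = set(range(n))
    heights = []
    dist = {(min(i, j), max(i, j)): D[i, j] for i in range(n) for j in range(i + 1, n)}
    next_id = n
    while len(active) > 1:
        (a, b), h = min(dist.items(), key=lambda kv: kv[1])
        heights.append(h)
        active -= {a, b}
        merged = next_id
        next_id += 1
        for c in active:
            da = dist.pop((min(a, c), max(a, c)))
            db = dist.pop((min(b, c), max(b, c)))
            dist[(min(merged, c), max(merged, c))] = (
                sizes[a] * da + sizes[b] * db
            ) / (sizes[a] + sizes[b])
        for key in [k for k in dist if a in k or b in k]:
            dist.pop(key)
        sizes[merged] = sizes[a] + sizes[b]
        active.add(merged)
    return sorted(heights)
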