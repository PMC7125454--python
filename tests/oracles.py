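"""Independent brute-force reference implementations used only by tests.

These deliberately take the slow, obvious route (full enumeration,
convolution, O(n^3) distance matrices) so they share no code path with
the package implementations they check.
"""

import numpy as np
from scipy.stats import nbinom, poisson


def conditional_nb_pvalue_by_convolution(total_a, total_b, n_a, n_b, phi):
    """Two-sided conditional exact p via explicit convolution of per-sample pmfs.

    Builds the pmf of each group's total by convolving n copies of a single
    NB(mu, phi) pmf truncated at the grand total, then conditions on the
    grand total and sums minimum-likelihood outcomes.
    """
    s = total_a + total_b
    if s == 0:
        return 1.0
    mu = s / (n_a + n_b)
    support = np.arange(s + 1)
    if phi == 0:
        single = poisson.pmf(support, mu)
    else:
        r = 1.0 / phi
        single = nbinom.pmf(support, r, r / (r + mu))

    def group_pmf(n):
        pmf = single.copy()
        for _ in range(n - 1):
            pmf = np.convolve(pmf, single)[: s + 1]
        return pmf

    pa = group_pmf(n_a)
    pb = group_pmf(n_b)
    joint = pa * pb[::-1]  # P(A = k) * P(B = s - k)
    joint = joint / joint.sum()
    obs = joint[total_a]
    return float(joint[joint <= obs * (1 + 1e-9)].sum())


def bh_stepup_reference(p):
    """Textbook step-up BH: walk ranks from largest, take running minimum."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, p[order[i]] * m / (i + 1))
        adj[order[i]] = running
    return adj


def floyd_warshall(nodes, edges):
    """All-pairs hop distances; inf where unreachable."""
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for u, v in edges:
        dist[idx[u], idx[v]] = 1.0
        dist[idx[v], idx[u]] = 1.0
    for k in range(n):
        dist = np.minimum(dist, dist[:, [k]] + dist[[k], :])
    return dist, idx


def betweenness_by_path_counting(nodes, edges):
    """Brute-force betweenness: count shortest paths with a distance-matrix DP."""
    dist, idx = floyd_warshall(nodes, edges)
    n = len(nodes)
    adj = [[False] * n for _ in range(n)]
    for u, v in edges:
        adj[idx[u]][idx[v]] = adj[idx[v]][idx[u]] = True

    from functools import lru_cache

    @lru_cache(maxsize=None)
    def n_paths(s, t):
        if s == t:
            return 1
        return sum(
            n_paths(s, w) for w in range(n) if adj[w][t] and dist[s][w] == dist[s][t] - 1
        )

    bc = dict.fromkeys(nodes, 0.0)
    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(dist[s][t]):
                continue
            total = n_paths(s, t)
            for v in range(n):
                if v in (s, t) or not np.isfinite(dist[s][v]) or not np.isfinite(dist[v][t]):
                    continue
                if dist[s][v] + dist[v][t] == dist[s][t]:
                    bc[nodes[v]] += n_paths(s, v) * n_paths(v, t) / total
    norm = (n - 1) * (n - 2) / 2.0 if n > 2 else 1.0
    return {v: bc[v] / norm for v in nodes}


def auc_by_pair_counting(scores, labels):
    """AUC as the fraction of (positive, negative) pairs won, ties = 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def pearson_two_pass(x, y):
    """Naive two-pass Pearson correlation."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = (sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)) ** 0.5
    return num / den
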