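"""Independent brute-force oracles used to validate the package.

Everything here is written from the definitions with explicit loops
(triple loops, Floyd-Warshall, subgraph shortest paths, exhaustive
enumeration) and never calls into hubdisrupt.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations

import numpy as np

INF = float("inf")


def strength_oracle(w: np.ndarray) -> np.ndarray:
    n = len(w)
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            out[i] += w[i][j]
    return out


def clustering_oracle(w: np.ndarray) -> np.ndarray:
    """Onnela weighted clustering by explicit triple loop."""
    n = len(w)
    mx = max(w[i][j] for i in range(n) for j in range(n))
    wh = w / mx if mx > 0 else w
    out = np.zeros(n)
    for i in range(n):
        k = sum(1 for j in range(n) if w[i][j] > 0)
        if k < 2:
            continue
        s = 0.0
        for j in range(n):
            for h in range(n):
                s += (wh[i][j] * wh[i][h] * wh[j][h]) ** (1.0 / 3.0)
        out[i] = s / (k * (k - 1))
    return out


def transitivity_oracle(w: np.ndarray) -> float:
    n = len(w)
    mx = max(w[i][j] for i in range(n) for j in range(n))
    wh = w / mx if mx > 0 else w
    num = 0.0
    denom = 0.0
    for i in range(n):
        k = sum(1 for j in range(n) if w[i][j] > 0)
        denom += k * (k - 1)
        for j in range(n):
            for h in range(n):
                num += (wh[i][j] * wh[i][h] * wh[j][h]) ** (1.0 / 3.0)
    return num / denom if denom > 0 else 0.0


def floyd_warshall_oracle(w: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths on lengths 1/w, plain triple loop."""
    n = len(w)
    d = np.full((n, n), INF)
    for i in range(n):
        d[i][i] = 0.0
        for j in range(n):
            if w[i][j] > 0:
                d[i][j] = 1.0 / w[i][j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    return d


def global_efficiency_oracle(w: np.ndarray) -> float:
    n = len(w)
    d = floyd_warshall_oracle(w)
    s = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and d[i][j] < INF:
                s += 1.0 / d[i][j]
    return s / (n * (n - 1))


def betweenness_oracle(w: np.ndarray, rtol: float = 1e-10) -> np.ndarray:
    """Unnormalized betweenness by Floyd-Warshall + explicit path counting.

    sigma(s, t) is accumulated over nodes in order of distance from s;
    a node v lies on a shortest s-t path iff d(s,v) + d(v,t) == d(s,t)
    (within relative tolerance, since lengths are floats).
    """
    n = len(w)
    d = floyd_warshall_oracle(w)

    def close(a, b):
        return abs(a - b) <= rtol * max(1.0, abs(a), abs(b))

    # path counts from every source
    sigma = np.zeros((n, n))
    for s in range(n):
        order = sorted(range(n), key=lambda v: d[s][v])
        sigma[s][s] = 1.0
        for t in order:
            if t == s or d[s][t] == INF:
                continue
            cnt = 0.0
            for u in range(n):
                if w[u][t] > 0 and d[s][u] < INF and \
                        close(d[s][u] + 1.0 / w[u][t], d[s][t]):
                    cnt += sigma[s][u]
            sigma[s][t] = cnt
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if d[s][t] == INF:
                continue
            for v in range(n):
                if v in (s, t) or d[s][v] == INF or d[v][t] == INF:
                    continue
                if close(d[s][v] + d[v][t], d[s][t]):
                    bc[v] += sigma[s][v] * sigma[v][t] / sigma[s][t]
    return bc


def local_efficiency_oracle(w: np.ndarray) -> np.ndarray:
    """Per-node subgraph efficiency: shortest paths restricted to the
    neighbor set, on normalized-weight inverse lengths."""
    n = len(w)
    mx = max(w[i][j] for i in range(n) for j in range(n))
    wh = w / mx if mx > 0 else w
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if wh[i][j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        sub = wh[np.ix_(nbrs, nbrs)]
        d = floyd_warshall_oracle(sub)
        s = 0.0
        for a in range(k):
            for b in range(k):
                if a != b and d[a][b] < INF:
                    s += (wh[i][nbrs[a]] * wh[i][nbrs[b]] / d[a][b]) ** (1 / 3)
        out[i] = s / (k * (k - 1))
    return out


# ---------------------------------------------------------------------------
# statistics oracles


def mann_whitney_enumeration_oracle(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating group assignments and
    counting pairwise wins (half credit for ties) -- no ranks involved."""
    pooled = list(x) + list(y)
    n, m = len(x), len(y)
    total_n = n + m
    # pairwise-comparison matrix: G[i][j] = win credit of value i over j
    g = np.zeros((total_n, total_n))
    for i in range(total_n):
        for j in range(total_n):
            if pooled[i] > pooled[j]:
                g[i][j] = 1.0
            elif pooled[i] == pooled[j]:
                g[i][j] = 0.5
    def u_of(idx_x):
        in_x = np.zeros(total_n, dtype=bool)
        in_x[list(idx_x)] = True
        u = g[np.ix_(in_x, ~in_x)].sum()
        return min(u, n * m - u)
    u_obs = u_of(range(n))
    count = 0
    total = 0
    for idx in combinations(range(total_n), n):
        total += 1
        if u_of(idx) <= u_obs + 1e-9:
            count += 1
    return u_obs, count / total


def fisher_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by enumerating all tables with the observed
    margins, probabilities from the factorial formula in exact rationals."""
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d

    def prob(aa):
        bb, cc = r1 - aa, c1 - aa
        dd = r2 - cc
        if min(bb, cc, dd) < 0:
            return None
        num = (math.factorial(r1) * math.factorial(r2) *
               math.factorial(c1) * math.factorial(c2))
        den = (math.factorial(n) * math.factorial(aa) * math.factorial(bb) *
               math.factorial(cc) * math.factorial(dd))
        return Fraction(num, den)

    p_obs = prob(a)
    total = Fraction(0)
    for aa in range(0, min(r1, c1) + 1):
        p = prob(aa)
        if p is not None and p <= p_obs:
            total += p
    return total


def bh_stepup_oracle(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p straight from the definition:
    adj p_(i) = min_{j >= i} m p_(j) / j, capped at 1."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    for rank_i, idx in enumerate(order):
        best = min(m * p[order[j]] / (j + 1) for j in range(rank_i, m))
        adj[idx] = min(1.0, best)
    return np.array(adj)


def auc_concordance_oracle(scores, labels) -> float:
    """Pairwise-concordance AUC with half credit for ties, double loop."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def ols_slope_oracle(x, y) -> tuple[float, float]:
    """Closed-form simple-regression slope and intercept."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xb, yb = x.mean(), y.mean()
    slope = float(((x - xb) * (y - yb)).sum() / ((x - xb) ** 2).sum())
    return slope, float(yb - slope * xb)


def random_weighted_graph(rng: np.random.Generator, n: int,
                          density: float = 0.5) -> np.ndarray:
    """Random symmetric non-negative weight matrix with zero diagonal."""
    w = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    mask = rng.uniform(size=len(iu[0])) < density
    vals = np.where(mask, rng.lognormal(0.5, 0.8, size=len(iu[0])), 0.0)
    w[iu] = vals
    return w + w.T
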