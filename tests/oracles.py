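"""Independent oracles used by the tests.

These are deliberately naive implementations (quadratic dynamic programs,
exhaustive enumeration, plain breadth-first search) kept separate from the
package so they can disagree with it.
"""

from __future__ import annotations

import itertools
import math

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")

NEG = float("-inf")


def sw_affine_score(a: str, b: str, gap_open: int = 11,
                    gap_extend: int = 1) -> float:
    """Brute-force local affine-gap alignment score.

    A gap of length k costs gap_open + k * gap_extend.  Three-state DP
    (match, gap-in-a, gap-in-b) with scores floored at zero for locality.
    """
    n, m = len(a), len(b)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(M[i - 1][j] - (gap_open + gap_extend),
                          X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - (gap_open + gap_extend),
                          Y[i][j - 1] - gap_extend)
            s = _B62[a[i - 1], b[j - 1]]
            M[i][j] = max(0.0, s + max(M[i - 1][j - 1], X[i - 1][j - 1],
                                       Y[i - 1][j - 1]))
            best = max(best, M[i][j])
    return best


def mann_whitney_exact_p(a: list[float], b: list[float]) -> float:
    """Exact two-sided Mann-Whitney p by enumerating all labelings."""
    pooled = a + b
    n_a = len(a)

    def u_stat(group_a: tuple[float, ...], group_b: tuple[float, ...]) -> float:
        u = 0.0
        for x in group_a:
            for y in group_b:
                u += (x > y) + 0.5 * (x == y)
        return u

    observed = u_stat(tuple(a), tuple(b))
    n = len(pooled)
    mu = n_a * (n - n_a) / 2.0
    obs_dev = abs(observed - mu)
    count = total = 0
    for combo in itertools.combinations(range(n), n_a):
        ga = tuple(pooled[i] for i in combo)
        gb = tuple(pooled[i] for i in range(n) if i not in combo)
        dev = abs(u_stat(ga, gb) - mu)
        total += 1
        if dev >= obs_dev - 1e-12:
            count += 1
    return count / total


def kruskal_exact_p(groups: list[list[float]]) -> float:
    """Exact Kruskal-Wallis p by enumerating group label assignments."""
    from scipy.stats import kruskal

    pooled = [x for g in groups for x in g]
    sizes = [len(g) for g in groups]
    h_obs = kruskal(*groups).statistic
    n = len(pooled)
    count = total = 0
    indices = list(range(n))
    for first in itertools.combinations(indices, sizes[0]):
        rest = [i for i in indices if i not in first]
        for second in itertools.combinations(rest, sizes[1]):
            third = [i for i in rest if i not in second]
            parts = [[pooled[i] for i in first],
                     [pooled[i] for i in second],
                     [pooled[i] for i in third]]
            total += 1
            if kruskal(*parts).statistic >= h_obs - 1e-9:
                count += 1
    return count / total


def binom_tail(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p), by direct summation."""
    return sum(math.comb(n, i) * p ** i * (1 - p) ** (n - i)
               for i in range(k, n + 1))


def bfs_within(adjacency: dict[str, set[str]], seeds: set[str],
               max_depth: int) -> dict[str, int]:
    """Plain BFS distances from a seed set, truncated at max_depth."""
    dist = {s: 0 for s in seeds}
    frontier = set(seeds)
    for d in range(1, max_depth + 1):
        nxt = set()
        for node in frontier:
            for nb in adjacency.get(node, ()):
                if nb not in dist:
                    dist[nb] = d
                    nxt.add(nb)
        frontier = nxt
    return dist
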