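"""Independent brute-force oracles used only by the tests.

Deliberately naive implementations (python loops, exhaustive
enumeration) kept free of any code path from the package under test.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def pli_loop(phase_x, phase_y) -> float:
    """Direct loop over sign(sin(dphi))."""
    total = 0.0
    for a, b in zip(phase_x, phase_y):
        s = np.sin(a - b)
        total += 0.0 if s == 0 else (1.0 if s > 0 else -1.0)
    return abs(total / len(phase_x))


# ----------------------------------------------------------- graph metrics

def degrees(adj) -> list[int]:
    n = len(adj)
    return [sum(adj[i][j] for j in range(n)) for i in range(n)]


def clustering_coeffs(adj) -> list[float]:
    n = len(adj)
    out = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i][j]]
        k = len(nbrs)
        if k < 2:
            out.append(0.0)
            continue
        e = sum(1 for a, b in combinations(nbrs, 2) if adj[a][b])
        out.append(2.0 * e / (k * (k - 1)))
    return out


def shortest_paths(adj) -> list[list[float]]:
    """Floyd-Warshall on the unweighted graph; inf where unreachable."""
    n = len(adj)
    d = [[0.0 if i == j else (1.0 if adj[i][j] else np.inf) for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    return d


def char_path_length(adj) -> float:
    d = shortest_paths(adj)
    n = len(adj)
    finite = [d[i][j] for i in range(n) for j in range(n) if i != j and np.isfinite(d[i][j])]
    if not finite:
        raise ValueError("no finite path")
    return sum(finite) / len(finite)


def global_eff(adj) -> float:
    d = shortest_paths(adj)
    n = len(adj)
    if n < 2:
        return 0.0
    total = sum(
        1.0 / d[i][j]
        for i in range(n)
        for j in range(n)
        if i != j and np.isfinite(d[i][j])
    )
    return total / (n * (n - 1))


def local_effs(adj) -> list[float]:
    n = len(adj)
    out = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i][j]]
        if len(nbrs) < 2:
            out.append(0.0)
            continue
        sub = [[adj[a][b] for b in nbrs] for a in nbrs]
        out.append(global_eff(sub))
    return out


# --------------------------------------------------------------- statistics

def exhaustive_pairwise_p(values_a, values_b) -> float:
    """Exact two-group permutation p for |mean difference| by full enumeration."""
    pooled = list(values_a) + list(values_b)
    n_a = len(values_a)
    obs = abs(np.mean(values_a) - np.mean(values_b))
    count = total = 0
    for comb in combinations(range(len(pooled)), n_a):
        sel = [pooled[i] for i in comb]
        rest = [pooled[i] for i in range(len(pooled)) if i not in comb]
        total += 1
        if abs(np.mean(sel) - np.mean(rest)) >= obs - 1e-12:
            count += 1
    return count / total


def random_adjacency(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    a = (rng.random((n, n)) < p).astype(int)
    a = np.triu(a, 1)
    return a + a.T
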