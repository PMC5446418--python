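"""Independent brute-force oracles for graph statistics.

These deliberately avoid the library routes used by the package: shortest
paths are found by exhaustive simple-path enumeration (DFS with
branch-and-bound pruning) in exact Fraction arithmetic, so geodesic ties
are decided without floating-point ambiguity.
"""

from fractions import Fraction

import numpy as np


def _edges(matrix):
    w = np.asarray(matrix)
    n = len(w)
    adj = {i: [] for i in range(n)}
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] > 0:
                adj[i].append((j, Fraction(1, int(w[i, j]))))
    return adj


def enumerate_geodesics(matrix, s, t):
    """All simple shortest paths s->t: returns (min_cost, list of paths)."""
    adj = _edges(matrix)
    best = [None]
    paths = []

    def dfs(node, visited, cost, path):
        if best[0] is not None and cost > best[0]:
            return
        if node == t:
            if best[0] is None or cost < best[0]:
                best[0] = cost
                paths.clear()
            if cost == best[0]:
                paths.append(tuple(path))
            return
        for nxt, c in adj[node]:
            if nxt not in visited:
                visited.add(nxt)
                path.append(nxt)
                dfs(nxt, visited, cost + c, path)
                path.pop()
                visited.remove(nxt)

    dfs(s, {s}, Fraction(0), [s])
    return best[0], paths


def brute_force_betweenness(matrix):
    """BC(i) = sum over unordered pairs of the geodesic fraction through i."""
    n = len(matrix)
    bc = [Fraction(0)] * n
    for s in range(n):
        for t in range(s + 1, n):
            _, paths = enumerate_geodesics(matrix, s, t)
            if not paths:
                continue
            total = len(paths)
            for i in range(n):
                if i in (s, t):
                    continue
                through = sum(1 for p in paths if i in p[1:-1])
                bc[i] += Fraction(through, total)
    return np.array([float(x) for x in bc])


def brute_force_local_efficiency(matrix):
    """E(i) = mean over j != i of 1/d_ij via exhaustive geodesic search."""
    n = len(matrix)
    out = np.zeros(n)
    for i in range(n):
        acc = Fraction(0)
        for j in range(n):
            if j == i:
                continue
            cost, paths = enumerate_geodesics(matrix, i, j)
            if paths:
                acc += 1 / cost
        out[i] = float(acc / (n - 1))
    return out


def random_test_graph(rng, n_max=12, weighted=True):
    """Random symmetric graph; weights from {1,2,4,8} keep 1/w sums exact
    in binary floating point, so float and Fraction tie detection agree."""
    n = int(rng.integers(4, n_max + 1))
    p = rng.uniform(0.2, 0.5)
    w = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                w[i, j] = w[j, i] = float(rng.choice([1, 2, 4, 8])) if weighted else 1.0
    return w
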