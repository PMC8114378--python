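"""Independent brute-force oracles for graph algorithms.

Everything here is deliberately naive — exhaustive enumeration over
simple paths, subsets and partitions — so that the package's efficient
implementations can be checked against an unrelated computation on
small graphs.
"""

from __future__ import annotations

from itertools import combinations, permutations

import numpy as np


def all_simple_paths(weights: np.ndarray, src: int, dst: int) -> list[list[int]]:
    """Every simple path src -> dst over nonzero-weight edges (DFS)."""
    p = weights.shape[0]
    paths: list[list[int]] = []

    def extend(path: list[int]) -> None:
        node = path[-1]
        if node == dst:
            paths.append(list(path))
            return
        for nxt in range(p):
            if weights[node, nxt] != 0 and nxt not in path:
                path.append(nxt)
                extend(path)
                path.pop()

    extend([src])
    return paths


def path_length(weights: np.ndarray, path: list[int]) -> float:
    return sum(1.0 / abs(weights[a, b]) for a, b in zip(path, path[1:]))


def brute_shortest_path(
    weights: np.ndarray, src: int, dst: int
) -> tuple[float, list[int]]:
    """Minimum 1/|w| path length and the lexicographically smallest argmin."""
    if src == dst:
        return 0.0, [src]
    paths = all_simple_paths(weights, src, dst)
    if not paths:
        return np.inf, []
    lengths = [path_length(weights, p) for p in paths]
    best = min(lengths)
    ties = [p for p, l in zip(paths, lengths) if l <= best + 1e-12]
    return best, min(ties)


def brute_betweenness(weights: np.ndarray) -> np.ndarray:
    """All-pairs enumeration with fractional credit for tied geodesics."""
    p = weights.shape[0]
    bc = np.zeros(p)
    for s in range(p):
        for t in range(s + 1, p):
            paths = all_simple_paths(weights, s, t)
            if not paths:
                continue
            lengths = [path_length(weights, q) for q in paths]
            best = min(lengths)
            geodesics = [q for q, l in zip(paths, lengths) if l <= best + 1e-12]
            for q in geodesics:
                for v in q[1:-1]:
                    bc[v] += 1.0 / len(geodesics)
    return bc


def brute_closeness(weights: np.ndarray) -> np.ndarray:
    p = weights.shape[0]
    out = np.zeros(p)
    for i in range(p):
        total = 0.0
        reachable = 0
        for j in range(p):
            if j == i:
                continue
            d, _ = brute_shortest_path(weights, i, j)
            if np.isfinite(d):
                total += d
                reachable += 1
        out[i] = 1.0 / total if reachable else 0.0
    return out


def brute_cliques(weights: np.ndarray, k: int) -> list[tuple[int, ...]]:
    p = weights.shape[0]
    out = []
    for subset in combinations(range(p), k):
        if all(weights[a, b] != 0 for a, b in combinations(subset, 2)):
            out.append(subset)
    return out


def brute_cycles(weights: np.ndarray, length: int) -> set[tuple[int, ...]]:
    """Canonical simple cycles of the given length via permutation search."""
    p = weights.shape[0]
    found: set[tuple[int, ...]] = set()
    for subset in combinations(range(p), length):
        for perm in permutations(subset[1:]):
            ring = (subset[0],) + perm
            if all(
                weights[ring[i], ring[(i + 1) % length]] != 0 for i in range(length)
            ):
                fwd = min(
                    tuple(ring[(i + s) % length] for s in range(length))
                    for i in range(length)
                )
                rev_ring = ring[::-1]
                rev = min(
                    tuple(rev_ring[(i + s) % length] for s in range(length))
                    for i in range(length)
                )
                found.add(min(fwd, rev))
    return found


def brute_best_modularity(weights: np.ndarray) -> float:
    """Maximum modularity over all partitions (Bell-number search, p <= 7)."""
    p = weights.shape[0]
    w = np.abs(weights)
    m = w.sum() / 2.0
    if m == 0:
        return 0.0

    def q_of(assign: list[int]) -> float:
        arr = np.array(assign)
        q = 0.0
        for c in set(assign):
            mask = arr == c
            e_c = w[np.ix_(mask, mask)].sum() / 2.0
            a_c = w[mask].sum() / 2.0
            q += e_c / m - (a_c / m) ** 2
        return q

    best = -np.inf
    partitions: list[list[int]] = [[0]]
    for _ in range(p - 1):
        nxt = []
        for part in partitions:
            k = max(part) + 1
            for c in range(k + 1):
                nxt.append(part + [c])
        partitions = nxt
    for part in partitions:
        best = max(best, q_of(part))
    return best


def sample_partial_correlations(x: np.ndarray) -> np.ndarray:
    """Partial correlations by direct inversion of the sample covariance."""
    prec = np.linalg.inv(np.cov(x, rowvar=False))
    d = np.sqrt(np.diag(prec))
    rho = -prec / np.outer(d, d)
    np.fill_diagonal(rho, 0.0)
    return rho


def random_signed_network(
    rng: np.random.Generator, p: int, density: float = 0.4
) -> np.ndarray:
    """Random symmetric signed weight matrix with |w| in [0.1, 0.9)."""
    w = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            if rng.random() < density:
                w[i, j] = w[j, i] = rng.uniform(0.1, 0.9) * rng.choice([-1, 1])
    return w
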