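"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library code paths they check:
shortest paths and betweenness are computed by exhaustive simple-path
enumeration, modularity by direct evaluation of the Newman formula, and
Spearman by rank-then-Pearson from first principles.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from netpsych.catalog import build_item_catalog
from netpsych.cohort import PlantedSem, simulate_cohort, simulate_planted_sem


@pytest.fixture(scope="session")
def catalog():
    return build_item_catalog()


@pytest.fixture(scope="session")
def small_cohort(catalog):
    """A 60-participant synthetic cohort shared across read-only tests."""
    return simulate_cohort(60, catalog, seed=11)


@pytest.fixture(scope="session")
def chain_data():
    """n=5,000 draws from the planted 3-node chain X -> Y -> Z (coef 0.7)."""
    sem = PlantedSem.chain(["X", "Y", "Z"], coef=0.7)
    return sem, simulate_planted_sem(sem, 5000, seed=42)


# --------------------------------------------------------------------------- #
# brute-force oracles


def enumerate_simple_paths(W: np.ndarray, s: int, t: int):
    """All simple paths s -> t with their total length on edge lengths 1/w."""
    n = W.shape[0]
    paths = []

    def extend(path, length):
        u = path[-1]
        if u == t:
            paths.append((list(path), length))
            return
        for v in range(n):
            if W[u, v] > 0 and v not in path:
                path.append(v)
                extend(path, length + 1.0 / W[u, v])
                path.pop()

    extend([s], 0.0)
    return paths


def brute_force_distances(W: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for s, t in itertools.combinations(range(n), 2):
        paths = enumerate_simple_paths(W, s, t)
        if paths:
            d = min(length for _, length in paths)
            D[s, t] = D[t, s] = d
    return D


def brute_force_path_length(W: np.ndarray) -> float:
    """Mean shortest-path length over connected ordered pairs, by enumeration."""
    D = brute_force_distances(W)
    n = D.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = off & np.isfinite(D)
    return float(D[finite].mean())


def brute_force_betweenness(W: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Betweenness by enumerating all shortest paths and splitting fractionally."""
    n = W.shape[0]
    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths = enumerate_simple_paths(W, s, t)
        if not paths:
            continue
        best = min(length for _, length in paths)
        shortest = [p for p, length in paths if length <= best + tol]
        for path in shortest:
            for v in path[1:-1]:
                bc[v] += 1.0 / len(shortest)
    return bc


def newman_q(W: np.ndarray, communities) -> float:
    """Direct evaluation of weighted Newman modularity for a partition."""
    m2 = W.sum()  # 2m
    k = W.sum(axis=1)
    label = np.empty(W.shape[0], dtype=int)
    for c, nodes in enumerate(communities):
        for v in nodes:
            label[v] = c
    q = 0.0
    for i in range(W.shape[0]):
        for j in range(W.shape[0]):
            if label[i] == label[j]:
                q += W[i, j] - k[i] * k[j] / m2
    return q / m2
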