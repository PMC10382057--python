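"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — explicit Python loops over voxels,
pairs and neighbors — and shares no code with the package implementation.
"""

from __future__ import annotations

from itertools import product

import numpy as np

DIRECTIONS_13 = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]


def _inside(shape, v):
    return all(0 <= v[a] < shape[a] for a in range(3))


def brute_glcm(labels: np.ndarray, L: int, distance: int = 1) -> np.ndarray:
    """Counts over 13 directions, symmetrized, normalized."""
    C = np.zeros((L, L))
    shape = labels.shape
    for v in product(*[range(n) for n in shape]):
        a = labels[v]
        if a <= 0:
            continue
        for d in DIRECTIONS_13:
            w = tuple(v[i] + distance * d[i] for i in range(3))
            if _inside(shape, w) and labels[w] > 0:
                C[a - 1, labels[w] - 1] += 1
    C = C + C.T
    tot = C.sum()
    return C / tot if tot > 0 else C


def brute_glrlm(labels: np.ndarray, L: int, direction) -> np.ndarray:
    """Run-length matrix along one direction by explicit line walking."""
    shape = labels.shape
    runs = []
    for v in product(*[range(n) for n in shape]):
        a = labels[v]
        if a <= 0:
            continue
        prev = tuple(v[i] - direction[i] for i in range(3))
        if _inside(shape, prev) and labels[prev] == a:
            continue  # not a run start
        length = 1
        w = tuple(v[i] + direction[i] for i in range(3))
        while _inside(shape, w) and labels[w] == a:
            length += 1
            w = tuple(w[i] + direction[i] for i in range(3))
        runs.append((a, length))
    rmax = max((r for _, r in runs), default=1)
    M = np.zeros((L, rmax))
    for a, r in runs:
        M[a - 1, r - 1] += 1
    return M


def brute_glszm(labels: np.ndarray, L: int) -> np.ndarray:
    """Zone-size matrix by flood fill over the 26-neighborhood."""
    shape = labels.shape
    seen = np.zeros(shape, dtype=bool)
    neigh = [d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]
    zones = []
    for v in product(*[range(n) for n in shape]):
        if labels[v] <= 0 or seen[v]:
            continue
        level = labels[v]
        stack = [v]
        seen[v] = True
        size = 0
        while stack:
            u = stack.pop()
            size += 1
            for d in neigh:
                w = tuple(u[i] + d[i] for i in range(3))
                if _inside(shape, w) and not seen[w] and labels[w] == level:
                    seen[w] = True
                    stack.append(w)
        zones.append((level, size))
    smax = max((s for _, s in zones), default=1)
    M = np.zeros((L, smax))
    for a, s in zones:
        M[a - 1, s - 1] += 1
    return M


def brute_ngtdm(labels: np.ndarray, L: int):
    """Per-level sums of |level - neighborhood mean| and counted voxels."""
    shape = labels.shape
    neigh = [d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]
    s = np.zeros(L)
    n = np.zeros(L, dtype=int)
    for v in product(*[range(n_) for n_ in shape]):
        a = labels[v]
        if a <= 0:
            continue
        vals = []
        for d in neigh:
            w = tuple(v[i] + d[i] for i in range(3))
            if _inside(shape, w) and labels[w] > 0:
                vals.append(labels[w])
        if not vals:
            continue
        s[a - 1] += abs(a - sum(vals) / len(vals))
        n[a - 1] += 1
    return s, n


def brute_auc(scores, labels) -> float:
    """Pairwise positive-vs-negative counting with half-credit ties."""
    scores = list(scores)
    labels = list(labels)
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_relieff(X: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """ReliefF weights with explicit neighbor lists (stable tie order)."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    w = np.zeros(p)
    for i in range(n):
        dists = [
            (sum((X[i, f] - X[j, f]) ** 2 for f in range(p)), j)
            for j in range(n)
            if j != i
        ]
        hits = sorted([(d, j) for d, j in dists if y[j] == y[i]])[:k]
        misses = sorted([(d, j) for d, j in dists if y[j] != y[i]])[:k]
        for _, j in misses:
            for f in range(p):
                w[f] += abs(X[i, f] - X[j, f]) / (n * k)
        for _, j in hits:
            for f in range(p):
                w[f] -= abs(X[i, f] - X[j, f]) / (n * k)
    return w


def random_labeled_volume(shape, L, rng, mask_fraction=0.85):
    """Random quantized volume with an irregular mask (0 = outside)."""
    labels = rng.integers(1, L + 1, size=shape)
    mask = rng.random(shape) < mask_fraction
    labels = np.where(mask, labels, 0)
    if not (labels > 0).any():
        labels.flat[0] = 1
    return labels.astype(np.int32)
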