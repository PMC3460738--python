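"""Independent brute-force oracles used by the test suite.

Each oracle computes its quantity by direct enumeration or a closed form,
deliberately avoiding the code paths (FFT, morphology, trapezoid sweeps,
greedy tree growth) it is used to check.
"""

import numpy as np


def sum_of_squares(img) -> float:
    """Parseval oracle for the mean power spectrum: plain Σ pixels²."""
    return float((np.asarray(img, dtype=float) ** 2).sum())


def plateau_minima(img) -> np.ndarray:
    """Regional minima by exhaustive plateau search.

    Flood-fills each 8-connected component of equal-valued pixels and marks
    it iff every neighbour outside the component is strictly brighter.
    """
    img = np.asarray(img)
    m, n = img.shape
    seen = np.zeros((m, n), bool)
    out = np.zeros((m, n), bool)
    for i in range(m):
        for j in range(n):
            if seen[i, j]:
                continue
            v = img[i, j]
            stack, comp, is_min = [(i, j)], [], True
            seen[i, j] = True
            while stack:
                a, b = stack.pop()
                comp.append((a, b))
                for da in (-1, 0, 1):
                    for db in (-1, 0, 1):
                        if da == 0 and db == 0:
                            continue
                        x, y = a + da, b + db
                        if 0 <= x < m and 0 <= y < n:
                            if img[x, y] == v:
                                if not seen[x, y]:
                                    seen[x, y] = True
                                    stack.append((x, y))
                            elif img[x, y] < v:
                                is_min = False
            if is_min:
                for a, b in comp:
                    out[a, b] = True
    return out


def median_3x3_replicated(img) -> np.ndarray:
    """Brute-force 3×3 median with edge replication."""
    img = np.asarray(img)
    m, n = img.shape
    out = np.empty_like(img)
    for i in range(m):
        for j in range(n):
            vals = []
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    vals.append(img[min(max(i + di, 0), m - 1), min(max(j + dj, 0), n - 1)])
            out[i, j] = sorted(vals)[4]
    return out


def auc_pair_counting(values, labels) -> float:
    """Mann–Whitney AUC: P(pos > neg) + ½·P(pos = neg) by enumeration."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    pos = values[labels == 1]
    neg = values[labels == 0]
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return (gt + 0.5 * eq) / (len(pos) * len(neg))


def quadtree_area(counts: dict) -> int:
    """Total tiled area Σ counts(s)·s² of a quadtree decomposition."""
    return sum(c * s * s for s, c in counts.items())


def best_stump_error(X, y) -> int:
    """Minimum training errors over all single-split (2-leaf) trees."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    best = len(y)
    for j in range(X.shape[1]):
        for t in np.unique(X[:, j]):
            left = X[:, j] <= t
            for cl in (0, 1):
                pred = np.where(left, cl, 1 - cl)
                best = min(best, int((pred != y).sum()))
    return best
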