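"""Independent brute-force oracles used by the test suite.

These are deliberately naive re-derivations (enumeration, closed forms) kept
separate from the package implementation they check.
"""
from itertools import combinations, product

import numpy as np


def brute_force_mec(points):
    """Smallest enclosing circle by trying every 1-, 2-, 3-point candidate."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n == 1:
        return pts[0], 0.0
    best = None

    def consider(c, r):
        nonlocal best
        if np.all(np.linalg.norm(pts - c, axis=1) <= r + 1e-9 * (1 + r)):
            if best is None or r < best[1]:
                best = (c, r)

    for i, j in combinations(range(n), 2):
        c = (pts[i] + pts[j]) / 2
        consider(c, float(np.linalg.norm(pts[i] - c)))
    for i, j, k in combinations(range(n), 3):
        ax, ay = pts[i]
        bx, by = pts[j]
        cx, cy = pts[k]
        d = 2 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
        if abs(d) < 1e-12:
            continue
        ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
              + (cx**2 + cy**2) * (ay - by)) / d
        uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
              + (cx**2 + cy**2) * (bx - ax)) / d
        c = np.array([ux, uy])
        consider(c, float(np.linalg.norm(pts[i] - c)))
    return best


def brute_force_sign_flip_p(lifts):
    """One-sided sign-flip p-value by full enumeration (n small)."""
    lifts = np.asarray(lifts, dtype=float)
    obs = lifts.mean()
    count = 0
    for signs in product((-1, 1), repeat=len(lifts)):
        if np.mean(np.array(signs) * lifts) >= obs - 1e-9 * (1 + abs(obs)):
            count += 1
    return count / 2 ** len(lifts)


def best_constant_binary_error(labels):
    """100 * min over the two constant guesses of the misclassification rate."""
    labels = np.asarray(labels).astype(int)
    return min(100.0 * np.mean(labels != c) for c in (0, 1))


def best_constant_rmse(levels, grid):
    """Min RMSE over a fine grid of constant guesses."""
    levels = np.asarray(levels, dtype=float)
    return min(float(np.sqrt(np.mean((levels - c) ** 2))) for c in grid)
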