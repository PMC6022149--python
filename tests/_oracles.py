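"""Independent brute-force oracles used by the test suite.

These deliberately use straight loops and textbook definitions, sharing
no code with the package implementation.
"""

from __future__ import annotations

from math import comb

import numpy as np


def lof_oracle(points: np.ndarray, k: int) -> np.ndarray:
    """Textbook local outlier factor by exhaustive sorting.

    k-distance(p): distance to the k-th nearest other point.
    N(p): all other points within k-distance(p) (ties included).
    reach-dist(p, o) = max(k-distance(o), d(p, o)).
    lrd(p) = |N(p)| / sum_{o in N(p)} reach-dist(p, o).
    LOF(p) = mean_{o in N(p)} lrd(o) / lrd(p).
    """
    pts = np.asarray(points, dtype=float)
    m = len(pts)

    def d(i, j):
        return float(np.linalg.norm(pts[i] - pts[j]))

    kdist = np.empty(m)
    neighbors: list[list[int]] = []
    for i in range(m):
        dists = sorted((d(i, j), j) for j in range(m) if j != i)
        kdist[i] = dists[k - 1][0]
        neighbors.append([j for dist, j in dists if dist <= kdist[i]])

    lrd = np.empty(m)
    for i in range(m):
        total = sum(max(kdist[j], d(i, j)) for j in neighbors[i])
        lrd[i] = np.inf if total == 0 else len(neighbors[i]) / total

    lof = np.empty(m)
    for i in range(m):
        num = float(np.mean([lrd[j] for j in neighbors[i]]))
        if np.isinf(lrd[i]):
            lof[i] = 1.0 if np.isinf(num) else 0.0
        else:
            lof[i] = num / lrd[i]
    return lof


def fisher_oracle(table) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration.

    Enumerates every table with the observed margins and sums the
    probabilities of those no more probable than the observed table.
    """
    (a, b), (c, d) = np.asarray(table, dtype=int)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):  # P(top-left cell = x | margins)
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = prob(a)
    return float(sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-12)))


def feature_oracle(a_mag, w_mag, gyro, rate_hz) -> list[float]:
    """Straight-loop re-derivation of the 13 window features."""
    def stats(track):
        track = list(map(float, track))
        L = len(track)
        mean = sum(track) / L
        std = (sum((v - mean) ** 2 for v in track) / L) ** 0.5
        energy = sum(v * v for v in track) / L
        crossings = 0
        for i in range(L - 1):
            if (track[i] - mean) * (track[i + 1] - mean) < 0:
                crossings += 1
        return [mean, std, energy, crossings / (L - 1), max(track), min(track)]

    dt = 1.0 / rate_hz
    ix = sum(row[0] for row in gyro) * dt
    iz = sum(row[2] for row in gyro) * dt
    return stats(a_mag) + stats(w_mag) + [(ix * ix + iz * iz) ** 0.5]
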