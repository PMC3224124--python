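"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's code paths: exact rational
arithmetic for the pairwise count test, direct enumeration for diagonal
detection, and a textbook UPGMA loop for clustering.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def ac_exact_p(x: int, y: int, n1: int, n2: int) -> float:
    """Exact two-sided conditional-test p-value in rational arithmetic."""
    r = Fraction(n2, n1)
    one_plus_r = 1 + r

    def pmf(k: int) -> Fraction:
        return r**k * comb(x + k, k) / one_plus_r ** (x + k + 1)

    lower = sum(pmf(k) for k in range(y + 1))
    upper = 1 - sum(pmf(k) for k in range(y))
    return float(min(Fraction(1), 2 * min(lower, upper)))


def brute_force_diagonals(cells: np.ndarray, min_run: int, max_gap: int,
                          seed_mask: np.ndarray | None = None):
    """Enumerate maximal gap-tolerant diagonal runs by direct scanning.

    Returns a set of (start_i, start_j, length, n_matched) tuples.  A run is
    a maximal chain of matched cells along one diagonal whose consecutive
    matches are separated by at most ``max_gap`` non-matches; runs start and
    end on seed-eligible matches, and weak (non-seed) matches may neither
    open a chain nor survive at its tail.
    """
    cells = np.asarray(cells, dtype=bool)
    seed = cells if seed_mask is None else (cells & np.asarray(seed_mask, dtype=bool))
    n_a, n_b = cells.shape
    found = set()
    for d in range(-(n_a - 1), n_b):
        i_vals = [i for i in range(n_a) if 0 <= i + d < n_b]
        matches = [i for i in i_vals if cells[i, i + d]]
        # chain matches greedily from each seed not already absorbed
        used_until = -1
        for start in matches:
            if start <= used_until or not seed[start, start + d]:
                continue
            chain = [start]
            for m in matches:
                if m > chain[-1] and m - chain[-1] - 1 <= max_gap:
                    chain.append(m)
            while chain and not seed[chain[-1], chain[-1] + d]:
                chain.pop()
            end = chain[-1]
            if len(chain) >= min_run:
                found.add((start, start + d, end - start + 1, len(chain)))
            used_until = end
    return found


def brute_force_upgma(dist: np.ndarray) -> list[float]:
    """Textbook UPGMA; returns the sorted list of n-1 merge heights."""
    D = np.asarray(dist, dtype=float).copy()
    n = D.shape[0]
    clusters = {i: [i] for i in range(n)}
    heights = []
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                a, b = keys[ai], keys[bi]
                d = float(np.mean([D[i, j] for i in clusters[a] for j in clusters[b]]))
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[min(a, b)] = clusters.pop(a) + clusters.pop(b)
    return sorted(heights)


def pooled_frequency(counts: list[int], sizes: list[int]) -> float:
    """Per-10k frequency of pooled counts (weighted-mean cross-check)."""
    return 10_000.0 * sum(counts) / sum(sizes)
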