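"""Independent brute-force oracles used to validate the fast implementations.

Each oracle restates the defining rule of an operation in the most literal way
possible (explicit loops, breadth-first path searches, exhaustive candidate
scans) and shares no code with the implementation it checks.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def huang_threshold_bruteforce(histogram) -> int:
    """Exhaustive Huang fuzzy-entropy minimization over every candidate threshold."""
    h = np.asarray(histogram, dtype=float)
    occ = np.flatnonzero(h > 0)
    first, last = int(occ[0]), int(occ[-1])
    c = float(last - first)
    costs: dict[int, float] = {}
    for t in range(first, last):
        w0 = h[: t + 1].sum()
        s0 = (h[: t + 1] * np.arange(t + 1)).sum()
        w1 = h[t + 1 :].sum()
        s1 = (h[t + 1 :] * np.arange(t + 1, h.size)).sum()
        mu0, mu1 = s0 / w0, s1 / w1
        cost = 0.0
        for g in range(h.size):
            if h[g] == 0:
                continue
            mu = mu0 if g <= t else mu1
            u = 1.0 / (1.0 + abs(g - mu) / c)
            if u < 1.0:
                cost += h[g] * (-u * math.log(u) - (1 - u) * math.log(1 - u))
        costs[t] = cost
    minimum = min(costs.values())
    tied = [t for t, v in costs.items() if v == minimum]
    return tied[len(tied) // 2]


def maxima_bruteforce(img: np.ndarray, mask: np.ndarray, prominence: float):
    """Accepted local maxima by literal path search.

    A regional-maximum plateau at value v is accepted iff (a) no strictly
    higher pixel can be reached from it through pixels >= v - prominence
    (8-connected, inside the mask), and (b) v exceeds the minimum of its mask
    component by more than the prominence. Returns sorted plateau centroids.
    """
    h, w = img.shape

    def nbrs(r, c):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and mask[rr, cc]:
                    yield rr, cc

    seen = np.zeros(img.shape, bool)
    plateaus = []
    for r in range(h):
        for c in range(w):
            if not mask[r, c] or seen[r, c]:
                continue
            v = img[r, c]
            plat = [(r, c)]
            seen[r, c] = True
            queue = deque([(r, c)])
            is_max = True
            while queue:
                pr, pc = queue.popleft()
                for rr, cc in nbrs(pr, pc):
                    if img[rr, cc] > v:
                        is_max = False
                    if img[rr, cc] == v and not seen[rr, cc]:
                        seen[rr, cc] = True
                        plat.append((rr, cc))
                        queue.append((rr, cc))
            if is_max:
                plateaus.append((v, plat))

    accepted = []
    for v, plat in plateaus:
        level = v - prominence
        queue = deque([plat[0]])
        visited = {plat[0]}
        reaches_higher = False
        while queue:
            pr, pc = queue.popleft()
            for rr, cc in nbrs(pr, pc):
                if (rr, cc) in visited or img[rr, cc] < level:
                    continue
                if img[rr, cc] > v:
                    reaches_higher = True
                visited.add((rr, cc))
                queue.append((rr, cc))
        if reaches_higher:
            continue
        queue = deque([plat[0]])
        comp = {plat[0]}
        comp_min = v
        while queue:
            pr, pc = queue.popleft()
            for rr, cc in nbrs(pr, pc):
                if (rr, cc) in comp:
                    continue
                comp_min = min(comp_min, img[rr, cc])
                comp.add((rr, cc))
                queue.append((rr, cc))
        if v - comp_min > prominence:
            rows = [p[0] for p in plat]
            cols = [p[1] for p in plat]
            accepted.append(
                (round(sum(rows) / len(rows), 9), round(sum(cols) / len(cols), 9))
            )
    return sorted(accepted)


def nearest_neighbour_bruteforce(points_a, points_b):
    """All-pairs O(n^2) nearest neighbour: (distance, index) per A point.

    Ties break toward the lowest B index; empty B gives (None, None).
    """
    out = []
    for pa in points_a:
        best_d, best_j = None, None
        for j, pb in enumerate(points_b):
            d = math.hypot(pa[0] - pb[0], pa[1] - pb[1])
            if best_d is None or d < best_d:
                best_d, best_j = d, j
        out.append((best_d, best_j))
    return out
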