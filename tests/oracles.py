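"""Independent reference implementations used only to cross-check the package.

These deliberately avoid the package's vectorized code paths: costs are
recomputed from raw slices with Python arithmetic, merging uses union-find
over the pairwise relation, and Venn tallies come from per-element membership
enumeration.
"""

from __future__ import annotations

import math


def poisson_cost_naive(seg) -> float:
    s = float(sum(seg))
    n = len(seg)
    if s <= 0:
        return 0.0
    return s - s * math.log(s / n)


def changepoints_naive(v, min_fold=0.8, min_segment_len=100, max_isoform=20,
                       split_penalty_factor=2.0) -> list[int]:
    """Exhaustive-search binary segmentation over a Python list.

    Returns the accepted split positions plus the extinction end, sorted.
    """
    v = list(float(x) for x in v)
    while v and v[-1] == 0:
        v.pop()
    if not v or sum(v) == 0:
        return []
    n = len(v)
    penalty = split_penalty_factor * math.log(n)
    splits: list[int] = []

    def rec(lo: int, hi: int) -> None:
        if len(splits) + 1 >= max_isoform:
            return
        best_cost, best_s = None, None
        for s in range(lo + min_segment_len, hi - min_segment_len + 1):
            c = poisson_cost_naive(v[lo:s]) + poisson_cost_naive(v[s:hi])
            if best_cost is None or c < best_cost - 1e-9:
                best_cost, best_s = c, s
            elif abs(c - best_cost) <= 1e-9:
                best_s = s  # ties resolved toward the most downstream position
        if best_s is None:
            return
        m1 = sum(v[lo:best_s]) / (best_s - lo)
        m2 = sum(v[best_s:hi]) / (hi - best_s)
        if m1 <= 0 or m2 >= m1 or m2 / m1 > min_fold:
            return
        gain = poisson_cost_naive(v[lo:hi]) - best_cost
        if gain <= penalty:
            return
        splits.append(best_s)
        rec(lo, best_s)
        rec(best_s, hi)

    rec(0, n)
    return sorted(splits) + [n]


def merge_naive(ends, window=100) -> list[tuple[int, ...]]:
    """Union-find over the pairwise |a-b| < window relation; returns sorted clusters."""
    ends = sorted(ends)
    parent = list(range(len(ends)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(ends)):
        for j in range(i + 1, len(ends)):
            if abs(ends[i] - ends[j]) < window:
                parent[find(i)] = find(j)
    clusters: dict[int, list[int]] = {}
    for i, e in enumerate(ends):
        clusters.setdefault(find(i), []).append(e)
    return sorted(tuple(sorted(c)) for c in clusters.values())


def hexamer_scan_naive(seq: str, hexamers) -> list[tuple[str, int]]:
    """Per-position sliding-window scan."""
    seq = seq.upper()
    hits = []
    for i in range(len(seq) - 5):
        window = seq[i : i + 6]
        for h in hexamers:
            if window == h:
                hits.append((h, i + 1))
    return sorted(hits, key=lambda x: (x[1], x[0]))


def nested_coverage(ends, abundances, depth0=10.0):
    """Noiseless nested-isoform coverage: depth at p = depth0 * sum of covering abundances."""
    out = []
    for p in range(1, max(ends) + 1):
        out.append(depth0 * sum(a for e, a in zip(ends, abundances) if e >= p))
    return out


def venn_naive(sets: dict):
    """Membership-pattern tallies by element-wise enumeration."""
    union = set().union(*sets.values())
    tally: dict[tuple[str, ...], int] = {}
    for x in union:
        key = tuple(name for name in sets if x in sets[name])
        tally[key] = tally.get(key, 0) + 1
    return tally
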