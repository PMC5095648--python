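"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an operation's result by the most literal route
available (exhaustive scan, fraction arithmetic, subset enumeration) and is
kept free of the production code paths it checks.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations


def truncate_oracle(quals: list[int], q_threshold: int, nth_low: int) -> int:
    """Kept prefix length by literal enumeration of low-quality positions."""
    low_positions = [i for i, q in enumerate(quals) if q < q_threshold]
    if len(low_positions) < nth_low:
        return len(quals)
    return low_positions[nth_low - 1]


def ambiguity_oracle(best: int, second: int) -> bool:
    """Literal rule with exact rational arithmetic: second > 95% (90%) of best."""
    threshold = Fraction(9, 10) if best < 100 else Fraction(19, 20)
    return Fraction(second) > threshold * Fraction(best)


def interval_distance(start: int, end: int, pos: int) -> int:
    """Distance of a point to a half-open interval, by cases."""
    if pos < start:
        return start - pos
    if pos >= end:
        return pos - (end - 1)
    return 0


def nearest_scan(intervals: list[tuple[int, int]], pos: int):
    """(min distance, indices at that distance) by full linear scan."""
    dists = [interval_distance(s, e, pos) for s, e in intervals]
    best = min(dists)
    return best, [i for i, d in enumerate(dists) if d == best]


def overlap_scan(intervals: list[tuple[int, int]], pos: int) -> list[int]:
    return [i for i, (s, e) in enumerate(intervals) if s <= pos < e]


def chunk_sizes_oracle(n: int, n_bins: int) -> list[int]:
    """Equal-split sizes with larger chunks first (independent formulation)."""
    out = []
    remaining, bins_left = n, n_bins
    for _ in range(n_bins):
        size = -(-remaining // bins_left)  # ceil
        out.append(size)
        remaining -= size
        bins_left -= 1
    return out


def hotspot_count_exhaustive_windows(
    positions: list[int], window: int, min_sites: int
) -> int:
    """Max number of disjoint qualifying site-anchored windows, by DP recursion.

    A window anchored at site i covers every site in [p_i, p_i + window]
    (inclusive) and qualifies when it covers >= min_sites sites. Windows are
    disjoint (no shared sites). Independent of the production greedy scan.
    """
    pos = sorted(positions)
    n = len(pos)
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def best(i: int) -> int:
        if i >= n:
            return 0
        j = i
        while j + 1 < n and pos[j + 1] <= pos[i] + window:
            j += 1
        covered = j - i + 1
        take = 1 + best(j + 1) if covered >= min_sites else 0
        return max(best(i + 1), take)

    for i in range(n, -1, -1):  # fill the memo right-to-left, depth stays O(1)
        best(i)
    return best(0)


def hotspot_count_all_anchor_subsets(
    positions: list[int], window: int, min_sites: int
) -> int:
    """Truly exhaustive check over every subset of anchors (tiny n only)."""
    pos = sorted(positions)
    n = len(pos)
    covers = []
    for i in range(n):
        members = frozenset(j for j in range(n) if pos[i] <= pos[j] <= pos[i] + window)
        if len(members) >= min_sites:
            covers.append(members)
    best = 0
    for r in range(1, len(covers) + 1):
        for combo in combinations(covers, r):
            union = set()
            total = 0
            ok = True
            for c in combo:
                if union & c:
                    ok = False
                    break
                union |= c
                total += 1
            if ok:
                best = max(best, total)
    return best


def chisq_closed_form(observed: list[int], props: list[float]) -> float:
    total = sum(observed)
    return sum(
        (o - total * p) ** 2 / (total * p) for o, p in zip(observed, props)
    )
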