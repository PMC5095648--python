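"""Integration hotspot detection on matched-size site subsets.

A hotspot is a genomic window of fixed width (5 kb or 50 kb here) holding at
least ``min_sites`` integration sites. To compare vectors with different
total site yields, each data set is first split into non-overlapping,
randomly drawn subsets of identical size (e.g. 320 or 511 sites) and the
hotspot count is reported as mean ± SEM over subsets.

Candidate windows are anchored at site positions (left edge on a site) and
inclusive: a site at ``anchor + window_bp`` still belongs to the window.
The greedy scan walks sites left to right, opens a window at each site not
yet consumed by an emitted hotspot, and emits when the window holds
``min_sites`` or more — sites of sub-threshold windows stay available as
later anchors. Under this anchoring the greedy count equals the maximum
number of disjoint qualifying windows (earliest-feasible-anchor exchange
argument), which ``count_hotspots(..., method="exhaustive")`` computes
independently by dynamic programming over anchor choices.

Hotspots never span chromosomes and strand is ignored.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np

from .annotate import _FeatureArrays
from .reference import Peak
from .sites import IntegrationSite


def partition_matched_subsets(
    sites: Sequence[IntegrationSite],
    k: int,
    min_subsets: int = 3,
    seed: int | np.random.Generator = 0,
) -> list[list[IntegrationSite]]:
    """Split sites into ``floor(N/k)`` disjoint random subsets of exactly ``k``.

    Leftover sites are unused. Raises when fewer than ``min_subsets`` full
    subsets can be formed.
    """
    n = len(sites)
    n_subsets = n // k
    if n_subsets < min_subsets:
        raise ValueError(
            f"{n} sites yield only {n_subsets} subsets of {k}; "
            f"at least {min_subsets * k} sites required"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = rng.permutation(n)
    return [
        [sites[j] for j in order[i * k:(i + 1) * k]] for i in range(n_subsets)
    ]


def _sorted_positions_by_chrom(
    sites: Sequence[IntegrationSite],
) -> dict[str, list[IntegrationSite]]:
    by_chrom: dict[str, list[IntegrationSite]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s)
    for v in by_chrom.values():
        v.sort(key=lambda s: (s.position, s.strand))
    return by_chrom


def _greedy_chrom(positions: list[int], window_bp: int, min_sites: int) -> list[tuple[int, int]]:
    """Emitted hotspots on one chromosome as (start_idx, end_idx) inclusive."""
    spans = []
    n = len(positions)
    i = 0
    while i < n:
        j = bisect.bisect_right(positions, positions[i] + window_bp) - 1
        if j - i + 1 >= min_sites:
            spans.append((i, j))
            i = j + 1
        else:
            i += 1
    return spans


def _exhaustive_chrom(positions: list[int], window_bp: int, min_sites: int) -> int:
    """Maximum number of disjoint qualifying anchored windows (DP, backwards)."""
    n = len(positions)
    best = [0] * (n + 1)
    for i in range(n - 1, -1, -1):
        j = bisect.bisect_right(positions, positions[i] + window_bp) - 1
        take = 1 + best[j + 1] if j - i + 1 >= min_sites else 0
        best[i] = max(best[i + 1], take)
    return best[0]


def count_hotspots(
    sites: Sequence[IntegrationSite],
    window_bp: int,
    min_sites: int = 3,
    method: str = "greedy",
) -> tuple[int, list[list[IntegrationSite]]]:
    """Count hotspots in one subset; returns (count, member lists).

    ``method="greedy"`` is the production single-pass scan;
    ``method="exhaustive"`` recomputes the count as a maximization over all
    disjoint anchored-window placements (members are not reconstructed).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    by_chrom = _sorted_positions_by_chrom(sites)
    if method == "exhaustive":
        count = sum(
            _exhaustive_chrom([s.position for s in v], window_bp, min_sites)
            for v in by_chrom.values()
        )
        return count, []
    if method != "greedy":
        raise ValueError(f"unknown method {method!r}")
    members: list[list[IntegrationSite]] = []
    for chrom in sorted(by_chrom):
        chrom_sites = by_chrom[chrom]
        positions = [s.position for s in chrom_sites]
        for i, j in _greedy_chrom(positions, window_bp, min_sites):
            members.append(chrom_sites[i:j + 1])
    return len(members), members


def hotspot_peak_proximity(
    members: Sequence[IntegrationSite],
    peaks: Sequence[Peak],
    near_kb: float = 50,
) -> tuple[int, float]:
    """(count, fraction) of hotspot member sites within ``near_kb`` of a peak."""
    if not members:
        return 0, 0.0
    arrays = _FeatureArrays(p.interval for p in peaks)
    near = 0
    by_chrom: dict[str, list[int]] = {}
    for s in members:
        by_chrom.setdefault(s.chrom, []).append(s.position)
    for chrom, pos in by_chrom.items():
        d = arrays.distances(chrom, np.array(pos, dtype=np.int64))
        near += int(np.sum(d <= near_kb * 1000))
    return near, near / len(members)


@dataclass
class HotspotResult:
    """Mean ± SEM hotspot counts over matched subsets for one window width."""

    window_bp: int
    subset_size: int
    n_subsets: int
    per_subset_counts: list[int]
    mean: float
    sem: float
    member_sites: list[IntegrationSite] = field(default_factory=list)
    near_peak_count: int | None = None
    near_peak_fraction: float | None = None


def hotspot_analysis(
    sites: Sequence[IntegrationSite],
    k: int,
    window_bp: int,
    min_sites: int = 3,
    min_subsets: int = 3,
    seed: int | np.random.Generator = 0,
    peaks: Sequence[Peak] | None = None,
    near_kb: float = 50,
) -> HotspotResult:
    """Partition into matched subsets, count hotspots per subset, summarize."""
    subsets = partition_matched_subsets(sites, k, min_subsets, seed)
    counts = []
    all_members: list[IntegrationSite] = []
    for subset in subsets:
        c, members = count_hotspots(subset, window_bp, min_sites)
        counts.append(c)
        for m in members:
            all_members.extend(m)
    arr = np.array(counts, dtype=float)
    sem = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
    result = HotspotResult(
        window_bp=window_bp,
        subset_size=k,
        n_subsets=len(subsets),
        per_subset_counts=counts,
        mean=float(arr.mean()),
        sem=sem,
        member_sites=all_members,
    )
    if peaks is not None:
        count, frac = hotspot_peak_proximity(all_members, peaks, near_kb)
        result.near_peak_count = count
        result.near_peak_fraction = frac
    return result


def write_hotspot_tsv(results: Sequence[HotspotResult], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "#window_bp\tsubset_size\tn_subsets\tper_subset_counts\tmean\tsem"
            "\tmembers_near_peak\tmembers_near_peak_frac\n"
        )
        for r in results:
            near = "NA" if r.near_peak_count is None else str(r.near_peak_count)
            frac = "NA" if r.near_peak_fraction is None else f"{r.near_peak_fraction:.4f}"
            fh.write(
                f"{r.window_bp}\t{r.subset_size}\t{r.n_subsets}\t"
                f"{','.join(map(str, r.per_subset_counts))}\t{r.mean:.3f}\t"
                f"{r.sem:.3f}\t{near}\t{frac}\n"
            )
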