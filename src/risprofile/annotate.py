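"""Per-site genomic feature annotation and profile summaries.

Each called integration site (a single junction base) is scored against
every feature class: RefSeq-style transcripts, TSS proximity, CpG islands,
repeat classes, centromeres, proto-oncogene transcripts/TSSs, and scored
ChIP-seq peak sets binned into strength deciles.

Distance conventions
--------------------
"within X kb" of a peak (proximity analyses) is inclusive: distance <= X kb.
"<X kb" (summary-table headers, e.g. TSS and oncogene columns) is strict.
Distance to an interval is 0 inside, else the base-step gap to the nearest
contained base. TSS distance is unsigned.

All per-chromosome feature queries are vectorized: features are sorted by
start with a running maximum of ends, so the nearest distance for a batch
of positions is exact (identical to an exhaustive scan) at O(log F) per
site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .reference import (
    GenomicInterval,
    Peak,
    ReferenceBundle,
    REPEAT_CLASSES,
)
from .sites import IntegrationSite

# repeat class priority when a junction base sits in overlapping repeats
_REPEAT_PRIORITY = ("Satellite", "LINE", "SINE", "LTR", "DNA", "Other")

DEFAULT_TSS_BINS_KB = (0.0, 10.0, 50.0, 100.0, 500.0, math.inf)
DEFAULT_CPG_BINS_KB = (0.0, 1.0, 10.0, 50.0, 100.0, math.inf)


def assign_strength_bins(
    peaks: Sequence[Peak], n_bins: int = 10, larger_bins_low: bool = True
) -> list[Peak]:
    """Sort peaks by strength and split into ``n_bins`` equal-size bins.

    Bin 1 holds the lowest-scoring peaks, bin ``n_bins`` the strongest.
    When the count does not divide evenly the extra peaks go to the lowest
    bins (default), keeping the strongest bin a conservative, never-inflated
    set. Strength ties at bin boundaries are broken by genomic order after
    sorting by (strength, chrom, start).
    """
    if len(peaks) < n_bins:
        raise ValueError(
            f"need at least {n_bins} peaks to form {n_bins} bins, got {len(peaks)}"
        )
    ordered = sorted(
        peaks,
        key=lambda p: (p.strength, p.interval.chrom, p.interval.start, p.interval.end),
    )
    n = len(ordered)
    base, extra = divmod(n, n_bins)
    sizes = [base + 1] * extra + [base] * (n_bins - extra)
    if not larger_bins_low:
        sizes.reverse()
    out: list[Peak] = []
    i = 0
    for b, size in enumerate(sizes, start=1):
        out.extend(replace(p, bin=b) for p in ordered[i:i + size])
        i += size
    return out


# ---------------------------------------------------------------------------
# vectorized per-chromosome feature geometry


class _FeatureArrays:
    """Per-chromosome (sorted starts, running max end) arrays for intervals."""

    def __init__(self, intervals: Iterable[GenomicInterval]) -> None:
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, pairs in per_chrom.items():
            pairs.sort()
            starts = np.array([s for s, _ in pairs], dtype=np.int64)
            maxend = np.maximum.accumulate(
                np.array([e for _, e in pairs], dtype=np.int64)
            )
            self._chrom[chrom] = (starts, maxend)

    def __bool__(self) -> bool:
        return bool(self._chrom)

    def distances(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Exact nearest-interval distance per position; inf when no feature."""
        out = np.full(positions.shape, np.inf)
        entry = self._chrom.get(chrom)
        if entry is None:
            return out
        starts, maxend = entry
        idx = np.searchsorted(starts, positions, side="right")
        has_left = idx > 0
        left = np.full(positions.shape, np.inf)
        li = np.clip(idx - 1, 0, None)
        left[has_left] = np.maximum(
            positions[has_left] - maxend[li[has_left]] + 1, 0
        )
        right = np.full(positions.shape, np.inf)
        has_right = idx < len(starts)
        ri = np.clip(idx, None, len(starts) - 1)
        right[has_right] = starts[ri[has_right]] - positions[has_right]
        return np.minimum(left, right)


class _PointArrays:
    """Per-chromosome sorted point sets (TSS positions)."""

    def __init__(self, points: Iterable[tuple[str, int]]) -> None:
        per_chrom: dict[str, list[int]] = {}
        for chrom, pos in points:
            per_chrom.setdefault(chrom, []).append(pos)
        self._chrom = {
            c: np.array(sorted(v), dtype=np.int64) for c, v in per_chrom.items()
        }

    def __bool__(self) -> bool:
        return bool(self._chrom)

    def distances(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        out = np.full(positions.shape, np.inf)
        pts = self._chrom.get(chrom)
        if pts is None or len(pts) == 0:
            return out
        idx = np.searchsorted(pts, positions)
        left = np.full(positions.shape, np.inf)
        has_left = idx > 0
        left[has_left] = np.abs(positions[has_left] - pts[np.clip(idx - 1, 0, None)[has_left]])
        right = np.full(positions.shape, np.inf)
        has_right = idx < len(pts)
        right[has_right] = np.abs(pts[np.clip(idx, None, len(pts) - 1)[has_right]] - positions[has_right])
        return np.minimum(left, right)


# ---------------------------------------------------------------------------
# annotations


@dataclass
class PeakRelation:
    """Site-to-peak geometry for one mark, per strength bin and headline subset."""

    dist_by_bin: dict[int, float]          # inf when the bin has no peak on any chrom
    in_peak: bool                           # within a peak of the headline bin subset
    near_peak: bool                         # within near_kb of a headline-subset peak
    dist: float                             # distance to nearest headline-subset peak


@dataclass
class SiteAnnotation:
    """All feature relations for one integration site."""

    site: IntegrationSite
    in_gene: bool
    dist_tss: float
    dist_cpg: float
    in_or_near_cpg: bool
    repeat_class: str | None
    dist_centromere: float
    near_centromere: bool
    dist_oncogene_tss: float
    in_oncogene_transcript: bool
    peaks: dict[str, PeakRelation] = field(default_factory=dict)


class Annotator:
    """Annotates batches of sites against a :class:`ReferenceBundle`.

    Thresholds (defaults are the analysis' standard rule set):

    - ``near_kb`` (50): inclusive peak-proximity window, kb
    - ``tss_kb`` (10): strict "<10 kb from TSS" cut
    - ``cpg_kb`` (1): inclusive "within or less than 1 kb from a CpG island"
    - ``centromere_mb`` (1): strict "<1 Mbp from centromere"
    - ``onco_kb`` ((50, 500)): strict oncogene-TSS cuts
    - ``peak_bins``: bins forming the headline "strong peaks" subset
      (default: the single strongest bin)
    - ``n_bins`` (10): decile count used when peak sets arrive unbinned
    """

    def __init__(
        self,
        reference: ReferenceBundle,
        near_kb: float = 50,
        tss_kb: float = 10,
        cpg_kb: float = 1,
        centromere_mb: float = 1,
        onco_kb: tuple[float, float] = (50, 500),
        peak_bins: Sequence[int] | None = None,
        n_bins: int = 10,
    ) -> None:
        self.reference = reference
        self.near_bp = near_kb * 1000
        self.tss_bp = tss_kb * 1000
        self.cpg_bp = cpg_kb * 1000
        self.centromere_bp = centromere_mb * 1_000_000
        self.onco_bp = tuple(kb * 1000 for kb in onco_kb)
        self.n_bins = n_bins

        genes = reference.genes
        self._genes = _FeatureArrays(g.interval for g in genes)
        self._tss = _PointArrays((g.interval.chrom, g.tss) for g in genes)
        onco = [g for g in genes if g.is_oncogene]
        self._onco = _FeatureArrays(g.interval for g in onco)
        self._onco_tss = _PointArrays((g.interval.chrom, g.tss) for g in onco)
        self._cpg = _FeatureArrays(reference.cpg_islands)
        self._centromeres = _FeatureArrays(reference.centromeres)
        self._repeats = {
            cls: _FeatureArrays(
                r.interval for r in reference.repeats if r.repeat_class == cls
            )
            for cls in _REPEAT_PRIORITY
        }

        self._peak_arrays: dict[str, dict[int, _FeatureArrays]] = {}
        self._headline_bins: dict[str, tuple[int, ...]] = {}
        for mark, peaks in reference.peak_sets.items():
            if peaks and all(p.bin is None for p in peaks):
                peaks = assign_strength_bins(peaks, n_bins=n_bins)
            elif any(p.bin is None for p in peaks):
                raise ValueError(f"peak set {mark!r} is only partially binned")
            bins = sorted({p.bin for p in peaks})
            self._peak_arrays[mark] = {
                b: _FeatureArrays(p.interval for p in peaks if p.bin == b)
                for b in bins
            }
            if peak_bins is None:
                self._headline_bins[mark] = (max(bins),)
            else:
                self._headline_bins[mark] = tuple(peak_bins)

    # -- core batch path ----------------------------------------------------

    def annotate(self, sites: Sequence[IntegrationSite]) -> list[SiteAnnotation]:
        for s in sites:
            if not self.reference.layout.has_chrom(s.chrom):
                raise ValueError(f"site chromosome {s.chrom!r} not in genome layout")
        annotations: list[SiteAnnotation | None] = [None] * len(sites)
        by_chrom: dict[str, list[int]] = {}
        for i, s in enumerate(sites):
            by_chrom.setdefault(s.chrom, []).append(i)
        for chrom, idxs in by_chrom.items():
            pos = np.array([sites[i].position for i in idxs], dtype=np.int64)
            d_gene = self._genes.distances(chrom, pos)
            d_tss = self._tss.distances(chrom, pos)
            d_onco = self._onco.distances(chrom, pos)
            d_onco_tss = self._onco_tss.distances(chrom, pos)
            d_cpg = self._cpg.distances(chrom, pos)
            d_cen = self._centromeres.distances(chrom, pos)
            d_rep = {
                cls: arr.distances(chrom, pos) for cls, arr in self._repeats.items()
            }
            d_peaks = {
                mark: {b: arr.distances(chrom, pos) for b, arr in by_bin.items()}
                for mark, by_bin in self._peak_arrays.items()
            }
            for k, i in enumerate(idxs):
                rep_cls = None
                for cls in _REPEAT_PRIORITY:
                    if d_rep[cls][k] == 0:
                        rep_cls = cls
                        break
                peaks: dict[str, PeakRelation] = {}
                for mark, by_bin in d_peaks.items():
                    dist_by_bin = {b: float(v[k]) for b, v in by_bin.items()}
                    head = [
                        dist_by_bin[b]
                        for b in self._headline_bins[mark]
                        if b in dist_by_bin
                    ]
                    d = min(head) if head else math.inf
                    peaks[mark] = PeakRelation(
                        dist_by_bin=dist_by_bin,
                        in_peak=bool(d == 0),
                        near_peak=bool(d <= self.near_bp),
                        dist=d,
                    )
                annotations[i] = SiteAnnotation(
                    site=sites[i],
                    in_gene=bool(d_gene[k] == 0),
                    dist_tss=float(d_tss[k]),
                    dist_cpg=float(d_cpg[k]),
                    in_or_near_cpg=bool(d_cpg[k] <= self.cpg_bp),
                    repeat_class=rep_cls,
                    dist_centromere=float(d_cen[k]),
                    near_centromere=bool(d_cen[k] < self.centromere_bp),
                    dist_oncogene_tss=float(d_onco_tss[k]),
                    in_oncogene_transcript=bool(d_onco[k] == 0),
                    peaks=peaks,
                )
        return annotations  # type: ignore[return-value]


def annotate_site(
    site: IntegrationSite, reference: ReferenceBundle, **thresholds
) -> SiteAnnotation:
    """Annotate a single site (convenience wrapper over :class:`Annotator`)."""
    return Annotator(reference, **thresholds).annotate([site])[0]


# ---------------------------------------------------------------------------
# profile summaries


@dataclass
class ProfileSummary:
    """Category counts/percentages for one site set.

    ``denominators`` records, per category, the site count the percentage is
    taken over: unique non-ambiguous sites for gene/TSS/CpG/oncogene/peak
    categories, unique sites *including* ambiguous ones for repeat and
    centromere categories (repeat placements are exactly what the ambiguous
    class contains).
    """

    counts: dict[str, int]
    denominators: dict[str, int]
    percentages: dict[str, float]
    n_unique: int
    n_unambiguous: int
    tss_histogram: tuple[tuple[float, ...], list[int]]
    cpg_histogram: tuple[tuple[float, ...], list[int]]

    def proportion(self, category: str) -> float:
        return self.counts[category] / self.denominators[category]


def _histogram(dists_kb: list[float], edges_kb: Sequence[float]) -> list[int]:
    counts = [0] * (len(edges_kb) - 1)
    for d in dists_kb:
        for j in range(len(edges_kb) - 1):
            if edges_kb[j] <= d < edges_kb[j + 1]:
                counts[j] += 1
                break
    return counts


def summarize_profile(
    annotations: Sequence[SiteAnnotation],
    tss_kb: float = 10,
    onco_kb: tuple[float, float] = (50, 500),
    near_kb: float = 50,
    tss_bins_kb: Sequence[float] = DEFAULT_TSS_BINS_KB,
    cpg_bins_kb: Sequence[float] = DEFAULT_CPG_BINS_KB,
) -> ProfileSummary:
    """Aggregate annotations into the standard summary-table categories."""
    if not annotations:
        raise ValueError("summarize_profile requires at least one annotation")
    all_ann = list(annotations)
    unamb = [a for a in all_ann if not a.site.ambiguous]
    n_all, n_unamb = len(all_ann), len(unamb)
    if n_unamb == 0:
        raise ValueError("no unambiguous sites: zero denominator for gene categories")

    counts: dict[str, int] = {}
    denominators: dict[str, int] = {}

    def add(category: str, value: int, denom: int) -> None:
        counts[category] = value
        denominators[category] = denom

    add("in_gene", int(sum(a.in_gene for a in unamb)), n_unamb)
    add("tss_lt_kb", sum(a.dist_tss < tss_kb * 1000 for a in unamb), n_unamb)
    add("cpg", sum(a.in_or_near_cpg for a in unamb), n_unamb)
    add("onco_lt_near_kb",
        sum(a.dist_oncogene_tss < onco_kb[0] * 1000 for a in unamb), n_unamb)
    add("onco_lt_far_kb",
        sum(a.dist_oncogene_tss < onco_kb[1] * 1000 for a in unamb), n_unamb)
    add("in_oncogene", sum(a.in_oncogene_transcript for a in unamb), n_unamb)
    add("centromere", sum(a.near_centromere for a in all_ann), n_all)
    for cls in _REPEAT_PRIORITY:
        add(f"repeat:{cls}", sum(a.repeat_class == cls for a in all_ann), n_all)
    marks = all_ann[0].peaks.keys()
    for mark in marks:
        add(f"in_peak:{mark}", sum(a.peaks[mark].in_peak for a in unamb), n_unamb)
        add(f"near_peak:{mark}", sum(a.peaks[mark].near_peak for a in unamb), n_unamb)
        bins = sorted(all_ann[0].peaks[mark].dist_by_bin)
        for b in bins:
            near = sum(
                a.peaks[mark].dist_by_bin[b] <= near_kb * 1000 for a in unamb
            )
            add(f"near_peak:{mark}:bin{b}", near, n_unamb)

    percentages = {
        k: 100.0 * counts[k] / denominators[k] for k in counts
    }
    return ProfileSummary(
        counts=counts,
        denominators=denominators,
        percentages=percentages,
        n_unique=n_all,
        n_unambiguous=n_unamb,
        tss_histogram=(
            tuple(tss_bins_kb),
            _histogram([a.dist_tss / 1000 for a in unamb], tss_bins_kb),
        ),
        cpg_histogram=(
            tuple(cpg_bins_kb),
            _histogram([a.dist_cpg / 1000 for a in unamb], cpg_bins_kb),
        ),
    )


# ---------------------------------------------------------------------------
# output writers (percentages printed to 1 decimal)


def write_annotations_tsv(
    annotations: Sequence[SiteAnnotation], path: str | Path
) -> None:
    marks = sorted(annotations[0].peaks) if annotations else []
    header = [
        "chrom", "pos0", "strand", "read_count", "ambiguous", "in_gene",
        "dist_tss", "dist_cpg", "cpg_le_cut", "repeat_class", "dist_centromere",
        "near_centromere", "dist_oncogene_tss", "in_oncogene",
    ] + [f"{m}_{f}" for m in marks for f in ("in_peak", "near_peak", "dist")]

    def fmt(v: float) -> str:
        return "NA" if math.isinf(v) else f"{int(v)}"

    with open(path, "w") as fh:
        fh.write("#" + "\t".join(header) + "\n")
        for a in annotations:
            s = a.site
            row = [
                s.chrom, str(s.position), s.strand, str(s.read_count),
                str(int(s.ambiguous)), str(int(a.in_gene)), fmt(a.dist_tss),
                fmt(a.dist_cpg), str(int(a.in_or_near_cpg)),
                a.repeat_class or "none", fmt(a.dist_centromere),
                str(int(a.near_centromere)), fmt(a.dist_oncogene_tss),
                str(int(a.in_oncogene_transcript)),
            ]
            for m in marks:
                rel = a.peaks[m]
                row += [str(int(rel.in_peak)), str(int(rel.near_peak)), fmt(rel.dist)]
            fh.write("\t".join(row) + "\n")


def write_summary_tsv(
    summaries: dict[str, ProfileSummary], path: str | Path
) -> None:
    """One row per sample; columns follow the summary-table layout."""
    if not summaries:
        raise ValueError("no summaries to write")
    first = next(iter(summaries.values()))
    categories = list(first.counts)
    with open(path, "w") as fh:
        fh.write("#sample\tn_unique\tn_unambiguous\t" + "\t".join(categories) + "\n")
        for sample, summ in summaries.items():
            row = [sample, str(summ.n_unique), str(summ.n_unambiguous)]
            row += [f"{summ.percentages[c]:.1f}" for c in categories]
            fh.write("\t".join(row) + "\n")


def write_histogram_tsv(summary: ProfileSummary, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#feature\tbin_lo_kb\tbin_hi_kb\tcount\n")
        for name, (edges, counts) in (
            ("TSS", summary.tss_histogram),
            ("CpG", summary.cpg_histogram),
        ):
            for j, c in enumerate(counts):
                hi = "inf" if math.isinf(edges[j + 1]) else f"{edges[j + 1]:g}"
                fh.write(f"{name}\t{edges[j]:g}\t{hi}\t{c}\n")
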