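"""Genome annotation inputs: coordinate types, parsers, and interval queries.

Everything downstream works in BED convention: 0-based, half-open
``[start, end)``. One-based inputs (SAM positions) are converted at the
parser boundary, never later.

Distance between a point ``p`` and an interval is 0 when the point lies
inside, otherwise the number of base steps to the nearest contained base:
``start - p`` to the left edge, ``p - (end - 1)`` past the right edge.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

REPEAT_CLASSES = ("LINE", "SINE", "LTR", "DNA", "Satellite")
STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval, 0-based half-open, optionally stranded/named."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end <= start ({self.chrom}:{self.start}-{self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand symbol {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def distance_to(self, pos: int) -> int:
        """Base-step distance from ``pos`` to this interval (0 if inside)."""
        if pos < self.start:
            return self.start - pos
        if pos >= self.end:
            return pos - (self.end - 1)
        return 0


@dataclass(frozen=True)
class Peak:
    """A scored interval (e.g. a ChIP-seq peak); ``bin`` set by decile binning."""

    interval: GenomicInterval
    strength: float
    bin: int | None = None

    def __post_init__(self) -> None:
        if self.strength < 0:
            raise ValueError("peak strength must be >= 0")
        if self.bin is not None and not 1 <= self.bin:
            raise ValueError("bin must be >= 1")


@dataclass(frozen=True)
class GeneModel:
    """One transcript with a strand-aware TSS and an oncogene flag."""

    name: str
    interval: GenomicInterval
    tss: int
    is_oncogene: bool = False

    def __post_init__(self) -> None:
        expected = (
            self.interval.start if self.interval.strand == "+" else self.interval.end - 1
        )
        if self.tss != expected:
            raise ValueError(
                f"TSS {self.tss} inconsistent with {self.interval.strand} strand "
                f"transcript {self.interval.start}-{self.interval.end}"
            )


@dataclass(frozen=True)
class RepeatFeature:
    interval: GenomicInterval
    repeat_class: str

    def __post_init__(self) -> None:
        if self.repeat_class not in REPEAT_CLASSES + ("Other",):
            raise ValueError(f"unknown repeat class {self.repeat_class!r}")


@dataclass
class GenomeLayout:
    """Ordered chromosomes with lengths and an optional mappability mask.

    The mask lists *excluded* intervals; random-site sampling avoids them.
    """

    chroms: list[tuple[str, int]]
    mask: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in layout")
        for name, length in self.chroms:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        self.lengths = dict(self.chroms)
        for iv in self.mask:
            if iv.chrom not in self.lengths:
                raise ValueError(f"mask chromosome {iv.chrom} not in layout")

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chroms)

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self.lengths

    def mappable_segments(self) -> list[GenomicInterval]:
        """Complement of the mask, per chromosome, in layout order."""
        masked: dict[str, list[tuple[int, int]]] = {}
        for iv in self.mask:
            masked.setdefault(iv.chrom, []).append((iv.start, iv.end))
        out: list[GenomicInterval] = []
        for chrom, length in self.chroms:
            cursor = 0
            for s, e in sorted(masked.get(chrom, [])):
                s, e = max(0, s), min(length, e)
                if s > cursor:
                    out.append(GenomicInterval(chrom, cursor, s))
                cursor = max(cursor, e)
            if cursor < length:
                out.append(GenomicInterval(chrom, cursor, length))
        return out


@dataclass
class ReferenceBundle:
    """All annotation inputs for one genome build, validated against the layout."""

    layout: GenomeLayout
    genes: list[GeneModel] = field(default_factory=list)
    cpg_islands: list[GenomicInterval] = field(default_factory=list)
    repeats: list[RepeatFeature] = field(default_factory=list)
    centromeres: list[GenomicInterval] = field(default_factory=list)
    peak_sets: dict[str, list[Peak]] = field(default_factory=dict)
    oncogene_names: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        def check(chrom: str, what: str) -> None:
            if not self.layout.has_chrom(chrom):
                raise ValueError(f"{what} chromosome {chrom!r} not in genome layout")

        for g in self.genes:
            check(g.interval.chrom, f"gene {g.name}")
        for iv in self.cpg_islands:
            check(iv.chrom, "CpG island")
        for r in self.repeats:
            check(r.interval.chrom, "repeat")
        for iv in self.centromeres:
            check(iv.chrom, "centromere")
        for mark, peaks in self.peak_sets.items():
            for p in peaks:
                check(p.interval.chrom, f"{mark} peak")
        gene_names = {g.name for g in self.genes}
        self.unresolved_oncogenes = sorted(self.oncogene_names - gene_names)

    @property
    def satellites(self) -> list[RepeatFeature]:
        return [r for r in self.repeats if r.repeat_class == "Satellite"]


# ---------------------------------------------------------------------------
# parsers

_SKIP_PREFIXES = ("#", "track", "browser")


def _data_lines(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            yield lineno, line.split("\t")


def _parse_coords(fields: Sequence[str], path, lineno: int) -> tuple[str, int, int]:
    if len(fields) < 3:
        raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
    if end <= start:
        raise ValueError(f"{path}:{lineno}: end <= start ({start} >= {end})")
    return chrom, start, end


def read_bed(
    path: str | Path, has_score: bool = False, score_column: int = 5
) -> list[GenomicInterval] | list[Peak]:
    """Read BED3/BED5/BED6; with ``has_score`` return scored :class:`Peak` objects.

    ``score_column`` is 1-based (5 = BED score, 7 = narrowPeak signalValue).
    Comment, ``track`` and ``browser`` lines are skipped; order is preserved.
    """
    out: list = []
    for lineno, fields in _data_lines(path):
        chrom, start, end = _parse_coords(fields, path, lineno)
        name = fields[3] if len(fields) > 3 and fields[3] != "." else None
        strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
        iv = GenomicInterval(chrom, start, end, strand, name)
        if has_score:
            idx = score_column - 1
            if len(fields) <= idx:
                raise ValueError(f"{path}:{lineno}: missing score column {score_column}")
            out.append(Peak(iv, float(fields[idx])))
        else:
            out.append(iv)
    return out


def read_narrowpeak(path: str | Path, use_signal_value: bool = False) -> list[Peak]:
    """Read narrowPeak; strength from the score column (5) or signalValue (7)."""
    return read_bed(path, has_score=True, score_column=7 if use_signal_value else 5)


def read_chrom_sizes(path: str | Path) -> GenomeLayout:
    chroms = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected chrom<TAB>length")
        chroms.append((fields[0], int(fields[1])))
    return GenomeLayout(chroms)


def read_gene_list(path: str | Path) -> set[str]:
    """One gene symbol per line (e.g. a cancer-gene catalogue export)."""
    names = set()
    with open(path) as fh:
        for raw in fh:
            name = raw.strip()
            if name and not name.startswith("#"):
                names.add(name)
    return names


def read_gene_table(
    path: str | Path, oncogene_names: set[str] | None = None
) -> list[GeneModel]:
    """Read a refGene-style TSV (name, chrom, strand, txStart, txEnd, ...).

    txStart is already 0-based in UCSC tables. The TSS is the transcript
    start on '+' and ``txEnd - 1`` (last transcribed base, 0-based) on '-'.
    Duplicate transcript rows are kept as distinct models; the oncogene flag
    is a case-sensitive name match.
    """
    oncogene_names = oncogene_names or set()
    genes = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 5:
            raise ValueError(f"{path}:{lineno}: expected >=5 columns")
        name, chrom, strand = fields[0], fields[1], fields[2]
        if strand not in ("+", "-"):
            raise ValueError(f"{path}:{lineno}: unknown strand symbol {strand!r}")
        start, end = int(fields[3]), int(fields[4])
        iv = GenomicInterval(chrom, start, end, strand, name)
        tss = start if strand == "+" else end - 1
        genes.append(GeneModel(name, iv, tss, is_oncogene=name in oncogene_names))
    return genes


def read_repeat_table(path: str | Path) -> list[RepeatFeature]:
    """Read a repeat table: chrom, start, end, repClass columns.

    Classes outside {LINE, SINE, LTR, DNA, Satellite} (including compound
    names such as ``LINE/L1`` whose head is unknown) collapse to ``Other``.
    """
    repeats = []
    for lineno, fields in _data_lines(path):
        chrom, start, end = _parse_coords(fields, path, lineno)
        if len(fields) < 4:
            raise ValueError(f"{path}:{lineno}: missing repeat class column")
        head = fields[3].split("/")[0]
        cls = head if head in REPEAT_CLASSES else "Other"
        repeats.append(RepeatFeature(GenomicInterval(chrom, start, end), cls))
    return repeats


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name or "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# interval queries


def _get_interval(obj) -> GenomicInterval:
    return obj if isinstance(obj, GenomicInterval) else obj.interval


class IntervalIndex:
    """Overlap and nearest-feature queries over a fixed feature set.

    Per chromosome the features are held as numpy start/end arrays; queries
    evaluate the exact distance of every feature on the chromosome in one
    vectorized pass, so results are identical to an exhaustive scan by
    construction. Equidistant nearest features are all returned, ordered by
    (start, name); the caller breaks ties.
    """

    def __init__(self, features: Iterable) -> None:
        per_chrom: dict[str, list] = {}
        for f in features:
            per_chrom.setdefault(_get_interval(f).chrom, []).append(f)
        self._chrom: dict[str, tuple[np.ndarray, np.ndarray, list]] = {}
        for chrom, feats in per_chrom.items():
            feats.sort(key=lambda f: (_get_interval(f).start, _get_interval(f).end))
            starts = np.array([_get_interval(f).start for f in feats], dtype=np.int64)
            ends = np.array([_get_interval(f).end for f in feats], dtype=np.int64)
            self._chrom[chrom] = (starts, ends, feats)

    def __len__(self) -> int:
        return sum(len(v[2]) for v in self._chrom.values())

    def overlap(self, chrom: str, pos: int) -> list:
        """All features whose interval contains ``pos`` (empty if none)."""
        entry = self._chrom.get(chrom)
        if entry is None:
            return []
        starts, ends, feats = entry
        hit = np.flatnonzero((starts <= pos) & (pos < ends))
        return [feats[i] for i in hit]

    def nearest(self, chrom: str, pos: int) -> tuple[int | None, list]:
        """(distance, features at that distance); ``(None, [])`` off-index."""
        entry = self._chrom.get(chrom)
        if entry is None:
            return None, []
        starts, ends, feats = entry
        dist = np.maximum(np.maximum(starts - pos, pos - ends + 1), 0)
        best = int(dist.min())
        hit = np.flatnonzero(dist == best)
        winners = [feats[i] for i in hit]
        winners.sort(
            key=lambda f: (_get_interval(f).start, _get_interval(f).name or "")
        )
        return best, winners


class PointIndex:
    """Nearest-point queries (e.g. TSS positions) via binary search."""

    def __init__(self, points: Iterable[tuple[str, int]]) -> None:
        per_chrom: dict[str, list[int]] = {}
        for chrom, pos in points:
            per_chrom.setdefault(chrom, []).append(pos)
        self._chrom = {c: sorted(v) for c, v in per_chrom.items()}

    def nearest_distance(self, chrom: str, pos: int) -> int | None:
        pts = self._chrom.get(chrom)
        if not pts:
            return None
        i = bisect.bisect_left(pts, pos)
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(pts):
                d = abs(pts[j] - pos)
                best = d if best is None else min(best, d)
        return best


def build_interval_index(features: Iterable) -> IntervalIndex:
    """Build an :class:`IntervalIndex` over intervals or interval-bearing objects."""
    return IntervalIndex(features)
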