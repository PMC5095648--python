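"""Integration-site calling from scored alignments.

A read placing almost equally well at two genomic locations (typically a
repeat) cannot be assigned a unique integration site. The repeat-ambiguity
rule: a read is ambiguous when its second-best alignment score exceeds 95%
of the best score, relaxed to 90% when the best score is below 100.
Ambiguous sites are excluded from all downstream analyses except repeat and
centromere proximity, where repeat placements are the object of study.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .reads import AlignmentRecord


@dataclass(frozen=True)
class IntegrationSite:
    """A unique called RIS: junction coordinate plus supporting-read count."""

    chrom: str
    position: int
    strand: str
    read_count: int = 1
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.read_count < 1:
            raise ValueError("read_count must be >= 1")
        if self.position < 0:
            raise ValueError("position must be >= 0")


def classify_ambiguity(
    records: Sequence[AlignmentRecord],
    ratio: float = 0.95,
    low_score_ratio: float = 0.90,
    low_score_cutoff: float = 100,
) -> tuple[AlignmentRecord, bool]:
    """Pick the best placement for one read and flag repeat ambiguity.

    Ambiguous iff ``second > ratio * best`` (strict), with ``low_score_ratio``
    substituted when ``best < low_score_cutoff``. The comparison is done by
    exact cross-multiplication (``100*second > 95*best``) so that integer
    boundary cases — e.g. scores (200, 190), exactly 95% — are classified by
    the stated strict inequality rather than by floating-point rounding of
    ``0.95 * best``. Exactly tied top scores are ambiguous (ratio 1 > 0.95).
    """
    if not records:
        raise ValueError("classify_ambiguity requires at least one alignment record")
    ordered = sorted(records, key=lambda r: (-r.score, r.chrom, r.pos, r.strand))
    best = ordered[0]
    if len(ordered) == 1:
        return best, False
    second = ordered[1]
    r = low_score_ratio if best.score < low_score_cutoff else ratio
    # second > r * best, cross-multiplied with r as an exact percentage
    pct = round(r * 100)
    ambiguous = 100 * second.score > pct * best.score
    return best, ambiguous


def dedupe_sites(
    junctions: Iterable[tuple[str, int, str, bool]]
) -> list[IntegrationSite]:
    """Collapse identical (chrom, position, strand) junctions into unique sites.

    ``read_count`` is the number of collapsed junctions; the ambiguous flag is
    the majority vote of the collapsed records, ties counting as ambiguous.
    """
    groups: dict[tuple[str, int, str], list[bool]] = defaultdict(list)
    for chrom, pos, strand, amb in junctions:
        groups[(chrom, pos, strand)].append(bool(amb))
    sites = []
    for (chrom, pos, strand), flags in sorted(groups.items()):
        n_amb = sum(flags)
        sites.append(
            IntegrationSite(
                chrom, pos, strand,
                read_count=len(flags),
                ambiguous=2 * n_amb >= len(flags),
            )
        )
    return sites


def call_sites(
    records: Iterable[AlignmentRecord],
    ratio: float = 0.95,
    low_score_ratio: float = 0.90,
    low_score_cutoff: float = 100,
) -> list[IntegrationSite]:
    """Full calling step: group alignments per read, classify, deduplicate."""
    by_read: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for rec in records:
        by_read[rec.read_id].append(rec)
    junctions = []
    for read_records in by_read.values():
        best, amb = classify_ambiguity(
            read_records, ratio, low_score_ratio, low_score_cutoff
        )
        junctions.append((best.chrom, best.pos, best.strand, amb))
    return dedupe_sites(junctions)


# ---------------------------------------------------------------------------
# I/O


def read_alignment_tsv(path: str | Path) -> list[AlignmentRecord]:
    """Read alignment records: read_id, chrom, pos0, strand, score (TSV)."""
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns")
            records.append(
                AlignmentRecord(fields[0], fields[1], int(fields[2]),
                                fields[3], float(fields[4]))
            )
    return records


def write_alignment_tsv(records: Iterable[AlignmentRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#read_id\tchrom\tpos0\tstrand\tscore\n")
        for r in records:
            fh.write(f"{r.read_id}\t{r.chrom}\t{r.pos}\t{r.strand}\t{r.score:g}\n")


def read_alignment_sam(path: str | Path) -> list[AlignmentRecord]:
    """Read candidate placements from SAM; score from the AS tag.

    pysam's ``reference_start``/``reference_end`` are already 0-based
    half-open. The junction base is the read's 5' end on the genome: the
    leftmost aligned base for forward placements, the rightmost for reverse.
    """
    records = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            strand = "-" if aln.is_reverse else "+"
            pos = aln.reference_end - 1 if aln.is_reverse else aln.reference_start
            score = float(aln.get_tag("AS")) if aln.has_tag("AS") else float(
                aln.query_alignment_length
            )
            records.append(
                AlignmentRecord(aln.query_name, aln.reference_name, pos, strand, score)
            )
    return records


def write_sites_tsv(sites: Iterable[IntegrationSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tpos0\tstrand\tread_count\tambiguous\n")
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.position}\t{s.strand}\t{s.read_count}"
                f"\t{int(s.ambiguous)}\n"
            )


def read_sites_tsv(path: str | Path) -> list[IntegrationSite]:
    sites = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            chrom, pos, strand, count, amb = line.split("\t")[:5]
            sites.append(
                IntegrationSite(chrom, int(pos), strand, int(count), bool(int(amb)))
            )
    return sites


def write_sites_bed(sites: Iterable[IntegrationSite], path: str | Path) -> None:
    """BED6 with the read count in the score column."""
    with open(path, "w") as fh:
        for s in sites:
            name = "ambiguous" if s.ambiguous else "unique"
            fh.write(
                f"{s.chrom}\t{s.position}\t{s.position + 1}\t{name}"
                f"\t{s.read_count}\t{s.strand}\n"
            )
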