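"""Clonality: per-clone capture frequencies from junction-read counts.

Each unique integration site marks one cell clone; the fraction of all
captured junction reads attributed to that site (its capture frequency) is
the available proxy for clonal abundance. A population is polyclonal when
no clone dominates; clones at or above a reporting threshold (default 1%)
are listed individually.

Ambiguous (repeat-placed) sites are excluded from the denominator, so clone
counts for repeat-targeted vectors may be slightly underrepresented; the
report records how many sites were dropped for this reason.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .sites import IntegrationSite


@dataclass(frozen=True)
class CloneRecord:
    site: IntegrationSite
    frequency: float


@dataclass
class ClonalityReport:
    """Capture-frequency summary for one sample."""

    total_sites: int                 # unique unambiguous sites (clones)
    total_reads: int                 # reads over those sites
    n_ambiguous_excluded: int
    frequencies: list[CloneRecord]   # all clones, descending frequency
    flagged: list[CloneRecord]       # clones at/above the reporting threshold
    threshold: float

    @property
    def max_frequency(self) -> float:
        return self.frequencies[0].frequency if self.frequencies else 0.0


def capture_frequencies(
    sites: Sequence[IntegrationSite],
    threshold: float = 0.01,
    include_ambiguous: bool = False,
) -> ClonalityReport:
    """Compute per-site capture frequencies and flag clones >= ``threshold``.

    The threshold is inclusive: a clone at exactly 1.0% is reported.
    Frequencies sum to 1 over the retained sites.
    """
    kept = [s for s in sites if include_ambiguous or not s.ambiguous]
    n_excluded = len(sites) - len(kept)
    if not kept:
        raise ValueError("no sites left after ambiguity filtering")
    total_reads = sum(s.read_count for s in kept)
    records = [
        CloneRecord(s, s.read_count / total_reads) for s in kept
    ]
    records.sort(
        key=lambda r: (-r.frequency, r.site.chrom, r.site.position, r.site.strand)
    )
    flagged = [r for r in records if r.frequency >= threshold]
    return ClonalityReport(
        total_sites=len(kept),
        total_reads=total_reads,
        n_ambiguous_excluded=n_excluded,
        frequencies=records,
        flagged=flagged,
        threshold=threshold,
    )


def write_clonality_tsv(report: ClonalityReport, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"#total_sites={report.total_sites}\ttotal_reads={report.total_reads}"
            f"\tambiguous_excluded={report.n_ambiguous_excluded}"
            f"\tthreshold={report.threshold:g}\n"
        )
        fh.write("#chrom\tpos0\tstrand\tread_count\tfrequency\tflagged\n")
        for r in report.frequencies:
            s = r.site
            fh.write(
                f"{s.chrom}\t{s.position}\t{s.strand}\t{s.read_count}"
                f"\t{r.frequency:.6f}\t{int(r.frequency >= report.threshold)}\n"
            )
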