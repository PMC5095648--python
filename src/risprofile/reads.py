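"""Junction-read preprocessing: pair merging, quality truncation, naive placement.

The quality model is Sanger Phred: a base with quality Q has error
probability ``p = 10^(-Q/10)``, so Q < 27 means p >= 0.002. Reads are
truncated at the n-th low-quality base so that sequencing errors do not
poison the genome alignment of the vector-genome junction.

``naive_locate`` is a deliberately small seed-and-verify matcher for
synthetic references only; production alignments are consumed as input.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Read:
    """A sequencing read with per-base Phred qualities."""

    id: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.id}: {len(self.bases)} bases vs {len(self.quals)} quals"
            )
        if any(q < 0 for q in self.quals):
            raise ValueError(f"read {self.id}: negative quality score")

    def __len__(self) -> int:
        return len(self.bases)

    def reverse_complement(self) -> "Read":
        return Read(self.id, revcomp(self.bases), self.quals[::-1])


@dataclass(frozen=True)
class AlignmentRecord:
    """One candidate placement of a read; ``pos`` is the 0-based junction base."""

    read_id: str
    chrom: str
    pos: int
    strand: str
    score: float

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("alignment score must be >= 0")


def truncate_by_quality(read: Read, q_threshold: int = 27, nth_low: int = 3,
                        keep_trigger: bool = False) -> Read:
    """Truncate at the ``nth_low``-th base with Q below ``q_threshold``.

    Scanning 5'->3', the prefix strictly before the triggering base is kept
    (``keep_trigger`` retains the triggering base itself — the alternative
    reading of "truncated at"). Reads with fewer than ``nth_low`` low-quality
    bases are returned unchanged.
    """
    n_low = 0
    for i, q in enumerate(read.quals):
        if q < q_threshold:
            n_low += 1
            if n_low == nth_low:
                cut = i + 1 if keep_trigger else i
                return Read(read.id, read.bases[:cut], read.quals[:cut])
    return read


def merge_read_pair(forward: Read, reverse: Read, min_overlap: int = 10,
                    max_mismatch_rate: float = 0.1) -> Read | None:
    """Merge a read pair by best 3' overlap; ``None`` when no acceptable overlap.

    The reverse read is reverse-complemented, then every overlap length from
    ``min_overlap`` up is scored as matches minus mismatches; the best-scoring
    overlap (ties -> longest) with mismatch rate <= ``max_mismatch_rate``
    wins. In the overlap the base with higher quality is kept, with its
    quality; quality ties keep the forward base.
    """
    if len(forward) == 0 or len(reverse) == 0:
        raise ValueError("cannot merge an empty read")
    rc = reverse.reverse_complement()
    fb, rb = forward.bases, rc.bases
    best: tuple[int, int] | None = None  # (score, overlap_len)
    max_len = min(len(fb), len(rb))
    for L in range(max_len, min_overlap - 1, -1):
        f_tail = fb[len(fb) - L:]
        r_head = rb[:L]
        mismatches = sum(a != b for a, b in zip(f_tail, r_head))
        if mismatches / L > max_mismatch_rate:
            continue
        score = (L - mismatches) - mismatches
        if best is None or score > best[0]:
            best = (score, L)
    if best is None:
        return None
    L = best[1]
    off = len(fb) - L
    bases = list(fb[:off])
    quals = list(forward.quals[:off])
    for i in range(L):
        fq, rq = forward.quals[off + i], rc.quals[i]
        if rq > fq:
            bases.append(rb[i])
            quals.append(rq)
        else:
            bases.append(fb[off + i])
            quals.append(fq)
    bases += list(rb[L:])
    quals += list(rc.quals[L:])
    return Read(forward.id, "".join(bases), tuple(quals))


def trim_fixed(read: Read, prefix: str = "", suffix: str = "") -> Read | None:
    """Exact-match trim of a fixed vector/linker prefix and suffix.

    Returns ``None`` when a non-empty prefix/suffix does not match exactly,
    signalling that the read carries no recognisable junction structure.
    """
    bases, quals = read.bases, read.quals
    if prefix:
        if not bases.startswith(prefix):
            return None
        bases, quals = bases[len(prefix):], quals[len(prefix):]
    if suffix:
        if not bases.endswith(suffix):
            return None
        bases, quals = bases[: len(bases) - len(suffix)], quals[: len(quals) - len(suffix)]
    return Read(read.id, bases, quals)


def naive_locate(read: Read, reference: dict[str, str], min_score: int,
                 max_mismatches: int = 2, seed_length: int = 20) -> list[AlignmentRecord]:
    """Place a read on small reference sequences by exact-seed + Hamming verify.

    Both strands are searched; the score is the number of matching bases and
    placements with ``score >= min_score`` and at most ``max_mismatches``
    mismatches are returned sorted by descending score. The reported position
    is the junction base: the leftmost matched base on '+', the rightmost on
    '-' (the genomic base adjacent to the vector LTR under the convention
    that reads run 5'->3' away from the junction).
    """
    L = len(read)
    if L < seed_length:
        return []
    records: list[AlignmentRecord] = []
    for strand in ("+", "-"):
        query = read.bases if strand == "+" else revcomp(read.bases)
        # three seeds tolerate up to two mismatches anywhere in the read
        offsets = sorted({0, (L - seed_length) // 2, L - seed_length})
        for chrom, seq in reference.items():
            if L > len(seq):
                continue
            candidates: set[int] = set()
            for off in offsets:
                seed = query[off:off + seed_length]
                hit = seq.find(seed)
                while hit != -1:
                    start = hit - off
                    if 0 <= start <= len(seq) - L:
                        candidates.add(start)
                    hit = seq.find(seed, hit + 1)
            for start in candidates:
                window = seq[start:start + L]
                mismatches = sum(a != b for a, b in zip(query, window))
                score = L - mismatches
                if mismatches <= max_mismatches and score >= min_score:
                    pos = start if strand == "+" else start + L - 1
                    records.append(AlignmentRecord(read.id, chrom, pos, strand, score))
    records.sort(key=lambda r: (-r.score, r.chrom, r.pos, r.strand))
    return records


# ---------------------------------------------------------------------------
# FASTQ / FASTA I/O (Sanger Phred+33)


def read_fastq(path: str | Path) -> Iterator[Read]:
    for rec in SeqIO.parse(str(path), "fastq"):
        yield Read(rec.id, str(rec.seq).upper(),
                   tuple(rec.letter_annotations["phred_quality"]))


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.bases), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = list(r.quals)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
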