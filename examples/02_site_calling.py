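"""Call unique integration sites from scored candidate alignments.

A read placing almost equally well at two loci (a repeat) is ambiguous:
its second-best score exceeds 95% of the best (90% when the best score is
below 100). Ambiguous sites are kept, flagged, and later excluded from all
analyses except repeat/centromere proximity.
"""

from risprofile import AlignmentRecord, call_sites

records = [
    # read_a: unique placement
    AlignmentRecord("read_a", "chr1", 150_000, "+", 150),
    AlignmentRecord("read_a", "chr2", 900_000, "+", 80),
    # read_b: second-best 96% of best -> ambiguous
    AlignmentRecord("read_b", "chr1", 500_000, "+", 100),
    AlignmentRecord("read_b", "chr3", 200_000, "-", 96),
    # read_c: duplicate capture of read_a's site
    AlignmentRecord("read_c", "chr1", 150_000, "+", 148),
]

for site in call_sites(records):
    tag = "AMBIGUOUS" if site.ambiguous else "unique"
    print(f"{site.chrom}:{site.position} ({site.strand})  "
          f"reads={site.read_count}  {tag}")

# Two junctions at chr1:150000 collapse into one site with read_count 2;
# read_b's site carries the ambiguity flag from the 96% score ratio.
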