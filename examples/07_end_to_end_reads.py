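"""From raw junction read pairs to called sites on a sequence-level genome.

Simulates a small genome carrying one exact 2 kb duplication (a repeat
decoy), generates read pairs from known sites, and runs the full read-level
pipeline: merge -> quality-truncate -> place -> disambiguate -> deduplicate.
Reads from the duplicated segment tie between the two copies and are
flagged ambiguous.
"""

from risprofile import (
    IntegrationSite,
    ReferenceConfig,
    TetherModel,
    generate_reference,
    simulate_reads,
    simulate_sites,
)
from risprofile.pipeline import process_read_pairs

config = ReferenceConfig(
    n_chroms=2, chrom_length=1_000_000, n_genes=40, n_oncogenes=5, n_cpg=30,
    n_peaks=40, n_satellites_per_chrom=6, satellite_length=5_000,
    pericentromeric_halfwidth=60_000, centromere_halfwidth=10_000,
    gene_length_range=(2_000, 10_000), with_sequence=True, n_decoys=1,
)
reference = generate_reference(config, seed=8)
src, dst = reference.decoys[0]

sites, _ = simulate_sites(TetherModel(), reference, 30, seed=9, edge_margin=300)
sites = [s for s in sites
         if not (s.chrom == src.chrom and src.start - 200 <= s.position < src.end + 200)
         and not (s.chrom == dst.chrom and dst.start - 200 <= s.position < dst.end + 200)]
decoy_site = IntegrationSite(src.chrom, src.start + 500, "+", 1)

pairs, _ = simulate_reads(sites + [decoy_site], reference.sequences, seed=10)
called = process_read_pairs(pairs, reference.sequences, min_score=50)

truth = {(s.chrom, s.position, s.strand) for s in sites}
recovered = {(s.chrom, s.position, s.strand) for s in called if not s.ambiguous}
print(f"read pairs: {len(pairs)}")
print(f"unique truth sites recovered exactly: {len(truth & recovered)}/{len(truth)}")
print(f"ambiguous calls (decoy reads): {sum(s.ambiguous for s in called)}")

# All uniquely placeable sites come back at their exact coordinates; the one
# site inside the duplication is called but flagged ambiguous by the
# tied-score rule.
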