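import math

import numpy as np
import pytest

from oracles import chunk_sizes_oracle, interval_distance
from risprofile import (
    Annotator,
    GenomicInterval,
    IntegrationSite,
    Peak,
    annotate_site,
    assign_strength_bins,
    summarize_profile,
)


def peak(start, strength, chrom="chr1", length=100):
    return Peak(GenomicInterval(chrom, start, start + length), strength)


class TestStrengthBinning:
    def test_even_split_twenty_peaks(self, rng):
        peaks = [peak(i * 1000, float(s)) for i, s in enumerate(rng.permutation(20))]
        binned = assign_strength_bins(peaks, 10)
        sizes = [sum(p.bin == b for p in binned) for b in range(1, 11)]
        assert sizes == [2] * 10

    def test_extremes_land_in_outer_bins(self):
        peaks = [peak(i * 1000, float(i + 1)) for i in range(10)]
        binned = assign_strength_bins(peaks, 10)
        by_strength = {p.strength: p.bin for p in binned}
        assert by_strength[10.0] == 10 and by_strength[1.0] == 1

    def test_remainder_goes_to_low_bins(self, rng):
        peaks = [peak(i * 1000, float(s)) for i, s in enumerate(rng.permutation(25))]
        binned = assign_strength_bins(peaks, 10)
        sizes = [sum(p.bin == b for p in binned) for b in range(1, 11)]
        assert sizes == [3, 3, 3, 3, 3, 2, 2, 2, 2, 2]

    def test_too_few_peaks_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            assign_strength_bins([peak(0, 1.0)] * 5, 10)

    @pytest.mark.parametrize("n", [10, 57, 103, 1007])
    def test_matches_chunking_oracle_and_is_ordered(self, n, rng):
        peaks = [peak(int(p) * 10, float(s))
                 for p, s in zip(rng.permutation(n), rng.random(n) * 100)]
        binned = assign_strength_bins(peaks, 10)
        sizes = [sum(p.bin == b for p in binned) for b in range(1, 11)]
        assert sizes == chunk_sizes_oracle(n, 10)
        assert max(sizes) - min(sizes) <= 1
        means = [
            np.mean([p.strength for p in binned if p.bin == b]) for b in range(1, 11)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(means, means[1:]))


class TestAnnotateSite:
    def ann(self, bundle, chrom, pos, **kw):
        kw.setdefault("n_bins", 3)
        return annotate_site(IntegrationSite(chrom, pos, "+"), bundle, **kw)

    def test_site_inside_peak_is_in_and_near(self, tiny_bundle):
        a = self.ann(tiny_bundle, "chr1", 701_000)  # inside strongest peak
        rel = a.peaks["H3K9me3"]
        assert rel.in_peak and rel.near_peak and rel.dist == 0

    def test_near_peak_boundary_is_inclusive(self, tiny_bundle):
        # strongest peak chr1:700000-705000; site exactly 50 kb from its end
        a = self.ann(tiny_bundle, "chr1", 704_999 + 50_000)
        assert a.peaks["H3K9me3"].near_peak
        b = self.ann(tiny_bundle, "chr1", 704_999 + 50_001)
        assert not b.peaks["H3K9me3"].near_peak

    def test_tss_cut_is_strict(self, tiny_bundle):
        a = self.ann(tiny_bundle, "chr1", 100_000 - 9_999)
        b = self.ann(tiny_bundle, "chr1", 100_000 - 10_000)
        assert a.dist_tss == 9_999 and b.dist_tss == 10_000
        # strictness applied at summary time
        sa = summarize_profile([a])
        sb = summarize_profile([b])
        assert sa.counts["tss_lt_kb"] == 1 and sb.counts["tss_lt_kb"] == 0

    def test_cpg_window_is_inclusive(self, tiny_bundle):
        # CpG island chr1:99000-99500; 1 kb past the last base still counts
        a = self.ann(tiny_bundle, "chr1", 99_499 + 1_000)
        b = self.ann(tiny_bundle, "chr1", 99_499 + 1_001)
        assert a.in_or_near_cpg and not b.in_or_near_cpg

    def test_oncogene_transcript_containment(self, tiny_bundle):
        a = self.ann(tiny_bundle, "chr1", 425_000)
        assert a.in_oncogene_transcript and a.in_gene
        assert a.dist_oncogene_tss == 449_999 - 425_000

    def test_repeat_class_and_centromere(self, tiny_bundle):
        a = self.ann(tiny_bundle, "chr1", 510_000)
        assert a.repeat_class == "Satellite"
        assert a.near_centromere and a.dist_centromere == 0
        b = self.ann(tiny_bundle, "chr2", 500_000)
        assert b.repeat_class is None and not b.near_centromere

    def test_unknown_chromosome_named_in_error(self, tiny_bundle):
        with pytest.raises(ValueError, match="chrM"):
            self.ann(tiny_bundle, "chrM", 100)

    def test_in_peak_implies_near_peak_over_random_sites(self, tiny_bundle, rng):
        annot = Annotator(tiny_bundle, n_bins=3)
        sites = [
            IntegrationSite("chr1" if rng.random() < 0.5 else "chr2",
                            int(rng.integers(0, 1_000_000)), "+")
            for _ in range(500)
        ]
        for a in annot.annotate(sites):
            for rel in a.peaks.values():
                assert not rel.in_peak or rel.near_peak


class TestBatchAgainstScanOracle:
    def test_batch_distances_match_per_feature_scan(self, tiny_bundle, rng):
        annot = Annotator(tiny_bundle, n_bins=3)
        sites = [
            IntegrationSite(c, int(p), "+")
            for c, p in zip(
                rng.choice(["chr1", "chr2"], 60),
                rng.integers(0, 1_000_000, 60),
            )
        ]
        anns = annot.annotate(sites)
        genes = [g.interval for g in tiny_bundle.genes]
        for s, a in zip(sites, anns):
            gd = [interval_distance(g.start, g.end, s.position)
                  for g in genes if g.chrom == s.chrom]
            assert a.in_gene == (bool(gd) and min(gd) == 0)
            td = [abs(g.tss - s.position) for g in tiny_bundle.genes
                  if g.interval.chrom == s.chrom]
            assert a.dist_tss == (min(td) if td else math.inf)


class TestSummarize:
    def test_simple_percentages(self, tiny_bundle):
        annot = Annotator(tiny_bundle, n_bins=3)
        in_gene = [IntegrationSite("chr1", 120_000 + i, "+") for i in range(4)]
        out_gene = [IntegrationSite("chr2", 900_000 + i, "+") for i in range(6)]
        summ = summarize_profile(annot.annotate(in_gene + out_gene))
        assert summ.percentages["in_gene"] == 40.0
        assert summ.denominators["in_gene"] == 10

    def test_ambiguous_sites_only_count_for_repeats_and_centromere(self, tiny_bundle):
        annot = Annotator(tiny_bundle, n_bins=3)
        sites = [
            IntegrationSite("chr1", 510_000, "+", 1, True),   # ambiguous satellite
            IntegrationSite("chr2", 900_000, "+", 1, False),
        ]
        summ = summarize_profile(annot.annotate(sites))
        assert summ.denominators["in_gene"] == 1
        assert summ.denominators["repeat:Satellite"] == 2
        assert summ.counts["repeat:Satellite"] == 1
        assert summ.denominators["centromere"] == 2

    def test_all_ambiguous_is_zero_denominator_error(self, tiny_bundle):
        annot = Annotator(tiny_bundle, n_bins=3)
        sites = [IntegrationSite("chr1", 1000, "+", 1, True)]
        with pytest.raises(ValueError, match="denominator"):
            summarize_profile(annot.annotate(sites))

    def test_histogram_counts_cover_all_sites(self, tiny_bundle, rng):
        annot = Annotator(tiny_bundle, n_bins=3)
        sites = [IntegrationSite("chr1", int(p), "+")
                 for p in rng.integers(0, 1_000_000, 200)]
        summ = summarize_profile(annot.annotate(sites))
        assert sum(summ.tss_histogram[1]) == 200
        assert sum(summ.cpg_histogram[1]) == 200
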