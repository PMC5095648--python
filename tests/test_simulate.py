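import numpy as np
import pytest

from risprofile import (
    Annotator,
    GenomeLayout,
    ReferenceBundle,
    ReferenceConfig,
    TetherModel,
    generate_reference,
    simulate_reads,
    simulate_sites,
    truncate_by_quality,
)
from risprofile.pipeline import process_read_pairs
from risprofile.reads import merge_read_pair


class TestGenerateReference:
    def test_determinism_and_seed_sensitivity(self):
        a = generate_reference(seed=3)
        b = generate_reference(seed=3)
        c = generate_reference(seed=4)
        pos = lambda ref: [g.interval.start for g in ref.bundle.genes]
        assert pos(a) == pos(b)
        assert pos(a) != pos(c)

    def test_every_feature_class_nonempty(self, synth_ref):
        bundle = synth_ref.bundle
        assert bundle.genes and bundle.cpg_islands and bundle.centromeres
        assert bundle.satellites and bundle.peak_sets["H3K9me3"]
        assert any(g.is_oncogene for g in bundle.genes)
        assert bundle.unresolved_oncogenes == []

    def test_satellites_flank_centromeres(self, synth_ref):
        config = ReferenceConfig()
        for sat in synth_ref.bundle.satellites:
            mid = config.chrom_length // 2
            assert abs((sat.interval.start + sat.interval.end) // 2 - mid) <= (
                config.pericentromeric_halfwidth + config.satellite_length
            )

    def test_genes_avoid_pericentromeric_zone(self, synth_ref):
        config = ReferenceConfig()
        mid = config.chrom_length // 2
        lo, hi = mid - 600_000, mid + 600_000
        for g in synth_ref.bundle.genes:
            assert g.interval.end <= lo or g.interval.start >= hi

    def test_infeasible_packing_rejected(self):
        config = ReferenceConfig(chrom_length=1_000_000)
        with pytest.raises(ValueError, match="infeasible"):
            generate_reference(config)


class TestSimulateSites:
    def test_pure_background_model(self, synth_ref):
        sites, truth = simulate_sites(TetherModel(), synth_ref, 50, seed=1)
        assert truth.component_counts == {
            "peak": 0, "satellite": 0, "background": 50
        }

    def test_degenerate_peak_model_places_every_site_in_a_peak(self, synth_ref):
        model = TetherModel(pi_peak=1.0, d_peak=0)
        sites, truth = simulate_sites(model, synth_ref, 100, seed=2)
        annot = Annotator(synth_ref.bundle)
        anns = annot.annotate(sites)
        assert all(a.peaks["H3K9me3"].in_peak for a in anns)

    def test_component_fractions_converge(self, synth_ref):
        _, truth = simulate_sites(
            TetherModel(pi_peak=0.35, pi_sat=0.2), synth_ref, 5000, seed=3
        )
        se = np.sqrt(0.35 * 0.65 / 5000)
        assert abs(truth.component_counts["peak"] / 5000 - 0.35) <= 3 * se

    def test_truth_labels_agree_with_annotation(self, synth_ref):
        """Peak-tethered sites sit within d_peak <= 50 kb of a strong peak."""
        sites, truth = simulate_sites(
            TetherModel(pi_peak=0.5, d_peak=10_000), synth_ref, 400, seed=4
        )
        anns = Annotator(synth_ref.bundle).annotate(sites)
        peak_sites = [a for a, l in zip(anns, truth.labels) if l == "peak"]
        near = sum(a.peaks["H3K9me3"].near_peak for a in peak_sites)
        assert near >= 0.99 * len(peak_sites)

    def test_satellite_without_satellites_rejected(self, synth_ref):
        bare = ReferenceBundle(
            layout=GenomeLayout([("chr1", 1_000_000)]),
        )
        with pytest.raises(ValueError, match="satellite"):
            simulate_sites(TetherModel(pi_sat=0.5), bare, 10)

    def test_invalid_mixture_weights(self):
        with pytest.raises(ValueError):
            TetherModel(pi_peak=0.7, pi_sat=0.5)

    def test_clone_count_distributions(self, synth_ref):
        _, truth = simulate_sites(
            TetherModel(), synth_ref, 200,
            clone_count_distribution=("logseries", 0.9), seed=5,
        )
        assert all(c >= 1 for c in truth.read_counts)
        assert truth.total_reads >= 200
        sites, truth2 = simulate_sites(
            TetherModel(), synth_ref, 3,
            clone_count_distribution=[5, 1, 1], seed=6,
        )
        assert [s.read_count for s in sites] == [5, 1, 1]


@pytest.fixture(scope="module")
def small_seq_ref():
    config = ReferenceConfig(
        n_chroms=2, chrom_length=500_000, n_genes=40, n_oncogenes=5,
        n_cpg=30, n_peaks=40, n_satellites_per_chrom=6, satellite_length=5_000,
        pericentromeric_halfwidth=60_000, centromere_halfwidth=10_000,
        repeat_counts={"LINE": 20, "SINE": 20, "LTR": 10, "DNA": 10},
        gene_length_range=(2_000, 10_000), with_sequence=True,
    )
    return generate_reference(config, seed=17)


class TestSimulateReads:
    def test_pair_merging_reconstructs_template(self, small_seq_ref):
        sites, _ = simulate_sites(
            TetherModel(), small_seq_ref, 20, seed=7, edge_margin=300
        )
        pairs, origins = simulate_reads(sites, small_seq_ref.sequences, seed=8)
        assert len(pairs) == 20 and origins == list(range(20))
        for (fwd, rev), site in zip(pairs, sites):
            merged = merge_read_pair(fwd, rev)
            assert merged is not None and len(merged) == 150
            seq = small_seq_ref.sequences[site.chrom]
            if site.strand == "+":
                assert merged.bases == seq[site.position:site.position + 150]

    def test_low_quality_tail_drives_truncation(self, small_seq_ref):
        sites, _ = simulate_sites(
            TetherModel(), small_seq_ref, 5, seed=9, edge_margin=300
        )
        pairs, _ = simulate_reads(
            sites, small_seq_ref.sequences, lowq_tail_start=40, seed=10
        )
        for fwd, _ in pairs:
            assert len(truncate_by_quality(fwd)) <= 42

    def test_read_length_validation(self, small_seq_ref):
        sites, _ = simulate_sites(TetherModel(), small_seq_ref, 1, seed=11)
        with pytest.raises(ValueError):
            simulate_reads(sites, small_seq_ref.sequences,
                           read_length=200, template_length=150)

    def test_end_to_end_recovery_without_errors(self, small_seq_ref):
        sites, _ = simulate_sites(
            TetherModel(), small_seq_ref, 30, seed=12, edge_margin=300
        )
        pairs, _ = simulate_reads(sites, small_seq_ref.sequences, seed=13)
        called = process_read_pairs(pairs, small_seq_ref.sequences, min_score=50)
        truth = {(s.chrom, s.position, s.strand) for s in sites}
        got = {(s.chrom, s.position, s.strand) for s in called if not s.ambiguous}
        assert len(truth & got) >= 0.95 * len(truth)
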