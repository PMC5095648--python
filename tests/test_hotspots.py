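import numpy as np
import pytest

from oracles import (
    hotspot_count_all_anchor_subsets,
    hotspot_count_exhaustive_windows,
)
from risprofile import (
    GenomicInterval,
    IntegrationSite,
    Peak,
    count_hotspots,
    hotspot_analysis,
    hotspot_peak_proximity,
    partition_matched_subsets,
)
from risprofile.simulate import TetherModel, simulate_sites


def sites_at(positions, chrom="chr1"):
    return [IntegrationSite(chrom, int(p), "+") for p in positions]


class TestPartition:
    def test_floor_division_into_matched_subsets(self):
        sites = sites_at(range(1000))
        subsets = partition_matched_subsets(sites, k=320, seed=5)
        assert len(subsets) == 3 and all(len(s) == 320 for s in subsets)
        used = {id(x) for sub in subsets for x in sub}
        assert len(used) == 960  # pairwise disjoint, 40 left unused

    def test_insufficient_sites_is_an_error(self):
        with pytest.raises(ValueError, match="960"):
            partition_matched_subsets(sites_at(range(959)), k=320)

    def test_seed_determinism(self):
        sites = sites_at(range(1000))
        a = partition_matched_subsets(sites, 320, seed=9)
        b = partition_matched_subsets(sites, 320, seed=9)
        assert [[s.position for s in sub] for sub in a] == [
            [s.position for s in sub] for sub in b
        ]


class TestCountHotspots:
    def test_three_sites_in_one_window(self):
        count, members = count_hotspots(sites_at([1000, 2000, 3000]), 5000)
        assert count == 1 and len(members[0]) == 3

    def test_below_min_sites_is_not_a_hotspot(self):
        assert count_hotspots(sites_at([10, 20]), 5000)[0] == 0

    def test_no_single_window_holds_three(self):
        # spans 4999 and 5000 pairwise, but no 5 kb window covers all three
        assert count_hotspots(sites_at([0, 4999, 9999]), 5000)[0] == 0

    def test_failed_anchor_does_not_consume_sites(self):
        # window at 0 holds only {0,4000}; the one at 4000 holds three sites
        count, members = count_hotspots(sites_at([0, 4000, 6000, 7000]), 5000)
        assert count == 1
        assert [s.position for s in members[0]] == [4000, 6000, 7000]

    def test_hotspots_do_not_span_chromosomes(self):
        sites = sites_at([100, 200]) + sites_at([150], chrom="chr2")
        assert count_hotspots(sites, 5000)[0] == 0

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            count_hotspots(sites_at([1]), 0)

    def test_permutation_invariance(self, rng):
        base = sites_at(rng.integers(0, 200_000, 80))
        ref_count = count_hotspots(base, 5000)[0]
        for _ in range(5):
            perm = [base[i] for i in rng.permutation(len(base))]
            assert count_hotspots(perm, 5000)[0] == ref_count

    def test_greedy_equals_dp_on_random_fixtures(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 120))
            positions = rng.integers(0, 300_000, n)
            ss = sites_at(positions)
            for window in (5_000, 50_000):
                greedy = count_hotspots(ss, window)[0]
                dp = count_hotspots(ss, window, method="exhaustive")[0]
                oracle = hotspot_count_exhaustive_windows(
                    [int(p) for p in positions], window, 3
                )
                assert greedy == dp == oracle

    def test_dp_matches_all_subset_enumeration_tiny(self, rng):
        """The DP itself is validated against full subset enumeration."""
        for _ in range(150):
            n = int(rng.integers(3, 9))
            positions = [int(p) for p in rng.integers(0, 40, n)]
            for window in (5, 12):
                dp = hotspot_count_exhaustive_windows(positions, window, 3)
                full = hotspot_count_all_anchor_subsets(positions, window, 3)
                assert dp == full, (positions, window)


class TestPeakProximity:
    peaks = [Peak(GenomicInterval("chr1", 10_000, 12_000), 9.0)]

    def test_members_inside_peaks(self):
        members = sites_at([10_500, 11_000, 11_500])
        assert hotspot_peak_proximity(members, self.peaks) == (3, 1.0)

    def test_no_peaks_on_chromosome(self):
        members = sites_at([100, 200, 300], chrom="chr9")
        assert hotspot_peak_proximity(members, self.peaks) == (0, 0.0)

    def test_empty_members_defined(self):
        assert hotspot_peak_proximity([], self.peaks) == (0, 0.0)

    def test_mixed_members_match_per_site_distance(self):
        members = sites_at([11_000, 12_000 + 49_999, 12_000 + 50_001])
        count, frac = hotspot_peak_proximity(members, self.peaks)
        assert count == 2 and frac == pytest.approx(2 / 3)


class TestHotspotAnalysis:
    def test_mean_and_sem_match_direct_formulas(self, rng):
        sites = sites_at(rng.integers(0, 3_000_000, 400))
        res = hotspot_analysis(sites, k=100, window_bp=50_000, seed=3)
        counts = np.array(res.per_subset_counts, dtype=float)
        assert res.n_subsets == 4
        assert res.mean == pytest.approx(counts.mean())
        assert res.sem == pytest.approx(counts.std(ddof=1) / np.sqrt(len(counts)))

    def test_tethered_sites_form_more_hotspots_than_uniform(self, synth_ref):
        """Qualitative pattern: peak-tethered integration inflates hotspot counts."""
        wins = {5_000: 0, 50_000: 0}
        n_rep = 10
        for rep in range(n_rep):
            tether, _ = simulate_sites(
                TetherModel(pi_peak=0.35, pi_sat=0.3), synth_ref, 320,
                seed=100 + rep,
            )
            uniform, _ = simulate_sites(
                TetherModel(), synth_ref, 320, seed=200 + rep
            )
            for w in wins:
                if count_hotspots(tether, w)[0] > count_hotspots(uniform, w)[0]:
                    wins[w] += 1
        for w, n_win in wins.items():
            assert n_win >= 0.95 * n_rep, (w, n_win)
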