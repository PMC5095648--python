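import numpy as np
import pytest

from oracles import truncate_oracle
from risprofile import Read, merge_read_pair, naive_locate, revcomp, truncate_by_quality
from risprofile.reads import read_fastq, trim_fixed, write_fastq


def mk(bases: str, quals=None, rid="r1") -> Read:
    quals = quals if quals is not None else [40] * len(bases)
    return Read(rid, bases, tuple(quals))


class TestTruncateByQuality:
    def test_high_quality_read_unchanged(self):
        r = mk("ACGTACGT")
        assert truncate_by_quality(r) is r

    def test_truncates_before_third_low_base(self):
        r = mk("ACGTACGT", [40, 10, 40, 10, 40, 10, 40, 40])
        out = truncate_by_quality(r)
        assert out.bases == "ACGTA" and len(out.quals) == 5

    def test_two_low_bases_not_enough(self):
        r = mk("ACGTAC", [40, 26, 40, 26, 40, 40])
        assert truncate_by_quality(r) is r

    def test_keep_trigger_variant_retains_one_more_base(self):
        r = mk("ACGTACGT", [10, 10, 10, 40, 40, 40, 40, 40])
        assert len(truncate_by_quality(r)) == 2
        assert len(truncate_by_quality(r, keep_trigger=True)) == 3

    def test_agrees_with_bruteforce_and_is_idempotent(self, rng):
        for _ in range(1000):
            n = int(rng.integers(0, 60))
            quals = [int(q) for q in rng.integers(2, 41, n)]
            r = mk("A" * n, quals, "x")
            out = truncate_by_quality(r)
            assert len(out) == truncate_oracle(quals, 27, 3)
            # never >= 3 low-quality bases survive; applying twice is a no-op
            assert sum(q < 27 for q in out.quals) < 3
            assert truncate_by_quality(out).bases == out.bases


class TestMergeReadPair:
    @staticmethod
    def _pair_from_template(template: str, read_len: int, q=35):
        fwd = mk(template[:read_len], [q] * read_len, "p")
        rev = mk(revcomp(template)[:read_len], [q] * read_len, "p")
        return fwd, rev

    def test_perfect_overlap_reconstructs_template(self, rng):
        template = "".join(rng.choice(list("ACGT"), 100))
        fwd, rev = self._pair_from_template(template, 60)
        merged = merge_read_pair(fwd, rev, min_overlap=10)
        assert merged is not None and len(merged) == 100
        assert merged.bases == template

    def test_disjoint_reads_do_not_merge(self):
        fwd = mk("A" * 30)
        rev = mk("C" * 30)  # revcomp = G*30, no overlap with A*30
        assert merge_read_pair(fwd, rev, min_overlap=10) is None

    def test_overlap_mismatch_resolved_by_higher_quality(self):
        # forward ...TTTT, revcomp(reverse) = TATT...: mismatch at overlap pos 1
        fwd = Read("m", "AACCGGTTTT", tuple([40] * 6 + [20] * 4))
        rc_rev = "TATTCCGGAA"
        rev = Read("m", revcomp(rc_rev), tuple([39] * 10))
        merged = merge_read_pair(fwd, rev, min_overlap=4, max_mismatch_rate=0.3)
        assert merged is not None
        # overlap is the last 4 forward bases; reverse wins the mismatch (Q39>20)
        assert merged.bases == "AACCGGTATTCCGGAA"
        assert merged.quals[7] == 39

    def test_empty_read_rejected(self):
        with pytest.raises(ValueError):
            merge_read_pair(mk(""), mk("ACGT"))


@pytest.fixture(scope="module")
def toy_ref():
    rng = np.random.default_rng(7)
    chrom = "".join(rng.choice(list("ACGT"), 200))
    dup = chrom[30:70]  # 40-mer duplicated on the second sequence
    return {"c1": chrom, "c2": "".join(rng.choice(list("ACGT"), 80)) + dup}


class TestNaiveLocate:

    def test_unique_match_scores_full_length(self, toy_ref):
        read = mk(toy_ref["c1"][100:140])
        recs = naive_locate(read, {"c1": toy_ref["c1"]}, min_score=30)
        assert len(recs) == 1
        assert (recs[0].chrom, recs[0].pos, recs[0].strand, recs[0].score) == (
            "c1", 100, "+", 40)

    def test_duplicated_segment_yields_two_equal_placements(self, toy_ref):
        read = mk(toy_ref["c1"][30:70])
        recs = naive_locate(read, toy_ref, min_score=30)
        assert len(recs) == 2 and recs[0].score == recs[1].score == 40

    def test_reverse_strand_junction_is_rightmost_base(self, toy_ref):
        read = mk(revcomp(toy_ref["c1"][100:140]))
        recs = naive_locate(read, {"c1": toy_ref["c1"]}, min_score=30)
        assert len(recs) == 1
        assert (recs[0].strand, recs[0].pos) == ("-", 139)

    def test_read_shorter_than_seed_is_unplaced(self, toy_ref):
        assert naive_locate(mk("ACGTACGT"), toy_ref, min_score=1) == []

    def test_tolerates_configured_mismatches(self, toy_ref):
        seg = list(toy_ref["c1"][100:140])
        seg[25] = "A" if seg[25] != "A" else "C"
        recs = naive_locate(mk("".join(seg)), {"c1": toy_ref["c1"]}, min_score=30)
        assert len(recs) == 1 and recs[0].score == 39


def test_trim_fixed_requires_exact_prefix():
    r = mk("TTAAGGCCAT")
    out = trim_fixed(r, prefix="TTAA")
    assert out is not None and out.bases == "GGCCAT"
    assert trim_fixed(r, prefix="GGGG") is None


def test_fastq_roundtrip(tmp_path):
    reads = [mk("ACGTN", [2, 40, 30, 20, 10], "a"), mk("TTTT", [33] * 4, "b")]
    p = tmp_path / "x.fastq"
    write_fastq(reads, p)
    back = list(read_fastq(p))
    assert [(r.id, r.bases, r.quals) for r in reads] == [
        (r.id, r.bases, r.quals) for r in back
    ]
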