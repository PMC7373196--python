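import numpy as np
import pytest

from dcscan.align import (
    AlignedRead,
    build_coverage,
    compare_profiles,
    export_bedgraph,
    import_bedgraph,
    length_histogram,
    library_size,
    load_alignments,
    map_exact,
    rpm_scale,
    trim_adapter,
)
from dcscan.genome import Genome, revcomp

ADAPTER = "AGATCGGAAG"


class TestTrimAdapter:
    def test_full_adapter_removed(self):
        reads, stats = trim_adapter([("r1", "ACGTACGTACGTACGT" + ADAPTER)], ADAPTER)
        assert reads == [("r1", "ACGTACGTACGTACGT")]
        assert stats.trimmed == 1

    def test_three_base_adapter_prefix_at_end(self):
        # hand trace: suffix AGA == adapter[:3], min_overlap 3
        body = "C" * 16
        reads, stats = trim_adapter([("r1", body + "AGA")], ADAPTER, min_overlap=3)
        assert reads == [("r1", body)]

    def test_no_match_kept_and_flagged(self):
        reads, stats = trim_adapter([("r1", "C" * 20)], ADAPTER)
        assert reads == [("r1", "C" * 20)]
        assert stats.untrimmed == 1

    def test_short_after_trim_discarded(self):
        reads, stats = trim_adapter([("r1", "ACGT" + ADAPTER)], ADAPTER, min_len=15)
        assert reads == [] and stats.discarded == 1

    def test_empty_adapter_rejected(self):
        with pytest.raises(ValueError):
            trim_adapter([("r1", "ACGT")], "")


class TestMapExact:
    def test_forward_and_reverse_placement(self, small_genome):
        chrom = next(iter(small_genome))
        fwd = small_genome.fetch(chrom, 100, 122)
        rev = revcomp(small_genome.fetch(chrom, 98, 120))
        als, stats = map_exact([("a", fwd), ("b", rev)], small_genome)
        placements = {(a.start, a.end, a.strand) for a in als}
        # the random 50 kb genome could in principle multi-place a 22-mer,
        # but with seed 42 both reads are unique
        assert (100, 122, "+") in placements
        assert (98, 120, "-") in placements

    def test_multi_occurring_read_dropped(self):
        g = Genome({"c": "TTTT" + "ACGTACGTACGTACGTACGTA" + "CCC" + "ACGTACGTACGTACGTACGTA" + "TT"})
        read = "ACGTACGTACGTACGTACGTA"
        als, stats = map_exact([("r", read)], g)
        assert als == [] and stats.multi_mapped == 1

    def test_non_acgt_dropped(self, small_genome):
        als, stats = map_exact([("r", "ACGTN" * 5)], small_genome)
        assert als == [] and stats.invalid == 1

    def test_agrees_with_brute_force_scan(self, small_genome, rng):
        """Oracle: scan the genome and its reverse complement directly."""
        chrom = next(iter(small_genome))
        ref = small_genome[chrom]
        ref_rc = revcomp(ref)
        n = len(ref)
        reads = []
        for i in range(300):
            L = int(rng.integers(18, 29))
            s = int(rng.integers(0, n - L))
            seq = ref[s : s + L]
            if rng.random() < 0.5:
                seq = revcomp(seq)
            if rng.random() < 0.1:  # some unmappable reads
                seq = "A" * L
            reads.append((f"r{i}", seq))
        als, stats = map_exact(reads, small_genome)
        got = {(a.start, a.end, a.strand): a.count for a in als}

        expected: dict[tuple[int, int, str], int] = {}
        for _, seq in reads:
            L = len(seq)
            fwd_hits = [
                i for i in range(n - L + 1) if ref[i : i + L] == seq
            ]
            # minus placements: read occurs in the reverse-complement strand;
            # position j in ref_rc maps to genomic start n - j - L
            rc_hits = [
                n - j - L
                for j in range(n - L + 1)
                if ref_rc[j : j + L] == seq
            ]
            if len(fwd_hits) + len(rc_hits) == 1:
                key = (
                    (fwd_hits[0], fwd_hits[0] + L, "+")
                    if fwd_hits
                    else (rc_hits[0], rc_hits[0] + L, "-")
                )
                expected[key] = expected.get(key, 0) + 1
        assert got == expected


class TestLoadAlignments:
    def test_bed6(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t98\t120\tr1\t0\t-\n")
        (a,) = load_alignments(p)
        assert (a.chrom, a.start, a.end, a.strand) == ("chr1", 98, 120, "-")

    def test_sam_coordinate_conversion_and_skips(self, tmp_path):
        p = tmp_path / "a.sam"
        p.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:1000\n"
            "r1\t0\tchr1\t101\t60\t22M\t*\t0\t0\t" + "A" * 22 + "\t*\n"
            "r2\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n"
            "r3\t16\tchr1\t51\t60\t21M\t*\t0\t0\t" + "C" * 21 + "\t*\n"
        )
        als = load_alignments(p)
        assert [(a.start, a.end, a.strand) for a in als] == [
            (100, 122, "+"),
            (50, 71, "-"),
        ]

    def test_malformed_bed_reports_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t98\n")
        with pytest.raises(ValueError, match="1"):
            load_alignments(p)


class TestLengthHistogram:
    def test_fractions(self):
        reads = [("a", "A" * 21), ("b", "C" * 21), ("c", "G" * 21), ("d", "T" * 22)]
        assert length_histogram(reads) == {21: 0.75, 22: 0.25}

    def test_count_weighted_mode(self):
        als = [
            AlignedRead("c", 0, 21, "+", count=2000),
            AlignedRead("c", 30, 44, "+", count=8000),
        ]
        h = length_histogram(als)
        assert max(h, key=h.get) == 14
        assert abs(sum(h.values()) - 1) < 1e-9

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            length_histogram([])


class TestCoverage:
    def test_single_read_and_conservation(self, small_genome):
        chrom = next(iter(small_genome))
        track = build_coverage(
            [AlignedRead(chrom, 5, 8, "+", count=2)], small_genome
        )
        assert list(track.plus[4:9]) == [0, 2, 2, 2, 0]
        assert track.total() == 6  # count * length

    def test_matches_naive_per_base_oracle(self, small_genome, rng):
        chrom = next(iter(small_genome))
        n = small_genome.length(chrom)
        als = [
            AlignedRead(
                chrom,
                s := int(rng.integers(0, n - 30)),
                s + int(rng.integers(15, 30)),
                "+" if rng.random() < 0.5 else "-",
                count=int(rng.integers(1, 4)),
            )
            for _ in range(200)
        ]
        track = build_coverage(als, small_genome)
        plus = np.zeros(n)
        minus = np.zeros(n)
        for a in als:
            tgt = plus if a.strand == "+" else minus
            for p in range(a.start, a.end):
                tgt[p] += a.count
        assert np.array_equal(track.plus, plus)
        assert np.array_equal(track.minus, minus)
        # conservation
        assert track.total() == sum(a.count * a.length for a in als)

    def test_combined_mode_sums_strands(self, small_genome):
        chrom = next(iter(small_genome))
        als = [AlignedRead(chrom, 5, 8, "+"), AlignedRead(chrom, 6, 9, "-")]
        t = build_coverage(als, small_genome, strand_mode="combined")
        assert list(t.plus[5:9]) == [1, 2, 2, 1]
        assert t.minus.sum() == 0


class TestRpmScale:
    @pytest.mark.parametrize(
        "value,lib,expected", [(1, 10**6, 1.0), (2000, 10**6, 2000.0), (3, 2 * 10**6, 1.5)]
    )
    def test_values(self, small_genome, value, lib, expected):
        chrom = next(iter(small_genome))
        t = build_coverage([AlignedRead(chrom, 0, 1, "+", count=value)], small_genome)
        assert rpm_scale(t, lib).plus[0] == pytest.approx(expected)

    def test_no_double_scaling_and_linearity(self, small_genome):
        chrom = next(iter(small_genome))
        t1 = build_coverage([AlignedRead(chrom, 0, 10, "+", count=3)], small_genome)
        t5 = build_coverage([AlignedRead(chrom, 0, 10, "+", count=15)], small_genome)
        r1, r5 = rpm_scale(t1, 1000), rpm_scale(t5, 1000)
        assert np.allclose(5 * r1.plus, r5.plus)
        with pytest.raises(ValueError):
            rpm_scale(r1, 1000)


class TestBedgraph:
    def test_runs_merged(self, tmp_path):
        from dcscan.align import CoverageTrack

        t = CoverageTrack("c", np.array([0.0, 2, 2, 0]), np.zeros(4), strand_mode="combined")
        (path,) = export_bedgraph(t, tmp_path / "t")
        lines = [l for l in path.read_text().splitlines() if not l.startswith("track")]
        assert lines == ["c\t1\t3\t2"]

    def test_all_zero_empty(self, tmp_path):
        from dcscan.align import CoverageTrack

        t = CoverageTrack("c", np.zeros(10), np.zeros(10), strand_mode="combined")
        (path,) = export_bedgraph(t, tmp_path / "z")
        assert [l for l in path.read_text().splitlines() if not l.startswith("track")] == []

    def test_round_trip_identity(self, tmp_path, small_genome, rng):
        chrom = next(iter(small_genome))
        n = small_genome.length(chrom)
        als = [
            AlignedRead(
                chrom,
                s := int(rng.integers(0, n - 40)),
                s + int(rng.integers(15, 30)),
                "+" if rng.random() < 0.5 else "-",
            )
            for _ in range(150)
        ]
        t = build_coverage(als, small_genome)
        plus, minus = export_bedgraph(t, tmp_path / "cov")
        back = import_bedgraph(plus, minus, n)
        assert np.array_equal(back.plus, t.plus)
        assert np.array_equal(back.minus, t.minus)


class TestCompareProfiles:
    def _track(self, values):
        from dcscan.align import CoverageTrack

        v = np.asarray(values, dtype=float)
        return CoverageTrack("c", v, np.zeros_like(v), strand_mode="combined")

    def test_identical_profiles(self):
        t = self._track([1, 2, 3, 4, 2])
        r, p = compare_profiles(t, t, 0, 5)
        assert r == pytest.approx(1.0)

    def test_negated_profile(self):
        a = np.array([1.0, 2, 3, 4])
        t1 = self._track(a)
        t2 = self._track(2 * a.mean() - a)
        r, _ = compare_profiles(t1, t2, 0, 4)
        assert r == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # closed-form Pearson for (1,2,3,4) vs (1,2,3,5): 6.5/sqrt(5*8.75)
        r, p = compare_profiles(self._track([1, 2, 3, 4]), self._track([1, 2, 3, 5]), 0, 4)
        assert r == pytest.approx(0.9827076298239908)
        assert 0 < p < 1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            compare_profiles(self._track([1, 1, 1, 1]), self._track([1, 2, 3, 4]), 0, 4)
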