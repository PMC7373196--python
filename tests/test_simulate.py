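import collections

import numpy as np
import pytest

from dcscan.composition import CompositionParams, positional_gc
from dcscan.genome import gc_fraction, revcomp
from dcscan.simulate import (
    SimulationConfig,
    digest_duplexes,
    emit_reads,
    generate_genome,
    p19_capture,
    plant_composition_reads,
    plant_loci,
    simulate,
    write_fastq,
)


def locus_config(**kwargs):
    defaults = dict(
        genome_length=20_000,
        locus_plan=[{"architecture": "convergent3", "overlap_length": 400, "abundance": 100}],
        seed=5,
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


class TestPlantLoci:
    def _planted(self, arch, overlap, **spec_kwargs):
        cfg = SimulationConfig(
            genome_length=20_000,
            locus_plan=[
                {"architecture": arch, "overlap_length": overlap, "abundance": 10,
                 **spec_kwargs}
            ],
            seed=1,
        )
        g = generate_genome(cfg.genome_length, cfg.genome_gc, cfg.seed)
        return plant_loci(g, cfg)

    def test_divergent_overlap_at_5prime_ends(self):
        _, truth = self._planted("divergent5", 100)
        (locus,) = truth.loci
        s, a, ov = locus.sense, locus.antisense, locus.overlap
        assert ov[1] - ov[0] == 100
        # the overlap must sit at the sense 5' end and the antisense 5' end
        assert ov[0] == s[0]  # sense 5' end (plus strand: left)
        assert ov[1] == a[1]  # antisense 5' end (minus strand: right)
        inter = (max(s[0], a[0]), min(s[1], a[1]))
        assert inter == ov

    def test_convergent_overlap_at_3prime_ends(self):
        _, truth = self._planted("convergent3", 100)
        (locus,) = truth.loci
        s, a, ov = locus.sense, locus.antisense, locus.overlap
        assert ov[1] == s[1]  # sense 3' end
        assert ov[0] == a[0]  # antisense 3' end
        assert ov[1] - ov[0] == 100

    def test_full_overlap_contained_antisense_225nt(self):
        """A 225-nt antisense gene fully inside a 300-nt sense transcript."""
        _, truth = self._planted("full_overlap", 225, sense_length=300)
        (locus,) = truth.loci
        s, a = locus.sense, locus.antisense
        assert a[1] - a[0] == 225
        assert s[0] <= a[0] and a[1] <= s[1]
        assert locus.overlap == a  # intersection equals the antisense interval

    def test_novel_as_not_annotated(self):
        ann, truth = self._planted("novel_as", 150)
        assert len(truth.loci) == 1
        assert [g.strand for g in ann] == ["+"]  # only the sense gene

    def test_empty_plan(self):
        cfg = SimulationConfig(genome_length=1000, locus_plan=[], seed=1)
        g = generate_genome(1000, 0.5, 1)
        ann, truth = plant_loci(g, cfg)
        assert ann == [] and truth.loci == []

    def test_unplaceable_plan_names_locus(self):
        cfg = SimulationConfig(
            genome_length=900,
            locus_plan=[
                {"architecture": "convergent3", "overlap_length": 200, "abundance": 1},
                {"architecture": "convergent3", "overlap_length": 200, "abundance": 1},
            ],
            seed=1,
        )
        g = generate_genome(900, 0.5, 1)
        with pytest.raises(ValueError, match="locus 1"):
            plant_loci(g, cfg)

    def test_overlap_must_fit_products(self):
        with pytest.raises(ValueError, match="product_length_mean"):
            SimulationConfig(
                genome_length=10_000,
                locus_plan=[{"architecture": "convergent3", "overlap_length": 20, "abundance": 1}],
                digestion_mode="mn",
            )


def digested(cfg):
    g = generate_genome(cfg.genome_length, cfg.genome_gc, cfg.seed)
    _, truth = plant_loci(g, cfg)
    digest_duplexes(g, truth, cfg)
    return g, truth


class TestDigestion:
    def test_overhang_geometry_exhaustive(self):
        _, truth = digested(locus_config())
        products = [p for p in truth.products if p.is_duplex]
        assert products
        for p in products:
            assert p.minus_start == p.plus_start - 2
            assert p.minus_end == p.plus_end - 2

    def test_terminal_fragments_flagged(self):
        _, truth = digested(locus_config(seed=8))
        terminals = [p for p in truth.products if not p.is_duplex]
        # each fully digested molecule leaves two terminal fragments
        assert terminals
        (locus,) = truth.loci
        for p in terminals:
            assert p.plus_start == locus.overlap[0] or p.plus_end == locus.overlap[1]

    def test_unbiased_length_mean_within_3se(self):
        cfg = locus_config(cleavage_preference_strength=0.0, seed=9,
                           locus_plan=[{"architecture": "convergent3",
                                        "overlap_length": 800, "abundance": 200}])
        _, truth = digested(cfg)
        lengths = np.array([p.length for p in truth.products if p.is_duplex])
        se = lengths.std(ddof=1) / np.sqrt(len(lengths))
        assert abs(lengths.mean() - cfg.product_length_mean) < 3 * se

    @pytest.mark.parametrize("mode,expected", [("mg", 14), ("mn", 21)])
    def test_modal_product_length_by_mode(self, mode, expected):
        cfg = locus_config(
            digestion_mode=mode, seed=17,
            locus_plan=[{"architecture": "convergent3", "overlap_length": 800,
                         "abundance": 400}],
        )
        _, truth = digested(cfg)
        lengths = [p.length for p in truth.products if p.is_duplex]
        assert collections.Counter(lengths).most_common(1)[0][0] == expected

    def test_cut_site_au_enrichment_with_bias(self):
        """With beta_site > 0 the 3-nt windows flanking realised cuts are more
        AU-rich than in an unbiased run (>= 5000 cuts each)."""

        def mean_flank_au(beta, seed):
            cfg = locus_config(
                cleavage_preference_strength=beta, seed=seed,
                locus_plan=[{"architecture": "convergent3", "overlap_length": 1500,
                             "abundance": 150}],
            )
            g, truth = digested(cfg)
            ref = g[cfg.chrom_name]
            assert len(truth.cut_sites) >= 5000
            au = []
            for _, c, _mc in truth.cut_sites:
                window = ref[c - 5 : c - 2] + ref[c : c + 3]
                au.append((window.count("A") + window.count("T")) / 6)
            return np.mean(au)

        assert mean_flank_au(3.0, seed=21) > mean_flank_au(0.0, seed=21)

    def test_too_short_overlap_yields_no_products(self):
        # overlap barely above the config floor but below one spacing+jitter
        cfg = locus_config(
            locus_plan=[{"architecture": "convergent3", "overlap_length": 25,
                         "abundance": 5}],
            digestion_mode="mg", product_length_sd=0.5, seed=2,
        )
        _, truth = digested(cfg)
        # molecules may yield at most one cut -> no internal duplex products
        assert all(
            not p.is_duplex or p.length >= 6 for p in truth.products
        )


class TestP19Capture:
    def test_length_filter_only_21_22(self):
        cfg = locus_config(p19_body_gc_coeff=0.0, seed=12)
        g, truth = digested(cfg)
        p19_capture(truth, g, cfg)
        assert truth.captured_products
        assert {cp.length for cp in truth.captured_products} <= {21, 22}

    def test_terminal_fragments_never_captured(self):
        cfg = locus_config(seed=13)
        g, truth = digested(cfg)
        p19_capture(truth, g, cfg)
        duplex_coords = {
            (p.plus_start, p.plus_end) for p in truth.products if p.is_duplex
        }
        for cp in truth.captured_products:
            assert (cp.plus_start, cp.plus_end) in duplex_coords

    def test_body_gc_enrichment_direction(self):
        cfg = locus_config(
            p19_body_gc_coeff=4.0, seed=14,
            locus_plan=[{"architecture": "full_overlap", "overlap_length": 1500,
                         "abundance": 300}],
        )
        g, truth = digested(cfg)
        p19_capture(truth, g, cfg)
        ref = g[cfg.chrom_name]

        def body_gc(s, e):
            return gc_fraction(ref[s + 3 : e - 5])

        pool = [
            body_gc(p.plus_start, p.plus_end)
            for p in truth.products
            if p.is_duplex and p.length in (21, 22)
        ]
        captured = [
            body_gc(cp.plus_start, cp.plus_end)
            for cp in truth.captured_products
            for _ in range(cp.count)
        ]
        assert np.mean(captured) > np.mean(pool)

    def test_empty_cleavage_set(self):
        cfg = locus_config()
        g = generate_genome(cfg.genome_length, cfg.genome_gc, cfg.seed)
        _, truth = plant_loci(g, cfg)
        p19_capture(truth, g, cfg)
        assert truth.captured_products == []


class TestEmitReads:
    def test_reads_are_genomic_substrings(self):
        cfg = locus_config(seed=15, noise_read_count=50)
        res = simulate(cfg)
        ref = res.genome[cfg.chrom_name]
        for a in res.emitted.alignments:
            expected = ref[a.start : a.end]
            if a.strand == "-":
                expected = revcomp(expected)
            assert a.sequence == expected

    def test_zero_noise_reads_map_inside_captured_duplexes(self):
        cfg = locus_config(seed=16, noise_read_count=0)
        res = simulate(cfg)
        spans = [
            (cp.minus_start, cp.plus_end) for cp in res.truth.captured_products
        ]
        for a in res.emitted.alignments:
            assert any(s <= a.start and a.end <= e for s, e in spans)

    def test_strand_ratio_unbiased_within_3se(self):
        cfg = locus_config(
            strand_bias_sd=0.0, seed=18,
            locus_plan=[{"architecture": "convergent3", "overlap_length": 1000,
                         "abundance": 1200}],
        )
        res = simulate(cfg)
        n_plus = sum(a.count for a in res.emitted.duplex_alignments if a.strand == "+")
        n_minus = sum(a.count for a in res.emitted.duplex_alignments if a.strand == "-")
        # difference of two equal-rate Poisson totals: SE = sqrt(n+ + n-)
        assert abs(n_plus - n_minus) < 3 * np.sqrt(n_plus + n_minus)

    def test_same_seed_byte_identical_fastq(self, tmp_path):
        cfg = locus_config(seed=19, noise_read_count=25)
        a = tmp_path / "a"
        b = tmp_path / "b"
        simulate(cfg, out_dir=a)
        simulate(cfg, out_dir=b)
        assert (a / "reads.fastq").read_bytes() == (b / "reads.fastq").read_bytes()
        assert (a / "cleavage_sites.tsv").read_text() == (b / "cleavage_sites.tsv").read_text()

    def test_fastq_is_q40(self, tmp_path):
        write_fastq([("r1", "ACGT")], tmp_path / "r.fastq")
        lines = (tmp_path / "r.fastq").read_text().splitlines()
        assert lines == ["@r1", "ACGT", "+", "IIII"]


class TestPlantCompositionReads:
    def test_planted_region_composition_recovered(self):
        params = CompositionParams(read_length=22)
        genome, reads = plant_composition_reads(
            5000, params, overhang_gc=0.60, flank_au=0.60, seed=4
        )
        profile = positional_gc(reads, genome, params)
        summary = profile.region_summary()
        assert abs(summary["overhang_this_strand"] - 0.60) < 0.03
        assert abs(summary["overhang_partner"] - 0.60) < 0.03
        assert abs((1 - summary["cleavage_flank"]) - 0.60) < 0.03

    def test_emitted_22mers_show_cleavage_signature(self):
        """End-to-end: profiles of simulator output show elevated overhang GC
        and depressed cleavage-flank GC relative to background."""
        cfg = locus_config(
            cleavage_preference_strength=4.0, seed=23,
            locus_plan=[{"architecture": "convergent3", "overlap_length": 1500,
                         "abundance": 400}],
        )
        res = simulate(cfg)
        params = CompositionParams(read_length=22)
        reads22 = [a for a in res.emitted.duplex_alignments if a.length == 22]
        profile = positional_gc(reads22, res.genome, params, weighting="abundance")
        s = profile.region_summary()
        assert s["overhang_this_strand"] > s["background"]
        assert s["overhang_partner"] > s["background"]
        assert s["cleavage_flank"] < s["background"]
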