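from __future__ import annotations

import math

import numpy as np
import pytest

from popdiv import dstat, simulate
from popdiv.dstat import FourGenomeSite, PatternCounts


def site(g1, g2, arch, outg, pos=100, chrom="1"):
    return FourGenomeSite(chrom, pos, g1, g2, arch, outg)


class TestResolveAllele:
    def test_homozygous_any_policy(self):
        rng = np.random.default_rng(0)
        for policy in ("random_draw", "homozygous_only", "major_allele"):
            assert dstat.resolve_allele(("A", "A"), policy, rng) == "A"

    def test_het_homozygous_only_missing(self):
        assert dstat.resolve_allele(("A", "C"), "homozygous_only") is None

    def test_het_major_allele_alphabetical(self):
        assert dstat.resolve_allele(("T", "C"), "major_allele") == "C"

    def test_het_random_draw_reproducible(self):
        picks1 = [dstat.resolve_allele(("A", "C"), "random_draw", np.random.default_rng(42))
                  for _ in range(5)]
        picks2 = [dstat.resolve_allele(("A", "C"), "random_draw", np.random.default_rng(42))
                  for _ in range(5)]
        assert picks1 == picks2
        assert set(picks1) <= {"A", "C"}

    def test_unknown_policy_errors(self):
        with pytest.raises(ValueError, match="policy"):
            dstat.resolve_allele(("A", "C"), "mode_allele")  # type: ignore[arg-type]

    def test_missing_allele_returns_none(self):
        assert dstat.resolve_allele((None, "C"), "major_allele") is None


class TestClassifyPattern:
    def test_baba(self):
        # A↔T is a transversion; G1 and archaic carry the derived allele
        assert dstat.classify_pattern(site("T", "A", "T", "A")) == "BABA"

    def test_abba(self):
        assert dstat.classify_pattern(site("A", "T", "T", "A")) == "ABBA"

    def test_transition_excluded(self):
        assert dstat.classify_pattern(site("G", "A", "G", "A")) == "other"

    def test_archaic_matching_outgroup_uninformative(self):
        assert dstat.classify_pattern(site("T", "A", "A", "A")) == "other"

    def test_three_alleles_other_not_error(self):
        assert dstat.classify_pattern(site("T", "C", "A", "A")) == "other"

    def test_missing_allele_other(self):
        assert dstat.classify_pattern(site(None, "A", "T", "A")) == "other"

    def test_g1_equals_g2_uninformative(self):
        # both moderns carry B: neither BABA nor ABBA
        assert dstat.classify_pattern(site("T", "T", "T", "A")) == "other"


class TestDStatistic:
    @pytest.mark.parametrize(
        "n_baba, n_abba, pct, places",
        [(73774, 69606, 2.907, 3), (61203, 62837, -1.317, 3),
         (65428, 68000, -1.93, 2), (55720, 56822, -0.98, 2)],
    )
    def test_worked_count_pairs(self, n_baba, n_abba, pct, places):
        assert round(100 * dstat.dstatistic(n_baba, n_abba), places) == pct

    def test_equal_counts_give_zero(self):
        assert dstat.dstatistic(500, 500) == 0.0

    def test_one_sided_boundary(self):
        assert dstat.dstatistic(500, 0) == 1.0
        assert dstat.dstatistic(0, 500) == -1.0

    def test_zero_counts_error(self):
        with pytest.raises(ZeroDivisionError):
            dstat.dstatistic(0, 0)


class TestBlockPartition:
    def test_same_block(self):
        blocks = dstat.block_partition([("1", 1, "BABA"), ("1", 4_999_999, "ABBA")])
        assert len(blocks) == 1
        assert (blocks[0].n_baba, blocks[0].n_abba) == (1, 1)

    def test_block_boundary(self):
        blocks = dstat.block_partition([("1", 4_999_999, "BABA"), ("1", 5_000_001, "BABA")])
        assert len(blocks) == 2
        assert blocks[0].end == 5_000_000 and blocks[1].start == 5_000_001

    def test_unsorted_input_errors(self):
        with pytest.raises(ValueError, match="sorted"):
            dstat.block_partition([("1", 100, "BABA"), ("1", 50, "ABBA")])

    def test_uniform_sites_fill_expected_blocks(self):
        rng = np.random.default_rng(1)
        pos = np.sort(rng.integers(1, 50_000_000, size=5000))
        sites = [("1", int(p), "BABA") for p in pos]
        blocks = dstat.block_partition(sites)
        assert len(blocks) == 10
        assert sum(b.n_baba for b in blocks) == 5000

    def test_other_sites_not_tallied(self):
        blocks = dstat.block_partition([("1", 10, "other"), ("1", 20, "BABA")])
        assert len(blocks) == 1 and blocks[0].n_baba == 1


def make_blocks(counts):
    return [
        PatternCounts(("1", i), "1", i * 5_000_000 + 1, (i + 1) * 5_000_000, b, a)
        for i, (b, a) in enumerate(counts)
    ]


class TestJackknife:
    def test_hand_computed_two_block_example(self):
        """Blocks (10,0) and (0,10): D = 0, delete-one estimates ±1, SE = 1."""
        res = dstat.jackknife(make_blocks([(10, 0), (0, 10)]))
        assert res.dstat == 0.0
        assert res.se == pytest.approx(1.0)
        assert res.m_blocks == 2

    def test_identical_blocks_degenerate_variance(self):
        res = dstat.jackknife(make_blocks([(6, 3), (6, 3), (6, 3)]))
        assert res.se == 0.0
        assert res.degenerate_variance
        assert math.isnan(res.z)

    def test_totals_match_blocks(self):
        blocks = make_blocks([(10, 5), (20, 8), (3, 7)])
        res = dstat.jackknife(blocks)
        assert res.n_baba == sum(b.n_baba for b in blocks)
        assert res.n_abba == sum(b.n_abba for b in blocks)
        assert res.dstat == pytest.approx(dstat.dstatistic(res.n_baba, res.n_abba))

    def test_single_block_errors(self):
        with pytest.raises(ValueError, match="≥2"):
            dstat.jackknife(make_blocks([(10, 5)]))

    def test_weighted_variant_close_to_equal_weight_for_balanced_blocks(self):
        rng = np.random.default_rng(8)
        counts = [(int(b), int(a)) for b, a in
                  zip(rng.poisson(50, 40), rng.poisson(40, 40))]
        eq = dstat.jackknife(make_blocks(counts))
        wt = dstat.jackknife(make_blocks(counts), weighted=True)
        assert wt.dstat == eq.dstat
        assert wt.se == pytest.approx(eq.se, rel=0.2)


class TestPipelineConsistency:
    def test_site_layer_matches_pattern_layer(self):
        """Classifying the rendered allele table reproduces the pattern draws."""
        cfg = simulate.DstatSimConfig(n_sites=5000, n_blocks=10,
                                      p_baba=0.02, p_abba=0.01, seed=13)
        block_ids, patterns = simulate.simulate_dstat_patterns(cfg)
        sites = simulate.simulate_dstat_sites(cfg)
        n_baba = int((patterns == 1).sum())
        n_abba = int((patterns == 2).sum())
        classified = [dstat.classify_pattern(s) for s in sites]
        assert classified.count("BABA") == n_baba
        assert classified.count("ABBA") == n_abba
        res_sites = dstat.dstat_from_sites(sites, block_size=cfg.block_size)
        res_arrays = dstat.jackknife_from_arrays(block_ids, patterns, cfg.n_blocks)
        assert res_sites.n_baba == res_arrays.n_baba
        assert res_sites.n_abba == res_arrays.n_abba
        assert res_sites.dstat == pytest.approx(res_arrays.dstat)
        assert res_sites.se == pytest.approx(res_arrays.se)

    def test_antisymmetry_under_genome_swap(self):
        cfg = simulate.DstatSimConfig(n_sites=20000, n_blocks=8,
                                      p_baba=0.01, p_abba=0.004, seed=21)
        sites = simulate.simulate_dstat_sites(cfg)
        swapped = [FourGenomeSite(s.chrom, s.pos, s.g2, s.g1, s.archaic, s.outgroup)
                   for s in sites]
        a = dstat.dstat_from_sites(sites, block_size=cfg.block_size)
        b = dstat.dstat_from_sites(swapped, block_size=cfg.block_size)
        assert b.dstat == pytest.approx(-a.dstat)
        assert (b.n_baba, b.n_abba) == (a.n_abba, a.n_baba)
        assert abs(b.z) == pytest.approx(abs(a.z))

    def test_site_table_round_trip(self, tmp_path):
        cfg = simulate.DstatSimConfig(n_sites=200, n_blocks=4,
                                      p_baba=0.05, p_abba=0.05, seed=2)
        sites = simulate.simulate_dstat_sites(cfg)
        path = tmp_path / "sites.tsv"
        simulate.write_dstat_site_table(sites, path)
        assert dstat.read_site_table(path) == sites


class TestTrackJoining:
    def test_vcf_tracks_to_dstat(self, tmp_path):
        """Two modern + one archaic single-sample VCF joined with a chimp track."""
        header = ("##fileformat=VCFv4.2\n"
                  "##contig=<ID=1,length=20000000>\n"
                  '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
                  "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{}\n")
        # G1 derived (T/T), G2 ancestral (A/A), archaic derived at two BABA sites
        rows = {
            "g1": ["1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t1/1",
                   "1\t6000000\t.\tA\tT\t.\tPASS\t.\tGT\t1/1"],
            "g2": ["1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/0",
                   "1\t6000000\t.\tA\tT\t.\tPASS\t.\tGT\t0/0"],
            "arch": ["1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t1/1",
                     "1\t6000000\t.\tA\tT\t.\tPASS\t.\tGT\t1/1"],
        }
        tracks = {}
        for name, lines in rows.items():
            p = tmp_path / f"{name}.vcf"
            p.write_text(header.format(name.upper()) + "\n".join(lines) + "\n")
            tracks[name] = dstat.load_allele_track(p, policy="major_allele")
        outg_path = tmp_path / "chimp.tsv"
        outg_path.write_text("chrom\tpos\tbase\n1\t100\tA\n1\t6000000\tA\n")
        outg = dstat.read_outgroup_track(outg_path)
        sites = dstat.join_tracks(tracks["g1"], tracks["g2"], tracks["arch"], outg)
        assert len(sites) == 2
        res = dstat.dstat_from_sites(sites)
        assert (res.n_baba, res.n_abba) == (2, 0)
        assert res.dstat == 1.0
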