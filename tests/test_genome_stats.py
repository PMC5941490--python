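"""Unit tests for heterozygosity, PSMC-input, and window statistics."""

import numpy as np
import pytest

from phylosel.genome_stats import (
    ChromHetSummary,
    SiteCall,
    false_positive_rate,
    filter_sites,
    het_per_kb,
    make_psmcfa,
    read_psmcfa,
    read_sites_tsv,
    scale_time,
    window_stats,
    write_psmcfa,
    write_sites_tsv,
)


def _site(chrom="chr1", pos=100, major=27, minor=3, qual=30, depth=None, n_alleles=2):
    alleles = [("A", major), ("C", minor)]
    if n_alleles == 3:
        alleles.append(("G", 1))
    if n_alleles == 1:
        alleles = [("A", major)]
    total = depth if depth is not None else sum(d for _, d in alleles)
    return SiteCall(chrom=chrom, pos=pos, alleles=alleles, total_depth=total,
                    base_quality=qual)


class TestFilterSites:
    def test_maf_boundary_retained(self):
        kept, _ = filter_sites([_site(major=27, minor=3)])  # MAF exactly 0.1
        assert len(kept) == 1

    def test_low_depth_dropped(self):
        kept, report = filter_sites([_site(major=16, minor=3)])  # depth 19
        assert not kept and report.n_depth == 1

    def test_three_alleles_dropped(self):
        kept, report = filter_sites([_site(n_alleles=3)])
        assert not kept and report.n_not_biallelic == 1

    def test_monomorphic_dropped(self):
        kept, _ = filter_sites([_site(n_alleles=1, major=30)])
        assert not kept

    def test_low_maf_dropped(self):
        kept, report = filter_sites([_site(major=28, minor=2)])  # MAF 1/15
        assert not kept and report.n_maf == 1

    def test_quality_threshold(self):
        kept, report = filter_sites([_site(qual=19)])
        assert not kept and report.n_quality == 1

    def test_max_depth_bound_for_psmc(self):
        kept, _ = filter_sites([_site(major=45, minor=10)], min_depth=10, max_depth=50)
        assert not kept  # depth 55 > 50
        kept, _ = filter_sites([_site(major=40, minor=8)], min_depth=10, max_depth=50)
        assert len(kept) == 1

    def test_autosome_restriction_and_unmapped_report(self):
        sites = [
            _site(chrom="scaf1"), _site(chrom="scafZ"), _site(chrom="orphan"),
        ]
        chrom_map = {"scaf1": "chr1", "scafZ": "Z"}
        kept, report = filter_sites(
            sites, chrom_map=chrom_map, autosomes_only=True
        )
        assert [s.chrom for s in kept] == ["scaf1"]
        assert report.n_unmapped_scaffold == 1
        assert report.n_sex_chrom == 1


class TestHetPerKb:
    def test_per_chrom_recombines_to_pooled(self):
        sites = [_site(chrom="chr1", pos=p) for p in (10, 20, 30)]
        sites += [_site(chrom="chr2", pos=p) for p in (5, 15)]
        per_chrom, total = het_per_kb(sites, {"chr1": 3000, "chr2": 2000})
        assert total.het_bases == sum(s.het_bases for s in per_chrom)
        assert total.callable_bases == 5000
        assert total.het_per_kb == pytest.approx(1000 * 5 / 5000)

    def test_zero_het(self):
        _, total = het_per_kb([], {"chr1": 1000})
        assert total.het_per_kb == 0.0

    def test_het_per_kb_identity(self):
        summary = ChromHetSummary(chrom="c", callable_bases=2_000, het_bases=9)
        assert summary.het_per_kb == pytest.approx(1000 * 9 / 2000)

    def test_zero_callable_rejected(self):
        with pytest.raises(ValueError):
            het_per_kb([], {"chr1": 0})


class TestFalsePositiveRate:
    def test_calls_identical_to_truth(self):
        regions = [("chr1", 0, 100)]
        truth_het = {("chr1", 5), ("chr1", 50)}
        calls = set(truth_het)
        assert false_positive_rate(calls, regions, truth_het) == 0.0

    def test_planted_miscalls_recovered(self):
        regions = [("chr1", 0, 1000)]
        truth_het = set()
        calls = {("chr1", p) for p in range(1, 1001, 100)}  # 10 miscalls / 1000 hom
        assert false_positive_rate(calls, regions, truth_het) == pytest.approx(1.0)

    def test_no_homozygous_truth_gives_nan(self):
        regions = [("chr1", 0, 3)]
        truth_het = {("chr1", 1), ("chr1", 2), ("chr1", 3)}
        assert np.isnan(false_positive_rate(set(), regions, truth_het))


def _naive_psmcfa(het_positions, length, bin_size=100, masked=()):
    """Independent oracle: per-bin loops, no vectorization."""
    n_bins = length // bin_size
    out = []
    masked_set = set(masked)
    for b in range(n_bins):
        lo, hi = b * bin_size + 1, (b + 1) * bin_size
        if any(lo <= p <= hi for p in het_positions):
            out.append("K")
        elif sum(1 for p in range(lo, hi + 1) if p in masked_set) > 0.9 * bin_size:
            out.append("N")
        else:
            out.append("T")
    return "".join(out)


class TestMakePsmcfa:
    def _sites(self, chrom, positions):
        return [
            SiteCall(chrom=chrom, pos=p, alleles=[("A", 10), ("C", 10)],
                     total_depth=20, base_quality=30)
            for p in positions
        ]

    def test_hand_binning_with_partial_bin_dropped(self):
        records = make_psmcfa(self._sites("s", [37, 152]), {"s": 250})
        assert records[0].bins == "KK"

    def test_no_hets_all_T(self):
        records = make_psmcfa([], {"s": 300})
        assert records[0].bins == "TTT"

    def test_segment_splitting_arithmetic(self):
        records = make_psmcfa([], {"s": 25_000 * 100})
        assert len(records) == 3
        assert [len(r.bins) for r in records] == [10_000, 10_000, 5_000]
        assert records[0].name == "s_1"

    def test_mask_yields_N_and_het_wins(self, caplog):
        import logging

        mask = {"s": [(0, 100)]}
        with caplog.at_level(logging.WARNING):
            records = make_psmcfa(self._sites("s", [50]), {"s": 200}, missing_mask=mask)
        assert records[0].bins == "KT"  # het call overrules the mask, logged
        assert any("kept as K" in m for m in caplog.messages)
        records = make_psmcfa([], {"s": 200}, missing_mask=mask)
        assert records[0].bins == "NT"

    def test_matches_naive_oracle_on_random_chromosome(self):
        rng = np.random.default_rng(12)
        length = 100_000
        het = sorted(rng.choice(length, size=200, replace=False) + 1)
        mask_start = int(rng.integers(0, length - 5000))
        mask = {"c": [(mask_start, mask_start + 5000)]}
        records = make_psmcfa(
            self._sites("c", het), {"c": length}, missing_mask=mask
        )
        expected = _naive_psmcfa(
            het, length, masked=range(mask_start + 1, mask_start + 5001)
        )
        assert records[0].bins == expected

    def test_roundtrip_serialization(self, tmp_path):
        rng = np.random.default_rng(3)
        het = sorted(rng.choice(40_000, size=77, replace=False) + 1)
        records = make_psmcfa(self._sites("c1", het), {"c1": 40_000, "c2": 1_500})
        path = tmp_path / "out.psmcfa"
        write_psmcfa(records, path)
        lines = path.read_text().splitlines()
        assert all(len(l) <= 60 for l in lines)
        assert read_psmcfa(path) == records

    def test_out_of_range_position_rejected(self):
        with pytest.raises(ValueError):
            make_psmcfa(self._sites("s", [301]), {"s": 300})


class TestScaleTime:
    def test_flat_lambda_gives_flat_ne(self):
        frame = scale_time(np.linspace(0, 1, 5), np.ones(5), theta0=0.000764)
        n0 = 0.000764 / (4 * 1.91e-9 * 1.0 * 100)
        assert n0 == pytest.approx(1000.0)
        assert np.allclose(frame.Ne, n0)

    def test_doubling_mu_halves_everything(self):
        times, lams = np.array([0.1, 0.5]), np.array([1.0, 2.0])
        base = scale_time(times, lams, theta0=0.01)
        double = scale_time(times, lams, theta0=0.01, mu=2 * 1.91e-9)
        assert np.allclose(double.Ne, base.Ne / 2)
        assert np.allclose(double.years, base.years / 2)

    def test_invalid_theta_rejected(self):
        with pytest.raises(ValueError):
            scale_time(np.array([0.1]), np.array([1.0]), theta0=0.0)


class TestWindowStats:
    def test_fully_aligned_identical_window(self):
        n = 1000
        frame = window_stats(
            np.ones(n, bool), np.zeros(n, bool), np.zeros(n, bool), np.zeros(n, bool),
            window=n,
        )
        assert frame.fraction_aligned.iloc[0] == 1.0
        assert frame.divergence.iloc[0] == 0.0

    def test_divergence_arithmetic(self):
        n = 2000
        aligned = np.zeros(n, bool)
        aligned[:1000] = True
        mismatch = np.zeros(n, bool)
        mismatch[:50] = True
        frame = window_stats(aligned, mismatch, np.zeros(n, bool), np.zeros(n, bool),
                             window=n)
        assert frame.divergence.iloc[0] == pytest.approx(0.05)
        assert frame.fraction_aligned.iloc[0] == pytest.approx(0.5)

    def test_empty_window_divergence_nan(self):
        n = 200_000
        aligned = np.zeros(n, bool)
        aligned[:100_000] = True
        frame = window_stats(aligned, np.zeros(n, bool), np.zeros(n, bool),
                             np.zeros(n, bool))
        assert np.isnan(frame.divergence.iloc[1])

    def test_planted_divergence_recovered(self):
        rng = np.random.default_rng(8)
        n = 500_000
        aligned = rng.random(n) < 0.9
        mismatch = rng.random(n) < 0.054
        frame = window_stats(aligned, mismatch, np.zeros(n, bool), np.zeros(n, bool))
        assert frame.divergence.mean() == pytest.approx(0.054, abs=0.003)


class TestSitesTsv:
    def test_roundtrip(self, tmp_path):
        sites = [_site(pos=5), _site(chrom="chr2", pos=9, major=20, minor=5)]
        path = tmp_path / "sites.tsv"
        write_sites_tsv(sites, path)
        assert read_sites_tsv(path) == sites

    def test_sitecall_validation(self):
        with pytest.raises(ValueError):
            SiteCall("c", 0, [("A", 1)], 1, 30)  # pos must be >= 1
        with pytest.raises(ValueError):
            SiteCall("c", 1, [("A", 5), ("C", 6)], 10, 30)  # depths exceed total


class TestVcfIo:
    def test_roundtrip_through_vcf(self, tmp_path):
        sites = [
            _site(chrom="chr1", pos=100),
            _site(chrom="chr1", pos=205, major=20, minor=6, qual=35),
            _site(chrom="chr2", pos=9),
        ]
        from phylosel.genome_stats import read_vcf_sites, write_vcf_sites

        path = tmp_path / "sites.vcf"
        write_vcf_sites(sites, path)
        back = read_vcf_sites(path)
        assert back == sorted(sites, key=lambda s: (s.chrom, s.pos))
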