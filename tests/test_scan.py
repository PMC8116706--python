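"""Sliding-window ROH detection against brute-force enumeration and filters."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rohscan import MISSING, MarkerMap, ROHSegment, ScanParams, classify_segments, \
    per_chromosome_summary, scan_individual, scan_population
from conftest import make_matrix, random_fixture
from _oracles import brute_force_roh


def _scan_lists(calls, chroms, positions, params=None, sample="S"):
    mm = MarkerMap(pd.DataFrame({
        "snp_id": [f"s{i}" for i in range(len(calls))],
        "chrom": chroms, "pos": positions}))
    return scan_individual(np.asarray(calls, dtype=np.int8), mm, params, sample=sample)


class TestScanIndividual:
    def test_all_het_yields_nothing(self):
        g = make_matrix(np.ones((1, 500), dtype=np.int8))
        assert scan_individual(g.calls[0], g.markers) == []

    def test_planted_run_recovered_within_window(self):
        """300 hom SNPs at 10-kb spacing inside a het background: one segment
        whose boundaries sit within window_snp SNPs of the plant."""
        rng = np.random.default_rng(0)
        n = 1000
        calls = np.ones(n, dtype=np.int8)
        calls[400:700] = rng.choice([0, 2], size=300)
        g = make_matrix(calls[None, :])
        segs = scan_individual(g.calls[0], g.markers, sample="X")
        assert len(segs) == 1
        seg = segs[0]
        pos = g.markers.table["pos"].to_numpy()
        w = ScanParams().window_snp
        assert abs(seg.start_bp - pos[400]) <= w * 10_000
        assert abs(seg.end_bp - pos[699]) <= w * 10_000
        # and agrees with the exhaustive enumeration oracle
        oracle = brute_force_roh(calls.tolist(), ["1"] * n, pos.tolist())
        assert [(s.chrom, s.start_bp, s.end_bp, s.n_snps) for s in segs] == oracle

    def test_short_run_fails_length_filter(self):
        """120 hom SNPs spanning ~0.8 Mb: passes min_snp, fails min_length."""
        calls = np.ones(400, dtype=np.int8)
        calls[100:220] = 0
        segs = _scan_lists(calls.tolist(), ["1"] * 400,
                           (np.arange(1, 401) * 6_700).tolist())
        assert segs == []

    def test_sparse_run_fails_density_filter(self):
        """150 hom SNPs at one per 60 kb: length passes, density 60 kb/SNP fails."""
        calls = np.zeros(150, dtype=np.int8)
        segs = _scan_lists(calls.tolist(), ["1"] * 150,
                           (np.arange(1, 151) * 60_000).tolist())
        assert segs == []

    def test_gap_splits_run(self):
        """A >1 Mb gap inside a homozygous run splits it; both halves detected."""
        pos = np.concatenate([np.arange(1, 151) * 10_000,
                              1_500_000 + 2_000_000 + np.arange(150) * 10_000])
        calls = np.zeros(300, dtype=np.int8)
        segs = _scan_lists(calls.tolist(), ["1"] * 300, pos.tolist())
        assert len(segs) == 2
        assert all(s.n_snps == 150 for s in segs)

    def test_chromosome_shorter_than_window(self):
        g = make_matrix(np.zeros((1, 30), dtype=np.int8))
        assert scan_individual(g.calls[0], g.markers) == []

    def test_segment_never_ends_on_het_or_missing(self):
        rng = np.random.default_rng(3)
        for seed in range(5):
            calls, chroms, positions = random_fixture(np.random.default_rng(seed))
            segs = _scan_lists(calls, chroms, positions)
            pos_map = {("%s" % c, p): v for c, p, v in zip(chroms, positions, calls)}
            for s in segs:
                assert pos_map[(s.chrom, s.start_bp)] in (0, 2)
                assert pos_map[(s.chrom, s.end_bp)] in (0, 2)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force(self, seed):
        calls, chroms, positions = random_fixture(np.random.default_rng(seed))
        segs = _scan_lists(calls, chroms, positions)
        oracle = brute_force_roh(calls, chroms, positions)
        assert [(s.chrom, s.start_bp, s.end_bp, s.n_snps) for s in segs] == oracle


class TestMonotonicity:
    @pytest.mark.parametrize("seed", [20, 21, 22])
    def test_min_length_and_het_tolerance(self, seed):
        calls, chroms, positions = random_fixture(np.random.default_rng(seed))
        base = _scan_lists(calls, chroms, positions, ScanParams())
        stricter_len = _scan_lists(calls, chroms, positions,
                                   ScanParams(min_length_bp=2_000_000))
        assert len(stricter_len) <= len(base)
        no_het = _scan_lists(calls, chroms, positions, ScanParams(window_het_max=0))
        assert sum(s.length_bp for s in no_het) <= sum(s.length_bp for s in base)


class TestScanPopulation:
    def test_identical_individuals_identical_segments(self):
        rng = np.random.default_rng(1)
        row = np.ones(600, dtype=np.int8)
        row[100:400] = rng.choice([0, 2], size=300)
        g = make_matrix(np.vstack([row, row]))
        segs = scan_population(g)
        a = [s for s in segs if s.sample == "I0"]
        b = [s for s in segs if s.sample == "I1"]
        assert [(s.chrom, s.start_bp, s.end_bp) for s in a] == \
               [(s.chrom, s.start_bp, s.end_bp) for s in b]

    def test_empty_cohort(self):
        g = make_matrix(np.empty((0, 200), dtype=np.int8))
        assert scan_population(g) == []


class TestClassify:
    def test_percent_column_matches_count_shares(self):
        segs = []
        mk = lambda mb, k: [ROHSegment(f"I{i}", "1", 1, 1 + int(mb * 1e6), 200)
                            for i in range(k)]
        segs = mk(2.32, 3) + mk(6.79, 2) + mk(15.38, 1)
        out = classify_segments(segs, n_individuals=6, genome_length_bp=100_000_000)
        assert list(out["count"]) == [3, 2, 1, 6]
        np.testing.assert_allclose(out["percent"], [50.0, 100 / 3, 100 / 6, 100.0])
        # coverage identity: total row equals the sum of the class rows
        assert out["coverage_percent"].iloc[-1] == pytest.approx(
            out["coverage_percent"].iloc[:-1].sum())

    def test_single_1mb_segment_in_first_class(self):
        segs = [ROHSegment("A", "1", 1_000_000, 2_000_000, 150)]
        out = classify_segments(segs, n_individuals=1, genome_length_bp=100_000_000)
        assert list(out["count"]) == [1, 0, 0, 1]
        assert out["percent"].iloc[0] == 100.0

    def test_sub_threshold_segment_rejected(self):
        segs = [ROHSegment("A", "1", 1, 500_000, 150)]
        with pytest.raises(ValueError, match="below the first class bound"):
            classify_segments(segs, n_individuals=1, genome_length_bp=1_000_000)


class TestPerChromosome:
    def test_planted_coverage(self):
        """10 individuals, one 5-Mb tract each on a 100-Mb chromosome: 5% coverage."""
        segs = [ROHSegment(f"I{i}", "1", 10_000_000, 15_000_000, 300) for i in range(10)]
        out = per_chromosome_summary(segs, {"1": 100_000_000, "2": 50_000_000}, 10)
        row1 = out[out["chrom"] == "1"].iloc[0]
        row2 = out[out["chrom"] == "2"].iloc[0]
        assert row1["count"] == 10 and row1["coverage_percent"] == pytest.approx(5.0)
        assert row2["count"] == 0 and row2["coverage_percent"] == 0.0

    def test_empty_input_all_zero(self):
        out = per_chromosome_summary([], {"1": 1_000_000}, 5)
        assert out["count"].sum() == 0
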