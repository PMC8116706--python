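"""Inbreeding estimators: pedigree recursion, F_ROH arithmetic, F_SNP, diversity."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from rohscan import (
    MISSING, GenotypeMatrix, MarkerMap, Pedigree, ROHSegment, DiversityStats,
    diversity, estimator_correlations, f_ped, f_roh, f_roh_table, f_snp, f_snp_all, ne,
)
from rohscan.inbreeding import correlation_report, summarize_estimators
from conftest import make_matrix
from _oracles import kinship_f


class TestFPed:
    def test_classical_values(self):
        ped = Pedigree([
            ("M", None, None), ("F", None, None),
            ("S1", "M", "F"), ("S2", "M", "F"),
            ("FS", "S1", "S2"),                       # full-sib offspring
            ("D2", None, None),
            ("H1", "M", "F"), ("H2", "M", "D2"),
            ("HS", "H1", "H2"),                       # half-sib offspring
            ("O", "M", "D2"),                         # unrelated founder parents
        ])
        f = f_ped(ped)
        assert f["FS"] == pytest.approx(0.25)
        assert f["HS"] == pytest.approx(0.125)
        assert f["O"] == 0.0
        assert f["M"] == 0.0

    def test_matches_kinship_oracle_exhaustively(self):
        """All pedigrees of <= 4 individuals where parents precede offspring."""
        n = 4
        ids = [f"I{k}" for k in range(n)]
        checked = 0
        for choices in itertools.product(*[
                list(itertools.product([None] + ids[:k], repeat=2)) for k in range(n)]):
            parents = {ids[k]: choices[k] for k in range(n)}
            if any(s is not None and s == d for s, d in parents.values()):
                continue  # selfing is not representable in a sire/dam pedigree
            ped = Pedigree([(i, *parents[i]) for i in ids])
            expected = kinship_f(parents)
            got = f_ped(ped)
            for i in ids:
                assert got[i] == pytest.approx(expected[i]), parents
            checked += 1
        assert checked == 273  # 576 parent assignments minus selfing cases

    def test_matches_kinship_oracle_random(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(5, 9))
            ids = [f"I{k}" for k in range(n)]
            parents = {}
            for k, ind in enumerate(ids):
                pool = [None] + ids[:k]
                s = pool[rng.integers(len(pool))]
                d = pool[rng.integers(len(pool))]
                if s is not None and s == d:
                    d = None
                parents[ind] = (s, d)
            ped = Pedigree([(i, *parents[i]) for i in ids])
            expected = kinship_f(parents)
            got = f_ped(ped)
            for i in ids:
                assert got[i] == pytest.approx(expected[i])


class TestFRoh:
    def test_no_segments_all_zero(self):
        total, comps = f_roh([], 1_000_000)
        assert total == 0.0 and comps == (0.0, 0.0, 0.0)

    def test_component_arithmetic(self):
        segs = [ROHSegment("A", "1", 1, 2_000_001, 150),
                ROHSegment("A", "2", 1, 6_000_001, 300),
                ROHSegment("A", "3", 1, 12_000_001, 500)]
        total, comps = f_roh(segs, 100_000_000)
        np.testing.assert_allclose(comps, (0.02, 0.06, 0.12))
        assert total == pytest.approx(0.20)

    def test_full_coverage_is_one(self):
        segs = [ROHSegment("A", "1", 1, 100_000_001, 999)]
        total, _ = f_roh(segs, 100_000_000)
        assert total == pytest.approx(1.0)

    def test_overlap_rejected(self):
        segs = [ROHSegment("A", "1", 1_000_000, 3_000_000, 150),
                ROHSegment("A", "1", 2_500_000, 5_000_000, 150)]
        with pytest.raises(ValueError, match="overlapping"):
            f_roh(segs, 100_000_000)

    def test_components_sum_exactly(self):
        rng = np.random.default_rng(5)
        segs = []
        start = 1
        for k in range(40):
            ln = int(rng.integers(1_000_000, 20_000_000))
            segs.append(ROHSegment("A", "1", start, start + ln, 200))
            start += ln + 10_000
        total, comps = f_roh(segs, 10_000_000_000)
        assert total == sum(comps)  # exact, by construction

    def test_table_covers_segment_free_samples(self):
        segs = [ROHSegment("A", "1", 1, 2_000_001, 150)]
        tab = f_roh_table(segs, ["A", "B"], 100_000_000)
        assert tab.loc["B", "F_ROH_all"] == 0.0
        assert tab.loc["A", "F_ROH_all"] == pytest.approx(0.02)


class TestFSnp:
    def test_all_homozygous_individual_f2_is_one(self):
        rng = np.random.default_rng(2)
        calls = rng.integers(0, 3, size=(20, 50)).astype(np.int8)
        calls[0] = np.where(calls[0] == 1, 2, calls[0])  # make individual 0 all-hom
        g = make_matrix(calls)
        assert f_snp(g, 2).iloc[0] == pytest.approx(1.0)

    def test_single_snp_direct_substitution(self):
        # cohort 0,1,1,2 -> p=0.5, h=0.5; het individual: F2 = 1 - 1/0.5 = -1
        g = make_matrix(np.array([[0], [1], [1], [2]], dtype=np.int8))
        f2 = f_snp(g, 2)
        assert f2.iloc[1] == pytest.approx(-1.0)
        # hom-alt individual: F1 = (2-1)^2/0.5 - 1 = 1
        f1 = f_snp(g, 1)
        assert f1.iloc[3] == pytest.approx(1.0)

    def test_hwe_null_means_near_zero(self):
        """Cohort simulated under HWE: each estimator's mean within 3 SE of 0."""
        rng = np.random.default_rng(42)
        n, m = 200, 2000
        p = rng.uniform(0.05, 0.5, size=m)
        calls = rng.binomial(2, p, size=(n, m)).astype(np.int8)
        g = make_matrix(calls)
        tab = f_snp_all(g)
        for col in tab:
            mean = tab[col].mean()
            se = tab[col].std(ddof=1) / np.sqrt(n)
            assert abs(mean) < 3 * se, f"{col}: mean {mean:.4f}, SE {se:.4f}"

    def test_missing_calls_reduce_n_not_imputed(self):
        g_full = make_matrix(np.array([[0, 0], [1, 1], [1, 1], [2, 2]], dtype=np.int8))
        calls = np.array([[0, MISSING], [1, 1], [1, 1], [2, 2]], dtype=np.int8)
        g_miss = make_matrix(calls)
        # individual 0 now has only SNP 0 usable; value equals the 1-SNP estimate
        p0 = g_miss.allele_freq()[0]
        h0 = 2 * p0 * (1 - p0)
        assert f_snp(g_miss, 1).iloc[0] == pytest.approx((0 - 2 * p0) ** 2 / h0 - 1)

    def test_no_usable_snps_flagged(self):
        calls = np.array([[MISSING, MISSING], [0, 1], [1, 1], [2, 0]], dtype=np.int8)
        g = make_matrix(calls)
        with pytest.warns(UserWarning, match="no usable SNPs"):
            tab = f_snp_all(g)
        assert np.isnan(tab.iloc[0]).all()


class TestDiversity:
    def test_all_het_ho_is_one(self):
        g = make_matrix(np.ones((6, 20), dtype=np.int8))
        assert diversity(g).ho == pytest.approx(1.0)

    def test_he_half_at_balanced_snp(self):
        g = make_matrix(np.array([[0], [2], [1], [1]], dtype=np.int8))
        assert diversity(g).he == pytest.approx(0.5)

    def test_ne_formulas(self):
        assert ne(17, 76) == pytest.approx(16 * 17 * 76 / 93)
        assert ne(17, 76) == pytest.approx(222.28, abs=0.005)
        assert ne(17, 76, classical=True) == pytest.approx(4 * 17 * 76 / 93)
        with pytest.raises(ValueError):
            ne(0, 10)


class TestCorrelations:
    def test_self_and_negation(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=30)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": -x})
        r, p = estimator_correlations(df)
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert r.loc["a", "c"] == pytest.approx(-1.0)
        assert p.loc["a", "b"] < 1e-10

    def test_zero_variance_flagged(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [1.0, 1.0, 1.0, 1.0]})
        with pytest.warns(UserWarning, match="zero variance"):
            r, _ = estimator_correlations(df)
        assert np.isnan(r.loc["a", "b"])

    def test_report_stars_and_summary(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=50)
        df = pd.DataFrame({"a": x, "b": x + rng.normal(scale=0.1, size=50)})
        rep = correlation_report(df)
        assert rep.loc["b", "a"].endswith("**")
        summ = summarize_estimators(df)
        assert set(summ.columns) == {"mean", "min", "max", "sd"}
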