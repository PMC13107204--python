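import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from scisoqtl import enrich
from scisoqtl.models import GenomicInterval


class TestLdPrune:
    def test_duplicated_column_one_kept(self):
        rng = np.random.default_rng(1)
        g = rng.binomial(2, 0.3, 100).astype(float)
        df = pd.DataFrame({"v1": g, "v2": g, "v3": rng.binomial(2, 0.3, 100)})
        kept = enrich.ld_prune(df)
        assert kept == ["v1", "v3"]

    def test_orthogonal_variants_all_kept(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {f"v{k}": rng.binomial(2, 0.3, 500).astype(float) for k in range(8)}
        )
        assert enrich.ld_prune(df) == list(df.columns)

    def test_three_variant_chain_hand_trace(self):
        # construct r2(1,2)~0.5, r2(1,3)~0, r2(2,3)~0.5: greedy drops v2 only
        rng = np.random.default_rng(3)
        n = 4000
        a = rng.normal(0, 1, n)
        c = rng.normal(0, 1, n)
        b = (a + c) / np.sqrt(2) + rng.normal(0, 0.05, n)
        df = pd.DataFrame({"v1": a, "v2": b, "v3": c})
        r12 = np.corrcoef(a, b)[0, 1] ** 2
        r13 = np.corrcoef(a, c)[0, 1] ** 2
        assert r12 > 0.4 and r13 < 0.05  # fixture sanity
        assert enrich.ld_prune(df) == ["v1", "v3"]

    def test_invariant_to_duplicating_kept_variant(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            {f"v{k}": rng.binomial(2, 0.3, 300).astype(float) for k in range(5)}
        )
        kept = enrich.ld_prune(df)
        df2 = df.copy()
        df2["dup"] = df[kept[0]]
        kept2 = enrich.ld_prune(df2)
        assert kept2 == kept  # the duplicate is removed


class TestContingency:
    def test_printed_rare_allele_example(self):
        res = enrich.contingency_test(
            np.array([[158, 1161], [103, 1231]]), method="chi2_yates"
        )
        assert res.p == pytest.approx(2.987e-4, rel=1e-3)

    def test_balanced_table_null(self):
        res = enrich.contingency_test(np.array([[10, 10], [10, 10]]))
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_chi2_equals_classical_formula(self):
        t = np.array([[12, 30], [45, 13]], dtype=float)
        res = enrich.contingency_test(t, method="chi2")
        rows, cols = t.sum(axis=1), t.sum(axis=0)
        E = np.outer(rows, cols) / t.sum()
        expected = ((t - E) ** 2 / E).sum()
        assert res.statistic == pytest.approx(expected, abs=1e-12)

    def test_fisher_matches_hypergeometric_enumeration(self):
        t = np.array([[3, 1], [1, 3]])
        res = enrich.contingency_test(t, method="fisher")
        # enumerate all tables with the same margins; two-sided = sum of
        # probabilities <= that of the observed table
        n, K, N = 4, 4, 8  # row1 total, col1 total, grand total
        probs = {
            a: st.hypergeom.pmf(a, N, K, n) for a in range(max(0, n + K - N), min(n, K) + 1)
        }
        obs = probs[3]
        expected = sum(p for p in probs.values() if p <= obs + 1e-12)
        assert res.p == pytest.approx(expected, abs=1e-10)

    def test_zero_margin_null_report(self):
        res = enrich.contingency_test(np.array([[0, 0], [5, 7]]))
        assert res.p == 1.0 and res.odds_ratio is None

    def test_swapping_groups_inverts_odds_ratio(self):
        t = np.array([[20, 5], [8, 30]])
        a = enrich.contingency_test(t)
        b = enrich.contingency_test(t[::-1])
        assert a.odds_ratio == pytest.approx(1 / b.odds_ratio)


class TestSjs:
    def _windows(self):
        # intron 201-299: windows 201-202 and 298-299
        return [
            GenomicInterval("chr1", 201, 202),
            GenomicInterval("chr1", 298, 299),
        ]

    def test_first_intron_base_flagged(self):
        variants = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "pos": [201, 203]}, index=["in", "out"]
        )
        counts = pd.Series({"in": 2, "out": 1})
        flags, _ = enrich.classify_sjs(variants, self._windows(), counts)
        assert bool(flags["in"]) and not bool(flags["out"])

    def test_three_bp_into_intron_not_flagged(self):
        variants = pd.DataFrame({"chrom": ["chr1"], "pos": [203]}, index=["v"])
        flags, _ = enrich.classify_sjs(variants, self._windows(), pd.Series({"v": 1}))
        assert not flags["v"]

    def test_multi_isoform_cell_populated(self):
        variants = pd.DataFrame(
            {"chrom": ["chr1"] * 3, "pos": [201, 298, 500]}, index=["a", "b", "c"]
        )
        counts = pd.Series({"a": 2, "b": 1, "c": 1})
        flags, res = enrich.classify_sjs(variants, self._windows(), counts)
        assert flags.sum() == 2

    def test_empty_windows_all_false(self):
        variants = pd.DataFrame({"chrom": ["chr1"], "pos": [201]}, index=["v"])
        flags, res = enrich.classify_sjs(variants, [], pd.Series({"v": 3}))
        assert not flags.any() and res.p == 1.0


class TestIntervalEnrichment:
    def test_category_covering_everything_is_null(self):
        q = pd.DataFrame({"chrom": "chr1", "pos": [10, 20]}, index=["a", "b"])
        bg = pd.DataFrame({"chrom": "chr1", "pos": [30, 40]}, index=["c", "d"])
        cover = {"all": [GenomicInterval("chr1", 1, 100)]}
        df = enrich.interval_enrichment(q, cover, bg)
        assert df["p"].iloc[0] == pytest.approx(1.0)

    def test_query_only_category_infinite_or(self):
        q = pd.DataFrame({"chrom": "chr1", "pos": [10, 12]}, index=["a", "b"])
        bg = pd.DataFrame({"chrom": "chr1", "pos": [500, 600]}, index=["c", "d"])
        cat = {"hot": [GenomicInterval("chr1", 5, 20)]}
        df = enrich.interval_enrichment(q, cat, bg)
        assert np.isinf(df["odds_ratio"].iloc[0])

    def test_planted_enrichment_detected(self):
        rng = np.random.default_rng(5)
        n = 500
        qpos = np.where(rng.random(n) < 0.5, rng.integers(1, 100, n),
                        rng.integers(1000, 5000, n))
        bpos = np.where(rng.random(n) < 0.05, rng.integers(1, 100, n),
                        rng.integers(1000, 5000, n))
        q = pd.DataFrame({"chrom": "chr1", "pos": qpos})
        bg = pd.DataFrame({"chrom": "chr1", "pos": bpos})
        cat = {"m": [GenomicInterval("chr1", 1, 100)]}
        df = enrich.interval_enrichment(q, cat, bg)
        assert df["adjusted_p"].iloc[0] < 0.05


class TestPopulationSpecificity:
    def _ld(self, vals):
        ids = sorted({i for pair in vals for i in pair})
        m = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
        for (a, b), r in vals.items():
            m.loc[a, b] = m.loc[b, a] = r
        return m

    def test_rare_panel_maf_restricted(self):
        ld = self._ld({("v1", "r1"): 0.0})
        df = enrich.population_specificity(
            ["v1"], pd.Series({"v1": 0.009}), ["r1"], ld
        ).set_index("variant")
        assert bool(df.loc["v1", "population_restricted"])

    def test_moderate_ld_with_replication_not_independent(self):
        ld = self._ld({("v1", "r1"): 0.15})
        df = enrich.population_specificity(
            ["v1"], pd.Series({"v1": 0.2}), ["r1"], ld
        ).set_index("variant")
        assert not bool(df.loc["v1", "independent_signal"])

    def test_high_ld_leads_collapsed(self):
        ld = self._ld({("v1", "v2"): 0.9})
        df = enrich.population_specificity(
            ["v1", "v2"], pd.Series({"v1": 0.2, "v2": 0.2}), [], ld
        )
        assert list(df["variant"]) == ["v1"]

    def test_missing_frequency_is_monomorphic_independent(self):
        ld = self._ld({("v1", "r1"): 0.9})
        df = enrich.population_specificity(
            ["v1"], pd.Series(dtype=float), ["r1"], ld
        ).set_index("variant")
        assert bool(df.loc["v1", "monomorphic"])
        assert bool(df.loc["v1", "independent_signal"])


class TestPromoterOverlap:
    def test_alternative_tss_only_flagged(self):
        tss = {"iso1": ("chr1", 10_000)}
        canonical = [("chr1", 50_000)]
        peak = GenomicInterval("chr1", 9_500, 10_500)
        out = enrich.promoter_overlap(tss, [peak], canonical)
        assert out == [("iso1", peak)]

    def test_peak_spanning_both_not_flagged(self):
        tss = {"iso1": ("chr1", 10_000)}
        canonical = [("chr1", 12_000)]
        peak = GenomicInterval("chr1", 9_500, 11_000)  # within 2 kb of both
        assert enrich.promoter_overlap(tss, [peak], canonical) == []

    def test_no_peaks_no_flags(self):
        assert enrich.promoter_overlap({"i": ("chr1", 5)}, [], [("chr1", 5)]) == []
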