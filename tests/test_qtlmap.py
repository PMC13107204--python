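import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from scisoqtl import cellops, qtlmap, syndata


class TestNbGlm:
    def test_intercept_only_closed_form(self):
        fit = qtlmap.fit_nb_glm(np.array([5.0, 5, 5, 5]), np.ones((4, 1)))
        assert fit.coef[0] == pytest.approx(np.log(5), abs=1e-6)
        assert fit.alpha < 1e-6  # Poisson limit on equidispersed data

    def test_poisson_oracle_agreement(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        n = 500
        g = rng.binomial(2, 0.3, n).astype(float)
        X = np.column_stack([np.ones(n), g])
        y = rng.poisson(np.exp(1.0 + 0.5 * g)).astype(float)
        fit = qtlmap.fit_nb_glm(y, X)
        oracle = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert np.abs(fit.coef - oracle.params).max() < 1e-2

    def test_nb_oracle_agreement_overdispersed(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        n = 600
        g = rng.binomial(2, 0.4, n).astype(float)
        X = np.column_stack([np.ones(n), g])
        mu = np.exp(2.0 + 0.4 * g)
        alpha = 0.5
        y = rng.poisson(rng.gamma(1 / alpha, mu * alpha)).astype(float)
        fit = qtlmap.fit_nb_glm(y, X)
        oracle = sm.GLM(
            y, X, family=sm.families.NegativeBinomial(alpha=fit.alpha)
        ).fit()
        assert np.abs(fit.coef - oracle.params).max() < 1e-4
        assert fit.alpha == pytest.approx(alpha, rel=0.3)

    def test_collinear_design_errors(self):
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(ValueError, match="collinear"):
            qtlmap.fit_nb_glm(np.arange(10, dtype=float), X)

    def test_offset_shifts_intercept(self):
        y = np.full(6, 8.0)
        off = np.log(np.full(6, 2.0))
        fit = qtlmap.fit_nb_glm(y, np.ones((6, 1)), offset=off)
        assert fit.coef[0] == pytest.approx(np.log(4), abs=1e-6)


class TestScoreScan:
    def _null_inputs(self, n=80, m=60, seed=3):
        rng = np.random.default_rng(seed)
        G = rng.binomial(2, 0.3, (n, m)).astype(float)
        y = rng.poisson(5.0, n).astype(float)
        return y, G

    def test_null_score_p_uniform(self):
        y, G = self._null_inputs()
        X0 = qtlmap.add_intercept(None, len(y))
        fit = qtlmap.fit_nb_glm(y, X0)
        ns = qtlmap._null_state(fit, y, X0)
        ps = []
        rng = np.random.default_rng(4)
        for _ in range(20):
            ps.extend(qtlmap._score_pvalues(G[rng.permutation(len(y))], ns))
        assert st.kstest(ps, "uniform").pvalue > 0.01

    def test_score_and_wald_agree_in_magnitude(self):
        rng = np.random.default_rng(5)
        n = 150
        g = rng.binomial(2, 0.3, n).astype(float)
        y = rng.poisson(np.exp(1.5 + 0.2 * g)).astype(float)
        res = qtlmap.scan_isoform(
            y, None, np.zeros(n), g[:, None], ["v"], n_perm=0
        )
        assert abs(np.log10(res["nominal_p"]) - np.log10(res["wald_p"])) < 1

    def test_window_inclusive_both_ends(self):
        variants = pd.DataFrame(
            {"chrom": ["chr1"] * 3, "pos": [1_000_000, 3_000_000, 3_000_001]},
            index=["a", "b", "c"],
        )
        mask = qtlmap.cis_variant_mask(variants, "chr1", 2_000_000, 1_000_000)
        assert list(mask) == [True, True, False]


class TestPermutationCalibration:
    def test_beta_one_m_limit_for_independent_variants(self):
        # min of M independent uniforms is Beta(1, M)
        rng = np.random.default_rng(6)
        M = 20
        mins = rng.uniform(size=(2000, M)).min(axis=1)
        cal = qtlmap.calibrate_permutations(0.01, mins, len(mins))
        assert cal.k == pytest.approx(1.0, rel=0.1)
        assert cal.n == pytest.approx(M, rel=0.15)
        direct = 1 - (1 - 0.01) ** M
        assert cal.adjusted_p == pytest.approx(direct, rel=0.1)

    def test_observed_min_p_one_gives_adjusted_one(self):
        rng = np.random.default_rng(7)
        mins = rng.beta(1, 10, 500)
        cal = qtlmap.calibrate_permutations(1.0, mins, 500)
        assert cal.adjusted_p == pytest.approx(1.0)

    def test_adjusted_p_monotone_in_observed(self):
        rng = np.random.default_rng(8)
        mins = rng.beta(1, 30, 400)
        obs = np.linspace(1e-5, 0.5, 20)
        adj = [qtlmap.calibrate_permutations(o, mins, 400).adjusted_p for o in obs]
        assert all(a <= b + 1e-12 for a, b in zip(adj, adj[1:]))

    def test_degenerate_sample_falls_back_to_rank(self):
        mins = np.full(200, 0.3)
        cal = qtlmap.calibrate_permutations(0.1, mins, 200)
        assert cal.degenerate
        assert cal.adjusted_p == pytest.approx(1 / 201)

    def test_too_few_permutations_error(self):
        with pytest.raises(ValueError, match="100"):
            qtlmap.calibrate_permutations(0.1, np.random.uniform(size=50), 50)


class TestStoreyFdr:
    def test_uniform_pvalues_pi0_near_one(self):
        rng = np.random.default_rng(9)
        ps = rng.uniform(size=10_000)
        fdr = qtlmap.storey_fdr(ps)
        assert 0.9 <= fdr.pi0 <= 1.0

    def test_all_tiny_p_all_significant(self):
        ps = np.full(200, 1e-8)
        fdr = qtlmap.storey_fdr(ps)
        assert (fdr.qvalues <= 1e-7).all()

    def test_single_p_fallback(self):
        fdr = qtlmap.storey_fdr(np.array([0.5]))
        assert fdr.qvalues[0] == pytest.approx(0.5)

    def test_qvalues_monotone_in_p(self):
        rng = np.random.default_rng(10)
        ps = rng.uniform(size=500)
        fdr = qtlmap.storey_fdr(ps)
        order = np.argsort(ps)
        assert (np.diff(fdr.qvalues[order]) >= -1e-12).all()

    def test_out_of_range_p_errors(self):
        with pytest.raises(ValueError):
            qtlmap.storey_fdr(np.array([0.5, 1.5]))


class TestNominalThresholds:
    def _calib(self, k, n):
        return qtlmap.PermutationCalibration(
            k=k, n=n, n_perm=1000, min_p_sample=np.array([0.1]),
            observed_min_p=0.01, adjusted_p=float(st.beta.cdf(0.01, k, n)),
        )

    def test_shared_beta_params_identical_thresholds(self):
        cals = [self._calib(1.0, 50.0) for _ in range(5)]
        fdr = qtlmap.storey_fdr(np.array([c.adjusted_p for c in cals]))
        thr = qtlmap.nominal_thresholds(cals, fdr)
        assert np.allclose(thr, thr[0])

    def test_inverse_identity(self):
        cals = [self._calib(1.2, 80.0), self._calib(0.9, 40.0)]
        fdr = qtlmap.storey_fdr(np.array([c.adjusted_p for c in cals]))
        thr = qtlmap.nominal_thresholds(cals, fdr)
        p0 = cals[np.argmin(np.abs(fdr.qvalues - 0.05))].adjusted_p
        for c, t in zip(cals, thr):
            assert st.beta.cdf(t, c.k, c.n) == pytest.approx(p0, abs=1e-10)

    def test_closest_to_level_rule(self):
        # adjusted p 0.049 has q-value closest to 0.05
        cals = []
        for adj in (0.01, 0.049, 0.2):
            c = self._calib(1.0, 30.0)
            c.adjusted_p = adj
            cals.append(c)
        fdr = qtlmap.FdrSummary(
            pi0=1.0, qvalues=np.array([0.01, 0.05, 0.2]), level=0.05
        )
        thr = qtlmap.nominal_thresholds(cals, fdr)
        assert st.beta.cdf(thr[0], 1.0, 30.0) == pytest.approx(0.049, abs=1e-10)


class TestProportionQtl:
    def test_proportions_sum_to_one_and_level(self):
        rng = np.random.default_rng(11)
        counts = pd.DataFrame(
            rng.poisson(10, (40, 4)),
            index=[f"i{k}" for k in range(40)],
            columns=list("abcd"),
        )
        dosage = pd.Series(rng.binomial(2, 0.3, 40).astype(float), index=counts.index)
        out = qtlmap.proportion_qtl(counts, dosage)
        assert out["bonferroni_level"].iloc[0] == pytest.approx(0.0125)
        props = counts.div(counts.sum(axis=1), axis=0)
        np.testing.assert_allclose(props.sum(axis=1), 1.0)

    def test_zero_total_individual_dropped(self):
        rng = np.random.default_rng(13)
        counts = pd.DataFrame(
            rng.poisson(6, (10, 2)) + 1, index=[f"i{k}" for k in range(10)],
            columns=["a", "b"],
        )
        counts.iloc[3] = 0  # this individual has no gene counts
        dosage = pd.Series(
            rng.binomial(2, 0.4, 10).astype(float), index=counts.index
        )
        out = qtlmap.proportion_qtl(counts, dosage)
        assert len(out) == 2  # both isoforms tested, i3 dropped internally

    def test_reciprocal_pair_opposite_proportion_signs(self):
        rng = np.random.default_rng(12)
        n = 150
        d = rng.binomial(2, 0.4, n).astype(float)
        a = rng.poisson(np.exp(2.0 + 0.6 * d))
        b = rng.poisson(np.exp(2.0 - 0.6 * d))
        counts = pd.DataFrame({"a": a, "b": b}, index=[f"i{k}" for k in range(n)])
        dosage = pd.Series(d, index=counts.index)
        out = qtlmap.proportion_qtl(counts, dosage).set_index("isoform")
        assert out.loc["a", "beta"] > 0 > out.loc["b", "beta"]
        assert out["significant"].all()


class TestMapCellType:
    def test_planted_effect_recovered(self, small_cohort):
        sc = small_cohort
        pb = cellops.filter_isoforms(cellops.pseudobulk(sc["cells"], "typeA"))
        df = qtlmap.map_cell_type(
            pb, sc["genotypes"], sc["tss"], n_perm=200, seed=1
        )
        rec = df.set_index("isoform").loc[sc["planted_isoform"]]
        assert rec["qvalue"] < 0.05
        assert rec["beta"] > 0

    def test_seed_reproducible(self, small_cohort):
        sc = small_cohort
        pb = cellops.filter_isoforms(cellops.pseudobulk(sc["cells"], "typeA"))
        a = qtlmap.map_cell_type(pb, sc["genotypes"], sc["tss"], n_perm=150, seed=2)
        b = qtlmap.map_cell_type(pb, sc["genotypes"], sc["tss"], n_perm=150, seed=2)
        pd.testing.assert_frame_equal(a, b)

    def test_linear_mode_agrees_on_strong_effect(self, small_cohort):
        sc = small_cohort
        pb = cellops.filter_isoforms(cellops.pseudobulk(sc["cells"], "typeA"))
        nb = qtlmap.map_cell_type(pb, sc["genotypes"], sc["tss"], n_perm=150, seed=3)
        lin = qtlmap.map_cell_type(
            pb, sc["genotypes"], sc["tss"], n_perm=150, seed=3, mode="linear"
        )
        nb_lead = nb.set_index("isoform").loc[sc["planted_isoform"], "lead_variant"]
        lin_lead = lin.set_index("isoform").loc[sc["planted_isoform"], "lead_variant"]
        # leads may differ within an LD block; betas must agree in sign
        assert lin.set_index("isoform").loc[sc["planted_isoform"], "beta"] > 0
        assert nb_lead in sc["genotypes"].dosages.columns
        assert lin_lead in sc["genotypes"].dosages.columns

    def test_nb_and_linear_modes_concordant_on_strong_effects(self):
        """On well-powered planted effects the NB and linear scans agree on
        the lead variant for at least 70% of effects discovered by both,
        with fully consistent effect signs."""
        from scisoqtl import syndata

        gt = syndata.simulate_genotypes(
            80, 200, maf_range=(0.2, 0.4), ld_block=5, flip_prob=0.15, seed=21
        )
        models, _, _ = syndata.simulate_transcriptome(30, 2, seed=22, gene_spacing=4000)
        ibg = {}
        for m in models:
            ibg.setdefault(m.gene_id, []).append(m.transcript_id)
        weights = syndata.default_usage_weights(
            ibg, ("t",), np.random.default_rng(23)
        )
        tssmap = {m.transcript_id: m.tss for m in models}
        pos = gt.variants["pos"]
        effects = [
            syndata.PlantedEffect(
                g, isos[0], (pos - tssmap[isos[0]]).abs().idxmin(), ("t",),
                0.8 if k % 2 == 0 else -0.8,
            )
            for k, (g, isos) in enumerate(list(ibg.items())[:15])
        ]
        design = syndata.EffectDesign(
            cell_types=("t",), effects=effects, usage_weights=weights
        )
        cohort = syndata.simulate_cells(gt, models, design, seed=24)
        pb = cellops.filter_isoforms(cellops.pseudobulk(cohort, "t"))
        tss = pd.DataFrame(
            {"chrom": [m.chrom for m in models], "tss": [m.tss for m in models]},
            index=[m.transcript_id for m in models],
        )
        cov = cellops.build_covariates(pb)
        nb = qtlmap.map_cell_type(
            pb, gt, tss, covariates=cov, n_perm=300, seed=25
        ).set_index("isoform")
        lin = qtlmap.map_cell_type(
            pb, gt, tss, covariates=cov, n_perm=300, seed=25, mode="linear"
        ).set_index("isoform")
        truth = {e.isoform: e.beta for e in effects}
        both = [
            i for i in truth
            if i in nb.index and i in lin.index
            and nb.loc[i, "eisoform"] and lin.loc[i, "eisoform"]
        ]
        assert len(both) >= 8  # well-powered design
        lead_agree = np.mean(
            [nb.loc[i, "lead_variant"] == lin.loc[i, "lead_variant"] for i in both]
        )
        sign_agree = np.mean(
            [np.sign(nb.loc[i, "beta"]) == np.sign(lin.loc[i, "beta"]) for i in both]
        )
        assert lead_agree >= 0.7
        assert sign_agree == 1.0

    def test_linear_mode_uniform_p_on_permuted_data(self):
        """The linear scan's nominal p-values are uniform when the genotype
        linkage is destroyed."""
        rng = np.random.default_rng(31)
        n, m = 100, 50
        G = rng.binomial(2, 0.3, (n, m)).astype(float)
        ps = []
        for _ in range(10):
            y = rng.normal(0, 1, n)
            res = qtlmap.scan_isoform_linear(y, None, G, [f"v{i}" for i in range(m)], n_perm=0)
            ps.extend(res["pvalues"])
        assert st.kstest(ps, "uniform").pvalue > 0.01

    def test_audit_seed_reproducible(self, small_cohort):
        sc = small_cohort
        pb = cellops.filter_isoforms(cellops.pseudobulk(sc["cells"], "typeA"))
        a = qtlmap.typeI_audit(pb, sc["genotypes"], sc["tss"], n_perm=120, seed=4)
        b = qtlmap.typeI_audit(pb, sc["genotypes"], sc["tss"], n_perm=120, seed=4)
        assert a["pi0"] == b["pi0"]
        pd.testing.assert_frame_equal(a["records"], b["records"])
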