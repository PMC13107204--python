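"""Self-contained benchmark studies over the synthetic cohort generator.

Each function builds its own inputs from :mod:`scisoqtl.syndata`, runs the
relevant pipeline stage(s), and returns the headline numbers.  The studies
double as calibration/recovery checks for the test suite and as the
quantities recomputed by ``scripts/acceptance.py``.

Problem sizes are desk-scale by design: cohorts of 50-100 individuals,
hundreds of cis variants and isoforms, 1,000 permutations per isoform.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats as st

from . import annotate, cellops, colocal, crosscell, diffexp, enrich, qtlmap, syndata
from .models import GenomicInterval, PseudobulkMatrix, TranscriptModel

# ---------------------------------------------------------------------------
# Shared cohort builder
# ---------------------------------------------------------------------------


def build_cohort(
    n_individuals: int,
    n_genes: int,
    isoforms_per_gene: int,
    n_variants: int,
    seed: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    planted: list[syndata.PlantedEffect] | None = None,
    cell_types: tuple[str, ...] = ("typeA",),
    gene_spacing: int = 4_000,
    **design_kwargs,
):
    """Genotypes, transcript models and single-cell counts for one study.

    Genes are laid inside the genotyped span so every isoform has cis
    variants within the 1-Mb window.  Returns (genotypes, models, design,
    cells, tss table).
    """
    rng = np.random.default_rng(seed)
    gt = syndata.simulate_genotypes(
        n_individuals, n_variants, maf_range=maf_range, ld_block=5,
        flip_prob=0.15, seed=int(rng.integers(2**31)),
    )
    models, _, _ = syndata.simulate_transcriptome(
        n_genes, isoforms_per_gene, seed=int(rng.integers(2**31)),
        start_pos=1_050_000, gene_spacing=gene_spacing,
    )
    isoforms_by_gene: dict[str, list[str]] = {}
    for m in models:
        isoforms_by_gene.setdefault(m.gene_id, []).append(m.transcript_id)
    weights = syndata.default_usage_weights(
        isoforms_by_gene, cell_types, np.random.default_rng(int(rng.integers(2**31)))
    )
    design = syndata.EffectDesign(
        cell_types=cell_types,
        effects=planted or [],
        usage_weights=weights,
        **design_kwargs,
    )
    cells = syndata.simulate_cells(gt, models, design, seed=int(rng.integers(2**31)))
    tss = pd.DataFrame(
        {"chrom": [m.chrom for m in models], "tss": [m.tss for m in models]},
        index=[m.transcript_id for m in models],
    )
    return gt, models, design, cells, tss


def _map_one_type(gt, cells, tss, cell_type: str, n_perm: int, seed: int):
    pb = cellops.filter_isoforms(cellops.pseudobulk(cells, cell_type))
    cov = cellops.build_covariates(pb)
    return qtlmap.map_cell_type(
        pb, gt, tss, covariates=cov, n_perm=n_perm, seed=seed
    ), pb, cov


# ---------------------------------------------------------------------------
# Studies
# ---------------------------------------------------------------------------


def worked_contingency() -> dict:
    """Chi-squared with continuity correction on the rare-allele 2x2
    (158/1,319 population-restricted leads among dataset-specific genes vs
    103/1,334 among replicated ones)."""
    table = np.array([[158, 1319 - 158], [103, 1334 - 103]])
    res = enrich.contingency_test(table, method="chi2_yates")
    return {"p": res.p, "statistic": res.statistic, "odds_ratio": res.odds_ratio}


def null_calibration_study(seed: int, n_perm: int = 1000) -> dict:
    """All-null cohort (50 individuals, 200 isoforms, 500 cis variants):
    count-shuffling audit pi0 and the fraction of isoforms with
    beta-approximated p below 1e-5."""
    gt, models, design, cells, tss = build_cohort(
        n_individuals=50, n_genes=100, isoforms_per_gene=2, n_variants=500,
        seed=seed,
    )
    pb = cellops.filter_isoforms(cellops.pseudobulk(cells, "typeA"))
    cov = cellops.build_covariates(pb)
    audit = qtlmap.typeI_audit(
        pb, gt, tss, covariates=cov, n_perm=n_perm, seed=seed + 1
    )
    return {
        "pi0": audit["pi0"],
        "frac_strong_pct": 100.0 * audit["frac_strong"],
        "n_isoforms": audit["n_isoforms"],
    }


def calibration_oracle_study(seed: int, n_perm_direct: int = 10_000) -> dict:
    """Beta-approximated adjusted p vs the direct empirical permutation p at
    10,000 permutations on one null locus; gap reported in Monte-Carlo SEs."""
    gt, models, design, cells, tss = build_cohort(
        n_individuals=50, n_genes=2, isoforms_per_gene=1, n_variants=200,
        seed=seed,
    )
    pb = cellops.filter_isoforms(cellops.pseudobulk(cells, "typeA"))
    iso = pb.isoforms[0]
    y = pb.counts[iso].to_numpy(dtype=float)
    offset = np.log(np.maximum(pb.library_sizes().astype(float), 1.0))
    G = gt.dosages.loc[pb.counts.index].to_numpy(dtype=float)
    vids = list(gt.variants.index)
    rng = np.random.default_rng(seed + 7)
    # both sides at the same 10,000-permutation resolution so the gap is
    # measured against comparable Monte-Carlo noise
    res = qtlmap.scan_isoform(
        y, None, offset, G, vids, n_perm=n_perm_direct, rng=rng
    )
    beta_adj = res["calibration"].adjusted_p
    # direct empirical permutation p at high resolution
    X0 = qtlmap.add_intercept(None, len(y))
    null_fit = qtlmap.fit_nb_glm(y, X0, offset)
    ns = qtlmap._null_state(null_fit, y, X0)
    rng2 = np.random.default_rng(seed + 8)
    mins = np.empty(n_perm_direct)
    done = 0
    while done < n_perm_direct:
        b = min(500, n_perm_direct - done)
        perms = np.stack([rng2.permutation(len(y)) for _ in range(b)])
        mins[done : done + b] = qtlmap._score_min_p_perms(G, ns, perms)
        done += b
    obs = res["nominal_p"]
    p_emp = (1 + np.sum(mins <= obs)) / (n_perm_direct + 1)
    se_emp = float(np.sqrt(p_emp * (1 - p_emp) / n_perm_direct))
    # Monte-Carlo SE of the Beta-calibrated p itself: delta method on the
    # Beta MLE (inverse Fisher information / N), so the gap is measured
    # against the noise of the difference of two Monte-Carlo estimates
    cal = res["calibration"]
    from scipy.special import polygamma

    k, nn = cal.k, cal.n
    N = cal.n_perm
    tri_k, tri_n, tri_kn = polygamma(1, k), polygamma(1, nn), polygamma(1, k + nn)
    info = N * np.array([[tri_k - tri_kn, -tri_kn], [-tri_kn, tri_n - tri_kn]])
    cov = np.linalg.inv(info)
    eps = 1e-5
    grad = np.array([
        (st.beta.cdf(obs, k + eps, nn) - st.beta.cdf(obs, k - eps, nn)) / (2 * eps),
        (st.beta.cdf(obs, k, nn + eps) - st.beta.cdf(obs, k, nn - eps)) / (2 * eps),
    ])
    se_beta = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
    mc_se = float(np.sqrt(se_emp**2 + se_beta**2))
    gap_se = abs(beta_adj - p_emp) / mc_se if mc_se > 0 else np.inf
    return {
        "beta_adjusted_p": float(beta_adj),
        "empirical_p": float(p_emp),
        "mc_se": mc_se,
        "gap_in_se": float(gap_se),
    }


def recovery_study(seed: int, n_perm: int = 1000) -> dict:
    """Planted-effect recovery: |beta| = 0.8 (alternating sign), causal MAF
    about 0.3, 100 individuals; sensitivity at FDR 0.05 and sign accuracy
    among discovered planted effects."""
    n_genes = 80
    rng = np.random.default_rng(seed)
    gt = syndata.simulate_genotypes(
        100, 400, maf_range=(0.25, 0.35), ld_block=5, flip_prob=0.15,
        seed=int(rng.integers(2**31)),
    )
    models, _, _ = syndata.simulate_transcriptome(
        n_genes, 2, seed=int(rng.integers(2**31)), gene_spacing=4_000
    )
    isoforms_by_gene: dict[str, list[str]] = {}
    for m in models:
        isoforms_by_gene.setdefault(m.gene_id, []).append(m.transcript_id)
    tssmap = {m.transcript_id: m.tss for m in models}
    weights = syndata.default_usage_weights(
        isoforms_by_gene, ("typeA",), np.random.default_rng(int(rng.integers(2**31)))
    )
    effects = []
    pos = gt.variants["pos"]
    for k, (gene, isos) in enumerate(list(isoforms_by_gene.items())[: n_genes // 2]):
        iso = isos[0]
        vid = (pos - tssmap[iso]).abs().idxmin()
        beta = 0.8 if k % 2 == 0 else -0.8
        effects.append(syndata.PlantedEffect(gene, iso, vid, ("typeA",), beta))
    design = syndata.EffectDesign(
        cell_types=("typeA",), effects=effects, usage_weights=weights
    )
    cells = syndata.simulate_cells(gt, models, design, seed=int(rng.integers(2**31)))
    tss = pd.DataFrame(
        {"chrom": [m.chrom for m in models], "tss": [m.tss for m in models]},
        index=[m.transcript_id for m in models],
    )
    df, pb, cov = _map_one_type(gt, cells, tss, "typeA", n_perm, seed + 3)
    truth = {e.isoform: e.beta for e in effects}
    planted_tested = [i for i in df["isoform"] if i in truth]
    hits = df[df["eisoform"]]
    discovered = [i for i in hits["isoform"] if i in truth]
    sensitivity = len(discovered) / len(planted_tested) if planted_tested else 0.0
    signs = [
        np.sign(hits.set_index("isoform").loc[i, "beta"]) == np.sign(truth[i])
        for i in discovered
    ]
    sign_acc = float(np.mean(signs)) if signs else 0.0
    false = [i for i in hits["isoform"] if i not in truth]
    return {
        "sensitivity": float(sensitivity),
        "sign_accuracy": sign_acc,
        "n_planted_tested": len(planted_tested),
        "n_discovered": len(discovered),
        "n_false_discoveries": len(false),
        "records": df,
    }


def _simulate_locus(
    rng: np.random.Generator,
    shared: bool,
    n: int = 100,
    m: int = 80,
    beta: float = 0.8,
):
    """Per-variant marginal OLS summary stats for two traits at one locus."""
    gt = syndata.simulate_genotypes(
        n, m, maf_range=(0.2, 0.4), ld_block=4, flip_prob=0.2,
        seed=int(rng.integers(2**31)),
    )
    G = gt.dosages.to_numpy()
    if shared:
        c1 = c2 = int(rng.integers(m))
    else:
        b1 = int(rng.integers(m // 8))
        b2 = int(rng.integers(m // 8))
        while b2 == b1:
            b2 = int(rng.integers(m // 8))
        c1, c2 = b1 * 8, b2 * 8  # different LD blocks: linkage equilibrium
    stats = []
    for causal in (c1, c2):
        # variance-standardized phenotype: total variance ~1 per allele effect
        f = G[:, causal].mean() / 2
        resid_sd = np.sqrt(max(1.0 - beta**2 * 2 * f * (1 - f), 0.25))
        y = beta * G[:, causal] + rng.normal(0, resid_sd, n)
        betas = np.empty(m)
        ses = np.empty(m)
        for v in range(m):
            g = G[:, v]
            gc = g - g.mean()
            denom = float(gc @ gc)
            if denom == 0:
                betas[v], ses[v] = 0.0, 1e6
                continue
            b = float(gc @ (y - y.mean())) / denom
            resid = (y - y.mean()) - b * gc
            s2 = float(resid @ resid) / (n - 2)
            betas[v], ses[v] = b, np.sqrt(s2 / denom)
        stats.append((betas, ses))
    return stats


def coloc_study(seed: int, n_loci: int = 20) -> dict:
    """Median posterior probabilities over shared-causal and distinct-causal
    synthetic loci (beta = 0.8, 100 individuals per trait)."""
    rng = np.random.default_rng(seed)
    pph4_shared, pph3_distinct, pph4_distinct = [], [], []
    for _ in range(n_loci):
        (b1, s1), (b2, s2) = _simulate_locus(rng, shared=True)
        res = colocal.coloc_abf(
            colocal.wakefield_labf(beta=b1, se=s1),
            colocal.wakefield_labf(beta=b2, se=s2),
        )
        pph4_shared.append(res.pp_h4)
    for _ in range(n_loci):
        (b1, s1), (b2, s2) = _simulate_locus(rng, shared=False)
        res = colocal.coloc_abf(
            colocal.wakefield_labf(beta=b1, se=s1),
            colocal.wakefield_labf(beta=b2, se=s2),
        )
        pph3_distinct.append(res.pp_h3)
        pph4_distinct.append(res.pp_h4)
    return {
        "median_pph4_shared": float(np.median(pph4_shared)),
        "median_pph3_distinct": float(np.median(pph3_distinct)),
        "median_pph4_distinct": float(np.median(pph4_distinct)),
    }


def sharing_study(seed: int, n_pairs: int = 200, n_random: int = 3000) -> dict:
    """Cell-type-specific vs pan-cell-type effect classification over 5 cell
    types at |beta| = 0.8 (lead-variant SE 0.15, so |z| about 5.3).

    Half the strong pairs carry the effect in one cell type only, half in
    all five; the EZ mixture is fit on a random (mostly null) set and the
    sharing rule applied to posterior effects.
    """
    rng = np.random.default_rng(seed)
    R = 5
    se = 0.15
    z_random = rng.normal(0, 1, (n_random, R))
    # a sprinkle of real effects in the random set, as in real data
    k = n_random // 20
    z_random[:k] += rng.choice([-0.8, 0.8], k)[:, None] / se
    V = crosscell.estimate_null_correlation(z_random)
    model = crosscell.fit_ez_mixture(z_random, V)

    labels = []
    Zs = np.empty((n_pairs, R))
    for i in range(n_pairs):
        b = np.zeros(R)
        sgn = -1.0 if rng.random() < 0.5 else 1.0
        if i % 2 == 0:
            b[rng.integers(R)] = sgn * 0.8
            labels.append("specific")
        else:
            b[:] = sgn * 0.8
            labels.append("shared")
        Zs[i] = b / se + rng.normal(0, 1, R)
    z = pd.DataFrame(Zs, columns=[f"ct{r}" for r in range(R)])
    se_df = pd.DataFrame(np.full_like(Zs, se), columns=z.columns)
    eff = crosscell.CrossCellEffects.from_tables(z, se_df)
    eff = crosscell.posterior_summaries(eff, model)
    profile, _ = crosscell.sharing_metrics(eff.posterior_beta, eff.lfsr)
    prof = profile.set_index("pair")
    correct = 0
    evaluated = 0
    for i, lab in enumerate(labels):
        if i not in prof.index:
            continue
        evaluated += 1
        pred_specific = bool(prof.loc[i, "specific"])
        if (lab == "specific") == pred_specific:
            correct += 1
    return {
        "accuracy": correct / evaluated if evaluated else 0.0,
        "n_evaluated": evaluated,
        "null_weight": model.null_weight,
    }


def annotation_fixture_study() -> dict:
    """Agreement with hand-constructed structural, NMD, AS-event and
    sjs-window fixtures."""
    chrom = "chrF"
    mk = lambda tid, exons, strand="+", **kw: TranscriptModel(
        tid, "geneF", chrom, strand,
        [GenomicInterval(chrom, s, e, strand) for s, e in exons], **kw
    )
    ref = mk("ref", [(100, 200), (300, 400), (500, 600), (700, 800), (900, 1000)])
    checks = []

    # structural categories
    checks.append(annotate.classify_structure(mk("fsm", [(80, 200), (300, 400), (500, 600), (700, 800), (900, 1050)]), [ref]) == "FSM")
    checks.append(annotate.classify_structure(mk("ism", [(500, 600), (700, 800), (900, 1000)]), [ref]) == "ISM")
    checks.append(annotate.classify_structure(mk("nic", [(100, 200), (300, 400), (500, 600), (900, 1000)]), [ref]) == "NIC")
    checks.append(annotate.classify_structure(mk("nnc", [(100, 205), (300, 400), (500, 600), (700, 800), (900, 1000)]), [ref]) == "NNC")
    # known donor joined to a known acceptor of a different junction -> NIC
    checks.append(annotate.classify_structure(mk("nic2", [(100, 200), (500, 600), (700, 800), (900, 1000)]), [ref]) == "NIC")
    # donor shifted 5 nt off every reference donor -> NNC
    checks.append(annotate.classify_structure(mk("nnc2", [(100, 195), (300, 400), (500, 600), (700, 800), (900, 1000)]), [ref]) == "NNC")
    checks.append(annotate.classify_structure(ref, [ref]) == "FSM")

    # NMD boundary: stop exactly 50 nt upstream -> sensitive; 49 -> insensitive
    # two exons of 100 nt: junction at spliced position 101
    def nmd_fixture(stop_spliced):
        m = mk("nmd", [(1000, 1099), (1200, 1299)])
        # stop at spliced coord stop_spliced lies in exon 1 (plus strand)
        from dataclasses import replace
        return replace(m, cds_start=1000, cds_end=1000 + stop_spliced - 1)

    checks.append(annotate.classify_nmd(nmd_fixture(101 - 50)) is True)
    checks.append(annotate.classify_nmd(nmd_fixture(101 - 49)) is False)
    single = mk("single", [(100, 400)], cds_start=120, cds_end=300)
    checks.append(annotate.classify_nmd(single) is False)

    # AS events
    a = mk("a", [(100, 200), (300, 400), (500, 600)])
    b = mk("b", [(100, 200), (500, 600)])
    ev = annotate.classify_as_events([a, b])
    checks.append([e.event_type for e in ev] == ["SE"])
    c = mk("c", [(100, 400)])
    d = mk("d", [(100, 200), (300, 400)])
    ev = annotate.classify_as_events([c, d])
    checks.append([e.event_type for e in ev] == ["RI"])
    e1 = mk("e1", [(100, 200), (300, 400)])
    e2 = mk("e2", [(100, 220), (300, 400)])
    ev = annotate.classify_as_events([e1, e2])
    checks.append([e.event_type for e in ev] == ["A5"])

    # sjs windows
    win = annotate.sjs_windows([mk("w", [(100, 200), (300, 400)])])
    got = {(w.start, w.end) for w in win}
    checks.append(got == {(201, 202), (298, 299)})
    shared = annotate.sjs_windows([mk("w1", [(100, 200), (300, 400)]), mk("w2", [(50, 200), (300, 450)])])
    checks.append(len(shared) == 2)

    return {
        "agreement_pct": 100.0 * float(np.mean(checks)),
        "n_checks": len(checks),
        "failures": [i for i, ok in enumerate(checks) if not ok],
    }


def nb_oracle_study(seed: int, n: int = 500) -> dict:
    """NB GLM coefficients vs a Poisson GLM oracle on Poisson data (the
    dispersion -> 0 limit); reports the max absolute coefficient gap."""
    import statsmodels.api as sm

    rng = np.random.default_rng(seed)
    g = rng.binomial(2, 0.3, n).astype(float)
    covar = rng.normal(0, 1, n)
    offset = np.log(rng.uniform(0.5, 2.0, n))
    X = np.column_stack([np.ones(n), covar, g])
    mu = np.exp(X @ np.array([1.0, 0.3, 0.5]) + offset)
    y = rng.poisson(mu).astype(float)
    fit = qtlmap.fit_nb_glm(y, X, offset)
    oracle = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
    gap = float(np.max(np.abs(fit.coef - oracle.params)))
    return {"max_coef_gap": gap, "beta_hat": float(fit.coef[-1]), "alpha": fit.alpha}


def dei_study(seed: int, n_perm: int = 1000) -> dict:
    """Differential-isoform recovery and the permutation audit.

    Two cell types, 30 individuals each passing the cell filter; a quarter
    of isoforms are planted at 4-fold higher mean in the target type.  The
    audit runs on a matched all-null cohort.
    """
    rng = np.random.default_rng(seed)
    n_ind, n_genes = 30, 40
    gt = syndata.simulate_genotypes(n_ind, 10, seed=int(rng.integers(2**31)))
    models, _, _ = syndata.simulate_transcriptome(
        n_genes, 2, seed=int(rng.integers(2**31))
    )
    isoforms_by_gene: dict[str, list[str]] = {}
    for m in models:
        isoforms_by_gene.setdefault(m.gene_id, []).append(m.transcript_id)
    cts = ("target", "rest")
    # identical baseline usage in both cell types: the planted fold is then
    # the only systematic target-vs-rest difference
    w_one = syndata.default_usage_weights(
        isoforms_by_gene, ("target",), np.random.default_rng(int(rng.integers(2**31)))
    )
    weights = {}
    for (gene, _), w in w_one.items():
        for ct in cts:
            weights[(gene, ct)] = dict(w)
    # plant a clean 4-fold increase of iso0's mean in the target cell type
    fold = 4.0
    multipliers = {}
    planted = []
    # keep the planted fraction small so the library-size offset stays an
    # almost-unbiased normalizer (composition effect < 0.2 on the log2 scale)
    for k, (gene, isos) in enumerate(list(isoforms_by_gene.items())[: 4]):
        iso = isos[0]
        multipliers[(iso, "target")] = fold
        planted.append((iso, fold))
    design = syndata.EffectDesign(
        cell_types=cts, effects=[], usage_weights=weights,
        cell_type_multipliers=multipliers,
    )
    cells = syndata.simulate_cells(gt, models, design, seed=int(rng.integers(2**31)))

    # assemble (individual, cell type) pseudobulk sample matrix
    samples, labels = [], []
    for ct in cts:
        pb = cellops.pseudobulk(cells, ct)
        for ind in pb.counts.index:
            samples.append(pb.counts.loc[ind].rename(f"{ind}|{ct}"))
            labels.append(ct)
    counts = pd.DataFrame(samples)
    labels = pd.Series(labels, index=counts.index)
    dei = diffexp.dei_one_vs_rest(counts, labels, "target")
    dei = dei.set_index("isoform")
    fc_errors = []
    for iso, true_fold in planted:
        if iso in dei.index:
            fc_errors.append(dei.loc[iso, "log2fc"] - np.log2(true_fold))
    mean_log2fc = float(
        np.mean([dei.loc[i, "log2fc"] for i, _ in planted if i in dei.index])
    )
    mean_true = float(np.mean([np.log2(f) for _, f in planted]))

    # audit on an all-null cohort of the same shape
    weights0 = syndata.default_usage_weights(
        isoforms_by_gene, cts, np.random.default_rng(int(rng.integers(2**31)))
    )
    design0 = syndata.EffectDesign(cell_types=cts, effects=[], usage_weights=weights0)
    cells0 = syndata.simulate_cells(gt, models, design0, seed=int(rng.integers(2**31)))
    samples0, labels0 = [], []
    for ct in cts:
        pb = cellops.pseudobulk(cells0, ct)
        for ind in pb.counts.index:
            samples0.append(pb.counts.loc[ind].rename(f"{ind}|{ct}"))
            labels0.append(ct)
    counts0 = pd.DataFrame(samples0)
    labels0 = pd.Series(labels0, index=counts0.index)
    audit = diffexp.dei_permutation_audit(
        counts0, labels0, "target", n_perm=n_perm, seed=seed + 5
    )
    return {
        "mean_log2fc_planted": mean_log2fc,
        "true_mean_log2fc": mean_true,
        "max_abs_fc_error": float(np.max(np.abs(fc_errors))) if fc_errors else np.nan,
        "audit_flag_rate_pct": 100.0 * float(audit["flagged"].mean()),
        "n_planted": len(planted),
        "dei": dei,
        "audit": audit,
    }
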