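"""Negative-binomial cis-QTL mapping with permutation beta calibration.

The count model is NB2 with a log link: y_i ~ NB(mu_i, alpha) with
Var(y) = mu + alpha * mu^2 and log mu = X gamma + g beta + offset, where the
offset is the log per-individual library size.  Fitting alternates IRLS for
the coefficients given the dispersion with bounded maximum-likelihood
updates of alpha given the coefficients; alpha is floored at 1e-8 (the
Poisson limit).

The cis scan uses the efficient score test of each variant against the
covariate-only null fit (fast, one null fit per isoform); the lead variant
is refit by Wald for its effect size.  Isoform-level multiplicity over cis
variants is corrected by permuting the genotype<->(phenotype, covariate)
linkage, fitting a Beta(k, n) distribution to the permutation minimum
p-values by maximum likelihood, and reading the adjusted p off the Beta CDF.
Genome-wide FDR uses the Storey-Tibshirani q-value procedure, and
per-isoform nominal significance thresholds invert the Beta CDF at the
adjusted p closest to the FDR level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from .cellops import normalize_log
from .models import GenotypeTable, PseudobulkMatrix

logger = logging.getLogger(__name__)

ALPHA_FLOOR = 1e-8
ALPHA_CEIL = 100.0


# ---------------------------------------------------------------------------
# NB GLM
# ---------------------------------------------------------------------------

@dataclass
class NbFit:
    coef: np.ndarray
    se: np.ndarray
    alpha: float
    loglik: float
    converged: bool
    mu: np.ndarray
    names: list[str] = field(default_factory=list)


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    if alpha < ALPHA_FLOOR * 1.0001:  # Poisson limit
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))
    inv = 1.0 / alpha
    return float(
        np.sum(
            gammaln(y + inv) - gammaln(inv) - gammaln(y + 1)
            + y * np.log(alpha * mu / (1 + alpha * mu))
            - inv * np.log1p(alpha * mu)
        )
    )


def _irls(y, X, offset, alpha, beta0, max_iter=50, tol=1e-10):
    beta = beta0.copy()
    ll_old = -np.inf
    for _ in range(max_iter):
        eta = X @ beta + offset
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        w = mu / (1 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        WX = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        beta = beta_new
        ll = _nb_loglik(y, np.exp(np.clip(X @ beta + offset, -30, 30)), alpha)
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1):
            break
        ll_old = ll
    mu = np.exp(np.clip(X @ beta + offset, -30, 30))
    return beta, mu


def fit_nb_glm(
    y: np.ndarray,
    X: np.ndarray,
    offset: Optional[np.ndarray] = None,
    names: Optional[Sequence[str]] = None,
    max_outer: int = 50,
    tol: float = 1e-8,
) -> NbFit:
    """Joint MLE of an NB2 GLM by alternating IRLS and dispersion updates.

    ``X`` must include the intercept column.  Raises on collinear design.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if offset is None:
        offset = np.zeros(n)
    offset = np.asarray(offset, dtype=float)
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("collinear design matrix")

    # Poisson start
    beta = np.zeros(p)
    beta[np.argmax(np.all(X == 1, axis=0))] = np.log(max(y.mean(), 0.1)) - offset.mean()
    alpha = 0.1
    beta, mu = _irls(y, X, offset, 0.0, beta)
    ll_old = -np.inf
    converged = False
    for _ in range(max_outer):
        res = minimize_scalar(
            lambda la: -_nb_loglik(y, mu, np.exp(la)),
            bounds=(np.log(ALPHA_FLOOR), np.log(ALPHA_CEIL)),
            method="bounded",
            options={"xatol": 1e-10},
        )
        alpha = max(float(np.exp(res.x)), ALPHA_FLOOR)
        beta, mu = _irls(y, X, offset, alpha, beta)
        ll = _nb_loglik(y, mu, alpha)
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1):
            converged = True
            break
        ll_old = ll
    w = mu / (1 + alpha * mu)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    se = np.sqrt(np.diag(cov))
    return NbFit(
        coef=beta,
        se=se,
        alpha=alpha,
        loglik=_nb_loglik(y, mu, alpha),
        converged=converged,
        mu=mu,
        names=list(names) if names is not None else [f"x{i}" for i in range(p)],
    )


def add_intercept(X: Optional[np.ndarray], n: int) -> np.ndarray:
    if X is None or X.size == 0:
        return np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    return np.column_stack([np.ones(n), X])


# ---------------------------------------------------------------------------
# Score-test scan machinery
# ---------------------------------------------------------------------------

@dataclass
class _NullState:
    """Cached quantities of the covariate-only null fit used by the scan."""

    r: np.ndarray      # (y - mu) / (1 + alpha*mu)
    w: np.ndarray      # mu / (1 + alpha*mu)
    WX: np.ndarray     # diag(w) @ X
    Ainv: np.ndarray   # (X' W X)^{-1}


def _null_state(fit: NbFit, y: np.ndarray, X: np.ndarray) -> _NullState:
    denom = 1 + fit.alpha * fit.mu
    r = (y - fit.mu) / denom
    w = fit.mu / denom
    WX = X * w[:, None]
    Ainv = np.linalg.inv(X.T @ WX)
    return _NullState(r=r, w=w, WX=WX, Ainv=Ainv)


def _score_pvalues(G: np.ndarray, ns: _NullState) -> np.ndarray:
    """Efficient-score p-values for each column of G against the null fit."""
    U = G.T @ ns.r
    D = (G**2).T @ ns.w
    B = G.T @ ns.WX
    corr = np.einsum("ij,jk,ik->i", B, ns.Ainv, B)
    V = np.maximum(D - corr, 1e-300)
    z2 = U**2 / V
    return st.chi2.sf(z2, df=1)


def _score_min_p_perms(
    G: np.ndarray, ns: _NullState, perms: np.ndarray
) -> np.ndarray:
    """Minimum score-test p per permutation of the genotype linkage.

    ``perms`` is (B, n) of row permutations applied jointly to the
    (phenotype, covariate) side; the null fit is permutation-invariant
    under that joint shuffle, so only cached vectors are re-indexed.
    """
    B = perms.shape[0]
    Rm = ns.r[perms.T]            # n x B
    Wm = ns.w[perms.T]            # n x B
    U = G.T @ Rm                  # M x B
    D = (G**2).T @ Wm             # M x B
    p_cov = ns.WX.shape[1]
    C = np.empty((p_cov, G.shape[1], B))
    for j in range(p_cov):
        C[j] = G.T @ ns.WX[:, j][perms.T]
    corr = np.einsum("jk,jmb,kmb->mb", ns.Ainv, C, C)
    V = np.maximum(D - corr, 1e-300)
    z2 = (U**2) / V
    z2max = z2.max(axis=0)
    return st.chi2.sf(z2max, df=1)


# ---------------------------------------------------------------------------
# Permutation beta calibration
# ---------------------------------------------------------------------------

@dataclass
class PermutationCalibration:
    k: float
    n: float
    n_perm: int
    min_p_sample: np.ndarray
    observed_min_p: float
    adjusted_p: float
    degenerate: bool = False


def _fit_beta_mle(sample: np.ndarray) -> tuple[float, float]:
    eps = 1e-12
    x = np.clip(sample, eps, 1 - eps)
    try:
        k, n, _, _ = st.beta.fit(x, floc=0, fscale=1)
    except Exception:  # fall back to method of moments
        m, v = x.mean(), x.var()
        if v <= 0:
            raise
        c = m * (1 - m) / v - 1
        k, n = m * c, (1 - m) * c
    return float(k), float(n)


def calibrate_permutations(
    observed_min_p: float,
    min_p_sample: np.ndarray,
    n_perm: int,
) -> PermutationCalibration:
    """Fit Beta(k, n) to permutation minimum p-values and adjust the observed one."""
    if n_perm < 100:
        raise ValueError("at least 100 permutations required for the beta fit")
    sample = np.asarray(min_p_sample, dtype=float)
    if np.allclose(sample, sample[0]):
        logger.warning("degenerate permutation min-p sample; using empirical rank p")
        adj = (1 + np.sum(sample <= observed_min_p)) / (n_perm + 1)
        return PermutationCalibration(
            k=np.nan, n=np.nan, n_perm=n_perm, min_p_sample=sample,
            observed_min_p=observed_min_p, adjusted_p=float(adj), degenerate=True,
        )
    k, n = _fit_beta_mle(sample)
    adj = float(st.beta.cdf(observed_min_p, k, n))
    return PermutationCalibration(
        k=k, n=n, n_perm=n_perm, min_p_sample=sample,
        observed_min_p=float(observed_min_p), adjusted_p=adj,
    )


# ---------------------------------------------------------------------------
# Storey FDR
# ---------------------------------------------------------------------------

@dataclass
class FdrSummary:
    pi0: float
    qvalues: np.ndarray
    level: float

    def significant(self) -> np.ndarray:
        return self.qvalues < self.level


def estimate_pi0(ps: np.ndarray) -> float:
    """Storey pi0 by the lambda-grid smoother (cubic trend, evaluated at the
    largest lambda); single-lambda 0.5 estimate below 100 tests."""
    ps = np.asarray(ps, dtype=float)
    m = len(ps)
    if m < 100:
        pi0 = np.mean(ps > 0.5) / 0.5
    else:
        lams = np.arange(0.05, 0.96, 0.05)
        pi0_l = np.array([np.mean(ps > la) / (1 - la) for la in lams])
        coeffs = np.polyfit(lams, pi0_l, 3)
        pi0 = float(np.polyval(coeffs, lams[-1]))
    return float(min(max(pi0, 1.0 / m if m else 1e-8), 1.0))


def storey_fdr(ps: np.ndarray, level: float = 0.05) -> FdrSummary:
    ps = np.asarray(ps, dtype=float)
    if ps.size == 0:
        raise ValueError("no p-values")
    if (ps < 0).any() or (ps > 1).any():
        raise ValueError("p-values outside [0, 1]")
    m = len(ps)
    pi0 = estimate_pi0(ps)
    order = np.argsort(ps)
    ranked = ps[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]  # step-up monotonicity
    q = np.clip(q, 0, 1)
    out = np.empty(m)
    out[order] = q
    return FdrSummary(pi0=pi0, qvalues=out, level=level)


def nominal_thresholds(
    calibrations: Sequence[PermutationCalibration],
    fdr: FdrSummary,
) -> np.ndarray:
    """Per-isoform nominal p thresholds from the Beta model of each isoform.

    p0 is the adjusted p whose q-value is closest to the FDR level; each
    isoform's threshold is the inverse Beta CDF of p0 under its (k, n).
    """
    if not calibrations:
        raise ValueError("empty calibration set")
    adj = np.array([c.adjusted_p for c in calibrations])
    p0 = float(adj[np.argmin(np.abs(fdr.qvalues - fdr.level))])
    out = np.empty(len(calibrations))
    for i, c in enumerate(calibrations):
        out[i] = (
            p0 if c.degenerate else float(st.beta.ppf(p0, c.k, c.n))
        )
    return out


# ---------------------------------------------------------------------------
# cis scan drivers
# ---------------------------------------------------------------------------

def cis_variant_mask(
    variants: pd.DataFrame, chrom: str, tss: int, window: int
) -> np.ndarray:
    """Cis-window membership, inclusive at both ends."""
    pos = variants["pos"].to_numpy()
    return (variants["chrom"].to_numpy() == chrom) & (
        np.abs(pos - tss) <= window
    )


def scan_isoform(
    y: np.ndarray,
    covariates: Optional[np.ndarray],
    offset: np.ndarray,
    G: np.ndarray,
    variant_ids: Sequence[str],
    n_perm: int = 1000,
    rng: Optional[np.random.Generator] = None,
    perm_block: int = 250,
) -> dict:
    """NB score scan of one isoform over its cis variants, with permutation
    beta calibration and a Wald refit for the lead variant."""
    n = len(y)
    X0 = add_intercept(covariates, n)
    null_fit = fit_nb_glm(y, X0, offset)
    ns = _null_state(null_fit, y, X0)
    pvals = _score_pvalues(G, ns)
    lead_idx = int(np.argmin(pvals))
    min_p = float(pvals[lead_idx])

    g_lead = G[:, lead_idx]
    if np.ptp(g_lead) == 0:
        raise ValueError("constant genotype column among cis variants")
    Xfull = np.column_stack([X0, g_lead])
    wald = fit_nb_glm(y, Xfull, offset)
    beta, se = float(wald.coef[-1]), float(wald.se[-1])
    wald_p = float(2 * st.norm.sf(abs(beta / se)))

    calibration = None
    if n_perm:
        if rng is None:
            rng = np.random.default_rng(0)
        mins = np.empty(n_perm)
        done = 0
        while done < n_perm:
            b = min(perm_block, n_perm - done)
            perms = np.stack([rng.permutation(n) for _ in range(b)])
            mins[done : done + b] = _score_min_p_perms(G, ns, perms)
            done += b
        calibration = calibrate_permutations(min_p, mins, n_perm)
    return {
        "lead_variant": variant_ids[lead_idx],
        "lead_index": lead_idx,
        "beta": beta,
        "se": se,
        "nominal_p": min_p,
        "wald_p": wald_p,
        "alpha": wald.alpha,
        "pvalues": pvals,
        "calibration": calibration,
        "null_fit": null_fit,
    }


def map_cell_type(
    pb: PseudobulkMatrix,
    genotypes: GenotypeTable,
    tss: pd.DataFrame,
    covariates: Optional[pd.DataFrame] = None,
    window: int = 1_000_000,
    n_perm: int = 1000,
    seed: int = 0,
    fdr_level: float = 0.05,
    mode: str = "nb",
) -> pd.DataFrame:
    """Full per-cell-type cis-QTL map: scan, calibrate, FDR, thresholds.

    ``tss`` is indexed by isoform with columns chrom and tss.  Returns one
    row per mapped isoform (QtlRecord layout).  ``mode`` selects the NB
    engine or the linear OLS engine on log-normalized expression.
    """
    inds = pb.counts.index
    D = genotypes.dosages.loc[inds].to_numpy(dtype=float)
    lib = pb.library_sizes().astype(float)
    offset = np.log(np.maximum(lib, 1.0))
    cov = covariates.loc[inds].to_numpy(dtype=float) if covariates is not None else None
    if mode == "linear":
        norm = normalize_log(pb.counts)
        norm = (norm - norm.mean()) / norm.std().replace(0, 1.0)
    rows, calibs = [], []
    rng_master = np.random.default_rng(seed)
    for iso in pb.isoforms:
        if iso not in tss.index:
            logger.info("isoform %s has no TSS; skipped", iso)
            continue
        chrom, t = tss.loc[iso, "chrom"], int(tss.loc[iso, "tss"])
        mask = cis_variant_mask(genotypes.variants, chrom, t, window)
        if not mask.any():
            logger.info("isoform %s has no cis variants; skipped", iso)
            continue
        G = D[:, mask]
        vids = list(genotypes.variants.index[mask])
        rng = np.random.default_rng(rng_master.integers(2**31))
        try:
            if mode == "linear":
                res = scan_isoform_linear(
                    norm[iso].to_numpy(), cov, G, vids, n_perm=n_perm, rng=rng
                )
            else:
                res = scan_isoform(
                    pb.counts[iso].to_numpy(dtype=float), cov, offset, G, vids,
                    n_perm=n_perm, rng=rng,
                )
        except ValueError as exc:
            logger.warning("isoform %s dropped: %s", iso, exc)
            continue
        rows.append(
            dict(
                isoform=iso,
                cell_type=pb.cell_type,
                lead_variant=res["lead_variant"],
                beta=res["beta"],
                se=res["se"],
                nominal_p=res["nominal_p"],
                adjusted_p=res["calibration"].adjusted_p,
                beta_k=res["calibration"].k,
                beta_n=res["calibration"].n,
            )
        )
        calibs.append(res["calibration"])
    if not rows:
        return pd.DataFrame(
            columns=["isoform", "cell_type", "lead_variant", "beta", "se",
                     "nominal_p", "adjusted_p", "beta_k", "beta_n",
                     "qvalue", "eisoform", "nominal_threshold"]
        )
    df = pd.DataFrame(rows)
    fdr = storey_fdr(df["adjusted_p"].to_numpy(), level=fdr_level)
    df["qvalue"] = fdr.qvalues
    df["eisoform"] = fdr.significant()
    df["nominal_threshold"] = nominal_thresholds(calibs, fdr)
    df.attrs["pi0"] = fdr.pi0
    return df


# ---------------------------------------------------------------------------
# Linear-model mode
# ---------------------------------------------------------------------------

def scan_isoform_linear(
    y: np.ndarray,
    covariates: Optional[np.ndarray],
    G: np.ndarray,
    variant_ids: Sequence[str],
    n_perm: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> dict:
    """OLS scan on standardized log-normalized expression, with the same
    permutation beta-calibration machinery as the NB scan."""
    n = len(y)
    X0 = add_intercept(covariates, n)
    H = X0 @ np.linalg.solve(X0.T @ X0, X0.T)
    y_res = y - H @ y
    G_res = G - H @ G
    dof = n - X0.shape[1] - 1
    if dof < 1:
        raise ValueError("insufficient degrees of freedom for linear scan")

    def _pvals(yv: np.ndarray) -> np.ndarray:
        gss = np.einsum("ij,ij->j", G_res, G_res)
        gss = np.maximum(gss, 1e-300)
        num = G_res.T @ yv
        yss = float(yv @ yv)
        r2 = np.clip(num**2 / (gss * max(yss, 1e-300)), 0, 1 - 1e-12)
        tstat2 = r2 * dof / (1 - r2)
        return st.f.sf(tstat2, 1, dof)

    pvals = _pvals(y_res)
    lead_idx = int(np.argmin(pvals))
    g = G_res[:, lead_idx]
    beta = float(g @ y_res / (g @ g))
    resid = y_res - beta * g
    se = float(np.sqrt((resid @ resid) / dof / (g @ g)))
    calibration = None
    if n_perm:
        if rng is None:
            rng = np.random.default_rng(0)
        mins = np.empty(n_perm)
        for b in range(n_perm):
            mins[b] = _pvals(y_res[rng.permutation(n)]).min()
        calibration = calibrate_permutations(float(pvals[lead_idx]), mins, n_perm)
    return {
        "lead_variant": variant_ids[lead_idx],
        "lead_index": lead_idx,
        "beta": beta,
        "se": se,
        "nominal_p": float(pvals[lead_idx]),
        "wald_p": float(pvals[lead_idx]),
        "pvalues": pvals,
        "calibration": calibration,
        "null_fit": None,
    }


# ---------------------------------------------------------------------------
# Proportion QTL and type-I audit
# ---------------------------------------------------------------------------

def proportion_qtl(
    iso_counts: pd.DataFrame,
    dosage: pd.Series,
    covariates: Optional[pd.DataFrame] = None,
    level: float = 0.05,
) -> pd.DataFrame:
    """Isoform-usage QTL: per-isoform OLS of (isoform count / gene total) on
    dosage plus covariates, Bonferroni-corrected over the isoforms tested."""
    if iso_counts.shape[1] < 2:
        raise ValueError("need at least 2 isoforms")
    totals = iso_counts.sum(axis=1)
    keep = totals > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d individuals with zero gene total", dropped)
    iso = iso_counts.loc[keep]
    totals = totals.loc[keep]
    props = iso.div(totals, axis=0)
    g = dosage.loc[props.index].to_numpy(dtype=float)
    X = add_intercept(
        covariates.loc[props.index].to_numpy(dtype=float) if covariates is not None else None,
        len(props),
    )
    X = np.column_stack([X, g])
    XtX_inv = np.linalg.inv(X.T @ X)
    dof = X.shape[0] - X.shape[1]
    if dof < 1:
        raise ValueError("too few individuals with nonzero gene totals")
    rows = []
    for col in props.columns:
        yv = props[col].to_numpy(dtype=float)
        coefs = XtX_inv @ (X.T @ yv)
        resid = yv - X @ coefs
        sigma2 = float(resid @ resid) / dof
        se = float(np.sqrt(sigma2 * XtX_inv[-1, -1]))
        beta = float(coefs[-1])
        p = float(2 * st.t.sf(abs(beta / se), dof)) if se > 0 else 1.0
        rows.append(dict(isoform=col, beta=beta, se=se, p=p))
    out = pd.DataFrame(rows)
    out["bonferroni_level"] = level / len(out)
    out["significant"] = out["p"] < out["bonferroni_level"]
    return out


def typeI_audit(
    pb: PseudobulkMatrix,
    genotypes: GenotypeTable,
    tss: pd.DataFrame,
    covariates: Optional[pd.DataFrame] = None,
    window: int = 1_000_000,
    n_perm: int = 1000,
    seed: int = 0,
    strong_p: float = 1e-5,
) -> dict:
    """Type-I-error audit: shuffle each isoform's counts across individuals
    independently, rerun the scan + calibration, and report pi0 and the
    fraction of isoforms with beta-approximated p below ``strong_p``."""
    rng = np.random.default_rng(seed)
    shuffled = pb.counts.copy()
    for col in shuffled.columns:
        shuffled[col] = rng.permutation(shuffled[col].to_numpy())
    pb_null = PseudobulkMatrix(
        counts=shuffled, cell_type=pb.cell_type, covariates=pb.covariates
    )
    df = map_cell_type(
        pb_null, genotypes, tss, covariates=covariates, window=window,
        n_perm=n_perm, seed=int(rng.integers(2**31)),
    )
    adj = df["adjusted_p"].to_numpy()
    return {
        "pi0": float(estimate_pi0(adj)),
        "frac_strong": float(np.mean(adj < strong_p)) if len(adj) else 0.0,
        "n_isoforms": int(len(adj)),
        "records": df,
    }
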