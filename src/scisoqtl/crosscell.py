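"""Cross-cell-type harmonization of lead-QTL effects and sharing classification.

An empirical-Bayes normal-means model on z-scores (the EZ parameterization):
for each (isoform, lead variant) pair, the vector of per-cell-type z-scores
is z = b + e with e ~ N(0, V) (V the null correlation among cell types) and
b drawn from a mixture of zero-mean normals over a canonical covariance set

    identity, per-cell-type singletons, equal-effects (all-ones),

each scaled over a grid, plus a point mass at zero.  Mixture weights are fit
by EM on a random (mostly null) set of pairs; posterior means and local
false sign rates (lfsr) are then computed on the strong set (lead pairs).
Posterior effects on the beta scale are posterior z times the reported SE.

Sharing semantics, applied to posterior effects at an lfsr cut: the top cell
type carries the largest |effect| among significant ones; a cell type is
shared by magnitude when significant, same sign as top, and within a factor
``fold`` of it; shared by sign when significant and same sign; a pair is
cell-type-specific when exactly one cell type is shared by magnitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

DEFAULT_SCALES = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0)


def canonical_covariances(n_cell_types: int) -> list[tuple[str, np.ndarray]]:
    R = n_cell_types
    out = [("identity", np.eye(R))]
    for r in range(R):
        U = np.zeros((R, R))
        U[r, r] = 1.0
        out.append((f"singleton_{r}", U))
    out.append(("equal_effects", np.ones((R, R))))
    return out


@dataclass
class MixtureModel:
    components: list[tuple[str, np.ndarray]]  # includes the null (zero) matrix
    weights: np.ndarray
    V: np.ndarray
    loglik_path: list[float] = field(default_factory=list)

    @property
    def null_weight(self) -> float:
        return float(self.weights[0])


def estimate_null_correlation(
    z_random: np.ndarray, max_abs_z: float = 2.0, shrink: float = 0.1,
    min_rows: int = 50,
) -> np.ndarray:
    """Null correlation among cell types from approximately-null random rows
    (max |z| below ``max_abs_z``), shrunk toward the identity."""
    Z = np.asarray(z_random, dtype=float)
    R = Z.shape[1]
    mask = np.nanmax(np.abs(Z), axis=1) < max_abs_z
    nulls = Z[mask]
    if nulls.shape[0] < min_rows:
        logger.warning(
            "only %d approximately-null rows; using identity null correlation",
            nulls.shape[0],
        )
        return np.eye(R)
    C = np.corrcoef(nulls, rowvar=False)
    C = np.nan_to_num(C, nan=0.0)
    V = (1 - shrink) * C + shrink * np.eye(R)
    np.fill_diagonal(V, 1.0)
    # symmetrize and clip tiny negative eigenvalues
    V = (V + V.T) / 2
    evals, evecs = np.linalg.eigh(V)
    evals = np.clip(evals, 1e-8, None)
    V = evecs @ np.diag(evals) @ evecs.T
    d = np.sqrt(np.diag(V))
    return V / np.outer(d, d)


def _component_sigmas(
    R: int, V: np.ndarray, scales: Sequence[float]
) -> list[tuple[str, np.ndarray]]:
    comps = [("null", np.zeros((R, R)))]
    for name, U in canonical_covariances(R):
        for w in scales:
            comps.append((f"{name}@{w:g}", w * U))
    return comps


def fit_ez_mixture(
    z_random: np.ndarray,
    V: np.ndarray,
    scales: Sequence[float] = DEFAULT_SCALES,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> MixtureModel:
    """EM over mixture weights for fixed component covariances."""
    Z = np.asarray(z_random, dtype=float)
    n, R = Z.shape
    comps = _component_sigmas(R, V, scales)
    K = len(comps)
    # per-component log densities, computed once
    L = np.empty((n, K))
    for k, (_, Sig) in enumerate(comps):
        cov = V + Sig
        L[:, k] = st.multivariate_normal.logpdf(Z, mean=np.zeros(R), cov=cov)
    w = np.full(K, 1.0 / K)
    ll_old = -np.inf
    path = []
    for _ in range(max_iter):
        logpost = L + np.log(np.maximum(w, 1e-300))
        norm = logsumexp(logpost, axis=1)
        ll = float(norm.sum())
        if not np.isfinite(ll):
            raise ValueError("non-finite mixture likelihood")
        path.append(ll)
        resp = np.exp(logpost - norm[:, None])
        w = resp.mean(axis=0)
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1):
            break
        ll_old = ll
    return MixtureModel(components=comps, weights=w, V=V, loglik_path=path)


@dataclass
class CrossCellEffects:
    z: pd.DataFrame
    se: pd.DataFrame
    mask: pd.DataFrame                  # True where the pair was actually tested
    posterior_z: Optional[pd.DataFrame] = None
    posterior_beta: Optional[pd.DataFrame] = None
    lfsr: Optional[pd.DataFrame] = None

    @classmethod
    def from_tables(
        cls, z: pd.DataFrame, se: pd.DataFrame
    ) -> "CrossCellEffects":
        """Impute untested entries as z = 0 with SE 1, recording the mask."""
        mask = z.notna()
        return cls(
            z=z.fillna(0.0), se=se.fillna(1.0).where(mask, 1.0), mask=mask
        )


def posterior_summaries(
    effects: CrossCellEffects, model: MixtureModel
) -> CrossCellEffects:
    """Posterior mean z-scores and lfsr per (pair, cell type) under the model."""
    Z = effects.z.to_numpy(dtype=float)
    SE = effects.se.to_numpy(dtype=float)
    if not np.isfinite(SE).all() or (SE <= 0).any():
        raise ValueError("missing or non-positive SE for an observed z")
    n, R = Z.shape
    V = model.V
    K = len(model.components)
    logw = np.log(np.maximum(model.weights, 1e-300))

    # component posteriors: m_k(z) = Sig_k (Sig_k+V)^{-1} z ; C_k fixed per k
    A = np.empty((K, R, R))
    Cdiag = np.empty((K, R))
    logdens = np.empty((n, K))
    for k, (_, Sig) in enumerate(model.components):
        cov = V + Sig
        sol = np.linalg.solve(cov, Sig).T  # Sig (Sig+V)^{-1}
        A[k] = sol
        Ck = Sig - sol @ Sig
        Cdiag[k] = np.clip(np.diag(Ck), 0.0, None)
        logdens[:, k] = st.multivariate_normal.logpdf(Z, mean=np.zeros(R), cov=cov)
    logpost = logdens + logw
    resp = np.exp(logpost - logsumexp(logpost, axis=1)[:, None])

    means = np.einsum("krj,nj->nkr", A, Z)  # n x K x R
    post_mean = np.einsum("nk,nkr->nr", resp, means)

    sd = np.sqrt(Cdiag)  # K x R
    p_le = np.zeros((n, R))
    p_ge = np.zeros((n, R))
    for k in range(K):
        point = sd[k] < 1e-8
        m = means[:, k, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            cdf0 = st.norm.cdf((0.0 - m) / np.where(point, 1.0, sd[k]))
        # point-mass coordinates contribute fully to both sign tails
        le = np.where(point, 1.0, cdf0)
        ge = np.where(point, 1.0, 1.0 - cdf0)
        p_le += resp[:, [k]] * le
        p_ge += resp[:, [k]] * ge
    lfsr = np.minimum(p_le, p_ge)

    idx, cols = effects.z.index, effects.z.columns
    effects.posterior_z = pd.DataFrame(post_mean, index=idx, columns=cols)
    effects.posterior_beta = pd.DataFrame(post_mean * SE, index=idx, columns=cols)
    effects.lfsr = pd.DataFrame(lfsr, index=idx, columns=cols)
    return effects


def sharing_metrics(
    posterior_effects: pd.DataFrame,
    lfsr: pd.DataFrame,
    fold: float = 2.0,
    lfsr_cut: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-pair sharing profile and the pairwise cell-type sharing matrix."""
    cols = list(posterior_effects.columns)
    rows = []
    for pair in posterior_effects.index:
        eff = posterior_effects.loc[pair].to_numpy(dtype=float)
        sig = lfsr.loc[pair].to_numpy(dtype=float) < lfsr_cut
        if not sig.any():
            continue
        masked = np.where(sig, np.abs(eff), -np.inf)
        top = int(np.argmax(masked))
        top_eff = eff[top]
        same_sign = sig & (np.sign(eff) == np.sign(top_eff)) & (eff != 0)
        by_mag = same_sign & (np.abs(eff) >= abs(top_eff) / fold)
        rows.append(
            dict(
                pair=pair,
                top_cell_type=cols[top],
                n_significant=int(sig.sum()),
                n_shared_sign=int(same_sign.sum()),
                n_shared_magnitude=int(by_mag.sum()),
                specific=bool(by_mag.sum() == 1),
            )
        )
    profile = pd.DataFrame(rows)

    R = len(cols)
    mat = np.eye(R)
    eff_all = posterior_effects.to_numpy(dtype=float)
    sig_all = lfsr.to_numpy(dtype=float) < lfsr_cut
    for i in range(R):
        for j in range(i + 1, R):
            use = sig_all[:, i] | sig_all[:, j]
            if not use.any():
                mat[i, j] = mat[j, i] = np.nan
                continue
            a, b = eff_all[use, i], eff_all[use, j]
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(b != 0, a / b, np.inf * np.sign(a + 1e-300))
            shared = (ratio > 0) & (ratio >= 1.0 / fold) & (ratio <= fold)
            mat[i, j] = mat[j, i] = float(np.mean(shared))
    pairwise = pd.DataFrame(mat, index=cols, columns=cols)
    return profile, pairwise
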