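"""Approximate-Bayes-factor colocalization under a single causal variant.

Per variant, the Wakefield log approximate Bayes factor for association is

    lABF = 1/2 log(1 - r) + 1/2 r z^2,     r = W / (V + W)

with z the Wald statistic, V = SE^2 the sampling variance and W the prior
effect variance.  For summary statistics carrying only p, allele frequency
f and sample size N, the sampling variance of a quantitative-trait effect
is reconstructed as V ~ 1 / (2 N f (1 - f)) and z from the two-sided p.

A locus's posterior over the five hypotheses (H0 no association, H1/H2 one
trait only, H3 two distinct causal variants, H4 one shared causal variant)
uses the standard per-configuration sums with priors p1, p2, p12,
accumulated in log space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

PRIOR_SD_QUANTITATIVE = 0.15
PRIOR_SD_BINARY = 0.2

_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def wakefield_labf(
    beta: np.ndarray | None = None,
    se: np.ndarray | None = None,
    p: np.ndarray | None = None,
    maf: np.ndarray | None = None,
    n: np.ndarray | None = None,
    prior_sd: float = PRIOR_SD_QUANTITATIVE,
) -> np.ndarray:
    """Per-variant log ABF from beta/SE, or from p/MAF/N when beta is absent."""
    W = prior_sd**2
    if beta is not None and se is not None:
        V = np.asarray(se, dtype=float) ** 2
        if (V <= 0).any():
            raise ValueError("non-positive sampling variance")
        z = np.asarray(beta, dtype=float) / np.asarray(se, dtype=float)
    else:
        if p is None or maf is None or n is None:
            raise ValueError("need beta/se or p/maf/n")
        f = np.asarray(maf, dtype=float)
        if ((f <= 0) | (f >= 1)).any():
            raise ValueError("allele frequency must be in (0, 1)")
        pv = np.asarray(p, dtype=float).copy()
        tiny = np.finfo(float).tiny
        if (pv <= 0).any():
            logger.warning("clamping %d zero p-values", int((pv <= 0).sum()))
            pv = np.maximum(pv, tiny)
        V = 1.0 / (2.0 * np.asarray(n, dtype=float) * f * (1 - f))
        z = st.norm.isf(pv / 2.0)
    r = W / (V + W)
    return 0.5 * np.log1p(-r) + 0.5 * r * z**2


@dataclass
class ColocResult:
    pp_h0: float
    pp_h1: float
    pp_h2: float
    pp_h3: float
    pp_h4: float
    p1: float
    p2: float
    p12: float
    n_variants: int

    def as_dict(self) -> dict:
        return dict(
            PP_H0=self.pp_h0, PP_H1=self.pp_h1, PP_H2=self.pp_h2,
            PP_H3=self.pp_h3, PP_H4=self.pp_h4, n_variants=self.n_variants,
        )


def coloc_abf(
    labf1: np.ndarray,
    labf2: np.ndarray,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
) -> ColocResult:
    """Posterior hypothesis probabilities from two aligned lABF vectors."""
    l1 = np.asarray(labf1, dtype=float)
    l2 = np.asarray(labf2, dtype=float)
    if l1.shape != l2.shape:
        raise ValueError("variant sets of the two traits do not match")
    m = len(l1)
    if m == 0:
        raise ValueError("empty locus")
    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    # sum over ordered distinct pairs: (sum_i e^a_i)(sum_j e^b_j) - sum_i e^(a_i+b_i)
    lh0 = 0.0
    lh1 = np.log(p1) + s1
    lh2 = np.log(p2) + s2
    both = s1 + s2
    if m > 1:
        # log( e^both - e^s12 ), guarded for the single-variant case
        diff = both + np.log1p(-np.exp(np.minimum(s12 - both, 0.0)))
        lh3 = np.log(p1) + np.log(p2) + diff if np.isfinite(diff) else -np.inf
    else:
        lh3 = -np.inf
    lh4 = np.log(p12) + s12
    ls = np.array([lh0, lh1, lh2, lh3, lh4])
    post = np.exp(ls - logsumexp(ls[np.isfinite(ls)]))
    post[~np.isfinite(ls)] = 0.0
    post = post / post.sum()
    return ColocResult(*post, p1=p1, p2=p2, p12=p12, n_variants=m)


def align_alleles(
    t1: pd.DataFrame, t2: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Intersect two summary-stat tables on (chrom, pos, ref, alt), flipping
    strand-unambiguous allele swaps (beta sign and frequency) and dropping
    ambiguous A/T and C/G variants with a log message.

    Both tables need chrom, pos, ref, alt columns; beta/maf are adjusted when
    a swap is applied.
    """
    key = ["chrom", "pos"]
    merged = t1.merge(t2, on=key, suffixes=("_1", "_2"))
    keep, flip = [], []
    n_ambiguous = 0
    for idx, row in merged.iterrows():
        r1, a1 = str(row["ref_1"]).upper(), str(row["alt_1"]).upper()
        r2, a2 = str(row["ref_2"]).upper(), str(row["alt_2"]).upper()
        if (r1, a1) in _AMBIGUOUS:
            n_ambiguous += 1
            continue
        if (r1, a1) == (r2, a2):
            keep.append(idx); flip.append(False)
        elif (r1, a1) == (a2, r2):
            keep.append(idx); flip.append(True)
        elif (_COMP.get(r1), _COMP.get(a1)) == (r2, a2):
            keep.append(idx); flip.append(False)
        elif (_COMP.get(r1), _COMP.get(a1)) == (a2, r2):
            keep.append(idx); flip.append(True)
    if n_ambiguous:
        logger.info("dropped %d strand-ambiguous variants", n_ambiguous)
    merged = merged.loc[keep].copy()
    flip = np.asarray(flip, dtype=bool)
    if "beta_2" in merged.columns:
        merged.loc[flip, "beta_2"] *= -1
    if "maf_2" in merged.columns:
        merged.loc[flip, "maf_2"] = 1 - merged.loc[flip, "maf_2"]
    out1 = merged[[c for c in merged.columns if not c.endswith("_2")]].rename(
        columns=lambda c: c[:-2] if c.endswith("_1") else c
    )
    out2 = merged[key + [c for c in merged.columns if c.endswith("_2")]].rename(
        columns=lambda c: c[:-2] if c.endswith("_2") else c
    )
    return out1.reset_index(drop=True), out2.reset_index(drop=True)
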