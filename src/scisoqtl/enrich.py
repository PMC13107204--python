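"""LD pruning, splice-junction-site classification, interval enrichment,
contingency tests and population-specificity flags for QTL variants."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from .models import GenomicInterval

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def ld_prune(
    dosages: pd.DataFrame,
    window: int = 200,
    step: int = 1,
    r2: float = 0.1,
) -> list[str]:
    """Greedy left-to-right pruning (plink indep-pairwise semantics).

    ``dosages`` columns must be position-sorted variants.  Within each
    sliding window of ``window`` variants advancing by ``step``, for any
    surviving pair with dosage r-squared above ``r2`` the later variant is
    dropped.  Deterministic.
    """
    cols = list(dosages.columns)
    n = len(cols)
    if n == 0:
        return []
    X = dosages.to_numpy(dtype=float)
    sd = X.std(axis=0)
    kept = np.ones(n, dtype=bool)
    kept[sd == 0] = True  # monomorphic columns carry no LD signal; keep as-is

    def _r2(i: int, j: int) -> float:
        if sd[i] == 0 or sd[j] == 0:
            return 0.0
        c = np.corrcoef(X[:, i], X[:, j])[0, 1]
        return float(c * c) if np.isfinite(c) else 0.0

    for s in range(0, max(n - 1, 1), step):
        idx = [i for i in range(s, min(s + window, n)) if kept[i]]
        for a in range(len(idx)):
            if not kept[idx[a]]:
                continue
            for b in range(a + 1, len(idx)):
                j = idx[b]
                if kept[j] and _r2(idx[a], j) > r2:
                    kept[j] = False
        if s + window >= n:
            break
    return [c for c, k in zip(cols, kept) if k]


# ---------------------------------------------------------------------------
# Contingency tests
# ---------------------------------------------------------------------------

@dataclass
class ContingencyResult:
    statistic: Optional[float]
    odds_ratio: Optional[float]
    p: float
    method: str


def contingency_test(
    table: np.ndarray, method: str = "chi2_yates"
) -> ContingencyResult:
    """2x2 test: chi-squared with/without Yates continuity correction, or
    Fisher's exact (two-sided).  Sample odds ratio ad/bc; a zero margin
    yields p = 1 with the odds ratio undefined."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return ContingencyResult(statistic=None, odds_ratio=None, p=1.0, method=method)
    a, b, c, d = t.ravel()
    odds = float(a * d / (b * c)) if b * c > 0 else np.inf
    if method in ("chi2_yates", "chi2"):
        res = st.chi2_contingency(t, correction=(method == "chi2_yates"))
        return ContingencyResult(float(res.statistic), odds, float(res.pvalue), method)
    if method == "fisher":
        _, p = st.fisher_exact(t.astype(int), alternative="two-sided")
        return ContingencyResult(None, odds, float(p), method)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Splice-junction-site classification
# ---------------------------------------------------------------------------

def classify_sjs(
    variants: pd.DataFrame,
    windows: Sequence[GenomicInterval],
    eisoform_counts: pd.Series,
    method: str = "chi2_yates",
) -> tuple[pd.Series, ContingencyResult]:
    """Flag variants falling inside any splice-junction-site window and test
    whether sjs variants are enriched for association with >1 eIsoform.

    ``variants`` needs chrom and pos columns (index = variant ids, assumed
    LD-pruned); ``eisoform_counts`` maps variant id -> number of associated
    eIsoforms.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append((w.start, w.end))
    flags = pd.Series(False, index=variants.index)
    for vid, row in variants.iterrows():
        for s, e in by_chrom.get(row["chrom"], ()):
            if s <= row["pos"] <= e:
                flags.loc[vid] = True
                break
    multi = eisoform_counts.reindex(variants.index).fillna(0) > 1
    table = np.array(
        [
            [int((flags & multi).sum()), int((flags & ~multi).sum())],
            [int((~flags & multi).sum()), int((~flags & ~multi).sum())],
        ]
    )
    return flags, contingency_test(table, method=method)


# ---------------------------------------------------------------------------
# Interval enrichment
# ---------------------------------------------------------------------------

def _in_any(pos_df: pd.DataFrame, intervals: Sequence[GenomicInterval]) -> np.ndarray:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = np.zeros(len(pos_df), dtype=bool)
    for i, (_, row) in enumerate(pos_df.iterrows()):
        for s, e in by_chrom.get(row["chrom"], ()):
            if s <= row["pos"] <= e:
                out[i] = True
                break
    return out


def interval_enrichment(
    query: pd.DataFrame,
    interval_sets: dict[str, Sequence[GenomicInterval]],
    background: pd.DataFrame,
    method: str = "fisher",
) -> pd.DataFrame:
    """Per-category enrichment of query variants vs background variants in
    interval sets (Fisher by default), BH-adjusted across categories."""
    rows = []
    for cat, ivs in interval_sets.items():
        if not ivs:
            logger.info("category %s has no intervals; skipped", cat)
            continue
        q_in = int(_in_any(query, ivs).sum())
        b_in = int(_in_any(background, ivs).sum())
        table = np.array(
            [[q_in, len(query) - q_in], [b_in, len(background) - b_in]]
        )
        res = contingency_test(table, method=method)
        rows.append(
            dict(
                category=cat, query_in=q_in, query_total=len(query),
                background_in=b_in, background_total=len(background),
                odds_ratio=res.odds_ratio, p=res.p,
            )
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["adjusted_p"] = multipletests(df["p"], method="fdr_bh")[1]
        df["significant"] = df["adjusted_p"] < 0.05
    return df


# ---------------------------------------------------------------------------
# Population specificity
# ---------------------------------------------------------------------------

def population_specificity(
    leads: Sequence[str],
    panel_maf: pd.Series,
    replication_leads: Sequence[str],
    ld_r2: pd.DataFrame,
    collapse_r2: float = 0.8,
    rare_maf: float = 0.01,
    independent_r2: float = 0.1,
) -> pd.DataFrame:
    """Collapse lead variants in high LD to one representative, then flag
    each independent lead as population-restricted (comparison-panel MAF
    below ``rare_maf``; absent = monomorphic) and/or independent-signal
    (r-squared below ``independent_r2`` with every replication lead, or
    monomorphic in the panel)."""
    reps = []
    for v in leads:
        absorbed = any(
            v != r and v in ld_r2.index and r in ld_r2.columns
            and float(ld_r2.loc[v, r]) > collapse_r2
            for r in reps
        )
        if not absorbed:
            reps.append(v)
    rows = []
    for v in reps:
        maf = float(panel_maf.get(v, 0.0))
        monomorphic = maf <= 0.0
        restricted = maf < rare_maf
        if monomorphic:
            independent = True
        else:
            r2s = [
                float(ld_r2.loc[v, r])
                for r in replication_leads
                if v in ld_r2.index and r in ld_r2.columns
            ]
            independent = all(r < independent_r2 for r in r2s) if r2s else True
        rows.append(
            dict(
                variant=v, panel_maf=maf, monomorphic=monomorphic,
                population_restricted=restricted, independent_signal=independent,
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Alternative-promoter overlap
# ---------------------------------------------------------------------------

def promoter_overlap(
    isoform_tss: dict[str, tuple[str, int]],
    peaks: Sequence[GenomicInterval],
    canonical_tss: Sequence[tuple[str, int]],
    window: int = 2000,
) -> list[tuple[str, GenomicInterval]]:
    """(isoform, peak) pairs where the peak overlaps the isoform's TSS +/-
    ``window`` but no canonical TSS +/- ``window``."""
    out = []
    for iso, (chrom, tss) in isoform_tss.items():
        lo, hi = tss - window, tss + window
        for peak in peaks:
            if peak.chrom != chrom or peak.end < lo or peak.start > hi:
                continue
            hits_canonical = any(
                peak.chrom == c and peak.end >= t - window and peak.start <= t + window
                for c, t in canonical_tss
            )
            if not hits_canonical:
                out.append((iso, peak))
    return out
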