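"""One-vs-rest pseudo-bulk differential isoform expression.

Each (individual, cell type) pseudo-bulk sample is one observation; for a
target cell type, an NB GLM with a group indicator (target vs rest) and a
log library-size offset is fit per isoform.  log2FC is the group
coefficient divided by ln 2, p-values are Wald, and BH adjustment runs
across isoforms within the cell type.  A DEI requires log2FC > 1 (strict)
and adjusted p < 0.05.

The permutation audit shuffles cell-type labels of the samples, recomputes
significance (adjusted p < 0.05, no fold-change gate) ``n_perm`` times, and
flags isoforms significant in strictly more than ``flag_count`` permutations
as potential false positives.  For speed the audit uses the NB score test
against each isoform's label-free null fit, which is permutation-invariant;
score and Wald tests are asymptotically equivalent here.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from .qtlmap import _null_state, _score_pvalues, add_intercept, fit_nb_glm

logger = logging.getLogger(__name__)

LN2 = float(np.log(2.0))


def dei_one_vs_rest(
    counts: pd.DataFrame,
    cell_types: pd.Series,
    target: str,
    log2fc_cut: float = 1.0,
    alpha: float = 0.05,
    most_abundant: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Differential isoform expression of ``target`` against all other cell types.

    ``counts`` holds pseudo-bulk samples (rows = (individual, cell type)
    samples, columns = isoforms) and ``cell_types`` the per-sample label.
    """
    labels = cell_types.loc[counts.index]
    if target not in set(labels):
        raise ValueError(f"cell type {target!r} absent")
    group = (labels == target).to_numpy(dtype=float)
    lib = counts.to_numpy().sum(axis=1).astype(float)
    offset = np.log(np.maximum(lib, 1.0))
    X = np.column_stack([np.ones(len(group)), group])
    rows = []
    for iso in counts.columns:
        y = counts[iso].to_numpy(dtype=float)
        try:
            fit = fit_nb_glm(y, X, offset)
        except ValueError as exc:
            logger.warning("isoform %s dropped from DE: %s", iso, exc)
            continue
        beta, se = float(fit.coef[1]), float(fit.se[1])
        p = 2 * st.norm.sf(abs(beta / se)) if se > 0 else 1.0
        rows.append(dict(isoform=iso, cell_type=target, log2fc=beta / LN2, p=float(p)))
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["adjusted_p"] = multipletests(df["p"], method="fdr_bh")[1]
    df["dei"] = (df["log2fc"] > log2fc_cut) & (df["adjusted_p"] < alpha)
    if most_abundant is not None:
        df["most_abundant"] = df["isoform"].map(most_abundant).fillna(False)
    return df


def dei_all_cell_types(
    counts: pd.DataFrame, cell_types: pd.Series, **kwargs
) -> pd.DataFrame:
    parts = [
        dei_one_vs_rest(counts, cell_types, ct, **kwargs)
        for ct in sorted(set(cell_types.loc[counts.index]))
    ]
    return pd.concat(parts, ignore_index=True)


def dei_permutation_audit(
    counts: pd.DataFrame,
    cell_types: pd.Series,
    target: str,
    n_perm: int = 1000,
    flag_count: int = 50,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Flag isoforms significant in strictly more than ``flag_count`` of
    ``n_perm`` label permutations (adjusted p < alpha, no fold-change gate)."""
    if n_perm < 100:
        raise ValueError("the audit rule is undefined below 100 permutations")
    labels = cell_types.loc[counts.index]
    if target not in set(labels):
        raise ValueError(f"cell type {target!r} absent")
    rng = np.random.default_rng(seed)
    group = (labels == target).to_numpy(dtype=float)
    lib = counts.to_numpy().sum(axis=1).astype(float)
    offset = np.log(np.maximum(lib, 1.0))
    n = len(group)
    X0 = np.ones((n, 1))

    # label-free null fits are permutation-invariant; cache their score state
    states = {}
    for iso in counts.columns:
        y = counts[iso].to_numpy(dtype=float)
        try:
            fit = fit_nb_glm(y, X0, offset)
        except ValueError:
            continue
        states[iso] = _null_state(fit, y, X0)

    isos = list(states)
    hits = np.zeros(len(isos), dtype=int)
    for _ in range(n_perm):
        g = group[rng.permutation(n)][:, None]
        ps = np.array([_score_pvalues(g, states[iso])[0] for iso in isos])
        adj = multipletests(ps, method="fdr_bh")[1]
        hits += adj < alpha
    out = pd.DataFrame(
        {"isoform": isos, "times_significant": hits, "n_perm": n_perm}
    )
    out["flagged"] = out["times_significant"] > flag_count
    return out
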