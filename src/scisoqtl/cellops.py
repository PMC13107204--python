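"""Cell calling, pseudo-bulk aggregation and expression covariates.

Cell calling follows the percentile heuristic used for long-read droplet
data: take the P-th percentile of per-barcode UMI totals, divide by 10, and
keep barcodes at or above the cutoff.  The percentile is calibrated per
batch against an external expected cell number (here, a short-read count):
among candidate percentiles, pick the one whose called count is the
smallest count still exceeding the reference.

Pseudo-bulking sums single-cell counts per individual within one cell type,
keeping only individuals contributing more than ``min_cells`` cells, and
only isoforms expressed by more than ``min_frac`` of retained individuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .models import CellCounts, PseudobulkMatrix

logger = logging.getLogger(__name__)


@dataclass
class CellCallingResult:
    percentile: float
    cutoff: float
    called: list[str]

    @property
    def n_called(self) -> int:
        return len(self.called)


def call_cells(umi_counts: pd.Series, percentile: float) -> CellCallingResult:
    """Call cells whose UMI total is at least (P-th percentile) / 10.

    Percentiles use linear interpolation between order statistics.
    """
    if len(umi_counts) == 0:
        raise ValueError("no barcodes")
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    cutoff = float(np.percentile(umi_counts.to_numpy(dtype=float), percentile)) / 10.0
    called = umi_counts.index[umi_counts.to_numpy(dtype=float) >= cutoff].tolist()
    return CellCallingResult(percentile=percentile, cutoff=cutoff, called=called)


def calibrate_percentile(
    umi_counts: pd.Series,
    reference_n: int,
    candidates: Sequence[float] = (95, 96, 97, 98, 99),
) -> CellCallingResult:
    """Pick the candidate percentile whose called count is the smallest one
    still exceeding ``reference_n``; if none exceeds it, fall back to the
    candidate calling the most cells (logged as under-calling)."""
    if not candidates:
        raise ValueError("empty candidate set")
    if reference_n < 0:
        raise ValueError("reference_n must be >= 0")
    results = [call_cells(umi_counts, p) for p in candidates]
    exceeding = [r for r in results if r.n_called > reference_n]
    if exceeding:
        return min(exceeding, key=lambda r: (r.n_called, r.percentile))
    best = max(results, key=lambda r: r.n_called)
    logger.warning(
        "no candidate percentile exceeds reference %d cells; "
        "under-calling with P=%g (%d cells)",
        reference_n, best.percentile, best.n_called,
    )
    return best


def pseudobulk(
    cells: CellCounts, cell_type: str, min_cells: int = 5
) -> PseudobulkMatrix:
    """Sum counts per individual over one cell type's cells.

    Individuals with ``min_cells`` or fewer cells of that type are excluded
    (the inclusion rule is strictly more than ``min_cells``).
    """
    if cell_type not in set(cells.cells["cell_type"]):
        raise ValueError(f"cell type {cell_type!r} absent from metadata")
    mask = (cells.cells["cell_type"] == cell_type).to_numpy()
    sub = cells.matrix[mask]
    inds = cells.cells.loc[mask, "individual"].to_numpy()
    counts_by_ind = {}
    for ind in pd.unique(inds):
        rows = np.flatnonzero(inds == ind)
        if len(rows) <= min_cells:
            continue
        counts_by_ind[ind] = np.asarray(sub[rows].sum(axis=0)).ravel()
    if not counts_by_ind:
        logger.warning("no individual passes the >%d cells filter for %s", min_cells, cell_type)
        empty = pd.DataFrame(columns=cells.isoforms, dtype=int)
        return PseudobulkMatrix(counts=empty, cell_type=cell_type)
    df = pd.DataFrame.from_dict(counts_by_ind, orient="index", columns=cells.isoforms)
    df = df.astype(int).sort_index()
    return PseudobulkMatrix(counts=df, cell_type=cell_type)


def filter_isoforms(pb: PseudobulkMatrix, min_frac: float = 0.2) -> PseudobulkMatrix:
    """Keep isoforms with nonzero counts in strictly more than ``min_frac``
    of the retained individuals."""
    if pb.counts.empty:
        return pb
    n = pb.counts.shape[0]
    expressed = (pb.counts.to_numpy() > 0).sum(axis=0)
    keep = expressed > min_frac * n
    return PseudobulkMatrix(
        counts=pb.counts.loc[:, pb.counts.columns[keep]],
        cell_type=pb.cell_type,
        covariates=pb.covariates,
    )


def normalize_log(pb_counts: pd.DataFrame) -> pd.DataFrame:
    """log1p of counts scaled to the median library size (per individual)."""
    lib = pb_counts.to_numpy().sum(axis=1).astype(float)
    lib[lib == 0] = 1.0
    scale = np.median(lib) / lib
    return pd.DataFrame(
        np.log1p(pb_counts.to_numpy() * scale[:, None]),
        index=pb_counts.index,
        columns=pb_counts.columns,
    )


def elbow_k(eigenvalues: np.ndarray) -> int:
    """Elbow of a scree curve: the point with maximum perpendicular distance
    to the chord from the first to the last eigenvalue (at least 1)."""
    ev = np.asarray(eigenvalues, dtype=float)
    m = len(ev)
    if m <= 2:
        return 1
    x = np.arange(m, dtype=float)
    p0 = np.array([x[0], ev[0]])
    p1 = np.array([x[-1], ev[-1]])
    chord = p1 - p0
    norm = np.hypot(*chord)
    if norm == 0:
        return 1
    pts = np.stack([x, ev], axis=1) - p0
    dist = np.abs(pts[:, 0] * chord[1] - pts[:, 1] * chord[0]) / norm
    return max(1, int(np.argmax(dist)) + 1)


def expression_pcs(pb: PseudobulkMatrix, max_k: int | None = None) -> tuple[pd.DataFrame, int]:
    """Principal components of the standardized log-normalized isoform matrix.

    Returns all PCs up to the matrix rank together with the elbow-selected
    number K; callers use the first K columns as covariates.
    """
    if pb.counts.shape[0] < 3:
        raise ValueError("need at least 3 individuals for expression PCs")
    X = normalize_log(pb.counts).to_numpy()
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = X / sd
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    tol = s.max() * max(X.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int((s > tol).sum())
    rank = max(rank, 1)
    eigen = (s[:rank] ** 2) / max(X.shape[0] - 1, 1)
    k = min(elbow_k(eigen), rank)
    if max_k is not None:
        k = min(k, max_k)
    pcs = pd.DataFrame(
        u[:, :rank] * s[:rank],
        index=pb.counts.index,
        columns=[f"PC{i + 1}" for i in range(rank)],
    )
    return pcs, k


def build_covariates(
    pb: PseudobulkMatrix,
    genotype_pcs: pd.DataFrame | None = None,
    batch: pd.Series | None = None,
    age: pd.Series | None = None,
    n_genotype_pcs: int = 3,
    max_expression_pcs: int | None = None,
) -> pd.DataFrame:
    """Covariate table: genotype PCs, elbow-selected expression PCs,
    one-hot batch (drop-first), and age, aligned to the pseudobulk rows.

    The expression-PC count is the scree elbow, additionally capped at one
    tenth of the cohort size (or ``max_expression_pcs``) so the covariate
    count stays well below the number of individuals.
    """
    idx = pb.counts.index
    parts = []
    if genotype_pcs is not None:
        parts.append(genotype_pcs.loc[idx].iloc[:, :n_genotype_pcs].add_prefix("geno_"))
    if max_expression_pcs is None:
        max_expression_pcs = max(1, len(idx) // 10)
    pcs, k = expression_pcs(pb, max_k=max_expression_pcs)
    parts.append(pcs.iloc[:, :k].add_prefix("expr_"))
    if batch is not None:
        dummies = pd.get_dummies(batch.loc[idx], prefix="batch", drop_first=True).astype(float)
        parts.append(dummies)
    if age is not None:
        parts.append(age.loc[idx].rename("age").to_frame().astype(float))
    return pd.concat(parts, axis=1)
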