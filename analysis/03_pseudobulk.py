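#!/usr/bin/env python
"""Pseudo-bulk the simulated cells per cell type and build covariates.

Applies the inclusion filters (more than 5 cells per individual, isoforms
expressed by more than 20% of retained individuals), computes elbow-selected
expression PCs plus batch covariates, and writes one counts + covariates TSV
pair per cell type.
"""

from pathlib import Path

import pandas as pd

from scisoqtl import cellops, io

SIM = Path(__file__).resolve().parent.parent / "results" / "sim"
OUT = SIM.parent / "pseudobulk"
OUT.mkdir(parents=True, exist_ok=True)

cells = io.read_cell_counts(SIM / "counts.mtx", SIM / "cells.tsv", SIM / "features.tsv")
batch_by_ind = (
    cells.cells.groupby("individual")["batch"].first()
)

for ct in sorted(cells.cells["cell_type"].unique()):
    pb = cellops.filter_isoforms(cellops.pseudobulk(cells, ct))
    cov = cellops.build_covariates(pb, batch=batch_by_ind)
    pb.counts.to_csv(OUT / f"{ct}.counts.tsv", sep="\t")
    cov.to_csv(OUT / f"{ct}.covariates.tsv", sep="\t")
    n_expr_pcs = sum(c.startswith("expr_") for c in cov.columns)
    print(
        f"{ct}: {pb.counts.shape[0]} individuals x {pb.counts.shape[1]} isoforms, "
        f"{n_expr_pcs} expression PCs, {cov.shape[1]} covariate columns"
    )
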