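#!/usr/bin/env python
"""Functional enrichment of the mapped isoQTLs.

LD-prunes the tested variants, flags splice-junction-site isoQTLs against
the annotation windows, tests sjs enrichment for multi-isoform association,
and runs an interval enrichment of significant vs background variants in
the sjs windows, plus the worked rare-allele contingency example.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from scisoqtl import enrich, io
from scisoqtl.config import RunConfig

ROOT = Path(__file__).resolve().parent.parent / "results"
SIM, QTL, ANN, OUT = ROOT / "sim", ROOT / "qtl", ROOT / "annotation", ROOT / "enrichment"
OUT.mkdir(parents=True, exist_ok=True)
cfg = RunConfig.from_yaml(SIM / "config.yaml")

genotypes = io.read_genotypes(SIM / "genotypes.vcf")
windows = io.read_bed(ANN / "sjs_windows.bed")
qtl = pd.concat(
    [pd.read_csv(p, sep="\t") for p in sorted(QTL.glob("*.qtl.tsv"))],
    ignore_index=True,
)

kept = enrich.ld_prune(
    genotypes.dosages,
    window=cfg.ld_prune_window, step=cfg.ld_prune_step, r2=cfg.ld_prune_r2,
)
print(f"LD pruning kept {len(kept)}/{genotypes.n_variants} variants")

sig = qtl[qtl["eisoform"]]
lead_counts = sig.groupby("lead_variant")["isoform"].nunique()
lead_ids = [v for v in lead_counts.index if v in kept]
variants = genotypes.variants.loc[lead_ids, ["chrom", "pos"]]
flags, test = enrich.classify_sjs(variants, windows, lead_counts.loc[lead_ids])
print(
    f"sjs-isoQTLs: {int(flags.sum())}/{len(flags)} lead variants in 2-bp "
    f"intron-end windows (multi-isoform enrichment p = {test.p:.3g})"
)

background = genotypes.variants.loc[
    [v for v in kept if v not in set(lead_counts.index)], ["chrom", "pos"]
]
enr = enrich.interval_enrichment(
    genotypes.variants.loc[lead_ids, ["chrom", "pos"]],
    {"sjs_windows": windows},
    background,
)
enr.to_csv(OUT / "interval_enrichment.tsv", sep="\t", index=False)
if not enr.empty:
    r = enr.iloc[0]
    odds = "NA" if r["odds_ratio"] is None else f"{r['odds_ratio']:.2f}"
    print(f"interval enrichment (sjs windows): OR {odds}, p {r['p']:.3g}")

res = enrich.contingency_test(np.array([[158, 1161], [103, 1231]]), "chi2_yates")
print(f"rare-allele 2x2 worked example: chi2 p = {res.p:.6g}")
pd.Series(flags, name="sjs").to_csv(OUT / "sjs_flags.tsv", sep="\t")
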