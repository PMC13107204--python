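#!/usr/bin/env python
"""Harmonize lead-QTL effects across cell types and classify sharing.

Builds the strong set (lead pairs) from the per-cell-type QTL tables with
z imputed as 0 where a pair was untested, fits the EZ mixture on a random
z set drawn from the null scan background, and writes posterior effects,
lfsr and the sharing profile.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from scisoqtl import crosscell
from scisoqtl.config import RunConfig

ROOT = Path(__file__).resolve().parent.parent / "results"
QTL, OUT = ROOT / "qtl", ROOT / "sharing"
OUT.mkdir(parents=True, exist_ok=True)
cfg = RunConfig.from_yaml(ROOT / "sim" / "config.yaml")

tables = {
    p.name.split(".")[0]: pd.read_csv(p, sep="\t") for p in sorted(QTL.glob("*.qtl.tsv"))
}
cell_types = sorted(tables)

# strong set: union of eIsoform lead pairs across cell types
strong_pairs = sorted(
    {
        (r["isoform"], r["lead_variant"])
        for df in tables.values()
        for _, r in df[df["eisoform"]].iterrows()
    }
)
z = pd.DataFrame(index=pd.MultiIndex.from_tuples(strong_pairs), columns=cell_types, dtype=float)
se = z.copy()
for ct, df in tables.items():
    d = df.set_index("isoform")
    for iso, var in strong_pairs:
        if iso in d.index:
            row = d.loc[iso]
            z.loc[(iso, var), ct] = row["beta"] / row["se"]
            se.loc[(iso, var), ct] = row["se"]

# random set: z at one randomly drawn cis variant per isoform per cell type
# (mostly null, as the background set should be)
import numpy as _np

from scisoqtl import io as _io
from scisoqtl import qtlmap as _qtlmap
from scisoqtl.models import PseudobulkMatrix as _PB

rng = _np.random.default_rng(cfg.child_seed("share-random"))
genotypes = _io.read_genotypes(ROOT / "sim" / "genotypes.vcf")
tss = pd.read_csv(ROOT / "sim" / "tss.tsv", sep="\t").set_index("isoform")
rand_rows = {}
for ct in cell_types:
    counts = pd.read_csv(ROOT / "pseudobulk" / f"{ct}.counts.tsv", sep="\t", index_col=0)
    offset = _np.log(_np.maximum(counts.sum(axis=1).to_numpy(dtype=float), 1.0))
    D = genotypes.dosages.loc[counts.index]
    col = {}
    for iso in counts.columns:
        if iso not in tss.index:
            continue
        mask = _qtlmap.cis_variant_mask(
            genotypes.variants, tss.loc[iso, "chrom"], int(tss.loc[iso, "tss"]),
            cfg.cis_window,
        )
        vids = list(genotypes.variants.index[mask])
        if not vids:
            continue
        vid = vids[int(rng.integers(len(vids)))]
        X = _np.column_stack([_np.ones(len(counts)), D[vid].to_numpy()])
        try:
            fit = _qtlmap.fit_nb_glm(counts[iso].to_numpy(dtype=float), X, offset)
            col[iso] = fit.coef[1] / fit.se[1]
        except ValueError:
            continue
    rand_rows[ct] = pd.Series(col)
rand = pd.DataFrame(rand_rows).dropna()
V = crosscell.estimate_null_correlation(rand.to_numpy())
model = crosscell.fit_ez_mixture(rand.to_numpy(), V)

effects = crosscell.CrossCellEffects.from_tables(z, se)
effects = crosscell.posterior_summaries(effects, model)
profile, pairwise = crosscell.sharing_metrics(
    effects.posterior_beta, effects.lfsr, fold=cfg.sharing_fold
)
effects.posterior_beta.to_csv(OUT / "posterior_beta.tsv", sep="\t")
effects.lfsr.to_csv(OUT / "lfsr.tsv", sep="\t")
profile.to_csv(OUT / "sharing_profile.tsv", sep="\t", index=False)
pairwise.to_csv(OUT / "pairwise_sharing.tsv", sep="\t")

print(f"{len(strong_pairs)} lead pairs harmonized across {len(cell_types)} cell types")
if not profile.empty:
    print(
        f"specific to one cell type: {int(profile['specific'].sum())}"
        f"/{len(profile)} pairs"
    )
print("pairwise magnitude sharing:")
print(pairwise.round(2).to_string())
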