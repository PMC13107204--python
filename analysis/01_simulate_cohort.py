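#!/usr/bin/env python
"""Generate the synthetic cohort and write it in the pipeline's file formats.

Builds a desk-scale cohort — 60 individuals in batches of 6, two cell types,
40 genes x 3 isoforms, 400 cis variants — with ten planted cis effects
(six cell-type-specific, two shared, two reciprocal pairs), then writes
GTF + VCF + Matrix Market + truth TSV under results/sim/ so every later
stage runs from files alone.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from scisoqtl import io, syndata
from scisoqtl.config import RunConfig

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"
OUT.mkdir(parents=True, exist_ok=True)

cfg = RunConfig(seed=20260924)
rng = np.random.default_rng(cfg.seed)

genotypes = syndata.simulate_genotypes(
    60, 400, ld_block=5, flip_prob=0.15, seed=cfg.child_seed("genotypes")
)
models, references, expected_cat = syndata.simulate_transcriptome(
    40, 3, seed=cfg.child_seed("transcriptome"), gene_spacing=8_000
)
isoforms_by_gene: dict[str, list[str]] = {}
for m in models:
    isoforms_by_gene.setdefault(m.gene_id, []).append(m.transcript_id)

cell_types = ("typeA", "typeB")
weights = syndata.default_usage_weights(
    isoforms_by_gene, cell_types, np.random.default_rng(cfg.child_seed("weights"))
)
tss = {m.transcript_id: m.tss for m in models}
pos = genotypes.variants["pos"]

effects = []
genes = list(isoforms_by_gene)
common = genotypes.variants[genotypes.variants["maf"] >= 0.1]
for k, gene in enumerate(genes[:10]):
    iso = isoforms_by_gene[gene][0]
    vid = (common["pos"] - tss[iso]).abs().idxmin()
    beta = 0.8 if k % 2 == 0 else -0.8
    if k < 6:  # cell-type-specific
        effects.append(syndata.PlantedEffect(gene, iso, vid, ("typeA",), beta))
    elif k < 8:  # shared across both cell types
        effects.append(syndata.PlantedEffect(gene, iso, vid, cell_types, beta))
    else:  # reciprocal pair within the gene
        partner = isoforms_by_gene[gene][1]
        effects.append(
            syndata.PlantedEffect(gene, iso, vid, ("typeA",), beta,
                                  reciprocal_partner=partner)
        )

design = syndata.EffectDesign(
    cell_types=cell_types, effects=effects, usage_weights=weights
)
cells = syndata.simulate_cells(genotypes, models, design, seed=cfg.child_seed("cells"))

io.write_transcripts(models, OUT / "isoforms.gtf")
io.write_transcripts(references, OUT / "reference.gtf")
io.write_genotypes_vcf(genotypes, OUT / "genotypes.vcf")
io.write_cell_counts(cells, OUT / "counts.mtx", OUT / "cells.tsv", OUT / "features.tsv")
truth = syndata.truth_table(design, [m.transcript_id for m in models])
truth.to_csv(OUT / "truth.tsv", sep="\t", index=False)
pd.DataFrame(
    {"isoform": list(tss), "chrom": [m.chrom for m in models], "tss": list(tss.values())}
).to_csv(OUT / "tss.tsv", sep="\t", index=False)
cfg.to_yaml(OUT / "config.yaml")

n_planted = (truth["label"] != "null").sum()
print(f"wrote cohort to {OUT}")
print(f"  {genotypes.n_individuals} individuals, {genotypes.n_variants} variants")
print(f"  {len(models)} isoforms in {len(genes)} genes, {cells.n_cells} cells")
print(f"  {n_planted} non-null (isoform, cell type) truth rows")
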