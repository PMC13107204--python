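#!/usr/bin/env python
"""Annotate the simulated isoform catalogue against its reference subset.

Reads results/sim/isoforms.gtf, classifies each isoform's structure
(FSM/ISM/NIC/NNC), applies the 50-nt NMD rule, calls pairwise AS events and
writes the splice-junction-site windows as BED.
"""

from pathlib import Path

import pandas as pd

from scisoqtl import annotate, io

SIM = Path(__file__).resolve().parent.parent / "results" / "sim"
OUT = SIM.parent / "annotation"
OUT.mkdir(parents=True, exist_ok=True)

models = io.read_transcripts(SIM / "isoforms.gtf")
references = io.read_transcripts(SIM / "reference.gtf")

table = annotate.annotate_catalogue(models, references)
table.to_csv(OUT / "categories.tsv", sep="\t", index=False)

by_gene: dict[str, list] = {}
for m in models:
    by_gene.setdefault(m.gene_id, []).append(m)
events = []
for gene, isos in by_gene.items():
    events.extend(annotate.classify_as_events(isos))
pd.DataFrame(
    [(e.gene_id, e.isoform_a, e.isoform_b, e.event_type, e.chrom,
      e.region_start, e.region_end) for e in events],
    columns=["gene", "isoform_a", "isoform_b", "event", "chrom", "start", "end"],
).to_csv(OUT / "as_events.tsv", sep="\t", index=False)

windows = annotate.sjs_windows(models)
io.write_bed(windows, OUT / "sjs_windows.bed")

print(f"annotated {len(models)} isoforms:")
print(table["category"].value_counts().to_string())
print(f"NMD-sensitive: {int(table['nmd_sensitive'].fillna(False).sum())}")
print(f"AS events: {len(events)} ({pd.Series([e.event_type for e in events]).value_counts().to_dict()})")
print(f"sjs windows: {len(windows)} -> {OUT / 'sjs_windows.bed'}")
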