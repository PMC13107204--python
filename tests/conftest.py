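import numpy as np
import pandas as pd
import pytest

from scisoqtl.models import GenomicInterval, TranscriptModel


def make_transcript(tid, exons, strand="+", gene="geneX", chrom="chr1", **kw):
    return TranscriptModel(
        tid, gene, chrom, strand,
        [GenomicInterval(chrom, s, e, strand) for s, e in exons], **kw
    )


@pytest.fixture
def two_exon_plus():
    return make_transcript("t1", [(100, 200), (300, 400)])


@pytest.fixture
def five_exon_ref():
    return make_transcript(
        "ref", [(100, 200), (300, 400), (500, 600), (700, 800), (900, 1000)]
    )


@pytest.fixture
def small_cohort():
    """A tiny cohort with one planted effect, shared across tests needing
    realistic genotype/count inputs."""
    from scisoqtl import syndata

    gt = syndata.simulate_genotypes(40, 60, ld_block=3, flip_prob=0.1, seed=7)
    models, refs, expected = syndata.simulate_transcriptome(
        6, 2, seed=8, gene_spacing=5_000
    )
    isoforms_by_gene = {}
    for m in models:
        isoforms_by_gene.setdefault(m.gene_id, []).append(m.transcript_id)
    weights = syndata.default_usage_weights(
        isoforms_by_gene, ("typeA",), np.random.default_rng(9)
    )
    iso = models[0].transcript_id
    vid = (gt.variants["pos"] - models[0].tss).abs().idxmin()
    effects = [syndata.PlantedEffect(models[0].gene_id, iso, vid, ("typeA",), 0.9)]
    design = syndata.EffectDesign(
        cell_types=("typeA",), effects=effects, usage_weights=weights
    )
    cells = syndata.simulate_cells(gt, models, design, seed=10)
    tss = pd.DataFrame(
        {"chrom": [m.chrom for m in models], "tss": [m.tss for m in models]},
        index=[m.transcript_id for m in models],
    )
    return dict(
        genotypes=gt, models=models, design=design, cells=cells, tss=tss,
        planted_isoform=iso, planted_variant=vid,
    )
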