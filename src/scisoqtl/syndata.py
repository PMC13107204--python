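"""Synthetic cohort generator: genotypes, transcript models and single-cell
isoform counts with planted cis effects.

The generator emulates the structure of a multiplexed single-cell long-read
QTL study: N individuals split into batches of ~6, several cell types,
per-cell negative-binomial isoform counts with lognormal library-size
variation and multiplicative lognormal batch effects, and cis effects
planted on isoform means that can be cell-type-specific, shared across cell
types, or reciprocal between two isoforms of one gene (usage shifts in
opposite directions with the gene total preserved).

Per cell c of individual i in cell type t, the count of isoform j of gene g
is NB(mean, alpha_sim) with

    mean = s_c * b_batch(i) * mu_(g,t) * w_(j,t) * exp(beta * dosage_i)

where s_c is a lognormal cell size factor, b the batch multiplier, mu the
gene-level per-cell mean, w the isoform usage weight (summing to 1 within
the gene) and beta the planted allelic log effect (0 unless planted for t).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .models import CellCounts, GenomicInterval, GenotypeTable, TranscriptModel

NULL, SPECIFIC, SHARED, RECIPROCAL = "null", "specific", "shared", "reciprocal"


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(
    n_individuals: int,
    n_variants: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_block: int = 1,
    flip_prob: float = 0.1,
    seed: int = 0,
    chrom: str = "chr1",
    start_pos: int = 1_000_000,
    spacing: int = 2_000,
) -> GenotypeTable:
    """Hardy-Weinberg dosages with block LD structure.

    Variants are grouped into blocks of ``ld_block``; the block founder is
    drawn under HW equilibrium and the other members copy each founder
    haplotype, resampling it from its allele frequency with probability
    ``flip_prob`` (so pairwise allele correlation is about 1 - flip_prob and
    flip_prob = 0 gives exact copies, r^2 = 1).
    """
    if n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    lo, hi = maf_range
    if not (0.05 <= lo <= hi <= 0.5):
        raise ValueError("maf_range bounds must lie in [0.05, 0.5]")
    if ld_block < 1:
        raise ValueError("ld_block must be >= 1")
    rng = np.random.default_rng(seed)
    hap = np.empty((2, n_individuals, n_variants), dtype=np.int8)
    mafs = np.empty(n_variants)
    for v in range(n_variants):
        if v % ld_block == 0:
            p = rng.uniform(lo, hi)
            founder = rng.random((2, n_individuals)) < p
            hap[:, :, v] = founder
            mafs[v] = p
        else:
            f = v - (v % ld_block)
            p = mafs[f]
            resample = rng.random((2, n_individuals)) < flip_prob
            fresh = rng.random((2, n_individuals)) < p
            hap[:, :, v] = np.where(resample, fresh, hap[:, :, f])
            mafs[v] = p
    dose = hap.sum(axis=0).astype(float)
    inds = [f"ind{i:04d}" for i in range(n_individuals)]
    vids = [f"var{v:05d}" for v in range(n_variants)]
    realized = dose.mean(axis=0) / 2.0
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": start_pos + spacing * np.arange(n_variants),
            "ref": "A",
            "alt": "G",
            "maf": np.minimum(realized, 1 - realized),
            "rsq": 1.0,
        },
        index=vids,
    )
    return GenotypeTable(
        dosages=pd.DataFrame(dose, index=inds, columns=vids), variants=variants
    )


# ---------------------------------------------------------------------------
# Transcriptome
# ---------------------------------------------------------------------------

_EXON_LEN = 150
_INTRON_LEN = 350
_N_EXONS = 5


def _canonical_model(gene: str, chrom: str, strand: str, base: int) -> TranscriptModel:
    exons = [
        GenomicInterval(chrom, base + k * (_EXON_LEN + _INTRON_LEN),
                        base + k * (_EXON_LEN + _INTRON_LEN) + _EXON_LEN - 1, strand)
        for k in range(_N_EXONS)
    ]
    return TranscriptModel(f"{gene}.ref", gene, chrom, strand, exons)


def _variant_model(ref: TranscriptModel, kind: str, tid: str) -> tuple[TranscriptModel, str]:
    """One structural variant of the canonical model plus its expected category."""
    ex = ref.exons
    chrom, strand = ref.chrom, ref.strand
    if kind == "skip":  # exon skipping: novel junction from known sites -> NIC
        exons = [e for i, e in enumerate(ex) if i != 2]
        expected = "NIC"
    elif kind == "ism":  # 5' truncation: contiguous intron sub-chain -> ISM
        exons = ex[1:]
        expected = "ISM"
    elif kind == "nnc":  # donor shifted off any reference site -> NNC
        exons = list(ex)
        exons[1] = GenomicInterval(chrom, ex[1].start, ex[1].end + 5, strand)
        expected = "NNC"
    elif kind == "ri":  # intron retention: remaining junctions known -> NIC
        exons = [ex[0], ex[1], GenomicInterval(chrom, ex[2].start, ex[3].end, strand), ex[4]]
        expected = "NIC"
    elif kind == "af":  # alternative first exon with a novel donor -> NNC
        new_first = GenomicInterval(chrom, ex[0].start - 600, ex[0].start - 451, strand)
        exons = [new_first] + list(ex[1:])
        expected = "NNC"
    else:
        raise ValueError(f"unknown variant kind {kind!r}")
    return TranscriptModel(tid, ref.gene_id, chrom, strand, exons), expected


def _place_cds(model: TranscriptModel, nmd: bool) -> TranscriptModel:
    """CDS spanning most of the transcript, with the stop codon placed either
    in the terminal exon (NMD-insensitive) or >=50 nt upstream of the last
    junction (sensitive)."""
    ex = model.exons
    if model.strand != "-":
        cds_start = ex[0].start + 10
        cds_end = (ex[-2].end - 60) if (nmd and len(ex) >= 2) else (ex[-1].start + 60)
    else:
        cds_end = ex[-1].end - 10
        cds_start = (ex[1].start + 60) if (nmd and len(ex) >= 2) else (ex[0].end - 60)
    from dataclasses import replace

    return replace(model, cds_start=cds_start, cds_end=cds_end)


def simulate_transcriptome(
    n_genes: int,
    isoforms_per_gene: int = 3,
    nmd_fraction: float = 0.25,
    seed: int = 0,
    chrom: str = "chr1",
    start_pos: int = 1_050_000,
    gene_spacing: int = 40_000,
) -> tuple[list[TranscriptModel], list[TranscriptModel], dict[str, str]]:
    """Toy multi-exon transcript models with designed structural categories.

    Returns (all models, the reference subset, expected category per
    non-reference isoform).  CDS are placed so that about ``nmd_fraction``
    of isoforms are NMD-sensitive under the 50-nt rule.
    """
    if isoforms_per_gene < 1:
        raise ValueError("isoforms_per_gene must be >= 1")
    rng = np.random.default_rng(seed)
    kinds = ["skip", "ism", "nnc", "ri", "af"]
    models, references, expected = [], [], {}
    for g in range(n_genes):
        gene = f"gene{g:04d}"
        strand = "+" if g % 2 == 0 else "-"
        base = start_pos + g * gene_spacing
        ref = _canonical_model(gene, chrom, strand, base)
        gene_models = [ref]
        for k in range(isoforms_per_gene - 1):
            kind = kinds[k % len(kinds)]
            tid = f"{gene}.{kind}{k}"
            var, cat = _variant_model(ref, kind, tid)
            expected[tid] = cat
            gene_models.append(var)
        for m in gene_models:
            nmd = bool(rng.random() < nmd_fraction)
            models.append(_place_cds(m, nmd))
        references.append(models[-len(gene_models)])  # the CDS-bearing ref
    return models, references, expected


# ---------------------------------------------------------------------------
# Effect design and cell simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedEffect:
    gene: str
    isoform: str
    variant: str
    cell_types: tuple[str, ...]
    beta: float
    reciprocal_partner: Optional[str] = None


@dataclass
class EffectDesign:
    """Everything the cell simulator needs beyond genotypes and models."""

    cell_types: tuple[str, ...]
    effects: list[PlantedEffect] = field(default_factory=list)
    gene_means: dict = field(default_factory=dict)        # (gene, cell_type) -> mu
    usage_weights: dict = field(default_factory=dict)     # (gene, cell_type) -> {iso: w}
    # dosage-independent cell-type expression multipliers: (isoform, cell_type) -> fold
    cell_type_multipliers: dict = field(default_factory=dict)
    batch_sd: float = 0.2
    libsize_sigma: float = 0.3
    cells_per_individual: int = 20
    batch_size: int = 6
    alpha_sim: float = 0.5
    default_gene_mean: float = 2.0

    def validate(self, isoforms_by_gene: dict[str, list[str]]) -> None:
        for e in self.effects:
            if not np.isfinite(e.beta):
                raise ValueError("non-finite effect size")
            if e.isoform not in isoforms_by_gene.get(e.gene, []):
                raise ValueError(f"effect isoform {e.isoform} not in gene {e.gene}")
            if e.reciprocal_partner is not None and e.reciprocal_partner not in isoforms_by_gene.get(e.gene, []):
                raise ValueError("reciprocal partner must belong to the same gene")
        for (gene, ct), w in self.usage_weights.items():
            total = sum(w.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"usage weights for {gene}/{ct} sum to {total}, not 1")


def default_usage_weights(
    isoforms_by_gene: dict[str, list[str]],
    cell_types: Sequence[str],
    rng: np.random.Generator,
    concentration: float = 5.0,
) -> dict:
    out = {}
    for gene, isos in isoforms_by_gene.items():
        for ct in cell_types:
            w = rng.dirichlet(np.full(len(isos), concentration))
            out[(gene, ct)] = dict(zip(isos, w))
    return out


def simulate_cells(
    genotypes: GenotypeTable,
    models: Sequence[TranscriptModel],
    design: EffectDesign,
    seed: int = 0,
) -> CellCounts:
    """Draw per-cell NB isoform counts under the design's planted effects."""
    rng = np.random.default_rng(seed)
    isoforms_by_gene: dict[str, list[str]] = {}
    for m in models:
        isoforms_by_gene.setdefault(m.gene_id, []).append(m.transcript_id)
    design.validate(isoforms_by_gene)
    for e in design.effects:
        if e.variant not in genotypes.dosages.columns:
            raise ValueError(f"planted variant {e.variant} absent from genotypes")

    inds = list(genotypes.dosages.index)
    n_ind = len(inds)
    batches = {ind: f"batch{i // design.batch_size:03d}" for i, ind in enumerate(inds)}
    batch_names = sorted(set(batches.values()))
    batch_mult = {
        b: float(np.exp(rng.normal(0.0, design.batch_sd))) for b in batch_names
    }

    iso_ids = [m.transcript_id for m in models]
    iso_index = {t: j for j, t in enumerate(iso_ids)}
    genes = [m.gene_id for m in models]

    # per (cell_type, individual) isoform mean before cell factors
    effects_by_key: dict[tuple[str, str], list[PlantedEffect]] = {}
    for e in design.effects:
        for ct in e.cell_types:
            effects_by_key.setdefault((ct, e.isoform), []).append(e)

    rows_meta = []
    blocks = []
    for ct in design.cell_types:
        # baseline per-isoform per-cell mean for this cell type
        base = np.empty(len(iso_ids))
        for j, (iso, gene) in enumerate(zip(iso_ids, genes)):
            mu_g = design.gene_means.get((gene, ct), design.default_gene_mean)
            w = design.usage_weights.get((gene, ct))
            wj = w[iso] if w else 1.0 / len(isoforms_by_gene[gene])
            base[j] = mu_g * wj * design.cell_type_multipliers.get((iso, ct), 1.0)
        mean_by_ind = np.tile(base, (n_ind, 1))
        dos = genotypes.dosages.to_numpy()
        for (ect, iso), effs in effects_by_key.items():
            if ect != ct:
                continue
            j = iso_index[iso]
            for e in effs:
                d = genotypes.dosages[e.variant].to_numpy()
                shifted = mean_by_ind[:, j] * np.exp(e.beta * d)
                if e.reciprocal_partner is not None:
                    jp = iso_index[e.reciprocal_partner]
                    pair_total = mean_by_ind[:, j] + mean_by_ind[:, jp]
                    shifted = np.minimum(shifted, pair_total * 0.999)
                    mean_by_ind[:, jp] = pair_total - shifted
                mean_by_ind[:, j] = shifted
        for i, ind in enumerate(inds):
            n_cells = design.cells_per_individual
            s = np.exp(rng.normal(0.0, design.libsize_sigma, size=n_cells))
            mult = batch_mult[batches[ind]]
            mean = s[:, None] * (mult * mean_by_ind[i])[None, :]
            if design.alpha_sim <= 1e-8:
                counts = rng.poisson(mean)
            else:
                shape = 1.0 / design.alpha_sim
                lam = rng.gamma(shape, mean * design.alpha_sim)
                counts = rng.poisson(lam)
            blocks.append(sp.csr_matrix(counts))
            for c in range(n_cells):
                rows_meta.append(
                    (f"{ind}-{ct}-{c:03d}", ind, ct, batches[ind])
                )
    matrix = sp.vstack(blocks).tocsr()
    cells = pd.DataFrame(
        rows_meta, columns=["barcode", "individual", "cell_type", "batch"]
    ).set_index("barcode")
    return CellCounts(matrix=matrix, cells=cells, isoforms=iso_ids)


def truth_table(design: EffectDesign, isoforms: Sequence[str]) -> pd.DataFrame:
    """Deterministic truth restatement: one row per (isoform, cell type) with
    the causal variant, true beta and class label."""
    rows = {}
    for ct in design.cell_types:
        for iso in isoforms:
            rows[(iso, ct)] = dict(
                isoform=iso, cell_type=ct, causal_variant=None, beta=0.0, label=NULL
            )
    for e in design.effects:
        label = (
            RECIPROCAL if e.reciprocal_partner is not None
            else (SHARED if len(e.cell_types) == len(design.cell_types) else SPECIFIC)
        )
        for ct in e.cell_types:
            rows[(e.isoform, ct)] = dict(
                isoform=e.isoform, cell_type=ct, causal_variant=e.variant,
                beta=e.beta, label=label,
            )
            if e.reciprocal_partner is not None:
                rows[(e.reciprocal_partner, ct)] = dict(
                    isoform=e.reciprocal_partner, cell_type=ct,
                    causal_variant=e.variant, beta=-e.beta, label=RECIPROCAL,
                )
    return pd.DataFrame(rows.values()).reset_index(drop=True)
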