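"""Readers and writers for the pipeline's interchange formats.

GTF (exon/CDS features), VCF with DS or GT genotype fields, Matrix Market
cell x isoform triplets with TSV sidecars, BED intervals, and TSV summary
statistics.  Internal coordinates are 1-based inclusive; BED is converted
from 0-based half-open on read and back on write.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import pyranges as pr
import scipy.io as sio
import scipy.sparse as sp

from .models import CellCounts, GenomicInterval, GenotypeTable, TranscriptModel

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Raised for malformed input, carrying the offending line number."""


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def _validate_gtf(path: str | Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 tab-separated fields")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinates") from None
            if start < 1 or end < start:
                raise ParseError(f"{path}: line {lineno}: invalid interval {start}-{end}")


def read_transcripts(path: str | Path) -> list[TranscriptModel]:
    """Read transcript models (exon + optional CDS features) from a GTF file.

    Exons are sorted by genomic coordinate; the strand-aware TSS is available
    as :attr:`TranscriptModel.tss`.  A transcript with no exon feature is
    rejected.
    """
    _validate_gtf(path)
    df = pr.read_gtf(str(path)).df
    if df.empty:
        return []
    if "transcript_id" not in df.columns or "gene_id" not in df.columns:
        raise ParseError(f"{path}: missing transcript_id/gene_id attributes")
    all_tids = set(df["transcript_id"].dropna().astype(str))
    df = df[df["Feature"].isin(["exon", "CDS"])].copy()
    exonless = all_tids - set(df.loc[df["Feature"] == "exon", "transcript_id"].astype(str))
    if exonless:
        raise ParseError(
            f"{path}: transcript {sorted(exonless)[0]} has zero exon features"
        )
    # pyranges stores 0-based half-open coordinates
    df["Start"] = df["Start"].astype(int) + 1
    df["End"] = df["End"].astype(int)

    models: list[TranscriptModel] = []
    for tid, sub in df.groupby("transcript_id", sort=False, observed=True):
        exon_rows = sub[sub["Feature"] == "exon"]
        if exon_rows.empty:
            raise ParseError(f"{path}: transcript {tid} has zero exon features")
        chrom = str(exon_rows["Chromosome"].iloc[0])
        strand = str(exon_rows["Strand"].iloc[0])
        gene_id = str(exon_rows["gene_id"].iloc[0])
        exons = [
            GenomicInterval(chrom, int(r.Start), int(r.End), strand)
            for r in exon_rows.itertuples()
        ]
        cds_rows = sub[sub["Feature"] == "CDS"]
        cds_start = cds_end = None
        if not cds_rows.empty:
            cds_start = int(cds_rows["Start"].min())
            cds_end = int(cds_rows["End"].max())
        models.append(
            TranscriptModel(
                transcript_id=str(tid),
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                exons=exons,
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    return models


def write_transcripts(models: Sequence[TranscriptModel], path: str | Path) -> None:
    """Write transcript models as GTF (transcript/exon/CDS features)."""
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            fh.write(
                f"{m.chrom}\tscisoqtl\ttranscript\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t{attrs}\n"
            )
            for e in m.exons:
                fh.write(
                    f"{m.chrom}\tscisoqtl\texon\t{e.start}\t{e.end}\t.\t{m.strand}\t.\t{attrs}\n"
                )
            if m.has_cds:
                # CDS emitted per overlapping exon segment
                for e in m.exons:
                    s = max(e.start, m.cds_start)
                    t = min(e.end, m.cds_end)
                    if s <= t:
                        fh.write(
                            f"{m.chrom}\tscisoqtl\tCDS\t{s}\t{t}\t.\t{m.strand}\t0\t{attrs}\n"
                        )


# ---------------------------------------------------------------------------
# VCF genotypes
# ---------------------------------------------------------------------------

def read_genotypes(
    path: str | Path,
    maf_min: float = 0.05,
    rsq_min: float = 0.3,
) -> GenotypeTable:
    """Read biallelic dosages from a VCF, applying MAF and imputation-quality filters.

    Dosage comes from the DS FORMAT field when present, otherwise from GT
    (alt-allele count).  Missing genotypes are mean-imputed per variant.
    Variants with MAF < ``maf_min`` or imputation R2 < ``rsq_min`` are
    excluded; multiallelic records are skipped with a warning count.  A VCF
    without an imputation-quality INFO field (R2/DR2) is treated as quality
    1.0 and this is logged.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, rows, meta = [], [], []
    n_multi = n_missing = 0
    saw_rsq_field = False
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        rsq = v.INFO.get("R2", v.INFO.get("DR2", None))
        if rsq is None:
            rsq = 1.0
        else:
            saw_rsq_field = True
            rsq = float(rsq)
        ds = v.format("DS")
        if ds is not None:
            dose = np.asarray(ds, dtype=float).ravel()
            dose[~np.isfinite(dose)] = np.nan
        else:
            gt = np.asarray(v.gt_types, dtype=float)  # 0 homref, 1 het, 3 homalt, 2 unknown
            dose = np.where(gt == 3, 2.0, gt)
            dose[gt == 2] = np.nan
        if np.isnan(dose).any():
            n_missing += int(np.isnan(dose).sum())
            fill = np.nanmean(dose) if np.isfinite(np.nanmean(dose)) else 0.0
            dose = np.where(np.isnan(dose), fill, dose)
        p = dose.mean() / 2.0
        maf = min(p, 1.0 - p)
        if maf < maf_min or rsq < rsq_min:
            continue
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}:{v.REF}:{v.ALT[0]}"
        ids.append(vid)
        rows.append(dose)
        meta.append((v.CHROM, v.POS, v.REF, v.ALT[0], maf, rsq))
    if n_multi:
        logger.warning("skipped %d multiallelic records in %s", n_multi, path)
    if n_missing:
        logger.info("mean-imputed %d missing genotype calls in %s", n_missing, path)
    if not saw_rsq_field:
        logger.info("%s carries no imputation-quality field; treating R2 as 1.0", path)
    dosages = pd.DataFrame(
        np.asarray(rows).T if rows else np.empty((len(samples), 0)),
        index=samples,
        columns=ids,
    )
    variants = pd.DataFrame(
        meta, index=ids, columns=["chrom", "pos", "ref", "alt", "maf", "rsq"]
    )
    return GenotypeTable(dosages=dosages, variants=variants)


def write_genotypes_vcf(table: GenotypeTable, path: str | Path) -> None:
    """Write hard dosages as a minimal VCF with GT and DS fields."""
    inds = list(table.dosages.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(inds) + "\n")
        for vid, row in table.variants.iterrows():
            doses = table.dosages[vid].to_numpy()
            rsq = row.get("rsq", 1.0)
            cells = []
            for d in doses:
                k = int(round(d))
                gt = {0: "0/0", 1: "0/1", 2: "1/1"}.get(k, "./.")
                cells.append(f"{gt}:{d:g}")
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{vid}\t{row['ref']}\t{row['alt']}\t.\tPASS\t"
                f"R2={rsq:g}\tGT:DS\t" + "\t".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# Cell counts (Matrix Market + TSV sidecars)
# ---------------------------------------------------------------------------

def read_cell_counts(
    matrix_path: str | Path,
    cells_path: str | Path,
    features_path: str | Path,
) -> CellCounts:
    """Read a sparse cell x isoform count matrix with its metadata sidecars.

    The cells TSV must carry barcode, individual, cell_type and batch columns;
    the features TSV lists isoform ids in column order.
    """
    mat = sio.mmread(str(matrix_path)).tocsr()
    cells = pd.read_csv(cells_path, sep="\t", dtype=str).set_index("barcode")
    feats = pd.read_csv(features_path, sep="\t", dtype=str)
    isoforms = feats["isoform"].tolist()
    if mat.shape[0] != len(cells) or mat.shape[1] != len(isoforms):
        raise ValueError(
            f"matrix shape {mat.shape} does not match {len(cells)} cells x {len(isoforms)} isoforms"
        )
    mat = sp.csr_matrix(mat)
    mat.sum_duplicates()
    return CellCounts(matrix=mat, cells=cells, isoforms=isoforms)


def write_cell_counts(
    counts: CellCounts,
    matrix_path: str | Path,
    cells_path: str | Path,
    features_path: str | Path,
) -> None:
    sio.mmwrite(str(matrix_path), sp.coo_matrix(counts.matrix))
    meta = counts.cells.copy()
    meta.insert(0, "barcode", meta.index)
    meta["total_umi"] = counts.total_umi()
    meta.to_csv(cells_path, sep="\t", index=False)
    pd.DataFrame({"isoform": counts.isoforms}).to_csv(features_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED and summary statistics
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED intervals, converting 0-based half-open to 1-based inclusive."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >=3 BED fields")
            chrom, start0, end0 = fields[0], int(fields[1]), int(fields[2])
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            out.append(GenomicInterval(chrom, start0 + 1, end0, strand))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t.\t0\t{iv.strand}\n")


SUMMARY_STAT_COLUMNS = ["variant", "beta", "se", "p", "maf", "n"]


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    """Read a TSV of per-variant association summary statistics.

    Requires a ``variant`` column plus either (beta, se) or (p, maf, n).
    """
    df = pd.read_csv(path, sep="\t")
    if "variant" not in df.columns:
        raise ParseError(f"{path}: missing 'variant' column")
    has_beta = {"beta", "se"}.issubset(df.columns)
    has_p = {"p", "maf", "n"}.issubset(df.columns)
    if not (has_beta or has_p):
        raise ParseError(f"{path}: need beta/se or p/maf/n columns")
    return df
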