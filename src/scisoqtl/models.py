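"""Core domain types shared across the pipeline.

Coordinates are 1-based inclusive throughout (GTF convention); BED input is
converted on read.  A transcript is represented by its sorted exon intervals;
introns, splice junctions and the spliced (transcript-coordinate) layout are
derived, never stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos <= self.end


@dataclass(frozen=True)
class SpliceJunction:
    """An intron boundary pair.

    ``donor`` is the intron end on the 5' side of the transcript (first intron
    base in transcript direction), ``acceptor`` the 3' side (last intron base).
    On the minus strand the donor is therefore the higher genomic coordinate.
    """

    chrom: str
    donor: int
    acceptor: int
    strand: str
    dinucleotides: Optional[str] = None

    @property
    def intron_start(self) -> int:
        return min(self.donor, self.acceptor)

    @property
    def intron_end(self) -> int:
        return max(self.donor, self.acceptor)


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one isoform."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]
    cds_start: Optional[int] = None  # genomic first coding base (min coord)
    cds_end: Optional[int] = None  # genomic last coding base (max coord)
    structural_category: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has zero exons")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError("cds_start and cds_end must be set together")
        if self.cds_start is not None and self.cds_start > self.cds_end:
            raise ValueError("cds_start > cds_end")

    # -- derived geometry ----------------------------------------------------

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def tss(self) -> int:
        """Strand-aware transcript start site."""
        return self.end if self.strand == "-" else self.start

    @property
    def has_cds(self) -> bool:
        return self.cds_start is not None

    def introns(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(self.chrom, a.end + 1, b.start - 1, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
        ]

    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        """Ordered (start, end) genomic intron coordinates; the splice-pattern key."""
        return tuple((i.start, i.end) for i in self.introns())

    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def genomic_to_spliced(self, pos: int) -> int:
        """Map a genomic exon position to 1-based spliced-transcript coordinate."""
        offset = 0
        exons = self.exons if self.strand != "-" else self.exons[::-1]
        for e in exons:
            if e.start <= pos <= e.end:
                within = (pos - e.start) if self.strand != "-" else (e.end - pos)
                return offset + within + 1
            offset += len(e)
        raise ValueError(f"position {pos} not in exons of {self.transcript_id}")

    def with_category(self, category: str) -> "TranscriptModel":
        return replace(self, structural_category=category)


@dataclass(frozen=True)
class AsEvent:
    """A local alternative-splicing event between two isoforms of one gene."""

    gene_id: str
    isoform_a: str
    isoform_b: str
    event_type: str  # SE, RI, A3, A5, AF, AL, MX
    chrom: str
    region_start: int
    region_end: int

    def key(self) -> tuple:
        return (self.gene_id, self.event_type, self.chrom, self.region_start, self.region_end)


@dataclass
class CellCounts:
    """Sparse cell x isoform counts with per-cell metadata.

    ``matrix`` is scipy.sparse CSR of shape (n_cells, n_isoforms).
    ``cells`` is a DataFrame indexed by barcode with columns
    individual, cell_type, batch; ``isoforms`` the ordered feature ids.
    """

    matrix: "object"
    cells: "object"  # pandas DataFrame
    isoforms: list[str]

    def __post_init__(self) -> None:
        n_cells, n_iso = self.matrix.shape
        if n_cells != len(self.cells):
            raise ValueError("cell metadata does not match matrix rows")
        if n_iso != len(self.isoforms):
            raise ValueError("isoform list does not match matrix columns")
        for col in ("individual", "cell_type", "batch"):
            if col not in self.cells.columns:
                raise ValueError(f"cell metadata missing column {col!r}")
        if self.cells.index.duplicated().any():
            raise ValueError("duplicate cell barcodes")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    def total_umi(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=1)).ravel()


@dataclass
class GenotypeTable:
    """Hard dosages in [0, 2], individuals x variants, with per-variant metadata.

    ``dosages``: pandas DataFrame (index individuals, columns variant ids).
    ``variants``: pandas DataFrame indexed by variant id with columns
    chrom, pos, ref, alt, maf and (optionally) rsq.
    """

    dosages: "object"
    variants: "object"

    def __post_init__(self) -> None:
        if list(self.dosages.columns) != list(self.variants.index):
            raise ValueError("dosage columns and variant table misaligned")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]


@dataclass
class PseudobulkMatrix:
    """Individual x isoform summed counts for one cell type."""

    counts: "object"  # pandas DataFrame, index individuals, columns isoforms
    cell_type: str
    covariates: Optional["object"] = None  # pandas DataFrame aligned on index

    @property
    def individuals(self) -> list[str]:
        return list(self.counts.index)

    @property
    def isoforms(self) -> list[str]:
        return list(self.counts.columns)

    def library_sizes(self) -> np.ndarray:
        return self.counts.to_numpy().sum(axis=1)
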