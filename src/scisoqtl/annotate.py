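"""Transcript structural annotation against a reference catalogue.

Covers the four splice-pattern categories (FSM, ISM, NIC, NNC), the 50-nt
rule for nonsense-mediated decay sensitivity, local alternative-splicing
event calls between isoform pairs (SE, RI, A3, A5, AF, AL, MX), splice
junction extraction and the 2-bp splice-junction-site windows at intron
ends.

Category semantics (relative to the reference isoforms of the same gene):

* FSM  -- the candidate's ordered intron chain equals a reference chain.
* ISM  -- the chain is a contiguous sub-chain of some reference chain.
* NNC  -- at least one donor or acceptor coordinate is absent from the
          gene's reference site sets (a novel splice site).
* NIC  -- all sites are known but their combination is novel.

Mono-exon candidates are called FSM when contained within a mono-exon
reference of the gene, otherwise "other".
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Optional, Sequence

from .models import AsEvent, GenomicInterval, SpliceJunction, TranscriptModel

FSM, ISM, NIC, NNC, OTHER = "FSM", "ISM", "NIC", "NNC", "other"

CANONICAL_DINUCLEOTIDES = {"GT-AG", "GC-AG", "AT-AC"}


# ---------------------------------------------------------------------------
# Junctions
# ---------------------------------------------------------------------------

def extract_junctions(
    model: TranscriptModel, genome: Optional[dict[str, str]] = None
) -> list[SpliceJunction]:
    """Splice junctions of a transcript, in transcript order.

    The donor is the intron end on the transcript's 5' side: the lower
    genomic coordinate on the plus strand, the higher one on the minus
    strand.  With an optional genome (chrom -> sequence, 1-based indexing
    via position-1), the donor/acceptor dinucleotide pair is annotated.
    """
    introns = model.introns()
    if model.strand == "-":
        introns = introns[::-1]
    out = []
    for iv in introns:
        if model.strand == "-":
            donor, acceptor = iv.end, iv.start
        else:
            donor, acceptor = iv.start, iv.end
        dinuc = None
        if genome is not None and model.chrom in genome:
            seq = genome[model.chrom]
            d = seq[iv.start - 1 : iv.start + 1]
            a = seq[iv.end - 2 : iv.end]
            if model.strand == "-":
                d, a = _revcomp(a), _revcomp(d)
            dinuc = f"{d.upper()}-{a.upper()}"
        out.append(SpliceJunction(model.chrom, donor, acceptor, model.strand, dinuc))
    return out


def _revcomp(s: str) -> str:
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    return "".join(comp.get(c.upper(), "N") for c in reversed(s))


def is_canonical(junction: SpliceJunction) -> Optional[bool]:
    if junction.dinucleotides is None:
        return None
    return junction.dinucleotides in CANONICAL_DINUCLEOTIDES


# ---------------------------------------------------------------------------
# Structural categories
# ---------------------------------------------------------------------------

def _donor_acceptor_sets(
    references: Sequence[TranscriptModel],
) -> tuple[set[int], set[int]]:
    donors, acceptors = set(), set()
    for ref in references:
        for j in extract_junctions(ref):
            donors.add(j.donor)
            acceptors.add(j.acceptor)
    return donors, acceptors


def _is_contiguous_subchain(sub: tuple, chain: tuple) -> bool:
    n, m = len(sub), len(chain)
    if n == 0 or n > m:
        return False
    return any(chain[i : i + n] == sub for i in range(m - n + 1))


def classify_structure(
    candidate: TranscriptModel, references: Sequence[TranscriptModel]
) -> str:
    """Structural category of ``candidate`` against reference isoforms of its gene."""
    if not references:
        raise ValueError("empty reference set")
    for ref in references:
        if ref.chrom != candidate.chrom or ref.strand != candidate.strand:
            raise ValueError(
                f"reference {ref.transcript_id} is on a different chrom/strand "
                f"than candidate {candidate.transcript_id}"
            )
    chain = candidate.intron_chain()
    if not chain:  # mono-exon candidate
        for ref in references:
            if len(ref.exons) == 1 and (
                ref.start <= candidate.start and candidate.end <= ref.end
            ):
                return FSM
        return OTHER
    ref_chains = [r.intron_chain() for r in references]
    if any(chain == rc for rc in ref_chains):
        return FSM
    if any(_is_contiguous_subchain(chain, rc) for rc in ref_chains):
        return ISM
    donors, acceptors = _donor_acceptor_sets(references)
    for j in extract_junctions(candidate):
        if j.donor not in donors or j.acceptor not in acceptors:
            return NNC
    return NIC


def nnc_witness(
    candidate: TranscriptModel, references: Sequence[TranscriptModel]
) -> Optional[int]:
    """A splice-site coordinate of ``candidate`` absent from the reference sets."""
    donors, acceptors = _donor_acceptor_sets(references)
    for j in extract_junctions(candidate):
        if j.donor not in donors:
            return j.donor
        if j.acceptor not in acceptors:
            return j.acceptor
    return None


# ---------------------------------------------------------------------------
# NMD rule
# ---------------------------------------------------------------------------

def classify_nmd(model: TranscriptModel, min_distance: int = 50) -> bool:
    """Predict NMD sensitivity by the 50-nt rule.

    The distance runs, in spliced-transcript coordinates, from the last base
    of the stop codon to the first base 3' of the last splice junction; the
    transcript is called sensitive when it is at least ``min_distance``.
    Mono-exon transcripts have no junction and are insensitive.
    """
    if not model.has_cds:
        raise ValueError(f"{model.transcript_id}: no CDS")
    if len(model.exons) == 1:
        return False
    stop_genomic = model.cds_end if model.strand != "-" else model.cds_start
    stop_spliced = model.genomic_to_spliced(stop_genomic)  # raises if outside exons
    # first base of the terminal exon, in transcript direction
    last_exon = model.exons[-1] if model.strand != "-" else model.exons[0]
    junction_spliced = model.genomic_to_spliced(
        last_exon.start if model.strand != "-" else last_exon.end
    )
    return (junction_spliced - stop_spliced) >= min_distance


# ---------------------------------------------------------------------------
# Alternative splicing events
# ---------------------------------------------------------------------------

def _pair_events(a: TranscriptModel, b: TranscriptModel) -> list[AsEvent]:
    """Geometric AS-event calls between one ordered isoform pair."""
    events: list[AsEvent] = []
    gene, chrom = a.gene_id, a.chrom
    ia, ib = sorted((a.transcript_id, b.transcript_id))

    def emit(kind: str, start: int, end: int) -> None:
        events.append(AsEvent(gene, ia, ib, kind, chrom, start, end))

    ex_a, ex_b = a.exons, b.exons

    # SE: internal exon of one isoform absent in the other, flanks shared
    for donor_iso, other in ((a, b), (b, a)):
        exs, exo = donor_iso.exons, other.exons
        for k in range(1, len(exs) - 1):
            e = exs[k]
            if any(e.overlaps(x) for x in exo):
                continue
            prev_end, next_start = exs[k - 1].end, exs[k + 1].start
            for j in range(len(exo) - 1):
                if exo[j].end == prev_end and exo[j + 1].start == next_start:
                    emit("SE", e.start, e.end)
                    break

    # RI: one exon spans two consecutive exons of the other plus the intron
    for big, small in ((a, b), (b, a)):
        for e in big.exons:
            for j in range(len(small.exons) - 1):
                s1, s2 = small.exons[j], small.exons[j + 1]
                if e.start == s1.start and e.end == s2.end:
                    emit("RI", s1.end + 1, s2.start - 1)

    # junction-sharing comparisons (A5/A3/AF/AL)
    ja = extract_junctions(a)
    jb = extract_junctions(b)
    for pa, xa in enumerate(ja):
        for pb, xb in enumerate(jb):
            if xa.donor == xb.donor and xa.acceptor == xb.acceptor:
                continue
            if xa.acceptor == xb.acceptor and xa.donor != xb.donor:
                # alternative donor (5' splice site) or alternative first exon
                up_a = _exon_ending_at_donor(a, xa.donor)
                up_b = _exon_ending_at_donor(b, xb.donor)
                lo, hi = sorted((xa.donor, xb.donor))
                if up_a is not None and up_b is not None and up_a.overlaps(up_b):
                    emit("A5", lo, hi)
                elif pa == 0 and pb == 0:
                    emit("AF", lo, hi)
            elif xa.donor == xb.donor and xa.acceptor != xb.acceptor:
                down_a = _exon_starting_at_acceptor(a, xa.acceptor)
                down_b = _exon_starting_at_acceptor(b, xb.acceptor)
                lo, hi = sorted((xa.acceptor, xb.acceptor))
                if down_a is not None and down_b is not None and down_a.overlaps(down_b):
                    emit("A3", lo, hi)
                elif pa == len(ja) - 1 and pb == len(jb) - 1:
                    emit("AL", lo, hi)

    # MX: mutually exclusive internal exons with shared outer flanks
    for k in range(1, len(ex_a) - 1):
        ea = ex_a[k]
        if any(ea.overlaps(x) for x in ex_b):
            continue
        for m in range(1, len(ex_b) - 1):
            eb = ex_b[m]
            if eb.overlaps(ea) or any(eb.overlaps(x) for x in ex_a):
                continue
            if (
                ex_a[k - 1].end == ex_b[m - 1].end
                and ex_a[k + 1].start == ex_b[m + 1].start
            ):
                lo = min(ea.start, eb.start)
                hi = max(ea.end, eb.end)
                emit("MX", lo, hi)
    return events


def _exon_ending_at_donor(model: TranscriptModel, donor: int):
    # donor flanks the exon on its transcript-5' side
    for e in model.exons:
        boundary = e.end + 1 if model.strand != "-" else e.start - 1
        if boundary == donor:
            return e
    return None


def _exon_starting_at_acceptor(model: TranscriptModel, acceptor: int):
    for e in model.exons:
        boundary = e.start - 1 if model.strand != "-" else e.end + 1
        if boundary == acceptor:
            return e
    return None


def classify_as_events(isoforms: Sequence[TranscriptModel]) -> list[AsEvent]:
    """All pairwise AS events among the isoforms of one gene, deduplicated."""
    seen = {}
    for i in range(len(isoforms)):
        for j in range(i + 1, len(isoforms)):
            if isoforms[i].gene_id != isoforms[j].gene_id:
                continue
            for ev in _pair_events(isoforms[i], isoforms[j]):
                seen.setdefault(ev.key() + (ev.isoform_a, ev.isoform_b), ev)
    return sorted(
        seen.values(), key=lambda e: (e.event_type, e.region_start, e.region_end)
    )


# ---------------------------------------------------------------------------
# Splice-junction-site windows
# ---------------------------------------------------------------------------

def sjs_windows(
    models: Iterable[TranscriptModel], width: int = 2
) -> list[GenomicInterval]:
    """The ``width``-bp windows at both ends of every distinct intron."""
    out = set()
    for m in models:
        for iv in m.introns():
            out.add((iv.chrom, iv.start, min(iv.start + width - 1, iv.end)))
            out.add((iv.chrom, max(iv.end - width + 1, iv.start), iv.end))
    return sorted(
        (GenomicInterval(c, s, e) for c, s, e in out),
        key=lambda iv: (iv.chrom, iv.start, iv.end),
    )


def annotate_catalogue(
    candidates: Sequence[TranscriptModel],
    references: Sequence[TranscriptModel],
    nmd_distance: int = 50,
) -> "object":
    """Per-isoform category and NMD flag table for a candidate catalogue."""
    import pandas as pd

    ref_by_gene: dict[str, list[TranscriptModel]] = defaultdict(list)
    for r in references:
        ref_by_gene[r.gene_id].append(r)
    rows = []
    for c in candidates:
        refs = ref_by_gene.get(c.gene_id, [])
        cat = classify_structure(c, refs) if refs else OTHER
        nmd = classify_nmd(c, nmd_distance) if c.has_cds else None
        rows.append((c.transcript_id, c.gene_id, cat, nmd))
    return pd.DataFrame(rows, columns=["isoform", "gene", "category", "nmd_sensitive"])
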