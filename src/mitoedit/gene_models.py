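"""Strand-aware gene models for organellar transcripts.

Plant mitochondrial genes sit on either strand of a circular genome and are
frequently interrupted by group-II introns.  Everything downstream of the
read counts — editing-degree bookkeeping, codon-effect calls, splicing
labels — hangs off a correct genome <-> transcript coordinate transform, so
this module owns that math.

Conventions
-----------
* All coordinates are 1-based and inclusive (GFF3-compatible).  Half-open
  intervals appear only at file boundaries.
* ``exons`` are ordered 5'->3' along the *transcript*; for a minus-strand
  gene the genomic coordinates therefore decrease along the list.
* A C-to-U event is always described on the sense strand.  On a
  minus-strand gene it shows up as G->A on the reference plus strand; all
  codon arithmetic here happens after reverse-complementing to the sense
  strand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, Mapping, Optional, Sequence, Tuple

from Bio.Seq import Seq, reverse_complement

__all__ = [
    "Intron",
    "GeneModel",
    "TranscriptLocation",
    "EffectAnnotation",
    "CoordinateError",
    "NotEditableError",
    "genome_to_transcript",
    "transcript_to_genome",
    "codon_index",
    "classify_effect",
    "annotate_genome_site",
    "sense_transcript_sequence",
]


class CoordinateError(ValueError):
    """A coordinate fell outside the range the operation admits."""


class NotEditableError(ValueError):
    """The focal base is not a cytidine on the sense strand."""


@dataclass(frozen=True)
class Intron:
    """A genomic interval between two consecutive exons, with a field label
    such as ``"nad4 intron 1"``."""

    start: int
    end: int
    label: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"intron {self.label!r}: start > end")


@dataclass(frozen=True)
class TranscriptLocation:
    """Where a genomic position lands relative to a transcript."""

    region: str  # 'exonic' | 'intronic' | 'outside'
    tpos: Optional[int] = None
    intron_label: Optional[str] = None

    @property
    def is_exonic(self) -> bool:
        return self.region == "exonic"


@dataclass(frozen=True)
class EffectAnnotation:
    """Codon-level consequence of a single C-to-U edit.

    ``category`` is one of ``synonymous``, ``nonsynonymous``, ``intronic``,
    ``noncoding``.  Codon fields are populated only for exonic positions
    inside the CDS.
    """

    region: str  # 'exonic' | 'intronic' | 'outside'
    category: str
    aa_position: Optional[int] = None
    codon_position: Optional[int] = None
    ref_codon: Optional[str] = None
    edited_codon: Optional[str] = None
    ref_aa: Optional[str] = None
    edited_aa: Optional[str] = None
    intron_label: Optional[str] = None


@dataclass(frozen=True)
class GeneModel:
    """Transcript structure of one gene: ordered exons, labelled introns and
    the transcript offset at which the CDS starts.

    Parameters
    ----------
    exons
        Genomic ``(start, end)`` intervals, 1-based inclusive, ordered
        5'->3' along the transcript.  For ``strand == '-'`` the intervals
        must be in decreasing genomic order.
    cds_start_tpos
        1-based transcript position of the first CDS base.  The CDS is
        taken to run in full codons from there to the last complete codon
        of the transcript.
    code_table
        NCBI genetic-code table id; plant mitochondria use the standard
        code (1) for these genes.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: Tuple[Tuple[int, int], ...]
    introns: Tuple[Intron, ...] = ()
    cds_start_tpos: int = 1
    code_table: int = 1

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = tuple(tuple(e) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        object.__setattr__(self, "introns", tuple(self.introns))
        if not exons:
            raise ValueError("gene model needs at least one exon")
        for s, e in exons:
            if s > e:
                raise ValueError(f"{self.gene_id}: exon start {s} > end {e}")
        by_genome = sorted(exons)
        for (s1, e1), (s2, e2) in zip(by_genome, by_genome[1:]):
            if e1 >= s2:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        # transcript order must follow the strand
        starts = [s for s, _ in exons]
        ordered = starts == sorted(starts) if self.strand == "+" else starts == sorted(starts, reverse=True)
        if not ordered:
            raise ValueError(f"{self.gene_id}: exons not in 5'->3' order for strand {self.strand}")
        # introns strictly between consecutive exons on the genome
        for intron, (ex_a, ex_b) in zip(self.introns, zip(exons, exons[1:])):
            lo = min(ex_a[1], ex_b[1]) + 1
            hi = max(ex_a[0], ex_b[0]) - 1
            if not (lo <= intron.start and intron.end <= hi):
                raise ValueError(
                    f"{self.gene_id}: intron {intron.label!r} [{intron.start},{intron.end}] "
                    f"not between its flanking exons"
                )
        if self.cds_start_tpos < 1:
            raise ValueError("cds_start_tpos must be >= 1")
        if self.transcript_length - self.cds_start_tpos + 1 < 3:
            raise ValueError("CDS shorter than one codon")

    @property
    def transcript_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def span(self) -> Tuple[int, int]:
        """Genomic (min, max) extent including introns."""
        return min(s for s, _ in self.exons), max(e for _, e in self.exons)

    # -- coordinate transforms -------------------------------------------

    def genome_to_transcript(self, pos: int) -> TranscriptLocation:
        return genome_to_transcript(pos, self)

    def transcript_to_genome(self, tpos: int) -> int:
        return transcript_to_genome(tpos, self)


def genome_to_transcript(pos: int, gene: GeneModel) -> TranscriptLocation:
    """Map a 1-based genome coordinate into transcript space.

    Exonic positions return a 1-based transcript coordinate; a position in
    an annotated intron returns the intron's label (never a ``tpos``);
    anything outside the gene span is flagged ``outside``.
    """
    offset = 0
    for s, e in gene.exons:
        if s <= pos <= e:
            if gene.strand == "+":
                return TranscriptLocation("exonic", tpos=offset + pos - s + 1)
            return TranscriptLocation("exonic", tpos=offset + e - pos + 1)
        offset += e - s + 1
    for intron in gene.introns:
        if intron.start <= pos <= intron.end:
            return TranscriptLocation("intronic", intron_label=intron.label)
    return TranscriptLocation("outside")


def transcript_to_genome(tpos: int, gene: GeneModel) -> int:
    """Inverse of :func:`genome_to_transcript` on exonic positions."""
    if not 1 <= tpos <= gene.transcript_length:
        raise CoordinateError(
            f"transcript position {tpos} outside 1..{gene.transcript_length} for {gene.gene_id}"
        )
    offset = 0
    for s, e in gene.exons:
        length = e - s + 1
        if tpos <= offset + length:
            within = tpos - offset  # 1-based within exon
            return s + within - 1 if gene.strand == "+" else e - within + 1
        offset += length
    raise AssertionError("unreachable")  # pragma: no cover


def codon_index(tpos: int, cds_start_tpos: int) -> Optional[Tuple[int, int]]:
    """Return ``(aa_position, codon_position)`` for a transcript coordinate.

    ``aa_position = ceil((tpos - cds_start + 1) / 3)`` and
    ``codon_position = ((tpos - cds_start) mod 3) + 1``.  Positions ahead of
    the CDS start are noncoding and return ``None``.
    """
    if tpos < cds_start_tpos:
        return None
    rel = tpos - cds_start_tpos
    return rel // 3 + 1, rel % 3 + 1


def classify_effect(
    site_tpos: int,
    gene: GeneModel,
    transcript_seq: str,
    co_edited_tpos: Iterable[int] = (),
) -> EffectAnnotation:
    """Classify the codon-level effect of a C-to-U edit at an exonic
    transcript position.

    The reference codon is read from the sense-strand ``transcript_seq``;
    the edited codon applies C->T at the focal site *and* at every supplied
    co-edited transcript position that falls in the same codon (multiple
    edits within a codon are common in plant mitochondria and change the
    amino-acid call, e.g. TCC->TTT).  Synonymy is decided by translating
    both codons with the gene's code table.
    """
    if not 1 <= site_tpos <= len(transcript_seq):
        raise CoordinateError(f"tpos {site_tpos} outside transcript of length {len(transcript_seq)}")
    if transcript_seq[site_tpos - 1].upper() != "C":
        raise NotEditableError(
            f"{gene.gene_id} tpos {site_tpos}: not a cytidine on sense strand "
            f"(found {transcript_seq[site_tpos - 1]!r})"
        )
    ci = codon_index(site_tpos, gene.cds_start_tpos)
    if ci is None:
        return EffectAnnotation(region="exonic", category="noncoding")
    aa_pos, codon_pos = ci
    codon_start = gene.cds_start_tpos + 3 * (aa_pos - 1)
    if codon_start + 2 > len(transcript_seq):
        # trailing partial codon — no amino acid to speak of
        return EffectAnnotation(region="exonic", category="noncoding")
    ref_codon = transcript_seq[codon_start - 1 : codon_start + 2].upper()
    edits = {site_tpos} | {t for t in co_edited_tpos if codon_start <= t <= codon_start + 2}
    edited = list(ref_codon)
    for t in edits:
        idx = t - codon_start
        if edited[idx] == "C":
            edited[idx] = "T"
    edited_codon = "".join(edited)
    ref_aa = str(Seq(ref_codon).translate(table=gene.code_table))
    edited_aa = str(Seq(edited_codon).translate(table=gene.code_table))
    category = "synonymous" if ref_aa == edited_aa else "nonsynonymous"
    return EffectAnnotation(
        region="exonic",
        category=category,
        aa_position=aa_pos,
        codon_position=codon_pos,
        ref_codon=ref_codon,
        edited_codon=edited_codon,
        ref_aa=ref_aa,
        edited_aa=edited_aa,
    )


def annotate_genome_site(
    pos: int,
    gene: GeneModel,
    transcript_seq: str,
    co_edited_tpos: Iterable[int] = (),
) -> EffectAnnotation:
    """Annotate an edit given its *genome* coordinate.

    Intronic sites are labelled with their intron; positions outside the
    gene span come back ``noncoding``; exonic sites defer to
    :func:`classify_effect`.
    """
    loc = genome_to_transcript(pos, gene)
    if loc.region == "intronic":
        return EffectAnnotation(region="intronic", category="intronic", intron_label=loc.intron_label)
    if loc.region == "outside":
        return EffectAnnotation(region="outside", category="noncoding")
    return classify_effect(loc.tpos, gene, transcript_seq, co_edited_tpos)


def sense_transcript_sequence(genome_seq: str, gene: GeneModel) -> str:
    """Splice the exons out of the plus-strand genome sequence and return
    the sense-strand transcript."""
    parts = []
    for s, e in sorted(gene.exons):
        parts.append(genome_seq[s - 1 : e])
    spliced = "".join(parts)
    if gene.strand == "-":
        spliced = reverse_complement(spliced)
    return spliced
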