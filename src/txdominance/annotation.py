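"""In-memory gene models and the interval arithmetic built on them.

Genes own transcripts; transcripts own exons and (optionally) CDS intervals.
Everything else the package needs from an annotation — introns, TSS groups,
splice junctions, length flags — is derived on demand from exon coordinates.

Coordinates are 0-based half-open throughout the package; GTF input/output
(see :mod:`txdominance.gtf`) converts at the boundary.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

#: Chromosome names treated as mitochondrial unless overridden at parse time.
MITOCHONDRIAL_CHROMS = frozenset({"MT", "chrM", "M"})


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True, order=True)
class Junction:
    """A splice junction: donor = upstream exon end, acceptor = next exon start.

    Identity is (chrom, donor, acceptor, strand) in half-open exon coordinates,
    so two transcripts share a junction exactly when consecutive exons abut the
    same intron.
    """

    chrom: str
    donor: int
    acceptor: int
    strand: str

    def __post_init__(self) -> None:
        if self.donor >= self.acceptor:
            raise ValueError(f"junction donor {self.donor} >= acceptor {self.acceptor}")


@dataclass
class TranscriptRecord:
    """One annotated transcript: ordered exons, optional CDS, a biotype."""

    transcript_id: str
    gene_id: str
    biotype: str
    exons: list[GenomicInterval]
    cds: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )
        self.cds = sorted(self.cds, key=lambda iv: iv.start)
        for c in self.cds:
            if not any(e.contains(c) for e in self.exons):
                raise ValueError(
                    f"transcript {self.transcript_id}: CDS {c.start}-{c.end} "
                    "not contained in any exon"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def length(self) -> int:
        """Mature transcript length in nt (sum of exon lengths)."""
        return sum(e.length for e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(c.length for c in self.cds)

    @property
    def is_coding(self) -> bool:
        return self.cds_length > 0

    @property
    def tss(self) -> int:
        """5'-most transcribed base, strand-aware (0-based position)."""
        if self.strand == "+":
            return self.exons[0].start
        return self.exons[-1].end - 1

    @property
    def junctions(self) -> list[Junction]:
        return [
            Junction(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
        ]


@dataclass
class GeneRecord:
    """A gene and all of its annotated transcripts."""

    gene_id: str
    biotype: str
    chrom: str
    strand: str
    transcripts: list[TranscriptRecord]
    is_mitochondrial: bool | None = None

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        for t in self.transcripts:
            if t.gene_id != self.gene_id:
                raise ValueError(
                    f"transcript {t.transcript_id} carries gene_id {t.gene_id}, "
                    f"expected {self.gene_id}"
                )
            if t.chrom != self.chrom or t.strand != self.strand:
                raise ValueError(
                    f"transcript {t.transcript_id} disagrees with gene "
                    f"{self.gene_id} on chrom/strand"
                )
        if self.is_mitochondrial is None:
            self.is_mitochondrial = self.chrom in MITOCHONDRIAL_CHROMS

    @property
    def span(self) -> GenomicInterval:
        """Min exon start to max exon end over all transcripts."""
        start = min(e.start for t in self.transcripts for e in t.exons)
        end = max(e.end for t in self.transcripts for e in t.exons)
        return GenomicInterval(self.chrom, start, end, self.strand)

    @property
    def transcript_ids(self) -> list[str]:
        return [t.transcript_id for t in self.transcripts]

    def transcript(self, transcript_id: str) -> TranscriptRecord:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(transcript_id)


@dataclass(frozen=True)
class IntronRegion:
    """A genic region not overlapped by any exon of any transcript."""

    gene_id: str
    interval: GenomicInterval
    index: int


@dataclass
class AnnotationModel:
    """The full annotation: gene_id -> GeneRecord plus provenance notes."""

    genes: dict[str, GeneRecord] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes.values():
            for t in g.transcripts:
                if t.transcript_id in seen:
                    raise ValueError(f"duplicate transcript_id {t.transcript_id}")
                seen.add(t.transcript_id)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def transcripts(self) -> Iterator[TranscriptRecord]:
        for g in self.genes.values():
            yield from g.transcripts

    @property
    def n_transcripts(self) -> int:
        return sum(len(g.transcripts) for g in self.genes.values())

    @cached_property
    def transcript_gene(self) -> dict[str, str]:
        """Mapping transcript_id -> gene_id."""
        return {t.transcript_id: g.gene_id for g in self.genes.values() for t in g.transcripts}

    def get_transcript(self, transcript_id: str) -> TranscriptRecord:
        return self.genes[self.transcript_gene[transcript_id]].transcript(transcript_id)


# ---------------------------------------------------------------------------
# interval helpers (sorted-merge arithmetic on (start, end) tuples)
# ---------------------------------------------------------------------------

def _merge(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge possibly-overlapping (start, end) pairs into maximal blocks."""
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _subtract(blocks: list[tuple[int, int]], holes: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Set difference blocks \\ holes; both inputs merged and sorted."""
    out: list[tuple[int, int]] = []
    for s, e in blocks:
        cur = s
        for hs, he in holes:
            if he <= cur or hs >= e:
                continue
            if hs > cur:
                out.append((cur, hs))
            cur = max(cur, he)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def exon_union(gene: GeneRecord) -> list[tuple[int, int]]:
    """Merged exonic blocks over all transcripts of the gene."""
    return _merge((e.start, e.end) for t in gene.transcripts for e in t.exons)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def build_study_set(model: AnnotationModel, min_tx_len: int = 300) -> AnnotationModel:
    """Restrict to protein-coding genes whose transcripts are all >= min_tx_len nt.

    Genes with at least one transcript strictly shorter than ``min_tx_len``
    are removed (short transcripts are lost to size selection in a standard
    RNA-seq library prep). Kept/dropped counts are recorded in provenance.
    """
    kept: dict[str, GeneRecord] = {}
    dropped_biotype = dropped_short = 0
    for gene_id, gene in model.genes.items():
        if gene.biotype != "protein_coding":
            dropped_biotype += 1
            continue
        if min_tx_len > 0 and any(t.length < min_tx_len for t in gene.transcripts):
            dropped_short += 1
            continue
        kept[gene_id] = gene
    provenance = dict(model.provenance)
    provenance["study_set"] = {
        "min_tx_len": min_tx_len,
        "kept": len(kept),
        "dropped_non_coding": dropped_biotype,
        "dropped_short_transcript": dropped_short,
    }
    if not kept:
        logger.warning("study set is empty after filtering")
    logger.info(
        "study set: kept %d genes (dropped %d non-coding, %d with short transcripts)",
        len(kept), dropped_biotype, dropped_short,
    )
    return AnnotationModel(genes=kept, provenance=provenance)


def derive_introns(gene: GeneRecord) -> list[IntronRegion]:
    """Maximal genic regions covered by no exon of any transcript.

    Returned in genomic order with 0-based ordinal indices; a single-exon
    gene (or one whose transcripts tile the span) yields an empty list.
    """
    span = gene.span
    exonic = exon_union(gene)
    introns: list[IntronRegion] = []
    for i, (s, e) in enumerate(_subtract([(span.start, span.end)], exonic)):
        introns.append(
            IntronRegion(gene.gene_id, GenomicInterval(gene.chrom, s, e, gene.strand), i)
        )
    return introns


def group_by_tss(gene: GeneRecord) -> dict[int, list[str]]:
    """Group transcript ids by exact transcription start site position.

    The TSS is the strand-aware 5'-most transcribed base (exon start on '+',
    last exon end - 1 on '-'); equality is exact coordinate equality.
    """
    groups: dict[int, list[str]] = {}
    for t in gene.transcripts:
        groups.setdefault(t.tss, []).append(t.transcript_id)
    return groups


def unique_junctions(gene: GeneRecord) -> tuple[dict[str, set[Junction]], bool]:
    """Junctions unique to each transcript, and whether all transcripts have one.

    A junction is unique to transcript t when exactly one transcript of the
    gene contains it. ``fully_identifiable`` is True iff every transcript has
    at least one unique junction (single-exon transcripts never do).
    """
    per_tx = {t.transcript_id: set(t.junctions) for t in gene.transcripts}
    counts = Counter(j for s in per_tx.values() for j in s)
    unique = {tid: {j for j in s if counts[j] == 1} for tid, s in per_tx.items()}
    fully = all(unique[tid] for tid in unique)
    return unique, fully


@dataclass(frozen=True)
class LengthFlags:
    is_longest_transcript: bool
    has_longest_cds: bool


def annotate_length_flags(gene: GeneRecord) -> dict[str, LengthFlags]:
    """Flag transcripts attaining the gene's maximal length / CDS length.

    Ties all receive the flag; a single-transcript gene is trivially both.
    """
    max_len = max(t.length for t in gene.transcripts)
    max_cds = max(t.cds_length for t in gene.transcripts)
    return {
        t.transcript_id: LengthFlags(t.length == max_len, t.cds_length == max_cds)
        for t in gene.transcripts
    }


def intron_relative_position(intron: IntronRegion, gene: GeneRecord) -> float:
    """Strand-aware relative position of the intron midpoint in the gene span.

    0 = transcriptional start, 1 = transcriptional end. Mirroring the gene to
    the opposite strand maps p -> 1 - p.
    """
    span = gene.span
    if span.length == 0:
        raise ValueError(f"gene {gene.gene_id} has zero-length span")
    mid = (intron.interval.start + intron.interval.end) / 2.0
    p = (mid - span.start) / span.length
    return p if gene.strand == "+" else 1.0 - p


def exclusive_exonic_regions(gene: GeneRecord, transcript_id: str) -> list[GenomicInterval]:
    """Regions covered by this transcript's exons and by no other transcript.

    For a retained-intron transcript this recovers the retained intron: the
    gene-level intron complement is empty by construction once the retaining
    transcript's own exon is included, so the retained region is defined
    against the *other* transcripts' exon union.
    """
    target = gene.transcript(transcript_id)
    own = _merge((e.start, e.end) for e in target.exons)
    others = _merge(
        (e.start, e.end)
        for t in gene.transcripts
        if t.transcript_id != transcript_id
        for e in t.exons
    )
    return [
        GenomicInterval(gene.chrom, s, e, gene.strand)
        for s, e in _subtract(own, others)
    ]
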