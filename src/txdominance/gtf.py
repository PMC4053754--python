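"""GTF/BED input and output for the annotation model.

Reads GENCODE-style GTF (gene/transcript/exon/CDS features with ``gene_id``,
``transcript_id`` and biotype attributes in either the GENCODE ``gene_type``
or Ensembl ``gene_biotype`` dialect) via :mod:`gffutils`, converting the
on-disk 1-based inclusive coordinates to the package's 0-based half-open
convention at the boundary. Writing inverts the conversion exactly, so a
write/parse round trip preserves every interval.
"""

from __future__ import annotations

import logging
from pathlib import Path

import gffutils
import pandas as pd

from .annotation import (
    AnnotationModel,
    GeneRecord,
    GenomicInterval,
    TranscriptRecord,
    MITOCHONDRIAL_CHROMS,
    derive_introns,
    unique_junctions,
)

logger = logging.getLogger(__name__)


class GtfParseError(ValueError):
    """Raised for malformed GTF input, with the offending line number."""


_BIOTYPE_KEYS_TX = ("transcript_type", "transcript_biotype")
_BIOTYPE_KEYS_GENE = ("gene_type", "gene_biotype")


def _attr(feature, keys) -> str | None:
    for k in keys:
        if k in feature.attributes:
            return feature.attributes[k][0]
    return None


def _validate_lines(path: Path) -> list[str]:
    """Light syntactic pass: field count, integer coordinates, end >= start.

    Records with end < start (empty in 1-based inclusive coordinates) are
    rejected and logged rather than failing the whole file.
    """
    clean: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.rstrip("\n")
            if not stripped.strip() or stripped.startswith("#"):
                continue
            fields = stripped.split("\t")
            if len(fields) < 9:
                raise GtfParseError(
                    f"{path}, line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise GtfParseError(
                    f"{path}, line {lineno}: non-integer coordinates "
                    f"{fields[3]!r}/{fields[4]!r}"
                ) from exc
            if end < start:
                logger.warning(
                    "%s, line %d: rejected %s record with end < start",
                    path, lineno, fields[2],
                )
                continue
            if "gene_id" not in fields[8]:
                raise GtfParseError(
                    f"{path}, line {lineno}: attribute column lacks gene_id"
                )
            clean.append(stripped)
    return clean


def parse_gtf(path: str | Path, mito_chroms=MITOCHONDRIAL_CHROMS) -> AnnotationModel:
    """Parse a GENCODE-dialect GTF file into an :class:`AnnotationModel`.

    Exons are grouped by transcript and transcripts by gene; transcript and
    gene features themselves are optional (models are assembled from exon and
    CDS records). An empty file yields an empty model with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    lines = _validate_lines(path)
    if not lines:
        logger.warning("%s: no usable GTF records, returning empty model", path)
        return AnnotationModel(provenance={"source": str(path), "n_records": 0})

    db = gffutils.create_db(
        "\n".join(lines),
        dbfn=":memory:",
        from_string=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    gene_biotype: dict[str, str] = {}
    gene_meta: dict[str, tuple[str, str]] = {}  # gene_id -> (chrom, strand)
    tx_exons: dict[str, list[GenomicInterval]] = {}
    tx_cds: dict[str, list[GenomicInterval]] = {}
    tx_biotype: dict[str, str] = {}
    tx_gene: dict[str, str] = {}
    gene_order: list[str] = []

    for f in db.all_features():
        gene_id = _attr(f, ("gene_id",))
        if gene_id is None:
            raise GtfParseError(f"{path}: {f.featuretype} record lacks gene_id")
        if gene_id not in gene_meta:
            gene_meta[gene_id] = (f.seqid, f.strand if f.strand in "+-" else "+")
            gene_order.append(gene_id)
        gb = _attr(f, _BIOTYPE_KEYS_GENE)
        if gb is not None:
            gene_biotype.setdefault(gene_id, gb)
        if f.featuretype not in ("exon", "CDS"):
            continue
        tx_id = _attr(f, ("transcript_id",))
        if tx_id is None:
            raise GtfParseError(
                f"{path}: {f.featuretype} record for {gene_id} lacks transcript_id"
            )
        tx_gene[tx_id] = gene_id
        tb = _attr(f, _BIOTYPE_KEYS_TX)
        if tb is not None:
            tx_biotype.setdefault(tx_id, tb)
        iv = GenomicInterval(f.seqid, f.start - 1, f.end, f.strand if f.strand in "+-" else "+")
        (tx_exons if f.featuretype == "exon" else tx_cds).setdefault(tx_id, []).append(iv)

    genes: dict[str, GeneRecord] = {}
    for gene_id in gene_order:
        chrom, strand = gene_meta[gene_id]
        transcripts = []
        for tx_id, exons in tx_exons.items():
            if tx_gene[tx_id] != gene_id:
                continue
            biotype = tx_biotype.get(tx_id) or gene_biotype.get(gene_id, "unknown")
            transcripts.append(
                TranscriptRecord(
                    transcript_id=tx_id,
                    gene_id=gene_id,
                    biotype=biotype,
                    exons=exons,
                    cds=tx_cds.get(tx_id, []),
                )
            )
        if not transcripts:
            continue  # gene feature without exon children
        transcripts.sort(key=lambda t: t.transcript_id)
        genes[gene_id] = GeneRecord(
            gene_id=gene_id,
            biotype=gene_biotype.get(gene_id, transcripts[0].biotype),
            chrom=chrom,
            strand=strand,
            transcripts=transcripts,
            is_mitochondrial=chrom in mito_chroms,
        )

    model = AnnotationModel(
        genes=genes,
        provenance={"source": str(path), "n_records": len(lines)},
    )
    logger.info("parsed %s: %d genes, %d transcripts", path, len(model), model.n_transcripts)
    return model


def _fmt_attrs(pairs: list[tuple[str, str]]) -> str:
    return " ".join(f'{k} "{v}";' for k, v in pairs)


def write_gtf(model: AnnotationModel, path: str | Path) -> None:
    """Write the model as GENCODE-dialect GTF (1-based inclusive on disk)."""
    path = Path(path)
    with open(path, "w") as fh:
        for gene in model.genes.values():
            span = gene.span
            fh.write(
                "\t".join(
                    [
                        gene.chrom, "txdominance", "gene",
                        str(span.start + 1), str(span.end), ".", gene.strand, ".",
                        _fmt_attrs([("gene_id", gene.gene_id), ("gene_type", gene.biotype)]),
                    ]
                )
                + "\n"
            )
            for t in gene.transcripts:
                attrs = [
                    ("gene_id", gene.gene_id),
                    ("transcript_id", t.transcript_id),
                    ("gene_type", gene.biotype),
                    ("transcript_type", t.biotype),
                ]
                fh.write(
                    "\t".join(
                        [
                            gene.chrom, "txdominance", "transcript",
                            str(t.exons[0].start + 1), str(t.exons[-1].end),
                            ".", gene.strand, ".", _fmt_attrs(attrs),
                        ]
                    )
                    + "\n"
                )
                for feature, ivs in (("exon", t.exons), ("CDS", t.cds)):
                    for iv in ivs:
                        fh.write(
                            "\t".join(
                                [
                                    gene.chrom, "txdominance", feature,
                                    str(iv.start + 1), str(iv.end),
                                    ".", gene.strand, ".", _fmt_attrs(attrs),
                                ]
                            )
                            + "\n"
                        )


def write_introns_bed(model: AnnotationModel, path: str | Path) -> None:
    """Write derived introns as BED6 (0-based half-open)."""
    path = Path(path)
    with open(path, "w") as fh:
        for gene in model.genes.values():
            for intron in derive_introns(gene):
                fh.write(
                    "\t".join(
                        [
                            intron.interval.chrom,
                            str(intron.interval.start),
                            str(intron.interval.end),
                            f"{gene.gene_id}:intron{intron.index}",
                            "0",
                            gene.strand,
                        ]
                    )
                    + "\n"
                )


def study_set_report(model: AnnotationModel) -> pd.DataFrame:
    """Per-gene summary of the (filtered) study set."""
    rows = []
    for gene in model.genes.values():
        _, fully = unique_junctions(gene)
        lengths = [t.length for t in gene.transcripts]
        rows.append(
            {
                "gene_id": gene.gene_id,
                "biotype": gene.biotype,
                "chrom": gene.chrom,
                "strand": gene.strand,
                "n_transcripts": len(gene.transcripts),
                "n_coding_transcripts": sum(t.is_coding for t in gene.transcripts),
                "min_tx_length": min(lengths),
                "max_tx_length": max(lengths),
                "fully_identifiable": fully,
                "is_mitochondrial": gene.is_mitochondrial,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "biotype", "chrom", "strand", "n_transcripts",
            "n_coding_transcripts", "min_tx_length", "max_tx_length",
            "fully_identifiable", "is_mitochondrial",
        ],
    )


def write_study_set_report(model: AnnotationModel, path: str | Path) -> None:
    study_set_report(model).to_csv(path, sep="\t", index=False)
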