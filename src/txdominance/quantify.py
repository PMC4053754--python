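"""Expression quantification: FPKM conversion, gene-level expression from
exons, relative transcript abundances, intron expression and junction-based
transcript support.

FPKM here is fragments per kilobase of feature per million mapped reads,
``count * 1e9 / (length_nt * library_size)``. Gene expression follows the
exon-average convention: the mean FPKM over the gene's *expressed* exons
(FPKM strictly greater than a threshold, default 0), which is deliberately
independent of the transcript-level quantification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import AnnotationModel, Junction, unique_junctions

logger = logging.getLogger(__name__)


@dataclass
class CountTable:
    """Feature-by-sample counts with per-feature lengths and library sizes.

    Counts are non-negative; they may be fractional when they are exact
    expectations from the synthetic generator's noiseless mode. Junction
    features conventionally carry a read-span "length" used only for
    expected-count arithmetic.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    library_sizes: pd.Series
    gene_ids: pd.Series | None = None  # optional feature -> gene mapping

    def __post_init__(self) -> None:
        if not self.lengths.index.equals(self.counts.index):
            self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            missing = self.lengths.index[self.lengths.isna()][:3].tolist()
            raise ValueError(f"features without lengths, e.g. {missing}")
        if not self.library_sizes.index.equals(pd.Index(self.counts.columns)):
            self.library_sizes = self.library_sizes.reindex(self.counts.columns)
        if self.library_sizes.isna().any() or (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be present and > 0 for every sample")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if self.gene_ids is not None and not self.gene_ids.index.equals(self.counts.index):
            self.gene_ids = self.gene_ids.reindex(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class ExpressionMatrix:
    """Feature-by-sample FPKM (or derived fraction) matrix.

    ``level`` tags the feature kind (transcript/gene/exon/intron/
    relative_abundance). Values are >= 0; NaN is reserved for genuinely
    undefined cells (relative abundances of silent genes).
    """

    data: pd.DataFrame
    level: str
    gene_ids: pd.Series | None = None

    def __post_init__(self) -> None:
        vals = self.data.to_numpy(dtype=float)
        if (vals[~np.isnan(vals)] < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.gene_ids is not None and not self.gene_ids.index.equals(self.data.index):
            self.gene_ids = self.gene_ids.reindex(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class SampleMetadata:
    """Sample annotations: condition, cellular compartment, replicate id."""

    table: pd.DataFrame  # columns: sample_id, condition, compartment, replicate

    def __post_init__(self) -> None:
        required = {"sample_id", "condition", "compartment", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"metadata lacks columns {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in metadata")
        self.table = self.table.set_index("sample_id", drop=False)

    def compartment_of(self, sample_id: str) -> str:
        return str(self.table.loc[sample_id, "compartment"])

    def condition_of(self, sample_id: str) -> str:
        return str(self.table.loc[sample_id, "condition"])

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()


@dataclass
class JunctionEvidence:
    """Junction-read support for each transcript of a fully identifiable gene."""

    gene_id: str
    sample_id: str
    support: dict[str, float]  # transcript_id -> mean count over unique junctions
    evidence_major: str | None
    tie: bool = False


def counts_to_fpkm(table: CountTable, level: str = "exon") -> ExpressionMatrix:
    """FPKM = count * 1e9 / (length_nt * library_size); linear in counts."""
    zero_len = table.lengths.index[table.lengths <= 0]
    if len(zero_len):
        raise ValueError(f"zero-length feature(s): {zero_len[:3].tolist()}")
    fpkm = (
        table.counts.astype(float)
        .mul(1e9)
        .div(table.lengths.astype(float), axis=0)
        .div(table.library_sizes.astype(float), axis=1)
    )
    return ExpressionMatrix(data=fpkm, level=level, gene_ids=table.gene_ids)


def gene_expression_from_exons(
    exon_fpkm: ExpressionMatrix,
    model: AnnotationModel,
    expressed_exon_min: float = 0.0,
) -> ExpressionMatrix:
    """Gene FPKM = mean FPKM over the gene's expressed exons.

    An exon counts as expressed when its FPKM is strictly greater than
    ``expressed_exon_min``; a gene with no expressed exon in a sample gets 0.
    """
    if exon_fpkm.gene_ids is None:
        raise ValueError("exon matrix lacks a feature -> gene mapping")
    unknown = set(exon_fpkm.gene_ids.dropna()) - set(model.genes)
    if unknown:
        raise ValueError(f"exon features mapped to unknown genes, e.g. {sorted(unknown)[:3]}")
    data = exon_fpkm.data
    expressed = data > expressed_exon_min
    grp = exon_fpkm.gene_ids
    sums = data.where(expressed, 0.0).groupby(grp).sum()
    ns = expressed.groupby(grp).sum()
    gene = sums.div(ns.where(ns > 0)).fillna(0.0)
    gene = gene.reindex(sorted(set(grp.dropna()) & set(model.genes))).fillna(0.0)
    return ExpressionMatrix(data=gene, level="gene")


def relative_abundances(
    tx_fpkm: ExpressionMatrix, model: AnnotationModel
) -> ExpressionMatrix:
    """Within-gene relative abundance of each transcript, per sample.

    Fractions sum to 1 for every gene-sample with non-zero transcript mass;
    cells of silent gene-samples are NaN (undefined, flagged downstream).
    """
    tx2gene = model.transcript_gene
    missing = [t for t in tx_fpkm.data.index if t not in tx2gene]
    if missing:
        raise ValueError(f"transcripts not in the annotation, e.g. {missing[:3]}")
    gene_ids = pd.Series({t: tx2gene[t] for t in tx_fpkm.data.index}, name="gene_id")
    totals = tx_fpkm.data.groupby(gene_ids).transform("sum")
    frac = tx_fpkm.data / totals.where(totals > 0)
    n_undefined = int(frac.isna().any(axis=1).sum())
    if n_undefined:
        logger.debug("relative_abundances: %d transcripts in silent gene-samples", n_undefined)
    return ExpressionMatrix(data=frac, level="relative_abundance", gene_ids=gene_ids)


@dataclass
class IntronExpression:
    introns: ExpressionMatrix                # per-intron FPKM
    gene_mean: pd.DataFrame                  # per-gene mean intronic FPKM


def intron_expression(intron_counts: CountTable, model: AnnotationModel) -> IntronExpression:
    """Per-intron FPKM plus the per-gene mean intronic FPKM."""
    fpkm = counts_to_fpkm(intron_counts, level="intron")
    if fpkm.gene_ids is None:
        raise ValueError("intron table lacks a feature -> gene mapping")
    gene_mean = fpkm.data.groupby(fpkm.gene_ids).mean()
    return IntronExpression(introns=fpkm, gene_mean=gene_mean)


def parse_junction_id(feature_id: str) -> Junction:
    """Parse a 'chrom:donor-acceptor:strand' junction feature id."""
    try:
        chrom, coords, strand = feature_id.rsplit(":", 2)
        donor_s, acceptor_s = coords.split("-")
        return Junction(chrom, int(donor_s), int(acceptor_s), strand)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"malformed junction id {feature_id!r}") from exc


def junction_id(j: Junction) -> str:
    return f"{j.chrom}:{j.donor}-{j.acceptor}:{j.strand}"


def junction_support(
    junction_counts: CountTable, model: AnnotationModel
) -> list[JunctionEvidence]:
    """Direct junction-read evidence for the major transcript.

    Restricted to fully identifiable genes (every transcript has >= 1 unique
    junction). Per transcript and sample, support is the mean count over its
    unique junctions (missing junction rows count 0); the evidence major is
    the argmax, with ties yielding no call. Count rows that match no
    annotated junction are ignored with a warning.
    """
    id_to_junction = {fid: parse_junction_id(fid) for fid in junction_counts.counts.index}
    annotated = {
        j
        for gene in model.genes.values()
        for t in gene.transcripts
        for j in t.junctions
    }
    unmatched = [fid for fid, j in id_to_junction.items() if j not in annotated]
    if unmatched:
        logger.warning(
            "%d junction features not present in the annotation (e.g. %s); ignored",
            len(unmatched), unmatched[:3],
        )
    counts_by_junction = {id_to_junction[fid]: junction_counts.counts.loc[fid] for fid in junction_counts.counts.index}
    zeros = pd.Series(0.0, index=junction_counts.counts.columns)

    evidence: list[JunctionEvidence] = []
    for gene in model.genes.values():
        uniq, fully = unique_junctions(gene)
        if not fully:
            continue
        per_tx_rows = {
            tid: [counts_by_junction.get(j, zeros) for j in js]
            for tid, js in uniq.items()
        }
        for sample in junction_counts.samples:
            support = {
                tid: float(np.mean([row[sample] for row in rows]))
                for tid, rows in per_tx_rows.items()
            }
            best = max(support.values())
            winners = sorted(t for t, v in support.items() if v == best)
            tie = len(winners) > 1
            evidence.append(
                JunctionEvidence(
                    gene_id=gene.gene_id,
                    sample_id=sample,
                    support=support,
                    evidence_major=None if tie else winners[0],
                    tie=tie,
                )
            )
    return evidence


# ---------------------------------------------------------------------------
# TSV readers (feature_id, length[, gene_id], then one column per sample)
# ---------------------------------------------------------------------------

def read_count_table(path, library_sizes: pd.Series) -> CountTable:
    df = pd.read_csv(path, sep="\t")
    if "feature_id" not in df.columns or "length" not in df.columns:
        raise ValueError(f"{path}: expected 'feature_id' and 'length' columns")
    df = df.set_index("feature_id")
    gene_ids = None
    if "gene_id" in df.columns:
        gene_ids = df.pop("gene_id")
    lengths = df.pop("length")
    return CountTable(
        counts=df, lengths=lengths, library_sizes=library_sizes, gene_ids=gene_ids
    )


def read_expression_matrix(path, level: str) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    gene_ids = df.pop("gene_id") if "gene_id" in df.columns else None
    return ExpressionMatrix(data=df, level=level, gene_ids=gene_ids)


def read_metadata(path) -> SampleMetadata:
    return SampleMetadata(table=pd.read_csv(path, sep="\t", dtype=str))


def read_library_sizes(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return df.set_index("sample_id")["library_size"].astype(float)
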