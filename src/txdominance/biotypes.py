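"""Biotype accounting for major transcripts.

Classifies each major transcript by annotation biotype, measures the
FPKM-mass each class contributes to the studied mRNA pool (non-coding majors
are a sizeable slice of the nuclear pool), and quantifies the positional
bias of major retained introns towards the transcriptional 3'-end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import (
    AnnotationModel,
    IntronRegion,
    exclusive_exonic_regions,
    intron_relative_position,
)
from .dominance import DominanceCall
from .quantify import ExpressionMatrix, SampleMetadata

logger = logging.getLogger(__name__)

BIOTYPE_CLASSES = (
    "protein_coding",
    "retained_intron",
    "processed_transcript",
    "nonsense_mediated_decay",
    "other",
)


@dataclass
class BiotypeSummary:
    """Per-sample biotype breakdown of major transcripts.

    ``mass_fractions`` share the mRNA-pool denominator with
    :func:`txdominance.dominance.pool_fractions` (total study-set transcript
    FPKM, mitochondrial genes excluded), so the class fractions recompose
    the overall major fraction.
    """

    sample_id: str
    counts: dict[str, int]
    mass_fractions: dict[str, float]
    noncoding_major_gene_count: int
    n_major_calls: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_major_calls:
            raise ValueError("biotype counts do not sum to the number of major calls")


def _biotype_class(biotype: str) -> str:
    if biotype in BIOTYPE_CLASSES:
        return biotype
    logger.debug("unknown biotype %r mapped to class 'other'", biotype)
    return "other"


def major_biotype_summary(
    calls: list[DominanceCall],
    model: AnnotationModel,
    tx_fpkm: ExpressionMatrix,
) -> list[BiotypeSummary]:
    """Classify major transcripts by biotype per sample.

    A major is non-coding when its transcript has no annotated CDS
    (cds_length == 0). Counts cover every major call; mass fractions follow
    the pool convention and therefore exclude mitochondrial genes.
    """
    tx2gene = model.transcript_gene
    biotype = {t.transcript_id: t.biotype for t in model.transcripts()}
    cds_len = {t.transcript_id: t.cds_length for t in model.transcripts()}
    keep = np.array(
        [not model.genes[tx2gene[t]].is_mitochondrial for t in tx_fpkm.data.index]
    )
    tx_pos = {t: i for i, t in enumerate(tx_fpkm.data.index)}
    by_sample: dict[str, list[DominanceCall]] = {s: [] for s in tx_fpkm.samples}
    for c in calls:
        by_sample.setdefault(c.sample_id, []).append(c)

    out: list[BiotypeSummary] = []
    values = tx_fpkm.data.to_numpy(dtype=float)
    for sample_j, sample in enumerate(tx_fpkm.samples):
        col = values[:, sample_j]
        denom = float(col[keep].sum())
        counts = {k: 0 for k in BIOTYPE_CLASSES}
        mass = {k: 0.0 for k in BIOTYPE_CLASSES}
        noncoding_genes = 0
        cs = by_sample.get(sample, [])
        for c in cs:
            cls = _biotype_class(biotype[c.major])
            counts[cls] += 1
            if not model.genes[c.gene_id].is_mitochondrial and denom > 0:
                mass[cls] += float(col[tx_pos[c.major]]) / denom
            if cds_len[c.major] == 0:
                noncoding_genes += 1
        out.append(
            BiotypeSummary(
                sample_id=sample,
                counts=counts,
                mass_fractions=mass,
                noncoding_major_gene_count=noncoding_genes,
                n_major_calls=len(cs),
            )
        )
    return out


def biotype_summary_frame(summaries: list[BiotypeSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"sample_id": s.sample_id, "n_major_calls": s.n_major_calls,
               "noncoding_major_gene_count": s.noncoding_major_gene_count}
        for cls in BIOTYPE_CLASSES:
            row[f"count_{cls}"] = s.counts[cls]
            row[f"mass_fraction_{cls}"] = s.mass_fractions[cls]
        rows.append(row)
    return pd.DataFrame(rows)


def compartment_contrast(
    summaries: list[BiotypeSummary],
    metadata: SampleMetadata,
    gene_fpkm: ExpressionMatrix | None = None,
    calls: list[DominanceCall] | None = None,
    model: AnnotationModel | None = None,
) -> dict:
    """Aggregate biotype fractions per cellular compartment.

    Returns mean per-class mass fractions per compartment, the
    nucleus-minus-cytosol difference in the non-coding major fraction, and —
    when gene-level expression and calls are supplied — the median log2
    nucleus/cytosol expression ratio for genes whose (modal) major is
    non-coding vs coding.
    """
    per_sample = biotype_summary_frame(summaries)
    per_sample["compartment"] = [
        metadata.compartment_of(s) for s in per_sample["sample_id"]
    ]
    noncoding_classes = [c for c in BIOTYPE_CLASSES if c != "protein_coding"]
    per_sample["mass_fraction_noncoding"] = sum(
        per_sample[f"mass_fraction_{c}"] for c in noncoding_classes
    )
    agg_cols = [f"mass_fraction_{c}" for c in BIOTYPE_CLASSES] + ["mass_fraction_noncoding"]
    per_compartment = per_sample.groupby("compartment")[agg_cols].mean()

    result: dict = {"per_compartment": per_compartment}
    have = set(per_compartment.index)
    if {"nucleus", "cytosol"} <= have:
        result["nucleus_cytosol_noncoding_diff"] = float(
            per_compartment.loc["nucleus", "mass_fraction_noncoding"]
            - per_compartment.loc["cytosol", "mass_fraction_noncoding"]
        )
    else:
        logger.info("nucleus/cytosol contrast skipped: compartments present = %s", sorted(have))
        result["nucleus_cytosol_noncoding_diff"] = None

    if (
        gene_fpkm is not None
        and calls is not None
        and model is not None
        and {"nucleus", "cytosol"} <= have
    ):
        nuc = [s for s in gene_fpkm.samples if metadata.compartment_of(s) == "nucleus"]
        cyt = [s for s in gene_fpkm.samples if metadata.compartment_of(s) == "cytosol"]
        cds_len = {t.transcript_id: t.cds_length for t in model.transcripts()}
        # modal coding status of each gene's majors across samples
        status: dict[str, list[bool]] = {}
        for c in calls:
            status.setdefault(c.gene_id, []).append(cds_len[c.major] == 0)
        ratios: dict[bool, list[float]] = {True: [], False: []}
        for gene_id, flags in status.items():
            noncoding = sum(flags) * 2 > len(flags)
            a = float(gene_fpkm.data.loc[gene_id, nuc].mean())
            b = float(gene_fpkm.data.loc[gene_id, cyt].mean())
            if a > 0 and b > 0:
                ratios[noncoding].append(np.log2(a / b))
        result["median_log2_nuc_vs_cyt_noncoding_major"] = (
            float(np.median(ratios[True])) if ratios[True] else None
        )
        result["median_log2_nuc_vs_cyt_coding_major"] = (
            float(np.median(ratios[False])) if ratios[False] else None
        )
    return result


@dataclass
class RetainedIntronPositions:
    positions: pd.DataFrame  # gene_id, sample_id, major, position
    median: float
    q25: float
    q75: float
    by_compartment: pd.DataFrame | None = None


def retained_intron_position_stats(
    calls: list[DominanceCall],
    model: AnnotationModel,
    metadata: SampleMetadata | None = None,
) -> RetainedIntronPositions:
    """Strand-aware relative positions of major retained introns.

    For each major call whose transcript biotype is ``retained_intron``, the
    retained region is the transcript's exonic sequence covered by no other
    transcript of the gene; when several such regions exist the most 3' one
    is summarized. Position 0 is the transcriptional start of the gene span,
    1 the end. Majors with no identifiable retained region are excluded
    (logged).
    """
    biotype = {t.transcript_id: t.biotype for t in model.transcripts()}
    region_cache: dict[str, IntronRegion | None] = {}
    rows = []
    n_excluded = 0
    for c in calls:
        if biotype[c.major] != "retained_intron":
            continue
        if c.major not in region_cache:
            gene = model.genes[c.gene_id]
            regions = exclusive_exonic_regions(gene, c.major)
            if not regions:
                region_cache[c.major] = None
            else:
                # most 3' region, strand-aware
                pick = max(regions, key=lambda iv: iv.start) if gene.strand == "+" \
                    else min(regions, key=lambda iv: iv.start)
                region_cache[c.major] = IntronRegion(c.gene_id, pick, 0)
        region = region_cache[c.major]
        if region is None:
            n_excluded += 1
            continue
        pos = intron_relative_position(region, model.genes[c.gene_id])
        rows.append(
            {"gene_id": c.gene_id, "sample_id": c.sample_id, "major": c.major, "position": pos}
        )
    if n_excluded:
        logger.warning(
            "%d retained_intron majors had no identifiable retained region; excluded",
            n_excluded,
        )
    df = pd.DataFrame(rows, columns=["gene_id", "sample_id", "major", "position"])
    if df.empty:
        return RetainedIntronPositions(df, float("nan"), float("nan"), float("nan"))
    q25, med, q75 = np.percentile(df["position"], [25, 50, 75])
    by_comp = None
    if metadata is not None:
        df = df.assign(
            compartment=[metadata.compartment_of(s) for s in df["sample_id"]]
        )
        by_comp = df.groupby("compartment")["position"].median().to_frame("median_position")
    return RetainedIntronPositions(df, float(med), float(q25), float(q75), by_comp)
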