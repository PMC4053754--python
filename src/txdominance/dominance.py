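"""Major / dominant transcript calling and its summary statistics.

The major transcript of a gene in a sample is the highest-FPKM transcript;
it is x-fold dominant when its FPKM is at least x times that of the
runner-up. A gene enters the calling for a sample only when its exon-based
gene FPKM exceeds the expression gate (default 1 FPKM, the conventional
minimum for protein detectability); transcripts are then considered detected
regardless of their own level.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import AnnotationModel, annotate_length_flags, group_by_tss
from .quantify import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class DominanceCall:
    """Per gene per sample: the major transcript and its fold ratio."""

    gene_id: str
    sample_id: str
    major: str
    runner_up: str | None
    fold_ratio: float  # major FPKM / runner-up FPKM; +inf without competition
    gene_fpkm: float
    major_fpkm: float
    runner_up_fpkm: float = 0.0
    tie: bool = False

    def __post_init__(self) -> None:
        if self.runner_up is not None and self.major == self.runner_up:
            raise ValueError("major and runner-up must differ")
        if self.fold_ratio < 1:
            raise ValueError("fold ratio below 1: ranking violated")


@dataclass
class PoolFractions:
    """FPKM-mass shares of transcript classes in the studied mRNA pool.

    Denominator: total FPKM of all study-set transcripts (mitochondrial
    genes excluded from numerator and denominator alike).
    """

    sample_id: str
    fraction_major: float
    fraction_twofold: float
    fraction_fivefold: float
    fraction_noncoding_major: float

    def __post_init__(self) -> None:
        eps = 1e-9
        if not (
            -eps <= self.fraction_fivefold
            <= self.fraction_twofold + eps
            and self.fraction_twofold <= self.fraction_major + eps
            and self.fraction_major <= 1 + eps
        ):
            raise ValueError(f"pool-fraction ordering violated: {self}")


@dataclass
class ThresholdSummary:
    """One row of the expression-threshold sweep for one sample."""

    sample_id: str
    threshold: float
    n_expressed_genes: int
    pct_of_study_set: float
    n_twofold: int
    pct_twofold: float
    n_fivefold: int
    pct_fivefold: float


def _gene_rows(tx_fpkm: ExpressionMatrix, model: AnnotationModel) -> dict[str, np.ndarray]:
    """Row positions of each gene's transcripts, pre-sorted lexicographically."""
    tx2gene = model.transcript_gene
    missing = [t for t in tx_fpkm.data.index if t not in tx2gene]
    if missing:
        raise ValueError(f"transcripts not in the annotation, e.g. {missing[:3]}")
    pos = {t: i for i, t in enumerate(tx_fpkm.data.index)}
    rows: dict[str, list[int]] = {}
    for t in sorted(tx_fpkm.data.index):
        rows.setdefault(tx2gene[t], []).append(pos[t])
    return {g: np.asarray(r) for g, r in rows.items()}


def call_major(
    tx_fpkm: ExpressionMatrix,
    gene_fpkm: ExpressionMatrix,
    model: AnnotationModel,
    gene_expressed_min: float = 1.0,
) -> list[DominanceCall]:
    """Call the major transcript for every expressed gene in every sample.

    FPKM ties for the top rank are broken by lexicographically smallest
    transcript id and flagged. A gene whose transcripts are all at 0 FPKM
    despite passing the gene gate yields no call (logged).
    """
    rows = _gene_rows(tx_fpkm, model)
    tx_ids = tx_fpkm.data.index.to_numpy()
    values = tx_fpkm.data.to_numpy(dtype=float)
    calls: list[DominanceCall] = []
    n_skipped = 0
    for sample_j, sample in enumerate(tx_fpkm.samples):
        if sample not in gene_fpkm.data.columns:
            raise ValueError(f"sample {sample!r} missing from gene-level matrix")
        gcol = gene_fpkm.data[sample]
        col = values[:, sample_j]
        for gene_id, r in rows.items():
            g_val = float(gcol.get(gene_id, 0.0))
            if not g_val > gene_expressed_min:
                continue
            vals = col[r]
            if not (vals > 0).any():
                n_skipped += 1
                continue
            order = np.argsort(-vals, kind="stable")  # stable: ties stay lexicographic
            top = r[order[0]]
            major_fpkm = float(vals[order[0]])
            if len(r) > 1:
                second = r[order[1]]
                runner_fpkm = float(vals[order[1]])
                fold = math.inf if runner_fpkm == 0 else major_fpkm / runner_fpkm
                calls.append(
                    DominanceCall(
                        gene_id=gene_id,
                        sample_id=sample,
                        major=str(tx_ids[top]),
                        runner_up=str(tx_ids[second]),
                        fold_ratio=fold,
                        gene_fpkm=g_val,
                        major_fpkm=major_fpkm,
                        runner_up_fpkm=runner_fpkm,
                        tie=major_fpkm == runner_fpkm,
                    )
                )
            else:
                calls.append(
                    DominanceCall(
                        gene_id=gene_id,
                        sample_id=sample,
                        major=str(tx_ids[top]),
                        runner_up=None,
                        fold_ratio=math.inf,
                        gene_fpkm=g_val,
                        major_fpkm=major_fpkm,
                    )
                )
    if n_skipped:
        logger.warning(
            "%d expressed gene-samples had all-zero transcript FPKMs; no call", n_skipped
        )
    return calls


def classify_dominance(call: DominanceCall, x: float) -> bool:
    """True iff the major transcript is x-fold dominant (fold ratio >= x)."""
    if x <= 1:
        raise ValueError("dominance fold must exceed 1")
    return call.fold_ratio >= x


def calls_to_frame(calls: list[DominanceCall]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "sample_id": c.sample_id,
                "major": c.major,
                "runner_up": c.runner_up if c.runner_up is not None else "",
                "fold_ratio": c.fold_ratio,
                "gene_fpkm": c.gene_fpkm,
                "major_fpkm": c.major_fpkm,
                "runner_up_fpkm": c.runner_up_fpkm,
                "twofold": c.fold_ratio >= 2,
                "fivefold": c.fold_ratio >= 5,
                "tie": c.tie,
            }
            for c in calls
        ]
    )
    if df.empty:
        df = pd.DataFrame(
            columns=[
                "gene_id", "sample_id", "major", "runner_up", "fold_ratio",
                "gene_fpkm", "major_fpkm", "runner_up_fpkm", "twofold",
                "fivefold", "tie",
            ]
        )
    return df.sort_values(["sample_id", "gene_id"]).reset_index(drop=True)


def pool_fractions(
    tx_fpkm: ExpressionMatrix,
    calls: list[DominanceCall],
    model: AnnotationModel,
) -> list[PoolFractions]:
    """mRNA-pool mass fractions of major / dominant / non-coding-major classes.

    The denominator is the summed FPKM of every study-set transcript in the
    sample; mitochondrial genes are excluded throughout because their copy
    number inflates the pool.
    """
    tx2gene = model.transcript_gene
    keep = np.array(
        [not model.genes[tx2gene[t]].is_mitochondrial for t in tx_fpkm.data.index]
    )
    cds_len = {t.transcript_id: t.cds_length for t in model.transcripts()}
    tx_pos = {t: i for i, t in enumerate(tx_fpkm.data.index)}
    by_sample: dict[str, list[DominanceCall]] = {}
    for c in calls:
        by_sample.setdefault(c.sample_id, []).append(c)

    out: list[PoolFractions] = []
    for sample_j, sample in enumerate(tx_fpkm.samples):
        col = tx_fpkm.data.to_numpy(dtype=float)[:, sample_j]
        denom = float(col[keep].sum())
        if denom <= 0:
            raise ValueError(f"zero mRNA-pool denominator in sample {sample!r}")
        major = two = five = noncoding = 0.0
        for c in by_sample.get(sample, []):
            if model.genes[c.gene_id].is_mitochondrial:
                continue
            v = col[tx_pos[c.major]]
            major += v
            if c.fold_ratio >= 2:
                two += v
            if c.fold_ratio >= 5:
                five += v
            if cds_len[c.major] == 0:
                noncoding += v
        out.append(
            PoolFractions(
                sample_id=sample,
                fraction_major=major / denom,
                fraction_twofold=two / denom,
                fraction_fivefold=five / denom,
                fraction_noncoding_major=noncoding / denom,
            )
        )
    return out


def transcripts_per_gene_ratio(
    tx_fpkm: ExpressionMatrix,
    gene_fpkm: ExpressionMatrix,
    model: AnnotationModel,
    min_fpkm: float = 1.0,
) -> pd.Series:
    """(# transcripts above threshold) / (# genes above threshold), per sample.

    May drop below 1 because gene expression is exon-based while transcript
    expression is quantifier-based. Samples with no expressed gene get NaN.
    """
    tx_n = (tx_fpkm.data > min_fpkm).sum(axis=0)
    gene_n = (gene_fpkm.data > min_fpkm).sum(axis=0)
    gene_n = gene_n.reindex(tx_n.index)
    ratio = tx_n / gene_n.where(gene_n > 0)
    if ratio.isna().any():
        logger.warning(
            "transcripts-per-gene ratio undefined for samples %s (no expressed genes)",
            ratio.index[ratio.isna()].tolist(),
        )
    return ratio.rename("transcripts_per_gene")


def threshold_sweep(
    tx_fpkm: ExpressionMatrix,
    gene_fpkm: ExpressionMatrix,
    model: AnnotationModel,
    thresholds: tuple[float, ...] = (1.0, 5.0, 10.0),
) -> list[ThresholdSummary]:
    """Expressed-gene and dominant-major counts at increasing FPKM gates.

    Percentages of the study set use the filtered study-set size (number of
    genes in the model) as denominator; dominance percentages are taken among
    the expressed genes of the same sample and threshold.
    """
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be ascending")
    study_size = len(model)
    out: list[ThresholdSummary] = []
    for thr in thresholds:
        calls = call_major(tx_fpkm, gene_fpkm, model, gene_expressed_min=thr)
        by_sample: dict[str, list[DominanceCall]] = {s: [] for s in tx_fpkm.samples}
        for c in calls:
            by_sample[c.sample_id].append(c)
        for sample in tx_fpkm.samples:
            cs = by_sample[sample]
            n_expr = len(cs)
            n2 = sum(c.fold_ratio >= 2 for c in cs)
            n5 = sum(c.fold_ratio >= 5 for c in cs)
            out.append(
                ThresholdSummary(
                    sample_id=sample,
                    threshold=thr,
                    n_expressed_genes=n_expr,
                    pct_of_study_set=100.0 * n_expr / study_size if study_size else 0.0,
                    n_twofold=n2,
                    pct_twofold=100.0 * n2 / n_expr if n_expr else 0.0,
                    n_fivefold=n5,
                    pct_fivefold=100.0 * n5 / n_expr if n_expr else 0.0,
                )
            )
    return out


def threshold_sweep_frame(summaries: list[ThresholdSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "threshold": s.threshold,
                "n_expressed_genes": s.n_expressed_genes,
                "pct_of_study_set": s.pct_of_study_set,
                "n_twofold": s.n_twofold,
                "pct_twofold": s.pct_twofold,
                "n_fivefold": s.n_fivefold,
                "pct_fivefold": s.pct_fivefold,
            }
            for s in summaries
        ]
    )


def rank_abundance_profile(
    rel_abund: ExpressionMatrix,
    model: AnnotationModel,
    max_rank: int = 5,
) -> pd.DataFrame:
    """Quartile summary of relative abundance at each within-gene rank.

    For every gene-sample with defined fractions, transcripts are sorted by
    decreasing relative abundance; the fraction at rank r is pooled over all
    gene-samples and summarized by quartiles.
    """
    rows = _gene_rows(rel_abund, model)
    values = rel_abund.data.to_numpy(dtype=float)
    pooled: dict[int, list[float]] = {r: [] for r in range(1, max_rank + 1)}
    for r_idx in rows.values():
        sub = values[r_idx, :]
        for j in range(sub.shape[1]):
            v = sub[:, j]
            if np.isnan(v).any():
                continue
            sv = np.sort(v)[::-1]
            for r in range(min(max_rank, len(sv))):
                pooled[r + 1].append(float(sv[r]))
    records = []
    for r in range(1, max_rank + 1):
        arr = np.asarray(pooled[r])
        if arr.size:
            q25, med, q75 = np.percentile(arr, [25, 50, 75])
        else:
            q25 = med = q75 = np.nan
        records.append(
            {"rank": r, "n": arr.size, "q25": q25, "median": med, "q75": q75}
        )
    return pd.DataFrame(records).set_index("rank")


def tss_group_dominance(
    tx_fpkm: ExpressionMatrix,
    model: AnnotationModel,
    x: float = 2.0,
    gene_fpkm: ExpressionMatrix | None = None,
    gene_expressed_min: float = 1.0,
) -> pd.DataFrame:
    """Major/dominance calling within multi-transcript TSS groups.

    Each TSS group with >= 2 transcripts is treated as a miniature gene: the
    group's transcripts are ranked by FPKM and the top one classified for
    x-fold dominance. Singleton groups are excluded. The expression gate uses
    exon-based gene FPKM when supplied, otherwise the group's summed FPKM.
    """
    if x <= 1:
        raise ValueError("dominance fold must exceed 1")
    records = []
    data = tx_fpkm.data
    for gene in model.genes.values():
        for tss, tids in group_by_tss(gene).items():
            if len(tids) < 2:
                continue
            tids = sorted(t for t in tids if t in data.index)
            if len(tids) < 2:
                continue
            sub = data.loc[tids]
            for sample in data.columns:
                if gene_fpkm is not None:
                    gate = float(gene_fpkm.data[sample].get(gene.gene_id, 0.0))
                else:
                    gate = float(sub[sample].sum())
                if not gate > gene_expressed_min:
                    continue
                vals = sub[sample].to_numpy(dtype=float)
                if not (vals > 0).any():
                    continue
                order = np.argsort(-vals, kind="stable")
                major_fpkm = float(vals[order[0]])
                runner_fpkm = float(vals[order[1]])
                fold = math.inf if runner_fpkm == 0 else major_fpkm / runner_fpkm
                records.append(
                    {
                        "gene_id": gene.gene_id,
                        "tss": tss,
                        "sample_id": sample,
                        "group_size": len(tids),
                        "major": tids[order[0]],
                        "fold_ratio": fold,
                        "dominant": fold >= x,
                        "tie": major_fpkm == runner_fpkm,
                    }
                )
    cols = ["gene_id", "tss", "sample_id", "group_size", "major", "fold_ratio", "dominant", "tie"]
    return pd.DataFrame(records, columns=cols)


def longest_overlap_stats(
    calls: list[DominanceCall], model: AnnotationModel
) -> pd.DataFrame:
    """Per sample: fraction of major transcripts that are the longest annotated
    transcript, and fraction carrying the longest CDS.

    Only genes with a major call and more than one annotated transcript
    contribute (the question is vacuous otherwise).
    """
    flags_cache = {g: annotate_length_flags(gene) for g, gene in model.genes.items()}
    agg: dict[str, list[tuple[bool, bool]]] = {}
    for c in calls:
        gene = model.genes[c.gene_id]
        if len(gene.transcripts) < 2:
            continue
        f = flags_cache[c.gene_id][c.major]
        agg.setdefault(c.sample_id, []).append(
            (f.is_longest_transcript, f.has_longest_cds)
        )
    rows = []
    for sample, pairs in sorted(agg.items()):
        n = len(pairs)
        rows.append(
            {
                "sample_id": sample,
                "n_genes": n,
                "frac_major_is_longest": sum(p[0] for p in pairs) / n,
                "frac_major_has_longest_cds": sum(p[1] for p in pairs) / n,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "n_genes", "frac_major_is_longest", "frac_major_has_longest_cds"],
    )
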