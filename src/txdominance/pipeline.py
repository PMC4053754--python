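"""End-to-end orchestration: configuration, execution, reports, validation.

``run_pipeline`` drives study-set construction, quantification, dominance
calling, switch scanning, biotype accounting and (when junction counts are
available) junction-based validation, writing per-module TSV/JSON outputs
plus one machine-readable summary. Inputs come either from files (GTF +
TSV matrices) or from the synthetic generator via a scenario block; a fixed
seed makes the whole run byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import biotypes as bt
from . import dominance as dom
from . import switches as sw
from .annotation import AnnotationModel, build_study_set
from .gtf import parse_gtf, write_introns_bed, write_study_set_report
from .quantify import (
    CountTable,
    ExpressionMatrix,
    SampleMetadata,
    counts_to_fpkm,
    gene_expression_from_exons,
    junction_support,
    read_count_table,
    read_expression_matrix,
    read_library_sizes,
    read_metadata,
)
from .simulate import SyntheticDataset, SyntheticScenario, simulate_dataset, write_dataset

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    """Everything a run needs: inputs (files or scenario), thresholds, output."""

    # file inputs (ignored when a scenario is given)
    gtf: str | None = None
    tx_fpkm: str | None = None
    exon_counts: str | None = None
    intron_counts: str | None = None
    junction_counts: str | None = None
    metadata: str | None = None
    library_sizes: str | None = None
    # simulation input
    scenario: SyntheticScenario | None = None
    # thresholds
    min_tx_len: int = 300
    gene_expressed_min: float = 1.0
    expressed_exon_min: float = 0.0
    sweep: tuple[float, ...] = (1.0, 5.0, 10.0)
    folds: tuple[float, ...] = (2.0, 5.0)
    strong_hi: float = 5.0
    strong_lo: float = 1.0
    # output
    out_dir: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.sweep) or self.gene_expressed_min < 0:
            raise ValueError("thresholds must be positive")
        if any(x <= 1 for x in self.folds):
            raise ValueError("dominance/switch folds must exceed 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        scenario = raw.pop("scenario", None)
        if scenario is not None:
            scenario = SyntheticScenario(**scenario)
        for key in ("sweep", "folds"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(scenario=scenario, **raw)


@dataclass
class PipelineResult:
    summary: dict
    outputs: dict[str, Path]
    model: AnnotationModel
    tx_fpkm: ExpressionMatrix
    gene_fpkm: ExpressionMatrix
    calls: list[dom.DominanceCall]
    scans: dict[float, sw.SwitchScanResult]
    pools: list[dom.PoolFractions]
    biotype_summaries: list[bt.BiotypeSummary]
    junction_evidence: list | None = None
    dataset: SyntheticDataset | None = None
    metadata: SampleMetadata | None = None


def _require(path: str | None, name: str) -> Path:
    if path is None:
        raise ValueError(f"missing required input: {name}")
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"{name} not found at {p}")
    return p


def _load_inputs(config: PipelineConfig):
    if config.scenario is not None:
        scenario = dataclasses.replace(config.scenario, seed=config.scenario.seed)
        dataset = simulate_dataset(scenario)
        return (
            dataset.model,
            dataset.counts.tx_fpkm,
            dataset.counts.exons,
            dataset.counts.introns,
            dataset.counts.junctions,
            dataset.metadata,
            dataset,
        )
    model = parse_gtf(_require(config.gtf, "gtf"))
    tx_fpkm = read_expression_matrix(_require(config.tx_fpkm, "tx_fpkm"), level="transcript")
    metadata = read_metadata(config.metadata) if config.metadata else None
    lib = (
        read_library_sizes(config.library_sizes)
        if config.library_sizes
        else pd.Series(1e6, index=tx_fpkm.samples)
    )
    exons = (
        read_count_table(_require(config.exon_counts, "exon_counts"), lib)
        if config.exon_counts
        else None
    )
    introns = (
        read_count_table(_require(config.intron_counts, "intron_counts"), lib)
        if config.intron_counts
        else None
    )
    junctions = (
        read_count_table(_require(config.junction_counts, "junction_counts"), lib)
        if config.junction_counts
        else None
    )
    if metadata is not None:
        meta_samples = set(metadata.sample_ids)
        mat_samples = set(tx_fpkm.samples)
        if meta_samples != mat_samples:
            raise ValueError(
                "sample/metadata mismatch: only in metadata "
                f"{sorted(meta_samples - mat_samples)}, only in matrix "
                f"{sorted(mat_samples - meta_samples)}"
            )
    return model, tx_fpkm, exons, introns, junctions, metadata, None


def _restrict_to_study(
    study: AnnotationModel,
    tx_fpkm: ExpressionMatrix,
    exons: CountTable | None,
    introns: CountTable | None,
):
    tx_keep = [t for t in tx_fpkm.data.index if t in study.transcript_gene]
    tx_fpkm = ExpressionMatrix(
        data=tx_fpkm.data.loc[tx_keep], level="transcript",
        gene_ids=pd.Series({t: study.transcript_gene[t] for t in tx_keep}),
    )

    def restrict(table: CountTable | None) -> CountTable | None:
        if table is None or table.gene_ids is None:
            return table
        keep = table.gene_ids.isin(study.genes).to_numpy()
        return CountTable(
            counts=table.counts.loc[keep],
            lengths=table.lengths.loc[keep],
            library_sizes=table.library_sizes,
            gene_ids=table.gene_ids.loc[keep],
        )

    return tx_fpkm, restrict(exons), restrict(introns)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if math.isfinite(v) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, pd.DataFrame):
        return _jsonify(obj.to_dict())
    if isinstance(obj, pd.Series):
        return _jsonify(obj.to_dict())
    return obj


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full dominant-transcript analysis.

    Returns the in-memory results and, when ``config.out_dir`` is set,
    writes all per-module tables plus ``summary.json`` with stable ordering
    and fixed float formatting so identical configurations reproduce
    byte-identical outputs.
    """
    logging.getLogger("txdominance").setLevel(config.log_level)
    model_full, tx_fpkm, exons, introns, junctions, metadata, dataset = _load_inputs(config)

    study = build_study_set(model_full, min_tx_len=config.min_tx_len)
    tx_fpkm, exons, introns = _restrict_to_study(study, tx_fpkm, exons, introns)

    if exons is not None:
        exon_fpkm = counts_to_fpkm(exons, level="exon")
        gene_fpkm = gene_expression_from_exons(
            exon_fpkm, study, expressed_exon_min=config.expressed_exon_min
        )
    else:
        logger.info("no exon counts supplied; gene FPKM falls back to transcript sums")
        sums = tx_fpkm.data.groupby(tx_fpkm.gene_ids).sum()
        gene_fpkm = ExpressionMatrix(data=sums, level="gene")

    calls = dom.call_major(
        tx_fpkm, gene_fpkm, study, gene_expressed_min=config.gene_expressed_min
    )
    pools = dom.pool_fractions(tx_fpkm, calls, study)
    tpg = dom.transcripts_per_gene_ratio(
        tx_fpkm, gene_fpkm, study, min_fpkm=config.gene_expressed_min
    )
    sweep = dom.threshold_sweep(tx_fpkm, gene_fpkm, study, thresholds=config.sweep)
    recurrence = sw.recurrence_summary(calls, n_samples=len(tx_fpkm.samples))

    scans: dict[float, sw.SwitchScanResult] = {}
    if len(tx_fpkm.samples) >= 2:
        for x in config.folds:
            scans[x] = sw.pairwise_switch_scan(
                tx_fpkm, gene_fpkm, calls, metadata, x,
                strong_hi=config.strong_hi, strong_lo=config.strong_lo,
                gene_expressed_min=config.gene_expressed_min,
            )

    biotype_summaries = bt.major_biotype_summary(calls, study, tx_fpkm)
    ri_positions = bt.retained_intron_position_stats(calls, study, metadata)

    evidence = None
    if junctions is not None:
        evidence = junction_support(junctions, study)

    # ---- summary -----------------------------------------------------------
    n_rec = len(recurrence)
    n_recurrent = sum(r.recurrent for r in recurrence)
    ubiq = [r for r in recurrence if r.ubiquitous]
    summary: dict = {
        "n_genes_study_set": len(study),
        "n_transcripts_study_set": study.n_transcripts,
        "samples": list(tx_fpkm.samples),
        "pool_fractions": {
            p.sample_id: {
                "major": p.fraction_major,
                "twofold": p.fraction_twofold,
                "fivefold": p.fraction_fivefold,
                "noncoding_major": p.fraction_noncoding_major,
            }
            for p in pools
        },
        "transcripts_per_gene": tpg.to_dict(),
        "threshold_sweep": dom.threshold_sweep_frame(sweep).to_dict(orient="records"),
        "recurrence": {
            "n_genes_considered": n_rec,
            "pct_recurrent": 100.0 * n_recurrent / n_rec if n_rec else None,
            "n_ubiquitous": len(ubiq),
            "pct_ubiquitous_recurrent": (
                100.0 * sum(r.recurrent for r in ubiq) / len(ubiq) if ubiq else None
            ),
        },
        "switches": {
            f"fold_{x:g}": {
                "n_events": len(scan.events),
                "n_strong": sum(bool(e.strong) for e in scan.events),
                "n_genes_involved": int(scan.gene_summary.shape[0]),
                "pct_genes_involved": 100.0 * scan.gene_summary.shape[0] / len(study)
                if len(study)
                else None,
            }
            for x, scan in scans.items()
        },
        "biotypes": {
            s.sample_id: {
                "noncoding_major_gene_count": s.noncoding_major_gene_count,
                "mass_fractions": s.mass_fractions,
            }
            for s in biotype_summaries
        },
        "retained_intron_position_median": ri_positions.median
        if not math.isnan(ri_positions.median)
        else None,
    }
    if evidence is not None:
        with_call = {(c.gene_id, c.sample_id): c.major for c in calls}
        pairs = [
            (e.evidence_major, with_call.get((e.gene_id, e.sample_id)))
            for e in evidence
            if e.evidence_major is not None
            and (e.gene_id, e.sample_id) in with_call
        ]
        summary["junction_validation"] = {
            "n_compared": len(pairs),
            "pct_agreement": (
                100.0 * sum(a == b for a, b in pairs) / len(pairs) if pairs else None
            ),
        }

    outputs: dict[str, Path] = {}
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_study_set_report(study, out / "study_set.tsv")
        outputs["study_set"] = out / "study_set.tsv"
        write_introns_bed(study, out / "introns.bed")
        outputs["introns_bed"] = out / "introns.bed"
        dom.calls_to_frame(calls).to_csv(
            out / "dominance_calls.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
        )
        outputs["dominance_calls"] = out / "dominance_calls.tsv"
        dom.threshold_sweep_frame(sweep).to_csv(
            out / "threshold_summary.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
        )
        outputs["threshold_summary"] = out / "threshold_summary.tsv"
        with open(out / "pool_fractions.json", "w") as fh:
            json.dump(_jsonify(summary["pool_fractions"]), fh, indent=1, sort_keys=True)
            fh.write("\n")
        outputs["pool_fractions"] = out / "pool_fractions.json"
        pd.DataFrame(
            [dataclasses.asdict(r) for r in recurrence]
        ).to_csv(out / "recurrence.tsv", sep="\t", index=False)
        outputs["recurrence"] = out / "recurrence.tsv"
        for x, scan in scans.items():
            p = out / f"switch_events_x{x:g}.tsv"
            sw.events_to_frame(scan.events).to_csv(
                p, sep="\t", index=False, float_format=_FLOAT_FMT
            )
            outputs[f"switch_events_x{x:g}"] = p
        bt.biotype_summary_frame(biotype_summaries).to_csv(
            out / "biotype_summary.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
        )
        outputs["biotype_summary"] = out / "biotype_summary.tsv"
        ri_positions.positions.to_csv(
            out / "retained_intron_positions.tsv", sep="\t", index=False,
            float_format=_FLOAT_FMT,
        )
        outputs["retained_intron_positions"] = out / "retained_intron_positions.tsv"
        if evidence is not None:
            pd.DataFrame(
                [
                    {
                        "gene_id": e.gene_id,
                        "sample_id": e.sample_id,
                        "evidence_major": e.evidence_major or "",
                        "tie": e.tie,
                    }
                    for e in evidence
                ]
            ).to_csv(out / "junction_evidence.tsv", sep="\t", index=False)
            outputs["junction_evidence"] = out / "junction_evidence.tsv"
        if dataset is not None:
            outputs.update(write_dataset(dataset, out / "data"))
        with open(out / "summary.json", "w") as fh:
            json.dump(_jsonify(summary), fh, indent=1, sort_keys=True)
            fh.write("\n")
        outputs["summary"] = out / "summary.json"

    return PipelineResult(
        summary=summary,
        outputs=outputs,
        model=study,
        tx_fpkm=tx_fpkm,
        gene_fpkm=gene_fpkm,
        calls=calls,
        scans=scans,
        pools=pools,
        biotype_summaries=biotype_summaries,
        junction_evidence=evidence,
        dataset=dataset,
        metadata=metadata,
    )


def validate_against_truth(result: PipelineResult, dataset: SyntheticDataset | None = None) -> dict:
    """Recovery metrics of a synthetic run against its ground truth.

    Reports major-call accuracy, two-fold dominance confusion counts,
    strong-switch recall/precision against the planted registry, and
    junction-evidence vs quantification agreement.
    """
    dataset = dataset or result.dataset
    if dataset is None:
        raise ValueError("no ground truth available: run was not simulated")
    truth = dataset.truth

    n_correct = n_total = 0
    confusion = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
    for c in result.calls:
        true_major = truth.true_major.at[c.gene_id, c.sample_id]
        n_total += 1
        n_correct += c.major == true_major
        true_dom = truth.true_fold.at[c.gene_id, c.sample_id] >= 2
        called_dom = c.fold_ratio >= 2
        key = (
            "tp" if true_dom and called_dom
            else "fp" if called_dom
            else "fn" if true_dom
            else "tn"
        )
        confusion[key] += 1

    metrics: dict = {
        "major_call_accuracy": n_correct / n_total if n_total else None,
        "n_calls": n_total,
        "twofold_confusion": confusion,
    }

    planted = {
        (p.gene_id, frozenset((p.sample_a, p.sample_b)), frozenset((p.tx_a, p.tx_b)))
        for p in truth.planted_switches
    }
    strong_found = set()
    for scan in result.scans.values():
        for e in scan.events:
            if e.strong:
                strong_found.add(
                    (e.gene_id, frozenset((e.sample_a, e.sample_b)), frozenset((e.tx_a, e.tx_b)))
                )
    if planted:
        metrics["switch_recall"] = len(planted & strong_found) / len(planted)
        metrics["switch_precision"] = (
            len(planted & strong_found) / len(strong_found) if strong_found else None
        )
        metrics["n_spurious_strong"] = len(strong_found - planted)
    if result.junction_evidence is not None:
        with_call = {(c.gene_id, c.sample_id): c.major for c in result.calls}
        pairs = [
            (e.evidence_major, with_call.get((e.gene_id, e.sample_id)))
            for e in result.junction_evidence
            if e.evidence_major is not None and (e.gene_id, e.sample_id) in with_call
        ]
        metrics["junction_agreement"] = (
            sum(a == b for a, b in pairs) / len(pairs) if pairs else None
        )
        metrics["n_junction_compared"] = len(pairs)
    return metrics
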