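"""Synthetic annotations, abundances and counts with known ground truth.

The generator emulates the statistical structure the dominance analysis
assumes: multi-transcript genes built on a shared exon scaffold (each
transcript skips one distinct internal exon, giving it a private splice
junction), per-gene transcript relative abundances under a *dominant*
scenario (one designated major holding mass p, the rest splitting 1-p
evenly) or a *uniform* scenario (symmetric Dirichlet draws per gene and
sample), log-normal gene expression, Poisson count noise at a configurable
read depth, optional retained-intron / processed-transcript majors, and
planted strong switch events.

The count model is feature-level Poisson on expected coverage — a
deliberate simplification of read-level simulation that is sufficient for
every statistic the pipeline computes. In noiseless mode counts equal their
expectations exactly, so FPKM conversion inverts the generator by
construction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import (
    AnnotationModel,
    GeneRecord,
    GenomicInterval,
    TranscriptRecord,
    derive_introns,
)
from .gtf import write_gtf
from .quantify import (
    CountTable,
    ExpressionMatrix,
    SampleMetadata,
    counts_to_fpkm,
    junction_id,
)

logger = logging.getLogger(__name__)


@dataclass
class SyntheticScenario:
    """Generator configuration; the defaults are the study conditions.

    ``scenario`` selects the abundance regime: ``dominant`` gives the
    designated major transcript mass ``dominant_proportion`` (remainder
    split evenly), ``uniform`` draws symmetric Dirichlet(``dirichlet_alpha``)
    fractions per gene and sample. Gene totals are log-normal
    (``gene_mean_log_fpkm``/``gene_sd_log_fpkm`` on the natural-log scale,
    defaults giving a median near 20 FPKM) with a mild per-sample factor.
    """

    n_genes: int = 200
    transcripts_per_gene: int | tuple[int, int] = 4
    scenario: str = "dominant"
    dominant_proportion: float = 0.8
    dirichlet_alpha: float = 10.0
    gene_mean_log_fpkm: float = 3.0
    gene_sd_log_fpkm: float = 1.0
    sample_sd_log_fpkm: float = 0.25
    library_size: int = 5_000_000
    n_samples: int = 4
    conditions: list[str] | None = None
    compartments: list[str] | None = None
    fraction_noncoding_major: float = 0.0
    processed_transcript_share: float = 0.5
    retained_intron_target_position: float = 0.8
    extra_exons: int = 6
    unique_junction_prob: float = 1.0
    planted_switches: int = 0
    switch_high_fraction: float = 0.8
    switch_low_fraction: float = 0.02
    switch_gene_fpkm: float = 20.0
    junction_read_span: int = 75
    intron_leakage: float = 0.01
    nucleus_leakage_factor: float = 2.0
    noiseless: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("dominant", "uniform"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.scenario == "dominant" and not (0.5 < self.dominant_proportion < 1):
            raise ValueError("dominant_proportion must lie in (0.5, 1)")
        if self.dirichlet_alpha <= 0:
            raise ValueError("dirichlet_alpha must be positive")
        if self.n_samples < 1 or self.n_genes < 1:
            raise ValueError("need at least one sample and one gene")
        if self.conditions is not None and len(self.conditions) != self.n_samples:
            raise ValueError("conditions must match n_samples")
        if self.compartments is not None and len(self.compartments) != self.n_samples:
            raise ValueError("compartments must match n_samples")

    def sample_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_samples)]


@dataclass
class PlantedSwitch:
    gene_id: str
    tx_a: str
    tx_b: str
    sample_a: str
    sample_b: str


@dataclass
class TruthRegistry:
    """Ground truth emitted alongside the data, consistent by construction."""

    true_major: pd.DataFrame       # gene x sample, transcript ids
    true_fold: pd.DataFrame        # gene x sample, true fold ratios
    designated_major: dict[str, str]
    planted_switches: list[PlantedSwitch] = field(default_factory=list)


@dataclass
class CountsBundle:
    exons: CountTable
    introns: CountTable | None
    junctions: CountTable
    transcripts: CountTable
    tx_fpkm: ExpressionMatrix          # measured (FPKM from transcript counts)


@dataclass
class SyntheticDataset:
    scenario: SyntheticScenario
    model: AnnotationModel
    metadata: SampleMetadata
    fractions: pd.DataFrame            # transcript x sample true relative abundance
    gene_totals: pd.DataFrame          # gene x sample true gene FPKM
    tx_fpkm_true: ExpressionMatrix
    counts: CountsBundle
    truth: TruthRegistry


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _resolve_k(scenario: SyntheticScenario, rng: np.random.Generator) -> int:
    k = scenario.transcripts_per_gene
    if isinstance(k, int):
        return k
    lo, hi = k
    return int(rng.integers(lo, hi + 1))


def _nearest_intron_to(
    intron_spans: list[tuple[int, int]],
    span: tuple[int, int],
    strand: str,
    target: float,
) -> int:
    """Index of the intron whose strand-aware midpoint fraction is nearest target."""
    s0, e0 = span
    length = e0 - s0
    best, best_d = 0, float("inf")
    for i, (s, e) in enumerate(intron_spans):
        p = ((s + e) / 2.0 - s0) / length
        if strand == "-":
            p = 1.0 - p
        d = abs(p - target)
        if d < best_d:
            best, best_d = i, d
    return best


def simulate_annotation(
    scenario: SyntheticScenario, rng: np.random.Generator
) -> AnnotationModel:
    """Generate a GENCODE-like gene model with known structure.

    Each gene has K transcripts on a scaffold of K+2 exons; transcript k
    skips internal exon k+1, so with ``unique_junction_prob`` = 1 every
    transcript owns a private skip junction and the gene is fully
    identifiable. A ``fraction_noncoding_major`` share of genes replaces the
    transcript designated to be major with a retained-intron variant (one
    intron, chosen near ``retained_intron_target_position`` of the span,
    merged into the exon chain; no CDS) or a processed-transcript variant
    (same chain, no CDS). Coding transcripts carry the internal exons of
    their chain as CDS. Every transcript is at least 300 nt by construction.
    """
    genes: dict[str, GeneRecord] = {}
    designated: dict[str, str] = {}
    cursor = 10_000
    chrom = "chr1"
    for i in range(scenario.n_genes):
        gene_id = f"G{i + 1:05d}"
        K = _resolve_k(scenario, rng)
        if K < 1:
            raise ValueError("transcripts_per_gene must be >= 1")
        # K skippable internal exons plus flanks, plus constitutive extras so
        # the intron grid is fine enough to place retained introns on target
        E = (K + 2 if K > 1 else 3) + max(scenario.extra_exons, 0)
        if K > 1 and E - 2 < K:
            raise ValueError(
                f"cannot give {K} transcripts distinct skip exons with {E} exons"
            )
        exon_lens = rng.integers(100, 301, E)
        intron_lens = rng.integers(200, 501, E - 1)
        strand = "+" if rng.random() < 0.5 else "-"
        starts = np.zeros(E, dtype=int)
        pos = cursor
        exons: list[tuple[int, int]] = []
        introns: list[tuple[int, int]] = []
        for j in range(E):
            starts[j] = pos
            exons.append((pos, pos + int(exon_lens[j])))
            pos += int(exon_lens[j])
            if j < E - 1:
                introns.append((pos, pos + int(intron_lens[j])))
                pos += int(intron_lens[j])
        span = (exons[0][0], exons[-1][1])
        cursor = pos + 10_000

        # chain (exon indices) per transcript
        chains: list[list[int]] = []
        if K == 1:
            chains.append(list(range(E)))
        else:
            for k in range(K):
                skip = k + 1
                if k > 0 and rng.random() > scenario.unique_junction_prob:
                    skip = 1  # collide with transcript 0's chain: no unique junction
                chains.append([j for j in range(E) if j != skip])

        m = int(rng.integers(K))
        noncoding = rng.random() < scenario.fraction_noncoding_major
        processed = rng.random() < scenario.processed_transcript_share

        transcripts: list[TranscriptRecord] = []
        for k in range(K):
            tx_id = f"{gene_id}.t{k + 1:02d}"
            if noncoding and k == m and not processed:
                # retained-intron variant: full chain with one intron merged in
                j = _nearest_intron_to(
                    introns, span, strand, scenario.retained_intron_target_position
                )
                ivs: list[GenomicInterval] = []
                idx = 0
                while idx < E:
                    if idx == j:
                        ivs.append(
                            GenomicInterval(chrom, exons[j][0], exons[j + 1][1], strand)
                        )
                        idx += 2
                    else:
                        ivs.append(GenomicInterval(chrom, *exons[idx], strand))
                        idx += 1
                transcripts.append(
                    TranscriptRecord(tx_id, gene_id, "retained_intron", ivs)
                )
                continue
            chain = chains[k]
            ivs = [GenomicInterval(chrom, *exons[j], strand) for j in chain]
            if noncoding and k == m:
                transcripts.append(
                    TranscriptRecord(tx_id, gene_id, "processed_transcript", ivs)
                )
            else:
                cds = ivs[1:-1]
                transcripts.append(
                    TranscriptRecord(tx_id, gene_id, "protein_coding", ivs, cds=list(cds))
                )
        genes[gene_id] = GeneRecord(gene_id, "protein_coding", chrom, strand, transcripts)
        designated[gene_id] = transcripts[m].transcript_id

    model = AnnotationModel(
        genes=genes,
        provenance={"source": "simulate_annotation", "designated_major": designated},
    )
    return model


# ---------------------------------------------------------------------------
# abundances
# ---------------------------------------------------------------------------

def simulate_abundances(
    scenario: SyntheticScenario,
    model: AnnotationModel,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """True relative abundances (transcript x sample) and gene totals (FPKM)."""
    samples = scenario.sample_ids()
    designated = model.provenance["designated_major"]
    tx_index: list[str] = []
    frac_rows: list[np.ndarray] = []
    for gene in model.genes.values():
        tids = gene.transcript_ids
        K = len(tids)
        if scenario.scenario == "dominant":
            f = np.full(K, (1 - scenario.dominant_proportion) / max(K - 1, 1))
            f[tids.index(designated[gene.gene_id])] = scenario.dominant_proportion
            if K == 1:
                f = np.ones(1)
            block = np.tile(f[:, None], (1, len(samples)))
        else:
            if K == 1:
                block = np.ones((1, len(samples)))
            else:
                block = rng.dirichlet(
                    np.full(K, scenario.dirichlet_alpha), size=len(samples)
                ).T
        tx_index.extend(tids)
        frac_rows.append(block)
    fractions = pd.DataFrame(
        np.vstack(frac_rows), index=tx_index, columns=samples
    )
    base = np.exp(
        rng.normal(scenario.gene_mean_log_fpkm, scenario.gene_sd_log_fpkm, len(model))
    )
    factors = np.exp(
        rng.normal(0.0, scenario.sample_sd_log_fpkm, (len(model), len(samples)))
    )
    gene_totals = pd.DataFrame(
        base[:, None] * factors, index=list(model.genes), columns=samples
    )
    return fractions, gene_totals


def plant_switches(
    fractions: pd.DataFrame,
    gene_totals: pd.DataFrame,
    model: AnnotationModel,
    n_events: int,
    rng: np.random.Generator,
    scenario: SyntheticScenario,
) -> list[PlantedSwitch]:
    """Plant strong switch events by exchanging fractions between two samples.

    For each event a gene whose designated major is coding gets fractions
    (high, low) for the pair (designated major, another coding transcript)
    in one sample and (low, high) in another, with the gene total pinned to
    ``switch_gene_fpkm`` in *every* sample so the strong-switch FPKM
    conditions (high * total >= 5, low * total < 1) hold by construction in
    the planted pair while the untouched samples keep a dominant pattern
    whose minors sit at or above 1 FPKM — planting therefore creates no
    strong events outside the registry. Modifies ``fractions`` and
    ``gene_totals`` in place and returns the registry.
    """
    if n_events == 0:
        return []
    hi, lo, total = (
        scenario.switch_high_fraction,
        scenario.switch_low_fraction,
        scenario.switch_gene_fpkm,
    )
    if hi * total < 5 or lo * total >= 1:
        raise ValueError(
            "switch_high_fraction/switch_low_fraction/switch_gene_fpkm do not "
            "satisfy the strong-switch FPKM conditions"
        )
    samples = list(fractions.columns)
    if len(samples) < 2:
        raise ValueError("planting switches requires at least two samples")
    designated = model.provenance["designated_major"]
    eligible = [
        g.gene_id
        for g in model.genes.values()
        if sum(t.is_coding for t in g.transcripts) >= 2
        and g.transcript(designated[g.gene_id]).is_coding
    ]
    if len(eligible) < n_events:
        raise ValueError(
            f"only {len(eligible)} eligible genes (>= 2 coding transcripts and "
            f"a coding designated major); cannot plant {n_events} switches"
        )
    p = scenario.dominant_proportion
    chosen = rng.choice(len(eligible), size=n_events, replace=False)
    registry: list[PlantedSwitch] = []
    for gi in chosen:
        gene = model.genes[eligible[int(gi)]]
        tx_a = designated[gene.gene_id]
        others = sorted(
            t.transcript_id
            for t in gene.transcripts
            if t.is_coding and t.transcript_id != tx_a
        )
        tx_b = others[int(rng.integers(len(others)))]
        s_pos = rng.choice(len(samples), size=2, replace=False)
        s_a, s_b = samples[int(s_pos[0])], samples[int(s_pos[1])]
        tids = gene.transcript_ids
        K = len(tids)
        minor = (1.0 - p) / (K - 1)
        if minor * total < 1.0:
            raise ValueError(
                "dominant-pattern minors of a planted gene would drop below "
                "1 FPKM, creating unregistered strong switches; raise "
                "switch_gene_fpkm or lower transcripts_per_gene"
            )
        # untouched samples: dominant pattern anchored on tx_a
        base = pd.Series(minor, index=tids)
        base[tx_a] = p
        for s in samples:
            fractions.loc[tids, s] = base
        rest = (1.0 - hi - lo) / (K - 2) if K > 2 else 0.0
        f_a = pd.Series(rest, index=tids)
        f_a[tx_a], f_a[tx_b] = hi, lo
        if K == 2:
            f_a[tx_a] = 1.0 - lo
        f_b = f_a.copy()
        f_b[tx_a], f_b[tx_b] = f_a[tx_b], f_a[tx_a]
        fractions.loc[tids, s_a] = f_a
        fractions.loc[tids, s_b] = f_b
        gene_totals.loc[gene.gene_id, :] = total
        registry.append(PlantedSwitch(gene.gene_id, tx_a, tx_b, s_a, s_b))
    return registry


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _exonic_bins(gene: GeneRecord) -> list[tuple[int, int, list[str]]]:
    """Disjoint exonic bins with their covering transcripts (DEXSeq-style)."""
    points = sorted(
        {e.start for t in gene.transcripts for e in t.exons}
        | {e.end for t in gene.transcripts for e in t.exons}
    )
    bins = []
    for s, e in zip(points, points[1:]):
        covering = [
            t.transcript_id
            for t in gene.transcripts
            if any(x.start <= s and e <= x.end for x in t.exons)
        ]
        if covering:
            bins.append((s, e, covering))
    return bins


def _draw(expected: np.ndarray, rng: np.random.Generator, noiseless: bool) -> np.ndarray:
    return expected if noiseless else rng.poisson(expected).astype(float)


def simulate_counts(
    model: AnnotationModel,
    fractions: pd.DataFrame,
    gene_totals: pd.DataFrame,
    scenario: SyntheticScenario,
    rng: np.random.Generator,
    metadata: SampleMetadata | None = None,
    noiseless: bool | None = None,
) -> CountsBundle:
    """Exon/intron/junction/transcript counts from true abundances.

    Expected count per feature = (sum over transcripts carrying the feature
    of transcript FPKM) * feature length * library size / 1e9; junctions use
    the configured read span as their effective length. Intron expectations
    model splicing leakage: ``intron_leakage`` of the gene total, scaled by
    ``nucleus_leakage_factor`` in nuclear samples. Counts are
    Poisson-distributed, or exactly the expectation in noiseless mode.
    """
    if noiseless is None:
        noiseless = scenario.noiseless
    samples = list(fractions.columns)
    L = float(scenario.library_size)
    lib = pd.Series(L, index=samples)

    tx2gene = model.transcript_gene
    gene_of_tx = pd.Series({t: tx2gene[t] for t in fractions.index})
    tx_fpkm_true = fractions.mul(
        gene_totals.loc[gene_of_tx.to_numpy()].to_numpy(), axis=0
    )
    tx_arr = tx_fpkm_true.to_numpy()
    tx_row = {t: i for i, t in enumerate(fractions.index)}
    gt_arr = gene_totals.to_numpy()
    gene_row = {g: i for i, g in enumerate(gene_totals.index)}

    leak_factor = np.array(
        [
            scenario.nucleus_leakage_factor
            if metadata is not None and metadata.compartment_of(s) == "nucleus"
            else 1.0
            for s in samples
        ]
    )

    exon_ids, exon_lens, exon_genes, exon_expected = [], [], [], []
    intron_ids, intron_lens, intron_genes, intron_expected = [], [], [], []
    junc_ids, junc_genes, junc_expected = [], [], []
    scale = L / 1e9
    for gene in model.genes.values():
        gid = gene.gene_id
        for s, e, covering in _exonic_bins(gene):
            exon_ids.append(f"{gid}:{s}-{e}")
            exon_lens.append(e - s)
            exon_genes.append(gid)
            exon_expected.append(
                tx_arr[[tx_row[t] for t in covering]].sum(axis=0) * (e - s) * scale
            )
        for intron in derive_introns(gene):
            iv = intron.interval
            intron_ids.append(f"{gid}:{iv.start}-{iv.end}")
            intron_lens.append(iv.length)
            intron_genes.append(gid)
            intron_expected.append(
                gt_arr[gene_row[gid]]
                * scenario.intron_leakage
                * leak_factor
                * iv.length
                * scale
            )
        junc_to_tx: dict[str, list[str]] = {}
        for t in gene.transcripts:
            for j in t.junctions:
                junc_to_tx.setdefault(junction_id(j), []).append(t.transcript_id)
        for jid, tids in junc_to_tx.items():
            junc_ids.append(jid)
            junc_genes.append(gid)
            junc_expected.append(
                tx_arr[[tx_row[t] for t in tids]].sum(axis=0)
                * scenario.junction_read_span
                * scale
            )

    def table(ids, lens, genes_, expected) -> CountTable:
        exp = np.vstack(expected) if expected else np.zeros((0, len(samples)))
        return CountTable(
            counts=pd.DataFrame(_draw(exp, rng, noiseless), index=ids, columns=samples),
            lengths=pd.Series(lens, index=ids, dtype=float),
            library_sizes=lib.copy(),
            gene_ids=pd.Series(genes_, index=ids),
        )

    exons = table(exon_ids, exon_lens, exon_genes, exon_expected)
    introns = (
        table(intron_ids, intron_lens, intron_genes, intron_expected)
        if intron_ids
        else None
    )
    junc_lens = [scenario.junction_read_span] * len(junc_ids)
    junctions = table(junc_ids, junc_lens, junc_genes, junc_expected)

    tx_lengths = pd.Series(
        {t.transcript_id: float(t.length) for t in model.transcripts()}
    ).reindex(fractions.index)
    tx_expected = tx_fpkm_true.to_numpy() * tx_lengths.to_numpy()[:, None] * scale
    transcripts = CountTable(
        counts=pd.DataFrame(
            _draw(tx_expected, rng, noiseless), index=fractions.index, columns=samples
        ),
        lengths=tx_lengths,
        library_sizes=lib.copy(),
        gene_ids=gene_of_tx,
    )
    tx_fpkm = counts_to_fpkm(transcripts, level="transcript")
    return CountsBundle(
        exons=exons,
        introns=introns,
        junctions=junctions,
        transcripts=transcripts,
        tx_fpkm=tx_fpkm,
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _make_metadata(scenario: SyntheticScenario) -> SampleMetadata:
    samples = scenario.sample_ids()
    conditions = scenario.conditions or [f"cond{i + 1}" for i in range(len(samples))]
    compartments = scenario.compartments or ["whole_cell"] * len(samples)
    reps: dict[str, int] = {}
    rep_ids = []
    for c in conditions:
        reps[c] = reps.get(c, 0) + 1
        rep_ids.append(f"r{reps[c]}")
    return SampleMetadata(
        table=pd.DataFrame(
            {
                "sample_id": samples,
                "condition": conditions,
                "compartment": compartments,
                "replicate": rep_ids,
            }
        )
    )


def _truth_from_fractions(
    fractions: pd.DataFrame, model: AnnotationModel
) -> tuple[pd.DataFrame, pd.DataFrame]:
    majors = {}
    folds = {}
    for gene in model.genes.values():
        tids = sorted(gene.transcript_ids)
        sub = fractions.loc[tids]
        majors[gene.gene_id] = sub.idxmax(axis=0)  # first occurrence = lexicographic
        if len(tids) > 1:
            arr = np.sort(sub.to_numpy(), axis=0)[::-1]
            with np.errstate(divide="ignore", invalid="ignore"):
                fold = np.where(arr[1] > 0, arr[0] / np.where(arr[1] > 0, arr[1], 1), np.inf)
        else:
            fold = np.full(sub.shape[1], np.inf)
        folds[gene.gene_id] = pd.Series(fold, index=fractions.columns)
    true_major = pd.DataFrame(majors).T
    true_fold = pd.DataFrame(folds).T
    true_major.index.name = true_fold.index.name = "gene_id"
    return true_major, true_fold


def simulate_dataset(scenario: SyntheticScenario) -> SyntheticDataset:
    """End-to-end generation: annotation, abundances, planted switches, counts.

    Identical scenarios (including seed) produce identical datasets; all
    randomness flows from ``scenario.seed``.
    """
    rng = np.random.default_rng(scenario.seed)
    model = simulate_annotation(scenario, rng)
    fractions, gene_totals = simulate_abundances(scenario, model, rng)
    planted = plant_switches(
        fractions, gene_totals, model, scenario.planted_switches, rng, scenario
    )
    metadata = _make_metadata(scenario)
    counts = simulate_counts(
        model, fractions, gene_totals, scenario, rng, metadata=metadata
    )
    gene_of_tx = pd.Series(
        {t: model.transcript_gene[t] for t in fractions.index}
    )
    tx_fpkm_true = ExpressionMatrix(
        data=fractions.mul(gene_totals.loc[gene_of_tx.to_numpy()].to_numpy(), axis=0),
        level="transcript",
        gene_ids=gene_of_tx,
    )
    true_major, true_fold = _truth_from_fractions(fractions, model)
    truth = TruthRegistry(
        true_major=true_major,
        true_fold=true_fold,
        designated_major=dict(model.provenance["designated_major"]),
        planted_switches=planted,
    )
    return SyntheticDataset(
        scenario=scenario,
        model=model,
        metadata=metadata,
        fractions=fractions,
        gene_totals=gene_totals,
        tx_fpkm_true=tx_fpkm_true,
        counts=counts,
        truth=truth,
    )


_FLOAT_FMT = "%.6g"


def _write_count_table(table: CountTable, path: Path) -> None:
    df = table.counts.copy()
    df.insert(0, "length", table.lengths)
    if table.gene_ids is not None:
        df.insert(1, "gene_id", table.gene_ids)
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset as GTF + TSV/JSON files consumable by the pipeline."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["gtf"] = outdir / "annotation.gtf"
    write_gtf(dataset.model, paths["gtf"])

    paths["tx_fpkm"] = outdir / "tx_fpkm.tsv"
    df = dataset.counts.tx_fpkm.data.copy()
    df.index.name = "transcript_id"
    df.to_csv(paths["tx_fpkm"], sep="\t", float_format=_FLOAT_FMT)

    paths["tx_fpkm_true"] = outdir / "tx_fpkm_true.tsv"
    df = dataset.tx_fpkm_true.data.copy()
    df.index.name = "transcript_id"
    df.to_csv(paths["tx_fpkm_true"], sep="\t", float_format=_FLOAT_FMT)

    paths["exon_counts"] = outdir / "exon_counts.tsv"
    _write_count_table(dataset.counts.exons, paths["exon_counts"])
    if dataset.counts.introns is not None:
        paths["intron_counts"] = outdir / "intron_counts.tsv"
        _write_count_table(dataset.counts.introns, paths["intron_counts"])
    paths["junction_counts"] = outdir / "junction_counts.tsv"
    _write_count_table(dataset.counts.junctions, paths["junction_counts"])

    paths["library_sizes"] = outdir / "library_sizes.tsv"
    lib = dataset.counts.exons.library_sizes.rename("library_size")
    lib.index.name = "sample_id"
    lib.to_frame().to_csv(paths["library_sizes"], sep="\t", float_format=_FLOAT_FMT)

    paths["metadata"] = outdir / "metadata.tsv"
    dataset.metadata.table.to_csv(paths["metadata"], sep="\t", index=False)

    paths["truth"] = outdir / "truth.json"
    truth = {
        "designated_major": dataset.truth.designated_major,
        "true_major": {
            g: dataset.truth.true_major.loc[g].to_dict()
            for g in dataset.truth.true_major.index
        },
        "planted_switches": [asdict(p) for p in dataset.truth.planted_switches],
        "scenario": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(dataset.scenario).items()
        },
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
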