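"""Cross-sample recurrence of major transcripts and switch-event detection.

A gene undergoes an x-fold switch between transcripts I_k and I_l in samples
S_i and S_j when the expression ratio I_k/I_l is at least x in S_i and at
most 1/x in S_j (with the gene passing the expression gate in both samples).
A switch is *strong* when I_k in S_i and I_l in S_j are each at least 5 FPKM
while the reciprocal transcripts are below 1 FPKM — the regime where the two
samples plausibly produce different proteins.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from itertools import combinations, permutations

import numpy as np
import pandas as pd

from .annotation import AnnotationModel
from .dominance import DominanceCall
from .quantify import ExpressionMatrix, SampleMetadata

logger = logging.getLogger(__name__)


@dataclass
class SwitchEvent:
    gene_id: str
    tx_a: str          # I_k: dominant in sample_a
    tx_b: str          # I_l: dominant in sample_b
    sample_a: str      # S_i
    sample_b: str      # S_j
    x: float
    ratio_a: float     # expression(tx_a)/expression(tx_b) in sample_a
    ratio_b: float     # same ratio in sample_b
    strong: bool | None = None
    expression_dependent: bool | None = None

    def __post_init__(self) -> None:
        if self.tx_a == self.tx_b:
            raise ValueError("switch transcripts must differ")
        if self.sample_a == self.sample_b:
            raise ValueError("switch samples must differ")
        if not (self.ratio_a >= self.x and self.ratio_b <= 1.0 / self.x):
            raise ValueError("ratio conditions violated for declared fold x")


@dataclass
class SwitchProfile:
    """Per-sample log2 expression ratio of a switch's transcript pair."""

    gene_id: str
    tx_a: str
    tx_b: str
    lr: pd.Series  # log2(expression(tx_a)/expression(tx_b)); NaN when undefined


@dataclass
class RecurrenceSummary:
    gene_id: str
    n_samples_expressed: int
    n_distinct_majors: int
    recurrent: bool
    ubiquitous: bool

    def __post_init__(self) -> None:
        if self.recurrent != (self.n_distinct_majors == 1):
            raise ValueError("recurrent flag inconsistent with distinct-major count")


def recurrence_summary(
    calls: list[DominanceCall], n_samples: int
) -> list[RecurrenceSummary]:
    """Same-major recurrence per gene over the samples where it is expressed.

    Genes expressed (that is, with a major call) in fewer than two samples
    are excluded; a gene is recurrent when one transcript is the major in
    every sample where the gene is expressed, and ubiquitous when it is
    expressed in all ``n_samples``.
    """
    majors: dict[str, list[str]] = {}
    for c in calls:
        majors.setdefault(c.gene_id, []).append(c.major)
    out = []
    for gene_id in sorted(majors):
        ms = majors[gene_id]
        if len(ms) < 2:
            continue
        out.append(
            RecurrenceSummary(
                gene_id=gene_id,
                n_samples_expressed=len(ms),
                n_distinct_majors=len(set(ms)),
                recurrent=len(set(ms)) == 1,
                ubiquitous=len(ms) == n_samples,
            )
        )
    return out


def _ratio(num: float, den: float) -> float:
    if den == 0:
        return math.inf if num > 0 else math.nan
    return num / den


def detect_switch_events(
    tx_fpkm: ExpressionMatrix,
    gene_fpkm: ExpressionMatrix,
    calls: list[DominanceCall],
    sample_pair: tuple[str, str],
    x: float,
    exhaustive: bool = False,
    model: AnnotationModel | None = None,
) -> list[SwitchEvent]:
    """Detect x-fold switches between two samples.

    Candidate transcript pairs are the two samples' major transcripts (the
    cases with different majors are where switches live); with
    ``exhaustive=True`` all ordered transcript pairs of each gene are
    scanned instead (requires ``model``). A zero-expression denominator
    makes the ratio +inf, which passes the >= x condition and fails <= 1/x.
    """
    if x <= 1:
        raise ValueError("switch fold must exceed 1")
    s_i, s_j = sample_pair
    if s_i == s_j:
        raise ValueError("sample pair must be two distinct samples")
    data = tx_fpkm.data
    call_map: dict[tuple[str, str], DominanceCall] = {
        (c.gene_id, c.sample_id): c for c in calls
    }
    genes = sorted(
        {c.gene_id for c in calls if c.sample_id == s_i}
        & {c.gene_id for c in calls if c.sample_id == s_j}
    )
    events: list[SwitchEvent] = []
    for gene_id in genes:
        if exhaustive:
            if model is None:
                raise ValueError("exhaustive scanning requires the annotation model")
            tids = [t for t in model.genes[gene_id].transcript_ids if t in data.index]
            pairs = list(permutations(sorted(tids), 2))
        else:
            tx_a = call_map[(gene_id, s_i)].major
            tx_b = call_map[(gene_id, s_j)].major
            if tx_a == tx_b:
                continue
            pairs = [(tx_a, tx_b)]
        for tx_a, tx_b in pairs:
            ra = _ratio(float(data.at[tx_a, s_i]), float(data.at[tx_b, s_i]))
            rb = _ratio(float(data.at[tx_a, s_j]), float(data.at[tx_b, s_j]))
            if math.isnan(ra) or math.isnan(rb):
                continue
            if ra >= x and rb <= 1.0 / x:
                events.append(
                    SwitchEvent(
                        gene_id=gene_id,
                        tx_a=tx_a,
                        tx_b=tx_b,
                        sample_a=s_i,
                        sample_b=s_j,
                        x=x,
                        ratio_a=ra,
                        ratio_b=rb,
                    )
                )
    return events


def pair_mean_abs_gene_diff(
    gene_fpkm: ExpressionMatrix,
    sample_pair: tuple[str, str],
    gene_expressed_min: float = 1.0,
) -> float:
    """Mean |gene FPKM difference| over genes expressed in both samples."""
    s_i, s_j = sample_pair
    a = gene_fpkm.data[s_i]
    b = gene_fpkm.data[s_j]
    both = (a > gene_expressed_min) & (b > gene_expressed_min)
    if not both.any():
        return 0.0
    return float((a[both] - b[both]).abs().mean())


def annotate_switch(
    event: SwitchEvent,
    tx_fpkm: ExpressionMatrix,
    gene_fpkm: ExpressionMatrix,
    strong_hi: float = 5.0,
    strong_lo: float = 1.0,
    gene_expressed_min: float = 1.0,
    mean_abs_diff: float | None = None,
) -> SwitchEvent:
    """Attach strong and expression-dependence flags to a detected switch.

    Strong: tx_a in sample_a and tx_b in sample_b at least ``strong_hi``
    FPKM while tx_a in sample_b and tx_b in sample_a are strictly below
    ``strong_lo``. Expression dependent: the gene's |FPKM difference|
    between the two samples exceeds the mean of that quantity over all genes
    expressed in both (pass ``mean_abs_diff`` to reuse a precomputed mean).
    """
    data = tx_fpkm.data
    a_i = float(data.at[event.tx_a, event.sample_a])
    a_j = float(data.at[event.tx_a, event.sample_b])
    b_i = float(data.at[event.tx_b, event.sample_a])
    b_j = float(data.at[event.tx_b, event.sample_b])
    strong = a_i >= strong_hi and b_j >= strong_hi and a_j < strong_lo and b_i < strong_lo
    if mean_abs_diff is None:
        mean_abs_diff = pair_mean_abs_gene_diff(
            gene_fpkm, (event.sample_a, event.sample_b), gene_expressed_min
        )
    g_i = float(gene_fpkm.data.at[event.gene_id, event.sample_a])
    g_j = float(gene_fpkm.data.at[event.gene_id, event.sample_b])
    dependent = abs(g_i - g_j) > mean_abs_diff
    return replace(event, strong=strong, expression_dependent=dependent)


def switch_profile(
    gene_id: str,
    tx_a: str,
    tx_b: str,
    tx_fpkm: ExpressionMatrix,
    samples: list[str] | None = None,
) -> SwitchProfile:
    """log2 expression-ratio profile of a transcript pair across samples.

    Samples where either transcript is at 0 FPKM get a NaN sentinel.
    """
    samples = samples if samples is not None else tx_fpkm.samples
    a = tx_fpkm.data.loc[tx_a, samples].astype(float)
    b = tx_fpkm.data.loc[tx_b, samples].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        lr = np.log2(a.to_numpy() / b.to_numpy())
    lr = pd.Series(lr, index=samples, name="lr")
    lr[(a == 0) | (b == 0)] = np.nan
    return SwitchProfile(gene_id=gene_id, tx_a=tx_a, tx_b=tx_b, lr=lr)


def coding_change_switches(
    events: list[SwitchEvent], model: AnnotationModel
) -> list[SwitchEvent]:
    """Strong switches whose two transcripts encode different CDS intervals.

    Both transcripts must have an annotated CDS, and their CDS genomic
    interval sets must differ — a conservative proxy for a change in the
    protein sequence (no translation is performed).
    """
    out = []
    for e in events:
        if not e.strong:
            continue
        ta = model.get_transcript(e.tx_a)
        tb = model.get_transcript(e.tx_b)
        if not ta.cds or not tb.cds:
            continue
        if set(ta.cds) != set(tb.cds):
            out.append(e)
    return out


@dataclass
class SwitchScanResult:
    events: list[SwitchEvent]
    gene_summary: pd.DataFrame   # gene_id, in_switch, in_strong_switch
    pair_tallies: pd.DataFrame   # sample_a, sample_b, pair_type, n_events, n_strong


def pairwise_switch_scan(
    tx_fpkm: ExpressionMatrix,
    gene_fpkm: ExpressionMatrix,
    calls: list[DominanceCall],
    metadata: SampleMetadata | None,
    x: float,
    strong_hi: float = 5.0,
    strong_lo: float = 1.0,
    gene_expressed_min: float = 1.0,
) -> SwitchScanResult:
    """Detect and annotate switches over all unordered sample pairs.

    When metadata is supplied, pairs of samples sharing a condition label are
    tallied as replicate pairs, all others as condition pairs — replicate
    pairs of a well-behaved experiment should yield far fewer events.
    """
    samples = tx_fpkm.samples
    if len(samples) < 2:
        raise ValueError("pairwise scan needs at least two samples")
    all_events: list[SwitchEvent] = []
    tallies = []
    for s_i, s_j in combinations(samples, 2):
        events = detect_switch_events(
            tx_fpkm, gene_fpkm, calls, (s_i, s_j), x
        )
        mean_diff = pair_mean_abs_gene_diff(gene_fpkm, (s_i, s_j), gene_expressed_min)
        events = [
            annotate_switch(
                e, tx_fpkm, gene_fpkm, strong_hi, strong_lo,
                gene_expressed_min, mean_abs_diff=mean_diff,
            )
            for e in events
        ]
        all_events.extend(events)
        if metadata is not None:
            pair_type = (
                "replicate"
                if metadata.condition_of(s_i) == metadata.condition_of(s_j)
                else "condition"
            )
        else:
            pair_type = "condition"
        tallies.append(
            {
                "sample_a": s_i,
                "sample_b": s_j,
                "pair_type": pair_type,
                "n_events": len(events),
                "n_strong": sum(bool(e.strong) for e in events),
            }
        )
    in_switch = sorted({e.gene_id for e in all_events})
    in_strong = {e.gene_id for e in all_events if e.strong}
    gene_summary = pd.DataFrame(
        {
            "gene_id": in_switch,
            "in_switch": True,
            "in_strong_switch": [g in in_strong for g in in_switch],
        },
        columns=["gene_id", "in_switch", "in_strong_switch"],
    )
    return SwitchScanResult(
        events=all_events,
        gene_summary=gene_summary,
        pair_tallies=pd.DataFrame(
            tallies, columns=["sample_a", "sample_b", "pair_type", "n_events", "n_strong"]
        ),
    )


def events_to_frame(events: list[SwitchEvent]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "gene_id": e.gene_id,
                "tx_a": e.tx_a,
                "tx_b": e.tx_b,
                "sample_a": e.sample_a,
                "sample_b": e.sample_b,
                "x": e.x,
                "ratio_a": e.ratio_a,
                "ratio_b": e.ratio_b,
                "strong": e.strong,
                "expression_dependent": e.expression_dependent,
            }
            for e in events
        ]
    )
    if df.empty:
        df = pd.DataFrame(
            columns=[
                "gene_id", "tx_a", "tx_b", "sample_a", "sample_b", "x",
                "ratio_a", "ratio_b", "strong", "expression_dependent",
            ]
        )
    return df.sort_values(["gene_id", "sample_a", "sample_b"]).reset_index(drop=True)
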