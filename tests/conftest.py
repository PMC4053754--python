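"""Shared fixtures and builders for the test suite.

Fixtures construct tiny hand-traceable gene models and matrices in memory;
larger inputs come from the synthetic generator at fixed seeds.
"""

from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import settings

from txdominance.annotation import (
    AnnotationModel,
    GeneRecord,
    GenomicInterval,
    TranscriptRecord,
)
from txdominance.quantify import ExpressionMatrix
from txdominance.simulate import SyntheticScenario, simulate_dataset

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


def make_tx(tx_id, gene_id, exons, cds=(), biotype="protein_coding",
            chrom="chr1", strand="+"):
    return TranscriptRecord(
        transcript_id=tx_id,
        gene_id=gene_id,
        biotype=biotype,
        exons=[GenomicInterval(chrom, s, e, strand) for s, e in exons],
        cds=[GenomicInterval(chrom, s, e, strand) for s, e in cds],
    )


def make_gene(gene_id, transcripts, biotype="protein_coding",
              chrom="chr1", strand="+", is_mitochondrial=None):
    return GeneRecord(
        gene_id=gene_id,
        biotype=biotype,
        chrom=chrom,
        strand=strand,
        transcripts=transcripts,
        is_mitochondrial=is_mitochondrial,
    )


def make_model(*genes) -> AnnotationModel:
    return AnnotationModel(genes={g.gene_id: g for g in genes})


def expr(values: dict[str, dict[str, float]], level="transcript",
         gene_ids: dict[str, str] | None = None) -> ExpressionMatrix:
    """Build an ExpressionMatrix from {sample: {feature: value}}."""
    df = pd.DataFrame(values).fillna(0.0)
    gi = pd.Series(gene_ids).reindex(df.index) if gene_ids else None
    return ExpressionMatrix(data=df, level=level, gene_ids=gi)


@pytest.fixture
def two_tx_gene():
    """One gene, two transcripts (3 and 2 exons) sharing first/last exons."""
    t1 = make_tx("t1", "G1", [(100, 200), (300, 400), (500, 600)],
                 cds=[(300, 400)])
    t2 = make_tx("t2", "G1", [(100, 200), (500, 600)])
    return make_gene("G1", [t1, t2])


@pytest.fixture(scope="session")
def dominant_dataset():
    """Noiseless dominant-scenario dataset reused across read-only tests."""
    return simulate_dataset(
        SyntheticScenario(n_genes=60, n_samples=4, noiseless=True, seed=11)
    )


@pytest.fixture(scope="session")
def dominant_study(dominant_dataset):
    from txdominance.annotation import build_study_set

    return build_study_set(dominant_dataset.model)
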