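"""Major/dominant calling and the dominance summary statistics."""

import math

import numpy as np
import pytest

from txdominance.dominance import (
    call_major,
    classify_dominance,
    longest_overlap_stats,
    pool_fractions,
    rank_abundance_profile,
    threshold_sweep,
    transcripts_per_gene_ratio,
    tss_group_dominance,
)
from txdominance.quantify import (
    counts_to_fpkm,
    gene_expression_from_exons,
    relative_abundances,
)

from conftest import expr, make_gene, make_model, make_tx


def three_tx_model():
    return make_model(
        make_gene(
            "G1",
            [
                make_tx("t1", "G1", [(0, 400)]),
                make_tx("t2", "G1", [(0, 300)]),
                make_tx("t3", "G1", [(0, 350)]),
            ],
        )
    )


class TestCallMajor:
    def test_fold_ratio_vs_runner_up(self):
        tx = expr({"s1": {"t1": 10.0, "t2": 4.0, "t3": 1.0}})
        gene = expr({"s1": {"G1": 8.0}}, level="gene")
        (call,) = call_major(tx, gene, three_tx_model())
        assert call.major == "t1" and call.runner_up == "t2"
        assert call.fold_ratio == pytest.approx(2.5)

    def test_single_transcript_infinite_fold(self):
        m = make_model(make_gene("G1", [make_tx("t1", "G1", [(0, 400)])]))
        tx = expr({"s1": {"t1": 7.0}})
        gene = expr({"s1": {"G1": 7.0}}, level="gene")
        (call,) = call_major(tx, gene, m)
        assert call.runner_up is None and call.fold_ratio == math.inf

    def test_tie_lexicographic_and_flagged(self):
        tx = expr({"s1": {"t1": 5.0, "t2": 5.0, "t3": 0.0}})
        gene = expr({"s1": {"G1": 5.0}}, level="gene")
        (call,) = call_major(tx, gene, three_tx_model())
        assert call.major == "t1" and call.tie and call.fold_ratio == 1.0

    def test_gene_gate_excludes_low_expression(self):
        tx = expr({"s1": {"t1": 10.0, "t2": 4.0, "t3": 1.0}})
        gene = expr({"s1": {"G1": 0.5}}, level="gene")
        assert call_major(tx, gene, three_tx_model()) == []

    def test_expressed_gene_with_zero_transcripts_no_call(self, caplog):
        tx = expr({"s1": {"t1": 0.0, "t2": 0.0, "t3": 0.0}})
        gene = expr({"s1": {"G1": 3.0}}, level="gene")
        with caplog.at_level("WARNING"):
            assert call_major(tx, gene, three_tx_model()) == []
        assert any("no call" in r.message for r in caplog.records)


class TestClassifyDominance:
    def test_threshold_comparisons(self):
        tx = expr({"s1": {"t1": 10.0, "t2": 4.0, "t3": 1.0}})
        gene = expr({"s1": {"G1": 8.0}}, level="gene")
        (call,) = call_major(tx, gene, three_tx_model())
        assert classify_dominance(call, 2) and not classify_dominance(call, 5)

    def test_infinite_fold_dominant_at_any_x(self):
        m = make_model(make_gene("G1", [make_tx("t1", "G1", [(0, 400)])]))
        (call,) = call_major(
            expr({"s1": {"t1": 7.0}}), expr({"s1": {"G1": 7.0}}, level="gene"), m
        )
        assert classify_dominance(call, 2) and classify_dominance(call, 5)

    def test_exact_tie_never_dominant(self):
        tx = expr({"s1": {"t1": 5.0, "t2": 5.0, "t3": 0.0}})
        gene = expr({"s1": {"G1": 5.0}}, level="gene")
        (call,) = call_major(tx, gene, three_tx_model())
        for x in (1.0001, 2, 5, 100):
            assert not classify_dominance(call, x)


class TestPoolFractions:
    def _two_gene_model(self, mito=False):
        return make_model(
            make_gene(
                "G1",
                [make_tx("a1", "G1", [(0, 400)]), make_tx("a2", "G1", [(0, 300)])],
            ),
            make_gene(
                "G2",
                [make_tx("b1", "G2", [(1000, 1400)]), make_tx("b2", "G2", [(1000, 1300)])],
            ),
            *(
                [make_gene(
                    "GM",
                    [make_tx("m1", "GM", [(0, 400)], chrom="MT")],
                    chrom="MT",
                )]
                if mito
                else []
            ),
        )

    def test_hand_summed_fraction(self):
        tx = expr({"s1": {"a1": 10.0, "a2": 2.0, "b1": 6.0, "b2": 2.0}})
        gene = expr({"s1": {"G1": 8.0, "G2": 5.0}}, level="gene")
        model = self._two_gene_model()
        calls = call_major(tx, gene, model)
        (pf,) = pool_fractions(tx, calls, model)
        assert pf.fraction_major == pytest.approx(16 / 20)

    def test_single_transcript_genes_fraction_one(self):
        m = make_model(
            make_gene("G1", [make_tx("a1", "G1", [(0, 400)])]),
            make_gene("G2", [make_tx("b1", "G2", [(1000, 1400)])]),
        )
        tx = expr({"s1": {"a1": 9.0, "b1": 3.0}})
        gene = expr({"s1": {"G1": 9.0, "G2": 3.0}}, level="gene")
        (pf,) = pool_fractions(tx, call_major(tx, gene, m), m)
        assert pf.fraction_major == pytest.approx(1.0)

    def test_mitochondrial_gene_excluded(self):
        tx_plain = expr({"s1": {"a1": 10.0, "a2": 2.0, "b1": 6.0, "b2": 2.0}})
        gene_plain = expr({"s1": {"G1": 8.0, "G2": 5.0}}, level="gene")
        m_plain = self._two_gene_model()
        (pf_plain,) = pool_fractions(
            tx_plain, call_major(tx_plain, gene_plain, m_plain), m_plain
        )
        tx = expr({"s1": {"a1": 10.0, "a2": 2.0, "b1": 6.0, "b2": 2.0, "m1": 5000.0}})
        gene = expr({"s1": {"G1": 8.0, "G2": 5.0, "GM": 5000.0}}, level="gene")
        m = self._two_gene_model(mito=True)
        (pf,) = pool_fractions(tx, call_major(tx, gene, m), m)
        assert pf.fraction_major == pytest.approx(pf_plain.fraction_major)

    def test_ordering_invariant_on_synthetic(self, dominant_dataset, dominant_study):
        ds = dominant_dataset
        gene = gene_expression_from_exons(
            counts_to_fpkm(ds.counts.exons), dominant_study
        )
        calls = call_major(ds.counts.tx_fpkm, gene, dominant_study)
        for pf in pool_fractions(ds.counts.tx_fpkm, calls, dominant_study):
            assert 0 <= pf.fraction_fivefold <= pf.fraction_twofold
            assert pf.fraction_twofold <= pf.fraction_major <= 1


class TestTranscriptsPerGene:
    def test_hand_count(self):
        m = three_tx_model()
        tx = expr({"s1": {"t1": 3.0, "t2": 2.0, "t3": 1.5}})
        gene = expr({"s1": {"G1": 4.0, "G2": 2.0}}, level="gene")
        assert transcripts_per_gene_ratio(tx, gene, m)["s1"] == pytest.approx(1.5)

    def test_floor_and_identity(self):
        m = three_tx_model()
        gene = expr({"s1": {"G1": 4.0, "G2": 2.0}}, level="gene")
        assert transcripts_per_gene_ratio(
            expr({"s1": {"t1": 0.5, "t2": 0.2, "t3": 0.1}}), gene, m
        )["s1"] == 0.0
        assert transcripts_per_gene_ratio(
            expr({"s1": {"t1": 3.0, "t2": 0.2, "t3": 0.1}}),
            expr({"s1": {"G1": 4.0}}, level="gene"), m,
        )["s1"] == 1.0

    def test_no_expressed_genes_is_nan(self, caplog):
        m = three_tx_model()
        with caplog.at_level("WARNING"):
            r = transcripts_per_gene_ratio(
                expr({"s1": {"t1": 3.0, "t2": 0.0, "t3": 0.0}}),
                expr({"s1": {"G1": 0.2}}, level="gene"), m,
            )
        assert math.isnan(r["s1"])


class TestThresholdSweep:
    def test_expressed_counts_per_threshold(self):
        m = make_model(
            *[
                make_gene(f"G{i}", [make_tx(f"G{i}.t", f"G{i}", [(i * 1000, i * 1000 + 400)])])
                for i in (1, 2, 3)
            ]
        )
        tx = expr({"s1": {"G1.t": 0.5, "G2.t": 3.0, "G3.t": 8.0}})
        gene = expr({"s1": {"G1": 0.5, "G2": 3.0, "G3": 8.0}}, level="gene")
        rows = threshold_sweep(tx, gene, m, thresholds=(1.0, 5.0))
        assert [r.n_expressed_genes for r in rows] == [2, 1]
        assert rows[0].pct_of_study_set == pytest.approx(100 * 2 / 3)

    def test_threshold_above_everything_gives_zeros(self):
        m = three_tx_model()
        tx = expr({"s1": {"t1": 3.0, "t2": 1.0, "t3": 0.5}})
        gene = expr({"s1": {"G1": 4.0}}, level="gene")
        (row,) = threshold_sweep(tx, gene, m, thresholds=(100.0,))
        assert row.n_expressed_genes == row.n_twofold == row.n_fivefold == 0

    def test_nesting_on_synthetic(self, dominant_dataset, dominant_study):
        ds = dominant_dataset
        gene = gene_expression_from_exons(counts_to_fpkm(ds.counts.exons), dominant_study)
        for row in threshold_sweep(ds.counts.tx_fpkm, gene, dominant_study):
            assert row.n_fivefold <= row.n_twofold <= row.n_expressed_genes

    def test_unsorted_thresholds_rejected(self):
        m = three_tx_model()
        tx = expr({"s1": {"t1": 3.0, "t2": 1.0, "t3": 0.5}})
        gene = expr({"s1": {"G1": 4.0}}, level="gene")
        with pytest.raises(ValueError):
            threshold_sweep(tx, gene, m, thresholds=(5.0, 1.0))


class TestRankAbundanceProfile:
    def test_constant_fractions(self):
        m = make_model(
            make_gene("G1", [make_tx("t1", "G1", [(0, 400)]), make_tx("t2", "G1", [(0, 300)])]),
            make_gene("G2", [make_tx("u1", "G2", [(1000, 1400)]), make_tx("u2", "G2", [(1000, 1300)])]),
        )
        tx = expr({"s1": {"t1": 8.0, "t2": 2.0, "u1": 4.0, "u2": 1.0}})
        prof = rank_abundance_profile(relative_abundances(tx, m), m, max_rank=2)
        assert prof.at[1, "median"] == pytest.approx(0.8)
        assert prof.at[2, "median"] == pytest.approx(0.2)

    def test_single_transcript_rank_one_is_one(self):
        m = make_model(make_gene("G1", [make_tx("t1", "G1", [(0, 400)])]))
        tx = expr({"s1": {"t1": 5.0}})
        prof = rank_abundance_profile(relative_abundances(tx, m), m, max_rank=2)
        assert prof.at[1, "median"] == 1.0 and prof.at[2, "n"] == 0

    def test_uniform_simplex_matches_monte_carlo_oracle(self):
        """Flat Dirichlet fractions: rank medians match a direct oracle."""
        rng = np.random.default_rng(31)
        n = 2000
        genes, tx_rows = [], {}
        vals = {}
        draws = rng.dirichlet(np.ones(4), size=n)
        for i in range(n):
            gid = f"G{i:04d}"
            genes.append(
                make_gene(gid, [make_tx(f"{gid}.t{j}", gid, [(0, 400)]) for j in range(4)])
            )
            for j in range(4):
                vals[f"{gid}.t{j}"] = draws[i, j]
        m = make_model(*genes)
        tx = expr({"s1": vals})
        prof = rank_abundance_profile(relative_abundances(tx, m), m, max_rank=4)
        oracle = np.sort(rng.dirichlet(np.ones(4), size=200_000), axis=1)[:, ::-1]
        for r in range(4):
            assert prof.at[r + 1, "median"] == pytest.approx(
                np.median(oracle[:, r]), abs=0.02
            )


class TestTssGroupDominance:
    def _gene(self):
        return make_model(
            make_gene(
                "G1",
                [
                    make_tx("t1", "G1", [(0, 100), (200, 300)]),
                    make_tx("t2", "G1", [(0, 150), (200, 300)]),
                    make_tx("t3", "G1", [(50, 100), (200, 300)]),
                ],
            )
        )

    def test_only_multi_transcript_groups_analysed(self):
        tx = expr({"s1": {"t1": 9.0, "t2": 3.0, "t3": 50.0}})
        df = tss_group_dominance(tx, self._gene(), x=2)
        assert set(df["major"]) == {"t1"}  # t3's singleton group is skipped
        assert df.iloc[0]["fold_ratio"] == pytest.approx(3.0)
        assert bool(df.iloc[0]["dominant"])

    def test_all_singletons_empty(self):
        m = make_model(
            make_gene(
                "G1",
                [
                    make_tx("t1", "G1", [(0, 100), (200, 300)]),
                    make_tx("t2", "G1", [(50, 100), (200, 300)]),
                ],
            )
        )
        tx = expr({"s1": {"t1": 9.0, "t2": 3.0}})
        assert tss_group_dominance(tx, m, x=2).empty


class TestLongestOverlap:
    def test_fraction_of_majors_that_are_longest(self):
        genes, vals = [], {}
        # four 2-transcript genes; majors: longest in G1/G2, shorter in G3/G4
        for i, major_is_longest in enumerate([True, True, False, False], 1):
            gid = f"G{i}"
            long_tx = make_tx(f"{gid}.a", gid, [(i * 1000, i * 1000 + 800)],
                              cds=[(i * 1000, i * 1000 + 600)])
            short_tx = make_tx(f"{gid}.b", gid, [(i * 1000, i * 1000 + 400)])
            genes.append(make_gene(gid, [long_tx, short_tx]))
            vals[f"{gid}.a"] = 9.0 if major_is_longest else 1.0
            vals[f"{gid}.b"] = 1.0 if major_is_longest else 9.0
        m = make_model(*genes)
        tx = expr({"s1": vals})
        gene = expr({"s1": {f"G{i}": 5.0 for i in range(1, 5)}}, level="gene")
        stats = longest_overlap_stats(call_major(tx, gene, m), m)
        assert stats.iloc[0]["frac_major_is_longest"] == pytest.approx(0.5)
        # only the .a transcripts carry CDS, so longest-CDS tracks them
        assert stats.iloc[0]["frac_major_has_longest_cds"] == pytest.approx(0.5)

    def test_single_transcript_genes_excluded(self):
        m = make_model(make_gene("G1", [make_tx("t1", "G1", [(0, 400)])]))
        tx = expr({"s1": {"t1": 5.0}})
        gene = expr({"s1": {"G1": 5.0}}, level="gene")
        assert longest_overlap_stats(call_major(tx, gene, m), m).empty
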