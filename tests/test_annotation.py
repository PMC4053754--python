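"""Gene-model construction, interval derivations and GTF round trips."""

import pytest
from hypothesis import given, strategies as st

from txdominance.annotation import (
    annotate_length_flags,
    build_study_set,
    derive_introns,
    exclusive_exonic_regions,
    exon_union,
    group_by_tss,
    intron_relative_position,
    unique_junctions,
)
from txdominance.gtf import GtfParseError, parse_gtf, write_gtf
from txdominance.simulate import SyntheticScenario, simulate_annotation

from conftest import make_gene, make_model, make_tx

import numpy as np


TOY_GTF = """\
chr1\tsrc\tgene\t101\t600\t.\t+\t.\tgene_id "G1"; gene_type "protein_coding";
chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "G1"; transcript_id "t1"; transcript_type "protein_coding";
chr1\tsrc\texon\t301\t400\t.\t+\t.\tgene_id "G1"; transcript_id "t1"; transcript_type "protein_coding";
chr1\tsrc\texon\t501\t600\t.\t+\t.\tgene_id "G1"; transcript_id "t1"; transcript_type "protein_coding";
chr1\tsrc\tCDS\t301\t400\t.\t+\t.\tgene_id "G1"; transcript_id "t1"; transcript_type "protein_coding";
chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "G1"; transcript_id "t2"; transcript_type "processed_transcript";
chr1\tsrc\texon\t501\t600\t.\t+\t.\tgene_id "G1"; transcript_id "t2"; transcript_type "processed_transcript";
"""


class TestParseGtf:
    def test_toy_gtf_structure_and_lengths(self, tmp_path):
        p = tmp_path / "toy.gtf"
        p.write_text(TOY_GTF)
        model = parse_gtf(p)
        assert len(model) == 1 and model.n_transcripts == 2
        g = model.genes["G1"]
        t1, t2 = g.transcript("t1"), g.transcript("t2")
        assert t1.length == 300 and t2.length == 200  # hand-summed exon widths
        assert t1.cds_length == 100 and t2.cds_length == 0
        assert t2.biotype == "processed_transcript"

    def test_one_based_to_half_open(self, tmp_path):
        p = tmp_path / "one.gtf"
        p.write_text(
            'chr1\ts\texon\t101\t200\t.\t+\t.\tgene_id "G"; transcript_id "t";\n'
        )
        model = parse_gtf(p)
        exon = model.genes["G"].transcript("t").exons[0]
        assert (exon.start, exon.end, exon.length) == (100, 200, 100)

    def test_empty_file_gives_empty_model(self, tmp_path, caplog):
        p = tmp_path / "empty.gtf"
        p.write_text("# only a comment\n")
        with caplog.at_level("WARNING"):
            model = parse_gtf(p)
        assert len(model) == 0
        assert any("no usable GTF records" in r.message for r in caplog.records)

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text(TOY_GTF + "chr1\tonly\tthree\n")
        with pytest.raises(GtfParseError, match="line 8"):
            parse_gtf(p)

    def test_inverted_exon_rejected_and_logged(self, tmp_path, caplog):
        p = tmp_path / "inv.gtf"
        p.write_text(
            TOY_GTF
            + 'chr1\ts\texon\t900\t800\t.\t+\t.\tgene_id "G1"; transcript_id "t1";\n'
        )
        with caplog.at_level("WARNING"):
            model = parse_gtf(p)
        assert model.genes["G1"].transcript("t1").length == 300
        assert any("end < start" in r.message for r in caplog.records)

    def test_mitochondrial_flag(self, tmp_path):
        p = tmp_path / "mt.gtf"
        p.write_text(
            'MT\ts\texon\t1\t500\t.\t+\t.\tgene_id "Gm"; transcript_id "tm";\n'
        )
        assert parse_gtf(p).genes["Gm"].is_mitochondrial

    def test_ensembl_biotype_dialect(self, tmp_path):
        p = tmp_path / "ens.gtf"
        p.write_text(
            'chr1\ts\texon\t1\t500\t.\t+\t.\tgene_id "G"; transcript_id "t"; '
            'gene_biotype "lincRNA"; transcript_biotype "lincRNA";\n'
        )
        assert parse_gtf(p).genes["G"].biotype == "lincRNA"


class TestStudySet:
    def _three_gene_model(self):
        ok = make_gene("A", [make_tx("A.t1", "A", [(0, 400)])])
        short = make_gene(
            "B", [make_tx("B.t1", "B", [(1000, 1400)]), make_tx("B.t2", "B", [(1000, 1250)])]
        )
        linc = make_gene(
            "C", [make_tx("C.t1", "C", [(2000, 2500)], biotype="lincRNA")],
            biotype="lincRNA",
        )
        return make_model(ok, short, linc)

    def test_biotype_and_length_filters(self):
        study = build_study_set(self._three_gene_model())
        assert set(study.genes) == {"A"}
        prov = study.provenance["study_set"]
        assert prov["kept"] == 1
        assert prov["dropped_non_coding"] == 1 and prov["dropped_short_transcript"] == 1

    def test_zero_min_length_disables_length_filter(self):
        study = build_study_set(self._three_gene_model(), min_tx_len=0)
        assert set(study.genes) == {"A", "B"}

    def test_exactly_300nt_is_kept(self):
        g = make_gene("D", [make_tx("D.t1", "D", [(0, 300)])])
        assert "D" in build_study_set(make_model(g)).genes


class TestDeriveIntrons:
    def test_interval_complement(self):
        g = make_gene(
            "G",
            [make_tx("t", "G", [(0, 100), (200, 300), (400, 500)])],
        )
        introns = [(i.interval.start, i.interval.end) for i in derive_introns(g)]
        assert introns == [(100, 200), (300, 400)]

    def test_tiling_transcripts_leave_no_intron(self):
        g = make_gene(
            "G",
            [make_tx("t1", "G", [(0, 200)]), make_tx("t2", "G", [(200, 400)])],
        )
        assert derive_introns(g) == []

    def test_staggered_exons_union_then_complement(self):
        g = make_gene(
            "G",
            [
                make_tx("t1", "G", [(0, 100), (300, 400)]),
                make_tx("t2", "G", [(0, 200), (300, 400)]),
            ],
        )
        introns = [(i.interval.start, i.interval.end) for i in derive_introns(g)]
        assert introns == [(200, 300)]

    def test_partition_invariant_on_synthetic_genes(self):
        """Introns and exon union exactly tile the span, pairwise disjoint."""
        model = simulate_annotation(
            SyntheticScenario(n_genes=100, fraction_noncoding_major=0.3, seed=21),
            np.random.default_rng(21),
        )
        for gene in model.genes.values():
            span = gene.span
            blocks = sorted(
                [(i.interval.start, i.interval.end) for i in derive_introns(gene)]
                + exon_union(gene)
            )
            assert blocks[0][0] == span.start and blocks[-1][1] == span.end
            for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
                assert e1 == s2  # contiguous, no overlap, no gap


class TestTssGroups:
    def test_plus_strand_groups(self):
        g = make_gene(
            "G",
            [
                make_tx("t1", "G", [(0, 100), (200, 300)]),
                make_tx("t2", "G", [(0, 150), (200, 300)]),
                make_tx("t3", "G", [(50, 100), (200, 300)]),
            ],
        )
        groups = group_by_tss(g)
        assert sorted(len(v) for v in groups.values()) == [1, 2]
        assert set(groups[0]) == {"t1", "t2"}

    def test_minus_strand_same_end_one_group(self):
        g = make_gene(
            "G",
            [
                make_tx("t1", "G", [(0, 100), (200, 300)], strand="-"),
                make_tx("t2", "G", [(50, 120), (200, 300)], strand="-"),
            ],
            strand="-",
        )
        groups = group_by_tss(g)
        assert list(groups) == [299] and len(groups[299]) == 2

    def test_single_transcript_singleton(self, two_tx_gene):
        g = make_gene("S", [make_tx("s1", "S", [(0, 400)])])
        assert group_by_tss(g) == {0: ["s1"]}


class TestUniqueJunctions:
    def test_shared_and_private_junctions(self):
        # t1 junctions {a, b}, t2 junctions {a, c} -> unique {b}, {c}
        g = make_gene(
            "G",
            [
                make_tx("t1", "G", [(0, 100), (200, 300), (400, 500)]),
                make_tx("t2", "G", [(0, 100), (200, 300), (600, 700)]),
            ],
        )
        uniq, fully = unique_junctions(g)
        assert {(j.donor, j.acceptor) for j in uniq["t1"]} == {(300, 400)}
        assert {(j.donor, j.acceptor) for j in uniq["t2"]} == {(300, 600)}
        assert fully

    def test_identical_chains_indistinguishable(self):
        exons = [(0, 100), (200, 300)]
        g = make_gene("G", [make_tx("t1", "G", exons), make_tx("t2", "G", exons)])
        uniq, fully = unique_junctions(g)
        assert uniq["t1"] == set() and uniq["t2"] == set() and not fully

    def test_junction_subset_transcript_not_identifiable(self):
        g = make_gene(
            "G",
            [
                make_tx("t1", "G", [(0, 100), (200, 300), (400, 500)]),
                make_tx("t2", "G", [(0, 100), (200, 300)]),  # junction subset of t1
                make_tx("t3", "G", [(0, 100), (400, 500)]),
            ],
        )
        uniq, fully = unique_junctions(g)
        assert uniq["t2"] == set() and not fully
        assert len(uniq["t3"]) == 1

    def test_agrees_with_brute_force_oracle_on_synthetic(self):
        model = simulate_annotation(
            SyntheticScenario(n_genes=50, unique_junction_prob=0.6, seed=22),
            np.random.default_rng(22),
        )
        for gene in model.genes.values():
            uniq, fully = unique_junctions(gene)
            # oracle: count containment of each junction across transcripts
            all_j = [(t.transcript_id, j) for t in gene.transcripts for j in t.junctions]
            for t in gene.transcripts:
                expected = {
                    j
                    for j in t.junctions
                    if sum(j == oj for _, oj in all_j) == 1
                }
                assert uniq[t.transcript_id] == expected
            assert fully == all(uniq[t.transcript_id] for t in gene.transcripts)


class TestLengthFlags:
    def test_length_ties_flag_all_maxima(self):
        g = make_gene(
            "G",
            [
                make_tx("t1", "G", [(0, 500)]),
                make_tx("t2", "G", [(600, 1400)]),
                make_tx("t3", "G", [(1500, 2300)]),
            ],
        )
        flags = annotate_length_flags(g)
        assert [flags[t].is_longest_transcript for t in ("t1", "t2", "t3")] == [
            False, True, True,
        ]

    def test_cds_maximum(self):
        g = make_gene(
            "G",
            [
                make_tx("t1", "G", [(0, 500)], cds=[(0, 300)]),
                make_tx("t2", "G", [(600, 1200)]),
                make_tx("t3", "G", [(1500, 2300)], cds=[(1500, 1950)]),
            ],
        )
        flags = annotate_length_flags(g)
        assert [flags[t].has_longest_cds for t in ("t1", "t2", "t3")] == [
            False, False, True,
        ]

    def test_single_transcript_both_true(self):
        g = make_gene("G", [make_tx("t1", "G", [(0, 400)])])
        f = annotate_length_flags(g)["t1"]
        assert f.is_longest_transcript and f.has_longest_cds


class TestIntronRelativePosition:
    def _gene(self, strand="+"):
        return make_gene(
            "G",
            [make_tx("t", "G", [(0, 800), (900, 1000)], strand=strand)],
            strand=strand,
        )

    def test_plus_strand(self):
        g = self._gene("+")
        intron = derive_introns(g)[0]
        assert intron_relative_position(intron, g) == pytest.approx(0.85)

    def test_minus_strand_mirror(self):
        g = self._gene("-")
        intron = derive_introns(g)[0]
        assert intron_relative_position(intron, g) == pytest.approx(0.15)

    def test_midpoint_fixed_under_strand(self):
        for strand in "+-":
            g = make_gene(
                "G",
                [make_tx("t", "G", [(0, 450), (550, 1000)], strand=strand)],
                strand=strand,
            )
            intron = derive_introns(g)[0]
            assert intron_relative_position(intron, g) == pytest.approx(0.5)

    @given(st.integers(0, 10_000))
    def test_strand_mirror_property_on_synthetic_introns(self, seed):
        model = simulate_annotation(
            SyntheticScenario(n_genes=2, seed=seed % 2**31), np.random.default_rng(seed)
        )
        for gene in model.genes.values():
            flipped = "-" if gene.strand == "+" else "+"
            mirror = make_gene(
                gene.gene_id,
                [
                    make_tx(
                        t.transcript_id, gene.gene_id,
                        [(e.start, e.end) for e in t.exons],
                        strand=flipped, chrom=gene.chrom,
                    )
                    for t in gene.transcripts
                ],
                strand=flipped, chrom=gene.chrom,
            )
            for intron, m_intron in zip(derive_introns(gene), derive_introns(mirror)):
                p = intron_relative_position(intron, gene)
                q = intron_relative_position(m_intron, mirror)
                assert abs(p - (1 - q)) < 1e-12


class TestGtfRoundTrip:
    def test_write_then_parse_preserves_intervals(self, tmp_path):
        model = simulate_annotation(
            SyntheticScenario(n_genes=20, fraction_noncoding_major=0.3, seed=23),
            np.random.default_rng(23),
        )
        p = tmp_path / "rt.gtf"
        write_gtf(model, p)
        back = parse_gtf(p)
        assert set(back.genes) == set(model.genes)
        for gid, gene in model.genes.items():
            other = back.genes[gid]
            for t in gene.transcripts:
                ot = other.transcript(t.transcript_id)
                assert [(e.start, e.end) for e in t.exons] == [
                    (e.start, e.end) for e in ot.exons
                ]
                assert [(c.start, c.end) for c in t.cds] == [
                    (c.start, c.end) for c in ot.cds
                ]
                assert t.length == ot.length and t.biotype == ot.biotype


class TestExclusiveRegions:
    def test_retained_intron_region_recovered(self):
        ri = make_tx("ri", "G", [(0, 100), (200, 500), (600, 700)],
                     biotype="retained_intron")
        spliced = make_tx(
            "sp", "G", [(0, 100), (200, 300), (400, 500), (600, 700)],
            cds=[(200, 300)],
        )
        g = make_gene("G", [ri, spliced])
        regions = exclusive_exonic_regions(g, "ri")
        assert [(r.start, r.end) for r in regions] == [(300, 400)]

    def test_fully_shared_transcript_has_none(self, two_tx_gene):
        assert exclusive_exonic_regions(two_tx_gene, "t2") == []
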