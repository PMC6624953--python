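import itertools

import pytest

from utriso.gene_models import (
    AnnotationError,
    CurationOverride,
    GeneModel,
    build_mask,
    mask_intervals,
    parse_gene_models,
    read_mask_bed,
)


def gm(gid, start, end, strand="+", target=True, chrom="chr7", anchor=None):
    if anchor is None:
        anchor = end if strand == "+" else start
    return GeneModel(gid, chrom, strand, start, end, anchor, target)


class TestParseGeneModels:
    def test_single_isoform_plus_strand_anchor(self, write_gtf):
        # GTF is 1-based inclusive: CDS 100-400 with stop codon 398-400
        gtf = write_gtf(
            [
                ("chr1", "CDS", 100, 397, "+", "GA", "GA.t1"),
                ("chr1", "stop_codon", 398, 400, "+", "GA", "GA.t1"),
            ]
        )
        (g,) = parse_gene_models(gtf, "^G")
        assert g.cds_span == (99, 400)
        assert g.stop_anchor == 400
        assert g.utr_to_genomic(1) == 400  # first base after the stop codon

    def test_minus_strand_anchor(self, write_gtf):
        gtf = write_gtf(
            [
                ("chr1", "stop_codon", 100, 102, "-", "GA", "GA.t1"),
                ("chr1", "CDS", 103, 400, "-", "GA", "GA.t1"),
            ]
        )
        (g,) = parse_gene_models(gtf, "^G")
        assert g.stop_anchor == 99
        assert g.utr_to_genomic(1) == 98

    def test_cds_envelope_is_union_over_isoforms(self, write_gtf):
        gtf = write_gtf(
            [
                ("chr1", "CDS", 100, 397, "+", "GA", "GA.t1"),
                ("chr1", "stop_codon", 398, 400, "+", "GA", "GA.t1"),
                ("chr1", "CDS", 150, 397, "+", "GA", "GA.t2"),
                ("chr1", "stop_codon", 398, 400, "+", "GA", "GA.t2"),
            ]
        )
        (g,) = parse_gene_models(gtf, "^G")
        assert g.cds_span == (99, 400)

    def test_stop_anchor_inferred_from_cds_when_missing(self, write_gtf):
        gtf = write_gtf([("chr1", "CDS", 100, 400, "+", "GA", "GA.t1")])
        (g,) = parse_gene_models(gtf, "^G")
        assert g.stop_anchor == 400

    def test_drop_gene_override_removes_gene(self, write_gtf):
        gtf = write_gtf(
            [
                ("chr1", "CDS", 100, 400, "+", "GA", "GA.t1"),
                ("chr1", "CDS", 900, 1400, "+", "GB", "GB.t1"),
            ]
        )
        out = parse_gene_models(gtf, "^G", [CurationOverride("GA", "drop_gene")])
        assert [g.gene_id for g in out] == ["GB"]

    def test_multiple_stop_anchors_error_and_curation_rescue(self, write_gtf):
        features = [
            ("chr1", "CDS", 100, 400, "+", "GA", "GA.t1"),
            ("chr1", "CDS", 100, 500, "+", "GA", "GA.t2"),
        ]
        gtf = write_gtf(features)
        with pytest.raises(AnnotationError, match="GA"):
            parse_gene_models(gtf, "^G")
        out = parse_gene_models(
            gtf, "^G", [CurationOverride("GA", "drop_transcript", "GA.t2")]
        )
        assert out[0].stop_anchor == 400

    def test_set_alt_locus_splits_distant_loci(self, write_gtf):
        gtf = write_gtf(
            [
                ("chr1", "CDS", 100, 400, "+", "GA", "GA.t1"),
                ("chr1", "CDS", 500_000, 500_300, "+", "GA", "GA.t2"),
            ]
        )
        out = parse_gene_models(gtf, "^G", [CurationOverride("GA", "set_alt_locus")])
        assert [g.gene_id for g in out] == ["GA@1", "GA@2"]
        assert out[0].cds_span == (99, 400)

    def test_target_predicate_from_name(self, write_gtf):
        gtf = write_gtf(
            [
                ("chr1", "CDS", 100, 400, "+", "Olfr1", "Olfr1.t1"),
                ("chr1", "CDS", 900, 1400, "+", "Abc1", "Abc1.t1"),
            ]
        )
        out = parse_gene_models(gtf, "^Olfr")
        assert {g.gene_id: g.is_target for g in out} == {"Olfr1": True, "Abc1": False}


class TestBuildMask:
    def test_flanked_cluster_span_and_membership(self):
        genes = [
            gm("A", 1_000, 2_000, target=False),
            gm("T1", 10_000, 11_000),
            gm("T2", 20_000, 21_000),
            gm("B", 50_000, 52_000, target=False),
        ]
        (r,) = build_mask(genes)
        assert r.span == (2_000, 50_000)
        assert r.member_gene_ids == ("T1", "T2")

    def test_terminal_cluster_gets_default_edge(self):
        genes = [gm("T1", 30_000, 31_000), gm("B", 90_000, 91_000, target=False)]
        (r,) = build_mask(genes)
        assert r.start == 30_000 - 25_000
        assert r.end == 90_000

    def test_gene_density_per_mb(self):
        genes = [
            gm("A", 0, 1_000, target=False),
            gm("T1", 100_000, 101_000),
            gm("T2", 200_000, 201_000),
            gm("B", 501_000, 502_000, target=False),
        ]
        (r,) = build_mask(genes)
        assert r.length == 500_000
        assert r.gene_density == pytest.approx(4.0)  # 2 CDSs over 0.5 Mb

    def test_intervening_nontarget_splits_clusters(self):
        genes = [
            gm("T1", 10_000, 11_000),
            gm("N", 20_000, 21_000, target=False),
            gm("T2", 30_000, 31_000),
        ]
        regions = build_mask(genes)
        assert [r.member_gene_ids for r in regions] == [("T1",), ("T2",)]
        # every target gene in exactly one region
        members = list(itertools.chain.from_iterable(r.member_gene_ids for r in regions))
        assert sorted(members) == ["T1", "T2"]

    def test_permutation_invariance(self):
        genes = [
            gm("A", 1_000, 2_000, target=False),
            gm("T1", 10_000, 11_000),
            gm("T2", 20_000, 21_000),
            gm("B", 50_000, 52_000, target=False),
            gm("T3", 5_000, 6_000, chrom="chr8"),
        ]
        ref = build_mask(genes)
        for perm in itertools.permutations(genes):
            assert build_mask(list(perm)) == ref


class TestMaskIntervals:
    def test_bed_lines_and_roundtrip(self, tmp_path):
        genes = [
            gm("A", 0, 1_000, target=False),
            gm("T1", 5_000, 6_000),
            gm("B", 9_000, 9_500, target=False),
        ]
        regions = build_mask(genes)
        lines = mask_intervals(regions)
        assert lines[0].startswith("chr7\t1000\t9000")
        p = tmp_path / "mask.bed"
        p.write_text("\n".join(lines) + "\n")
        again = read_mask_bed(p)
        assert [(r.chrom, r.span) for r in again] == [(r.chrom, r.span) for r in regions]

    def test_empty_region_list_yields_header_comment(self):
        assert mask_intervals([]) == ["# empty mask: no target regions"]
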