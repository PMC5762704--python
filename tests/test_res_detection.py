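import itertools

import pytest

from scires.genotyping import GenotypeCall
from scires.io_formats import TranscriptModel
from scires.res_detection import (COMPLEMENT, CellEvidence, ResRecord,
                                  coverage_overlap, filter_liver_het,
                                  filter_multitype, find_candidates,
                                  occurrence_summary, resolve_editing_type,
                                  run_pipeline)


def C(pos, status, ref="A", alt="G", depth=10, sf=True, chrom="chr1"):
    alt_base = None if status in ("hom_ref", "no_call") else alt
    return GenotypeCall(chrom=chrom, pos=pos, ref_base=ref,
                        alt_base=alt_base, status=status, af=None,
                        depth=depth, p_value=None, strand_filter_pass=sf)


def _rec(pos, dna="A", rna="G", cells=("S1",), chrom="chr1"):
    return ResRecord(chrom=chrom, pos=pos, dna_base=dna, rna_base=rna,
                     cells={c: CellEvidence(dna, rna, 10, 10)
                            for c in cells})


class TestFindCandidates:
    def test_hom_hom_mismatch_is_candidate(self):
        out = find_candidates({"S1": [C(100, "hom_ref")]},
                              {"S1": [C(100, "hom_var", depth=12)]})
        assert len(out) == 1
        assert out[0].mismatch_type == "A>G"
        assert out[0].cells["S1"].rna_depth == 12

    def test_het_dna_excluded(self):
        out = find_candidates({"S1": [C(100, "het")]},
                              {"S1": [C(100, "hom_var")]})
        assert out == []

    def test_low_rna_depth_excluded(self):
        out = find_candidates({"S1": [C(100, "hom_ref")]},
                              {"S1": [C(100, "hom_var", depth=7)]})
        assert out == []

    def test_strand_filter_failure_excluded(self):
        out = find_candidates({"S1": [C(100, "hom_ref")]},
                              {"S1": [C(100, "hom_var", sf=False)]})
        assert out == []

    def test_matching_hom_calls_are_not_candidates(self):
        out = find_candidates({"S1": [C(100, "hom_ref")]},
                              {"S1": [C(100, "hom_ref")]})
        assert out == []

    def test_unpaired_cell_errors(self):
        with pytest.raises(ValueError, match="modality"):
            find_candidates({"S1": []}, {"S2": []})


class TestFilterMultitype:
    def test_agreeing_cells_kept_with_occurrence(self):
        kept, removed = filter_multitype(
            [_rec(100, cells=("S1",)), _rec(100, cells=("S2",))])
        assert removed == []
        assert len(kept) == 1 and kept[0].occurrence == 2

    def test_conflicting_mismatch_types_removed_entirely(self):
        kept, removed = filter_multitype(
            [_rec(100, rna="C", cells=("S1",)),
             _rec(100, rna="G", cells=("S2",))])
        assert kept == []
        assert len(removed) == 1
        assert removed[0].filter_trail[-1] == ("multitype", "fail")

    def test_single_cell_site_kept(self):
        kept, removed = filter_multitype([_rec(100)])
        assert len(kept) == 1 and removed == []


class TestFilterLiverHet:
    def test_liver_het_removed(self):
        kept, removed = filter_liver_het([_rec(100)], [C(100, "het")])
        assert kept == [] and len(removed) == 1

    def test_liver_hom_kept(self):
        kept, removed = filter_liver_het([_rec(100)], [C(100, "hom_ref")])
        assert len(kept) == 1 and not kept[0].liver_uncovered

    def test_liver_uncovered_kept_with_flag(self):
        kept, removed = filter_liver_het([_rec(100)], [])
        assert len(kept) == 1
        assert kept[0].liver_uncovered
        assert ("liver_het", "liver_uncovered") in kept[0].filter_trail


def _tx(strand, gene="g1", tid="t1", chrom="chr1",
        exons=((100, 199), (300, 399)), cds=(150, 349)):
    return TranscriptModel(gene_id=gene, transcript_id=tid, chrom=chrom,
                           strand=strand, exons=list(exons), cds=cds,
                           biotype="protein_coding")


class TestResolveEditingType:
    def test_watson_cds_site(self):
        rec = resolve_editing_type(_rec(180), [_tx("+")])
        assert rec.resolved_editing_type == "A-to-G"
        assert rec.region == "CDS"
        assert rec.gene_id == "g1"

    def test_crick_strand_complements(self):
        rec = resolve_editing_type(_rec(180, dna="A", rna="G"), [_tx("-")])
        assert rec.resolved_editing_type == "T-to-C"

    def test_intergenic_site_unresolved(self):
        rec = resolve_editing_type(_rec(5000), [_tx("+")])
        assert rec.region == "intergenic"
        assert rec.resolved_editing_type is None

    def test_both_strands_flagged_ambiguous(self):
        models = [_tx("+"), _tx("-", gene="g2", tid="t2")]
        rec = resolve_editing_type(_rec(180), models)
        assert rec.strand_ambiguous
        assert rec.resolved_editing_type is None

    @pytest.mark.parametrize("pos,region", [
        (150, "start_codon"), (152, "start_codon"),
        (347, "stop_codon"), (349, "stop_codon"),
        (180, "CDS"), (320, "CDS"),
        (120, "UTR5"), (380, "UTR3"),
        (250, "intron"), (50, "intergenic"),
    ])
    def test_region_precedence_watson(self, pos, region):
        rec = resolve_editing_type(_rec(pos), [_tx("+")])
        assert rec.region == region

    def test_utr_sides_flip_on_crick(self):
        assert resolve_editing_type(_rec(120), [_tx("-")]).region == "UTR3"
        assert resolve_editing_type(_rec(380), [_tx("-")]).region == "UTR5"

    def test_noncoding_exon_region(self):
        t = _tx("+", cds=None)
        t.biotype = "lncRNA"
        assert resolve_editing_type(_rec(120), [t]).region == \
            "noncoding_exon"

    def test_longest_transcript_wins_ties_by_gene_id(self):
        short = _tx("+", gene="gB", tid="tB", exons=((150, 249),), cds=None)
        long_ = _tx("+", gene="gA", tid="tA")
        rec = resolve_editing_type(_rec(180), [short, long_])
        assert rec.gene_id == "gA"

    def test_involution_all_twelve_mismatch_types(self):
        """Complementing a mismatch twice is the identity, for every
        ordered base pair."""
        for d, r in itertools.permutations("ACGT", 2):
            crick = resolve_editing_type(_rec(180, dna=d, rna=r), [_tx("-")])
            expect = f"{COMPLEMENT[d]}-to-{COMPLEMENT[r]}"
            assert crick.resolved_editing_type == expect
            back_d, back_r = expect.split("-to-")
            assert (COMPLEMENT[back_d], COMPLEMENT[back_r]) == (d, r)


class TestSummaries:
    def test_occurrence_histogram(self):
        records = [_rec(p, cells=("S1",)) for p in (1, 2, 3)] + \
            [_rec(9, cells=tuple(f"S{i}" for i in range(1, 7)))]
        hist, _table = occurrence_summary(records)
        assert hist == {1: 3, 6: 1}

    def test_empty_set(self):
        hist, table = occurrence_summary([])
        assert hist == {} and table.empty

    def test_per_gene_table_sorted(self):
        recs = [_rec(p) for p in (1, 2, 3)]
        for r in recs[:2]:
            r.gene_id = "gX"
        recs[2].gene_id = "gA"
        _hist, table = occurrence_summary(recs)
        assert list(table["gene_id"]) == ["gX", "gA"]
        assert list(table["n_res"]) == [2, 1]

    def test_coverage_overlap_set_arithmetic(self):
        a = {("chr1", p) for p in range(50)}
        b = {("chr1", p) for p in range(100)}
        ov = coverage_overlap({"A": a, "B": b})
        assert ov.rates.loc["A", "B"] == pytest.approx(0.5)
        assert ov.rates.loc["B", "A"] == pytest.approx(1.0)
        assert ov.rates.loc["A", "A"] == 1.0
        assert ov.counts.loc["A", "B"] == 50

    def test_coverage_overlap_disjoint_and_empty(self):
        import math
        a = {("chr1", 1)}
        ov = coverage_overlap({"A": a, "B": {("chr1", 2)}, "C": set()})
        assert ov.rates.loc["A", "B"] == 0.0
        assert math.isnan(ov.rates.loc["A", "C"])


class TestPipelineAudit:
    def test_conservation_at_every_stage(self):
        dna = {"S1": [C(100, "hom_ref"), C(200, "hom_ref"),
                      C(300, "hom_ref")],
               "S2": [C(100, "hom_ref"), C(200, "hom_ref")]}
        rna = {"S1": [C(100, "hom_var"), C(200, "hom_var", alt="C"),
                      C(300, "hom_var")],
               "S2": [C(100, "hom_var"), C(200, "hom_var", alt="T")]}
        liver = [C(300, "het")]
        result = run_pipeline(dna, rna, liver, [_tx("+")])
        for stage in result.audit:
            assert stage.n_in == stage.n_out + stage.n_removed
        # site 200 has two mismatch types, site 300 is liver-het
        assert {r.pos for r in result.records} == {100}
        assert result.records[0].occurrence == 2
        assert {r.pos for r in result.removed["multitype"]} == {200}
        assert {r.pos for r in result.removed["liver_het"]} == {300}
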