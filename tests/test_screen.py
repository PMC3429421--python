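"""RepeatMasker parsing, candidate filtering, flanks, presence calls and
confounding-event classification."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sinephylo import (AmpliconObservation, InsertionAnnotation, RepeatHit,
                       call_presence, classify_confounding, extract_flanks,
                       filter_candidates, parse_repeatmasker_out,
                       recode_near_parallel)
from sinephylo.errors import ConfigurationError, InputError, NoCallError
from sinephylo.fixtures import build_genome_fixture, inject_confounder_fixture

from conftest import make_matrix

RM_HEADER = (
    "   SW  perc perc perc  query      position in query   matching repeat\n"
    "score  div. del. ins.  sequence   begin  end  (left)  repeat  class\n"
    "\n"
)


def test_empty_annotation_body_gives_no_hits(tmp_path):
    p = tmp_path / "empty.out"
    p.write_text(RM_HEADER)
    assert parse_repeatmasker_out(p) == []


def test_three_records_parse_with_coordinates(tmp_path):
    p = tmp_path / "hits.out"
    p.write_text(RM_HEADER + "\n".join([
        " 1200 8.1 0.0 0.0 contig_1 101 400 (600) + AluL1 SINE/Alu 1 300 (0) 1",
        "  900 9.5 0.0 0.0 contig_1 501 781 (219) C AluL2 SINE/Alu 1 281 (0) 2",
        "  800 12.0 0.0 0.0 contig_2 11 310 (690) + AluJb SINE/Alu 1 300 (0) 3",
    ]) + "\n")
    hits = parse_repeatmasker_out(p)
    assert len(hits) == 3
    assert (hits[0].contig, hits[0].begin, hits[0].end) == ("contig_1", 101, 400)
    assert hits[1].strand == "-"            # "C" orientation
    assert hits[2].family == "AluJb"


def test_malformed_record_reports_line_number(tmp_path):
    p = tmp_path / "bad.out"
    p.write_text(RM_HEADER + "1200 8.1 0.0 0.0 contig_1 101 oops\n")
    with pytest.raises(InputError, match="line 4"):
        parse_repeatmasker_out(p)


class TestFilter:
    def hit(self, family="AluL1", length=300):
        return RepeatHit(contig="c", begin=1, end=length, strand="+",
                         family=family)

    def test_length_filter_is_strict(self):
        assert filter_candidates([self.hit(length=280)]) == []
        kept = filter_candidates([self.hit(length=281)])
        assert len(kept) == 1

    def test_wrong_family_rejected_regardless_of_length(self):
        assert filter_candidates([self.hit(family="AluJo", length=300)]) == []

    def test_explicit_family_set_is_exact_membership(self):
        hits = [self.hit("AluL1"), self.hit("AluL9")]
        assert len(filter_candidates(hits, families={"AluL1"})) == 1

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.tuples(st.sampled_from(["AluL1", "AluL4", "AluJb"]),
                              st.integers(250, 320))))
    def test_filter_is_idempotent(self, spec):
        hits = [RepeatHit(contig="c", begin=1, end=n, strand="+", family=f)
                for f, n in spec]
        once = filter_candidates(hits)
        assert filter_candidates(once) == once


class TestFlanks:
    def test_middle_element_yields_two_full_flanks(self):
        seq = "A" * 50 + "G" * 300 + "T" * 50
        hit = RepeatHit(contig="c", begin=51, end=350, strand="+",
                        family="AluL1")
        fl = extract_flanks(seq, hit, 50)
        assert fl.upstream == "A" * 50 and fl.downstream == "T" * 50
        assert not fl.upstream_truncated and not fl.downstream_truncated

    def test_contig_edge_truncates_and_flags(self):
        seq = "A" * 10 + "G" * 300 + "T" * 5
        hit = RepeatHit(contig="c", begin=11, end=310, strand="+",
                        family="AluL1")
        fl = extract_flanks(seq, hit, 50)
        assert len(fl.upstream) == 10 and fl.upstream_truncated
        assert len(fl.downstream) == 5 and fl.downstream_truncated

    def test_hit_outside_contig_is_an_error(self):
        hit = RepeatHit(contig="c", begin=1, end=100, strand="+",
                        family="AluL1")
        with pytest.raises(InputError):
            extract_flanks("ACGT", hit, 10)

    def test_flanks_match_genome_fixture_truth(self, tmp_path):
        fx = build_genome_fixture(2, 2000, [("AluL1", 300, "lineage_a")],
                                  seed=5, out_dir=tmp_path)
        from Bio import SeqIO
        contigs = {r.id: str(r.seq) for r in SeqIO.parse(fx.fasta_path,
                                                         "fasta")}
        row = fx.truth.iloc[0]
        hit = RepeatHit(contig=row.contig, begin=int(row.begin),
                        end=int(row.end), strand=row.strand, family=row.family)
        fl = extract_flanks(contigs[row.contig], hit, 30)
        seq = contigs[row.contig]
        assert fl.upstream == seq[max(0, row.begin - 31):row.begin - 1]
        assert fl.downstream == seq[row.end:row.end + 30]


class TestPresenceCalls:
    def obs(self, taxon, length):
        return AmpliconObservation(taxon=taxon, product_length=length)

    def test_product_sizes_map_to_states(self):
        calls = call_presence(
            [self.obs("a", 200), self.obs("b", 500),
             AmpliconObservation("c", None), self.obs("d", 350)],
            empty_size=200, element_size=300, tol=30)
        assert calls == {"a": 0, "b": 1, "c": -1, "d": -1}

    def test_overlapping_windows_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            call_presence([self.obs("a", 200)], empty_size=200,
                          element_size=50, tol=30)

    @settings(max_examples=50, deadline=None)
    @given(st.one_of(st.none(), st.integers(1, 1000)))
    def test_every_observation_gets_exactly_one_state(self, length):
        calls = call_presence([AmpliconObservation("x", length)],
                              empty_size=200, element_size=300, tol=30)
        assert calls["x"] in (1, 0, -1)


class TestConfounding:
    def ann(self, taxon, subfam, point, tsd):
        return InsertionAnnotation(taxon, subfam, point, tsd)

    def test_same_subfamily_same_spot_same_tsd_is_orthologous(self):
        call = classify_confounding("L", [
            self.ann("a", "AluL1", 100, "AATT"),
            self.ann("b", "AluL1", 100, "AATT")])
        assert call.verdict == "orthologous_same_element"

    def test_different_subfamilies_nearby_are_independent(self):
        call = classify_confounding("L", [
            self.ann("a", "AluL1", 100, "AATT"),
            self.ann("b", "AluL4", 104, "GGCC")])
        assert call.verdict == "near_parallel_independent"
        assert call.offset_bp == 4

    def test_same_subfamily_far_apart_is_independent(self):
        call = classify_confounding("L", [
            self.ann("a", "AluL1", 100, "AATT"),
            self.ann("b", "AluL1", 600, "AATT")])
        assert call.verdict == "near_parallel_independent"

    def test_tsd_mismatch_at_same_spot_is_other_indel(self):
        call = classify_confounding("L", [
            self.ann("a", "AluL1", 100, "AATT"),
            self.ann("b", "AluL1", 100, "GGCC")])
        assert call.verdict == "other_indel"

    def test_single_taxon_cannot_be_classified(self):
        with pytest.raises(NoCallError):
            classify_confounding("L", [self.ann("a", "AluL1", 100, "AATT")])

    def test_confounder_fixture_verdicts(self):
        fx = inject_confounder_fixture()
        call = classify_confounding(fx.locus_id, fx.annotations)
        assert call.verdict == "near_parallel_independent"
        ortho = inject_confounder_fixture(variant="orthologous")
        call2 = classify_confounding(ortho.locus_id, ortho.annotations)
        assert call2.verdict == "orthologous_same_element"

    def test_recoding_splits_one_column_into_two(self):
        taxa = ("che", "ind", "out")
        m = make_matrix(taxa, [{"che": 1, "ind": 1}], ids=["MmA20"])
        recoded = recode_near_parallel(m, "MmA20", ({"che"}, {"ind"}))
        assert recoded.n_loci == m.n_loci + 1
        assert recoded.locus_ids == ("MmA20", "MmA20A")
        assert recoded.state("che", "MmA20") == 1
        assert recoded.state("ind", "MmA20") == 0
        assert recoded.state("ind", "MmA20A") == 1
        assert recoded.state("che", "MmA20A") == 0
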