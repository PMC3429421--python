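"""Insertion-history simulator and fixture generators."""

import numpy as np
import pytest

from sinephylo import (SimConfig, build_genome_fixture, classify_characters,
                       filter_candidates, parse_repeatmasker_out,
                       simulate_insertions, tree_length)
from sinephylo.errors import InputError
from sinephylo.fixtures import LEMUR_CLADES, OUTGROUPS
from sinephylo.simulate import random_binary_tree


class TestSimulator:
    def test_zero_rate_yields_empty_matrix(self):
        tree = random_binary_tree(6, seed=1)
        m, truth = simulate_insertions(SimConfig(tree=tree, insertion_rate=0.0))
        assert m.n_loci == 0 and truth == {}

    def test_clean_columns_are_clade_consistent(self):
        tree = random_binary_tree(8, seed=2)
        m, truth = simulate_insertions(SimConfig(tree=tree, insertion_rate=4.0,
                                                 seed=3))
        score = tree_length(tree, m)
        assert all(v == 1 for v in score.per_locus.values())
        # per-branch tallies match the simulated columns exactly
        from sinephylo import reconstruct, synapomorphy_counts
        counts, amb = synapomorphy_counts(reconstruct(tree, m), tree)
        assert amb == []
        assert {c: k for c, k in counts.items() if k} == truth

    def test_fixed_seed_reproduces_matrix(self):
        tree = random_binary_tree(6, seed=4)
        cfg = SimConfig(tree=tree, insertion_rate=2.0, seed=42,
                        p_missing=0.1, p_excision=0.1)
        a, ta = simulate_insertions(cfg)
        b, tb = simulate_insertions(cfg)
        assert a == b and ta == tb

    def test_column_count_is_within_poisson_expectation(self):
        tree = random_binary_tree(6, seed=5)
        total_bl = sum(n.length for n in tree.postorder()
                       if n.parent is not None)
        rate = 2.0
        m, _ = simulate_insertions(SimConfig(tree=tree, insertion_rate=rate,
                                             seed=6))
        mean = rate * total_bl
        assert abs(m.n_loci - mean) <= 3 * np.sqrt(mean)

    def test_excision_reverts_a_subtree(self):
        tree = random_binary_tree(8, seed=7)
        m, truth = simulate_insertions(SimConfig(tree=tree, insertion_rate=5.0,
                                                 p_excision=1.0, seed=8))
        score = tree_length(tree, m)
        # with certain excision some columns need losses on the true tree
        assert any(v > 1 for v in score.per_locus.values())

    def test_missing_probability_masks_cells(self):
        tree = random_binary_tree(8, seed=9)
        m, _ = simulate_insertions(SimConfig(tree=tree, insertion_rate=5.0,
                                             p_missing=0.2, seed=10))
        frac = (m.states == -1).mean()
        assert 0.05 < frac < 0.4

    def test_parallel_duplicates_add_columns(self):
        tree = random_binary_tree(8, seed=11)
        base, _ = simulate_insertions(SimConfig(tree=tree, insertion_rate=4.0,
                                                seed=12))
        dup, _ = simulate_insertions(SimConfig(tree=tree, insertion_rate=4.0,
                                               p_parallel=1.0, seed=12))
        assert dup.n_loci > base.n_loci
        assert any(lid.endswith("A") for lid in dup.locus_ids)

    def test_nonbinary_tree_is_rejected(self):
        from sinephylo import RootedTree
        tree = RootedTree.from_newick("((A,B),C,D);")
        with pytest.raises(InputError):
            simulate_insertions(SimConfig(tree=tree))

    def test_probabilities_validated(self):
        tree = random_binary_tree(4, seed=0)
        with pytest.raises(InputError):
            SimConfig(tree=tree, p_missing=1.5)


class TestLemurFixture:
    def test_dimensions_and_totals(self, lemur_matrix):
        assert lemur_matrix.n_taxa == 24
        assert lemur_matrix.n_loci == 95
        assert lemur_matrix.panel.outgroups == OUTGROUPS

    def test_outgroups_carry_no_insertions(self, lemur_matrix):
        for og in OUTGROUPS:
            row = lemur_matrix.states[lemur_matrix.panel.index(og)]
            assert (row == 0).all()

    def test_classification_matches_clade_table(self, lemur_matrix):
        cls = classify_characters(lemur_matrix)
        assert cls.n_informative == 73
        assert cls.n_autapomorphic == 22
        assert cls.n_constant == 0

    def test_every_column_is_one_dollo_step_on_reference_tree(
            self, lemur_matrix, lemur_tree):
        score = tree_length(lemur_tree, lemur_matrix)
        assert score.total_length == 95

    def test_named_loci_are_present(self, lemur_matrix):
        for lid in ("MmM97", "LI1", "PcC1", "PcC2", "MmA2c", "Str71B",
                    "Str59", "Em6", "MmA27", "MmA20A", "Str67A"):
            assert lid in lemur_matrix.locus_ids
        assert lemur_matrix.present_taxa("MmA2c") == frozenset(
            ["Avahi_laniger"])
        assert lemur_matrix.present_taxa("MmM97") == LEMUR_CLADES[
            "lepilemur_cheirogaleidae"]

    def test_reference_tree_displays_exactly_the_supported_clades(
            self, lemur_tree):
        assert lemur_tree.clades() == set(LEMUR_CLADES.values())


class TestGenomeFixture:
    def test_zero_implants_gives_header_only_annotation(self, tmp_path):
        fx = build_genome_fixture(2, 500, [], seed=1, out_dir=tmp_path)
        assert parse_repeatmasker_out(fx.out_path) == []
        assert fx.truth.empty

    def test_single_implant_round_trips_through_the_parser(self, tmp_path):
        fx = build_genome_fixture(2, 1000, [("AluL1", 300, "lin_a")],
                                  seed=2, out_dir=tmp_path)
        hits = parse_repeatmasker_out(fx.out_path)
        assert len(hits) == 1
        row = fx.truth.iloc[0]
        assert (hits[0].begin, hits[0].end) == (row.begin, row.end)
        assert hits[0].length == 300

    def test_screen_recovers_exactly_the_qualifying_implants(self, tmp_path):
        implants = ([("AluL1", 300, "a")] * 6 + [("AluL4", 281, "b")] * 5
                    + [("AluL1", 280, "a")] * 3      # boundary: rejected
                    + [("AluJb", 300, "c")] * 4      # wrong family
                    + [("AluL2", 250, "d")] * 2)     # too short
        fx = build_genome_fixture(6, 3000, implants, seed=3,
                                  out_dir=tmp_path)
        hits = parse_repeatmasker_out(fx.out_path)
        kept = filter_candidates(hits, min_len=280)
        want = fx.truth[(fx.truth.family.str.startswith("AluL"))
                        & (fx.truth.length > 280)]
        assert {(h.contig, h.begin, h.end) for h in kept} == {
            (r.contig, r.begin, r.end) for r in want.itertuples()}
        assert len(kept) == 11

    def test_oversized_implant_is_rejected(self, tmp_path):
        with pytest.raises(InputError):
            build_genome_fixture(1, 200, [("AluL1", 300, "a")], seed=4,
                                 out_dir=tmp_path)

    def test_deterministic_given_seed(self, tmp_path):
        a = build_genome_fixture(3, 1000, [("AluL1", 300, "a")], seed=9,
                                 out_dir=tmp_path / "a")
        b = build_genome_fixture(3, 1000, [("AluL1", 300, "a")], seed=9,
                                 out_dir=tmp_path / "b")
        assert a.fasta_path.read_text() == b.fasta_path.read_text()
        assert a.out_path.read_text() == b.out_path.read_text()
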