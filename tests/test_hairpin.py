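import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_rna
from oracles import enumerate_structures, max_pairs_bruteforce
from sharpmir.energy import EnergyModel, evaluate_energy, pair_table
from sharpmir.errors import StarInferenceError, StructureError
from sharpmir.hairpin import (HairpinCriteria, HairpinPrecursor,
                              SecondaryStructure, count_mature_stem_loops,
                              count_terminal_loops, evaluate_hairpin, fold_maxpair,
                              fold_mfe, infer_star, locate_precursor)
from sharpmir.io_formats import RNASequence

rna = st.text(alphabet="acgu", min_size=4, max_size=12)


class TestFoldMaxpair:
    def test_simple_stem(self):
        structure = fold_maxpair("gggaaaccc")
        assert structure.n_pairs == 3
        assert structure.n_pairs == max_pairs_bruteforce("gggaaaccc")

    def test_unpairable_sequence_is_open(self):
        structure = fold_maxpair("aaaa")
        assert structure.dotbracket == "...."
        assert structure.n_pairs == 0
        assert structure.energy == 0.0

    @given(rna)
    def test_matches_bruteforce_maximum(self, seq):
        assert fold_maxpair(seq).n_pairs == max_pairs_bruteforce(seq)

    def test_matches_bruteforce_on_200_random_sequences(self):
        rng = np.random.default_rng(1234)
        for _ in range(200):
            seq = random_rna(rng, int(rng.integers(4, 13)))
            assert fold_maxpair(seq).n_pairs == max_pairs_bruteforce(seq), seq

    @given(rna)
    def test_structure_is_valid_and_counts_pairs(self, seq):
        structure = fold_maxpair(seq)
        pt = pair_table(structure.dotbracket)
        model = EnergyModel()
        for i, j in structure.pairs:
            assert j - i > 3
            assert model.can_pair(seq[i - 1], seq[j - 1])
        assert structure.energy == -structure.n_pairs


class TestEvaluateEnergy:
    def test_open_chain_is_zero(self):
        assert evaluate_energy("acguacgu", "........") == 0.0

    def test_gc_stem_beats_au_stem_of_same_shape(self):
        shape = "((((((....))))))"
        gc = "gggggg" + "aaaa" + "cccccc"
        au = "aaaaaa" + "gaaa" + "uuuuuu"
        assert evaluate_energy(gc, shape) < evaluate_energy(au, shape)

    def test_hand_summed_hairpin(self):
        # 4-bp stem (gc,gc,au,ua) around a 4-nt loop:
        # stacks gc:gc (-3.3), gc:au (-2.4), au:ua (-1.1); hairpin(4) = 5.6
        # closing pair of the hairpin is ua -> terminal AU/GU penalty 0.5
        seq = "ggaucaucaugucc"[:12]
        seq = "ggau" + "caua" + "aucc"
        db = "((((....))))"
        expected = -3.3 + -2.4 + -1.1 + 5.6 + 0.5
        assert evaluate_energy(seq, db) == pytest.approx(expected)

    def test_non_pairable_bases_raise(self):
        with pytest.raises(StructureError):
            evaluate_energy("aaga", "(..)")

    def test_length_mismatch_raises(self):
        with pytest.raises(StructureError):
            evaluate_energy("acgu", "(((...)))")


class TestFoldMfe:
    def test_open_chain_for_unpairable(self):
        structure = fold_mfe("aaaaaaaaaa")
        assert structure.dotbracket == ".........."
        assert structure.energy == 0.0

    def test_reported_energy_is_self_consistent(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            seq = random_rna(rng, int(rng.integers(10, 40)))
            structure = fold_mfe(seq)
            assert structure.energy == pytest.approx(
                evaluate_energy(seq, structure.dotbracket))

    @settings(max_examples=25)
    @given(st.text(alphabet="acgu", min_size=8, max_size=14))
    def test_mfe_is_lower_bound_over_enumeration(self, seq):
        mfe = fold_mfe(seq)
        for db in enumerate_structures(seq):
            assert mfe.energy <= evaluate_energy(seq, db) + 1e-9

    def test_mfe_equals_enumerated_minimum_on_random_sequences(self):
        rng = np.random.default_rng(77)
        for _ in range(25):
            seq = random_rna(rng, int(rng.integers(10, 15)))
            enumerated = min(evaluate_energy(seq, db)
                             for db in enumerate_structures(seq))
            assert fold_mfe(seq).energy == pytest.approx(min(enumerated, 0.0)), seq


class TestTerminalLoops:
    @pytest.mark.parametrize("db,expected", [
        ("((((...))))", 1),
        ("((..))..((..))", 2),
        ("..........", 0),
        ("((..((..))..((..))..))", 2),
    ])
    def test_examples(self, db, expected):
        assert count_terminal_loops(db) == expected

    def test_printed_structure_of_mir2062_has_one_loop(self, fixtures):
        assert count_terminal_loops(fixtures.structures["Hvi-miR2062"]) == 1

    def test_two_loop_printed_structures(self, fixtures):
        # these published structures branch, yet their mature stems do not
        for name in ("Hvi-miR9237", "Hvi-miR20768"):
            db = fixtures.structures[name]
            assert count_terminal_loops(db) == 2
            pre = fixtures.precursor(name).residues
            mat = fixtures.mature(name).residues
            pos = pre.find(mat)
            assert count_mature_stem_loops(db, (pos + 1, pos + len(mat))) == 1


class TestEvaluateHairpin:
    def test_printed_mir29035_passes(self, fixtures):
        name = "Hvi-miR29035"
        pre = fixtures.precursor(name).residues
        db = fixtures.structures[name]
        structure = SecondaryStructure.from_dotbracket(
            db, evaluate_energy(pre, db))
        pos = pre.find(fixtures.mature(name).residues)
        verdict = evaluate_hairpin(
            pre, structure, (pos + 1, pos + 22),
            HairpinCriteria(min_matched_pairs=15,
                            max_terminal_loops_on_mature_stem=1,
                            max_energy=0.0))
        assert verdict.passed, verdict.reasons

    def test_zero_pairs_fails_on_pair_count(self):
        seq = "a" * 30
        structure = SecondaryStructure.from_dotbracket("." * 30, 0.0)
        verdict = evaluate_hairpin(seq, structure, (1, 10))
        assert not verdict.passed
        assert "min_matched_pairs" in verdict.reasons

    def test_stricter_criteria_accept_fewer(self, fixtures):
        loose = HairpinCriteria(min_matched_pairs=10, max_energy=0.0)
        strict = HairpinCriteria(min_matched_pairs=30, max_energy=0.0)
        passed_loose, passed_strict = set(), set()
        for mat in fixtures.matures:
            pre = fixtures.precursor(mat.id).residues
            db = fixtures.structures[mat.id]
            structure = SecondaryStructure.from_dotbracket(
                db, evaluate_energy(pre, db))
            pos = pre.find(mat.residues)
            span = (pos + 1, pos + len(mat.residues))
            if evaluate_hairpin(pre, structure, span, loose).passed:
                passed_loose.add(mat.id)
            if evaluate_hairpin(pre, structure, span, strict).passed:
                passed_strict.add(mat.id)
        assert passed_strict <= passed_loose

    def test_mature_span_outside_candidate_raises(self):
        structure = SecondaryStructure.from_dotbracket("." * 10, 0.0)
        with pytest.raises(ValueError):
            evaluate_hairpin("a" * 10, structure, (5, 15))


class TestLocatePrecursor:
    def test_mature_is_prefix_of_its_own_precursor(self, fixtures):
        mature = fixtures.mature("Hvi-miR2062")
        precursor = fixtures.precursor("Hvi-miR2062")
        windows = locate_precursor(mature, precursor)
        assert windows  # occurrence at [1, 22]
        assert windows[0].mature_span == (1, 22)
        assert len(windows) == 2  # one 5'-arm and one 3'-arm window

    def test_absent_mature_gives_no_windows(self):
        mature = RNASequence("m", "ugcaacaguucuggcuuggcaa")
        transcript = RNASequence("t", "a" * 300)
        assert locate_precursor(mature, transcript) == []

    def test_two_occurrences_give_four_windows(self):
        core = "ugcaacaguucuggcuuggcaa"
        transcript = RNASequence("t", "gg" + core + "a" * 40 + core + "cc")
        windows = locate_precursor(RNASequence("m", core), transcript)
        assert len(windows) == 4


def perfect_hairpin(stem: str, loop: str = "gaaag"):
    from sharpmir.reads import reverse_complement
    return stem + loop + reverse_complement(stem)


class TestInferStar:
    def test_perfect_duplex_has_two_nt_overhangs(self):
        rng = np.random.default_rng(8)
        stem = random_rna(rng, 22)
        seq = perfect_hairpin(stem)
        structure = fold_mfe(seq)
        hp = HairpinPrecursor("x", seq, structure, (1, 22))
        star, span = infer_star(hp)
        # star = reverse complement of mature[3..22] extended 2 nt into the
        # loop side: its 3' end sits two short of the partner of mature
        # position 1, the 2-nt 3' overhang on each strand
        assert span == (26, 47)
        assert len(star) == 22

    def test_single_bulge_shortens_star_by_one(self):
        # mature arm carries a 1-nt bulge: 22-nt mature pairs a 21-nt star core
        from sharpmir.reads import reverse_complement
        rng = np.random.default_rng(12)
        left = random_rna(rng, 10)
        right = random_rna(rng, 11)
        mature = left + "a" + right  # 22 nt, "a" bulged out
        partner = reverse_complement(left + right)
        seq = mature + "gaaag" + partner
        db = "(" * 10 + "." + "(" * 11 + "....." + ")" * 21
        structure = SecondaryStructure.from_dotbracket(db, -1.0)
        hp = HairpinPrecursor("x", seq, structure, (1, 22))
        star, span = infer_star(hp)
        assert len(star) == 21

    def test_unpaired_mature_arm_is_uninferable(self):
        # mature (1-5) entirely unpaired, helix elsewhere
        seq = "aaaaa" + "gggg" + "aaaa" + "cccc"
        db = "....." + "((((" + "...." + "))))"
        structure = SecondaryStructure.from_dotbracket(db, -1.0)
        hp = HairpinPrecursor("x", seq, structure, (1, 5))
        with pytest.raises(StarInferenceError):
            infer_star(hp)

    def test_fixture_stars_never_overlap_matures(self, hairpins):
        for hp in hairpins:
            m5, m3 = hp.mature_span
            s5, s3 = hp.star_span
            assert s3 < m5 or s5 > m3
            assert 1 <= s5 <= s3 <= len(hp.residues)

    def test_star_of_star_recovers_mature_region(self):
        """On a perfect duplex, inferring the star of the star lands back on
        the mature arm (up to the 2-nt overhang bookkeeping)."""
        rng = np.random.default_rng(21)
        stem = random_rna(rng, 22)
        seq = perfect_hairpin(stem)
        structure = fold_mfe(seq)
        hp = HairpinPrecursor("x", seq, structure, (1, 22))
        star, span = infer_star(hp)
        hp2 = HairpinPrecursor("x*", seq, structure, span)
        star2, span2 = infer_star(hp2)
        # each application shifts both ends by its own 2-nt 3'-overhang
        # bookkeeping, so the round trip drifts by at most 2+2 nt per end
        assert abs(span2[0] - 1) <= 4 and abs(span2[1] - 22) <= 4
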