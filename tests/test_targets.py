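import numpy as np
import pytest

from conftest import random_rna
from oracles import best_duplex_score_bruteforce
from sharpmir.io_formats import RNASequence
from sharpmir.reads import reverse_complement
from sharpmir.targets import (ScoringScheme, align_duplex, duplex_energy,
                              predict_targets, rescore_columns, seed_filter)


def scheme(**kw):
    return ScoringScheme(**kw)


class TestAlignDuplex:
    def test_perfect_22mer_scores_230(self):
        rng = np.random.default_rng(1)
        mirna = RNASequence("m", random_rna(rng, 22))
        window = reverse_complement(mirna.residues)
        alignment = align_duplex(mirna, window, scheme())
        assert alignment.score == pytest.approx(8 * 5 * 4 + 14 * 5)
        assert all(c.kind == "watson_crick" for c in alignment.columns)

    def test_gu_wobble_is_recognised_in_seed(self):
        mirna = RNASequence("m", "aaguacguacguacguacguac".replace("t", "u"))
        window = list(reverse_complement(mirna.residues))
        # make miRNA position 4 (a 'u') pair 'g' instead of 'a': u:g wobble
        assert mirna.residues[3] == "u"
        window[len(window) - 4] = "g"
        alignment = align_duplex(mirna, "".join(window), scheme())
        kinds = {c.mirna_pos: c.kind for c in alignment.columns}
        assert kinds[4] == "gu"

    def test_emitted_columns_rescore_to_reported_score(self):
        rng = np.random.default_rng(7)
        sch = scheme()
        for _ in range(200):
            mirna = RNASequence("m", random_rna(rng, int(rng.integers(8, 23))))
            window = random_rna(rng, len(mirna.residues) + 8)
            alignment = align_duplex(mirna, window, sch)
            assert alignment.score == pytest.approx(
                rescore_columns(alignment, sch)), (mirna.residues, window)

    def test_matches_exhaustive_alignment_on_small_instances(self):
        rng = np.random.default_rng(11)
        sch = scheme()
        for _ in range(100):
            mirna = random_rna(rng, int(rng.integers(5, 11)))
            window = random_rna(rng, int(rng.integers(len(mirna), 15)))
            if len(window) < len(mirna):
                continue
            got = align_duplex(RNASequence("m", mirna), window, sch).score
            expected = best_duplex_score_bruteforce(mirna, window[::-1], sch)
            assert got == pytest.approx(expected), (mirna, window)

    def test_mirna_positions_each_consumed_once_in_order(self):
        rng = np.random.default_rng(3)
        mirna = RNASequence("m", random_rna(rng, 15))
        window = random_rna(rng, 23)
        alignment = align_duplex(mirna, window, scheme())
        consumed = [c.mirna_pos for c in alignment.columns
                    if c.kind != "gap_miRNA"]
        assert consumed == list(range(1, 16))


class TestDuplexEnergy:
    def test_perfect_complement_of_mir29035_passes_energy(self, fixtures):
        mirna = fixtures.mature("Hvi-miR29035")
        window = reverse_complement(mirna.residues)
        alignment = align_duplex(mirna, window, scheme())
        assert duplex_energy(alignment) <= -10.0

    def test_no_pairs_leaves_initiation_only(self):
        mirna = RNASequence("m", "aaaaaaaaaa")
        window = "a" * 18  # a:a columns are all mismatches
        alignment = align_duplex(mirna, window, scheme())
        assert duplex_energy(alignment) == pytest.approx(4.1)
        assert duplex_energy(alignment) > -10.0

    def test_energy_decreases_as_helix_grows(self):
        rng = np.random.default_rng(9)
        energies = []
        for length in (6, 10, 14, 18, 22):
            mirna = RNASequence("m", random_rna(rng, 22)[:length])
            alignment = align_duplex(mirna, reverse_complement(mirna.residues),
                                     scheme())
            energies.append(duplex_energy(alignment))
        assert energies == sorted(energies, reverse=True)


class TestSeedFilter:
    def make_perfect(self, seq="ugcaacaguucuggcuuggcaa"):
        mirna = RNASequence("m", seq)
        return mirna, reverse_complement(seq)

    def test_perfect_duplex_passes(self):
        mirna, window = self.make_perfect()
        ok, reasons = seed_filter(align_duplex(mirna, window, scheme()), scheme())
        assert ok and reasons == []

    def test_seed_mismatch_fails(self):
        mirna, window = self.make_perfect()
        w = list(window)
        w[len(w) - 4] = "c" if mirna.residues[3] != "g" else "a"  # break pos 4
        ok, reasons = seed_filter(align_duplex(mirna, "".join(w), scheme()),
                                  scheme())
        assert not ok
        assert "seed_mismatch" in reasons

    def test_two_seed_wobbles_fail(self):
        mirna = RNASequence("m", "auuacguacguacguacguacg")
        w = list(reverse_complement(mirna.residues))
        # positions 2 and 3 are 'u': pair them with 'g' -> two G:U in seed
        assert mirna.residues[1] == "u" and mirna.residues[2] == "u"
        w[len(w) - 2] = "g"
        w[len(w) - 3] = "g"
        ok, reasons = seed_filter(align_duplex(mirna, "".join(w), scheme()),
                                  scheme())
        assert not ok
        assert "seed_gu" in reasons


class TestPredictTargets:
    def test_embedded_complement_yields_one_site(self):
        rng = np.random.default_rng(5)
        mirna = RNASequence("m", random_rna(rng, 22))
        site_seq = reverse_complement(mirna.residues)
        transcript = RNASequence("t", random_rna(rng, 60) + site_seq +
                                 random_rna(rng, 60))
        sites = predict_targets(mirna, [transcript])
        assert len(sites) == 1
        lo, hi = sites[0].alignment.target_span
        assert transcript.residues[lo - 1:hi] == site_seq
        assert sites[0].alignment.score >= 145
        assert sites[0].energy <= -10

    def test_random_decoys_yield_no_sites(self):
        rng = np.random.default_rng(6)
        mirna = RNASequence("m", random_rna(rng, 22))
        decoys = [RNASequence(f"d{i}", random_rna(rng, 150)) for i in range(5)]
        assert predict_targets(mirna, decoys) == []

    def test_min_score_monotonicity(self):
        rng = np.random.default_rng(8)
        mirna = RNASequence("m", random_rna(rng, 22))
        transcript = RNASequence(
            "t", random_rna(rng, 30) + reverse_complement(mirna.residues) +
            random_rna(rng, 30))
        n145 = len(predict_targets(mirna, [transcript],
                                   ScoringScheme(min_score=145)))
        n200 = len(predict_targets(mirna, [transcript],
                                   ScoringScheme(min_score=200)))
        n231 = len(predict_targets(mirna, [transcript],
                                   ScoringScheme(min_score=231)))
        assert n145 >= n200 >= n231
        assert n231 == 0  # a perfect 22-mer scores exactly 230

    def test_deterministic_site_tables(self):
        rng = np.random.default_rng(10)
        mirna = RNASequence("m", random_rna(rng, 22))
        transcript = RNASequence(
            "t", random_rna(rng, 40) + reverse_complement(mirna.residues) +
            random_rna(rng, 40))
        a = predict_targets(mirna, [transcript])
        b = predict_targets(mirna, [transcript])
        assert [(s.alignment.target_span, s.alignment.score, s.energy)
                for s in a] == \
            [(s.alignment.target_span, s.alignment.score, s.energy)
             for s in b]

    def test_accepted_sites_satisfy_both_thresholds_on_reverification(self):
        rng = np.random.default_rng(13)
        sch = ScoringScheme()
        mirna = RNASequence("m", random_rna(rng, 22))
        parts = [random_rna(rng, 25), reverse_complement(mirna.residues),
                 random_rna(rng, 25), reverse_complement(mirna.residues),
                 random_rna(rng, 25)]
        transcript = RNASequence("t", "".join(parts))
        for site in predict_targets(mirna, [transcript], sch):
            assert site.alignment.score >= sch.min_score
            assert site.energy <= sch.max_energy
            assert rescore_columns(site.alignment, sch) == \
                pytest.approx(site.alignment.score)
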