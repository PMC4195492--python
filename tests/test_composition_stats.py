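"""Normalized oligonucleotide levels, dinucleotide ratios, deamination criteria."""

import numpy as np
import pytest

from genomesig import composition_stats as cs
from genomesig import seq_io, synthetic_data as sd
from genomesig.seq_io import reverse_complement

from conftest import make_fragment, random_fragment


class TestNormalizedLevel:
    def test_iid_uniform_is_near_one(self, rng):
        frags = [random_fragment(rng, length=100_000)]
        assert cs.normalized_level(frags, {"CG"}) == pytest.approx(1.0, abs=0.05)

    def test_alternating_cg_closed_form(self):
        # "CGCG...": half of all dinucleotide windows are CG; mono freqs are
        # C=G=0.5 so expected = 0.25 and the level is (0.5 / 0.25) = 2,
        # up to the single lost window at the boundary
        seq = "CG" * 200
        level = cs.normalized_level([seq], {"CG"})
        assert level == pytest.approx(2.0, rel=0.01)

    def test_generator_multiplier_recovery(self):
        preset = sd.SpeciesPreset("m", target_gc=0.43, oe_multipliers={"CG": 0.31})
        genome = sd.markov_genome(preset, 2_000_000, seed=9)
        level = cs.normalized_level([genome.records[0][1]], {"CG"})
        assert level == pytest.approx(0.31, abs=0.03)

    def test_invariant_to_fragment_order(self, rng):
        frags = [random_fragment(rng, length=1000) for _ in range(10)]
        a = cs.normalized_level(frags, {"CC", "GG"})
        b = cs.normalized_level(frags[::-1], {"CC", "GG"})
        assert a == b

    def test_strand_symmetric_sets_invariant_under_revcomp(self, rng):
        frags = [random_fragment(rng, length=2000) for _ in range(5)]
        rc = [make_fragment(reverse_complement(f.sequence)) for f in frags]
        for words in ({"CG"}, {"CC", "GG"}, {"CCC", "GGG"}):
            assert cs.normalized_level(frags, words) == pytest.approx(
                cs.normalized_level(rc, words), rel=1e-12
            )

    def test_missing_base_is_undefined(self):
        with pytest.raises(cs.UndefinedLevelError):
            cs.normalized_level(["AAAA" * 100], {"CG"})

    def test_mixed_word_lengths_rejected(self):
        with pytest.raises(ValueError):
            cs.normalized_level(["ACGT"], {"CG", "CCC"})


class TestDinucleotideRatio:
    def test_identity_ratio_is_exactly_one(self, rng):
        frags = [random_fragment(rng, length=5000)]
        assert cs.dinucleotide_ratio(frags, "CG", "CG") == 1.0

    def test_iid_cg_gc_near_one(self, rng):
        frags = [random_fragment(rng, length=200_000)]
        assert cs.dinucleotide_ratio(frags, "CG", "GC") == pytest.approx(1.0, abs=0.05)

    def test_deamination_shifts_all_three_ratios(self):
        preset = sd.SpeciesPreset("d", target_gc=0.45)
        base = sd.markov_genome(preset, 1_000_000, seed=11)
        mutated, _ = sd.deamination_genome(
            base, mutation_rounds=3, p=0.5, gc_protection=False, seed=12
        )
        seqs = [mutated.records[0][1]]
        assert cs.dinucleotide_ratio(seqs, "CG", "GC") < 1
        assert cs.dinucleotide_ratio(seqs, "TG", "GT") > 1
        assert cs.dinucleotide_ratio(seqs, "CA", "AC") > 1

    def test_zero_denominator_is_undefined(self):
        with pytest.raises(cs.UndefinedLevelError):
            cs.dinucleotide_ratio(["ATATAT" * 50], "AT", "CG")


def deamination_fixture(compensate=True, gc_protection=True, seed=2):
    base_preset = sd.SpeciesPreset(
        "deam", target_gc=0.45,
        isochore=sd.IsochoreSpec(seg_min=200_000, seg_max=800_000, gc_spread=0.08),
    )
    base = sd.markov_genome(base_preset, 4_000_000, seed=seed)
    mutated, _ = sd.deamination_genome(
        base, mutation_rounds=4, p=0.4,
        gc_protection=gc_protection, compensate=compensate, seed=seed + 1,
    )
    return seq_io.fragment_genome(mutated, 100_000)


class TestSimmenCriteria:
    def test_requires_thirty_fragments(self, rng):
        with pytest.raises(ValueError):
            cs.simmen_criteria([random_fragment(rng, length=200) for _ in range(5)])

    def test_iid_genome_fails_level_criteria(self):
        genome = sd.markov_genome(sd.SpeciesPreset("iid", target_gc=0.5), 4_000_000, seed=4)
        report = cs.simmen_criteria(seq_io.fragment_genome(genome, 100_000))
        by_name = {c.name: c for c in report.criteria}
        assert not by_name["i_genome_cg_suppression"].passed
        assert not by_name["ii_tg_ca_excess"].passed

    def test_protected_deamination_passes_all_four(self):
        report = cs.simmen_criteria(deamination_fixture())
        assert report.all_pass
        by_name = {c.name: c for c in report.criteria}
        assert by_name["iii_cg_vs_gc_positive"].statistic > 0.5
        assert by_name["iv_cg_vs_tg_ca_negative"].statistic < -0.5

    def test_uncompensated_depletion_flips_criterion_iv(self):
        report = cs.simmen_criteria(deamination_fixture(compensate=False))
        by_name = {c.name: c for c in report.criteria}
        assert by_name["i_genome_cg_suppression"].passed
        assert not by_name["iv_cg_vs_tg_ca_negative"].passed
        assert by_name["iv_cg_vs_tg_ca_negative"].statistic > 0

    def test_zero_variance_flags_not_evaluable(self):
        frags = ["ACGT" * 500] * 31
        report = cs.simmen_criteria(frags)
        by_name = {c.name: c for c in report.criteria}
        assert by_name["iii_cg_vs_gc_positive"].passed is None


class TestSignatureReport:
    def test_panel_contents_and_ranking(self):
        presets = {
            "lamprey_like": 0.78, "medaka_like": 0.46,
            "coelacanth_like": 0.31, "marsupial_like": 0.13,
        }
        levels = {}
        for i, (name, m) in enumerate(presets.items()):
            genome = sd.markov_genome(
                sd.SpeciesPreset(name, target_gc=0.42, oe_multipliers={"CG": m}),
                1_000_000, seed=20 + i,
            )
            report = cs.signature_report([genome.records[0][1]], name)
            assert set(report.levels) == {"CG", "CC+GG", "CCC+GGG", "CCCC+GGGG"}
            assert set(report.ratios) == {"CG/GC", "CA/AC", "TG/GT"}
            levels[name] = report.levels["CG"]
        ranked = sorted(levels, key=levels.get, reverse=True)
        assert ranked == ["lamprey_like", "medaka_like", "coelacanth_like", "marsupial_like"]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cs.signature_report([], "none")
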