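"""Generator calibration, determinism, deamination mass balance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genomesig import composition_stats as cs
from genomesig import seq_io, synthetic_data as sd


def dinuc_count(seq, word):
    return sum(
        1 for i in range(len(seq) - 1) if seq[i : i + 2].upper() == word
    )


class TestCalibration:
    def test_neutral_chain_is_independent(self):
        chain = sd.calibrate_chain(0.5)
        assert np.allclose(chain.realized_oe, 1.0, atol=1e-6)
        assert chain.gc == pytest.approx(0.5, abs=1e-4)

    @given(
        m=st.floats(0.1, 2.0),
        gc=st.floats(0.3, 0.6),
    )
    @settings(max_examples=30, deadline=None)
    def test_single_multiplier_hit_exactly(self, m, gc):
        chain = sd.calibrate_chain(gc, {"CG": m})
        assert chain.realized_oe[1, 2] == pytest.approx(m, rel=1e-3)
        assert chain.gc == pytest.approx(gc, abs=2e-4)

    def test_invalid_multiplier_rejected(self):
        with pytest.raises(ValueError):
            sd.SpeciesPreset("bad", oe_multipliers={"CG": -1})


class TestMarkovGenome:
    def test_same_seed_is_bit_identical(self):
        preset = sd.SpeciesPreset("t", target_gc=0.45, oe_multipliers={"CG": 0.4},
                                  repeat_fraction=0.1, n_run_rate=1e-5)
        a = sd.markov_genome(preset, 200_000, seed=7)
        b = sd.markov_genome(preset, 200_000, seed=7)
        assert a.records == b.records

    def test_different_seeds_differ(self):
        preset = sd.SpeciesPreset("t", target_gc=0.45)
        a = sd.markov_genome(preset, 50_000, seed=1)
        b = sd.markov_genome(preset, 50_000, seed=2)
        assert a.records != b.records

    def test_neutral_genome_cg_level_near_one(self):
        genome = sd.markov_genome(sd.SpeciesPreset("n", target_gc=0.5), 2_000_000, seed=3)
        assert cs.normalized_level([genome.records[0][1]], {"CG"}) == pytest.approx(
            1.0, abs=0.02
        )

    @pytest.mark.parametrize("m", [0.2, 0.5, 1.5])
    def test_multiplier_recovery_within_five_percent(self, m):
        preset = sd.SpeciesPreset("t", target_gc=0.42, oe_multipliers={"CG": m})
        genome = sd.markov_genome(preset, 2_000_000, seed=int(m * 10))
        level = cs.normalized_level([genome.records[0][1]], {"CG"})
        assert level == pytest.approx(m, rel=0.05)

    def test_repeat_blocks_are_lowercase_with_boosted_composition(self):
        preset = sd.SpeciesPreset(
            "r", target_gc=0.45, repeat_fraction=0.3,
            repeat_multipliers={"CC": 1.5, "GG": 1.5},
        )
        genome = sd.markov_genome(preset, 1_000_000, seed=5)
        seq = genome.records[0][1]
        lower = seq_io.lowercase_mask(seq)
        assert 0.15 < lower.mean() < 0.45
        repeat_seq = "".join(c for c in seq if c.islower())
        unique_seq = "".join(c for c in seq if c.isupper())
        rep = cs.normalized_level([repeat_seq], {"CC", "GG"})
        uni = cs.normalized_level([unique_seq], {"CC", "GG"})
        assert rep > uni + 0.2

    def test_n_runs_inserted(self):
        preset = sd.SpeciesPreset("n", target_gc=0.45, n_run_rate=5e-5)
        genome = sd.markov_genome(preset, 500_000, seed=6)
        assert "N" in genome.records[0][1]

    def test_isochore_mode_broadens_gc_spread(self):
        flat = sd.markov_genome(sd.SpeciesPreset("f", target_gc=0.45), 3_000_000, seed=8)
        iso = sd.markov_genome(
            sd.SpeciesPreset(
                "i", target_gc=0.45,
                isochore=sd.IsochoreSpec(seg_min=200_000, seg_max=500_000, gc_spread=0.08),
            ),
            3_000_000, seed=8,
        )
        def frag_gc_std(genome):
            frags = seq_io.fragment_genome(genome, 100_000)
            from genomesig.kmer_signature import mono_composition
            return np.std([mono_composition(f)[1] for f in frags])
        assert frag_gc_std(iso) > 5 * frag_gc_std(flat)


class TestDeamination:
    def test_zero_rounds_is_identity(self):
        base = sd.markov_genome(sd.SpeciesPreset("b", target_gc=0.45), 100_000, seed=1)
        out, counts = sd.deamination_genome(base, mutation_rounds=0, seed=2)
        assert out.records == base.records
        assert counts["cg_lost"] == 0

    def test_mass_conservation_cg_to_tg_ca(self):
        base = sd.markov_genome(sd.SpeciesPreset("b", target_gc=0.45), 500_000, seed=3)
        out, counts = sd.deamination_genome(
            base, mutation_rounds=3, p=0.5, gc_protection=False, seed=4
        )
        seq0, seq1 = base.records[0][1], out.records[0][1]
        cg_lost = dinuc_count(seq0, "CG") - dinuc_count(seq1, "CG")
        tg_gain = dinuc_count(seq1, "TG") - dinuc_count(seq0, "TG")
        ca_gain = dinuc_count(seq1, "CA") - dinuc_count(seq0, "CA")
        assert cg_lost == counts["cg_lost"]
        assert tg_gain + ca_gain == cg_lost
        assert tg_gain == counts["tg_gained"] and ca_gain == counts["ca_gained"]

    def test_tg_ca_levels_rise_as_cg_falls(self):
        base = sd.markov_genome(sd.SpeciesPreset("b", target_gc=0.45), 1_000_000, seed=5)
        out, _ = sd.deamination_genome(
            base, mutation_rounds=5, p=0.5, gc_protection=False, seed=6
        )
        seqs = [out.records[0][1]]
        assert cs.normalized_level(seqs, {"CG"}) < 0.4
        assert cs.normalized_level(seqs, {"TG"}) > 1
        assert cs.normalized_level(seqs, {"CA"}) > 1

    def test_invalid_probability_rejected(self):
        base = sd.markov_genome(sd.SpeciesPreset("b", target_gc=0.45), 50_000, seed=1)
        with pytest.raises(ValueError):
            sd.deamination_genome(base, p=1.5)


class TestCohort:
    def test_three_presets_give_expected_fragment_count(self):
        genomes = sd.cohort(
            ["coelacanth_like", "medaka_like", "lamprey_like"], 1_000_000, master_seed=1
        )
        assert len(genomes) == 3
        frags = [f for g in genomes for f in seq_io.fragment_genome(g, 100_000)]
        assert len(frags) == 30  # 3 presets x 10 windows (none N-filtered)

    def test_duplicate_labels_rejected(self):
        preset = sd.PRESETS["medaka_like"]
        with pytest.raises(ValueError):
            sd.cohort([preset, preset], 100_000)

    def test_cg_levels_rank_in_preset_order(self):
        order = ["lamprey_like", "medaka_like", "coelacanth_like", "marsupial_like"]
        genomes = sd.cohort(order, 2_000_000, master_seed=2)
        levels = [
            cs.normalized_level(
                [seq for _, seq in genome.records], {"CG"}
            )
            for genome in genomes
        ]
        assert levels == sorted(levels, reverse=True)

    def test_master_seed_reproducible(self):
        a = sd.cohort(["medaka_like"], 200_000, master_seed=9)
        b = sd.cohort(["medaka_like"], 200_000, master_seed=9)
        assert a[0].records == b[0].records
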