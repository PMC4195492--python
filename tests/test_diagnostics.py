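"""Per-lattice mono composition, observed/expected grids, territory contrast."""

import numpy as np
import pytest

from genomesig import blsom, diagnostics, kmer_signature as ks
from genomesig import seq_io, synthetic_data as sd

from conftest import make_fragment, random_fragment


def small_som(rng, fragments, k=2):
    key_map = ks.build_key_map(k, True)
    sig, fragments = ks.signature_matrix(fragments, key_map)
    X = sig[list(key_map.keys)].to_numpy()
    labels = sig["species_label"].tolist()
    grid = blsom.batch_train(blsom.pca_initialize(X, 10), X, epochs=30)
    assignment = blsom.assign(grid, X, labels)
    return key_map, sig, fragments, grid, assignment


class TestLatticeMonoComposition:
    def test_occupied_lattice_reflects_fragment_composition(self, rng):
        frags = [make_fragment("GGCC" * 100)] + [
            random_fragment(rng, length=400) for _ in range(40)
        ]
        key_map, sig, frags, grid, assignment = small_som(rng, frags)
        mono, from_data = diagnostics.lattice_mono_composition(
            grid, assignment, frags, key_map
        )
        i, j = assignment.coords[0]
        assert mono[i, j][1] + mono[i, j][2] > 0.9  # the GC-only fragment's cell

    def test_uniform_weight_marginal_gives_uniform_composition(self):
        key_map = ks.build_key_map(3, True)
        grid = blsom.SOMGrid(
            width=2, height=2, weights=np.full((2, 2, 32), 1 / 32)
        )
        assignment = blsom.LatticeAssignment(
            coords=np.empty((0, 2), dtype=int), labels=[], width=2, height=2, census={}
        )
        mono, from_data = diagnostics.lattice_mono_composition(
            grid, assignment, [], key_map
        )
        assert not from_data.any()
        assert np.allclose(mono, 0.25, atol=1e-12)

    def test_mean_matches_pooled_count_for_equal_length_fragments(self, rng):
        frags = [random_fragment(rng, length=500) for _ in range(30)]
        key_map, sig, frags, grid, assignment = small_som(rng, frags)
        mono, _ = diagnostics.lattice_mono_composition(grid, assignment, frags, key_map)
        # pick the most populated lattice point and pool its fragments
        (i, j), cell = max(assignment.census.items(), key=lambda kv: sum(kv[1].values()))
        pooled = "".join(
            f.sequence for f, c in zip(frags, assignment.coords) if tuple(c) == (i, j)
        )
        comp, _ = ks.mono_composition(make_fragment(pooled))
        assert np.allclose(mono[i, j], [comp[b] for b in "ACGT"], atol=1e-3)


class TestOEGrid:
    def test_uniform_composition_closed_form(self, rng):
        # i.i.d. uniform fragments: CG expected = 1/16 of windows, ratio ~ 1
        frags = [random_fragment(rng, length=5000) for _ in range(50)]
        key_map, sig, frags, grid, assignment = small_som(rng, frags)
        oe = diagnostics.oe_grid(grid, assignment, frags, sig, key_map, "CG")
        occupied = oe.n_fragments > 0
        assert np.nanmean(np.abs(oe.ratio[occupied] - 1.0)) < 0.1

    def test_iid_ratio_brackets_one(self, rng):
        frags = [random_fragment(rng, length=5000) for _ in range(60)]
        key_map, sig, frags, grid, assignment = small_som(rng, frags)
        oe = diagnostics.oe_grid(grid, assignment, frags, sig, key_map, "AC+GT")
        vals = oe.ratio[oe.n_fragments > 0]
        lo, hi = np.percentile(vals, [5, 95])
        assert lo <= 1.0 <= hi

    def test_suppressed_species_territory_recovers_multiplier(self, rng):
        preset = sd.SpeciesPreset("sup", target_gc=0.4, oe_multipliers={"CG": 0.3})
        genome = sd.markov_genome(preset, 2_000_000, seed=5)
        frags = seq_io.fragment_genome(genome, 50_000)
        key_map, sig, frags, grid, assignment = small_som(rng, frags)
        oe = diagnostics.oe_grid(grid, assignment, frags, sig, key_map, "CG")
        vals = oe.ratio[oe.n_fragments > 0]
        assert np.nanmean(vals) == pytest.approx(0.3, abs=0.03)

    def test_unknown_class_raises(self, rng):
        frags = [random_fragment(rng, length=500) for _ in range(30)]
        key_map, sig, frags, grid, assignment = small_som(rng, frags)
        with pytest.raises(KeyError):
            diagnostics.oe_grid(grid, assignment, frags, sig, key_map, "ZZ")


class TestTerritoryContrast:
    def test_identical_composition_gives_zero_difference(self, rng):
        frags = [
            random_fragment(rng, length=2000, species=f"sp{i % 2}") for i in range(40)
        ]
        key_map, sig, frags, grid, assignment = small_som(rng, frags)
        oe = diagnostics.oe_grid(grid, assignment, frags, sig, key_map, "CG")
        contrast = diagnostics.territory_contrast(oe, assignment, {"sp0"})
        assert abs(contrast["difference"]) < 0.1

    def test_cg_contrast_between_suppression_presets(self, rng):
        presets = [
            sd.SpeciesPreset("coel", target_gc=0.43, oe_multipliers={"CG": 0.31}),
            sd.SpeciesPreset("medaka", target_gc=0.405, oe_multipliers={"CG": 0.46}),
        ]
        genomes = sd.cohort(presets, 2_000_000, master_seed=3)
        frags = [f for g in genomes for f in seq_io.fragment_genome(g, 50_000)]
        key_map, sig, frags, grid, assignment = small_som(rng, frags)
        oe = diagnostics.oe_grid(grid, assignment, frags, sig, key_map, "CG")
        contrast = diagnostics.territory_contrast(oe, assignment, {"coel"})
        assert contrast["inside"] == pytest.approx(0.31, abs=0.05)
        assert contrast["outside"] == pytest.approx(0.46, abs=0.05)

    def test_cc_gg_excess_contrast_positive(self, rng):
        presets = [
            sd.SpeciesPreset("boosted", target_gc=0.42,
                             oe_multipliers={"CC": 1.3, "GG": 1.3}),
            sd.SpeciesPreset("plain", target_gc=0.42),
        ]
        genomes = sd.cohort(presets, 2_000_000, master_seed=4)
        frags = [f for g in genomes for f in seq_io.fragment_genome(g, 50_000)]
        key_map, sig, frags, grid, assignment = small_som(rng, frags, k=3)
        oe = diagnostics.oe_grid(grid, assignment, frags, sig, key_map, "CCC+GGG")
        contrast = diagnostics.territory_contrast(oe, assignment, {"boosted"})
        assert contrast["difference"] > 0

    def test_empty_partition_raises(self, rng):
        frags = [random_fragment(rng, length=500) for _ in range(30)]
        key_map, sig, frags, grid, assignment = small_som(rng, frags)
        oe = diagnostics.oe_grid(grid, assignment, frags, sig, key_map, "CG")
        with pytest.raises(ValueError):
            diagnostics.territory_contrast(oe, assignment, set())


def test_degenerate_label_grid_matches_member_pair(rng):
    # grids for a degenerate class queried via its single canonical label
    # and via the explicit member list are identical
    frags = [random_fragment(rng, length=2000) for _ in range(30)]
    key_map, sig, frags, grid, assignment = small_som(rng, frags)
    one = diagnostics.oe_grid(grid, assignment, frags, sig, key_map, "AC+GT")
    as_list = diagnostics.oe_grid(grid, assignment, frags, sig, key_map, ["AC+GT"])
    assert np.allclose(one.ratio, as_list.ratio, equal_nan=True)
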