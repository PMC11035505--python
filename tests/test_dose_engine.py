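import numpy as np
import pytest

from nmdose import dose, transport
from nmdose.nuclides import load_nuclide
from nmdose.phantoms import VoxelPhantom, make_point_scene, make_vial_phantom
from nmdose.physics import MATERIALS


class TestConversionTable:
    def test_exact_at_nodes(self):
        tab = dose.load_h10_table()
        for e, h in zip(tab.energies, tab.h10):
            assert dose.h10_per_fluence(e) == pytest.approx(h, rel=1e-12)

    def test_between_nodes_bounded(self):
        assert 0.61 < dose.h10_per_fluence(120.0) < 0.89

    def test_log_log_interpolation_oracle(self):
        # hand log-log interpolation between the 100 and 150 keV nodes
        e, e0, e1, h0, h1 = 140.511, 100.0, 150.0, 0.61, 0.89
        expected = h0 * (h1 / h0) ** (np.log(e / e0) / np.log(e1 / e0))
        assert dose.h10_per_fluence(e) == pytest.approx(expected, rel=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dose.h10_per_fluence(5.0)
        with pytest.raises(ValueError):
            dose.h10_per_fluence(5000.0)


class TestUnits:
    def test_zero(self):
        assert dose.convert_units(0.0) == 0.0

    def test_definition_arithmetic(self):
        assert dose.convert_units(1e-15) == pytest.approx(3.6, rel=1e-12)

    def test_round_trip(self):
        x = 2.345e-13
        assert dose.unconvert_units(dose.convert_units(x)) == pytest.approx(x, rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            dose.convert_units(-1.0)


class TestEffectiveDose:
    def test_uniform_dose_identity(self):
        # sum of tissue weights is exactly one
        weights = dose.load_tissue_weights()
        assert sum(weights.values()) == pytest.approx(1.0, abs=1e-15)
        doses = {t: 0.37 for t in weights}
        assert dose.effective_dose(doses, doses) == pytest.approx(0.37, rel=1e-12)

    def test_equal_sexes_reduce_to_single_weighted_sum(self):
        weights = dose.load_tissue_weights()
        rng = np.random.default_rng(0)
        doses = {t: float(rng.uniform(0.5, 2)) for t in weights}
        single = sum(w * doses[t] for t, w in weights.items())
        assert dose.effective_dose(doses, doses) == pytest.approx(single, rel=1e-12)

    def test_two_tissue_hand_value(self):
        weights = {"A": 0.12, "B": 0.88}
        e = dose.effective_dose({"A": 1.0, "B": 2.0}, {"A": 1.0, "B": 2.0}, weights)
        assert e == pytest.approx(1.88, rel=1e-12)

    def test_remainder_rule_and_missing_tissue(self):
        weights = {"A": 0.5, "B": 0.5}
        e = dose.effective_dose({"A": 1.0, "Remainder": 3.0},
                                {"A": 1.0, "Remainder": 3.0}, weights)
        assert e == pytest.approx(2.0)
        with pytest.raises(KeyError):
            dose.effective_dose({"A": 1.0}, {"A": 1.0}, weights)


class TestMonteCarloLimits:
    def test_vacuum_inverse_square_fluence(self, vacuum_point_phantom, mono140):
        # point isotropic source in vacuum: fluence = 1 / (4 pi r^2)
        for r in (30.0, 50.0, 80.0, 120.0, 200.0):
            scene = make_point_scene(vacuum_point_phantom, (0.0, r, 0.0))
            scene.ambient_material = "vacuum"
            tally = transport.mc_transport(scene, mono140, "Src", 5000, 11)
            expected = 1.0 / (4 * np.pi * r * r)
            flu = tally.fluence.sum()
            se = np.sqrt(np.sum(tally.fluence_se**2))
            assert abs(flu - expected) < 3 * se + 1e-3 * expected

    def test_slab_uncollided_fraction(self, mono140):
        # pencil beam through 10 cm of water: exp(-mu x) survives uncollided
        labels = np.zeros((8, 8, 24), dtype=np.int16)
        labels[:, :, 2:22] = 1
        labels[:, :, 0] = 2
        ph = VoxelPhantom(labels, 5.0, {1: ("Slab", "water"), 2: ("Src", "vacuum")},
                          (-2.0, -2.0, 0.0))
        scene = make_point_scene(ph, (0.0, 0.0, 500.0))
        scene.tally_point = None
        n = 40_000
        tally = transport.mc_transport(scene, mono140, "Src", n, 13,
                                       beam_direction=(0, 0, 1))
        p = np.exp(-MATERIALS["water"].mu(140.511) * 10.0)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(tally.uncollided_fraction - p) < 3 * se

    def test_same_seed_bit_identical(self, mono140):
        vial = make_vial_phantom()
        scene = make_point_scene(vial, (0.0, 100.0, 0.0))
        a = transport.mc_transport(scene, mono140, "Vial solution", 20_000, 17)
        b = transport.mc_transport(scene, mono140, "Vial solution", 20_000, 17)
        assert a.h10_per_particle == b.h10_per_particle
        assert np.array_equal(a.fluence, b.fluence)
        c = transport.mc_transport(scene, mono140, "Vial solution", 20_000, 18)
        assert c.h10_per_particle != a.h10_per_particle

    def test_energy_ledger_closes(self, mono140):
        vial = make_vial_phantom()
        scene = make_point_scene(vial, (0.0, 100.0, 0.0))
        t = transport.mc_transport(scene, mono140, "Vial solution", 10_000, 19)
        assert (t.energy_deposited + t.energy_escaped
                == pytest.approx(t.energy_emitted, rel=1e-9))

    def test_empty_source_region_rejected(self, mono140):
        vial = make_vial_phantom()
        scene = make_point_scene(vial, (0.0, 100.0, 0.0))
        with pytest.raises(KeyError):
            transport.mc_transport(scene, mono140, "Nonexistent", 100, 1)


class TestPointKernel:
    def test_vacuum_matches_analytic(self, vacuum_point_phantom):
        from nmdose.nuclides import EmissionLine, Radionuclide
        from nmdose.physics import E_GRID

        # a grid-node energy makes the engine's tabulated conversion exact,
        # isolating the geometric 1/(4 pi r^2) factor
        e_node = float(E_GRID[np.argmin(np.abs(E_GRID - 140.0))])
        mono = Radionuclide("node", 1000.0, (EmissionLine(e_node, 1.0),))
        r = 100.0
        scene = make_point_scene(vacuum_point_phantom, (0.0, r, 0.0))
        scene.ambient_material = "vacuum"
        factor = dose.point_kernel(scene, mono, "Src")
        expected = (dose.h10_per_fluence(e_node) / (4 * np.pi * r * r)
                    * dose.PSV_PER_DECAY_TO_USV_H_MBQ)
        assert factor.value == pytest.approx(expected, rel=1e-9)

    def test_inverse_square(self, vacuum_point_phantom, mono140):
        scene1 = make_point_scene(vacuum_point_phantom, (0.0, 60.0, 0.0))
        scene2 = make_point_scene(vacuum_point_phantom, (0.0, 120.0, 0.0))
        scene1.ambient_material = scene2.ambient_material = "vacuum"
        v1 = dose.point_kernel(scene1, mono140, "Src").value
        v2 = dose.point_kernel(scene2, mono140, "Src").value
        assert v1 / v2 == pytest.approx(4.0, rel=1e-9)

    def test_agrees_with_mc_on_vial(self):
        tc = load_nuclide("Tc99m")
        vial = make_vial_phantom()
        scene = make_point_scene(vial, (0.0, 100.0, 0.0))
        pk = dose.point_kernel(scene, tc, "Vial solution").value
        mc = dose.h10_factor(scene, tc, "Vial solution", 60_000, 23).value
        assert abs(pk - mc) / mc < 0.15


class TestVialReference:
    def test_distance_scaling_near_inverse_square(self):
        f1 = dose.vial_reference("Tc99m", n_histories=50_000, seed=3)
        f2 = dose.vial_reference("Tc99m", distance_m=2.0, n_histories=50_000, seed=3)
        # geometry dominates; ~1.7% residual air attenuation over the extra metre
        assert f1.value / f2.value == pytest.approx(4.0, rel=0.03)

    def test_bare_point_source_close_to_vial(self, mono140):
        # self-absorption in the half-filled vial is small at 140 keV
        tc = load_nuclide("Tc99m")
        vial_factor = dose.vial_reference(tc, n_histories=50_000, seed=5)
        labels = np.zeros((3, 3, 3), dtype=np.int16)
        labels[1, 1, 1] = 1
        bare = VoxelPhantom(labels, 2.0, {1: ("Src", "vacuum")}, (-0.3, -0.3, -0.3))
        scene = make_point_scene(bare, (0.0, 100.0, 0.0))
        pk = dose.point_kernel(scene, tc, "Src").value
        assert abs(vial_factor.value - pk) / pk < 0.10


class TestAdditivity:
    def test_factors_additive_over_source_regions(self, mono140):
        # activity-weighted sum over regions equals the mixed-source factor
        labels = np.zeros((5, 5, 5), dtype=np.int16)
        labels[1, 2, 2] = 1
        labels[3, 2, 2] = 2
        ph = VoxelPhantom(labels, 10.0, {1: ("A", "vacuum"), 2: ("B", "vacuum")},
                          (-2.5, -2.5, -2.5))
        scene = make_point_scene(ph, (0.0, 150.0, 0.0))
        scene.ambient_material = "vacuum"
        fa = dose.point_kernel(scene, mono140, "A").value
        fb = dose.point_kernel(scene, mono140, "B").value
        # a region covering both voxels equals the equal-weight mixture,
        # so per-region factors superpose linearly with activity fractions
        ph.label_map[1] = ("AB", "vacuum")
        ph.label_map[2] = ("AB", "vacuum")
        fab = dose.point_kernel(scene, mono140, "AB").value
        assert fab == pytest.approx(0.5 * fa + 0.5 * fb, rel=1e-9)
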