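import math

import numpy as np
import pytest

from protomer import (
    ConfigurationError,
    FEATURE_NAMES,
    Molecule,
    cba_polarizability,
    center_of_mass,
    compute_coe,
    element_counts,
    enumerate_models,
    featurize,
    interaction_angle,
    molecular_surface_area,
)
from protomer.elements import (
    ELECTRONEGATIVITY,
    POLARIZABILITY,
    VDW_RADIUS,
    atomic_mass,
)
import protomer.features

from conftest import random_rotation

ELEMENT_POOL = ["H", "C", "N", "O", "F", "S", "Cl", "Br"]


def _random_molecule(rng, n=None):
    n = n or int(rng.integers(2, 12))
    elements = list(rng.choice(ELEMENT_POOL, size=n))
    coords = rng.normal(scale=3.0, size=(n, 3))
    return Molecule("rand", elements, coords)


class TestCenterOfElectronegativity:
    def test_homonuclear_equals_centroid_and_com(self, rng):
        coords = rng.normal(size=(5, 3))
        mol = Molecule("c5", ["C"] * 5, coords)
        np.testing.assert_allclose(compute_coe(mol), coords.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(compute_coe(mol), center_of_mass(mol), atol=1e-12)

    def test_single_atom(self):
        mol = Molecule("n", ["N"], [[1.0, 2.0, 3.0]])
        np.testing.assert_allclose(compute_coe(mol), [1, 2, 3])

    def test_hf_hand_evaluation(self):
        hf = Molecule("hf", ["H", "F"], [[0, 0, 0], [0.92, 0, 0]])
        np.testing.assert_allclose(
            compute_coe(hf), [0.92 * 3.98 / (2.20 + 3.98), 0, 0], atol=1e-12
        )
        assert abs(compute_coe(hf)[0] - 0.5925) < 1e-3

    def test_matches_independent_weighted_mean(self, rng):
        for _ in range(200):
            mol = _random_molecule(rng)
            total = sum(ELECTRONEGATIVITY[el] for el in mol.elements)
            expected = sum(
                ELECTRONEGATIVITY[el] * mol.coords[i]
                for i, el in enumerate(mol.elements)
            ) / total
            np.testing.assert_allclose(compute_coe(mol), expected, atol=1e-12)

    def test_reduces_to_com_under_mass_weights(self, rng, monkeypatch):
        """COE and COM are the same weighted mean under swapped weight tables."""
        monkeypatch.setattr(protomer.features, "electronegativity", atomic_mass)
        for _ in range(20):
            mol = _random_molecule(rng)
            np.testing.assert_allclose(
                compute_coe(mol), center_of_mass(mol), atol=1e-12
            )

    def test_unknown_element_names_offender(self):
        mol = Molecule("xx", ["Xx"], [[0, 0, 0]])
        with pytest.raises(ConfigurationError, match="Xx"):
            compute_coe(mol)


class TestInteractionAngle:
    def test_orthogonal_rays(self):
        assert interaction_angle([1, 0, 0], [0, 0, 0], [0, 1, 0]) == pytest.approx(90.0)

    def test_antiparallel_rays(self):
        assert interaction_angle([1, 0, 0], [0, 0, 0], [-1, 0, 0]) == pytest.approx(
            180.0
        )

    def test_degenerate_geometry_flagged(self):
        angle, degenerate = interaction_angle(
            [1, 0, 0], [0, 1, 0], [0, 1, 0], with_flag=True
        )
        assert angle == 0.0 and degenerate
        _, ok = interaction_angle([1, 0, 0], [0, 0, 0], [0, 1, 0], with_flag=True)
        assert not ok


class TestSurfaceArea:
    def test_single_atom_analytic_sphere(self):
        for el in ("H", "O", "S"):
            mol = Molecule("a", [el], [[0.3, -1.2, 5.0]])
            r = VDW_RADIUS[el] + 1.4
            analytic = 4 * math.pi * r * r
            assert abs(molecular_surface_area(mol) - analytic) / analytic < 0.005

    def test_two_distant_atoms_additive(self):
        mol = Molecule("oo", ["O", "N"], [[0, 0, 0], [100.0, 0, 0]])
        analytic = sum(4 * math.pi * (VDW_RADIUS[el] + 1.4) ** 2 for el in ("O", "N"))
        assert abs(molecular_surface_area(mol) - analytic) / analytic < 0.005

    def test_rotation_invariance(self, toy_lib, rng):
        for name in ("water", "glycine", "pyridine"):
            mol = toy_lib[name]
            ref = molecular_surface_area(mol)
            for _ in range(10):
                moved = mol.copy()
                moved.coords = mol.coords @ random_rotation(rng).T + rng.normal(size=3)
                assert abs(molecular_surface_area(moved) - ref) / ref < 1e-6

    def test_against_monte_carlo_oracle(self, toy_lib, rng):
        """Independent check: random-direction dot sampling, no shared code."""
        for name in ("water", "ammonia", "acetic_acid", "imidazole", "ethane"):
            mol = toy_lib[name]
            radii = np.array([VDW_RADIUS[el] for el in mol.elements]) + 1.4
            n_dots = 20000
            total = 0.0
            for i in range(mol.n_atoms):
                dirs = rng.normal(size=(n_dots, 3))
                dirs /= np.linalg.norm(dirs, axis=1)[:, None]
                dots = mol.coords[i] + radii[i] * dirs
                ok = np.ones(n_dots, dtype=bool)
                for j in range(mol.n_atoms):
                    if j != i:
                        ok &= ((dots - mol.coords[j]) ** 2).sum(axis=1) > radii[j] ** 2
                total += 4 * math.pi * radii[i] ** 2 * ok.mean()
            impl = molecular_surface_area(mol)
            assert abs(impl - total) / total < 0.01


class TestCountsAndPolarizability:
    def test_water_counts(self, toy_lib):
        assert element_counts(toy_lib["water"]) == (1, 0, 0, 0)

    def test_freon_counts(self):
        mol = Molecule(
            "ccl3f",
            ["C", "Cl", "Cl", "Cl", "F"],
            [[0, 0, 0], [1.8, 0, 0], [0, 1.8, 0], [0, 0, 1.8], [-1.4, 0, 0]],
        )
        assert element_counts(mol) == (0, 0, 4, 0)

    def test_cysteine_counts(self, toy_lib):
        assert element_counts(toy_lib["cysteine"]) == (2, 1, 0, 1)

    def test_polarizability_table_lookup(self):
        assert cba_polarizability("O") == POLARIZABILITY["O"]
        assert cba_polarizability("N") > cba_polarizability("O")
        with pytest.raises(ConfigurationError, match="Xx"):
            cba_polarizability("Xx")


class TestFeaturize:
    def test_schema_has_ten_fields_in_order(self, toy_lib):
        model = enumerate_models(toy_lib["pyridine"], "[M+H]+")[0]
        vec = featurize(model)
        assert len(FEATURE_NAMES) == 10
        assert list(vec.as_dict()) == list(FEATURE_NAMES)
        assert vec.as_array().shape == (10,)

    def test_rigid_motion_invariance(self, toy_lib, rng):
        for name in ("glycine", "imidazole"):
            model = enumerate_models(toy_lib[name], "[M+H]+")[0]
            ref = featurize(model).as_array()
            for _ in range(10):
                moved = model.geometry.copy()
                moved.coords = (
                    model.geometry.coords @ random_rotation(rng).T + rng.normal(size=3)
                )
                clone = type(model)(
                    parent_name=model.parent_name,
                    mode=model.mode,
                    cba_index=model.cba_index,
                    geometry=moved,
                )
                np.testing.assert_allclose(featurize(clone).as_array(), ref, atol=1e-6)

    def test_only_cba_dependent_fields_change_with_cba(self, toy_lib):
        models = enumerate_models(toy_lib["glycine"], "[M+H]+")
        a = featurize(models[0])
        shared_geom_clone = type(models[0])(
            parent_name=models[0].parent_name,
            mode=models[0].mode,
            cba_index=models[1].cba_index,
            geometry=models[0].geometry,
        )
        b = featurize(shared_geom_clone)
        for field in ("dist_com_coe", "msa", "n_oxygen", "n_nitrogen",
                      "n_halogen", "n_othergen"):
            assert getattr(a, field) == getattr(b, field)
        assert a.cba_polarizability != b.cba_polarizability or (
            a.dist_cba_com != b.dist_cba_com
        )
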