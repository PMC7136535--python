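import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spincharge as sc
from spincharge.descriptors import SymmetryFunctionParams
from spincharge.errors import ConfigError, DegenerateGeometryError

from conftest import random_structure

P = SymmetryFunctionParams()


def naive_radial(structure, i, elem, p):
    """Independent triple-loop reference for the radial term."""
    total = 0.0
    for j in range(structure.n_atoms):
        if j == i or structure.elements[j] != elem:
            continue
        r = math.dist(structure.coords[i], structure.coords[j])
        if r < p.rc:
            fc = 0.5 * (math.cos(math.pi * r / p.rc) + 1.0)
        else:
            fc = 0.0
        total += math.exp(-p.eta * (r - p.rs) ** 2) * fc
    return total


def naive_angular(structure, i, ej, ek, p):
    """Independent reference for the angular term (unordered pairs)."""

    def fc(r):
        return 0.5 * (math.cos(math.pi * r / p.rc) + 1.0) if r < p.rc else 0.0

    total = 0.0
    n = structure.n_atoms
    for j in range(n):
        for k in range(j + 1, n):
            if i in (j, k):
                continue
            if {structure.elements[j], structure.elements[k]} != {ej, ek}:
                continue
            rij = math.dist(structure.coords[i], structure.coords[j])
            rik = math.dist(structure.coords[i], structure.coords[k])
            rjk = math.dist(structure.coords[j], structure.coords[k])
            vj = structure.coords[j] - structure.coords[i]
            vk = structure.coords[k] - structure.coords[i]
            cos_t = max(-1.0, min(1.0, float(np.dot(vj, vk)) / (rij * rik)))
            total += (
                (1.0 + p.lam * cos_t) ** p.zeta
                * math.exp(-p.eta * (rij**2 + rik**2 + rjk**2))
                * fc(rij) * fc(rik) * fc(rjk)
            )
    return 2.0 ** (1.0 - p.zeta) * total


class TestCutoff:
    @pytest.mark.parametrize(
        "r, expected", [(0.0, 1.0), (99.0, 0.0), (49.5, 0.5), (120.0, 0.0)]
    )
    def test_anchor_values(self, r, expected):
        assert sc.cutoff(r, 99.0) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(0.01, 50.0), st.floats(0.5, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_nonincreasing(self, r, rc):
        w = sc.cutoff(r, rc)
        assert 0.0 <= w <= 1.0
        assert sc.cutoff(min(r * 1.1, rc), rc) <= w + 1e-12

    def test_negative_distance_errors(self):
        with pytest.raises(ConfigError):
            sc.cutoff(-0.1, 99.0)


class TestRadialTerm:
    def test_single_neighbor_at_rs(self):
        # exp(0) * fc(1.0) evaluated by hand
        s = sc.Structure(("Fe", "O"), [[0, 0, 0], [1, 0, 0]], 0)
        expected = math.exp(0.0) * 0.5 * (math.cos(math.pi * 1.0 / 99.0) + 1.0)
        assert sc.radial_term(s, 0, "O", P) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.999748, abs=1e-6)

    def test_empty_sum_is_zero(self):
        s = sc.Structure(("Fe", "O"), [[0, 0, 0], [1, 0, 0]], 0)
        assert sc.radial_term(s, 0, "N", P) == 0.0

    def test_two_equidistant_neighbors_double_the_value(self):
        s1 = sc.Structure(("Fe", "O"), [[0, 0, 0], [1.3, 0, 0]], 0)
        s2 = sc.Structure(
            ("Fe", "O", "O"), [[0, 0, 0], [1.3, 0, 0], [-1.3, 0, 0]], 0
        )
        assert sc.radial_term(s2, 0, "O", P) == pytest.approx(
            2 * sc.radial_term(s1, 0, "O", P), rel=1e-12
        )


class TestAngularTerm:
    def test_right_angle_pair_value(self):
        s = sc.Structure(
            ("Fe", "O", "N"), [[0, 0, 0], [1, 0, 0], [0, 1, 0]], 0
        )
        got = sc.angular_term(s, 0, "O", "N", P)
        assert got == pytest.approx(naive_angular(s, 0, "O", "N", P), rel=1e-12)
        # single pair: (1+0) * e^-4 * fc(1)^2 * fc(sqrt 2)
        assert got == pytest.approx(0.018297, abs=1e-5)
        # symmetric in (J, K)
        assert got == sc.angular_term(s, 0, "N", "O", P)

    def test_collinear_opposite_neighbors_vanish(self):
        s = sc.Structure(
            ("Fe", "O", "O"), [[0, 0, 0], [1.2, 0, 0], [-1.2, 0, 0]], 0
        )
        assert sc.angular_term(s, 0, "O", "O", P) == pytest.approx(0.0, abs=1e-15)

    def test_single_fe_gives_zero_fe_fe_term(self, template):
        for i in (1, 5, 12):
            assert sc.angular_term(template, i, "Fe", "Fe", P) == 0.0


class TestLayout:
    def test_heme_composition_gives_19_components(self, template, heme_layout):
        assert heme_layout.size == 19
        assert len(heme_layout.radial_components) == 5
        assert len(heme_layout.angular_components) == 14
        assert heme_layout.dropped_components == (("Fe", "Fe"),)

    def test_water_drops_the_single_oxygen_pair(self):
        lay = sc.build_layout({"H": 2, "O": 1})
        assert lay.radial_components == ("H", "O")
        assert ("O", "O") in lay.dropped_components
        assert lay.size == 4

    def test_three_same_element_atoms(self):
        lay = sc.build_layout({"C": 3})
        assert lay.size == 2  # one radial + the C-C angular

    def test_layout_depends_only_on_composition(self):
        rng = np.random.default_rng(0)
        s = random_structure(rng, n_atoms=8)
        lay1 = sc.build_layout(s.composition())
        perm = rng.permutation(s.n_atoms)
        s2 = sc.Structure(
            tuple(s.elements[i] for i in perm), s.coords[perm], 0
        )
        assert sc.build_layout(s2.composition()) == lay1


class TestFeaturize:
    def test_matches_naive_oracle_on_random_structures(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            s = random_structure(rng)
            lay = sc.build_layout(s.composition())
            F = sc.featurize(s, lay)
            n_rad = len(lay.radial_components)
            for i in range(s.n_atoms):
                for c, e in enumerate(lay.radial_components):
                    assert F[i, c] == pytest.approx(
                        naive_radial(s, i, e, P), abs=1e-10
                    )
                for c, (ej, ek) in enumerate(lay.angular_components):
                    assert F[i, n_rad + c] == pytest.approx(
                        naive_angular(s, i, ej, ek, P), abs=1e-10
                    )

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        from scipy.spatial.transform import Rotation

        for _ in range(100):
            s = random_structure(rng)
            lay = sc.build_layout(s.composition())
            F = sc.featurize(s, lay)
            R = Rotation.random(random_state=int(rng.integers(1 << 31))).as_matrix()
            t = rng.uniform(-10, 10, 3)
            s2 = sc.Structure(s.elements, s.coords @ R.T + t, 0)
            np.testing.assert_allclose(sc.featurize(s2, lay), F, atol=1e-8)

    def test_same_element_swap_swaps_vectors(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            s = random_structure(rng, n_atoms=7)
            els = np.array(s.elements)
            # find two atoms of the same element, if any
            pairs = [
                (i, j)
                for i in range(7)
                for j in range(i + 1, 7)
                if els[i] == els[j]
            ]
            if not pairs:
                continue
            i, j = pairs[0]
            lay = sc.build_layout(s.composition())
            F = sc.featurize(s, lay)
            perm = np.arange(7)
            perm[[i, j]] = [j, i]
            s2 = sc.Structure(tuple(els[perm]), s.coords[perm], 0)
            F2 = sc.featurize(s2, lay)
            np.testing.assert_allclose(F2, F[perm], atol=1e-10)

    def test_distant_atom_beyond_cutoff_has_zero_vector(self):
        params = SymmetryFunctionParams(rc=5.0)
        s = sc.Structure(
            ("C", "C", "O"), [[0, 0, 0], [1.5, 0, 0], [20, 0, 0]], 0
        )
        lay = sc.build_layout(s.composition())
        F = sc.featurize(s, lay, params)
        np.testing.assert_allclose(F[2], 0.0, atol=1e-15)

    def test_rc_below_min_distance_zeroes_everything(self):
        rng = np.random.default_rng(3)
        s = random_structure(rng)
        lay = sc.build_layout(s.composition())
        F = sc.featurize(s, lay, SymmetryFunctionParams(rc=0.4))
        np.testing.assert_allclose(F, 0.0, atol=1e-15)

    def test_nonnegative_with_positive_lambda(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            s = random_structure(rng)
            lay = sc.build_layout(s.composition())
            assert (sc.featurize(s, lay) >= 0).all()


class TestInternalCoordinates:
    def test_distance_angle_anchors(self):
        assert sc.distance((0, 0, 0), (0, 0, 0.74)) == pytest.approx(0.74)
        assert sc.angle((1, 0, 0), (0, 0, 0), (0, 1, 0)) == pytest.approx(90.0)

    def test_dihedral_trans_and_perpendicular(self):
        a, b, c = (0, 1, 0), (0, 0, 0), (1, 0, 0)
        assert sc.dihedral(a, b, c, (1, -1, 0)) == pytest.approx(180.0)
        got = sc.dihedral(a, b, c, (1, 0, 1))
        # independent plane-normal oracle
        n1 = np.cross(np.subtract(b, a), np.subtract(c, b))
        n2 = np.cross(np.subtract(c, b), np.subtract((1, 0, 1), c))
        mag = math.degrees(
            math.acos(
                np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
            )
        )
        assert abs(got) == pytest.approx(mag, abs=1e-9)
        # right-hand convention about b->c: positive when n1 x n2 opposes b2
        sign = -np.sign(np.dot(np.cross(n1, n2), np.subtract(c, b)))
        assert np.sign(got) == sign

    def test_dihedral_collinear_errors(self):
        with pytest.raises(DegenerateGeometryError):
            sc.dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))

    def test_default_definition_has_11_components(self, template):
        defn = sc.default_internal_definition()
        assert defn.size == 11
        v = sc.internal_descriptors(template, defn)
        assert v.shape == (11,)
        # Fe-N1 template reference distance
        assert v[0] == pytest.approx(2.0)
        assert v[7] == pytest.approx(1.25)  # O12-O13 bond

    def test_internal_vector_is_rigid_motion_invariant(self, template):
        from scipy.spatial.transform import Rotation

        defn = sc.default_internal_definition()
        v = sc.internal_descriptors(template, defn)
        R = Rotation.from_euler("zyx", [20, -40, 75], degrees=True).as_matrix()
        moved = sc.Structure(
            template.elements, template.coords @ R.T + [1.0, -2.0, 0.5], 0
        )
        np.testing.assert_allclose(
            sc.internal_descriptors(moved, defn), v, atol=1e-8
        )

    def test_empty_definition_gives_empty_vector(self, template):
        v = sc.internal_descriptors(
            template, sc.InternalDescriptorDefinition()
        )
        assert v.size == 0
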