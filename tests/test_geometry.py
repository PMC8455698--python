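"""Geometry: distances, bond perception, angles, torsions, bond paths."""

import numpy as np
import pytest

from jcouple.geometry import (
    BondGraph,
    bond_angle,
    coupling_path,
    dihedral_angle,
    geometric_angles,
    infer_bonds,
    nearest_neighbor,
    pairwise_distances,
)
from jcouple.io import Molecule

from conftest import ethane_bonds, make_molecule, random_molecule, staggered_ethane


class TestDistances:
    def test_simple_pair(self):
        mol = make_molecule("m", ["C", "H"], [[0, 0, 0], [0, 0, 1.5]])
        assert pairwise_distances(mol)[0, 1] == pytest.approx(1.5)

    def test_symmetric_zero_diagonal(self):
        mol = random_molecule(np.random.default_rng(0))
        d = pairwise_distances(mol)
        np.testing.assert_allclose(d, d.T)
        np.testing.assert_allclose(np.diag(d), 0)

    def test_matches_per_pair_norm_oracle(self):
        rng = np.random.default_rng(1)
        mol = random_molecule(rng, n_atoms=6)
        d = pairwise_distances(mol)
        for i in range(6):
            for j in range(6):
                expect = float(np.sqrt(((mol.coords[i] - mol.coords[j]) ** 2).sum()))
                assert d[i, j] == pytest.approx(expect, abs=1e-12)


class TestInferBonds:
    def test_h2_bonded_at_default_scale(self):
        mol = make_molecule("h2", ["H", "H"], [[0, 0, 0], [0, 0, 0.74]])
        # 0.74 <= 1.3 * (0.31 + 0.31): the default cutoff captures H2
        assert infer_bonds(mol).n_bonds == 1

    def test_single_atom_no_bonds(self):
        mol = make_molecule("c", ["C"], [[0, 0, 0]])
        assert infer_bonds(mol).n_bonds == 0

    def test_ethane_brute_force_oracle(self, ethane):
        bonds = infer_bonds(ethane)
        assert bonds.n_bonds == 7
        # brute force over all pairs with the radius rule (no H cap needed here)
        from jcouple.geometry import COVALENT_RADII

        d = pairwise_distances(ethane)
        expected = set()
        for i in range(8):
            for j in range(i + 1, 8):
                r = COVALENT_RADII[ethane.elements[i]] + COVALENT_RADII[ethane.elements[j]]
                if d[i, j] <= 1.3 * r:
                    expected.add((i, j))
        assert bonds.edges == expected

    def test_hydrogen_keeps_single_shortest_bond(self):
        # H placed between two carbons, nearer the first
        mol = make_molecule(
            "m", ["C", "H", "C"], [[0, 0, 0], [0, 0, 1.0], [0, 0, 2.1]]
        )
        bonds = infer_bonds(mol)
        assert all(
            sum(1 for e in bonds.edges if i in e) <= 1
            for i, el in enumerate(mol.elements)
            if el == "H"
        )
        assert (0, 1) in bonds.edges and (1, 2) not in bonds.edges

    def test_disconnected_molecule_warns(self):
        mol = make_molecule("m", ["C", "C"], [[0, 0, 0], [0, 0, 9.0]])
        with pytest.warns(UserWarning, match="disconnected"):
            infer_bonds(mol)


class TestAngles:
    def test_collinear_and_perpendicular(self):
        mol = make_molecule(
            "m", ["C", "C", "C", "C"],
            [[1, 0, 0], [0, 0, 0], [-1, 0, 0], [0, 1, 0]],
        )
        assert bond_angle(mol, 0, 1, 2) == pytest.approx(180.0)
        assert bond_angle(mol, 0, 1, 3) == pytest.approx(90.0)

    def test_methane_tetrahedral_angle(self, methane_ideal):
        expect = float(np.degrees(np.arccos(-1.0 / 3.0)))  # 109.4712...
        assert bond_angle(methane_ideal, 1, 0, 2) == pytest.approx(expect, abs=1e-6)

    def test_zero_length_arm_rejected(self):
        mol = make_molecule("m", ["C", "H"], [[0, 0, 0], [0, 0, 1]])
        with pytest.raises(ValueError):
            bond_angle(mol, 0, 0, 1)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        mol = random_molecule(rng, 5)
        assert bond_angle(mol, 0, 1, 2) == pytest.approx(bond_angle(mol, 2, 1, 0))


class TestDihedral:
    def test_planar_cis_is_zero(self):
        mol = make_molecule(
            "m", ["C"] * 4, [[1, 1, 0], [1, 0, 0], [-1, 0, 0], [-1, 1, 0]]
        )
        assert dihedral_angle(mol, 0, 1, 2, 3) == pytest.approx(0.0, abs=1e-9)

    def test_planar_trans_is_180(self):
        mol = make_molecule(
            "m", ["C"] * 4, [[1, 1, 0], [1, 0, 0], [-1, 0, 0], [-1, -1, 0]]
        )
        assert dihedral_angle(mol, 0, 1, 2, 3) == pytest.approx(180.0, abs=1e-9)

    def test_staggered_ethane_is_60(self, ethane):
        # H2-C0-C1-H5 across the C-C bond of a staggered conformer
        assert dihedral_angle(ethane, 2, 0, 1, 5) == pytest.approx(60.0, abs=1e-5)

    def test_reversal_symmetry(self):
        rng = np.random.default_rng(4)
        mol = random_molecule(rng, 4)
        a = dihedral_angle(mol, 0, 1, 2, 3)
        b = dihedral_angle(mol, 3, 2, 1, 0)
        assert a == pytest.approx(b, abs=1e-9)

    def test_degenerate_returns_none(self):
        mol = make_molecule(
            "m", ["C"] * 4, [[2, 0, 0], [1, 0, 0], [0, 0, 0], [0, 1, 0]]
        )
        assert dihedral_angle(mol, 0, 1, 2, 3) is None


class TestGeometricAngles:
    def test_collinear_ends_give_zero(self):
        mol = make_molecule(
            "m", ["H", "C", "H"], [[0, 0, 0], [0, 0, 1.0], [0, 0, 2.2]]
        )
        a0, a1 = geometric_angles(mol, 0, 2)
        # partner and nearest neighbour lie on the same ray from each end
        assert a0 == pytest.approx(0.0, abs=1e-9)
        assert a1 == pytest.approx(0.0, abs=1e-9)

    def test_right_angle_tripod(self):
        # vertex atom0 at the origin; partner along x, nearest atom along y
        mol = make_molecule(
            "m", ["H", "C", "H"], [[0, 0, 0], [0, 0.9, 0], [1.0, 0, 0]]
        )
        a0, _ = geometric_angles(mol, 0, 2)
        assert a0 == pytest.approx(90.0, abs=1e-9)

    def test_two_atom_molecule_absent(self, h2):
        assert geometric_angles(h2, 0, 1) == (None, None)

    def test_nearest_neighbor_oracle(self):
        rng = np.random.default_rng(5)
        mol = random_molecule(rng, 7)
        d = pairwise_distances(mol)
        for i0, i1 in [(0, 1), (2, 5), (6, 3)]:
            a0, a1 = geometric_angles(mol, i0, i1)
            for center, partner, val in ((i0, i1, a0), (i1, i0, a1)):
                row = d[center].copy()
                row[center] = np.inf
                nn = int(np.argmin(row))
                if nn == partner:
                    assert val is None
                else:
                    assert val == pytest.approx(bond_angle(mol, partner, center, nn))

    def test_nearest_neighbor_function(self, ethane):
        # every hydrogen's closest atom is its parent carbon
        for i in range(2, 5):
            assert nearest_neighbor(ethane, i) == 0


class TestCouplingPath:
    def test_bonded_pair_and_ethane_hh(self, ethane):
        bonds = ethane_bonds(ethane)
        assert coupling_path(bonds, 0, 1) == [0, 1]
        assert coupling_path(bonds, 2, 5) == [2, 0, 1, 5]  # H...H over C-C

    def test_too_long_or_disconnected_absent(self, ethane):
        bonds = ethane_bonds(ethane)
        assert coupling_path(bonds, 2, 5, max_len=2) is None
        lonely = BondGraph(n_atoms=3, edges={(0, 1)}, lengths={(0, 1): 1.0})
        assert coupling_path(lonely, 0, 2) is None

    def test_tie_break_lexicographic(self):
        # diamond 0-1-3 / 0-2-3: both shortest; intermediate 1 < 2 wins
        g = BondGraph(
            n_atoms=4,
            edges={(0, 1), (0, 2), (1, 3), (2, 3)},
            lengths={(0, 1): 1, (0, 2): 1, (1, 3): 1, (2, 3): 1},
        )
        assert coupling_path(g, 0, 3) == [0, 1, 3]

    def test_exhaustive_enumeration_oracle(self, ethane):
        bonds = ethane_bonds(ethane)

        def brute(i, j, max_len=3):
            best = None
            stack = [[i]]
            while stack:
                path = stack.pop()
                if len(path) - 1 > max_len:
                    continue
                if path[-1] == j:
                    key = (len(path), path[1:-1])
                    if best is None or key < (len(best), best[1:-1]):
                        best = path
                    continue
                for w in bonds.neighbors(path[-1]):
                    if w not in path:
                        stack.append(path + [w])
            return best

        for i in range(8):
            for j in range(8):
                if i != j:
                    assert coupling_path(bonds, i, j) == brute(i, j)


class TestInvariances:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rigid_motion_leaves_geometry_unchanged(self, seed):
        rng = np.random.default_rng(seed)
        mol = random_molecule(rng, 6)
        # random rotation (QR of a Gaussian) + translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        moved = Molecule(
            name="m", elements=mol.elements, coords=mol.coords @ q.T + rng.normal(size=3)
        )
        np.testing.assert_allclose(
            pairwise_distances(mol), pairwise_distances(moved), atol=1e-9
        )
        assert bond_angle(mol, 0, 1, 2) == pytest.approx(
            bond_angle(moved, 0, 1, 2), abs=1e-9
        )
        a, b = dihedral_angle(mol, 0, 1, 2, 3), dihedral_angle(moved, 0, 1, 2, 3)
        if a is not None:
            assert a == pytest.approx(b, abs=1e-9)

    def test_angles_in_range(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            mol = random_molecule(rng, 5)
            assert 0 <= bond_angle(mol, 0, 1, 2) <= 180
            phi = dihedral_angle(mol, 0, 1, 2, 3)
            if phi is not None:
                assert 0 <= phi <= 180
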