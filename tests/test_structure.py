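"""Structure metrics: SASA, interface burial, rigid superposition."""

import numpy as np
import pytest

from gagntd.structure import (
    PROBE_RADIUS,
    VDW_RADII,
    StructureModel,
    buried_interface_area,
    kabsch_rotation,
    read_structure,
    sasa,
    superpose_rmsd,
)


def make_model(coords, elements=None, chains=None, resnums=None,
               atom_names=None):
    n = len(coords)
    return StructureModel(
        coords=np.asarray(coords, float),
        elements=np.array(elements or ["C"] * n),
        chains=np.array(chains or ["A"] * n),
        residue_numbers=np.array(resnums if resnums is not None else range(1, n + 1)),
        residue_names=np.array(["ALA"] * n),
        atom_names=np.array(atom_names or ["CA"] * n),
        occupancies=np.ones(n),
    )


PDB_FIXTURE = """\
ATOM      1  N   MET A   9      11.104   6.134  -6.504  1.00 20.00           N
ATOM      2  CA  MET A   9      12.560   6.351  -6.590  1.00 20.00           C
ATOM      3  CA ALEU A  10      12.560   8.351  -6.590  0.40 18.00           C
ATOM      4  CA BLEU A  10      12.000   8.000  -6.000  0.60 18.00           C
ATOM      5  CA  GLY B   9       0.000   0.000   0.000  1.00 15.00           C
HETATM    6  O   HOH A 101      30.000  30.000  30.000  1.00 30.00           O
HETATM    7 MG    MG A 201      31.000  31.000  31.000  1.00 30.00          MG
END
"""


class TestReadStructure:
    @pytest.fixture()
    def pdb_path(self, tmp_path):
        p = tmp_path / "fixture.pdb"
        p.write_text(PDB_FIXTURE)
        return p

    def test_atom_count_and_coordinates(self, pdb_path):
        m = read_structure(pdb_path)
        # waters and heteroatoms dropped, altloc pair collapsed to one atom
        assert len(m) == 4
        np.testing.assert_allclose(m.coords[0], [11.104, 6.134, -6.504])

    def test_highest_occupancy_altloc_kept(self, pdb_path):
        m = read_structure(pdb_path)
        leu = m.coords[(m.residue_numbers == 10) & (m.chains == "A")]
        np.testing.assert_allclose(leu[0], [12.0, 8.0, -6.0])  # occ 0.60

    def test_chains_preserved(self, pdb_path):
        m = read_structure(pdb_path)
        assert set(m.chains) == {"A", "B"}

    def test_malformed_file_raises(self, tmp_path):
        bad = tmp_path / "bad.pdb"
        bad.write_text("ATOM this is not a valid record\n")
        with pytest.raises(Exception):
            read_structure(bad)


class TestSASA:
    def test_isolated_atom_matches_analytic_sphere(self):
        m = make_model([[0.0, 0.0, 0.0]])
        r = VDW_RADII["C"] + PROBE_RADIUS
        assert sasa(m)[0] == pytest.approx(4 * np.pi * r**2, rel=1e-6)

    def test_distant_atoms_are_additive(self):
        m = make_model([[0, 0, 0], [100, 0, 0]], elements=["N", "S"])
        areas = sasa(m)
        rn = VDW_RADII["N"] + PROBE_RADIUS
        rs = VDW_RADII["S"] + PROBE_RADIUS
        assert areas[0] == pytest.approx(4 * np.pi * rn**2, rel=1e-6)
        assert areas[1] == pytest.approx(4 * np.pi * rs**2, rel=1e-6)

    def test_fully_buried_atom_has_no_area(self):
        """An atom caged inside a dense shell of neighbours is inaccessible."""
        shell = []
        golden = np.pi * (3 - 5**0.5)
        for i in range(60):
            z = 1 - 2 * (i + 0.5) / 60
            rho = np.sqrt(1 - z * z)
            phi = golden * i
            shell.append([3.0 * rho * np.cos(phi), 3.0 * rho * np.sin(phi), 3.0 * z])
        m = make_model([[0.0, 0.0, 0.0]] + shell)
        assert sasa(m)[0] == pytest.approx(0.0, abs=1e-6)

    def test_two_sphere_overlap_matches_cap_formula(self):
        """Two identical intersecting spheres: each loses a cap of height
        h = R - d/2 (area 2 pi R h)."""
        d = 2.0
        m = make_model([[0, 0, 0], [d, 0, 0]])
        r = VDW_RADII["C"] + PROBE_RADIUS
        h = r - d / 2
        expected = 2 * (4 * np.pi * r**2 - 2 * np.pi * r * h)
        assert sasa(m).sum() == pytest.approx(expected, rel=2e-3)

    def test_sampling_convergence_below_one_percent(self):
        rng = np.random.default_rng(4)
        m = make_model(rng.normal(scale=3.0, size=(30, 3)))
        a1 = sasa(m, points_per_atom=480).sum()
        a2 = sasa(m, points_per_atom=960).sum()
        assert abs(a1 - a2) / a2 < 0.01

    def test_probe_growth_inflates_accessible_surface(self):
        """For a convex solute the accessible surface is the outward offset
        surface: it grows with probe radius, and so does the buried area of
        an overlapping pair."""
        single = make_model([[0.0, 0.0, 0.0]])
        areas = [sasa(single, probe_radius=w)[0] for w in (1.0, 1.4, 2.0)]
        assert areas[0] < areas[1] < areas[2]
        pair = make_model([[0, 0, 0], [2.0, 0, 0]], chains=["A", "B"])
        buried = [buried_interface_area(pair, ["A"], ["B"], probe_radius=w).per_monomer
                  for w in (1.0, 1.4, 2.0)]
        assert buried[0] < buried[1] < buried[2]

    def test_cross_check_against_independent_implementation(self):
        """Total SASA of a random cluster agrees with biotite's
        Shrake-Rupley to ~2 % when using the same radii."""
        import biotite.structure as biotite_struc

        rng = np.random.default_rng(7)
        coords = rng.normal(scale=4.0, size=(40, 3))
        m = make_model(coords)
        ours = sasa(m, points_per_atom=960).sum()
        arr = biotite_struc.AtomArray(40)
        arr.coord = coords.astype(np.float32)
        arr.chain_id[:] = "A"
        arr.res_id[:] = np.arange(1, 41)
        arr.res_name[:] = "ALA"
        arr.atom_name[:] = "CA"
        arr.element[:] = "C"
        theirs = biotite_struc.sasa(
            arr, probe_radius=1.4, point_number=960,
            vdw_radii=np.full(40, VDW_RADII["C"]),
        ).sum()
        assert ours == pytest.approx(theirs, rel=0.02)


class TestInterfaceArea:
    def test_two_sphere_dimer_matches_cap_oracle(self):
        d = 2.0
        m = make_model([[0, 0, 0], [d, 0, 0]], chains=["A", "B"])
        r = VDW_RADII["C"] + PROBE_RADIUS
        h = r - d / 2
        res = buried_interface_area(m, ["A"], ["B"])
        assert res.per_monomer == pytest.approx(2 * np.pi * r * h, rel=5e-3)
        assert res.total_delta == pytest.approx(2 * res.per_monomer)

    def test_separated_chains_bury_nothing(self):
        m = make_model([[0, 0, 0], [100, 0, 0]], chains=["A", "B"])
        with pytest.warns(UserWarning, match="do not contact"):
            res = buried_interface_area(m, ["A"], ["B"])
        assert res.per_monomer == pytest.approx(0.0, abs=1e-9)
        assert not res.contacting

    def test_chain_sets_must_be_disjoint(self):
        m = make_model([[0, 0, 0], [2, 0, 0]], chains=["A", "B"])
        with pytest.raises(ValueError):
            buried_interface_area(m, ["A"], ["A"])


class TestSuperposition:
    @staticmethod
    def rigid_copy(coords, theta=0.8, shift=(3.0, -2.0, 5.0)):
        rot = np.array([
            [np.cos(theta), -np.sin(theta), 0.0],
            [np.sin(theta), np.cos(theta), 0.0],
            [0.0, 0.0, 1.0],
        ])
        return coords @ rot.T + np.asarray(shift)

    def test_rigid_copy_has_zero_rmsd(self):
        rng = np.random.default_rng(1)
        p = rng.normal(size=(25, 3))
        res = superpose_rmsd(make_model(p), make_model(self.rigid_copy(p)))
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert res.n_atoms == 25

    def test_rmsd_symmetric_in_arguments(self):
        rng = np.random.default_rng(2)
        p = rng.normal(size=(25, 3))
        q = p + rng.normal(scale=0.3, size=p.shape)
        ab = superpose_rmsd(make_model(p), make_model(q)).rmsd
        ba = superpose_rmsd(make_model(q), make_model(p)).rmsd
        assert ab == pytest.approx(ba, rel=1e-10)

    def test_invariant_under_rigid_motion_of_either_input(self):
        rng = np.random.default_rng(3)
        p = rng.normal(size=(25, 3))
        q = p + rng.normal(scale=0.3, size=p.shape)
        base = superpose_rmsd(make_model(p), make_model(q)).rmsd
        moved = superpose_rmsd(make_model(self.rigid_copy(p)), make_model(q)).rmsd
        assert moved == pytest.approx(base, rel=1e-9)

    def test_single_perturbed_atom_rmsd(self):
        """Perturbing one of N atoms by delta gives ~ delta/sqrt(N) before
        the re-superposition correction."""
        rng = np.random.default_rng(5)
        p = rng.normal(scale=10.0, size=(100, 3))
        q = p.copy()
        q[0] += [0.8, 0.0, 0.0]
        res = superpose_rmsd(make_model(p), make_model(q))
        assert res.rmsd == pytest.approx(0.8 / np.sqrt(100), rel=0.05)

    def test_collinear_selection_rejected(self):
        p = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
        with pytest.raises(ValueError, match="collinear|degenerate"):
            kabsch_rotation(p, p + 1.0)

    def test_pairing_respects_chain_map_and_shared_residues(self):
        p = np.random.default_rng(9).normal(scale=5.0, size=(10, 3))
        a = make_model(p, chains=["X"] * 10, resnums=list(range(1, 11)))
        # partner has only residues 3..10, under a different chain name
        b = make_model(p[2:], chains=["Y"] * 8, resnums=list(range(3, 11)))
        res = superpose_rmsd(a, b, chain_map={"X": "Y"})
        assert res.n_atoms == 8
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)

    def test_reflection_not_allowed(self):
        """A mirrored copy cannot be superposed to zero: the proper-rotation
        constraint forbids reflections."""
        rng = np.random.default_rng(6)
        p = rng.normal(size=(25, 3))
        mirrored = p * np.array([-1.0, 1.0, 1.0])
        res = superpose_rmsd(make_model(p), make_model(mirrored))
        assert res.rmsd > 0.1
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, rel=1e-9)
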