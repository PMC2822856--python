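"""Structure parsing, centroid reduction, superposition and RMSF."""

import logging

import numpy as np
import pytest

from mhc2struct import (
    EmptyStructureError,
    InputError,
    ParseError,
    ReductionError,
    backbone_rmsf,
    read_structure,
    reduce,
    superpose,
    virtual_cbeta,
)
from mhc2struct.structio import CBETA_BOND_LENGTH

from conftest import atom_line


class TestReadStructure:
    def test_two_residue_toy(self, two_residue_pdb):
        s = read_structure(two_residue_pdb)
        assert len(s.residues) == 2
        assert s.chains == ["A"]
        assert [r.name for r in s.residues] == ["ALA", "GLY"]
        assert s.sequence("A") == "AG"

    def test_filters_water_hetero_hydrogens(self, two_residue_pdb):
        extra = [
            atom_line(90, "O", "HOH", "A", 90, 9.0, 9.0, 9.0, record="HETATM"),
            atom_line(91, "SE", "MSE", "A", 91, 8.0, 8.0, 8.0, record="HETATM",
                      element="SE"),
            atom_line(92, "HA", "ALA", "A", 1, 1.5, 0.5, 0.5, element="H"),
        ]
        text = two_residue_pdb.replace("END", "\n".join(extra) + "\nEND")
        s = read_structure(text)
        assert len(s.residues) == 2
        assert "HA" not in s.residues[0].atoms

    def test_altloc_highest_occupancy_wins(self):
        lines = [
            atom_line(1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0),
            atom_line(2, "CA", "ALA", "A", 1, 1.0, 0.0, 0.0, occupancy=0.6,
                      altloc="A", element="C"),
            atom_line(3, "CA", "ALA", "A", 1, 9.0, 9.0, 9.0, occupancy=0.4,
                      altloc="B", element="C"),
            atom_line(4, "C", "ALA", "A", 1, 2.0, 1.4, 0.0, element="C"),
        ]
        s = read_structure("\n".join(lines) + "\nEND\n")
        assert len(s.residues) == 1
        np.testing.assert_allclose(s.residues[0].atoms["CA"].coord, [1.0, 0.0, 0.0])

    def test_altloc_tie_prefers_a(self):
        lines = [
            atom_line(1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0),
            atom_line(2, "CA", "ALA", "A", 1, 1.0, 0.0, 0.0, occupancy=0.5,
                      altloc="A", element="C"),
            atom_line(3, "CA", "ALA", "A", 1, 9.0, 9.0, 9.0, occupancy=0.5,
                      altloc="B", element="C"),
        ]
        s = read_structure("\n".join(lines) + "\nEND\n")
        np.testing.assert_allclose(s.residues[0].atoms["CA"].coord, [1.0, 0.0, 0.0])

    def test_multi_model_trajectory_mode(self, two_residue_pdb):
        body = two_residue_pdb.replace("END\n", "")
        models = []
        for k in range(3):
            shifted = body.replace("ATOM", "ATOM")  # same atoms, shifted below
            models.append(f"MODEL     {k + 1}\n{shifted}ENDMDL\n")
        text = "".join(models) + "END\n"
        assert read_structure(text, trajectory=True).n_frames == 3
        assert read_structure(text).n_frames == 1

    def test_malformed_atom_record_names_line(self, two_residue_pdb):
        bad = two_residue_pdb.replace("   1.458", "   xx.xx")
        with pytest.raises(ParseError, match="line 2"):
            read_structure(bad)

    def test_empty_structure_error(self):
        text = atom_line(1, "O", "HOH", "A", 1, 0.0, 0.0, 0.0, record="HETATM")
        with pytest.raises(EmptyStructureError):
            read_structure(text + "\nEND\n")


class TestReduce:
    def test_cm_alanine_is_cbeta(self, two_residue_pdb):
        s = read_structure(two_residue_pdb)
        model = reduce(s, "CM")
        np.testing.assert_allclose(model.entries[0].coord, [2.0, -0.8, -1.2])

    def test_cm_mean_of_side_chain_atoms(self):
        lines = [
            atom_line(1, "N", "SER", "A", 1, -1.46, 0.0, 0.0),
            atom_line(2, "CA", "SER", "A", 1, 0.0, 0.0, 0.0, element="C"),
            atom_line(3, "C", "SER", "A", 1, 1.52, 0.0, 0.0, element="C"),
            atom_line(4, "CB", "SER", "A", 1, 0.0, 0.0, 0.0, element="C"),
            atom_line(5, "OG", "SER", "A", 1, 2.0, 0.0, 0.0),
        ]
        model = reduce(read_structure("\n".join(lines) + "\nEND\n"), "CM")
        np.testing.assert_allclose(model.entries[0].coord, [1.0, 0.0, 0.0])

    def test_glycine_virtual_cbeta_bond_length(self, two_residue_pdb):
        s = read_structure(two_residue_pdb)
        model = reduce(s, "CB")
        gly = s.residues[1]
        dist = np.linalg.norm(model.entries[1].coord - gly.atoms["CA"].coord)
        assert dist == pytest.approx(CBETA_BOND_LENGTH, abs=1e-9)

    def test_virtual_cbeta_matches_real_geometry(self):
        # ideal backbone: virtual CB should sit ~tetrahedrally, 1.522 A out
        n = np.array([-1.458, 0.0, 0.0])
        ca = np.zeros(3)
        c = np.array([0.55, 1.42, 0.0])
        cb = virtual_cbeta(n, ca, c)
        assert np.linalg.norm(cb - ca) == pytest.approx(1.522)
        # roughly tetrahedral angles to both backbone neighbours
        for other in (n, c):
            cosang = np.dot(cb - ca, other - ca) / (
                np.linalg.norm(cb - ca) * np.linalg.norm(other - ca)
            )
            assert -0.55 < cosang < -0.2

    def test_missing_backbone_raises(self):
        lines = [
            atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, element="C"),
            atom_line(2, "C", "ALA", "A", 1, 1.52, 0.0, 0.0, element="C"),
        ]
        s = read_structure("\n".join(lines) + "\nEND\n")
        with pytest.raises(ReductionError, match="ALA"):
            reduce(s, "CA")

    def test_missing_side_chain_falls_back_with_warning(self, caplog):
        lines = [
            atom_line(1, "N", "LYS", "A", 1, -1.46, 0.0, 0.0),
            atom_line(2, "CA", "LYS", "A", 1, 0.0, 0.0, 0.0, element="C"),
            atom_line(3, "C", "LYS", "A", 1, 0.55, 1.42, 0.0, element="C"),
        ]
        s = read_structure("\n".join(lines) + "\nEND\n")
        with caplog.at_level(logging.WARNING):
            model = reduce(s, "CM")
        assert "virtual C-beta" in caplog.text
        assert np.isfinite(model.entries[0].coord).all()

    def test_atom_order_invariance(self, two_residue_pdb):
        lines = [l for l in two_residue_pdb.splitlines() if l.startswith("ATOM")]
        permuted = "\n".join(lines[::-1]) + "\nEND\n"
        for scheme in ("CA", "CB", "CM"):
            a = reduce(read_structure(two_residue_pdb), scheme)
            b = reduce(read_structure(permuted), scheme)
            np.testing.assert_allclose(a.coords, b.coords)

    def test_unknown_scheme(self, two_residue_pdb):
        with pytest.raises(InputError):
            reduce(read_structure(two_residue_pdb), "XX")


def _rotz(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


class TestSuperpose:
    def test_identity(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(8, 3))
        fit = superpose(a, a)
        assert fit.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(fit.rotation, np.eye(3), atol=1e-9)

    def test_rigid_transform_recovered(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(10, 3))
        b = a @ _rotz(np.pi / 2).T + np.array([1.0, -2.0, 3.0])
        fit = superpose(a, b)
        assert fit.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.det(fit.rotation) == pytest.approx(1.0)
        np.testing.assert_allclose(fit.apply(b), a, atol=1e-9)

    def test_congruent_sets_superpose_exactly(self):
        # {e_x, e_y} maps onto {e_x, e_z} by a proper rotation about x
        a = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        b = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        assert superpose(a, b).rmsd == pytest.approx(0.0, abs=1e-9)

    def test_against_numerical_minimisation_oracle(self):
        """Post-fit RMSD matches brute-force minimisation over rotations."""
        from scipy.optimize import minimize
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(42)
        a = rng.normal(size=(5, 3))
        b = rng.normal(size=(5, 3))
        fit = superpose(a, b)

        ac, bc = a - a.mean(0), b - b.mean(0)

        def objective(rotvec):
            rot = Rotation.from_rotvec(rotvec).as_matrix()
            return np.sqrt(np.mean(np.sum((bc @ rot.T - ac) ** 2, axis=1)))

        best = np.inf
        for _ in range(50):
            start = rng.uniform(-np.pi, np.pi, 3)
            res = minimize(objective, start, method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12})
            best = min(best, res.fun)
        assert fit.rmsd == pytest.approx(best, abs=1e-6)
        assert fit.rmsd <= best + 1e-9  # the analytic fit is never worse

    def test_rmsd_symmetric(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(6, 3))
        b = rng.normal(size=(6, 3))
        assert superpose(a, b).rmsd == pytest.approx(superpose(b, a).rmsd, abs=1e-9)

    def test_input_validation(self):
        a = np.zeros((3, 3))
        with pytest.raises(InputError):
            superpose(a, np.zeros((4, 3)))
        with pytest.raises(InputError):
            superpose(a[:2], a[:2])


def _trajectory_text(frames):
    """Multi-model PDB from a list of {atom name: xyz} dicts (one GLY)."""
    out = []
    for k, atoms in enumerate(frames, start=1):
        out.append(f"MODEL     {k}")
        for i, (name, xyz) in enumerate(atoms.items(), start=1):
            out.append(atom_line(i, name, "GLY", "A", 1, *xyz,
                                 element="C" if name in ("CA", "C") else name[0]))
        out.append("ENDMDL")
    return "\n".join(out) + "\nEND\n"


BASE = {"N": (-1.46, 0.0, 0.0), "CA": (0.0, 0.0, 0.0), "C": (1.52, 0.0, 0.0),
        "O": (2.12, 1.06, 0.0)}


class TestBackboneRMSF:
    def test_identical_frames_zero(self):
        s = read_structure(_trajectory_text([BASE] * 4), trajectory=True)
        rmsf = backbone_rmsf(s)
        assert rmsf[("A", 1, "")] == pytest.approx(0.0, abs=1e-12)

    def test_alternating_atom_half_range(self):
        moved = {**BASE, "CA": (2.0, 0.0, 0.0)}
        # CA alternates between x=0 and x=2 -> its fluctuation is 1.0 A;
        # averaged over the four backbone atoms the residue RMSF is 0.25
        s = read_structure(
            _trajectory_text([BASE, moved, BASE, moved]), trajectory=True
        )
        assert backbone_rmsf(s)[("A", 1, "")] == pytest.approx(0.25)

    def test_all_atoms_alternating(self):
        moved = {name: (x + 2.0, y, z) for name, (x, y, z) in BASE.items()}
        s = read_structure(
            _trajectory_text([BASE, moved, BASE, moved]), trajectory=True
        )
        assert backbone_rmsf(s)[("A", 1, "")] == pytest.approx(1.0)

    def test_isotropic_jitter_closed_form(self):
        # fluctuation sqrt(3) * sigma, with the (n-1)/n sample-mean bias
        rng = np.random.default_rng(7)
        sigma, n_frames, n_res = 0.5, 10, 250
        out = []
        for k in range(n_frames):
            out.append(f"MODEL     {k + 1}")
            serial = 1
            for r in range(1, n_res + 1):
                for name, (x, y, z) in BASE.items():
                    jx, jy, jz = rng.normal(0.0, sigma, 3)
                    out.append(
                        atom_line(serial, name, "GLY", "A", r,
                                  x + 10.0 * r + jx, y + jy, z + jz,
                                  element="C" if name in ("CA", "C") else name[0])
                    )
                    serial += 1
            out.append("ENDMDL")
        s = read_structure("\n".join(out) + "\nEND\n", trajectory=True)
        values = np.array(list(backbone_rmsf(s).values()))
        expected = sigma * np.sqrt(3.0) * np.sqrt((n_frames - 1) / n_frames)
        assert values.mean() == pytest.approx(expected, abs=0.02)

    def test_rigid_offset_changes_rmsf_without_presuperposition(self):
        # frames must be pre-superposed: a rigid shift of one frame inflates RMSF
        shifted = {name: (x + 3.0, y, z) for name, (x, y, z) in BASE.items()}
        s = read_structure(_trajectory_text([BASE, BASE, shifted]), trajectory=True)
        assert backbone_rmsf(s)[("A", 1, "")] > 1.0

    def test_requires_two_frames(self):
        s = read_structure(_trajectory_text([BASE]), trajectory=True)
        with pytest.raises(InputError):
            backbone_rmsf(s)
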