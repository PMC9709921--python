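"""Structure I/O, superposition and RMSD series."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from ttmd.core import (
    Frame,
    Trajectory,
    read_structure,
    rmsd,
    rmsd_series,
    superpose,
    apply_transform,
    write_structure,
)
from ttmd.errors import FormatError, GeometryError, SelectorError
from ttmd.synthetic import SyntheticEngine, SyntheticScenario

from conftest import pdb_line


def brute_force_fit_rmsd(mobile, reference):
    """Independent oracle: direct minimisation over rotation vectors."""
    mc = mobile - mobile.mean(axis=0)
    rc = reference - reference.mean(axis=0)

    def cost(rv):
        r = Rotation.from_rotvec(rv).as_matrix()
        return np.sqrt(((mc @ r.T - rc) ** 2).sum(axis=1).mean())

    rng = np.random.default_rng(0)
    best = np.inf
    for _ in range(12):
        res = minimize(cost, rng.normal(scale=2.0, size=3), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
        best = min(best, res.fun)
    return best


class TestReadStructure:
    def test_peptide_benzene_counts(self, peptide_benzene_pdb):
        system = read_structure(peptide_benzene_pdb, "BNZ")
        assert len(system.receptor_residues) == 3
        assert len(system.ligand_atoms) == 12

    def test_water_cutoff_default_excludes_distant(self, peptide_benzene_pdb):
        system = read_structure(peptide_benzene_pdb, "BNZ")
        waters = {a.residue_id for a in system.atoms if a.role == "water"}
        assert waters == {("A", 202, "")}  # the 6 A water is dropped at 4.5 A

    def test_water_cutoff_widened_retains(self, peptide_benzene_pdb):
        # brute-force check of the fixture geometry: min distance is 6.0 A
        system = read_structure(peptide_benzene_pdb, "BNZ", water_cutoff=10.0)
        waters = {a.residue_id for a in system.atoms if a.role == "water"}
        assert ("A", 201, "") in waters and ("A", 202, "") in waters
        lig = np.array([a.coords for a in system.atoms if a.role == "ligand"])
        w = np.array([a.coords for a in system.atoms if a.residue_id == ("A", 201, "")])
        dmin = min(np.linalg.norm(w[0] - p) for p in lig)
        assert dmin == pytest.approx(6.0, abs=1e-3)

    def test_missing_ligand_selector_raises(self, peptide_benzene_pdb):
        with pytest.raises(SelectorError):
            read_structure(peptide_benzene_pdb, "XXX")

    def test_duplicate_serials_raise(self, tmp_path):
        line = pdb_line(1, "CA", "GLY", "A", 1, (0, 0, 0), "C")
        bnz = pdb_line(2, "C1", "BNZ", "A", 2, (3, 0, 0), "C", hetatm=True)
        path = tmp_path / "dup.pdb"
        path.write_text("\n".join([line, line, bnz, "END"]) + "\n")
        with pytest.raises(FormatError):
            read_structure(path, "BNZ")

    def test_round_trip(self, toy_system, tmp_path):
        path = tmp_path / "toy.pdb"
        write_structure(toy_system, path)
        again = read_structure(path, "LIG")
        assert again.n_atoms == toy_system.n_atoms
        assert [a.name for a in again.atoms] == [a.name for a in toy_system.atoms]
        assert np.abs(again.coords0 - toy_system.coords0).max() < 1e-3


class TestSuperpose:
    def test_self_is_zero(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        _, _, r = superpose(pts, pts)
        assert r == pytest.approx(0.0, abs=1e-10)

    def test_translation_removed(self):
        pts = np.random.default_rng(1).normal(size=(8, 3))
        _, _, r = superpose(pts + np.array([3.0, 0.0, 0.0]), pts)
        assert r == pytest.approx(0.0, abs=1e-9)

    def test_matches_brute_force_oracle(self):
        ref = np.array([[0.0, 0, 0], [2, 0, 0], [0, 2, 0], [0, 0, 2]])
        mobile = ref.copy()
        mobile[3] += np.array([0.0, 0.0, 1.0])  # one atom displaced 1 A
        _, _, fitted = superpose(mobile, ref)
        assert fitted == pytest.approx(brute_force_fit_rmsd(mobile, ref), abs=1e-5)

    def test_fit_never_worse_than_unfitted(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.normal(size=(12, 3))
            b = a + rng.normal(scale=0.5, size=(12, 3))
            _, _, fitted = superpose(b, a)
            assert fitted <= rmsd(b, a) + 1e-12

    def test_rigid_invariance(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(9, 3))
        b = a + rng.normal(scale=0.3, size=(9, 3))
        _, _, r0 = superpose(b, a)
        rot = Rotation.random(random_state=5).as_matrix()
        shift = np.array([4.0, -2.0, 7.0])
        _, _, r1 = superpose(b @ rot.T + shift, a @ rot.T + shift)
        assert r1 == pytest.approx(r0, abs=1e-9)

    def test_collinear_selection_raises(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(GeometryError):
            superpose(line + 1.0, line)

    def test_transform_application(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=(7, 3))
        rot = Rotation.random(random_state=7).as_matrix()
        b = a @ rot.T + np.array([1.0, 2.0, 3.0])
        r_fit, t_fit, _ = superpose(b, a)
        assert np.allclose(apply_transform(b, r_fit, t_fit), a, atol=1e-8)


class TestRmsdSeries:
    def _identical_traj(self, system, n=4):
        return Trajectory(
            [Frame(coords=system.coords0.copy(), time=0.1 * (k + 1)) for k in range(n)]
        )

    def test_identical_frames_all_zero(self, toy_system):
        traj = self._identical_traj(toy_system)
        bb = toy_system.backbone_indices()
        series = rmsd_series(traj, bb, toy_system.ligand_heavy_indices())
        assert np.allclose(series, 0.0, atol=1e-10)

    def test_empty_selection_raises(self, toy_system):
        traj = self._identical_traj(toy_system)
        with pytest.raises(SelectorError):
            rmsd_series(traj, np.array([], dtype=int), toy_system.ligand_atoms)

    def test_unbinding_raises_ligand_rmsd(self, toy_system):
        engine = SyntheticEngine(SyntheticScenario("unbinder", unbind_window=2),
                                 frames_per_window=10)
        engine.equilibrate(toy_system, seed=1)
        ref = toy_system.coords0
        bb = toy_system.backbone_indices()
        lig = toy_system.ligand_heavy_indices()
        t1 = engine.run_window(toy_system, ref, 300.0, 10.0, seed=2)
        t2 = engine.run_window(toy_system, ref, 310.0, 10.0, seed=3)
        before = rmsd_series(t1, bb, lig, reference=ref)
        after = rmsd_series(t2, bb, lig, reference=ref)
        assert after.min() > before.max() + 10.0  # scripted exit dominates jitter

    def test_small_jitter_keeps_rmsd_small(self, toy_system):
        engine = SyntheticEngine(SyntheticScenario("stable", sigma0=0.1),
                                 frames_per_window=20)
        traj = engine.run_window(toy_system, toy_system.coords0, 300.0, 10.0, seed=4)
        bb = toy_system.backbone_indices()
        lig = toy_system.ligand_heavy_indices()
        bb_r = rmsd_series(traj, bb, bb, reference=toy_system.coords0)
        lig_r = rmsd_series(traj, bb, lig, reference=toy_system.coords0)
        assert bb_r.max() < 1.0 and lig_r.max() < 1.0
        assert lig_r.mean() < 3 * bb_r.mean()  # same jitter scale
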