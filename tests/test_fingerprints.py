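"""Feature perception and interaction-fingerprint geometry."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ttmd.core import AtomRecord, MolecularSystem
from ttmd.fingerprints import (
    CHANNELS,
    FingerprintCalculator,
    compute_fingerprint,
    perceive_features,
)

from conftest import benzene_coords, build_system


def channels_of(system, coords=None):
    calc = FingerprintCalculator(system)
    fp = calc.compute(system.coords0 if coords is None else coords)
    return fp.channels_set(), fp


def far_gly(resnum=1, base=(40.0, 40.0, 0.0)):
    """A glycine far from everything (satisfies the >=1 protein residue
    invariant without contributing contacts)."""
    base = np.asarray(base, dtype=float)
    return [
        ("N", "N", "GLY", resnum, base, "protein"),
        ("CA", "C", "GLY", resnum, base + (1.47, 0.3, 0.0), "protein"),
        ("C", "C", "GLY", resnum, base + (2.5, -0.8, 0.0), "protein"),
        ("O", "O", "GLY", resnum, base + (2.5, -2.03, 0.0), "protein"),
    ]


class TestPerception:
    def test_benzene_ligand(self):
        carbons, hydrogens = benzene_coords()
        entries = far_gly() + [
            (f"C{i}", "C", "BNZ", 90, xyz, "ligand") for i, xyz in enumerate(carbons, 1)
        ] + [
            (f"H{i}", "H", "BNZ", 90, xyz, "ligand") for i, xyz in enumerate(hydrogens, 1)
        ]
        system = build_system(entries)
        _, lig = perceive_features(system)
        assert len(lig.aromatic_rings) == 1
        assert len(lig.hydrophobic_atoms) == 6
        assert len(lig.hbond_donors) == 0
        assert len(lig.hbond_acceptors) == 0

    def test_aspartate_anionic_group(self, toy_system):
        prot, _ = perceive_features(toy_system)
        asp_atoms = {
            a.name for grp in prot.anionic_groups for i in grp
            if (a := toy_system.atoms[i]).residue_name == "ASP"
        }
        assert asp_atoms == {"OD1", "OD2", "CG"}

    def test_lysine_cationic_group(self, toy_system):
        prot, _ = perceive_features(toy_system)
        lys_atoms = {
            toy_system.atoms[i].name
            for grp in prot.cationic_groups
            for i in grp
            if toy_system.atoms[i].residue_name == "LYS"
        }
        assert lys_atoms == {"NZ"}

    def test_unknown_element_warns_and_excluded(self):
        entries = far_gly() + [
            ("X1", "XX", "LIG", 90, (0.0, 0.0, 0.0), "ligand"),
            ("C1", "C", "LIG", 90, (3.0, 0.0, 0.0), "ligand"),
        ]
        system = build_system(entries)
        with pytest.warns(UserWarning, match="unknown element"):
            _, lig = perceive_features(system)
        assert 4 not in lig.hydrophobic_atoms  # the XX atom contributes nothing


class TestChannels:
    def test_distant_ligand_all_zero(self, toy_system, toy_calculator):
        coords = toy_system.coords0.copy()
        coords[toy_system.ligand_atoms] += 200.0
        fp = toy_calculator.compute(coords)
        assert fp.bits.sum() == 0

    def test_hydrogen_bond_protein_donor_good_angle(self):
        # N-H...O at 2.9 A donor-acceptor distance and 170 deg angle
        entries = [
            ("N", "N", "GLY", 1, (0.0, 0.0, 0.0), "protein"),
            ("H", "H", "GLY", 1, (1.0, 0.0, 0.0), "protein"),
            ("CA", "C", "GLY", 1, (-0.8, 1.2, 0.0), "protein"),
            ("C", "C", "GLY", 1, (-0.9, -1.1, 0.0), "protein"),
            ("O1", "O", "LIG", 90, (2.881, 0.332, 0.0), "ligand"),
            ("C1", "C", "LIG", 90, (3.9, 0.9, 0.0), "ligand"),
        ]
        system = build_system(entries)
        chans, fp = channels_of(system)
        assert chans == {"HB_PD"}
        assert fp.set_bits() == [(("A", 1, ""), "HB_PD")]

    def test_hydrogen_bond_rejected_at_bad_angle(self):
        # same donor-acceptor distance but D-H...A angle of 90 deg
        entries = [
            ("N", "N", "GLY", 1, (0.0, 0.0, 0.0), "protein"),
            ("H", "H", "GLY", 1, (1.0, 0.0, 0.0), "protein"),
            ("CA", "C", "GLY", 1, (-0.8, 1.2, 0.0), "protein"),
            ("O1", "O", "LIG", 90, (1.0, 2.722, 0.0), "ligand"),
            ("C1", "C", "LIG", 90, (1.0, 3.95, 0.8), "ligand"),
        ]
        chans, _ = channels_of(build_system(entries))
        assert "HB_PD" not in chans

    def test_salt_bridge_protein_positive(self):
        # Lys ammonium 3.2 A from a ligand carboxylate oxygen
        entries = [
            ("NZ", "N", "LYS", 1, (0.0, 0.0, 0.0), "protein"),
            ("CE", "C", "LYS", 1, (-1.49, 0.0, 0.0), "protein"),
            ("CD", "C", "LYS", 1, (-2.5, 1.1, 0.0), "protein"),
            ("O1", "O", "LIG", 90, (3.2, 0.0, 0.0), "ligand"),
            ("C1", "C", "LIG", 90, (3.82, 1.06, 0.0), "ligand"),
            ("O2", "O", "LIG", 90, (3.82, 2.12, 0.9), "ligand"),
        ]
        chans, fp = channels_of(build_system(entries))
        assert chans == {"SB_PP"}

    def test_face_to_face_and_edge_to_face(self):
        prot_c, _ = benzene_coords()
        prot_ring = [(f"C{i}", "C", "PHE", 1, xyz, "protein") for i, xyz in enumerate(prot_c, 1)]

        # parallel rings, centroid distance 4.2 A (no atom pair under 4.0)
        lig_c, _ = benzene_coords(z=4.2)
        lig_ring = [(f"C{i}", "C", "LIG", 90, xyz, "ligand") for i, xyz in enumerate(lig_c, 1)]
        chans, _ = channels_of(build_system(prot_ring + lig_ring))
        assert chans == {"F2F"}

        # rings tilted to 85 deg, centroid distance 5.45 A: edge-to-face only
        rot = Rotation.from_rotvec(np.radians(85.0) * np.array([1.0, 0.0, 0.0])).as_matrix()
        tilted = np.array(benzene_coords()[0]) @ rot.T + np.array([0.0, 0.0, 5.45])
        lig_ring = [(f"C{i}", "C", "LIG", 90, xyz, "ligand") for i, xyz in enumerate(tilted, 1)]
        chans, _ = channels_of(build_system(prot_ring + lig_ring))
        assert "E2F" in chans and "F2F" not in chans

    def test_metal_coordination(self):
        entries = far_gly() + [
            ("ZN", "ZN", "ZN", 50, (0.0, 0.0, 0.0), "ion"),
            ("O1", "O", "LIG", 90, (2.2, 0.0, 0.0), "ligand"),
            ("C1", "C", "LIG", 90, (3.1, 0.9, 0.0), "ligand"),
        ]
        chans, fp = channels_of(build_system(entries))
        assert chans == {"MET"}
        assert (("A", 50, ""), "MET") in fp.set_bits()

    def test_hydrophobic_contact(self):
        entries = far_gly() + [
            ("CB", "C", "ALA", 2, (0.0, 0.0, 0.0), "protein"),
            ("C1", "C", "LIG", 90, (3.5, 0.0, 0.0), "ligand"),
        ]
        chans, _ = channels_of(build_system(entries))
        assert chans == {"HY"}


class TestInvariants:
    def test_rigid_transform_invariance(self, toy_system, toy_calculator, toy_reference):
        rng = np.random.default_rng(12)
        for k in range(100):
            rot = Rotation.random(random_state=k).as_matrix()
            shift = rng.normal(scale=20.0, size=3)
            fp = toy_calculator.compute(toy_system.coords0 @ rot.T + shift)
            assert np.array_equal(fp.bits, toy_reference.bits)

    def test_translation_beyond_cutoffs_clears_all_bits(
        self, toy_system, toy_calculator, toy_reference
    ):
        # once every ligand-receptor pair distance exceeds the largest
        # channel cutoff, translating further can only keep the bits cleared
        ray = np.array([1.0, 0.3, -0.2])
        ray /= np.linalg.norm(ray)
        receptor = np.array(
            [a.coords for a in toy_system.atoms if a.role in ("protein", "ion")]
        )
        max_cutoff = 5.5
        previous = None
        for dist in (25.0, 40.0, 80.0):
            coords = toy_system.coords0.copy()
            coords[toy_system.ligand_atoms] += ray * dist
            lig = coords[toy_system.ligand_atoms]
            dmin = np.linalg.norm(lig[:, None] - receptor[None], axis=-1).min()
            assert dmin > max_cutoff  # precondition of the property
            fp = toy_calculator.compute(coords)
            current = set(map(tuple, np.argwhere(fp.to_matrix())))
            if previous is not None:
                assert current <= previous
            previous = current
        assert previous == set()

    def test_determinism(self, toy_system, toy_calculator):
        a = toy_calculator.compute(toy_system.coords0)
        b = toy_calculator.compute(toy_system.coords0)
        c = compute_fingerprint(toy_system.coords0, toy_system)
        assert np.array_equal(a.bits, b.bits) and np.array_equal(a.bits, c.bits)

    def test_channel_layout(self, toy_reference):
        assert CHANNELS == ("HY", "F2F", "E2F", "HB_PD", "HB_PA", "SB_PP", "SB_PN", "MET")
        assert len(toy_reference) == 8 * len(toy_reference.residue_order)
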