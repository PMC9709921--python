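"""Shared fixtures: ad-hoc system builder, hand-written PDB fixtures and
the deterministic toy complex."""

from __future__ import annotations

import numpy as np
import pytest

from ttmd.core import AtomRecord, MolecularSystem
from ttmd.fingerprints import FingerprintCalculator
from ttmd.synthetic import make_toy_complex


def build_system(entries) -> MolecularSystem:
    """Construct a system from (name, element, resname, resnum, xyz, role)
    tuples, optionally extended with (charge, sigma, epsilon)."""
    records = []
    for serial, e in enumerate(entries, start=1):
        name, element, resname, resnum, xyz, role = e[:6]
        charge = e[6] if len(e) > 6 else None
        lj = (e[7], e[8]) if len(e) > 8 else None
        records.append(
            AtomRecord(
                serial=serial,
                name=name,
                element=element,
                residue_id=("A", resnum, ""),
                residue_name=resname,
                coords=tuple(np.asarray(xyz, dtype=float)),
                role=role,
                partial_charge=charge,
                lj_params=lj,
            )
        )
    return MolecularSystem(records)


def pdb_line(serial, name, resname, chain, resnum, xyz, element, hetatm=False, occ=1.0):
    rec = "HETATM" if hetatm else "ATOM  "
    nm = name if len(name) >= 4 else (" " + name).ljust(4)
    x, y, z = xyz
    return (
        f"{rec}{serial:5d} {nm} {resname:<3} {chain}{resnum:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00          {element:>2}"
    )


def benzene_coords(center=(0.0, 0.0, 0.0), z=0.0):
    """Benzene heavy+H coordinates: 6 C at r=1.39, 6 H at r=2.47."""
    cx, cy, cz = center
    carbons, hydrogens = [], []
    for k in range(6):
        ang = np.radians(60 * k)
        carbons.append((cx + 1.39 * np.cos(ang), cy + 1.39 * np.sin(ang), cz + z))
        hydrogens.append((cx + 2.47 * np.cos(ang), cy + 2.47 * np.sin(ang), cz + z))
    return carbons, hydrogens


@pytest.fixture(scope="session")
def peptide_benzene_pdb(tmp_path_factory):
    """Three-glycine peptide + benzene ligand + two waters (one 6 A from the
    ligand, one adjacent)."""
    lines = []
    serial = 1
    # 3 glycine residues, spaced apart around (10, 10, 0)
    for resnum in range(1, 4):
        base = np.array([10.0 + 4.0 * resnum, 10.0, 0.0])
        for name, off in (
            ("N", (0.0, 0.0, 0.0)),
            ("CA", (1.47, 0.3, 0.0)),
            ("C", (2.5, -0.8, 0.0)),
            ("O", (2.5, -2.03, 0.0)),
        ):
            lines.append(
                pdb_line(serial, name, "GLY", "A", resnum, base + np.array(off),
                         name[0])
            )
            serial += 1
    carbons, hydrogens = benzene_coords()
    for i, xyz in enumerate(carbons, start=1):
        lines.append(pdb_line(serial, f"C{i}", "BNZ", "A", 90, xyz, "C", hetatm=True))
        serial += 1
    for i, xyz in enumerate(hydrogens, start=1):
        lines.append(pdb_line(serial, f"H{i}", "BNZ", "A", 90, xyz, "H", hetatm=True))
        serial += 1
    # water 1: exactly 6.0 A above a ring carbon (the nearest ligand atom)
    lines.append(pdb_line(serial, "O", "HOH", "A", 201, (1.39, 0.0, 6.0), "O", hetatm=True))
    serial += 1
    # water 2: 3.0 A above the ring centroid (within the default cutoff)
    lines.append(pdb_line(serial, "O", "HOH", "A", 202, (0.0, 0.0, 3.0), "O", hetatm=True))
    lines.append("END")
    path = tmp_path_factory.mktemp("pdb") / "peptide_benzene.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture(scope="session")
def toy_system():
    return make_toy_complex(seed=0)


@pytest.fixture(scope="session")
def toy_calculator(toy_system):
    return FingerprintCalculator(toy_system)


@pytest.fixture(scope="session")
def toy_reference(toy_system, toy_calculator):
    return toy_calculator.compute(toy_system.coords0)
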