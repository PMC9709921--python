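"""Pharmacophoric feature perception and r x 8 interaction fingerprints.

Each receptor residue is encoded into eight bits, one per interaction type:

====== =====================================================
HY     hydrophobic contact
F2F    aromatic face-to-face stacking
E2F    aromatic edge-to-face stacking
HB_PD  hydrogen bond, protein acting as the donor
HB_PA  hydrogen bond, protein acting as the acceptor
SB_PP  salt bridge, protein acting as the positive member
SB_PN  salt bridge, protein acting as the negative member
MET    ligand coordination to a metal ion
====== =====================================================

A bit is set when at least one ligand--residue feature pair satisfies the
channel's geometric criterion (thresholds in
:class:`~ttmd.config.InteractionThresholds`). Bits are binary, not counts.
Metal-ion residues are included in the residue order so the MET channel has
a row to live on; systems without metals are unaffected.

Feature perception is deterministic and purely geometric: bonds are
inferred from interatomic distances, aromatic rings are planar 5/6-rings,
and charged groups come from residue-name templates (protein) or partial
charges / carboxylate-like patterns (ligand). When a side carries no
hydrogens, hydrogen-bond detection falls back to a heavy-atom
distance-only criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from scipy.spatial import cKDTree

from .config import InteractionThresholds
from .core import METAL_ELEMENTS, Frame, MolecularSystem, ResidueKey
from .errors import UsageError

__all__ = [
    "CHANNELS",
    "Ring",
    "FeatureSet",
    "InteractionFingerprint",
    "perceive_features",
    "FingerprintCalculator",
    "compute_fingerprint",
]

#: fixed channel enumeration; fingerprint element (i, c) is residue i, channel c
CHANNELS = ("HY", "F2F", "E2F", "HB_PD", "HB_PA", "SB_PP", "SB_PN", "MET")

_KNOWN_ELEMENTS = {"C", "N", "O", "S", "P", "H", "F", "CL", "BR", "I"} | METAL_ELEMENTS

_PROTEIN_CATION_TEMPLATES = {
    "ARG": ("NE", "NH1", "NH2", "CZ"),
    "LYS": ("NZ",),
    "HIP": ("ND1", "NE2", "CE1", "CD2", "CG"),
    "HSP": ("ND1", "NE2", "CE1", "CD2", "CG"),
}
_PROTEIN_ANION_TEMPLATES = {
    "ASP": ("OD1", "OD2", "CG"),
    "GLU": ("OE1", "OE2", "CD"),
}


@dataclass(frozen=True)
class Ring:
    """A 5- or 6-membered planar ring, stored as atom indices; centroid and
    normal are evaluated on whatever coordinates are passed in."""

    atom_indices: tuple[int, ...]

    def centroid(self, coords: np.ndarray) -> np.ndarray:
        return coords[list(self.atom_indices)].mean(axis=0)

    def normal(self, coords: np.ndarray) -> np.ndarray:
        pts = coords[list(self.atom_indices)]
        centered = pts - pts.mean(axis=0)
        # smallest principal axis of the ring atoms = plane normal
        _, _, vt = np.linalg.svd(centered)
        n = vt[-1]
        return n / np.linalg.norm(n)

    def planarity(self, coords: np.ndarray) -> float:
        pts = coords[list(self.atom_indices)]
        centered = pts - pts.mean(axis=0)
        return float(np.abs(centered @ self.normal(coords)).max())


@dataclass
class FeatureSet:
    """Perceived pharmacophoric features for one side of the complex."""

    hydrophobic_atoms: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    aromatic_rings: list[Ring] = field(default_factory=list)
    hbond_donors: list[tuple[int, int | None]] = field(default_factory=list)  # (heavy, H)
    hbond_acceptors: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    cationic_groups: list[np.ndarray] = field(default_factory=list)
    anionic_groups: list[np.ndarray] = field(default_factory=list)
    metal_ions: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))


@dataclass
class InteractionFingerprint:
    """Binary interaction fingerprint: 8 bits per receptor residue."""

    bits: np.ndarray
    residue_order: tuple[ResidueKey, ...]
    channel_order: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.int8)
        if self.bits.size != 8 * len(self.residue_order):
            raise ValueError("fingerprint length must be 8 x number of residues")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("fingerprint elements must be 0 or 1")

    def __len__(self) -> int:
        return self.bits.size

    def to_matrix(self) -> np.ndarray:
        """(n_residues, 8) view of the bit vector."""
        return self.bits.reshape(len(self.residue_order), 8)

    def set_bits(self) -> list[tuple[ResidueKey, str]]:
        rows, cols = np.nonzero(self.to_matrix())
        return [(self.residue_order[r], CHANNELS[c]) for r, c in zip(rows, cols)]

    def channels_set(self) -> set[str]:
        return {ch for _, ch in self.set_bits()}


# ---------------------------------------------------------------------- #
# bond inference and feature perception
# ---------------------------------------------------------------------- #


def _bond_cutoff(e1: str, e2: str) -> float:
    if e1 == "H" and e2 == "H":
        return 0.0
    if "H" in (e1, e2):
        return 1.25
    if e1 in METAL_ELEMENTS or e2 in METAL_ELEMENTS:
        return 0.0  # metals are treated as bare ions
    if "S" in (e1, e2) or "P" in (e1, e2):
        return 2.16
    return 1.85


def _infer_bonds(system: MolecularSystem) -> dict[int, list[int]]:
    elements = [a.element.upper() for a in system.atoms]
    tree = cKDTree(system.coords0)
    pairs = tree.query_pairs(r=2.2)
    adj: dict[int, list[int]] = {i: [] for i in range(system.n_atoms)}
    for i, j in pairs:
        d = np.linalg.norm(system.coords0[i] - system.coords0[j])
        if d <= _bond_cutoff(elements[i], elements[j]):
            adj[i].append(j)
            adj[j].append(i)
    return adj


def _find_rings(indices, elements, adj, coords, planarity_tol) -> list[Ring]:
    sub = set(indices)
    g = nx.Graph()
    g.add_nodes_from(sub)
    for i in sub:
        for j in adj[i]:
            if j in sub and elements[j] != "H" and elements[i] != "H":
                g.add_edge(i, j)
    rings = []
    for cycle in nx.minimum_cycle_basis(g):
        if len(cycle) not in (5, 6):
            continue
        if any(elements[i] not in ("C", "N", "O", "S") for i in cycle):
            continue
        ring = Ring(tuple(sorted(cycle)))
        if ring.planarity(coords) <= planarity_tol:
            rings.append(ring)
    return rings


def perceive_features(
    system: MolecularSystem,
    thresholds: InteractionThresholds | None = None,
) -> tuple[FeatureSet, FeatureSet]:
    """Perceive features on both sides of the complex.

    Returns ``(protein_side, ligand_side)``; the protein side covers protein
    residues plus metal ions. Rules (heavy-atom geometric heuristics):

    * hydrophobic: C/S atoms bonded only to C, H or S
    * aromatic ring: planar (<= ``ring_planarity_tol``) 5/6-ring of C/N/O/S
    * donor: N/O/S with a bonded hydrogen; without any hydrogens on that
      side, N/O with free valence (fewer heavy neighbours than the nominal
      valence)
    * acceptor: O; N or S with at most two neighbours
    * cations/anions: residue templates (Arg/Lys/His+; Asp/Glu) on the
      protein, partial-charge or carboxylate/phosphate/sulfonate patterns on
      the ligand; charged-group atoms are removed from the donor/acceptor
      pools so salt bridges are not double-counted as hydrogen bonds
    * metals: ions with a metallic element
    """
    thresholds = thresholds or InteractionThresholds()
    elements = [a.element.upper() for a in system.atoms]
    adj = _infer_bonds(system)

    for i, e in enumerate(elements):
        if e not in _KNOWN_ELEMENTS:
            warnings.warn(
                f"atom serial {system.atoms[i].serial}: unknown element {e!r}; "
                "excluded from all feature classes"
            )

    def heavy_neighbors(i):
        return [j for j in adj[i] if elements[j] != "H"]

    def h_neighbors(i):
        return [j for j in adj[i] if elements[j] == "H"]

    def build(indices: np.ndarray, side: str) -> FeatureSet:
        idx = [int(i) for i in indices if elements[i] in _KNOWN_ELEMENTS]
        has_h = any(elements[i] == "H" for i in idx)
        fs = FeatureSet()

        hydro = [
            i
            for i in idx
            if elements[i] in ("C", "S")
            and all(elements[j] in ("C", "H", "S") for j in adj[i])
        ]
        fs.hydrophobic_atoms = np.asarray(hydro, dtype=int)

        fs.aromatic_rings = _find_rings(
            idx, elements, adj, system.coords0, thresholds.ring_planarity_tol
        )

        # charged groups first: their atoms are excluded from donors/acceptors
        cation_atoms: set[int] = set()
        anion_atoms: set[int] = set()
        if side == "protein":
            by_res: dict = {}
            for i in idx:
                by_res.setdefault(system.atoms[i].residue_id, []).append(i)
            for key, res_idx in by_res.items():
                resname = system.residue_names[key]
                names = {system.atoms[i].name: i for i in res_idx}
                for tmpl_names in (_PROTEIN_CATION_TEMPLATES.get(resname),):
                    if tmpl_names:
                        grp = [names[n] for n in tmpl_names if n in names]
                        if grp:
                            fs.cationic_groups.append(np.asarray(grp, dtype=int))
                            cation_atoms.update(grp)
                for tmpl_names in (_PROTEIN_ANION_TEMPLATES.get(resname),):
                    if tmpl_names:
                        grp = [names[n] for n in tmpl_names if n in names]
                        if grp:
                            fs.anionic_groups.append(np.asarray(grp, dtype=int))
                            anion_atoms.update(grp)
                if "OXT" in names:  # C-terminal carboxylate
                    grp = [names[n] for n in ("C", "O", "OXT") if n in names]
                    fs.anionic_groups.append(np.asarray(grp, dtype=int))
                    anion_atoms.update(grp)
        else:
            for i in idx:
                q = system.atoms[i].partial_charge
                if elements[i] == "N" and (
                    (q is not None and q >= 0.4) or len(heavy_neighbors(i)) + len(h_neighbors(i)) >= 4
                ):
                    fs.cationic_groups.append(np.asarray([i], dtype=int))
                    cation_atoms.add(i)
            # carboxylate / sulfonate / phosphate: central C/S/P with >=2
            # terminal oxygens, or explicitly negative oxygens
            seen_centers: set[int] = set()
            for i in idx:
                if elements[i] not in ("C", "S", "P") or i in seen_centers:
                    continue
                term_o = [
                    j
                    for j in heavy_neighbors(i)
                    if elements[j] == "O" and len(heavy_neighbors(j)) == 1 and j in idx
                ]
                if len(term_o) >= 2:
                    grp = sorted(term_o + [i])
                    fs.anionic_groups.append(np.asarray(grp, dtype=int))
                    anion_atoms.update(grp)
                    seen_centers.add(i)
            for i in idx:
                q = system.atoms[i].partial_charge
                if elements[i] == "O" and q is not None and q <= -0.6 and i not in anion_atoms:
                    fs.anionic_groups.append(np.asarray([i], dtype=int))
                    anion_atoms.add(i)

        charged = cation_atoms | anion_atoms

        donors: list[tuple[int, int | None]] = []
        acceptors: list[int] = []
        for i in idx:
            e = elements[i]
            if i in charged:
                continue
            if e in ("N", "O", "S"):
                hs = h_neighbors(i)
                if has_h:
                    for h in hs:
                        donors.append((i, h))
                else:
                    nominal = {"N": 3, "O": 2, "S": 2}[e]
                    if len(heavy_neighbors(i)) < nominal:
                        donors.append((i, None))
                if e == "O" or (e in ("N", "S") and len(heavy_neighbors(i)) + len(hs) <= 2):
                    acceptors.append(i)
        fs.hbond_donors = donors
        fs.hbond_acceptors = np.asarray(acceptors, dtype=int)

        fs.metal_ions = np.asarray(
            [i for i in idx if system.atoms[i].role == "ion" and elements[i] in METAL_ELEMENTS],
            dtype=int,
        )
        return fs

    receptor_idx = np.concatenate(
        [system.indices_by_role("protein"), system.indices_by_role("ion")]
    )
    protein_fs = build(receptor_idx, "protein")
    ligand_fs = build(system.ligand_atoms, "ligand")
    return protein_fs, ligand_fs


# ---------------------------------------------------------------------- #
# per-frame fingerprint computation
# ---------------------------------------------------------------------- #


def _pairwise(coords, idx_a, idx_b) -> np.ndarray:
    a = coords[idx_a]
    b = coords[idx_b]
    return np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)


class FingerprintCalculator:
    """Precomputes features and index maps for fast per-frame fingerprints.

    Build once per system; :meth:`compute` then evaluates the r x 8 bit
    vector for any frame of that system.
    """

    def __init__(
        self,
        system: MolecularSystem,
        thresholds: InteractionThresholds | None = None,
        features: tuple[FeatureSet, FeatureSet] | None = None,
    ):
        self.system = system
        self.thresholds = thresholds or InteractionThresholds()
        self.protein_features, self.ligand_features = (
            features if features is not None else perceive_features(system, self.thresholds)
        )
        self.residue_order: tuple[ResidueKey, ...] = tuple(system.receptor_residues)
        self._row = {key: r for r, key in enumerate(self.residue_order)}
        self._atom_row = np.full(system.n_atoms, -1, dtype=int)
        for i, a in enumerate(system.atoms):
            if a.residue_id in self._row:
                self._atom_row[i] = self._row[a.residue_id]

        lig_anion_atoms = (
            np.unique(np.concatenate(self.ligand_features.anionic_groups))
            if self.ligand_features.anionic_groups
            else np.empty(0, dtype=int)
        )
        lig_acc = self.ligand_features.hbond_acceptors
        # metal coordination partners: ligand acceptors plus anionic oxygens
        self._lig_metal_partners = np.unique(
            np.concatenate([lig_acc, lig_anion_atoms])
        ) if (lig_acc.size or lig_anion_atoms.size) else np.empty(0, dtype=int)
        self._lig_anion_atoms = lig_anion_atoms
        self._lig_cation_atoms = (
            np.unique(np.concatenate(self.ligand_features.cationic_groups))
            if self.ligand_features.cationic_groups
            else np.empty(0, dtype=int)
        )

    @property
    def n_residues(self) -> int:
        return len(self.residue_order)

    # ------------------------------------------------------------------ #
    def compute(self, frame: Frame | np.ndarray) -> InteractionFingerprint:
        coords = frame.coords if isinstance(frame, Frame) else np.asarray(frame, dtype=float)
        th = self.thresholds
        pf, lf = self.protein_features, self.ligand_features
        mat = np.zeros((self.n_residues, 8), dtype=np.int8)

        def mark(atom_indices, channel):
            for i in np.atleast_1d(atom_indices):
                row = self._atom_row[int(i)]
                if row >= 0:
                    mat[row, channel] = 1

        # HY — hydrophobic contacts
        if pf.hydrophobic_atoms.size and lf.hydrophobic_atoms.size:
            d = _pairwise(coords, pf.hydrophobic_atoms, lf.hydrophobic_atoms)
            hits = pf.hydrophobic_atoms[(d <= th.hydrophobic_cutoff).any(axis=1)]
            mark(hits, 0)

        # F2F / E2F — aromatic stacking
        for pring in pf.aromatic_rings:
            pc = pring.centroid(coords)
            pn = pring.normal(coords)
            for lring in lf.aromatic_rings:
                dist = float(np.linalg.norm(pc - lring.centroid(coords)))
                cosang = abs(float(np.dot(pn, lring.normal(coords))))
                angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                if dist <= th.f2f_centroid_cutoff and angle <= th.f2f_max_angle:
                    mark(np.asarray(pring.atom_indices), 1)
                lo, hi = th.e2f_angle_range
                if dist <= th.e2f_centroid_cutoff and lo <= angle <= hi:
                    mark(np.asarray(pring.atom_indices), 2)

        # HB_PD / HB_PA — hydrogen bonds
        def hbond_hits(donors, acceptor_idx):
            hit_donor_atoms = []
            if not donors or acceptor_idx.size == 0:
                return hit_donor_atoms
            acc = coords[acceptor_idx]
            for d_atom, h_atom in donors:
                dvec = acc - coords[d_atom]
                dd = np.linalg.norm(dvec, axis=1)
                ok = dd <= th.hbond_distance_cutoff
                if h_atom is not None and ok.any():
                    h = coords[h_atom]
                    v1 = coords[d_atom] - h
                    v2 = acc - h
                    cosang = (v2 @ v1) / (
                        np.linalg.norm(v2, axis=1) * np.linalg.norm(v1) + 1e-300
                    )
                    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                    ok &= ang >= th.hbond_min_angle
                if ok.any():
                    hit_donor_atoms.append(d_atom)
            return hit_donor_atoms

        mark(np.asarray(hbond_hits(pf.hbond_donors, lf.hbond_acceptors), dtype=int), 3)
        # protein as acceptor: iterate ligand donors, mark hit protein acceptors
        if lf.hbond_donors and pf.hbond_acceptors.size:
            acc = coords[pf.hbond_acceptors]
            hit = np.zeros(len(pf.hbond_acceptors), dtype=bool)
            for d_atom, h_atom in lf.hbond_donors:
                dd = np.linalg.norm(acc - coords[d_atom], axis=1)
                ok = dd <= th.hbond_distance_cutoff
                if h_atom is not None and ok.any():
                    h = coords[h_atom]
                    v1 = coords[d_atom] - h
                    v2 = acc - h
                    cosang = (v2 @ v1) / (
                        np.linalg.norm(v2, axis=1) * np.linalg.norm(v1) + 1e-300
                    )
                    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                    ok &= ang >= th.hbond_min_angle
                hit |= ok
            mark(pf.hbond_acceptors[hit], 4)

        # SB_PP — protein cation vs ligand anion
        if self._lig_anion_atoms.size:
            for grp in pf.cationic_groups:
                d = _pairwise(coords, grp, self._lig_anion_atoms)
                if (d <= th.salt_bridge_cutoff).any():
                    mark(grp, 5)
        # SB_PN — protein anion vs ligand cation
        if self._lig_cation_atoms.size:
            for grp in pf.anionic_groups:
                d = _pairwise(coords, grp, self._lig_cation_atoms)
                if (d <= th.salt_bridge_cutoff).any():
                    mark(grp, 6)

        # MET — metal coordination
        if pf.metal_ions.size and self._lig_metal_partners.size:
            d = _pairwise(coords, pf.metal_ions, self._lig_metal_partners)
            mark(pf.metal_ions[(d <= th.metal_cutoff).any(axis=1)], 7)

        return InteractionFingerprint(bits=mat.ravel(), residue_order=self.residue_order)


def compute_fingerprint(
    frame: Frame | np.ndarray,
    system: MolecularSystem,
    features: tuple[FeatureSet, FeatureSet] | None = None,
    thresholds: InteractionThresholds | None = None,
) -> InteractionFingerprint:
    """One-shot fingerprint for a single frame.

    For scoring whole trajectories build a :class:`FingerprintCalculator`
    once and reuse it; this convenience wrapper re-perceives features on
    every call unless ``features`` is supplied.
    """
    calc = FingerprintCalculator(system, thresholds=thresholds, features=features)
    return calc.compute(frame)
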