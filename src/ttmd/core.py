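"""Molecular systems, trajectory frames, superposition and RMSD.

This module is the geometric substrate for the rest of the toolkit: a
:class:`MolecularSystem` holds the atoms of a protein--ligand complex with
their roles (protein / ligand / water / ion), a :class:`Trajectory` holds
ordered coordinate :class:`Frame` objects, and the free functions implement
least-squares rigid superposition and per-frame RMSD series.

All coordinates are in Angstrom and frames are absolute (unwrapped)
coordinates; any periodic-box imaging is the duty of the MD backend that
produced the frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import FormatError, GeometryError, SelectorError

__all__ = [
    "AtomRecord",
    "MolecularSystem",
    "Frame",
    "Trajectory",
    "read_structure",
    "write_structure",
    "read_frames",
    "write_frames",
    "superpose",
    "apply_transform",
    "rmsd",
    "rmsd_series",
    "fit_rmsd_series",
]

#: residue names recognised as water
WATER_RESNAMES = {"HOH", "WAT", "TIP3", "TIP", "SOL", "H2O", "SPC"}

#: single-atom residue names recognised as (metal or halide) ions
ION_RESNAMES = {"ZN", "MG", "MN", "CA", "FE", "NA", "K", "CL", "BR", "I", "LI", "CU", "NI", "CO", "CD"}

#: elements treated as metals by the metal-coordination channel
METAL_ELEMENTS = {"ZN", "MG", "MN", "CA", "FE", "NA", "K", "LI", "CU", "NI", "CO", "CD"}

ResidueKey = tuple[str, int, str]  # (chain, residue number, insertion code)


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a molecular system.

    ``role`` partitions the system into {protein, ligand, water, ion};
    ``partial_charge`` (e) and ``lj_params`` (sigma Angstrom, epsilon
    kcal/mol) are optional and only required for energy decomposition.
    """

    serial: int
    name: str
    element: str
    residue_id: ResidueKey
    residue_name: str
    coords: tuple[float, float, float]
    role: str
    partial_charge: float | None = None
    lj_params: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.role not in ("protein", "ligand", "water", "ion"):
            raise ValueError(f"unknown atom role {self.role!r}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom serial {self.serial}")


class MolecularSystem:
    """A protein--ligand complex: ordered atoms plus derived residue index.

    Residue order follows atom (file) order and is the order in which
    residues appear in interaction fingerprints; it includes protein
    residues and metal-ion residues (the receptor side), in that file order.
    """

    def __init__(self, atoms: Sequence[AtomRecord]):
        self.atoms: list[AtomRecord] = list(atoms)
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise FormatError("duplicate atom serial numbers in system")
        self.coords0 = np.array([a.coords for a in self.atoms], dtype=float)

        # ordered residue index (stable: file order)
        self.residues: list[ResidueKey] = []
        self.residue_names: dict[ResidueKey, str] = {}
        self._residue_atoms: dict[ResidueKey, list[int]] = {}
        seen: set[ResidueKey] = set()
        for i, a in enumerate(self.atoms):
            if a.residue_id not in seen:
                seen.add(a.residue_id)
                self.residues.append(a.residue_id)
                self.residue_names[a.residue_id] = a.residue_name
                self._residue_atoms[a.residue_id] = []
            self._residue_atoms[a.residue_id].append(i)

        self.ligand_atoms = np.array(
            [i for i, a in enumerate(self.atoms) if a.role == "ligand"], dtype=int
        )
        n_protein_res = len({a.residue_id for a in self.atoms if a.role == "protein"})
        if n_protein_res < 1 or len(self.ligand_atoms) < 1:
            raise FormatError("system needs at least one protein residue and one ligand atom")

    # ------------------------------------------------------------------ #
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def receptor_residues(self) -> list[ResidueKey]:
        """Protein plus metal-ion residues, in file order (fingerprint rows)."""
        keys = []
        for key in self.residues:
            roles = {self.atoms[i].role for i in self._residue_atoms[key]}
            if "protein" in roles or "ion" in roles:
                keys.append(key)
        return keys

    def residue_atom_indices(self, key: ResidueKey) -> np.ndarray:
        return np.asarray(self._residue_atoms[key], dtype=int)

    def indices_by_role(self, role: str) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if a.role == role], dtype=int)

    def backbone_indices(self) -> np.ndarray:
        """Protein backbone heavy atoms (N, CA, C, O)."""
        return np.array(
            [
                i
                for i, a in enumerate(self.atoms)
                if a.role == "protein" and a.name in ("N", "CA", "C", "O")
            ],
            dtype=int,
        )

    def ligand_heavy_indices(self) -> np.ndarray:
        return np.array(
            [i for i in self.ligand_atoms if self.atoms[i].element.upper() != "H"], dtype=int
        )

    def reference_frame(self) -> "Frame":
        return Frame(coords=self.coords0.copy(), time=0.0, temperature_set=0.0)


@dataclass
class Frame:
    """A single trajectory frame: absolute coordinates in Angstrom."""

    coords: np.ndarray
    time: float = 0.0  # ns
    temperature_set: float = 0.0  # K

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("frame coordinates must be (n_atoms, 3)")


@dataclass
class Trajectory:
    """Ordered frames plus a provenance tag (backend id + window index)."""

    frames: list[Frame]
    provenance: str = ""

    def __post_init__(self) -> None:
        times = [f.time for f in self.frames]
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    @property
    def final_frame(self) -> Frame:
        return self.frames[-1]

    def coordinate_array(self) -> np.ndarray:
        return np.stack([f.coords for f in self.frames])


# ---------------------------------------------------------------------- #
# structure I/O (PDB via MDAnalysis)
# ---------------------------------------------------------------------- #


def _guess_element(name: str) -> str:
    stripped = "".join(c for c in name if c.isalpha())
    if not stripped:
        return "X"
    if stripped[:2].upper() in METAL_ELEMENTS and len(stripped) >= 2:
        return stripped[:2].upper()
    return stripped[0].upper()


def _match_ligand(resname: str, chain: str, selector: str) -> bool:
    if selector.startswith("chain:"):
        return chain == selector.split(":", 1)[1]
    if selector.startswith("resname:"):
        selector = selector.split(":", 1)[1]
    return resname == selector


def read_structure(
    path: str | Path,
    ligand_selector: str,
    water_cutoff: float = 4.5,
) -> MolecularSystem:
    """Read a PDB file into a :class:`MolecularSystem`.

    ``ligand_selector`` is a residue name (optionally ``resname:<NAME>``) or
    ``chain:<ID>``. Water residues farther than ``water_cutoff`` (Angstrom,
    default 4.5) from any ligand atom are dropped; retained waters keep
    ``role='water'``. When alternate locations are present, the highest
    occupancy conformer is kept.
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))

    serials = u.atoms.ids
    if len(set(serials.tolist())) != len(serials):
        raise FormatError(f"duplicate atom serial numbers in {path}")

    try:
        elements = [e if e else None for e in u.atoms.elements]
    except Exception:
        elements = [None] * len(u.atoms)
    try:
        icodes = list(u.atoms.icodes)
    except Exception:
        icodes = [""] * len(u.atoms)
    try:
        chains = list(u.atoms.chainIDs)
    except Exception:
        chains = [seg or "A" for seg in u.atoms.segids]
    try:
        altlocs = list(u.atoms.altLocs)
    except Exception:
        altlocs = [""] * len(u.atoms)
    try:
        occupancies = list(u.atoms.occupancies)
    except Exception:
        occupancies = [1.0] * len(u.atoms)

    # resolve alternate locations: keep the highest-occupancy conformer
    best: dict[tuple, int] = {}
    for i in range(len(u.atoms)):
        key = (chains[i], int(u.atoms.resids[i]), icodes[i], u.atoms.names[i])
        if key not in best or occupancies[i] > occupancies[best[key]]:
            best[key] = i
    keep = sorted(best.values())

    records: list[AtomRecord] = []
    positions = u.atoms.positions
    for i in keep:
        name = u.atoms.names[i]
        resname = str(u.atoms.resnames[i]).strip()
        chain = str(chains[i]).strip() or "A"
        element = (elements[i] or _guess_element(name)).upper()
        if _match_ligand(resname, chain, ligand_selector):
            role = "ligand"
        elif resname in WATER_RESNAMES:
            role = "water"
        elif resname in ION_RESNAMES and element in METAL_ELEMENTS | {"CL", "BR", "I"}:
            role = "ion"
        else:
            role = "protein"
        records.append(
            AtomRecord(
                serial=int(serials[i]),
                name=str(name),
                element=element,
                residue_id=(chain, int(u.atoms.resids[i]), str(icodes[i]).strip()),
                residue_name=resname,
                coords=tuple(float(x) for x in positions[i]),
                role=role,
            )
        )

    if not any(r.role == "ligand" for r in records):
        raise SelectorError(f"ligand selector {ligand_selector!r} matched no residue in {path}")

    # drop waters beyond the cutoff from the ligand
    lig_xyz = np.array([r.coords for r in records if r.role == "ligand"])
    water_keys = {r.residue_id for r in records if r.role == "water"}
    keep_water: set[ResidueKey] = set()
    for key in water_keys:
        w_xyz = np.array([r.coords for r in records if r.residue_id == key])
        d = np.linalg.norm(w_xyz[:, None, :] - lig_xyz[None, :, :], axis=-1)
        if d.min() <= water_cutoff:
            keep_water.add(key)
    records = [r for r in records if r.role != "water" or r.residue_id in keep_water]

    return MolecularSystem(records)


def _universe_from_system(system: MolecularSystem, coords: np.ndarray | None = None):
    import MDAnalysis as mda

    n = system.n_atoms
    res_index = []
    res_keys = system.residues
    key_to_idx = {k: i for i, k in enumerate(res_keys)}
    for a in system.atoms:
        res_index.append(key_to_idx[a.residue_id])
    u = mda.Universe.empty(
        n,
        n_residues=len(res_keys),
        atom_resindex=np.array(res_index),
        residue_segindex=np.zeros(len(res_keys), dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", [a.name for a in system.atoms])
    u.add_TopologyAttr("elements", [a.element for a in system.atoms])
    u.add_TopologyAttr("ids", [a.serial for a in system.atoms])
    u.add_TopologyAttr("resnames", [system.residue_names[k] for k in res_keys])
    u.add_TopologyAttr("resids", [k[1] for k in res_keys])
    u.add_TopologyAttr("icodes", [k[2] for k in res_keys])
    u.add_TopologyAttr("chainIDs", [a.residue_id[0] for a in system.atoms])
    u.add_TopologyAttr("record_types", ["ATOM" if a.role == "protein" else "HETATM" for a in system.atoms])
    u.atoms.positions = system.coords0 if coords is None else coords
    return u


def write_structure(system: MolecularSystem, path: str | Path) -> None:
    """Write the system's reference coordinates as a PDB file."""
    import MDAnalysis as mda

    u = _universe_from_system(system)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=system.n_atoms) as w:
            w.write(u.atoms)


def write_frames(system: MolecularSystem, trajectory: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (text fixture format)."""
    import MDAnalysis as mda

    u = _universe_from_system(system)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=system.n_atoms, multiframe=True) as w:
            for f in trajectory:
                u.atoms.positions = f.coords
                w.write(u.atoms)


def read_frames(
    path: str | Path,
    system: MolecularSystem,
    dt: float = 0.1,
    temperature: float = 0.0,
    provenance: str = "",
) -> Trajectory:
    """Read trajectory frames (multi-model PDB or any MDAnalysis-readable
    coordinate container) for an existing system.

    ``dt`` (ns) assigns frame times when the container carries none.
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    if len(u.atoms) != system.n_atoms:
        raise FormatError(
            f"frame file has {len(u.atoms)} atoms, system has {system.n_atoms}"
        )
    frames = []
    for k, _ts in enumerate(u.trajectory):
        frames.append(
            Frame(coords=u.atoms.positions.astype(float).copy(), time=(k + 1) * dt,
                  temperature_set=temperature)
        )
    return Trajectory(frames=frames, provenance=provenance or str(path))


# ---------------------------------------------------------------------- #
# superposition and RMSD
# ---------------------------------------------------------------------- #


def _as_coords(frame_or_coords) -> np.ndarray:
    if isinstance(frame_or_coords, Frame):
        return frame_or_coords.coords
    return np.asarray(frame_or_coords, dtype=float)


def rmsd(a, b) -> float:
    """Plain (unfitted) RMSD between two coordinate sets."""
    a, b = _as_coords(a), _as_coords(b)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def superpose(
    mobile,
    reference,
    selection: np.ndarray | Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits the reference over the
    selection; the RMSD is the post-fit value over the selection. Requires
    at least three non-collinear selection atoms.
    """
    from MDAnalysis.analysis.align import rotation_matrix

    mob = _as_coords(mobile)
    ref = _as_coords(reference)
    if selection is not None:
        sel = np.asarray(selection, dtype=int)
        mob_s, ref_s = mob[sel], ref[sel]
    else:
        mob_s, ref_s = mob, ref
    if len(mob_s) < 3:
        raise GeometryError("superposition needs at least 3 selection atoms")
    centered = mob_s - mob_s.mean(axis=0)
    # rank < 2 means coincident or collinear points: rotation is underdetermined
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise GeometryError("degenerate (collinear or coincident) superposition selection")

    mob_mean = mob_s.mean(axis=0)
    ref_mean = ref_s.mean(axis=0)
    R, fitted_rmsd = rotation_matrix(mob_s - mob_mean, ref_s - ref_mean)
    R = np.asarray(R)
    t = ref_mean - mob_mean @ R.T
    return R, t, float(fitted_rmsd)


def apply_transform(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ np.asarray(rotation).T + translation


def _kabsch(mobile_centered: np.ndarray, ref_centered: np.ndarray) -> np.ndarray:
    """Optimal rotation R with mobile_centered @ R.T ~= ref_centered."""
    h = mobile_centered.T @ ref_centered
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    return vt.T @ np.diag([1.0, 1.0, d]) @ u.T


def fit_rmsd_series(
    traj: Trajectory,
    fit_selection: np.ndarray | Sequence[int],
    measure_selections: Sequence[np.ndarray | Sequence[int]],
    reference: Frame | np.ndarray | None = None,
    stride: int = 1,
) -> list[np.ndarray]:
    """Fit every frame onto the reference once (over ``fit_selection``) and
    measure RMSD for several selections in one pass."""
    fit_sel = np.asarray(fit_selection, dtype=int)
    meas = [np.asarray(m, dtype=int) for m in measure_selections]
    if fit_sel.size == 0 or any(m.size == 0 for m in meas):
        raise SelectorError("empty selection for RMSD series")
    ref = _as_coords(reference if reference is not None else traj.frames[0])
    ref_fit = ref[fit_sel]
    ref_mean = ref_fit.mean(axis=0)
    ref_centered = ref_fit - ref_mean
    if np.linalg.matrix_rank(ref_centered, tol=1e-8) < 2 or fit_sel.size < 3:
        raise GeometryError("degenerate (collinear or coincident) fit selection")
    ref_meas = [ref[m] for m in meas]
    out: list[list[float]] = [[] for _ in meas]
    for f in traj.frames[::stride]:
        mob_fit = f.coords[fit_sel]
        mob_mean = mob_fit.mean(axis=0)
        rot = _kabsch(mob_fit - mob_mean, ref_centered)
        moved = (f.coords - mob_mean) @ rot.T + ref_mean
        for k, m in enumerate(meas):
            diff = moved[m] - ref_meas[k]
            out[k].append(float(np.sqrt((diff * diff).sum() / len(m))))
    return [np.asarray(o) for o in out]


def rmsd_series(
    traj: Trajectory,
    fit_selection: np.ndarray | Sequence[int],
    measure_selection: np.ndarray | Sequence[int],
    reference: Frame | np.ndarray | None = None,
    stride: int = 1,
) -> np.ndarray:
    """Per-frame RMSD of ``measure_selection`` after fitting each frame onto
    the reference over ``fit_selection``.

    The reference defaults to the trajectory's first frame. ``stride``
    subsamples the saved frames (default: every frame).
    """
    return fit_rmsd_series(
        traj, fit_selection, [measure_selection], reference=reference, stride=stride
    )[0]
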