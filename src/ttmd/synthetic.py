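"""Synthetic toy complexes and a scripted MD backend.

These stand in for GPU molecular dynamics so the whole titration pipeline
is exercisable on a desk machine. The generator mimics the *fingerprint
dynamics* of a thermal titration — thermal jitter that grows with
temperature, a scripted unbinding event, a scripted partial unfold — with
no claim of physical realism: there are no forces, no thermostat and no
kinetics.

The toy complex is a ten-residue binding pocket (hydrophobic, aromatic,
H-bonding, cationic and anionic residues) around a small benzene-derived
ligand carrying a carboxylate, an ammonium nitrogen, a hydroxyl oxygen and
a methyl group. Its reference pose sets seven fingerprint bits over six
channels (HY, F2F, HB_PD, HB_PA, SB_PP, SB_PN).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aggregation import DEFAULT_MS_CUTOFF, replicate_set
from .analysis import ms_coefficient, titration_profile
from .core import AtomRecord, Frame, MolecularSystem, Trajectory
from .errors import ConfigurationError
from .protocol import EngineContract, TemperatureRamp, run_ttmd

__all__ = [
    "make_toy_complex",
    "SyntheticScenario",
    "SyntheticEngine",
    "replicate_ms_values",
    "classification_study",
]


# ---------------------------------------------------------------------- #
# toy complex construction
# ---------------------------------------------------------------------- #

_LJ_BY_ELEMENT = {
    "C": (3.40, 0.086),
    "N": (3.25, 0.170),
    "O": (2.96, 0.210),
    "S": (3.56, 0.250),
}
_Q_BY_ELEMENT = {"C": 0.0, "N": -0.30, "O": -0.40, "S": -0.10}


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _perp(direction: np.ndarray) -> np.ndarray:
    d = _unit(direction)
    ref = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    return _unit(np.cross(d, ref))


def _chain(start, direction, n, bond=1.53, zig=0.35) -> list[np.ndarray]:
    """Zig-zag chain of ``n`` atoms extending from ``start`` (excluded)."""
    d = _unit(direction)
    p = _perp(d)
    pts, cur = [], np.asarray(start, dtype=float)
    for k in range(n):
        step = _unit(d + zig * p * (-1) ** k) * bond
        cur = cur + step
        pts.append(cur.copy())
    return pts


def _backbone(ca, out_dir) -> dict[str, np.ndarray]:
    d = _unit(out_dir)
    p = _perp(d)
    n = ca + 1.47 * _unit(d + p)
    c = ca + 1.52 * _unit(d - p)
    o = c + 1.23 * d
    return {"N": n, "CA": np.asarray(ca, dtype=float), "C": c, "O": o}


def _ring(center, radius=1.39, z_offset=0.0, normal_z=True) -> list[np.ndarray]:
    center = np.asarray(center, dtype=float)
    pts = []
    for k in range(6):
        ang = np.radians(60.0 * k)
        pts.append(center + np.array([radius * np.cos(ang), radius * np.sin(ang), z_offset]))
    return pts


def make_toy_complex(seed: int = 0) -> MolecularSystem:
    """Deterministic ten-residue pocket + engineered ligand.

    The same seed always yields the identical system; different seeds apply
    a random rigid rotation/translation to the whole complex (interaction
    geometry, and therefore the reference fingerprint, is unchanged).
    Per-atom partial charges and Lennard-Jones parameters are embedded.
    """
    atoms: list[tuple[str, str, str, int, np.ndarray, str]] = []
    # (name, element, resname, resnum, xyz, role)

    def add(name, element, resname, resnum, xyz, role):
        atoms.append((name, element, resname, resnum, np.asarray(xyz, dtype=float), role))

    # ---------------- ligand (resnum 100, resname LIG) ----------------- #
    ring = _ring((0.0, 0.0, 0.0))
    for i, xyz in enumerate(ring, start=1):
        add(f"C{i}", "C", "LIG", 100, xyz, "ligand")
    c1, c2, c4, c5 = ring[0], ring[1], ring[3], ring[4]
    c7 = c1 + np.array([1.50, 0.0, 0.0])
    add("C7", "C", "LIG", 100, c7, "ligand")  # carboxylate carbon
    add("O1", "O", "LIG", 100, c7 + np.array([0.617, 1.064, 0.0]), "ligand")
    add("O2", "O", "LIG", 100, c7 + np.array([0.617, -1.064, 0.0]), "ligand")
    n1 = c4 + np.array([-1.47, 0.0, 0.0])
    add("N1", "N", "LIG", 100, n1, "ligand")  # ammonium nitrogen
    o3 = c2 + 1.43 * _unit(c2)
    add("O3", "O", "LIG", 100, o3, "ligand")  # hydroxyl oxygen
    c8 = c5 + 1.50 * _unit(c5)
    add("C8", "C", "LIG", 100, c8, "ligand")  # methyl carbon

    # --------------- interacting pocket residues ----------------------- #
    # LEU 1: hydrophobic contact CD1 ... ligand C8 at 3.4 A
    d1 = _unit(c8)
    cd1 = c8 + 3.4 * d1
    cg, cb, ca = _chain(cd1, d1, 3)
    add("CD1", "C", "LEU", 1, cd1, "protein")
    add("CD2", "C", "LEU", 1, cg + 1.53 * _perp(d1), "protein")
    add("CG", "C", "LEU", 1, cg, "protein")
    add("CB", "C", "LEU", 1, cb, "protein")
    for nm, xyz in _backbone(ca, d1).items():
        add(nm, {"N": "N", "CA": "C", "C": "C", "O": "O"}[nm], "LEU", 1, xyz, "protein")

    # PHE 2: ring stacked face-to-face 3.6 A above the ligand ring
    phe_ring = _ring((0.0, 0.0, 3.6))
    for nm, xyz in zip(("CG", "CD1", "CD2", "CE1", "CE2", "CZ"), phe_ring):
        add(nm, "C", "PHE", 2, xyz, "protein")
    d2 = _unit((1.0, 0.0, 0.6))
    cb = phe_ring[0] + 1.50 * d2
    (ca,) = _chain(cb, d2, 1)
    add("CB", "C", "PHE", 2, cb, "protein")
    for nm, xyz in _backbone(ca, d2).items():
        add(nm, {"N": "N", "CA": "C", "C": "C", "O": "O"}[nm], "PHE", 2, xyz, "protein")

    # SER 3: OG donor/acceptor 2.9 A from ligand hydroxyl O3
    d3 = _unit(o3)
    og = o3 + 2.9 * d3
    cb, ca = _chain(og, d3, 2, bond=1.47)
    add("OG", "O", "SER", 3, og, "protein")
    add("CB", "C", "SER", 3, cb, "protein")
    for nm, xyz in _backbone(ca, d3).items():
        add(nm, {"N": "N", "CA": "C", "C": "C", "O": "O"}[nm], "SER", 3, xyz, "protein")

    # LYS 4: NZ 3.1 A from the ligand carboxylate O1 (salt bridge, protein +)
    o1 = c7 + np.array([0.617, 1.064, 0.0])
    d4 = _unit(o1)
    nz = o1 + 3.1 * d4
    ce, cd, cg, cb, ca = _chain(nz, d4, 5, bond=1.52)
    for nm, xyz in (("NZ", nz), ("CE", ce), ("CD", cd), ("CG", cg), ("CB", cb)):
        add(nm, "N" if nm == "NZ" else "C", "LYS", 4, xyz, "protein")
    for nm, xyz in _backbone(ca, d4).items():
        add(nm, {"N": "N", "CA": "C", "C": "C", "O": "O"}[nm], "LYS", 4, xyz, "protein")

    # ASP 5: carboxylate OD1 3.1 A from the ligand ammonium N1 (protein -)
    od1 = n1 + np.array([-3.1, 0.0, 0.0])
    a1 = np.array([0.5, -0.866, 0.0])
    a2 = np.array([0.5, 0.866, 0.0])
    cg = od1 - 1.25 * a1
    od2 = cg + 1.25 * a2
    cb, ca = _chain(cg, (-1.0, 0.0, 0.0), 2, bond=1.52)
    for nm, el, xyz in (("OD1", "O", od1), ("OD2", "O", od2), ("CG", "C", cg), ("CB", "C", cb)):
        add(nm, el, "ASP", 5, xyz, "protein")
    for nm, xyz in _backbone(ca, (-1.0, 0.0, 0.0)).items():
        add(nm, {"N": "N", "CA": "C", "C": "C", "O": "O"}[nm], "ASP", 5, xyz, "protein")

    # --------------- filler residues (no contacts) --------------------- #
    fillers = [
        ("GLY", 6, (0.0, 0.0, -1.0), 6.5, False),
        ("ALA", 7, (-0.7, 0.7, -0.4), 8.0, True),
        ("GLY", 8, (0.3, -0.8, 0.5), 8.5, False),
        ("ALA", 9, (-0.6, -0.3, 0.7), 9.0, True),
        ("GLY", 10, (0.2, 0.9, 0.4), 25.0, False),  # beyond the energy cutoff
    ]
    for resname, resnum, direction, radius, has_cb in fillers:
        d = _unit(direction)
        ca = radius * d
        if has_cb:
            add("CB", "C", resname, resnum, ca + 1.52 * _perp(d), "protein")
        for nm, xyz in _backbone(ca, d).items():
            add(nm, {"N": "N", "CA": "C", "C": "C", "O": "O"}[nm], resname, resnum, xyz, "protein")

    # --------------- charges, LJ parameters, rigid placement ----------- #
    charge_overrides = {
        ("LIG", "N1"): 0.90,
        ("LIG", "O1"): -0.80,
        ("LIG", "O2"): -0.80,
        ("LIG", "C7"): 0.70,
        ("LIG", "O3"): -0.40,
        ("LYS", "NZ"): 0.80,
        ("ASP", "OD1"): -0.80,
        ("ASP", "OD2"): -0.80,
        ("ASP", "CG"): 0.60,
    }
    rng = np.random.default_rng(seed)
    # random rigid transform: interaction geometry is rotation-invariant
    axis_angles = rng.normal(size=3) * 0.5
    from scipy.spatial.transform import Rotation

    R = Rotation.from_rotvec(axis_angles).as_matrix()
    t = rng.normal(scale=3.0, size=3)

    records = []
    for serial, (name, element, resname, resnum, xyz, role) in enumerate(atoms, start=1):
        q = charge_overrides.get((resname, name), _Q_BY_ELEMENT[element])
        records.append(
            AtomRecord(
                serial=serial,
                name=name,
                element=element,
                residue_id=("A", resnum, ""),
                residue_name=resname,
                coords=tuple(xyz @ R.T + t),
                role=role,
                partial_charge=q,
                lj_params=_LJ_BY_ELEMENT[element],
            )
        )
    return MolecularSystem(records)


# ---------------------------------------------------------------------- #
# scripted trajectory engine
# ---------------------------------------------------------------------- #


@dataclass
class SyntheticScenario:
    """What the scripted backend should emulate.

    ``stable``: Gaussian thermal jitter about the reference pose, with
    sigma(T) = sigma0 * T / ref_temperature (contacts survive to 450 K at
    the default sigma0 = 0.3 A). ``unbinder``: identical until
    ``unbind_window``, then the ligand is translated ``unbind_distance``
    Angstrom along ``exit_vector`` (all contacts lost). ``partial_unfold``:
    stable contacts, but from ``unfold_window`` on, part of the backbone is
    displaced far enough to trip the fold monitor.
    """

    kind: str = "stable"
    unbind_window: int = 3
    sigma0: float = 0.3
    ref_temperature: float = 300.0
    exit_vector: np.ndarray = field(default_factory=lambda: _unit((1.0, 1.0, 0.5)))
    unbind_distance: float = 18.0
    unfold_window: int = 15
    unfold_shift: float = 8.0

    def __post_init__(self) -> None:
        if self.kind not in ("stable", "unbinder", "partial_unfold"):
            raise ConfigurationError(f"unknown scenario kind {self.kind!r}")
        if self.unbind_window < 1:
            raise ConfigurationError("unbind_window must be >= 1")
        self.exit_vector = _unit(self.exit_vector)

    def jitter_sigma_at(self, temperature: float) -> float:
        return self.sigma0 * temperature / self.ref_temperature


class SyntheticEngine(EngineContract):
    """Deterministic scripted backend satisfying the engine contract.

    Identical (system, temperature, length, seed) inputs produce identical
    trajectories. The engine counts windows internally, so a fresh run
    (starting with :meth:`equilibrate`) replays bit-identically.
    """

    def __init__(
        self,
        scenario: SyntheticScenario | None = None,
        frames_per_window: int = 100,
        equil_frames: int = 5,
        equil_sigma: float = 0.05,
    ):
        self.scenario = scenario or SyntheticScenario()
        self.frames_per_window = int(frames_per_window)
        self.equil_frames = int(equil_frames)
        self.equil_sigma = float(equil_sigma)
        self._window = 0

    def equilibrate(self, system: MolecularSystem, seed: int) -> Trajectory:
        self._window = 0
        rng = np.random.default_rng(seed)
        frames = []
        n = self.equil_frames
        for k in range(n - 1):
            coords = system.coords0 + rng.normal(scale=self.equil_sigma, size=(system.n_atoms, 3))
            frames.append(Frame(coords=coords, time=0.1 * (k + 1 - n), temperature_set=self.scenario.ref_temperature))
        # final equilibration frame is the exact reference pose
        frames.append(Frame(coords=system.coords0.copy(), time=0.0,
                            temperature_set=self.scenario.ref_temperature))
        return Trajectory(frames=frames, provenance="synthetic:equilibration")

    def run_window(
        self,
        system: MolecularSystem,
        start_coords: np.ndarray,
        temperature: float,
        length_ns: float,
        seed: int,
    ) -> Trajectory:
        self._window += 1
        w = self._window
        sc = self.scenario
        rng = np.random.default_rng(seed)
        sigma = sc.jitter_sigma_at(temperature)

        base = system.coords0.copy()
        if sc.kind == "unbinder" and w >= sc.unbind_window:
            base[system.ligand_atoms] += sc.exit_vector * sc.unbind_distance
        if sc.kind == "partial_unfold" and w >= sc.unfold_window:
            protein = system.indices_by_role("protein")
            half = protein[: len(protein) // 2]
            base[half] += np.array([0.0, 0.0, sc.unfold_shift])

        dt = length_ns / self.frames_per_window
        t0 = (w - 1) * length_ns
        frames = [
            Frame(
                coords=base + rng.normal(scale=sigma, size=(system.n_atoms, 3)),
                time=t0 + (k + 1) * dt,
                temperature_set=temperature,
            )
            for k in range(self.frames_per_window)
        ]
        return Trajectory(frames=frames, provenance=f"synthetic:{sc.kind}:window{w}")


# ---------------------------------------------------------------------- #
# end-to-end recovery studies
# ---------------------------------------------------------------------- #


def replicate_ms_values(
    system: MolecularSystem,
    scenario: SyntheticScenario,
    ramp: TemperatureRamp | None = None,
    n_replicates: int = 5,
    master_seed: int = 0,
    frames_per_window: int = 100,
    epsilon: float = 1e-4,
) -> list[float]:
    """Run ``n_replicates`` independent TTMD replicates and return their MS
    coefficients (the per-ligand protocol)."""
    ramp = ramp or TemperatureRamp()
    values = []
    for rep in range(n_replicates):
        engine = SyntheticEngine(scenario=scenario, frames_per_window=frames_per_window)
        seed = int(np.random.SeedSequence([master_seed, rep]).generate_state(1)[0] % (2**31))
        run = run_ttmd(system, engine, ramp, seed=seed, epsilon=epsilon,
                       store_trajectories=False)
        values.append(ms_coefficient(titration_profile(run)).value)
    return values


def classification_study(
    n_sets: int = 20,
    base_seed: int = 0,
    n_replicates: int = 5,
    ramp: TemperatureRamp | None = None,
    frames_per_window: int = 100,
    cutoff: float = DEFAULT_MS_CUTOFF,
) -> dict:
    """Tight/weak recovery over seeded synthetic replicate sets.

    For each of ``n_sets`` seeds, one stable and one early-unbinding
    (window 3) replicate set of ``n_replicates`` runs is aggregated and
    classified. Returns per-scenario recovery fractions (stable expected
    tight, unbinder expected weak) and the aggregate MS values.
    """
    ramp = ramp or TemperatureRamp()
    out = {"stable": [], "unbinder": []}
    for s in range(n_sets):
        system = make_toy_complex(seed=base_seed + s)
        for kind in ("stable", "unbinder"):
            scenario = SyntheticScenario(kind=kind)
            ms_vals = replicate_ms_values(
                system,
                scenario,
                ramp=ramp,
                n_replicates=n_replicates,
                master_seed=base_seed * 10007 + s,
                frames_per_window=frames_per_window,
            )
            out[kind].append(replicate_set(f"{kind}-{s}", ms_vals, cutoff=cutoff))
    stable_ok = np.mean([r.label == "tight" for r in out["stable"]])
    unbind_ok = np.mean([r.label == "weak" for r in out["unbinder"]])
    return {
        "stable_sets": out["stable"],
        "unbinder_sets": out["unbinder"],
        "stable_recovery": float(stable_ok),
        "unbinder_recovery": float(unbind_ok),
    }
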