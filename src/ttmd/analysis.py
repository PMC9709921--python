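"""Post-run analyses: titration profile, MS coefficient, per-residue
interaction-energy decomposition, and the three standard plots.

The titration profile is the mean IFP_CS of each TTMD-step against the
step temperature; the MS coefficient is the slope of the straight line
joining the initial state (IFP_CS = -1 at the starting temperature) and
the final step's mean at the last explored temperature:

    MS = (<IFP_CS>_end + 1) / (T_end - T_start)        [K^-1]

MS = 0 indicates a binding mode fully retained across the whole ramp
(strong binding); larger values indicate earlier loss of the native
binding mode.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Frame, MolecularSystem, ResidueKey, Trajectory
from .errors import ParameterError, UsageError
from .fingerprints import InteractionFingerprint
from .protocol import TTMDRunResult

__all__ = [
    "TitrationProfile",
    "titration_profile",
    "MSCoefficient",
    "ms_coefficient",
    "EnergyDecomposition",
    "per_residue_energy",
    "energy_decomposition",
    "most_contacted_residues",
    "render_plots",
    "COULOMB_CONSTANT",
]

#: Coulomb constant in kcal * Angstrom / (mol * e^2)
COULOMB_CONSTANT = 332.06


@dataclass
class TitrationProfile:
    """Mean IFP_CS per TTMD step vs step temperature.

    ``initial_value`` is the constant -1 of the initial (equilibrated)
    state at ``t_start``; it is stored separately from the step points
    because the first step shares the starting temperature.
    """

    points: list[tuple[float, float]]
    t_start: float
    initial_value: float = -1.0

    def __post_init__(self) -> None:
        temps = [t for t, _ in self.points]
        if any(a >= b for a, b in zip(temps, temps[1:])):
            raise ValueError("profile temperatures must be strictly increasing")
        if any(v < -1 - 1e-9 or v > 1e-9 for _, v in self.points):
            raise ValueError("profile values must lie in [-1, 0]")

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([t for t, _ in self.points])

    @property
    def values(self) -> np.ndarray:
        return np.array([v for _, v in self.points])

    @property
    def final_mean(self) -> float:
        return self.points[-1][1]

    @property
    def t_end(self) -> float:
        return self.points[-1][0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"temperature_K": self.temperatures, "mean_ifp_cs": self.values})


def titration_profile(run: TTMDRunResult) -> TitrationProfile:
    """Profile of a run: one (temperature, mean IFP_CS) point per executed
    step, plus the initial state (-1 at t_start) kept alongside."""
    if not run.steps:
        raise UsageError("run has no executed steps")
    points = [(s.temperature, s.mean_ifp_cs) for s in run.steps]
    return TitrationProfile(points=points, t_start=run.ramp.t_start)


@dataclass(frozen=True)
class MSCoefficient:
    """The binding-stability slope statistic, units K^-1."""

    value: float
    t_start: float
    t_end: float
    final_mean_ifp: float


def ms_coefficient(profile: TitrationProfile) -> MSCoefficient:
    """Slope of the line through (t_start, -1) and (t_end, final mean).

    t_end is the last explored temperature, so early-terminated runs get a
    steeper slope than runs surviving the full ramp.
    """
    t_start, t_end = profile.t_start, profile.t_end
    if t_end <= t_start:
        raise UsageError("MS slope undefined: final temperature equals the starting one")
    value = (profile.final_mean - profile.initial_value) / (t_end - t_start)
    return MSCoefficient(
        value=float(value), t_start=t_start, t_end=t_end, final_mean_ifp=profile.final_mean
    )


# ---------------------------------------------------------------------- #
# per-residue nonbonded interaction energy
# ---------------------------------------------------------------------- #


def _nonbonded_params(system: MolecularSystem, indices: np.ndarray):
    missing = [
        system.atoms[i].serial
        for i in indices
        if system.atoms[i].partial_charge is None or system.atoms[i].lj_params is None
    ]
    if missing:
        raise ParameterError(
            f"missing partial charge / LJ parameters for atom serials {missing}"
        )
    q = np.array([system.atoms[i].partial_charge for i in indices])
    sig = np.array([system.atoms[i].lj_params[0] for i in indices])
    eps = np.array([system.atoms[i].lj_params[1] for i in indices])
    return q, sig, eps


def per_residue_energy(
    frame: Frame | np.ndarray,
    system: MolecularSystem,
    cutoff: float = 9.0,
) -> pd.DataFrame:
    """Ligand--residue Lennard-Jones and Coulomb energies for one frame.

    Pair energies use Lorentz-Berthelot combination rules and plain Coulomb
    electrostatics, both truncated at ``cutoff`` (Angstrom; default 9.0,
    the simulation's LJ cutoff). Returns one row per receptor residue with
    at least one atom pair inside the cutoff: columns
    ``residue`` (key), ``e_lj`` and ``e_elec`` in kcal/mol.
    """
    coords = frame.coords if isinstance(frame, Frame) else np.asarray(frame, dtype=float)
    lig_idx = system.ligand_atoms
    q_l, sig_l, eps_l = _nonbonded_params(system, lig_idx)
    lig_xyz = coords[lig_idx]

    rows = []
    for key in system.receptor_residues:
        res_idx = system.residue_atom_indices(key)
        res_xyz = coords[res_idx]
        d = np.linalg.norm(res_xyz[:, None, :] - lig_xyz[None, :, :], axis=-1)
        within = d <= cutoff
        if not within.any():
            continue
        q_r, sig_r, eps_r = _nonbonded_params(system, res_idx)
        sig_ij = 0.5 * (sig_r[:, None] + sig_l[None, :])
        eps_ij = np.sqrt(eps_r[:, None] * eps_l[None, :])
        with np.errstate(divide="ignore"):
            sr6 = (sig_ij / d) ** 6
            e_lj = 4.0 * eps_ij * (sr6**2 - sr6)
            e_elec = COULOMB_CONSTANT * q_r[:, None] * q_l[None, :] / d
        rows.append(
            {
                "residue": key,
                "e_lj": float(e_lj[within].sum()),
                "e_elec": float(e_elec[within].sum()),
            }
        )
    return pd.DataFrame(rows, columns=["residue", "e_lj", "e_elec"])


def residue_label(key: ResidueKey, resname: str = "") -> str:
    chain, resnum, icode = key
    return f"{chain}:{resname}{resnum}{icode}"


@dataclass
class EnergyDecomposition:
    """Per-frame, per-residue interaction energies for a whole run."""

    times: np.ndarray  # ns
    residues: list[ResidueKey]
    e_lj: np.ndarray  # (n_frames, n_residues)
    e_elec: np.ndarray  # (n_frames, n_residues)
    labels: list[str] | None = None

    @property
    def total(self) -> np.ndarray:
        return self.e_lj + self.e_elec

    def column_labels(self) -> list[str]:
        return self.labels or [residue_label(k) for k in self.residues]

    def to_frame(self) -> pd.DataFrame:
        """Total (LJ + electrostatic) energy table, one column per residue."""
        df = pd.DataFrame(self.total, columns=self.column_labels())
        df.insert(0, "time_ns", self.times)
        return df


def energy_decomposition(
    run: TTMDRunResult, system: MolecularSystem, cutoff: float = 9.0, stride: int = 1
) -> EnergyDecomposition:
    """Decomposition over every stored frame of every executed step."""
    residues = system.receptor_residues
    col = {key: j for j, key in enumerate(residues)}
    times, lj_rows, el_rows = [], [], []
    for step in run.steps:
        if step.trajectory is None:
            raise UsageError("run was executed without stored trajectories")
        for f in step.trajectory.frames[::stride]:
            df = per_residue_energy(f, system, cutoff=cutoff)
            lj = np.zeros(len(residues))
            el = np.zeros(len(residues))
            for _, row in df.iterrows():
                lj[col[row["residue"]]] = row["e_lj"]
                el[col[row["residue"]]] = row["e_elec"]
            times.append(f.time)
            lj_rows.append(lj)
            el_rows.append(el)
    return EnergyDecomposition(
        times=np.array(times), residues=list(residues), e_lj=np.array(lj_rows),
        e_elec=np.array(el_rows),
        labels=[residue_label(k, system.residue_names[k]) for k in residues],
    )


def most_contacted_residues(
    fingerprints: list[InteractionFingerprint], n: int = 25
) -> list[ResidueKey]:
    """The ``n`` residues with any fingerprint bit set in the most frames.

    Ties are broken by residue (file) order; fewer than ``n`` contacted
    residues returns all of them.
    """
    if not fingerprints:
        return []
    order = fingerprints[0].residue_order
    counts = np.zeros(len(order), dtype=int)
    for fp in fingerprints:
        counts += fp.to_matrix().any(axis=1)
    contacted = [i for i in range(len(order)) if counts[i] > 0]
    contacted.sort(key=lambda i: (-counts[i], i))
    return [order[i] for i in contacted[:n]]


# ---------------------------------------------------------------------- #
# plots
# ---------------------------------------------------------------------- #


def render_plots(
    profile: TitrationProfile,
    timeseries: pd.DataFrame,
    out_dir: str | Path,
    energy_table: pd.DataFrame | None = None,
    contact_order: list[str] | None = None,
    fmt: str = "png",
) -> list[Path]:
    """Produce the three standard TTMD plots under ``out_dir``.

    1. titration profile with the interpolating start-to-end line (slope,
       i.e. the MS coefficient, in the legend);
    2. time-resolved per-residue interaction-energy heat map for the (up
       to) 25 most contacted residues (when an energy table is given);
    3. ligand / backbone RMSD and IFP_CS against simulation time.

    ``timeseries`` needs columns ``time_ns``, ``ifp_cs``, ``backbone_rmsd``
    and ``ligand_rmsd``; ``energy_table`` has ``time_ns`` plus one column
    per residue. ``contact_order`` lists the energy-table columns in
    contact-frequency order (most contacted first); without it, residues
    are ranked by mean absolute interaction energy.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    ms = ms_coefficient(profile)

    # 1 — titration profile
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(profile.temperatures, profile.values, "o-", label="mean IFP$_{CS}$ per step")
    ax.plot(
        [profile.t_start, ms.t_end],
        [profile.initial_value, ms.final_mean_ifp],
        "--",
        color="crimson",
        label=f"slope (MS) = {ms.value:.4f}",
    )
    ax.set_xlabel("temperature (K)")
    ax.set_ylabel("mean IFP$_{CS}$")
    ax.set_ylim(-1.05, 0.05)
    ax.legend()
    fig.tight_layout()
    p = out_dir / f"titration_profile.{fmt}"
    fig.savefig(p)
    plt.close(fig)
    written.append(p)

    # 2 — per-residue energy heat map (up to 25 most contacted residues)
    if energy_table is not None and len(energy_table):
        cols = [c for c in energy_table.columns if c != "time_ns"]
        if contact_order:
            ranked = [c for c in contact_order if c in cols][:25]
        else:
            strength = energy_table[cols].abs().mean(axis=0)
            ranked = strength.sort_values(ascending=False).index[:25].tolist()
        ranked = [c for c in cols if c in set(ranked)]  # back to residue order
        if ranked:
            fig, ax = plt.subplots(figsize=(8, 4.5))
            sns.heatmap(
                energy_table[ranked].to_numpy().T,
                ax=ax,
                cmap="vlag",
                center=0.0,
                cbar_kws={"label": "E (kcal/mol)"},
            )
            ax.set_yticks(np.arange(len(ranked)) + 0.5)
            ax.set_yticklabels(ranked, rotation=0, fontsize=7)
            ax.set_xlabel("frame")
            ax.set_ylabel("residue")
            fig.tight_layout()
            p = out_dir / f"energy_heatmap.{fmt}"
            fig.savefig(p)
            plt.close(fig)
            written.append(p)

    # 3 — RMSD + IFP_CS vs time
    t = timeseries["time_ns"].to_numpy()
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(t, timeseries["ligand_rmsd"], label="ligand RMSD", color="tab:orange", lw=0.9)
    ax.plot(t, timeseries["backbone_rmsd"], label="backbone RMSD", color="tab:blue", lw=0.9)
    ax.set_xlabel("time (ns)")
    ax.set_ylabel("RMSD (Å)")
    ax2 = ax.twinx()
    ax2.plot(t, timeseries["ifp_cs"], label="IFP$_{CS}$", color="tab:green", lw=0.9)
    ax2.set_ylabel("IFP$_{CS}$")
    ax2.set_ylim(-1.05, 0.05)
    h1, l1 = ax.get_legend_handles_labels()
    h2, l2 = ax2.get_legend_handles_labels()
    ax.legend(h1 + h2, l1 + l2, loc="upper left", fontsize=8)
    fig.tight_layout()
    p = out_dir / f"rmsd_ifpcs.{fmt}"
    fig.savefig(p)
    plt.close(fig)
    written.append(p)
    return written
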