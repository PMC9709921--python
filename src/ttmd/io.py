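"""Text I/O helpers: per-atom parameter tables and run artifacts.

A parameter table is a plain TSV with columns ``serial``, ``name``,
``charge`` (e), ``sigma`` (Angstrom) and ``epsilon`` (kcal/mol); it carries
the nonbonded parameters a PDB file cannot hold.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from .core import AtomRecord, MolecularSystem
from .errors import ParameterError

__all__ = [
    "parameter_table",
    "write_parameter_table",
    "read_parameter_table",
    "apply_parameters",
    "save_results",
    "load_run_record",
]


def parameter_table(system: MolecularSystem) -> pd.DataFrame:
    rows = []
    for a in system.atoms:
        if a.partial_charge is None or a.lj_params is None:
            raise ParameterError(f"atom serial {a.serial} has no nonbonded parameters")
        rows.append(
            {
                "serial": a.serial,
                "name": a.name,
                "charge": a.partial_charge,
                "sigma": a.lj_params[0],
                "epsilon": a.lj_params[1],
            }
        )
    return pd.DataFrame(rows)


def write_parameter_table(system: MolecularSystem, path: str | Path) -> None:
    parameter_table(system).to_csv(path, sep="\t", index=False)


def read_parameter_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def apply_parameters(
    system: MolecularSystem, table: pd.DataFrame | str | Path
) -> MolecularSystem:
    """Return a new system with charges/LJ parameters from a table, matched
    by atom serial."""
    if not isinstance(table, pd.DataFrame):
        table = read_parameter_table(table)
    by_serial = {int(r.serial): r for r in table.itertuples()}
    missing = [a.serial for a in system.atoms if a.serial not in by_serial]
    if missing:
        raise ParameterError(f"parameter table lacks atom serials {missing}")
    records = [
        dataclasses.replace(
            a,
            partial_charge=float(by_serial[a.serial].charge),
            lj_params=(float(by_serial[a.serial].sigma), float(by_serial[a.serial].epsilon)),
        )
        for a in system.atoms
    ]
    return MolecularSystem(records)


# ---------------------------------------------------------------------- #
# run artifacts
# ---------------------------------------------------------------------- #


def save_results(results, out_dir: str | Path, with_energies: bool = True) -> Path:
    """Persist a fitted run as text artifacts under ``out_dir``:

    * ``run.json`` — step means, termination, MS coefficient, contact order
    * ``timeseries.csv`` — per-frame time, temperature, IFP_CS, RMSDs
    * ``profile.csv`` — the titration profile points
    * ``energy.csv`` — per-frame per-residue energies (when computable)
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "run.json", "w") as fh:
        json.dump(results.to_dict(), fh, indent=2)
    results.timeseries().to_csv(out_dir / "timeseries.csv", index=False)
    results.profile.to_frame().to_csv(out_dir / "profile.csv", index=False)
    if with_energies and results.run.steps[0].trajectory is not None:
        try:
            results.energies().to_frame().to_csv(out_dir / "energy.csv", index=False)
        except ParameterError:
            pass  # systems without per-atom parameters: no energy table
    return out_dir


def load_run_record(run_dir: str | Path) -> dict:
    """Load the saved artifacts of one run (for re-analysis/aggregation)."""
    run_dir = Path(run_dir)
    with open(run_dir / "run.json") as fh:
        record = json.load(fh)
    record["timeseries"] = pd.read_csv(run_dir / "timeseries.csv")
    profile = pd.read_csv(run_dir / "profile.csv")
    record["profile_points"] = list(
        zip(profile["temperature_K"].tolist(), profile["mean_ifp_cs"].tolist())
    )
    energy_path = run_dir / "energy.csv"
    record["energy_table"] = pd.read_csv(energy_path) if energy_path.exists() else None
    return record
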