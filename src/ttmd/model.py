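"""Model-style front end: a :class:`TTMD` object built from a complex and
an engine, whose :meth:`TTMD.fit` executes the titration and returns a
:class:`TTMDResults` carrying the per-step scores, the titration profile,
the MS coefficient, diagnostics and a ``summary()`` table.

Typical use::

    from ttmd import TTMD
    from ttmd.synthetic import make_toy_complex, SyntheticEngine, SyntheticScenario

    system = make_toy_complex(seed=0)
    model = TTMD(system, engine=SyntheticEngine(SyntheticScenario("stable")))
    res = model.fit(seed=1)
    print(res.summary())
    reps = model.fit_replicates(n_replicates=5, master_seed=1)
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .aggregation import DEFAULT_MS_CUTOFF, ReplicateSet, replicate_set
from .analysis import (
    EnergyDecomposition,
    MSCoefficient,
    TitrationProfile,
    energy_decomposition,
    most_contacted_residues,
    ms_coefficient,
    render_plots,
    residue_label,
    titration_profile,
)
from .config import InteractionThresholds, RunConfig
from .core import MolecularSystem, read_structure
from .errors import ConfigurationError, UsageError
from .protocol import EngineContract, TemperatureRamp, TTMDRunResult, monitor_fold, run_ttmd

__all__ = ["TTMD", "TTMDResults"]


class TTMD:
    """Thermal-titration model for one protein--ligand complex.

    Parameters
    ----------
    system:
        The complex (reference pose defines fingerprint features).
    engine:
        An :class:`~ttmd.protocol.EngineContract` backend; defaults to the
        synthetic stable-binder backend.
    ramp:
        Temperature schedule (default 300 -> 450 K, 10 K steps, 10 ns).
    thresholds:
        Interaction-geometry thresholds for the fingerprint channels.
    epsilon:
        Termination tolerance: a step whose mean IFP_CS is >= -epsilon
        counts as "binding mode never sampled" and stops the run.
    """

    def __init__(
        self,
        system: MolecularSystem,
        engine: EngineContract | None = None,
        ramp: TemperatureRamp | None = None,
        thresholds: InteractionThresholds | None = None,
        epsilon: float = 1e-4,
        stride: int = 1,
        backbone_threshold: float = 5.0,
        ms_cutoff: float = DEFAULT_MS_CUTOFF,
    ):
        if engine is None:
            from .synthetic import SyntheticEngine

            engine = SyntheticEngine()
        self.system = system
        self.engine = engine
        self.ramp = ramp or TemperatureRamp()
        self.thresholds = thresholds or InteractionThresholds()
        self.epsilon = float(epsilon)
        self.stride = int(stride)
        self.backbone_threshold = float(backbone_threshold)
        self.ms_cutoff = float(ms_cutoff)

    # ------------------------------------------------------------------ #
    @classmethod
    def from_pdb(
        cls,
        path: str | Path,
        ligand_selector: str,
        water_cutoff: float = 4.5,
        **kwargs,
    ) -> "TTMD":
        """Build a model straight from a PDB file."""
        return cls(read_structure(path, ligand_selector, water_cutoff=water_cutoff), **kwargs)

    @classmethod
    def from_config(cls, config: RunConfig, system: MolecularSystem | None = None) -> "TTMD":
        """Build a model from a validated run configuration."""
        from .io import apply_parameters
        from .synthetic import SyntheticEngine, SyntheticScenario, make_toy_complex

        if system is None:
            if config.system.pdb is None:
                system = make_toy_complex(seed=config.replicates.master_seed)
            else:
                system = read_structure(
                    config.system.pdb,
                    config.system.ligand,
                    water_cutoff=config.system.water_cutoff,
                )
                if config.system.params:
                    system = apply_parameters(system, config.system.params)
        if config.engine.kind != "synthetic":
            raise ConfigurationError(
                "external engines require a user-supplied EngineContract adapter"
            )
        engine = SyntheticEngine(
            SyntheticScenario(
                kind=config.engine.scenario,
                unbind_window=config.engine.unbind_window,
                sigma0=config.engine.jitter_sigma0,
            ),
            frames_per_window=config.engine.frames_per_window,
        )
        ramp = TemperatureRamp(
            t_start=config.ramp.t_start,
            t_end=config.ramp.t_end,
            increment=config.ramp.increment,
            window_length=config.ramp.window_length_ns,
        )
        return cls(
            system,
            engine=engine,
            ramp=ramp,
            thresholds=config.interactions,
            epsilon=config.scoring.epsilon,
            stride=config.scoring.stride,
            backbone_threshold=config.backbone_threshold,
            ms_cutoff=config.ms_cutoff,
        )

    # ------------------------------------------------------------------ #
    def fit(self, seed: int = 0, store_trajectories: bool = True) -> "TTMDResults":
        """Execute one full TTMD run (one replicate)."""
        run = run_ttmd(
            self.system,
            self.engine,
            self.ramp,
            thresholds=self.thresholds,
            epsilon=self.epsilon,
            stride=self.stride,
            seed=seed,
            store_trajectories=store_trajectories,
        )
        return TTMDResults(model=self, run=run)

    def fit_replicates(
        self,
        n_replicates: int = 5,
        master_seed: int = 0,
        ligand_id: str = "ligand",
        store_trajectories: bool = False,
    ) -> tuple[ReplicateSet, list["TTMDResults"]]:
        """Run the full per-ligand protocol: ``n_replicates`` independent
        runs, trimmed-mean aggregation and tight/weak classification."""
        results = []
        for rep in range(n_replicates):
            seed = int(
                np.random.SeedSequence([master_seed, rep]).generate_state(1)[0] % (2**31)
            )
            results.append(self.fit(seed=seed, store_trajectories=store_trajectories))
        ms_values = [r.ms.value for r in results]
        return replicate_set(ligand_id, ms_values, cutoff=self.ms_cutoff), results


@dataclass
class TTMDResults:
    """Fitted results of one TTMD run."""

    model: TTMD
    run: TTMDRunResult

    def __post_init__(self) -> None:
        self.profile: TitrationProfile = titration_profile(self.run)
        self.ms: MSCoefficient = ms_coefficient(self.profile)
        self.fold_flags: list[bool] = monitor_fold(self.run, self.model.backbone_threshold)
        self._energies: EnergyDecomposition | None = None

    # ------------------------------------------------------------------ #
    @property
    def terminated_early(self) -> bool:
        return self.run.terminated_early

    @property
    def last_temperature(self) -> float:
        return self.run.last_temperature

    def timeseries(self) -> pd.DataFrame:
        """Per-frame table: time, set temperature, IFP_CS, RMSDs."""
        rows = []
        for step in self.run.steps:
            s = step.similarity
            rows.append(
                pd.DataFrame(
                    {
                        "time_ns": s.times,
                        "temperature_K": np.full(len(s), step.temperature),
                        "ifp_cs": s.values,
                        "backbone_rmsd": step.backbone_rmsd,
                        "ligand_rmsd": step.ligand_rmsd,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def energies(self, cutoff: float = 9.0, stride: int = 1) -> EnergyDecomposition:
        """Per-residue interaction-energy decomposition (needs stored
        trajectories and per-atom parameters)."""
        if self._energies is None:
            self._energies = energy_decomposition(
                self.run, self.model.system, cutoff=cutoff, stride=stride
            )
        return self._energies

    def most_contacted(self, n: int = 25) -> list[str]:
        """Labels of the n most contacted residues (by frames with any bit)."""
        fps = [fp for step in self.run.steps for fp in step.similarity.fingerprints]
        keys = most_contacted_residues(fps, n=n)
        names = self.model.system.residue_names
        return [residue_label(k, names[k]) for k in keys]

    def plot(self, out_dir: str | Path, with_energies: bool = True, fmt: str = "png"):
        """Write the three standard plots; returns the file paths."""
        energy_table = None
        if with_energies and self.run.steps[0].trajectory is not None:
            try:
                energy_table = self.energies().to_frame()
            except Exception:
                energy_table = None
        return render_plots(
            self.profile,
            self.timeseries(),
            out_dir,
            energy_table=energy_table,
            contact_order=self.most_contacted(),
            fmt=fmt,
        )

    # ------------------------------------------------------------------ #
    def classification(self) -> str:
        """Tight/weak label of this single run's MS against the cutoff
        (the per-ligand protocol aggregates five replicates instead)."""
        from .aggregation import classify

        return classify(self.ms.value, self.model.ms_cutoff)

    def summary(self) -> str:
        """Human-readable run summary table."""
        sys_ = self.model.system
        lines = [
            "Thermal Titration MD results",
            "=" * 64,
            f"residues: {len(sys_.receptor_residues):>4d}    ligand atoms: "
            f"{len(sys_.ligand_atoms):>4d}    reference bits: {int(self.run.reference.bits.sum())}",
            f"ramp: {self.model.ramp.t_start:g} -> {self.model.ramp.t_end:g} K, "
            f"+{self.model.ramp.increment:g} K / {self.model.ramp.window_length:g} ns "
            f"({self.model.ramp.n_windows} windows)",
            "-" * 64,
            f"{'step':>4} {'T (K)':>8} {'<IFP_CS>':>10} {'max bb RMSD':>12} {'fold':>6}",
        ]
        for i, step in enumerate(self.run.steps):
            flag = "FLAG" if self.fold_flags[i] else "ok"
            lines.append(
                f"{i + 1:>4} {step.temperature:>8.1f} {step.mean_ifp_cs:>10.4f} "
                f"{step.backbone_rmsd_max:>12.2f} {flag:>6}"
            )
        lines += [
            "-" * 64,
            f"terminated early: {self.run.terminated_early}    "
            f"last temperature: {self.run.last_temperature:g} K",
            f"MS coefficient: {self.ms.value:.6f} K^-1  "
            f"(final <IFP_CS> = {self.ms.final_mean_ifp:.4f} at {self.ms.t_end:g} K)",
            f"single-run label at cutoff {self.model.ms_cutoff:g}: {self.classification()}",
            "=" * 64,
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-serializable record of the run."""
        return {
            "seed": self.run.seed,
            "terminated_early": self.run.terminated_early,
            "last_temperature": self.run.last_temperature,
            "t_start": self.model.ramp.t_start,
            "ms": {
                "value": self.ms.value,
                "t_start": self.ms.t_start,
                "t_end": self.ms.t_end,
                "final_mean_ifp": self.ms.final_mean_ifp,
            },
            "steps": [
                {
                    "temperature": s.temperature,
                    "mean_ifp_cs": s.mean_ifp_cs,
                    "backbone_rmsd_max": s.backbone_rmsd_max,
                    "n_frames": len(s.similarity),
                    "fold_flag": bool(flag),
                }
                for s, flag in zip(self.run.steps, self.fold_flags)
            ],
            "most_contacted": self.most_contacted(),
        }
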