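"""The thermal-titration protocol: temperature ramp, window-by-window
execution against an MD-engine contract, and the early-termination rule.

A TTMD run is a sequence of fixed-length MD windows ("TTMD-steps") at
stepwise increasing temperatures. After each window the mean IFP_CS is
computed; if the original binding mode was never sampled during the window
(mean score indistinguishable from zero) the run terminates early,
otherwise the next window starts from the previous window's final frame.
"""

from __future__ import annotations

import abc
from dataclasses import dataclass, field

import numpy as np

from .core import Frame, MolecularSystem, Trajectory, fit_rmsd_series
from .config import InteractionThresholds
from .errors import ConfigurationError, UsageError
from .fingerprints import FingerprintCalculator, InteractionFingerprint
from .scoring import SimilaritySeries, reference_fingerprint, score_trajectory, window_average

__all__ = [
    "TemperatureRamp",
    "build_ramp",
    "EngineContract",
    "TTMDStepResult",
    "TTMDRunResult",
    "run_ttmd",
    "monitor_fold",
    "derive_window_seed",
]


@dataclass(frozen=True)
class TemperatureRamp:
    """Arithmetic temperature schedule: t_start, t_start+increment, ... <= t_end.

    The default protocol is 300 -> 450 K in 10 K steps of 10 ns each
    (16 windows). No partial step beyond ``t_end`` is generated.
    """

    t_start: float = 300.0
    t_end: float = 450.0
    increment: float = 10.0
    window_length: float = 10.0  # ns

    def __post_init__(self) -> None:
        if self.increment <= 0:
            raise ConfigurationError("ramp increment must be > 0")
        if self.window_length <= 0:
            raise ConfigurationError("window length must be > 0")
        if self.t_end < self.t_start:
            raise ConfigurationError("t_end must be >= t_start")

    @property
    def temperatures(self) -> np.ndarray:
        n = int(np.floor((self.t_end - self.t_start) / self.increment + 1e-9)) + 1
        return self.t_start + self.increment * np.arange(n)

    @property
    def n_windows(self) -> int:
        return len(self.temperatures)


def build_ramp(
    t_start: float = 300.0,
    t_end: float = 450.0,
    increment: float = 10.0,
    window_length: float = 10.0,
) -> TemperatureRamp:
    """Validated constructor for :class:`TemperatureRamp`."""
    return TemperatureRamp(t_start, t_end, increment, window_length)


class EngineContract(abc.ABC):
    """Interface every MD backend must satisfy.

    Real-engine physics (minimization, restrained equilibration,
    thermostats) lives behind this contract; the built-in synthetic backend
    implements it deterministically for a fixed seed.
    """

    @abc.abstractmethod
    def equilibrate(self, system: MolecularSystem, seed: int) -> Trajectory:
        """Produce the equilibration trajectory; its final frame defines the
        reference fingerprint and the starting coordinates of window 1."""

    @abc.abstractmethod
    def run_window(
        self,
        system: MolecularSystem,
        start_coords: np.ndarray,
        temperature: float,
        length_ns: float,
        seed: int,
    ) -> Trajectory:
        """Run one NVT window at ``temperature`` starting from
        ``start_coords`` (velocities re-thermalized at the new temperature)."""


def derive_window_seed(master_seed: int, window_index: int) -> int:
    """Deterministic per-window sub-seed from the replicate master seed."""
    return int(np.random.SeedSequence([master_seed, window_index]).generate_state(1)[0] % (2**31))


@dataclass
class TTMDStepResult:
    """Scored outcome of one TTMD window."""

    temperature: float
    trajectory_ref: str
    similarity: SimilaritySeries
    mean_ifp_cs: float
    backbone_rmsd: np.ndarray
    ligand_rmsd: np.ndarray
    trajectory: Trajectory | None = None

    @property
    def backbone_rmsd_max(self) -> float:
        return float(self.backbone_rmsd.max()) if self.backbone_rmsd.size else 0.0


@dataclass
class TTMDRunResult:
    """Full record of one TTMD run (one replicate)."""

    steps: list[TTMDStepResult]
    terminated_early: bool
    last_temperature: float
    seed: int
    ramp: TemperatureRamp
    reference: InteractionFingerprint
    equilibration: Trajectory | None = None
    failed: bool = False
    failure: str | None = None

    @property
    def step_means(self) -> np.ndarray:
        return np.array([s.mean_ifp_cs for s in self.steps])

    @property
    def step_temperatures(self) -> np.ndarray:
        return np.array([s.temperature for s in self.steps])


def run_ttmd(
    system: MolecularSystem,
    engine: EngineContract,
    ramp: TemperatureRamp,
    *,
    thresholds: InteractionThresholds | None = None,
    epsilon: float = 1e-4,
    stride: int = 1,
    seed: int = 0,
    store_trajectories: bool = True,
) -> TTMDRunResult:
    """Execute a full TTMD run.

    Windows run in ramp order, each starting from the previous window's
    final frame. After each window the mean IFP_CS is computed; the run
    stops as soon as the mean is >= ``-epsilon`` (the binding mode was not
    sampled during the whole step) or when the ramp is exhausted. An engine
    failure mid-window marks the run failed and preserves partial results.
    """
    calc = FingerprintCalculator(system, thresholds=thresholds)
    equil = engine.equilibrate(system, seed=derive_window_seed(seed, 0))
    reference = reference_fingerprint(equil, calc)
    ref_coords = equil.final_frame.coords
    backbone = system.backbone_indices()
    ligand = system.ligand_heavy_indices()

    steps: list[TTMDStepResult] = []
    terminated = False
    failed, failure = False, None
    start = ref_coords
    for widx, temp in enumerate(ramp.temperatures, start=1):
        try:
            traj = engine.run_window(
                system, start, temp, ramp.window_length, seed=derive_window_seed(seed, widx)
            )
        except Exception as exc:  # engine failure: preserve partial results
            failed, failure = True, f"window {widx} at {temp:g} K: {exc}"
            break
        series = score_trajectory(traj, calc, reference, window_id=widx, stride=stride)
        mean = window_average(series)
        bb, lig = fit_rmsd_series(
            traj, backbone, [backbone, ligand], reference=ref_coords, stride=stride
        )
        steps.append(
            TTMDStepResult(
                temperature=float(temp),
                trajectory_ref=traj.provenance,
                similarity=series,
                mean_ifp_cs=mean,
                backbone_rmsd=bb,
                ligand_rmsd=lig,
                trajectory=traj if store_trajectories else None,
            )
        )
        start = traj.final_frame.coords
        if mean >= -epsilon:
            terminated = True
            break

    if not steps:
        raise UsageError(f"no TTMD step completed ({failure or 'empty ramp'})")
    return TTMDRunResult(
        steps=steps,
        terminated_early=terminated,
        last_temperature=steps[-1].temperature,
        seed=seed,
        ramp=ramp,
        reference=reference,
        equilibration=equil if store_trajectories else None,
        failed=failed,
        failure=failure,
    )


def monitor_fold(run: TTMDRunResult, backbone_threshold: float) -> list[bool]:
    """Advisory fold-integrity flags: True for every step whose maximum
    backbone RMSD exceeds the threshold. Does not stop a run."""
    return [s.backbone_rmsd_max > backbone_threshold for s in run.steps]
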