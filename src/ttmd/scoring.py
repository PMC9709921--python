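"""IFP_CS scoring: cosine similarity of per-frame fingerprints against the
equilibrated reference.

The score is the negated cosine similarity between the query and reference
bit vectors: -1 means the query reproduces every interaction determinant of
the reference (total superposition), 0 means every reference determinant is
lost. A query with no set bits scores exactly 0 by convention (the cosine
is undefined for a null vector; total interaction loss is the semantics).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Trajectory
from .errors import ConfigurationError, UsageError
from .fingerprints import FingerprintCalculator, InteractionFingerprint

__all__ = [
    "ifp_cs",
    "reference_fingerprint",
    "SimilaritySeries",
    "score_trajectory",
    "window_average",
]


def ifp_cs(query: InteractionFingerprint, reference: InteractionFingerprint) -> float:
    """Interaction-fingerprint cosine-similarity score, in [-1, 0]."""
    if len(query) != len(reference) or query.residue_order != reference.residue_order:
        raise UsageError("query and reference fingerprints must share residue/channel order")
    q = query.bits.astype(np.int64)
    r = reference.bits.astype(np.int64)
    rr = int(r @ r)
    if rr == 0:
        raise ConfigurationError(
            "reference fingerprint has no set bits (no protein-ligand contacts)"
        )
    qq = int(q @ q)
    if qq == 0:
        return 0.0
    dot = int(q @ r)
    if dot * dot == qq * rr:  # exact endpoint for identical bit patterns
        return -1.0
    return float(-dot / np.sqrt(qq * rr))


def reference_fingerprint(
    equilibration_traj: Trajectory, calculator: FingerprintCalculator
) -> InteractionFingerprint:
    """Fingerprint of the last equilibration frame (the scoring reference)."""
    if len(equilibration_traj) == 0:
        raise UsageError("equilibration trajectory is empty")
    fp = calculator.compute(equilibration_traj.final_frame)
    if fp.bits.sum() == 0:
        raise ConfigurationError(
            "reference frame has no protein-ligand contacts; cannot score against it"
        )
    return fp


@dataclass
class SimilaritySeries:
    """Per-frame IFP_CS values for one TTMD window."""

    values: np.ndarray
    reference: InteractionFingerprint
    window_id: int = 0
    times: np.ndarray = field(default_factory=lambda: np.empty(0))
    temperature: float = 0.0
    fingerprints: list[InteractionFingerprint] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and (self.values.min() < -1 - 1e-9 or self.values.max() > 1e-9):
            raise ValueError("IFP_CS values must lie in [-1, 0]")

    def __len__(self) -> int:
        return self.values.size

    def to_frame(self) -> pd.DataFrame:
        """Tabular (frame, time, temperature, IFP_CS) view for text output."""
        n = len(self)
        times = self.times if len(self.times) == n else np.arange(n, dtype=float)
        return pd.DataFrame(
            {
                "frame": np.arange(n),
                "time_ns": times,
                "temperature_K": np.full(n, self.temperature),
                "ifp_cs": self.values,
            }
        )


def score_trajectory(
    traj: Trajectory,
    calculator: FingerprintCalculator,
    reference: InteractionFingerprint,
    window_id: int = 0,
    stride: int = 1,
) -> SimilaritySeries:
    """Score every ``stride``-th frame of a window against the reference."""
    frames = traj.frames[::stride]
    fps = [calculator.compute(f) for f in frames]
    values = np.array([ifp_cs(fp, reference) for fp in fps])
    times = np.array([f.time for f in frames])
    temp = frames[0].temperature_set if frames else 0.0
    return SimilaritySeries(
        values=values, reference=reference, window_id=window_id, times=times,
        temperature=temp, fingerprints=fps,
    )


def window_average(series: SimilaritySeries) -> float:
    """Arithmetic mean IFP_CS over a window (the per-step score)."""
    if len(series) == 0:
        raise UsageError("cannot average an empty similarity series")
    return float(series.values.mean())
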