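"""Replicate handling: trimmed-mean MS aggregation, protomer averaging and
tight/weak classification.

The reference protocol runs five independent TTMD replicates per ligand
and averages the three central MS values (one minimum and one maximum
occurrence are discarded). The aggregate is compared against a cutoff
(default 0.004 K^-1): below the cutoff the complex is labelled a tight
binder, at or above it a weak binder.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, UsageError

__all__ = [
    "DEFAULT_MS_CUTOFF",
    "aggregate_replicates",
    "classify",
    "combine_protomers",
    "select_representative",
    "ReplicateSet",
    "replicate_set",
    "results_table",
]

#: default tight/weak MS cutoff, K^-1
DEFAULT_MS_CUTOFF = 0.004


def aggregate_replicates(ms_values: Sequence[float]) -> tuple[float, list[int]]:
    """Trimmed mean of replicate MS values.

    Exactly one minimum and one maximum occurrence are discarded (even when
    extremes are duplicated); the mean of the remaining values and their
    indices (in input order) are returned. Requires at least 3 values.
    """
    values = [float(v) for v in ms_values]
    if len(values) < 3:
        raise UsageError("replicate aggregation needs at least 3 MS values")
    drop_min = values.index(min(values))
    drop_max = max(
        (i for i in range(len(values)) if i != drop_min), key=lambda i: values[i]
    )
    retained = [i for i in range(len(values)) if i not in (drop_min, drop_max)]
    return float(np.mean([values[i] for i in retained])), retained


def classify(aggregate_ms: float, cutoff: float = DEFAULT_MS_CUTOFF) -> str:
    """Label a complex tight (< cutoff) or weak (>= cutoff).

    The boundary value is assigned to the weak class: tight binders sit
    strictly below the cutoff.
    """
    if aggregate_ms < 0:
        raise UsageError(f"MS coefficient must be non-negative, got {aggregate_ms}")
    return "tight" if aggregate_ms < cutoff else "weak"


def combine_protomers(
    aggregate_ms: Sequence[float], weights: Sequence[float] | None = None
) -> float:
    """Weighted mean of per-protomer aggregate MS values.

    Used when a ligand's protonation state is ambiguous and several
    protomers are simulated; the default weights them equally (50/50 for
    two protomers). Weights must sum to 1.
    """
    values = np.asarray(aggregate_ms, dtype=float)
    if weights is None:
        weights = np.full(len(values), 1.0 / len(values))
    w = np.asarray(weights, dtype=float)
    if len(w) != len(values):
        raise ConfigurationError("one weight per protomer required")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ConfigurationError(f"protomer weights must sum to 1, got {w.sum()}")
    return float(values @ w)


def select_representative(ms_values: Sequence[float], aggregate_ms: float) -> int:
    """Index of the replicate whose MS is nearest the aggregate (ties go to
    the lowest index) — the replicate shown in per-ligand reports."""
    values = np.asarray(ms_values, dtype=float)
    if values.size == 0:
        raise UsageError("no replicate MS values")
    d = np.abs(values - aggregate_ms)
    # tolerance-aware tie break so exact equidistance resolves to the
    # lowest index despite floating-point rounding
    return int(np.argmax(d <= d.min() * (1 + 1e-9) + 1e-15))


@dataclass(frozen=True)
class ReplicateSet:
    """Per-ligand replicate collection with its aggregate and class label."""

    ligand_id: str
    ms_values: tuple[float, ...]
    aggregate_ms: float
    retained: tuple[int, ...]
    representative: int
    label: str
    cutoff: float = DEFAULT_MS_CUTOFF


def replicate_set(
    ligand_id: str, ms_values: Sequence[float], cutoff: float = DEFAULT_MS_CUTOFF
) -> ReplicateSet:
    """Build a :class:`ReplicateSet` from raw replicate MS values."""
    aggregate, retained = aggregate_replicates(ms_values)
    return ReplicateSet(
        ligand_id=ligand_id,
        ms_values=tuple(float(v) for v in ms_values),
        aggregate_ms=aggregate,
        retained=tuple(retained),
        representative=select_representative(ms_values, aggregate),
        label=classify(aggregate, cutoff),
        cutoff=cutoff,
    )


def results_table(sets: Sequence[ReplicateSet]) -> pd.DataFrame:
    """Ligand-level results table: one row per ligand with the individual
    replicate MS values, the trimmed-mean aggregate and the class label."""
    rows = []
    for s in sets:
        row = {"ligand": s.ligand_id}
        for i, v in enumerate(s.ms_values, start=1):
            row[f"ms_{i}"] = v
        row["aggregate_ms"] = s.aggregate_ms
        row["representative"] = s.representative + 1
        row["label"] = s.label
        rows.append(row)
    return pd.DataFrame(rows)
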