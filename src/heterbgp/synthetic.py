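"""Synthetic CGM cohort generation.

Produces cohorts of continuous glucose monitoring records with the kinds of
heterogeneity the downstream pipeline must handle: unequal record lengths,
two diabetes-type classes with distinct volatility profiles, circadian
structure, and postprandial excursions. The generator is a convention-driven
simulator, not a physiological model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "CGMRecord",
    "simulate_cohort",
    "cohort_summary",
    "write_cohort_csv",
    "read_cohort_csv",
]

#: 24-hour circadian period expressed in 15-minute steps.
STEPS_PER_DAY_AT_15MIN = 96


class ConfigurationError(ValueError):
    """Raised when a cohort specification violates its invariants."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated CGM cohort.

    Defaults mirror the shape of a mixed T1DM/T2DM hospital cohort sampled
    every 15 minutes: a small type-1 group, a larger and more volatile
    type-2 group, and record lengths spanning roughly 250-1300 points.
    """

    n_t1dm: int = 12
    n_t2dm: int = 100
    length_range: tuple[int, int] = (247, 1339)
    resolution_minutes: int = 15
    glucose_floor: float = 40.0
    glucose_ceiling: float = 400.0
    volatility_t1dm: float = 4.0
    volatility_t2dm: float = 12.0
    meal_spike_rate: float = 3.0
    seed: int = 0
    baseline_t1dm: float = 120.0
    baseline_t2dm: float = 150.0
    circadian_amplitude: float = 20.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "length_range", tuple(self.length_range))
        errors = []
        if self.n_t1dm < 0 or self.n_t2dm < 0:
            errors.append("cohort counts must be non-negative")
        if self.n_t1dm + self.n_t2dm < 1:
            errors.append("cohort must contain at least one record")
        lo, hi = self.length_range
        if lo < 2:
            errors.append("length_range minimum must be >= 2")
        if hi < lo:
            errors.append("length_range must satisfy max >= min")
        if self.resolution_minutes < 1:
            errors.append("resolution_minutes must be a positive integer")
        if not (self.glucose_ceiling > self.glucose_floor > 0):
            errors.append("glucose bounds must satisfy ceiling > floor > 0")
        if self.volatility_t1dm < 0 or self.volatility_t2dm < 0:
            errors.append("volatility values must be >= 0")
        if self.meal_spike_rate < 0:
            errors.append("meal_spike_rate must be >= 0")
        if errors:
            raise ConfigurationError("; ".join(errors))


@dataclass(frozen=True)
class CGMRecord:
    """A single patient's glucose series at fixed sampling resolution."""

    patient_id: str
    diabetes_type: str  # "T1DM" or "T2DM"
    values: np.ndarray  # mg/dL, 1-D float array
    start_time: pd.Timestamp = field(
        default_factory=lambda: pd.Timestamp("2020-01-01 00:00:00")
    )
    resolution_minutes: int = 15

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("CGMRecord requires a 1-D series of length >= 2")
        if self.diabetes_type not in ("T1DM", "T2DM"):
            raise ValueError(f"unknown diabetes_type {self.diabetes_type!r}")
        if self.resolution_minutes < 1:
            raise ValueError("resolution_minutes must be positive")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(
            self.start_time,
            periods=len(self),
            freq=f"{self.resolution_minutes}min",
        )


def _simulate_series(
    rng: np.random.Generator,
    length: int,
    baseline: float,
    volatility: float,
    spec: CohortSpec,
    drift: bool,
) -> np.ndarray:
    steps_per_day = 24 * 60 / spec.resolution_minutes
    t = np.arange(length, dtype=float)

    phase = rng.uniform(0.0, 2.0 * np.pi)
    circadian = spec.circadian_amplitude * np.sin(2.0 * np.pi * t / steps_per_day + phase)

    level = baseline + rng.normal(0.0, 10.0)

    # Postprandial excursions: sharp rise, exponential relaxation.
    spikes = np.zeros(length)
    p_event = spec.meal_spike_rate / steps_per_day
    event_mask = rng.random(length) < p_event
    decay_tau = 6.0  # steps (~90 min at 15-min resolution)
    for idx in np.flatnonzero(event_mask):
        amp = rng.uniform(30.0, 90.0)
        span = np.arange(length - idx, dtype=float)
        spikes[idx:] += amp * np.exp(-span / decay_tau)

    # AR(1) noise, type-specific scale.
    phi = 0.9
    innovations = rng.normal(0.0, volatility, size=length)
    noise = np.empty(length)
    noise[0] = innovations[0]
    for i in range(1, length):
        noise[i] = phi * noise[i - 1] + innovations[i]

    series = level + circadian + spikes + noise
    if drift:
        # Slow random-walk drift distinguishing the more volatile class.
        walk = np.cumsum(rng.normal(0.0, volatility / 8.0, size=length))
        series = series + walk

    return np.clip(series, spec.glucose_floor, spec.glucose_ceiling)


def simulate_cohort(spec: CohortSpec) -> list[CGMRecord]:
    """Simulate a heterogeneous CGM cohort.

    Each record's length is drawn independently from ``spec.length_range``;
    values are baseline + circadian sinusoid + random meal spikes + AR(1)
    noise (type-specific scale), clipped to the sensor bounds. T2DM records
    additionally carry a slow baseline drift. Deterministic under
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[CGMRecord] = []
    lo, hi = spec.length_range
    plan = [("T1DM", i) for i in range(spec.n_t1dm)] + [
        ("T2DM", i) for i in range(spec.n_t2dm)
    ]
    for dtype, i in plan:
        length = int(rng.integers(lo, hi + 1))
        if dtype == "T1DM":
            series = _simulate_series(
                rng, length, spec.baseline_t1dm, spec.volatility_t1dm, spec, drift=False
            )
            pid = f"t1-{i:03d}"
        else:
            series = _simulate_series(
                rng, length, spec.baseline_t2dm, spec.volatility_t2dm, spec, drift=True
            )
            pid = f"t2-{i:03d}"
        records.append(
            CGMRecord(
                patient_id=pid,
                diabetes_type=dtype,
                values=series,
                resolution_minutes=spec.resolution_minutes,
            )
        )
    return records


def cohort_summary(records: Sequence[CGMRecord]) -> pd.DataFrame:
    """Per-type record counts and length statistics (min/mean/max)."""
    if len(records) == 0:
        raise ValueError("cohort_summary requires a non-empty record list")
    rows = [
        {"diabetes_type": r.diabetes_type, "length": len(r)} for r in records
    ]
    frame = pd.DataFrame(rows)
    out = (
        frame.groupby("diabetes_type")["length"]
        .agg(count="size", min_length="min", mean_length="mean", max_length="max")
        .reset_index()
    )
    return out


def write_cohort_csv(records: Iterable[CGMRecord], path) -> None:
    """Write a cohort in long format: patient_id, diabetes_type, timestamp, glucose_mg_dl."""
    parts = []
    for rec in records:
        parts.append(
            pd.DataFrame(
                {
                    "patient_id": rec.patient_id,
                    "diabetes_type": rec.diabetes_type,
                    "timestamp": rec.timestamps,
                    "glucose_mg_dl": rec.values,
                }
            )
        )
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)


def read_cohort_csv(path) -> list[CGMRecord]:
    """Read a long-format cohort CSV back into records (order preserved)."""
    frame = pd.read_csv(path)
    required = {"patient_id", "diabetes_type", "timestamp", "glucose_mg_dl"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    frame["timestamp"] = pd.to_datetime(frame["timestamp"])
    records = []
    for pid, group in frame.groupby("patient_id", sort=False):
        group = group.sort_values("timestamp")
        stamps = group["timestamp"].to_numpy()
        if len(stamps) >= 2:
            deltas = np.diff(stamps).astype("timedelta64[s]").astype(int)
            resolution = int(deltas[0] // 60)
            if not np.all(deltas == deltas[0]):
                raise ValueError(f"irregular sampling for patient {pid}")
        else:
            resolution = 15
        records.append(
            CGMRecord(
                patient_id=str(pid),
                diabetes_type=str(group["diabetes_type"].iloc[0]),
                values=group["glucose_mg_dl"].to_numpy(dtype=float),
                start_time=pd.Timestamp(stamps[0]),
                resolution_minutes=resolution,
            )
        )
    return records
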