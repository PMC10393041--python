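"""Alignment of heterogeneous-length CGM records into fixed-shape tensors.

Records are min-max normalized per sample, segmented into sliding
(input, target) window pairs, and aligned across samples so every sample
contributes the same number of segment rows. Three alignment strategies are
provided:

* ``ssr`` — subsequence repetition: each sample's known segments are
  cyclically replicated until all samples reach the cohort maximum count.
* ``pad`` — missing segments are filled with all-zero windows.
* ``tra`` — all samples are truncated to the cohort minimum count, keeping
  the most recent segments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .synthetic import CGMRecord

__all__ = [
    "NormalizationParams",
    "SegmentSet",
    "AlignedDataset",
    "DegenerateRecordError",
    "minmax_normalize",
    "denormalize",
    "segment",
    "ssr_align",
    "pad_align",
    "tra_align",
    "train_test_split",
    "align_cohort",
]


class DegenerateRecordError(ValueError):
    """A constant series cannot be min-max normalized."""


@dataclass(frozen=True)
class NormalizationParams:
    """Per-record min/max retained for inverting the normalization."""

    minimum: float
    maximum: float

    def __post_init__(self) -> None:
        if not self.maximum > self.minimum:
            raise DegenerateRecordError(
                f"max ({self.maximum}) must exceed min ({self.minimum})"
            )


@dataclass(frozen=True)
class SegmentSet:
    """All (input window, target window) pairs cut from one record."""

    record_id: str
    inputs: np.ndarray  # (B, T) normalized units
    targets: np.ndarray  # (B, s)

    def __post_init__(self) -> None:
        if self.inputs.shape[0] != self.targets.shape[0]:
            raise ValueError("inputs and targets must have equal segment counts")
        if self.inputs.shape[0] == 0:
            raise ValueError("SegmentSet must be non-empty")

    @property
    def n_segments(self) -> int:
        return int(self.inputs.shape[0])


@dataclass(frozen=True)
class AlignedDataset:
    """Fixed-shape cohort tensors: X (beta, N, T) and Y (beta, N, s)."""

    X: np.ndarray
    Y: np.ndarray
    norm_params: dict[str, NormalizationParams]
    sample_order: list[str]
    role: str = "train"

    @property
    def n_segments(self) -> int:
        return int(self.X.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.X.shape[1])

    @property
    def window(self) -> int:
        return int(self.X.shape[2])

    @property
    def horizon_steps(self) -> int:
        return int(self.Y.shape[2])

    def save(self, directory) -> None:
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "tensors.npz", X=self.X, Y=self.Y)
        sidecar = {
            "role": self.role,
            "sample_order": self.sample_order,
            "norm_params": {
                k: [p.minimum, p.maximum] for k, p in self.norm_params.items()
            },
        }
        (directory / "aligned.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, directory) -> "AlignedDataset":
        from pathlib import Path

        directory = Path(directory)
        with np.load(directory / "tensors.npz") as data:
            X, Y = data["X"], data["Y"]
        sidecar = json.loads((directory / "aligned.json").read_text())
        params = {
            k: NormalizationParams(lo, hi)
            for k, (lo, hi) in sidecar["norm_params"].items()
        }
        return cls(
            X=X,
            Y=Y,
            norm_params=params,
            sample_order=list(sidecar["sample_order"]),
            role=sidecar["role"],
        )


def minmax_normalize(values: np.ndarray) -> tuple[np.ndarray, NormalizationParams]:
    """Scale a series to [0, 1]; the min maps to 0 and the max to 1.

    Raises :class:`DegenerateRecordError` for constant series.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("normalization requires a series of length >= 2")
    lo, hi = float(values.min()), float(values.max())
    params = NormalizationParams(lo, hi)  # raises on constant series
    return (values - lo) / (hi - lo), params


def denormalize(values: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Invert :func:`minmax_normalize`: ``x * (max - min) + min``."""
    values = np.asarray(values, dtype=float)
    return values * (params.maximum - params.minimum) + params.minimum


def segment(
    series: np.ndarray,
    window: int,
    horizon_steps: int,
    stride: int = 1,
    record_id: str = "",
) -> SegmentSet:
    """Cut a series into contiguous (input, target) window pairs.

    With stride 1 the number of pairs is ``len - window - horizon + 1``;
    each input covers ``window`` consecutive points and its target the
    ``horizon_steps`` points immediately after.
    """
    series = np.asarray(series, dtype=float)
    if window < 1 or horizon_steps < 1 or stride < 1:
        raise ValueError("window, horizon_steps and stride must be positive")
    n = series.size
    if n < window + horizon_steps:
        raise ValueError(
            f"series of length {n} too short for window {window} + horizon {horizon_steps}"
        )
    starts = np.arange(0, n - window - horizon_steps + 1, stride)
    inputs = np.stack([series[s : s + window] for s in starts])
    targets = np.stack(
        [series[s + window : s + window + horizon_steps] for s in starts]
    )
    return SegmentSet(record_id=record_id, inputs=inputs, targets=targets)


def _assemble(
    segment_sets: Sequence[SegmentSet],
    per_sample_rows: list[tuple[np.ndarray, np.ndarray]],
    norm_params: dict[str, NormalizationParams] | None,
    role: str,
) -> AlignedDataset:
    X = np.stack([rows[0] for rows in per_sample_rows], axis=1)
    Y = np.stack([rows[1] for rows in per_sample_rows], axis=1)
    order = [s.record_id for s in segment_sets]
    return AlignedDataset(
        X=X, Y=Y, norm_params=norm_params or {}, sample_order=order, role=role
    )


def _check_sets(segment_sets: Sequence[SegmentSet]) -> None:
    if len(segment_sets) == 0:
        raise ValueError("alignment requires at least one segment set")
    windows = {s.inputs.shape[1] for s in segment_sets}
    horizons = {s.targets.shape[1] for s in segment_sets}
    if len(windows) > 1 or len(horizons) > 1:
        raise ValueError("all segment sets must share window and horizon shapes")


def ssr_align(
    segment_sets: Sequence[SegmentSet],
    norm_params: dict[str, NormalizationParams] | None = None,
    role: str = "train",
) -> AlignedDataset:
    """Subsequence-repetition alignment.

    beta = max over samples of B(n). Output segment ``b`` (1-based) of each
    sample is its source segment ``((b - 1) mod B(n)) + 1`` — cyclic
    replication from the first segment, so the first B(n) rows are
    bit-identical to the originals and no novel values are introduced.
    """
    _check_sets(segment_sets)
    beta = max(s.n_segments for s in segment_sets)
    rows = []
    for sset in segment_sets:
        idx = np.arange(beta) % sset.n_segments
        rows.append((sset.inputs[idx], sset.targets[idx]))
    return _assemble(segment_sets, rows, norm_params, role)


def pad_align(
    segment_sets: Sequence[SegmentSet],
    norm_params: dict[str, NormalizationParams] | None = None,
    role: str = "train",
) -> AlignedDataset:
    """Zero-padding alignment: missing segments become all-zero windows."""
    _check_sets(segment_sets)
    beta = max(s.n_segments for s in segment_sets)
    window = segment_sets[0].inputs.shape[1]
    horizon = segment_sets[0].targets.shape[1]
    rows = []
    for sset in segment_sets:
        missing = beta - sset.n_segments
        x = np.concatenate([sset.inputs, np.zeros((missing, window))])
        y = np.concatenate([sset.targets, np.zeros((missing, horizon))])
        rows.append((x, y))
    return _assemble(segment_sets, rows, norm_params, role)


def tra_align(
    segment_sets: Sequence[SegmentSet],
    norm_params: dict[str, NormalizationParams] | None = None,
    role: str = "train",
) -> AlignedDataset:
    """Truncation alignment: keep the most recent min-over-samples segments."""
    _check_sets(segment_sets)
    b_min = min(s.n_segments for s in segment_sets)
    rows = [(s.inputs[-b_min:], s.targets[-b_min:]) for s in segment_sets]
    return _assemble(segment_sets, rows, norm_params, role)


_ALIGNERS = {"ssr": ssr_align, "pad": pad_align, "tra": tra_align}


def train_test_split(
    record: CGMRecord,
    test_points: int,
    history: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Reserve the most recent ``test_points`` observations for testing.

    Returns ``(train_series, test_series)`` where the test series carries a
    ``history``-point prefix of trailing training data so every test target
    has a full input window. No test point ever appears in a training
    target: the training series ends exactly at the split.
    """
    values = record.values
    n = len(values)
    if test_points < 0:
        raise ValueError("test_points must be >= 0")
    if test_points == 0:
        return values.copy(), np.empty(0)
    if n <= test_points + history:
        raise ValueError(
            f"record length {n} too short for {test_points} test points "
            f"with a {history}-point history prefix"
        )
    split = n - test_points
    return values[:split].copy(), values[split - history :].copy()


def align_cohort(
    records: Sequence[CGMRecord],
    window: int,
    horizon_steps: int,
    test_points: int = 144,
    method: str = "ssr",
    stride: int = 1,
    test_stride: int | None = None,
) -> tuple[AlignedDataset, AlignedDataset | None]:
    """Full cohort alignment pipeline: split, normalize, segment, align.

    Normalization parameters are fit on each record's training portion and
    reused for its test portion (no leakage). Test segments use a stride of
    ``horizon_steps`` by default, so the targets tile the reserved test
    points exactly once. Returns ``(train, test)``; ``test`` is ``None``
    when ``test_points == 0``.
    """
    if method not in _ALIGNERS:
        raise ValueError(f"unknown alignment method {method!r}")
    if test_stride is None:
        test_stride = horizon_steps
    if test_points > 0 and test_points % test_stride != 0:
        raise ValueError("test_points must be divisible by the test stride")

    train_sets, test_sets = [], []
    params: dict[str, NormalizationParams] = {}
    for rec in records:
        train_raw, test_raw = train_test_split(rec, test_points, history=window)
        norm_train, p = minmax_normalize(train_raw)
        params[rec.patient_id] = p
        train_sets.append(
            segment(norm_train, window, horizon_steps, stride, rec.patient_id)
        )
        if test_points > 0:
            norm_test = (test_raw - p.minimum) / (p.maximum - p.minimum)
            test_sets.append(
                segment(norm_test, window, horizon_steps, test_stride, rec.patient_id)
            )

    train = _ALIGNERS[method](train_sets, params, role="train")
    test = None
    if test_points > 0:
        # Test series share a common length, so counts agree by construction.
        test = ssr_align(test_sets, params, role="test")
    return train, test
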