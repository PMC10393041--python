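"""Training, evaluation, baselines, grid search and sensitivity sweeps."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import autodiff as ad
from .alignment import AlignedDataset, NormalizationParams, align_cohort, denormalize
from .metrics import mae, mape, pearson, rmse
from .model import HETERConfig, HETERParams, heter_forward
from .srgraph import SRGraph, srgraph_from_series
from .synthetic import CGMRecord

__all__ = [
    "TrainSpec",
    "PredictionResult",
    "train",
    "evaluate",
    "persistence_baseline",
    "grid_search",
    "sensitivity_sweep",
]


@dataclass(frozen=True)
class TrainSpec:
    epochs: int = 50
    learning_rate: float = 1e-3
    batch_size: int = 16
    seed: int = 0
    patience: int | None = None  # early stop on flat training loss

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class PredictionResult:
    """De-normalized predictions over the test set plus summary metrics."""

    predictions: np.ndarray  # (segments, N, s) mg/dL
    actuals: np.ndarray
    metrics: dict[str, float] = field(default_factory=dict)
    sample_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.predictions.shape != self.actuals.shape:
            raise ValueError("predictions and actuals must be congruent")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.metrics])


class _Adam:
    """Standard Adam over a parameter dict."""

    def __init__(self, params: HETERParams, lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def step(self) -> None:
        self.t += 1
        for name, tensor in self.params.items():
            if tensor.grad is None:
                continue
            g = tensor.grad
            self.m[name] = self.b1 * self.m[name] + (1 - self.b1) * g
            self.v[name] = self.b2 * self.v[name] + (1 - self.b2) * g * g
            m_hat = self.m[name] / (1 - self.b1 ** self.t)
            v_hat = self.v[name] / (1 - self.b2 ** self.t)
            tensor.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def train(
    params: HETERParams,
    data: AlignedDataset,
    graph: SRGraph,
    spec: TrainSpec,
    config: HETERConfig,
) -> list[float]:
    """Adam minimization of MSE in normalized space; returns per-epoch loss.

    Deterministic under ``spec.seed`` (shuffling and dropout share one
    seeded generator). Raises on divergence (non-finite loss).
    """
    rng = np.random.default_rng(spec.seed)
    optimizer = _Adam(params, spec.learning_rate)
    n_segments = data.n_segments
    history: list[float] = []
    best = np.inf
    stale = 0
    for epoch in range(spec.epochs):
        order = rng.permutation(n_segments)
        epoch_loss = 0.0
        for start in range(0, n_segments, spec.batch_size):
            batch_idx = order[start : start + spec.batch_size]
            xb = ad.Tensor(data.X[batch_idx])
            yb = data.Y[batch_idx]
            params.zero_grad()
            out = heter_forward(xb, graph, params, config, mode="train", rng=rng)
            loss = ((out - ad.Tensor(yb)) ** 2).mean()
            value = float(loss.data)
            if not np.isfinite(value):
                raise FloatingPointError(
                    f"training diverged: non-finite loss at epoch {epoch + 1}"
                )
            if spec.learning_rate > 0:
                ad.backward(loss)
                optimizer.step()
            epoch_loss += value * len(batch_idx)
        history.append(epoch_loss / n_segments)
        if spec.patience is not None:
            if history[-1] < best - 1e-9:
                best, stale = history[-1], 0
            else:
                stale += 1
                if stale > spec.patience:
                    break
    params.zero_grad()
    params.detach()
    return history


def _denorm_by_sample(
    values: np.ndarray,
    sample_order: Sequence[str],
    norm_params: dict[str, NormalizationParams],
) -> np.ndarray:
    out = np.empty_like(values)
    for idx, sample_id in enumerate(sample_order):
        out[:, idx, :] = denormalize(values[:, idx, :], norm_params[sample_id])
    return out


def _metric_block(actual: np.ndarray, predicted: np.ndarray) -> dict[str, float]:
    metrics = {
        "MAE": mae(actual, predicted),
        "MAPE": mape(actual, predicted),
        "RMSE": rmse(actual, predicted),
        "PCC": pearson(actual, predicted),
    }
    # Jensen: quadratic mean dominates the arithmetic mean of |errors|.
    assert metrics["RMSE"] >= metrics["MAE"] - 1e-12
    return metrics


def evaluate(
    params: HETERParams,
    data: AlignedDataset,
    graph: SRGraph,
    config: HETERConfig,
    batch_size: int = 64,
) -> PredictionResult:
    """Eval-mode forward pass, de-normalization, metric computation."""
    if not data.norm_params:
        raise ValueError("evaluation requires normalization parameters")
    preds_norm = np.empty_like(data.Y)
    for start in range(0, data.n_segments, batch_size):
        stop = start + batch_size
        out = heter_forward(
            ad.Tensor(data.X[start:stop]), graph, params, config, mode="eval"
        )
        preds_norm[start:stop] = out.data
    predictions = _denorm_by_sample(preds_norm, data.sample_order, data.norm_params)
    actuals = _denorm_by_sample(data.Y, data.sample_order, data.norm_params)
    return PredictionResult(
        predictions=predictions,
        actuals=actuals,
        metrics=_metric_block(actuals, predictions),
        sample_order=list(data.sample_order),
    )


def persistence_baseline(data: AlignedDataset) -> PredictionResult:
    """Naive forecast: repeat each window's last observed value for all
    horizon steps; evaluated identically to the model."""
    if not data.norm_params:
        raise ValueError("evaluation requires normalization parameters")
    last = data.X[:, :, -1:]
    preds_norm = np.repeat(last, data.horizon_steps, axis=2)
    predictions = _denorm_by_sample(preds_norm, data.sample_order, data.norm_params)
    actuals = _denorm_by_sample(data.Y, data.sample_order, data.norm_params)
    return PredictionResult(
        predictions=predictions,
        actuals=actuals,
        metrics=_metric_block(actuals, predictions),
        sample_order=list(data.sample_order),
    )


def _validation_split(data: AlignedDataset, fraction: float = 0.1):
    n_val = max(1, int(round(data.n_segments * fraction)))
    n_train = data.n_segments - n_val
    if n_train < 1:
        raise ValueError("not enough segments for a validation split")
    train_part = AlignedDataset(
        X=data.X[:n_train], Y=data.Y[:n_train],
        norm_params=data.norm_params, sample_order=data.sample_order, role="train",
    )
    val_part = AlignedDataset(
        X=data.X[n_train:], Y=data.Y[n_train:],
        norm_params=data.norm_params, sample_order=data.sample_order, role="test",
    )
    return train_part, val_part


def grid_search(
    configs: Sequence[HETERConfig],
    data: AlignedDataset,
    graph: SRGraph,
    spec: TrainSpec,
) -> tuple[HETERConfig, pd.DataFrame]:
    """Train every candidate, score on a held-out tail of the training
    segments, return (argmin-MAE config, full results table). Ties keep the
    first candidate in enumeration order."""
    if len(configs) == 0:
        raise ValueError("grid_search requires a non-empty grid")
    train_part, val_part = _validation_split(data)
    rows = []
    best_idx, best_mae = 0, np.inf
    for idx, config in enumerate(configs):
        params = HETERParams.initialize(config, graph.n_nodes)
        train(params, train_part, graph, spec, config)
        result = evaluate(params, val_part, graph, config)
        rows.append({"index": idx, **result.metrics, **config.to_dict()})
        if result.metrics["MAE"] < best_mae:
            best_idx, best_mae = idx, result.metrics["MAE"]
    return configs[best_idx], pd.DataFrame(rows)


def sensitivity_sweep(
    axis: str,
    values: Sequence[int],
    records: Sequence[CGMRecord],
    config: HETERConfig,
    spec: TrainSpec,
    test_points: int = 144,
    alignment_method: str = "ssr",
    dtw_band: int | None = None,
) -> pd.DataFrame:
    """Re-run the pipeline per swept value of ``T`` (window) or ``K``.

    Each row reports MAE/MAPE/RMSE/PCC on the held-out test points.
    """
    if axis not in ("T", "K"):
        raise ValueError("axis must be 'T' or 'K'")
    if len(values) == 0:
        raise ValueError("sweep requires at least one value")
    rows = []
    for value in values:
        cfg = replace(config, window=value) if axis == "T" else replace(config, k=value)
        n = len(records)
        if cfg.k >= n:
            raise ValueError(f"K={cfg.k} must be < number of records {n}")
        train_data, test_data = align_cohort(
            records, cfg.window, cfg.horizon_steps,
            test_points=test_points, method=alignment_method,
        )
        series = []
        for rec in records:
            split = len(rec.values) - test_points
            raw = rec.values[:split]
            lo, hi = raw.min(), raw.max()
            series.append((raw - lo) / (hi - lo))
        _, graph = srgraph_from_series(
            series, cfg.k, [r.patient_id for r in records], band=dtw_band
        )
        params = HETERParams.initialize(cfg, graph.n_nodes)
        history = train(params, train_data, graph, spec, cfg)
        result = evaluate(params, test_data, graph, cfg)
        rows.append(
            {axis: value, **result.metrics, "final_train_loss": history[-1]}
        )
    return pd.DataFrame(rows)
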