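"""End-to-end pipeline: simulate -> align -> build graph -> train -> evaluate.

Stages are cached by content hash: a stage is skipped when its output
exists alongside a meta file whose hash of (stage inputs, relevant config)
matches. Results are written as a CSV with a comment header carrying the
tool version, config hash and seed — no wall-clock content, so identical
configurations produce byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alignment import AlignedDataset, align_cohort
from .config import RunConfig, config_hash, validate_config
from .model import HETERConfig, HETERParams
from .srgraph import SRGraph, srgraph_from_series
from .synthetic import read_cohort_csv, simulate_cohort, write_cohort_csv
from .training import evaluate, persistence_baseline, train

logger = logging.getLogger("heterbgp")

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_key(parts: list) -> str:
    return hashlib.sha256(json.dumps(parts, sort_keys=True, default=str).encode()).hexdigest()


def _meta_path(output: Path) -> Path:
    if output.suffix:
        return output.with_suffix(output.suffix + ".meta.json")
    return output / "stage.meta.json"


def _cached(output: Path, key: str) -> bool:
    meta = _meta_path(output)
    if not output.exists() or not meta.exists():
        return False
    try:
        return json.loads(meta.read_text())["key"] == key
    except (json.JSONDecodeError, KeyError):
        return False


def _mark(output: Path, key: str, config: RunConfig) -> None:
    _meta_path(output).write_text(
        json.dumps(
            {
                "key": key,
                "tool_version": __version__,
                "config_hash": config_hash(config),
                "seed": config.seed,
            },
            indent=2,
        )
    )


def _timed(stage: str):
    class _Ctx:
        def __enter__(self):
            self.start = time.perf_counter()
            logger.info("stage %s: start", stage)
            return self

        def __exit__(self, exc_type, exc, tb):
            elapsed = time.perf_counter() - self.start
            if exc is None:
                logger.info("stage %s: done in %.2fs", stage, elapsed)
            return False

    return _Ctx()


def run_pipeline(config: RunConfig, force: bool = False) -> dict[str, Path]:
    """Execute all stages; returns the artifact paths.

    ``force`` disables stage caching. Any stage failure is re-raised as a
    :class:`PipelineError` naming the stage.
    """
    errors = validate_config(config)
    if config.test_points < 1:
        errors.append("pipeline evaluation requires test_points >= 1")
    if errors:
        raise PipelineError("validate", ValueError("; ".join(errors)))
    paths = config.paths
    Path(config.workdir).mkdir(parents=True, exist_ok=True)

    # -- simulate -----------------------------------------------------------
    stage = "simulate"
    try:
        with _timed(stage):
            if config.cohort_csv is None:
                key = _stage_key(["simulate", config.cohort.__dict__])
                if force or not _cached(paths["cohort"], key):
                    records = simulate_cohort(config.cohort)
                    write_cohort_csv(records, paths["cohort"])
                    _mark(paths["cohort"], key, config)
                else:
                    logger.info("stage simulate: cached, skipping")
            cohort_hash = _hash_file(paths["cohort"])
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # -- align --------------------------------------------------------------
    stage = "align"
    try:
        with _timed(stage):
            align_conf = {
                "window": config.model.window,
                "horizon_steps": config.horizon_steps,
                "test_points": config.test_points,
                "method": config.alignment_method,
                "stride": config.stride,
            }
            key = _stage_key(["align", cohort_hash, align_conf])
            aligned_dir = paths["aligned"]
            if force or not _cached(aligned_dir, key):
                records = read_cohort_csv(paths["cohort"])
                train_data, test_data = align_cohort(records, **align_conf)
                train_data.save(aligned_dir / "train")
                if test_data is not None:
                    test_data.save(aligned_dir / "test")
                aligned_dir.mkdir(parents=True, exist_ok=True)
                _mark(aligned_dir, key, config)
            else:
                logger.info("stage align: cached, skipping")
            train_data = AlignedDataset.load(aligned_dir / "train")
            test_data = AlignedDataset.load(aligned_dir / "test")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # -- build graph --------------------------------------------------------
    stage = "build-graph"
    try:
        with _timed(stage):
            key = _stage_key(["graph", cohort_hash, config.model.k,
                              config.test_points, config.dtw_band])
            graph_dir = paths["graph"]
            if force or not _cached(graph_dir, key):
                records = read_cohort_csv(paths["cohort"])
                series = []
                for rec in records:
                    split = len(rec.values) - config.test_points
                    raw = rec.values[:split]
                    lo, hi = raw.min(), raw.max()
                    series.append((raw - lo) / (hi - lo))
                _, graph = srgraph_from_series(
                    series, config.model.k,
                    [r.patient_id for r in records], band=config.dtw_band,
                )
                graph.save(graph_dir)
                _mark(graph_dir, key, config)
            else:
                logger.info("stage build-graph: cached, skipping")
            graph = SRGraph.load(graph_dir)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # -- train --------------------------------------------------------------
    stage = "train"
    try:
        with _timed(stage):
            model_config = _effective_model_config(config)
            key = _stage_key(["train", cohort_hash, model_config.to_dict(),
                              config.train.__dict__, align_conf])
            checkpoint = paths["checkpoint"]
            if force or not _cached(checkpoint, key):
                params = HETERParams.initialize(model_config, graph.n_nodes)
                history = train(params, train_data, graph, config.train, model_config)
                params.save(checkpoint, model_config)
                loss_csv = checkpoint.with_suffix(".loss.csv")
                pd.DataFrame(
                    {"epoch": np.arange(1, len(history) + 1), "loss": history}
                ).to_csv(loss_csv, index=False)
                _mark(checkpoint, key, config)
            else:
                logger.info("stage train: cached, skipping")
            params, model_config = HETERParams.load(checkpoint)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # -- evaluate -----------------------------------------------------------
    stage = "evaluate"
    try:
        with _timed(stage):
            key = _stage_key(["evaluate", cohort_hash, model_config.to_dict(),
                              config.train.__dict__, align_conf])
            results_path = paths["results"]
            if force or not _cached(results_path, key):
                model_result = evaluate(params, test_data, graph, model_config)
                naive_result = persistence_baseline(test_data)
                rows = []
                for method, result in (
                    ("heter", model_result),
                    ("persistence", naive_result),
                ):
                    rows.append(
                        {
                            "method": method,
                            "alignment": config.alignment_method,
                            "H": config.horizon_minutes,
                            **{k: round(v, 10) for k, v in result.metrics.items()},
                            "seed": config.seed,
                        }
                    )
                header = (
                    f"# heterbgp {__version__} config={config_hash(config)} "
                    f"seed={config.seed}\n"
                )
                body = pd.DataFrame(rows).to_csv(index=False)
                results_path.write_text(header + body)
                _mark(results_path, key, config)
            else:
                logger.info("stage evaluate: cached, skipping")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    return paths


def _effective_model_config(config: RunConfig) -> HETERConfig:
    from dataclasses import replace

    return replace(
        config.model,
        horizon_steps=config.horizon_steps,
        seed=config.seed,
    )
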