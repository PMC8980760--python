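"""End-to-end orchestration: load/generate -> stats -> sweep -> transmit -> pairs.

A :class:`PipelineConfig` (flat key/value, YAML on disk) fixes every input,
toggle and seed; :func:`run_pipeline` emits one delimited-text table per
stage plus a JSON manifest listing every output with a content digest, so a
re-run with the same configuration reproduces every stochastic output
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .covariation import partition_sweep, per_chromosome_cv, variability_index, \
    variance_decomposition
from .errors import ConfigurationError
from .insilico import correlation_sweep
from .nucleus_data import NucleusMatrix, read_nucleus_table, write_nucleus_table
from .pairs import adjacent_pairs, pairs_correlation, trend_fit
from .synthetic import female_like_config, generate, male_like_config
from .transmission import gamete_variance_prediction, predict_gametes

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Flat configuration of one pipeline run (all seeds explicit)."""

    input_path: str | None = None
    input_layout: str = "wide"
    preset: str | None = None          # "male-like" | "female-like"
    n_nuclei: int = 755
    seed: int = 0
    out_dir: str = "meiocovar_out"
    run_stats: bool = True
    run_sweep: bool = True
    run_transmit: bool = True
    run_pairs: bool = True
    sweep_fractions: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
    sweep_replicates: int = 5
    max_partitions: int = 200
    n_boot: int = 2000
    pair_metric: str = "co"
    gametes_per_meiocyte: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "sweep_fractions" in raw:
            raw["sweep_fractions"] = tuple(raw["sweep_fractions"])
        return cls(**raw)


def _load_input(config: PipelineConfig) -> NucleusMatrix:
    if config.input_path:
        return read_nucleus_table(config.input_path, layout=config.input_layout)
    if config.preset == "male-like":
        return generate(male_like_config(config.n_nuclei, seed=config.seed))
    if config.preset == "female-like":
        return generate(female_like_config(config.n_nuclei, seed=config.seed))
    raise ConfigurationError(
        "config needs either input_path or preset (male-like/female-like)")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; return the manifest (also written to disk).

    Any stage failure aborts with the stage name in the exception message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    timings: dict[str, float] = {}
    current = "load"

    def stage(name: str):
        nonlocal current
        current = name
        logger.info("stage %s", name)
        timings[name] = time.perf_counter()

    def done(name: str):
        timings[name] = round(time.perf_counter() - timings[name], 3)

    try:
        stage("load")
        matrix = _load_input(config)
        input_table = out / "input_matrix.csv"
        write_nucleus_table(matrix, input_table, layout="wide")
        outputs.append(input_table)
        done("load")

        if config.run_stats:
            stage("stats")
            summary = variance_decomposition(matrix)
            sweep = partition_sweep(matrix, max_partitions=config.max_partitions,
                                    seed=config.seed)
            vi = variability_index(matrix)
            cvs = per_chromosome_cv(matrix)
            rows = [
                ("grouped_correlation_mean", sweep.mean_r, sweep.se),
                ("grouped_correlation_partitions", sweep.n_partitions, 0.0),
                ("total_variance", summary.total_variance, float("nan")),
                ("intrinsic_variance", summary.intrinsic_variance, float("nan")),
                ("covariance", summary.covariance, float("nan")),
                ("covariance_contribution", summary.covariance_contribution,
                 float("nan")),
                ("mean_total", summary.mean_total, float("nan")),
                ("cv_total", summary.cv_total, float("nan")),
                ("variability_index", vi.index, float("nan")),
            ] + [(f"cv_{c}", v, float("nan")) for c, v in cvs.items()]
            path = out / "stats.csv"
            pd.DataFrame(rows, columns=["statistic", "value", "se"]).to_csv(
                path, index=False)
            outputs.append(path)
            done("stats")

        if config.run_sweep:
            stage("sweep")
            series = correlation_sweep(
                matrix, fractions=config.sweep_fractions,
                replicates=config.sweep_replicates, seed=config.seed,
                max_partitions=config.max_partitions)
            path = out / "sweep.csv"
            series.to_frame().to_csv(path, index=False)
            outputs.append(path)
            done("sweep")

        if config.run_transmit:
            stage("transmit")
            gametes = predict_gametes(matrix, config.gametes_per_meiocyte,
                                      seed=config.seed)
            path = out / "gametes.csv"
            write_nucleus_table(gametes.matrix, path, layout="wide")
            outputs.append(path)
            summary_m = variance_decomposition(matrix)
            pred = gamete_variance_prediction(summary_m)
            emp = variance_decomposition(gametes.matrix)
            path2 = out / "transmission.csv"
            pd.DataFrame([
                ("predicted_total_variance_g", pred.predicted_total_variance_g),
                ("empirical_total_variance_g", emp.total_variance),
                ("predicted_contribution_ratio",
                 pred.predicted_contribution_ratio),
                ("empirical_contribution_ratio",
                 summary_m.covariance_contribution
                 / emp.covariance_contribution),
                ("reduction_term_X_over_total_m", pred.reduction_term),
            ], columns=["statistic", "value"]).to_csv(path2, index=False)
            outputs.append(path2)
            done("transmit")

        if config.run_pairs:
            stage("pairs")
            metric = config.pair_metric
            pairs = adjacent_pairs(matrix, metric)
            results = pairs_correlation(matrix, pairs, metric,
                                        n_boot=config.n_boot, seed=config.seed)
            fit = trend_fit(results)
            path = out / "pairs.csv"
            pd.DataFrame([{
                "pair": f"{p.pair[0]}-{p.pair[1]}",
                "mean_metric": p.mean_metric,
                "r": p.r,
                "ci_low": p.ci95[0],
                "ci_high": p.ci95[1],
                "se": p.se,
            } for p in results]).to_csv(path, index=False)
            outputs.append(path)
            path2 = out / "pairs_trend.csv"
            pd.DataFrame([("slope", fit.slope), ("intercept", fit.intercept),
                          ("trend_r", fit.trend_r)],
                         columns=["statistic", "value"]).to_csv(path2,
                                                                index=False)
            outputs.append(path2)
            done("pairs")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "config": asdict(config),
        "stage_seconds": timings,
        "outputs": [{"path": p.name, "sha256": _digest(p)} for p in outputs],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
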