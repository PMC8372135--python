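"""End-to-end orchestration of the screening study.

Wires the stages together: simulate -> process -> evaluate grid ->
select -> train final models -> tune thresholds -> decide -> report.
Also provides the YAML run configuration and plain-text artefact I/O the
command-line interface builds on.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .evaluate import RateTable, detection_by_fraction, rate_table
from .factory import (
    DEFAULT_QUOTAS,
    evaluate_grid,
    rank_and_select,
    train_selected_models,
)
from .fusion import Scenario, ScenarioConfig, decide_samples, tune_thresholds
from .occ import Algorithm, TrainedOCCModel
from .preprocess import DEFAULT_PREPROCESSINGS, enumerate_model_grid
from .spectra import Sensor
from .synthetic import (
    ProcessedStudy,
    SensorTable,
    StudyDesign,
    generate_study,
    process_study,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run depends on, YAML-serialisable."""

    seed: int = 0
    design: dict = field(default_factory=dict)        # StudyDesign overrides
    preprocessings: tuple = DEFAULT_PREPROCESSINGS
    splits: tuple = (None, 1, 2, 3, 4)
    algorithms: tuple = tuple(a.value for a in Algorithm)
    quotas: dict = field(
        default_factory=lambda: {s.value: q for s, q in DEFAULT_QUOTAS.items()}
    )
    n_repeats: int = 5
    split_fraction: float = 0.8
    min_votes: int = 2
    evoo_rate_floor: float = 0.75

    def study_design(self) -> StudyDesign:
        overrides = dict(self.design)
        if "scans_per_run" in overrides:
            overrides["scans_per_run"] = {
                Sensor(k): int(v)
                for k, v in overrides["scans_per_run"].items()
            }
        overrides.setdefault("seed", self.seed)
        try:
            return StudyDesign(**overrides)
        except TypeError as exc:
            raise ConfigError(f"bad design override: {exc}") from exc

    def model_grid(self):
        splits = tuple(
            None if s in (None, "full") else int(s) for s in self.splits
        )
        return enumerate_model_grid(
            self.preprocessings, self.algorithms, splits
        )

    def sensor_quotas(self) -> dict[Sensor, int]:
        return {Sensor(k): int(v) for k, v in self.quotas.items()}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("preprocessings", "splits", "algorithms"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["preprocessings"] = list(d["preprocessings"])
        d["splits"] = ["full" if s is None else s for s in d["splits"]]
        d["algorithms"] = list(d["algorithms"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


@dataclass
class PipelineResult:
    config: RunConfig
    processed: ProcessedStudy
    performances: pd.DataFrame
    selected: list[str]
    models: dict[str, TrainedOCCModel]
    distances: pd.DataFrame
    thresholds: dict[str, dict[str, float]]       # scenario -> model -> thr
    decisions: dict[str, pd.DataFrame]            # scenario -> decisions
    tables: dict[str, RateTable]                  # scenario -> rate table

    def detection_curve(self, scenario: str = "S2") -> pd.DataFrame:
        return detection_by_fraction(
            self.decisions[scenario], self.processed.manifest
        )


def _scenario_cfg(config: RunConfig, scenario: Scenario) -> ScenarioConfig:
    return ScenarioConfig(
        scenario=scenario,
        min_votes=config.min_votes,
        evoo_rate_floor=config.evoo_rate_floor,
    )


def run_pipeline(
    config: RunConfig,
    processed: ProcessedStudy | None = None,
) -> PipelineResult:
    """Execute the full study.  A pre-processed study can be passed in to
    reuse simulated measurements across runs."""
    if processed is None:
        logger.info("simulating study (seed %d)", config.seed)
        processed = process_study(generate_study(config.study_design()))
    grid = config.model_grid()
    logger.info("evaluating %d grid points per sensor", len(grid))
    performances = evaluate_grid(
        processed, grid,
        n_repeats=config.n_repeats,
        fraction=config.split_fraction,
        seed=config.seed,
    )
    selected = rank_and_select(performances, config.sensor_quotas())
    logger.info("selected %d models", len(selected))
    models, distances = train_selected_models(
        processed, selected, seed=config.seed
    )
    manifest = processed.manifest
    evoo_ids = manifest.loc[
        (manifest["oil_class"] == "EVOO") & ~manifest["adulterated"],
        "sample_id",
    ].tolist()
    adulterated_ids = manifest.loc[
        manifest["adulterated"].astype(bool), "sample_id"
    ].tolist()
    thresholds, decisions, tables = {}, {}, {}
    for name, scenario in (
        ("S1", Scenario.S1_NO_FALSE_NEGATIVE),
        ("S2", Scenario.S2_FRAUD_SCREEN),
    ):
        cfg = _scenario_cfg(config, scenario)
        thr = tune_thresholds(distances, evoo_ids, adulterated_ids, cfg)
        thresholds[name] = thr
        decisions[name] = decide_samples(distances, thr, cfg.min_votes)
        tables[name] = rate_table(
            distances, thr, manifest, selected, cfg.min_votes
        )
    return PipelineResult(
        config, processed, performances, selected, models,
        distances, thresholds, decisions, tables,
    )


# ---------------------------------------------------------------------------
# artefact I/O for staged (CLI) execution
# ---------------------------------------------------------------------------

def save_processed(processed: ProcessedStudy, outdir: str | Path) -> None:
    """Write the measurement-level dataset: one wide CSV per sensor, the
    ground-truth manifest, and the per-sensor removal counts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    processed.manifest.to_csv(outdir / "manifest.csv", index=False)
    meta = {"removed": {s.value: int(n) for s, n in processed.removed.items()},
            "sensors": {}}
    for sensor, table in processed.tables.items():
        df = table.index.copy()
        wcols = [f"{w:.6f}" for w in table.wavelengths]
        df = pd.concat(
            [df, pd.DataFrame(table.X, columns=wcols, index=df.index)], axis=1
        )
        df.to_csv(outdir / f"measurements_{sensor.value}.csv", index=False,
                  float_format="%.10g")
        meta["sensors"][sensor.value] = len(wcols)
    (outdir / "run_manifest.json").write_text(json.dumps(meta, indent=2))


def load_processed(outdir: str | Path) -> ProcessedStudy:
    outdir = Path(outdir)
    meta_path = outdir / "run_manifest.json"
    if not meta_path.exists():
        raise ConfigError(
            f"no simulated study under {outdir}; run `simulate` first"
        )
    meta = json.loads(meta_path.read_text())
    manifest = pd.read_csv(outdir / "manifest.csv")
    tables = {}
    for sensor_name in meta["sensors"]:
        sensor = Sensor(sensor_name)
        df = pd.read_csv(outdir / f"measurements_{sensor_name}.csv")
        idx = df[["sample_id", "day", "rep"]].copy()
        wcols = [c for c in df.columns if c not in ("sample_id", "day", "rep")]
        tables[sensor] = SensorTable(
            sensor,
            np.array([float(c) for c in wcols]),
            df[wcols].to_numpy(dtype=float),
            idx,
        )
    removed = {Sensor(k): v for k, v in meta["removed"].items()}
    return ProcessedStudy(tables, removed, manifest)


__all__ = [
    "RunConfig", "PipelineResult", "run_pipeline",
    "save_processed", "load_processed",
]
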