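"""High-level decision fusion and threshold scenarios.

Each selected model votes a sample "out-of-class" when its per-sample
class distance strictly exceeds the model's threshold; a sample is
flagged non-EVOO when at least ``min_votes`` (default 2) of the selected
models vote out.  Two ways of setting the per-model thresholds are
provided:

* Scenario 1 (no false negatives): each threshold sits just above the
  largest cross-validated EVOO calibration distance of its model, so by
  construction every calibration EVOO is classified correctly.  Suited to
  raw-material identification; permissive toward admixtures.
* Scenario 2 (fraud screening): a common quantile of each model's EVOO
  calibration distances is searched on a grid, maximizing the fused
  detection rate of adulterated calibration samples subject to a floor
  on the fused EVOO correct rate (default 0.75).  Trades some authentic
  EVOOs for a much higher admixture hit rate.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, ScenarioError

logger = logging.getLogger(__name__)


class Scenario(str, enum.Enum):
    S1_NO_FALSE_NEGATIVE = "S1_NO_FALSE_NEGATIVE"
    S2_FRAUD_SCREEN = "S2_FRAUD_SCREEN"


@dataclass(frozen=True)
class ScenarioConfig:
    scenario: Scenario = Scenario.S1_NO_FALSE_NEGATIVE
    min_votes: int = 2
    evoo_rate_floor: float = 0.75
    threshold_grid: tuple[float, ...] = tuple(
        np.round(np.arange(0.50, 1.0001, 0.01), 4)
    )
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if self.min_votes < 1:
            raise ConfigError("min_votes must be >= 1")
        if not 0.0 <= self.evoo_rate_floor <= 1.0:
            raise ConfigError("evoo_rate_floor must lie in [0, 1]")


@dataclass
class FusedDecision:
    sample_id: str
    votes_out: int
    flag: str                              # "EVOO" or "NON_EVOO"
    per_model_distances: dict[str, float] = field(default_factory=dict)


def apply_threshold(distance: float, threshold: float) -> str:
    """Vote of one model on one sample: 'out' iff distance strictly
    exceeds the threshold (the boundary counts as in-class)."""
    if threshold <= 0:
        raise ConfigError("threshold must be positive")
    return "out" if distance > threshold else "in"


def combine_replicates(per_measurement_distances, policy: str = "mean") -> float:
    """Collapse a sample's replicate-measurement distances to one value
    before thresholding.  ``mean`` (default) matches the grid stage's
    per-sample aggregation; ``median`` is available as a robust option."""
    d = np.asarray(per_measurement_distances, dtype=float)
    if d.size == 0:
        raise DataError("no measurements to combine")
    if policy == "mean":
        return float(d.mean())
    if policy == "median":
        return float(np.median(d))
    raise ConfigError(f"unknown replicate policy {policy!r}")


def fuse_votes(
    votes,
    min_votes: int = 2,
    sample_id: str = "",
    per_model_distances: dict[str, float] | None = None,
) -> FusedDecision:
    """Count out-votes; flag non-EVOO iff at least ``min_votes`` vote out."""
    votes = list(votes)
    if not votes:
        raise DataError("empty vote list")
    n_out = sum(1 for v in votes if v in ("out", True))
    flag = "NON_EVOO" if n_out >= min_votes else "EVOO"
    return FusedDecision(sample_id, n_out, flag, per_model_distances or {})


def decide_samples(
    distances: pd.DataFrame,
    thresholds: dict[str, float],
    min_votes: int = 2,
    model_keys: list[str] | None = None,
) -> pd.DataFrame:
    """Fused decision for every sample in a (samples x models) distance
    table.  NaN distances (a sample with no retained measurement for that
    model's sensor) cast no vote.  Returns sample_id, votes_out, flag."""
    keys = model_keys if model_keys is not None else list(distances.columns)
    if not keys:
        raise DataError("no models to fuse")
    sub = distances[keys]
    thr = np.array([thresholds[k] for k in keys])
    if np.any(thr <= 0):
        raise ConfigError("all thresholds must be positive")
    votes_out = (sub.to_numpy() > thr).sum(axis=1)
    flags = np.where(votes_out >= min_votes, "NON_EVOO", "EVOO")
    return pd.DataFrame({
        "sample_id": sub.index,
        "votes_out": votes_out.astype(int),
        "flag": flags,
    }).reset_index(drop=True)


def _rates(decisions: pd.DataFrame, evoo_ids: set[str],
           adulterated_ids: set[str]) -> tuple[float, float]:
    flag = dict(zip(decisions["sample_id"], decisions["flag"]))
    evoo_ok = [flag[s] == "EVOO" for s in evoo_ids if s in flag]
    adu_hit = [flag[s] == "NON_EVOO" for s in adulterated_ids if s in flag]
    evoo_rate = float(np.mean(evoo_ok)) if evoo_ok else 1.0
    detect = float(np.mean(adu_hit)) if adu_hit else 0.0
    return evoo_rate, detect


def tune_thresholds(
    calibration_distances: pd.DataFrame,
    evoo_ids,
    adulterated_ids,
    config: ScenarioConfig,
) -> dict[str, float]:
    """Set one threshold per model from calibration distances.

    ``calibration_distances`` is a (samples x model keys) table whose EVOO
    rows are cross-validated distances.  See the module docstring for the
    two scenarios.  An infeasible scenario-2 floor falls back to the
    scenario-1 thresholds with a logged warning.
    """
    evoo_ids = {str(s) for s in evoo_ids}
    adulterated_ids = {str(s) for s in adulterated_ids}
    evoo_rows = calibration_distances.loc[
        calibration_distances.index.map(lambda s: str(s) in evoo_ids)
    ]
    if evoo_rows.empty:
        raise ScenarioError("calibration set contains no EVOO samples")
    s1 = {
        key: max(float(evoo_rows[key].max()) * (1.0 + config.epsilon), 1e-12)
        for key in calibration_distances.columns
    }
    if config.scenario is Scenario.S1_NO_FALSE_NEGATIVE:
        return s1

    if not adulterated_ids:
        raise ScenarioError("scenario 2 needs adulterated calibration samples")
    best = None        # (detect, evoo_rate, -quantile, thresholds)
    for q in config.threshold_grid:
        thr = {
            key: max(float(evoo_rows[key].quantile(q)), 1e-12)
            for key in calibration_distances.columns
        }
        decisions = decide_samples(calibration_distances, thr,
                                   config.min_votes)
        evoo_rate, detect = _rates(decisions, evoo_ids, adulterated_ids)
        if evoo_rate < config.evoo_rate_floor:
            continue
        cand = (detect, evoo_rate, -q, thr)
        if best is None or cand[:3] > best[:3]:
            best = cand
    if best is None:
        logger.warning(
            "scenario 2 infeasible at EVOO-rate floor %.2f; falling back "
            "to scenario-1 thresholds", config.evoo_rate_floor,
        )
        return s1
    return best[3]


__all__ = [
    "Scenario", "ScenarioConfig", "FusedDecision", "apply_threshold",
    "combine_replicates", "fuse_votes", "decide_samples", "tune_thresholds",
]
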