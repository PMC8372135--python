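"""Model-grid orchestration: grouped splitting, AUROC ranking, selection.

The screening workflow trains every (sensor, preprocessing, algorithm)
grid point on EVOO measurements only, under an outer sample-grouped 0.8
split so that all nine replicate measurements of an oil stay together on
one side.  Held-out EVOO distances and the distances of every non-EVOO
sample are averaged per sample, and each model is scored by three AUROCs:
EVOO vs lower-quality olive oils (RVOO + OPO), vs other edible oils, and
vs adulterated EVOOs.  Models are ranked by the mean of the three and a
per-sensor quota (default 6 FLUO + 2 VIS + 2 NIR = 10) is selected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ConfigError, DataError, SelectionError, SplitError
from .occ import (
    Algorithm,
    OCCModelSpec,
    TrainedOCCModel,
    inner_cv_select,
    make_estimator,
    train_occ_model,
)
from .preprocess import PreprocessSpec
from .spectra import Sensor
from .synthetic import ProcessedStudy

logger = logging.getLogger(__name__)

ADVERSARY_GROUPS = ("LOWER_QUALITY_OLIVE", "OTHER_OILS", "ADULTERATED")

DEFAULT_QUOTAS: dict[Sensor, int] = {
    Sensor.FLUO: 6, Sensor.VIS: 2, Sensor.NIR: 2,
}


@dataclass(frozen=True)
class GroupedSplit:
    """A sample-level train/test partition of the EVOO library."""

    train_sample_ids: frozenset[str]
    test_sample_ids: frozenset[str]
    fraction: float

    def __post_init__(self) -> None:
        if self.train_sample_ids & self.test_sample_ids:
            raise SplitError("train and test sample sets overlap")


def grouped_split(
    evoo_sample_ids, fraction: float = 0.8, seed: int = 0
) -> GroupedSplit:
    """Seeded uniform draw of floor(fraction * n) samples into training.

    Splitting at the sample level is what prevents replicate leakage: a
    measurement of a held-out oil can never influence a fitted model.
    """
    ids = sorted(set(map(str, evoo_sample_ids)))
    n_train = int(np.floor(fraction * len(ids)))
    if n_train < 1 or n_train >= len(ids):
        raise SplitError(
            f"split of {len(ids)} samples at fraction {fraction} leaves an "
            "empty side"
        )
    rng = np.random.default_rng(seed)
    train = rng.choice(ids, size=n_train, replace=False)
    return GroupedSplit(frozenset(train), frozenset(ids) - set(train), fraction)


def aggregate_sample_distance(per_measurement_distances) -> float:
    """Arithmetic mean of a sample's per-measurement class distances."""
    d = np.asarray(per_measurement_distances, dtype=float)
    if d.size == 0:
        raise DataError("no retained measurements for this sample")
    return float(d.mean())


def auroc(target_distances, adversary_distances) -> float:
    """Mann-Whitney AUROC: P(adversary > target) + 0.5 P(tie).

    The probability that a random out-of-class sample sits farther from
    the EVOO class model than a random authentic EVOO.
    """
    t = np.asarray(target_distances, dtype=float)
    a = np.asarray(adversary_distances, dtype=float)
    if t.size == 0 or a.size == 0:
        raise DataError("auroc needs nonempty target and adversary sets")
    ranks = rankdata(np.concatenate([t, a]))
    u = ranks[t.size:].sum() - a.size * (a.size + 1) / 2.0
    return float(u / (t.size * a.size))


@dataclass
class ModelPerformance:
    spec: OCCModelSpec
    auroc_by_adversary: dict[str, float]
    rank_score: float = field(init=False)

    def __post_init__(self) -> None:
        for v in self.auroc_by_adversary.values():
            if not 0.0 <= v <= 1.0:
                raise DataError("AUROC outside [0, 1]")
        self.rank_score = float(np.mean(list(self.auroc_by_adversary.values())))


def rank_and_select(
    performances: list[ModelPerformance] | pd.DataFrame,
    quotas: dict[Sensor, int] | None = None,
) -> list[str]:
    """Per-sensor top-quota selection by rank score.

    Replaces the study's manual pick with a deterministic rule: within
    each sensor, take the quota-many models with the highest mean AUROC,
    breaking exact ties by the lexicographically smaller spec key.
    """
    quotas = quotas if quotas is not None else DEFAULT_QUOTAS
    if isinstance(performances, pd.DataFrame):
        rows = [(r.spec_key, Sensor(r.sensor), float(r.rank_score))
                for r in performances.itertuples()]
    else:
        rows = [(p.spec.key, p.spec.sensor, p.rank_score)
                for p in performances]
    selected: list[str] = []
    for sensor, quota in quotas.items():
        if quota == 0:
            continue
        candidates = sorted(
            ((key, score) for key, sens, score in rows if sens == sensor),
            key=lambda ks: (-ks[1], ks[0]),
        )
        if len(candidates) < quota:
            raise SelectionError(
                f"{sensor.value}: quota {quota} but only "
                f"{len(candidates)} candidates"
            )
        selected.extend(key for key, _ in candidates[:quota])
    return selected


# ---------------------------------------------------------------------------
# grid evaluation
# ---------------------------------------------------------------------------

def _sample_groups(manifest: pd.DataFrame) -> dict[str, str]:
    """sample_id -> adversary group ('TARGET' for pure EVOO)."""
    groups = {}
    for r in manifest.itertuples():
        if r.adulterated:
            groups[r.sample_id] = "ADULTERATED"
        elif r.oil_class == "EVOO":
            groups[r.sample_id] = "TARGET"
        elif r.oil_class in ("RVOO", "OPO"):
            groups[r.sample_id] = "LOWER_QUALITY_OLIVE"
        else:
            groups[r.sample_id] = "OTHER_OILS"
    return groups


def _derived_seed(*keys: int) -> int:
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2**31))


def evaluate_grid(
    processed: ProcessedStudy,
    grid: list[tuple[PreprocessSpec, str]] | dict[Sensor, list],
    n_repeats: int = 5,
    fraction: float = 0.8,
    seed: int = 0,
    candidate_grids: dict[Algorithm, list[dict]] | None = None,
) -> pd.DataFrame:
    """Train and score every grid point on every sensor.

    The outer split is repeated ``n_repeats`` times with distances
    averaged per sample across repeats (one 0.8 split of a small EVOO
    library leaves very few held-out targets; averaging repeats stabilises
    the AUROCs).  Returns one row per model with the three adversary
    AUROCs and the mean rank score.
    """
    groups = _sample_groups(processed.manifest)
    records = []
    for sensor, table in processed.tables.items():
        sensor_grid = grid.get(sensor, []) if isinstance(grid, dict) else grid
        if not sensor_grid:
            continue
        sample_ids = table.index["sample_id"].to_numpy()
        is_evoo_row = np.array([groups[s] == "TARGET" for s in sample_ids])
        evoo_ids = sorted(set(sample_ids[is_evoo_row]))
        feat_cache: dict[str, np.ndarray] = {}
        for pspec, _ in sensor_grid:
            if pspec.key not in feat_cache:
                feat_cache[pspec.key], _ = pspec.apply(
                    table.X, table.wavelengths
                )
        # accumulate per (spec, sample): sum of per-repeat sample means
        dist_sum: dict[tuple[str, str], float] = {}
        dist_cnt: dict[tuple[str, str], int] = {}
        for r in range(n_repeats):
            split = grouped_split(
                evoo_ids, fraction, seed=_derived_seed(seed, 606, r)
            )
            train_mask = np.isin(sample_ids, sorted(split.train_sample_ids))
            score_mask = ~train_mask          # held-out EVOO + all non-EVOO
            score_ids = sample_ids[score_mask]
            for pspec, algo_name in sensor_grid:
                algo = Algorithm(algo_name)
                F = feat_cache[pspec.key]
                spec = OCCModelSpec(sensor, pspec, algo)
                cand = (candidate_grids or {}).get(algo)
                hyper = inner_cv_select(
                    algo, F[train_mask], sample_ids[train_mask],
                    candidate_grid=cand, seed=_derived_seed(seed, 707, r),
                )
                est = make_estimator(algo, **hyper).fit(F[train_mask])
                d = est.distance(F[score_mask])
                for sid in np.unique(score_ids):
                    key = (spec.key, str(sid))
                    val = aggregate_sample_distance(d[score_ids == sid])
                    dist_sum[key] = dist_sum.get(key, 0.0) + val
                    dist_cnt[key] = dist_cnt.get(key, 0) + 1
        for pspec, algo_name in sensor_grid:
            spec = OCCModelSpec(sensor, pspec, Algorithm(algo_name))
            by_group: dict[str, list[float]] = {
                g: [] for g in ("TARGET",) + ADVERSARY_GROUPS
            }
            for (skey, sid), total in dist_sum.items():
                if skey != spec.key:
                    continue
                by_group[groups[sid]].append(total / dist_cnt[(skey, sid)])
            aurocs = {
                g: auroc(by_group["TARGET"], by_group[g])
                for g in ADVERSARY_GROUPS if by_group[g]
            }
            perf = ModelPerformance(spec, aurocs)
            records.append({
                "spec_key": spec.key,
                "sensor": sensor.value,
                "preprocess": pspec.key,
                "algorithm": algo_name,
                **{f"auroc_{g.lower()}": v for g, v in aurocs.items()},
                "rank_score": perf.rank_score,
            })
    if not records:
        raise ConfigError("empty grid: nothing evaluated")
    return pd.DataFrame(records).sort_values("spec_key", ignore_index=True)


def train_selected_models(
    processed: ProcessedStudy,
    selected_keys: list[str],
    seed: int = 0,
    candidate_grids: dict[Algorithm, list[dict]] | None = None,
) -> tuple[dict[str, TrainedOCCModel], pd.DataFrame]:
    """Refit the selected models on the full EVOO library and build the
    per-sample distance table used for threshold tuning and decisions.

    EVOO samples receive their grouped-CV calibration distance (a sample
    never scored by a model it helped fit); every other sample is scored
    by the final model.  Returns (models, distances) with distances indexed
    by sample_id and one column per model key.
    """
    groups = _sample_groups(processed.manifest)
    models: dict[str, TrainedOCCModel] = {}
    columns: dict[str, pd.Series] = {}
    for key in selected_keys:
        spec = OCCModelSpec.from_key(key)
        table = processed.tables[spec.sensor]
        sample_ids = table.index["sample_id"].to_numpy()
        F, _ = spec.preprocess.apply(table.X, table.wavelengths)
        evoo_mask = np.array([groups[s] == "TARGET" for s in sample_ids])
        cand = (candidate_grids or {}).get(spec.algorithm)
        model = train_occ_model(
            spec, F[evoo_mask], sample_ids[evoo_mask],
            candidate_grid=cand, seed=_derived_seed(seed, 808),
        )
        dist = dict(zip(model.calibration_sample_ids,
                        model.calibration_distances))
        other_ids = sample_ids[~evoo_mask]
        d = model.distance(F[~evoo_mask])
        for sid in np.unique(other_ids):
            dist[str(sid)] = aggregate_sample_distance(d[other_ids == sid])
        models[key] = model
        columns[key] = pd.Series(dist, name=key)
    distances = pd.DataFrame(columns)
    distances.index.name = "sample_id"
    return models, distances


__all__ = [
    "GroupedSplit", "ModelPerformance", "ADVERSARY_GROUPS", "DEFAULT_QUOTAS",
    "grouped_split", "aggregate_sample_distance", "auroc", "rank_and_select",
    "evaluate_grid", "train_selected_models",
]
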