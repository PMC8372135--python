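"""Reporting: per-class classification rates, detection-by-fraction
curves, and conformity checking against EVOO regulatory limits.

The central artefact is the rate table: one row per truth class (the
four pure classes plus the two admixture groups), one column for the
fused decision and one per single sensor, each cell a correct-
classification percentage with its count audit retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DataError
from .fusion import decide_samples
from .occ import OCCModelSpec
from .spectra import Sensor

TRUTH_ROWS = ("EVOO", "RVOO", "OPO", "OTHER", "ADULT_OLIVE", "ADULT_OTHER")
SENSOR_COLUMNS = ("fused", "FLUO", "NIR", "VIS")


@dataclass
class RateTable:
    """Correct-classification percentages with their count audit.

    ``table`` holds percentages (rows = truth classes, columns = fused +
    per-sensor); ``numerators``/``denominators`` hold the underlying
    counts so every cell can be recomputed exactly.
    """

    table: pd.DataFrame
    numerators: pd.DataFrame
    denominators: pd.DataFrame

    def to_markdown(self) -> str:
        df = self.table.round(1)
        lines = ["| Sample | " + " | ".join(df.columns) + " |",
                 "|" + "---|" * (len(df.columns) + 1)]
        for row in df.itertuples():
            cells = " | ".join(
                "-" if np.isnan(v) else f"{v:.0f}" for v in row[1:]
            )
            lines.append(f"| {row.Index} | {cells} |")
        return "\n".join(lines)


def _truth_groups(manifest: pd.DataFrame) -> pd.Series:
    if "truth_group" in manifest.columns:
        return manifest.set_index("sample_id")["truth_group"]
    raise DataError("manifest lacks a truth_group column")


def _correct_mask(flags: pd.Series, groups: pd.Series) -> pd.Series:
    """A pure EVOO is correct when flagged EVOO; everything else —
    including every admixture, at any level — when flagged NON_EVOO."""
    want_evoo = groups == "EVOO"
    return (flags == "EVOO") == want_evoo


def rate_table(
    distances: pd.DataFrame,
    thresholds: Mapping[str, float],
    manifest: pd.DataFrame,
    selected_keys: list[str],
    min_votes: int = 2,
) -> RateTable:
    """Build the per-class rate table for the fused decision and for each
    sensor alone.

    Single-sensor columns reuse the identical thresholds and fusion rule,
    restricted to that sensor's selected models, with the vote quorum
    rescaled as max(1, round(min_votes * n_sensor / n_total)).
    """
    groups = _truth_groups(manifest)
    missing = [s for s in distances.index if s not in groups.index]
    if missing:
        raise DataError(f"samples without truth records: {missing}")

    subsets: dict[str, tuple[list[str], int]] = {
        "fused": (list(selected_keys), min_votes)
    }
    for sensor in (Sensor.FLUO, Sensor.NIR, Sensor.VIS):
        keys = [k for k in selected_keys
                if OCCModelSpec.from_key(k).sensor is sensor]
        if keys:
            quorum = max(1, round(min_votes * len(keys) / len(selected_keys)))
            subsets[sensor.value] = (keys, quorum)

    pct = pd.DataFrame(np.nan, index=list(TRUTH_ROWS),
                       columns=list(SENSOR_COLUMNS))
    num = pct.copy()
    den = pct.copy()
    for col, (keys, quorum) in subsets.items():
        decisions = decide_samples(distances, dict(thresholds), quorum, keys)
        decisions = decisions.set_index("sample_id")
        g = groups.loc[decisions.index]
        correct = _correct_mask(decisions["flag"], g)
        for row in TRUTH_ROWS:
            mask = g == row
            if mask.any():
                den.loc[row, col] = int(mask.sum())
                num.loc[row, col] = int(correct[mask].sum())
                pct.loc[row, col] = 100.0 * num.loc[row, col] / den.loc[row, col]
    return RateTable(pct, num, den)


def detection_by_fraction(
    decisions: pd.DataFrame,
    manifest: pd.DataFrame,
    fraction_bins: list[float] | None = None,
) -> pd.DataFrame:
    """Detection rate of admixtures per adulteration level and adulterant
    class.  Levels with no samples are simply absent from the output."""
    flags = decisions.set_index("sample_id")["flag"]
    adu = manifest[manifest["adulterated"].astype(bool)]
    records = []
    for (adu_class, frac), block in adu.groupby(
        ["adulterant_class", "fraction_v"]
    ):
        if fraction_bins is not None and frac not in fraction_bins:
            continue
        ids = [s for s in block["sample_id"] if s in flags.index]
        if not ids:
            continue
        hit = sum(flags[s] == "NON_EVOO" for s in ids)
        records.append({
            "adulterant_class": adu_class,
            "fraction_v": float(frac),
            "n": len(ids),
            "detected": int(hit),
            "detection_rate_pct": 100.0 * hit / len(ids),
        })
    return pd.DataFrame(
        records,
        columns=["adulterant_class", "fraction_v", "n", "detected",
                 "detection_rate_pct"],
    ).sort_values(["adulterant_class", "fraction_v"], ignore_index=True)


# ---------------------------------------------------------------------------
# regulatory reference-limit checking
# ---------------------------------------------------------------------------

#: analyte -> (limit, comparison); '<' limits are strict (MCPD esters and
#: glycidyl esters), the oxidation indices are inclusive
EVOO_LIMITS: dict[str, tuple[float, str]] = {
    "peroxide_index": (20.00, "le"),   # mEq O2 / kg
    "k232": (2.5, "le"),               # AU
    "k268": (0.22, "le"),              # AU
    "delta_k": (0.01, "le"),           # dimensionless
    "mcpd3": (0.10, "lt"),             # mg/kg
    "mcpd2": (0.07, "lt"),             # mg/kg
    "ges": (0.07, "lt"),               # mg/kg
}


@dataclass(frozen=True)
class ReferenceChemistry:
    """Wet-lab reference values for one EVOO; censored results below the
    limit of detection are given as strings like ``"<0.10"``."""

    peroxide_index: float | str | None = None
    k232: float | str | None = None
    k268: float | str | None = None
    delta_k: float | str | None = None
    mcpd3: float | str | None = None
    mcpd2: float | str | None = None
    ges: float | str | None = None


def check_reference_limits(values: ReferenceChemistry) -> dict[str, bool]:
    """Pass/fail per analyte against the EVOO limits; censored '<LOD'
    entries pass, absent analytes are skipped."""
    out: dict[str, bool] = {}
    for analyte, (limit, cmp) in EVOO_LIMITS.items():
        v = getattr(values, analyte)
        if v is None:
            continue
        if isinstance(v, str):
            if not v.strip().startswith("<"):
                raise DataError(f"uninterpretable value {v!r} for {analyte}")
            out[analyte] = True
            continue
        if v < 0:
            raise DataError(f"negative value for {analyte}")
        out[analyte] = (v <= limit) if cmp == "le" else (v < limit)
    if not out:
        raise DataError("no analyte present")
    return out


__all__ = [
    "RateTable", "ReferenceChemistry", "EVOO_LIMITS", "TRUTH_ROWS",
    "rate_table", "detection_by_fraction", "check_reference_limits",
]
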