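"""Core data model for multi-sensor oil spectra.

A portable transflectance sensor head carries three spectrometers: a
near-infrared (NIR) engine, and a UV-Vis detector that serves both diffuse
visible reflectance (VIS) and 365 nm-excited fluorescence emission (FLUO).
One *measurement run* acquires a burst of scans from every sensor plus a
dark reference and — for the reflectance channels — a white reference
against a 99% diffuse standard.

This module defines the sensor/spectrum/run/sample containers, the
reference-correction arithmetic, wavelength trimming, scan averaging,
detector-saturation screening, and a plain-text dataset format.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import (
    DataError,
    DegenerateReferenceError,
    EmptyMeasurementError,
    EmptyTrimError,
    GridMismatchError,
    SchemaError,
)

#: positive floor below which (white - dark) is considered degenerate,
#: in detector counts
REFERENCE_FLOOR = 1e-9


class Sensor(str, enum.Enum):
    """The three spectral channels of the hyphenated sensor."""

    FLUO = "FLUO"
    VIS = "VIS"
    NIR = "NIR"


@dataclass(frozen=True)
class SensorKind:
    """Static description of one sensor channel.

    ``raw_range_nm``/``raw_n_points`` describe the detector readout grid;
    ``used_range_nm`` is the sub-interval retained after discarding noisy
    detector edges.  The NIR grid is exactly 1 nm spaced (939 + k nm); the
    UV-Vis detector grid is modelled as uniform over its raw range.
    """

    name: Sensor
    raw_range_nm: tuple[float, float]
    raw_n_points: int
    used_range_nm: tuple[float, float]
    has_white: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.raw_range_nm
        ulo, uhi = self.used_range_nm
        if not (lo <= ulo < uhi <= hi):
            raise ValueError("used_range_nm must lie inside raw_range_nm")
        if self.raw_n_points < 2:
            raise ValueError("raw_n_points must be >= 2")

    def raw_grid(self) -> np.ndarray:
        """Wavelength grid of the raw readout, nm, strictly ascending."""
        lo, hi = self.raw_range_nm
        return np.linspace(lo, hi, self.raw_n_points)


#: Default sensor geometry.  FLUO shares the UV-Vis detector with VIS and is
#: dark-corrected only (no white reference is meaningful for emission).
DEFAULT_SENSORS: dict[Sensor, SensorKind] = {
    Sensor.NIR: SensorKind(Sensor.NIR, (939.0, 1833.0), 895, (1020.0, 1833.0)),
    Sensor.VIS: SensorKind(Sensor.VIS, (320.0, 889.0), 288, (400.0, 740.0)),
    Sensor.FLUO: SensorKind(
        Sensor.FLUO, (320.0, 889.0), 288, (340.0, 780.0), has_white=False
    ),
}


@dataclass
class Spectrum:
    """One wavelength-indexed intensity trace from one sensor."""

    sensor: Sensor
    wavelengths: np.ndarray
    intensities: np.ndarray
    saturated: bool = False

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.shape != self.intensities.shape:
            raise DataError("wavelengths and intensities differ in length")
        if self.wavelengths.size < 2:
            raise DataError("a spectrum needs at least 2 points")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise DataError("wavelengths must be strictly ascending")

    def __len__(self) -> int:
        return int(self.wavelengths.size)


@dataclass
class MeasurementRun:
    """All scans plus references from one acquisition event.

    ``day`` indexes the measurement day (1..3) and ``rep`` the run within
    that day (1..3); together they label the nine replicate measurements of
    a sample.
    """

    sample_id: str
    day: int
    rep: int
    scans: dict[Sensor, list[Spectrum]]
    dark: dict[Sensor, Spectrum]
    white: dict[Sensor, Spectrum] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sensor, scan_list in self.scans.items():
            ref = self.dark.get(sensor)
            grids = [s.wavelengths for s in scan_list]
            if ref is not None:
                grids.append(ref.wavelengths)
            w = self.white.get(sensor)
            if w is not None:
                grids.append(w.wavelengths)
            for g in grids[1:]:
                if not np.array_equal(grids[0], g):
                    raise GridMismatchError(
                        f"{sensor.value} scans/references on different grids "
                        f"for sample {self.sample_id}"
                    )


class OilClass(str, enum.Enum):
    EVOO = "EVOO"          # extra virgin olive oil (the target class)
    RVOO = "RVOO"          # refined + virgin olive oil blend
    OPO = "OPO"            # olive-pomace oil
    OTHER = "OTHER"        # non-olive edible oil


class AdulterantClass(str, enum.Enum):
    OLIVE_NON_EVOO = "OLIVE_NON_EVOO"   # RVOO or OPO mixed into EVOO
    OTHER_OIL = "OTHER_OIL"             # non-olive oil mixed into EVOO


@dataclass(frozen=True)
class OilSample:
    """Identity and ground-truth composition of one oil sample.

    Admixtures are EVOO-based: an ``adulterated`` sample has a base EVOO, an
    adulterant oil and a volume fraction ``fraction_v`` of adulterant.
    """

    sample_id: str
    oil_class: OilClass
    adulterated: bool = False
    base_id: str | None = None
    adulterant_id: str | None = None
    adulterant_class: AdulterantClass | None = None
    fraction_v: float | None = None

    def __post_init__(self) -> None:
        if self.adulterated:
            if self.oil_class is not OilClass.EVOO:
                raise DataError("admixtures are declared as EVOO-based")
            if not (self.base_id and self.adulterant_id):
                raise DataError("adulterated sample needs base and adulterant ids")
            if self.fraction_v is None or not (0.0 < self.fraction_v < 1.0):
                raise DataError("adulterant fraction must lie in (0, 1)")
        elif self.fraction_v is not None:
            raise DataError("pure sample must not carry a fraction")

    @property
    def truth_group(self) -> str:
        """Reporting group: pure class name, or ADULT_OLIVE / ADULT_OTHER."""
        if not self.adulterated:
            return self.oil_class.value
        if self.adulterant_class is AdulterantClass.OLIVE_NON_EVOO:
            return "ADULT_OLIVE"
        return "ADULT_OTHER"


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def reference_correct(
    scan: Spectrum, dark: Spectrum, white: Spectrum | None = None
) -> Spectrum:
    """Dark/white reference correction of a raw scan.

    Reflectance channels (VIS, NIR) return the relative reflectance
    ``(scan - dark) / (white - dark)``; the emission channel (FLUO) passes
    ``white=None`` and returns dark-corrected counts ``scan - dark``.

    Raises
    ------
    GridMismatchError
        if the inputs are not on one wavelength grid.
    DegenerateReferenceError
        if any ``white - dark`` element falls below ``REFERENCE_FLOOR``.
    """
    for other in (dark, white):
        if other is not None and not np.array_equal(
            scan.wavelengths, other.wavelengths
        ):
            raise GridMismatchError("scan and references on different grids")
    if white is None:
        out = scan.intensities - dark.intensities
    else:
        denom = white.intensities - dark.intensities
        if np.any(denom < REFERENCE_FLOOR):
            raise DegenerateReferenceError(
                "white - dark below the positive floor; reference unusable"
            )
        out = (scan.intensities - dark.intensities) / denom
    return Spectrum(scan.sensor, scan.wavelengths.copy(), out, scan.saturated)


def trim_spectrum(s: Spectrum, lo_nm: float, hi_nm: float) -> Spectrum:
    """Retain exactly the points with ``lo_nm <= wavelength <= hi_nm``.

    The interval is closed at both ends, so a 1 nm grid over 939–1833 nm
    trimmed to 1020–1833 nm keeps 814 points.
    """
    if not lo_nm < hi_nm:
        raise DataError("trim bounds must satisfy lo < hi")
    keep = (s.wavelengths >= lo_nm) & (s.wavelengths <= hi_nm)
    if not keep.any():
        raise EmptyTrimError(
            f"trim to [{lo_nm}, {hi_nm}] nm retains no points"
        )
    return Spectrum(s.sensor, s.wavelengths[keep], s.intensities[keep], s.saturated)


def detect_saturation(s: Spectrum, sat_level: float, min_run: int = 3) -> bool:
    """True iff at least ``min_run`` consecutive points reach ``sat_level``.

    This is an automated surrogate for visual screening of clipped detector
    signals: genuine saturation shows as a plateau at the ceiling, while a
    single-pixel spike does not (hence ``min_run`` defaults to 3).
    """
    if sat_level <= 0:
        raise ValueError("sat_level must be positive")
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    high = (s.intensities >= sat_level).astype(np.intp)
    if min_run == 1:
        return bool(high.any())
    if high.size < min_run:
        return False
    window = np.convolve(high, np.ones(min_run, dtype=np.intp), mode="valid")
    return bool((window >= min_run).any())


def average_scans(run: MeasurementRun, sensor: Sensor) -> Spectrum:
    """Pointwise mean over the sensor's non-saturated scans in one run."""
    scans = [s for s in run.scans.get(sensor, []) if not s.saturated]
    if not scans:
        raise EmptyMeasurementError(
            f"all {sensor.value} scans discarded for sample "
            f"{run.sample_id} day {run.day} rep {run.rep}"
        )
    mean = np.mean([s.intensities for s in scans], axis=0)
    return Spectrum(sensor, scans[0].wavelengths.copy(), mean)


def filter_saturated(
    measurements: list[tuple[str, Sensor, Spectrum]],
) -> tuple[list[tuple[str, Sensor, Spectrum]], dict[Sensor, int]]:
    """Drop saturation-flagged entries; report removals per sensor."""
    retained = []
    removed: dict[Sensor, int] = {}
    for entry in measurements:
        _, sensor, spec = entry
        if spec.saturated:
            removed[sensor] = removed.get(sensor, 0) + 1
        else:
            retained.append(entry)
    return retained, removed


# ---------------------------------------------------------------------------
# Dataset I/O (long-format CSV + YAML sidecar)
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "sample_id", "scan_kind", "scan_index", "day", "rep",
    "sensor", "wavelength_nm", "intensity",
]

_FLOAT_FMT = "%.12g"   # >= 10 significant digits for round-trip identity


def _sample_to_record(s: OilSample) -> dict:
    return {
        "sample_id": s.sample_id,
        "oil_class": s.oil_class.value,
        "adulterated": s.adulterated,
        "base_id": s.base_id,
        "adulterant_id": s.adulterant_id,
        "adulterant_class": (
            s.adulterant_class.value if s.adulterant_class else None
        ),
        "fraction_v": s.fraction_v,
    }


def _sample_from_record(rec: dict) -> OilSample:
    return OilSample(
        sample_id=rec["sample_id"],
        oil_class=OilClass(rec["oil_class"]),
        adulterated=bool(rec.get("adulterated", False)),
        base_id=rec.get("base_id") or None,
        adulterant_id=rec.get("adulterant_id") or None,
        adulterant_class=(
            AdulterantClass(rec["adulterant_class"])
            if rec.get("adulterant_class")
            else None
        ),
        fraction_v=rec.get("fraction_v"),
    )


def write_dataset(
    path: str | Path,
    samples: list[OilSample],
    runs: list[MeasurementRun],
) -> None:
    """Write samples + raw runs as ``<path>.csv`` and ``<path>.design.yaml``.

    The CSV is long format, one row per (scan, wavelength); the sidecar
    holds the sample table. Intensities are written with 12 significant
    digits so write→read round-trips bit-exactly at that precision.
    """
    path = Path(path)
    rows: list[tuple] = []
    for run in runs:
        for sensor, scan_list in sorted(run.scans.items(), key=lambda kv: kv[0].value):
            for kind, spec_or_list in (
                ("dark", [run.dark[sensor]]),
                ("white", [run.white[sensor]] if sensor in run.white else []),
                ("scan", scan_list),
            ):
                for i, spec in enumerate(spec_or_list):
                    sat = int(spec.saturated)
                    for w, y in zip(spec.wavelengths, spec.intensities):
                        rows.append(
                            (run.sample_id, kind, i, run.day, run.rep,
                             sensor.value, _FLOAT_FMT % w, _FLOAT_FMT % y, sat)
                        )
    df = pd.DataFrame(rows, columns=_CSV_COLUMNS + ["saturated"])
    df.to_csv(path.with_suffix(".csv"), index=False)
    sidecar = {"samples": [_sample_to_record(s) for s in samples]}
    path.with_suffix(".design.yaml").write_text(yaml.safe_dump(sidecar))


def read_dataset(
    path: str | Path,
) -> tuple[list[OilSample], list[MeasurementRun]]:
    """Inverse of :func:`write_dataset`; validates the schema row-wise."""
    path = Path(path)
    csv_path = path.with_suffix(".csv")
    sidecar_path = path.with_suffix(".design.yaml")
    if not csv_path.exists() or not sidecar_path.exists():
        raise SchemaError(f"dataset files not found at {path}")
    design = yaml.safe_load(sidecar_path.read_text())
    samples = [_sample_from_record(rec) for rec in design["samples"]]

    df = pd.read_csv(csv_path)
    missing = set(_CSV_COLUMNS + ["saturated"]) - set(df.columns)
    if missing:
        raise SchemaError(f"missing columns {sorted(missing)}")
    runs: list[MeasurementRun] = []
    group_cols = ["sample_id", "day", "rep"]
    for (sample_id, day, rep), run_df in df.groupby(group_cols, sort=True):
        scans: dict[Sensor, list[Spectrum]] = {}
        dark: dict[Sensor, Spectrum] = {}
        white: dict[Sensor, Spectrum] = {}
        for (sensor_name, kind, idx), block in run_df.groupby(
            ["sensor", "scan_kind", "scan_index"], sort=True
        ):
            try:
                sensor = Sensor(sensor_name)
            except ValueError:
                raise SchemaError(
                    f"unknown sensor {sensor_name!r}", row=int(block.index[0])
                ) from None
            w = block["wavelength_nm"].to_numpy(dtype=float)
            if np.any(np.diff(w) <= 0):
                bad = int(block.index[np.argmin(np.diff(w) > 0) + 1])
                raise SchemaError("non-monotone wavelengths", row=bad)
            spec = Spectrum(
                sensor, w, block["intensity"].to_numpy(dtype=float),
                saturated=bool(block["saturated"].iloc[0]),
            )
            if kind == "dark":
                dark[sensor] = spec
            elif kind == "white":
                white[sensor] = spec
            else:
                scans.setdefault(sensor, []).append(spec)
        runs.append(
            MeasurementRun(str(sample_id), int(day), int(rep), scans, dark, white)
        )
    return samples, runs


def process_run(
    run: MeasurementRun,
    sensors: dict[Sensor, SensorKind] | None = None,
    sat_level: float = 65535.0,
    min_run: int = 3,
    discard_fraction: float = 0.5,
) -> dict[Sensor, Spectrum | None]:
    """Reduce a raw run to one corrected, trimmed spectrum per sensor.

    Per sensor: each scan is screened with :func:`detect_saturation`; if
    more than ``discard_fraction`` of the scans clip, the whole measurement
    is discarded for that sensor (``None``).  Otherwise the retained scans
    are averaged, dark/white corrected, and trimmed to the sensor's used
    wavelength range.
    """
    sensors = sensors or DEFAULT_SENSORS
    out: dict[Sensor, Spectrum | None] = {}
    for sensor, scan_list in run.scans.items():
        kind = sensors[sensor]
        n_sat = 0
        for s in scan_list:
            s.saturated = detect_saturation(s, sat_level, min_run)
            n_sat += s.saturated
        if n_sat > discard_fraction * len(scan_list):
            out[sensor] = None
            continue
        avg = average_scans(run, sensor)
        corrected = reference_correct(
            avg, run.dark[sensor], run.white.get(sensor)
        )
        out[sensor] = trim_spectrum(corrected, *kind.used_range_nm)
    return out


def mark_run_saturated(run: MeasurementRun, sensor: Sensor,
                       ceiling: float) -> None:
    """Clip all of one sensor's scans at the detector ceiling, in place.

    Used by the simulator to inject measurement-level saturation: the signal
    is first scaled so its peak overshoots the ceiling, producing the flat
    plateau that :func:`detect_saturation` looks for.
    """
    for s in run.scans[sensor]:
        peak = float(s.intensities.max())
        if peak <= 0:
            continue
        scale = 1.3 * ceiling / peak
        s.intensities = np.minimum(s.intensities * scale, ceiling)


__all__ = [
    "Sensor", "SensorKind", "Spectrum", "MeasurementRun", "OilSample",
    "OilClass", "AdulterantClass", "DEFAULT_SENSORS", "REFERENCE_FLOOR",
    "reference_correct", "trim_spectrum", "detect_saturation",
    "average_scans", "filter_saturated", "read_dataset", "write_dataset",
    "process_run", "mark_run_saturated",
]
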