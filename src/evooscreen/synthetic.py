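"""Synthetic study generator for the olive-oil screening pipeline.

No public spectral dataset exists for this kind of portable multi-sensor
oil screening, so the pipeline is exercised end to end on simulated data
whose *structure* mirrors real oils:

* Fluorescence (365 nm excitation): olive oils emit from pheophytin-family
  pigments — a dominant q-band near 670 nm, the Soret band at 400–500 nm,
  and a phenolic/carotenoid region at 350–400 nm.  Extra virgin oil (EVOO)
  has the strongest, most uniform pigment emission; refined olive grades
  (RVOO, olive-pomace) lose most of their pigments; refined seed oils have
  almost no q-band at all.
* Visible reflectance: the same pigments absorb, so EVOO is strongly
  coloured while refined oils are nearly translucent.
* NIR: all edible oils share the triglyceride C-H overtone bands; class
  differences are tiny multiplicative offsets, which deliberately makes
  NIR-only models weak discriminators.

Admixtures mix latent spectra linearly in volume fraction.  Measurement
runs add dark level, instrument gain, per-day multiplicative drift and
white-referenced noise; a seeded subset of FLUO and VIS measurements is
clipped at the detector ceiling so the saturation filter has work to do.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import ConfigError
from .spectra import (
    DEFAULT_SENSORS,
    AdulterantClass,
    MeasurementRun,
    OilClass,
    OilSample,
    Sensor,
    SensorKind,
    Spectrum,
    mark_run_saturated,
    process_run,
)


@dataclass(frozen=True)
class BandModel:
    """A Gaussian spectral band: centre and width in nm, amplitude in the
    sensor's intensity unit (counts for emission, absorbance for pigments)."""

    center_nm: float
    width_nm: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.width_nm <= 0:
            raise ConfigError("band width must be positive")
        if self.amplitude < 0:
            raise ConfigError("band amplitude must be nonnegative")

    def evaluate(self, wavelengths: np.ndarray, scale: float = 1.0) -> np.ndarray:
        z = (wavelengths - self.center_nm) / self.width_nm
        return scale * self.amplitude * np.exp(-0.5 * z * z)


@dataclass(frozen=True)
class OilArchetype:
    """Latent spectral template of one oil class.

    ``between_sample_cv`` is the lognormal coefficient of variation applied
    per band when individual oils are drawn from the archetype; EVOO's is
    the smallest, matching the relative uniformity of genuine extra virgin
    oils against the large batch-to-batch spread of refined products.
    """

    oil_class: OilClass
    fluo_bands: tuple[BandModel, ...]
    vis_bands: tuple[BandModel, ...]        # absorbance bands
    nir_bands: tuple[BandModel, ...]        # shared overtone absorbances
    nir_offsets: tuple[float, ...]          # class multipliers, one per band
    between_sample_cv: float

    @property
    def q_band_amplitude(self) -> float:
        """Amplitude of the fluorescence q-band (the band nearest 670 nm)."""
        return min(
            self.fluo_bands, key=lambda b: abs(b.center_nm - 670.0)
        ).amplitude


def default_archetypes() -> dict[OilClass, OilArchetype]:
    """Class templates with strong fluorescence/visible separability.

    EVOO's q-band dominates its own spectrum; refined olive grades keep
    roughly 20–30% of the pigment amplitudes; seed oils keep under 5% of
    EVOO's q-band.  NIR bands are common to all classes up to ~1–4%
    multiplicative offsets.
    """
    nir = (
        BandModel(1210.0, 30.0, 0.12),
        BandModel(1400.0, 45.0, 0.22),
        BandModel(1725.0, 28.0, 0.40),
        BandModel(1765.0, 22.0, 0.28),
    )
    return {
        OilClass.EVOO: OilArchetype(
            OilClass.EVOO,
            fluo_bands=(
                BandModel(375.0, 18.0, 1200.0),
                BandModel(450.0, 25.0, 2500.0),
                BandModel(672.0, 14.0, 9000.0),
            ),
            vis_bands=(
                BandModel(410.0, 18.0, 1.10),
                BandModel(455.0, 20.0, 0.45),
                BandModel(670.0, 12.0, 0.70),
            ),
            nir_bands=nir,
            nir_offsets=(1.0, 1.0, 1.0, 1.0),
            between_sample_cv=0.08,
        ),
        OilClass.RVOO: OilArchetype(
            OilClass.RVOO,
            fluo_bands=(
                BandModel(375.0, 18.0, 1500.0),
                BandModel(450.0, 25.0, 900.0),
                BandModel(672.0, 14.0, 2600.0),
            ),
            vis_bands=(
                BandModel(410.0, 18.0, 0.28),
                BandModel(455.0, 20.0, 0.11),
                BandModel(670.0, 12.0, 0.18),
            ),
            nir_bands=nir,
            nir_offsets=(1.012, 1.008, 1.012, 1.01),
            between_sample_cv=0.30,
        ),
        OilClass.OPO: OilArchetype(
            OilClass.OPO,
            fluo_bands=(
                BandModel(375.0, 18.0, 1800.0),
                BandModel(450.0, 25.0, 700.0),
                BandModel(672.0, 14.0, 2000.0),
            ),
            vis_bands=(
                BandModel(410.0, 18.0, 0.22),
                BandModel(455.0, 20.0, 0.09),
                BandModel(670.0, 12.0, 0.14),
            ),
            nir_bands=nir,
            nir_offsets=(0.988, 0.992, 0.988, 0.99),
            between_sample_cv=0.30,
        ),
        OilClass.OTHER: OilArchetype(
            OilClass.OTHER,
            fluo_bands=(
                BandModel(375.0, 18.0, 2000.0),
                BandModel(450.0, 25.0, 300.0),
                BandModel(672.0, 14.0, 350.0),
            ),
            vis_bands=(
                BandModel(410.0, 18.0, 0.05),
                BandModel(455.0, 25.0, 0.08),
                BandModel(670.0, 12.0, 0.01),
            ),
            nir_bands=nir,
            nir_offsets=(1.04, 1.03, 1.04, 1.035),
            between_sample_cv=0.40,
        ),
    }


@dataclass(frozen=True)
class InstrumentModel:
    """Detector/illumination parameters shared by all simulated runs.

    Units are detector counts.  The gain profile maps latent reflectance
    (VIS/NIR, dimensionless) or latent emission (FLUO, counts at unit gain)
    to raw counts; ``drift`` is the half-width of the uniform per-day
    multiplicative drift emulating sample ageing over the study.
    """

    dark_level: float = 100.0
    dark_noise_sd: float = 2.0
    scan_noise_sd: float = 15.0
    white_span: float = 30000.0
    detector_ceiling: float = 65535.0
    drift: float = 0.02

    def gain_profile(self, wavelengths: np.ndarray) -> np.ndarray:
        """Smoothly curved illumination x detector response, counts."""
        mid = 0.5 * (wavelengths[0] + wavelengths[-1])
        half = 0.5 * (wavelengths[-1] - wavelengths[0])
        return self.white_span * (1.0 - 0.3 * ((wavelengths - mid) / half) ** 2)


@dataclass(frozen=True)
class StudyDesign:
    """Sample counts, mixture levels and measurement plan of the study.

    Defaults reproduce the full design: 16 EVOO + 32 RVOO + 9 OPO + 12
    other oils, 20 olive-based and 40 seed-oil admixtures at 10/25/50%
    (v/v), nine measurement runs per sample (3 days x 3), 10 VIS + 10 FLUO
    + 255 NIR scans per run, and 122 FLUO / 90 VIS measurements saturated.
    """

    n_evoo: int = 16
    n_rvoo: int = 32
    n_opo: int = 9
    n_other: int = 12
    n_mix_olive: int = 20
    n_mix_other: int = 40
    mix_levels: tuple[float, ...] = (0.10, 0.25, 0.50)
    n_days: int = 3
    n_per_day: int = 3
    scans_per_run: dict[Sensor, int] = field(
        default_factory=lambda: {Sensor.VIS: 10, Sensor.FLUO: 10, Sensor.NIR: 255}
    )
    n_saturated_fluo: int = 122
    n_saturated_vis: int = 90
    seed: int = 0
    instrument: InstrumentModel = field(default_factory=InstrumentModel)
    sensors: dict[Sensor, SensorKind] = field(
        default_factory=lambda: dict(DEFAULT_SENSORS)
    )

    def __post_init__(self) -> None:
        for name in ("n_evoo", "n_rvoo", "n_opo", "n_other",
                     "n_mix_olive", "n_mix_other", "n_days", "n_per_day"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if self.n_evoo < 1:
            raise ConfigError("the study needs at least one EVOO")
        for f in self.mix_levels:
            if not 0.0 < f < 1.0:
                raise ConfigError("mixture levels must lie in (0, 1)")

    @property
    def n_replicates(self) -> int:
        return self.n_days * self.n_per_day

    @property
    def n_samples(self) -> int:
        return (self.n_evoo + self.n_rvoo + self.n_opo + self.n_other
                + self.n_mix_olive + self.n_mix_other)

    @property
    def n_runs(self) -> int:
        return self.n_samples * self.n_replicates


@dataclass
class SyntheticOil:
    """An oil sample together with its latent noiseless spectra per sensor
    (FLUO in emission counts, VIS/NIR in relative reflectance), evaluated
    on each sensor's raw wavelength grid."""

    sample: OilSample
    latent: dict[Sensor, np.ndarray]


def _crc(text: str) -> int:
    return zlib.crc32(text.encode())


def _rng(*keys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(keys)))


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean lognormal multiplier with coefficient of variation cv."""
    if cv <= 0:
        return 1.0
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    return float(np.exp(rng.normal(-0.5 * sigma * sigma, sigma)))


def _latent_from_archetype(
    arch: OilArchetype,
    rng: np.random.Generator,
    sensors: dict[Sensor, SensorKind],
) -> dict[Sensor, np.ndarray]:
    grids = {s: k.raw_grid() for s, k in sensors.items()}
    fluo = np.zeros_like(grids[Sensor.FLUO])
    for band in arch.fluo_bands:
        fluo += band.evaluate(
            grids[Sensor.FLUO], _lognormal_factor(rng, arch.between_sample_cv)
        )
    vis_abs = np.zeros_like(grids[Sensor.VIS])
    for band in arch.vis_bands:
        vis_abs += band.evaluate(
            grids[Sensor.VIS], _lognormal_factor(rng, arch.between_sample_cv)
        )
    vis = 0.02 + 0.93 * np.exp(-vis_abs)
    nir_abs = np.zeros_like(grids[Sensor.NIR])
    nir_cv = min(arch.between_sample_cv, 0.02)   # macro-composition is stable
    for band, offset in zip(arch.nir_bands, arch.nir_offsets):
        nir_abs += band.evaluate(
            grids[Sensor.NIR], offset * _lognormal_factor(rng, nir_cv)
        )
    nir = 0.02 + 0.93 * np.exp(-nir_abs)
    return {Sensor.FLUO: fluo, Sensor.VIS: vis, Sensor.NIR: nir}


def generate_oil_library(
    design: StudyDesign,
    archetypes: dict[OilClass, OilArchetype] | None = None,
) -> list[SyntheticOil]:
    """Draw the pure-oil library: one latent spectrum per (oil, sensor)."""
    archetypes = archetypes or default_archetypes()
    counts = [
        (OilClass.EVOO, design.n_evoo),
        (OilClass.RVOO, design.n_rvoo),
        (OilClass.OPO, design.n_opo),
        (OilClass.OTHER, design.n_other),
    ]
    library: list[SyntheticOil] = []
    for oil_class, n in counts:
        arch = archetypes[oil_class]
        for i in range(n):
            sample_id = f"{oil_class.value}-{i + 1:02d}"
            rng = _rng(design.seed, 101, _crc(sample_id))
            latent = _latent_from_archetype(arch, rng, design.sensors)
            library.append(
                SyntheticOil(OilSample(sample_id, oil_class), latent)
            )
    return library


def mix_latent(
    base: SyntheticOil, adulterant: SyntheticOil, fraction: float
) -> dict[Sensor, np.ndarray]:
    """Linear volume mixing of latent spectra: (1-f)*base + f*adulterant."""
    return {
        s: (1.0 - fraction) * base.latent[s] + fraction * adulterant.latent[s]
        for s in base.latent
    }


def generate_admixtures(
    library: list[SyntheticOil], design: StudyDesign
) -> list[SyntheticOil]:
    """Draw the adulterated samples: EVOO base + adulterant + level, all
    chosen uniformly with the design seed."""
    evoo = [o for o in library if o.sample.oil_class is OilClass.EVOO]
    olive_pool = [
        o for o in library
        if o.sample.oil_class in (OilClass.RVOO, OilClass.OPO)
    ]
    other_pool = [o for o in library if o.sample.oil_class is OilClass.OTHER]
    if design.n_mix_olive and not olive_pool:
        raise ConfigError("no RVOO/OPO oils available as adulterants")
    if design.n_mix_other and not other_pool:
        raise ConfigError("no other edible oils available as adulterants")
    rng = _rng(design.seed, 202)
    out: list[SyntheticOil] = []
    plans = (
        [(AdulterantClass.OLIVE_NON_EVOO, olive_pool)] * design.n_mix_olive
        + [(AdulterantClass.OTHER_OIL, other_pool)] * design.n_mix_other
    )
    for i, (adu_class, pool) in enumerate(plans):
        base = evoo[rng.integers(len(evoo))]
        adu = pool[rng.integers(len(pool))]
        frac = float(design.mix_levels[rng.integers(len(design.mix_levels))])
        sample = OilSample(
            sample_id=f"MIX-{i + 1:02d}",
            oil_class=OilClass.EVOO,
            adulterated=True,
            base_id=base.sample.sample_id,
            adulterant_id=adu.sample.sample_id,
            adulterant_class=adu_class,
            fraction_v=frac,
        )
        out.append(SyntheticOil(sample, mix_latent(base, adu, frac)))
    return out


def simulate_run(
    oil: SyntheticOil, day: int, rep: int, design: StudyDesign
) -> MeasurementRun:
    """Simulate one acquisition event for one sample replicate.

    The raw scan model per sensor is ``dark + gain * latent * drift +
    noise``; VIS and NIR additionally get a white-reference scan ``dark +
    gain + noise`` so that downstream dark/white correction recovers
    ``latent * drift``.  Fully deterministic given (seed, sample_id, day,
    rep): the per-run random stream is derived by hashing those values, so
    any subset of the study can be regenerated independently.
    """
    inst = design.instrument
    rng = _rng(design.seed, 404, _crc(oil.sample.sample_id), day, rep)
    drift_rng = _rng(design.seed, 505, _crc(oil.sample.sample_id), day)
    drift = 1.0 + inst.drift * float(drift_rng.uniform(-1.0, 1.0))

    scans: dict[Sensor, list[Spectrum]] = {}
    dark: dict[Sensor, Spectrum] = {}
    white: dict[Sensor, Spectrum] = {}
    for sensor, kind in design.sensors.items():
        grid = kind.raw_grid()
        p = grid.size
        dark_trace = inst.dark_level + (
            rng.standard_normal(p) * inst.dark_noise_sd
            if inst.dark_noise_sd > 0 else 0.0
        )
        dark[sensor] = Spectrum(sensor, grid, np.broadcast_to(
            np.asarray(dark_trace, dtype=float), (p,)).copy())
        if kind.has_white:
            gain = inst.gain_profile(grid)
            signal = gain * oil.latent[sensor] * drift
            white_trace = dark_trace + gain + (
                rng.standard_normal(p) * inst.scan_noise_sd
                if inst.scan_noise_sd > 0 else 0.0
            )
            white[sensor] = Spectrum(sensor, grid, np.asarray(
                white_trace, dtype=float))
        else:
            signal = oil.latent[sensor] * drift
        n_scans = design.scans_per_run[sensor]
        raw = dark_trace + signal + (
            rng.standard_normal((n_scans, p)) * inst.scan_noise_sd
            if inst.scan_noise_sd > 0 else 0.0
        )
        raw = np.atleast_2d(np.broadcast_to(raw, (n_scans, p)))
        scans[sensor] = [Spectrum(sensor, grid, raw[i].copy())
                         for i in range(n_scans)]
    return MeasurementRun(oil.sample.sample_id, day, rep, scans, dark, white)


@dataclass
class SyntheticStudy:
    """The generated study: oils, measurement plan and ground truth.

    Raw runs are produced lazily by :meth:`iter_runs` — a full-scale study
    holds ~300k NIR scans, which are streamed rather than materialised.
    """

    design: StudyDesign
    oils: list[SyntheticOil]
    manifest: pd.DataFrame          # one row per sample, ground truth
    saturated: pd.DataFrame         # sample_id, day, rep, sensor

    @property
    def samples(self) -> list[OilSample]:
        return [o.sample for o in self.oils]

    def run_plan(self) -> list[tuple[str, int, int]]:
        return [
            (o.sample.sample_id, day, rep)
            for o in self.oils
            for day in range(1, self.design.n_days + 1)
            for rep in range(1, self.design.n_per_day + 1)
        ]

    def iter_runs(self) -> Iterator[MeasurementRun]:
        """Yield every measurement run, with saturation clipping applied."""
        sat_keys = {
            (r.sample_id, r.day, r.rep, Sensor(r.sensor))
            for r in self.saturated.itertuples()
        }
        ceiling = self.design.instrument.detector_ceiling
        for oil in self.oils:
            for day in range(1, self.design.n_days + 1):
                for rep in range(1, self.design.n_per_day + 1):
                    run = simulate_run(oil, day, rep, self.design)
                    for sensor in (Sensor.FLUO, Sensor.VIS):
                        if (run.sample_id, day, rep, sensor) in sat_keys:
                            mark_run_saturated(run, sensor, ceiling)
                    yield run


def generate_study(
    design: StudyDesign,
    archetypes: dict[OilClass, OilArchetype] | None = None,
) -> SyntheticStudy:
    """Generate the complete study: library, admixtures, run plan, and the
    seeded choice of saturated FLUO/VIS measurements."""
    library = generate_oil_library(design, archetypes)
    mixes = generate_admixtures(library, design)
    oils = library + mixes
    manifest = pd.DataFrame(
        [
            {
                "sample_id": o.sample.sample_id,
                "oil_class": o.sample.oil_class.value,
                "truth_group": o.sample.truth_group,
                "adulterated": o.sample.adulterated,
                "base_id": o.sample.base_id,
                "adulterant_id": o.sample.adulterant_id,
                "adulterant_class": (
                    o.sample.adulterant_class.value
                    if o.sample.adulterant_class else None
                ),
                "fraction_v": o.sample.fraction_v,
            }
            for o in oils
        ]
    )
    plan = [
        (o.sample.sample_id, day, rep)
        for o in oils
        for day in range(1, design.n_days + 1)
        for rep in range(1, design.n_per_day + 1)
    ]
    rng = _rng(design.seed, 303)
    records = []
    for sensor, n_sat in (
        (Sensor.FLUO, design.n_saturated_fluo),
        (Sensor.VIS, design.n_saturated_vis),
    ):
        if n_sat > len(plan):
            raise ConfigError(
                f"cannot saturate {n_sat} of {len(plan)} measurements"
            )
        chosen = rng.choice(len(plan), size=n_sat, replace=False)
        for idx in sorted(chosen):
            sid, day, rep = plan[idx]
            records.append(
                {"sample_id": sid, "day": day, "rep": rep,
                 "sensor": sensor.value}
            )
    saturated = pd.DataFrame(
        records, columns=["sample_id", "day", "rep", "sensor"]
    )
    return SyntheticStudy(design, oils, manifest, saturated)


@dataclass
class SensorTable:
    """Corrected, trimmed, averaged per-measurement spectra of one sensor:
    a (measurements x wavelengths) matrix plus its row index."""

    sensor: Sensor
    wavelengths: np.ndarray
    X: np.ndarray
    index: pd.DataFrame      # columns: sample_id, day, rep


@dataclass
class ProcessedStudy:
    """The measurement-level dataset every downstream stage consumes."""

    tables: dict[Sensor, SensorTable]
    removed: dict[Sensor, int]
    manifest: pd.DataFrame

    def n_retained(self, sensor: Sensor) -> int:
        return int(self.tables[sensor].X.shape[0])


def process_study(study: SyntheticStudy) -> ProcessedStudy:
    """Stream all runs through saturation screening, averaging, reference
    correction and trimming, one run at a time."""
    design = study.design
    rows: dict[Sensor, list[np.ndarray]] = {s: [] for s in design.sensors}
    idx: dict[Sensor, list[tuple]] = {s: [] for s in design.sensors}
    removed: dict[Sensor, int] = {s: 0 for s in design.sensors}
    grids: dict[Sensor, np.ndarray] = {}
    for run in study.iter_runs():
        reduced = process_run(
            run, design.sensors,
            sat_level=design.instrument.detector_ceiling,
        )
        for sensor, spec in reduced.items():
            if spec is None:
                removed[sensor] += 1
                continue
            rows[sensor].append(spec.intensities)
            idx[sensor].append((run.sample_id, run.day, run.rep))
            grids.setdefault(sensor, spec.wavelengths)
    tables = {
        sensor: SensorTable(
            sensor,
            grids[sensor],
            np.vstack(rows[sensor]),
            pd.DataFrame(idx[sensor], columns=["sample_id", "day", "rep"]),
        )
        for sensor in rows
        if rows[sensor]
    }
    return ProcessedStudy(tables, removed, study.manifest)


__all__ = [
    "BandModel", "OilArchetype", "InstrumentModel", "StudyDesign",
    "SyntheticOil", "SyntheticStudy", "SensorTable", "ProcessedStudy",
    "default_archetypes", "generate_oil_library", "generate_admixtures",
    "mix_latent", "simulate_run", "generate_study", "process_study",
]
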