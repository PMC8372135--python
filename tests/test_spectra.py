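"""Reference correction, trimming, averaging, saturation and dataset I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import evooscreen as es
from evooscreen.errors import (
    DataError,
    DegenerateReferenceError,
    EmptyMeasurementError,
    EmptyTrimError,
    GridMismatchError,
    SchemaError,
)
from evooscreen.spectra import (
    DEFAULT_SENSORS,
    MeasurementRun,
    Sensor,
    Spectrum,
    average_scans,
    detect_saturation,
    filter_saturated,
    read_dataset,
    reference_correct,
    trim_spectrum,
    write_dataset,
)


def spec(values, sensor=Sensor.VIS, wavelengths=None, saturated=False):
    values = np.asarray(values, dtype=float)
    w = np.arange(values.size, dtype=float) if wavelengths is None else wavelengths
    return Spectrum(sensor, w, values, saturated)


class TestReferenceCorrect:
    def test_scan_equals_white_gives_ones(self):
        out = reference_correct(spec([50, 40]), spec([10, 10]), spec([50, 40]))
        np.testing.assert_allclose(out.intensities, [1.0, 1.0])

    def test_scan_equals_dark_gives_zeros(self):
        out = reference_correct(spec([10, 10]), spec([10, 10]), spec([50, 40]))
        np.testing.assert_allclose(out.intensities, [0.0, 0.0])

    def test_hand_arithmetic(self):
        out = reference_correct(spec([30, 40]), spec([10, 10]), spec([50, 40]))
        np.testing.assert_allclose(out.intensities, [0.5, 1.0])

    def test_fluo_is_dark_corrected_only(self):
        out = reference_correct(
            spec([30, 40], Sensor.FLUO), spec([10, 10], Sensor.FLUO)
        )
        np.testing.assert_allclose(out.intensities, [20.0, 30.0])

    def test_gain_scale_invariance(self, rng):
        scan = spec(rng.uniform(100, 1000, 50))
        dark = spec(rng.uniform(0, 50, 50))
        white = spec(dark.intensities + rng.uniform(500, 2000, 50))
        base = reference_correct(scan, dark, white).intensities
        for c in (0.1, 7.3, 1e4):
            scaled = reference_correct(
                spec(c * scan.intensities), spec(c * dark.intensities),
                spec(c * white.intensities),
            ).intensities
            np.testing.assert_allclose(scaled, base, atol=1e-12, rtol=1e-12)

    def test_mismatched_grid_raises(self):
        with pytest.raises(GridMismatchError):
            reference_correct(
                spec([1, 2]), spec([1, 2], wavelengths=np.array([0.0, 2.0])),
                spec([3, 4]),
            )

    def test_degenerate_reference_raises(self):
        with pytest.raises(DegenerateReferenceError):
            reference_correct(spec([1, 2]), spec([5, 5]), spec([5, 5]))


class TestTrim:
    def test_nir_default_range_keeps_814_points(self):
        kind = DEFAULT_SENSORS[Sensor.NIR]
        s = Spectrum(Sensor.NIR, kind.raw_grid(), np.zeros(kind.raw_n_points))
        assert len(trim_spectrum(s, 1020.0, 1833.0)) == 814

    def test_full_range_is_identity(self):
        kind = DEFAULT_SENSORS[Sensor.NIR]
        s = Spectrum(Sensor.NIR, kind.raw_grid(), np.zeros(895))
        assert len(trim_spectrum(s, 939.0, 1833.0)) == 895

    def test_empty_trim_raises(self):
        s = spec([1, 2], wavelengths=np.array([400.0, 500.0]))
        with pytest.raises(EmptyTrimError):
            trim_spectrum(s, 450.0, 460.0)

    def test_idempotent(self, rng):
        s = spec(rng.normal(size=100))
        once = trim_spectrum(s, 20.0, 70.0)
        twice = trim_spectrum(once, 20.0, 70.0)
        np.testing.assert_array_equal(once.intensities, twice.intensities)


class TestDetectSaturation:
    def test_below_level_is_false(self):
        assert not detect_saturation(spec([1, 2, 3, 4]), sat_level=9.0)

    def test_plateau_exactly_at_level_fires(self):
        assert detect_saturation(spec([1, 9, 9, 9, 1]), 9.0, min_run=3)

    def test_min_run_boundary(self):
        s = spec([1, 9, 9, 1])
        assert not detect_saturation(s, 9.0, min_run=3)
        assert detect_saturation(s, 9.0, min_run=2)

    @given(st.lists(st.integers(0, 3), min_size=2, max_size=40),
           st.integers(1, 5))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_run_scan(self, values, min_run):
        s = spec(values)
        # brute force: longest run of points >= level
        longest = run = 0
        for v in values:
            run = run + 1 if v >= 2 else 0
            longest = max(longest, run)
        assert detect_saturation(s, 2.0, min_run) == (longest >= min_run)


def _run_of(scans, sensor=Sensor.VIS):
    w = np.arange(scans[0].size, dtype=float)
    return MeasurementRun(
        "s1", 1, 1,
        scans={sensor: [Spectrum(sensor, w, s) for s in scans]},
        dark={sensor: Spectrum(sensor, w, np.zeros(w.size))},
    )


class TestAverageScans:
    def test_identical_scans_return_that_scan(self):
        run = _run_of([np.array([1.0, 2.0, 3.0])] * 10)
        np.testing.assert_array_equal(
            average_scans(run, Sensor.VIS).intensities, [1, 2, 3]
        )

    def test_two_scan_symmetry(self):
        run = _run_of([np.array([0.0, 2.0]), np.array([2.0, 0.0])])
        np.testing.assert_array_equal(
            average_scans(run, Sensor.VIS).intensities, [1.0, 1.0]
        )

    def test_monte_carlo_mean_within_tolerance(self, rng):
        mu, sigma, n = 5.0, 0.8, 255
        scans = [mu + sigma * rng.standard_normal(30) for _ in range(n)]
        avg = average_scans(_run_of(scans), Sensor.VIS).intensities
        assert np.all(np.abs(avg - mu) < 4 * sigma / np.sqrt(n))

    def test_affine_commutation(self, rng):
        scans = [rng.normal(size=20) for _ in range(5)]
        base = average_scans(_run_of(scans), Sensor.VIS).intensities
        mapped = average_scans(
            _run_of([3.0 * s + 2.0 for s in scans]), Sensor.VIS
        ).intensities
        np.testing.assert_allclose(mapped, 3.0 * base + 2.0, atol=1e-12)

    def test_all_discarded_raises(self):
        run = _run_of([np.array([1.0, 2.0])])
        run.scans[Sensor.VIS][0].saturated = True
        with pytest.raises(EmptyMeasurementError):
            average_scans(run, Sensor.VIS)


class TestFilterSaturated:
    def test_study_scale_arithmetic(self):
        entries = [
            ("s", Sensor.FLUO, spec([1, 2], saturated=(i < 122)))
            for i in range(1161)
        ]
        retained, removed = filter_saturated(entries)
        assert len(retained) == 1039
        assert removed[Sensor.FLUO] == 122

    def test_no_flags_unchanged(self):
        entries = [("s", Sensor.VIS, spec([1, 2]))] * 5
        retained, removed = filter_saturated(entries)
        assert retained == entries and removed == {}

    def test_all_flagged(self):
        entries = [("s", Sensor.VIS, spec([1, 2], saturated=True))] * 4
        retained, removed = filter_saturated(entries)
        assert retained == [] and removed[Sensor.VIS] == 4

    def test_conservation(self, rng):
        entries = [
            ("s", Sensor.VIS, spec([1, 2], saturated=bool(rng.integers(2))))
            for _ in range(50)
        ]
        retained, removed = filter_saturated(entries)
        assert len(retained) + sum(removed.values()) == 50


class TestDatasetIO:
    def test_round_trip(self, tmp_path):
        design = es.StudyDesign(
            n_evoo=2, n_rvoo=1, n_opo=1, n_other=1,
            n_mix_olive=1, n_mix_other=1,
            scans_per_run={Sensor.VIS: 2, Sensor.FLUO: 2, Sensor.NIR: 2},
            n_saturated_fluo=0, n_saturated_vis=0, seed=3,
            n_days=1, n_per_day=2,
        )
        study = es.generate_study(design)
        runs = list(study.iter_runs())[:4]
        path = tmp_path / "ds"
        write_dataset(path, study.samples, runs)
        samples2, runs2 = read_dataset(path)
        assert samples2 == study.samples
        assert len(runs2) == 4
        orig = {(r.sample_id, r.day, r.rep): r for r in runs}
        for r2 in runs2:
            r1 = orig[(r2.sample_id, r2.day, r2.rep)]
            for sensor in r1.scans:
                for a, b in zip(r1.scans[sensor], r2.scans[sensor]):
                    np.testing.assert_allclose(
                        a.intensities, b.intensities, rtol=1e-10
                    )

    def test_two_sample_fixture_counts(self, tmp_path):
        design = es.StudyDesign(
            n_evoo=2, n_rvoo=1, n_opo=1, n_other=1,
            n_mix_olive=0, n_mix_other=0,
            scans_per_run={Sensor.VIS: 2, Sensor.FLUO: 2, Sensor.NIR: 2},
            n_saturated_fluo=0, n_saturated_vis=0, seed=3,
        )
        study = es.generate_study(design)
        two = [o for o in study.oils if o.sample.sample_id.startswith("EVOO")]
        runs = [
            es.simulate_run(o, day, rep, design)
            for o in two for day in (1, 2, 3) for rep in (1, 2, 3)
        ]
        path = tmp_path / "ds"
        write_dataset(path, [o.sample for o in two], runs)
        samples2, runs2 = read_dataset(path)
        assert len(samples2) == 2
        assert len(runs2) == 18

    def test_descending_wavelengths_is_schema_error(self, tmp_path):
        import pandas as pd
        df = pd.DataFrame({
            "sample_id": ["a"] * 3, "scan_kind": ["scan"] * 3,
            "scan_index": [0] * 3, "day": [1] * 3, "rep": [1] * 3,
            "sensor": ["VIS"] * 3,
            "wavelength_nm": [400.0, 399.0, 401.0],
            "intensity": [1.0, 2.0, 3.0], "saturated": [0] * 3,
        })
        df.to_csv(tmp_path / "bad.csv", index=False)
        (tmp_path / "bad.design.yaml").write_text("samples: []\n")
        with pytest.raises(SchemaError):
            read_dataset(tmp_path / "bad")

    def test_missing_column_is_schema_error(self, tmp_path):
        import pandas as pd
        pd.DataFrame({"sample_id": ["a"]}).to_csv(
            tmp_path / "bad.csv", index=False
        )
        (tmp_path / "bad.design.yaml").write_text("samples: []\n")
        with pytest.raises(SchemaError):
            read_dataset(tmp_path / "bad")


class TestInvariants:
    def test_spectrum_rejects_unsorted_grid(self):
        with pytest.raises(DataError):
            Spectrum(Sensor.VIS, np.array([2.0, 1.0]), np.array([0.0, 0.0]))

    def test_adulterated_sample_validation(self):
        with pytest.raises(DataError):
            es.OilSample("x", es.OilClass.RVOO, adulterated=True,
                         base_id="b", adulterant_id="a", fraction_v=0.1)
        with pytest.raises(DataError):
            es.OilSample("x", es.OilClass.EVOO, fraction_v=0.1)
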