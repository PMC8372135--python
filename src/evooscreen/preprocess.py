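"""Spectral preprocessing operators and the model-grid enumeration.

The screening grid crosses a small set of chemometric preprocessing
operators (standard normal variate, SNV + quadratic detrend, 1st/2nd
Savitzky-Golay derivatives with an 11-point window, and two discrete
wavelet feature extractors) with optional splitting of the spectrum into
four equal sections, and with five one-class algorithms.  Every operator
is a pure function of its input vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pywt
from scipy.signal import savgol_filter

from .errors import ConfigError, DataError, ZeroVarianceError

SG_WINDOW = 11
SG_POLY = 2          # minimal degree exact for both derivative orders
SG_EDGE = SG_WINDOW // 2
DWT_N_POINTS = 128

#: wavelet families: chemometric name -> (pywt wavelet, default detail levels)
DWT_FAMILIES = {
    "daubechies_len2": ("haar", (5, 6, 7)),
    "least_asymmetric_len8": ("sym4", (3, 4, 5)),
}


def snv(x: np.ndarray) -> np.ndarray:
    """Standard normal variate: centre and scale one spectrum to unit
    sample standard deviation (denominator n-1)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise DataError("snv expects a vector of length >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ZeroVarianceError("snv of a constant spectrum")
    return (x - x.mean()) / sd


def _quadratic_residual(y: np.ndarray, wavelengths: np.ndarray) -> np.ndarray:
    # centre/scale the wavelength axis before building the Vandermonde
    # matrix, otherwise nm^2 terms make the fit ill-conditioned
    t = (wavelengths - wavelengths.mean())
    span = np.abs(t).max()
    if span > 0:
        t = t / span
    A = np.column_stack([np.ones_like(t), t, t * t])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return y - A @ coef


def snv_detrend(x: np.ndarray, wavelengths: np.ndarray) -> np.ndarray:
    """SNV followed by removal of the least-squares quadratic baseline in
    wavelength; the output is orthogonal to {1, lambda, lambda^2}."""
    wavelengths = np.asarray(wavelengths, dtype=float)
    if wavelengths.size < 4:
        raise DataError("detrend needs at least 4 points")
    return _quadratic_residual(snv(x), wavelengths)


def sg_derivative(x: np.ndarray, deriv_order: int, delta: float = 1.0) -> np.ndarray:
    """Savitzky-Golay derivative, 11-point window, polynomial degree 2.

    The wavelength grid is assumed uniform with spacing ``delta``.  Edge
    points where the window does not fit are dropped rather than padded,
    so the output is 10 points shorter than the input.
    """
    if deriv_order not in (1, 2):
        raise ConfigError("derivative order must be 1 or 2")
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if n < SG_WINDOW:
        raise DataError(f"need at least {SG_WINDOW} points, got {n}")
    out = savgol_filter(
        x, SG_WINDOW, SG_POLY, deriv=deriv_order, delta=delta, axis=-1
    )
    return out[..., SG_EDGE:-SG_EDGE]


def dwt_features(
    x: np.ndarray,
    family: str = "daubechies_len2",
    levels: Sequence[int] | None = None,
) -> np.ndarray:
    """Wavelet detail coefficients of the spectrum.

    The spectrum is linearly interpolated onto 128 equally spaced points
    over its own range, decomposed with a periodic-boundary orthogonal
    DWT, and the detail coefficients of the requested levels are
    concatenated in ascending level order.  With 128 points, level j has
    128 / 2^j details: the Haar 5-7 set gives 4 + 2 + 1 = 7 features, the
    symlet-4 3-5 set gives 16 + 8 + 4 = 28.
    """
    if family not in DWT_FAMILIES:
        raise ConfigError(f"unknown wavelet family {family!r}")
    wavelet, default_levels = DWT_FAMILIES[family]
    levels = tuple(levels) if levels is not None else default_levels
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise DataError("dwt needs at least 2 points")
    grid = np.linspace(0.0, x.size - 1.0, DWT_N_POINTS)
    xi = np.interp(grid, np.arange(x.size), x)
    max_level = max(levels)
    with warnings.catch_warnings():
        # deep levels on 128 points trip pywt's boundary-effect warning;
        # with periodization the transform stays exactly orthogonal
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(xi, wavelet, mode="periodization", level=max_level)
    # wavedec returns [cA_L, cD_L, ..., cD_1]; detail of level j is coeffs[-j]
    return np.concatenate([coeffs[-j] for j in levels])


def split_spectrum(x: np.ndarray, section: int) -> np.ndarray:
    """Contiguous quarter ``section`` (1..4) of the vector; earlier
    sections receive the remainder points, and the four sections
    concatenate back to the input exactly."""
    if section not in (1, 2, 3, 4):
        raise ConfigError("section must be in 1..4")
    x = np.asarray(x)
    if x.shape[-1] < 4:
        raise DataError("cannot split fewer than 4 points")
    return np.array_split(x, 4, axis=-1)[section - 1]


_STEPS = ("none", "snv", "snv_detrend", "sg1", "sg2", "dwt_haar", "dwt_sym4")

_STEP_TO_DWT = {"dwt_haar": "daubechies_len2", "dwt_sym4": "least_asymmetric_len8"}


@dataclass(frozen=True)
class PreprocessSpec:
    """An ordered preprocessing chain plus an optional spectral section.

    When a split is present it is applied first and each section is
    preprocessed (and later modelled) independently.
    """

    steps: tuple[str, ...] = ("none",)
    split: int | None = None

    def __post_init__(self) -> None:
        for step in self.steps:
            if step not in _STEPS:
                raise ConfigError(f"unknown preprocessing step {step!r}")
        if self.split is not None and self.split not in (1, 2, 3, 4):
            raise ConfigError("split section must be in 1..4")

    @property
    def key(self) -> str:
        """Canonical string key, stable across runs, used in registries."""
        head = f"split{self.split}" if self.split else "full"
        return "|".join([head, *self.steps])

    @classmethod
    def from_key(cls, key: str) -> "PreprocessSpec":
        head, *steps = key.split("|")
        split = None if head == "full" else int(head.removeprefix("split"))
        return cls(tuple(steps), split)

    def output_length(self, n_points: int) -> int:
        """Feature dimension produced from an ``n_points`` spectrum."""
        if self.split is not None:
            sizes = [len(a) for a in np.array_split(np.arange(n_points), 4)]
            n = sizes[self.split - 1]
        else:
            n = n_points
        for step in self.steps:
            if step in ("sg1", "sg2"):
                n = n - 2 * SG_EDGE
            elif step in _STEP_TO_DWT:
                family = _STEP_TO_DWT[step]
                _, levels = DWT_FAMILIES[family]
                n = sum(DWT_N_POINTS // 2 ** j for j in levels)
        return n

    def apply(
        self, X: np.ndarray, wavelengths: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray | None]:
        """Transform a (rows x points) matrix; returns the feature matrix
        and the wavelength axis, or None once features are no longer
        wavelength-indexed (after a DWT)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        w: np.ndarray | None = np.asarray(wavelengths, dtype=float)
        if self.split is not None:
            cols = np.array_split(np.arange(X.shape[1]), 4)[self.split - 1]
            X = X[:, cols]
            w = w[cols]
        for step in self.steps:
            if step == "none":
                continue
            if step == "snv":
                X = np.apply_along_axis(snv, 1, X)
            elif step == "snv_detrend":
                if w is None:
                    raise ConfigError("detrend after dwt is undefined")
                X = np.apply_along_axis(lambda r: snv_detrend(r, w), 1, X)
            elif step in ("sg1", "sg2"):
                X = sg_derivative(X, 1 if step == "sg1" else 2)
                if w is not None:
                    w = w[SG_EDGE:-SG_EDGE]
            else:
                family = _STEP_TO_DWT[step]
                X = np.vstack([dwt_features(row, family) for row in X])
                w = None
        return X, w


def enumerate_model_grid(
    preprocessings: Sequence[Sequence[str] | str],
    algorithms: Sequence[str],
    splits: Sequence[int | None] = (None, 1, 2, 3, 4),
) -> list[tuple[PreprocessSpec, str]]:
    """Cartesian enumeration of (preprocessing, split-or-full, algorithm)
    combinations, deduplicated, in deterministic order."""
    specs: dict[tuple[str, str], tuple[PreprocessSpec, str]] = {}
    for pp in preprocessings:
        steps = (pp,) if isinstance(pp, str) else tuple(pp)
        for split in splits:
            pspec = PreprocessSpec(steps, split)
            for algo in algorithms:
                specs[(pspec.key, algo)] = (pspec, algo)
    if not specs:
        raise ConfigError("empty model grid")
    return [specs[k] for k in sorted(specs)]


DEFAULT_PREPROCESSINGS = ("snv", "snv_detrend", "sg1", "sg2",
                          "dwt_haar", "dwt_sym4")


__all__ = [
    "snv", "snv_detrend", "sg_derivative", "dwt_features", "split_spectrum",
    "PreprocessSpec", "enumerate_model_grid", "DEFAULT_PREPROCESSINGS",
    "DWT_FAMILIES", "SG_WINDOW", "SG_POLY",
]
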