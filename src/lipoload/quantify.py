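"""Measurement-side arithmetic: standard curves, spectra, retention.

Fluorescence quantification of encapsulated drug runs through a linear
standard curve (signal = slope * concentration + intercept) with inverse
prediction; co-loading of two dyes is confirmed by detecting two distinct
peaks in the emission spectrum; maleimide-lipid retention and the release
assay's sink condition are simple ratios, kept here so every number the
protocol prints has one named home.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "StandardCurve",
    "Spectrum",
    "fit_standard_curve",
    "invert_concentration",
    "detect_peaks",
    "maleimide_retention",
    "sink_ratio",
    "meets_sink_condition",
]


@dataclass(frozen=True)
class StandardCurve:
    """Linear calibration: signal = slope * concentration_mM + intercept."""

    slope: float
    intercept: float
    fit_quality: float  # coefficient of determination R^2

    def predict(self, concentration_mM: np.ndarray | float) -> np.ndarray | float:
        return self.slope * np.asarray(concentration_mM, dtype=float) + self.intercept


@dataclass(frozen=True)
class Spectrum:
    """An emission spectrum: intensities on a strictly ascending nm grid."""

    wavelengths_nm: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, dtype=float)
        i = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "intensities", i)
        if w.ndim != 1 or i.shape != w.shape:
            raise ValueError("wavelengths and intensities must be 1-D, equal length")
        if w.size == 0:
            raise ValueError("spectrum is empty")
        if np.any(np.diff(w) <= 0.0):
            raise ValueError("wavelengths must be strictly ascending")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"wavelength_nm": self.wavelengths_nm, "intensity": self.intensities}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Spectrum":
        df = pd.read_csv(path)
        missing = {"wavelength_nm", "intensity"} - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
        return cls(df["wavelength_nm"].to_numpy(), df["intensity"].to_numpy())


def fit_standard_curve(
    concentrations_mM: Sequence[float], signals: Sequence[float]
) -> StandardCurve:
    """Ordinary least-squares line through calibration points.

    Needs at least two points at two distinct concentrations (two points
    give exact interpolation).  The coefficient of determination is
    reported as ``fit_quality``.
    """
    x = np.asarray(concentrations_mM, dtype=float)
    y = np.asarray(signals, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("concentrations and signals must be 1-D, equal length")
    if x.size < 2:
        raise ValueError("need at least 2 calibration points")
    if np.unique(x).size < 2:
        raise ValueError(
            "degenerate calibration design: all concentrations are equal"
        )
    res = stats.linregress(x, y)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        fit_quality=float(res.rvalue**2),
    )


def invert_concentration(sc: StandardCurve, signal_value: float) -> float:
    """Inverse prediction: concentration (mM) = (signal - intercept) / slope.

    A negative result means the signal fell below the blank; it is returned
    as-is (the caller decides whether to clip) with a warning.
    """
    if sc.slope == 0.0:
        raise ValueError("standard curve has zero slope and cannot be inverted")
    c = (signal_value - sc.intercept) / sc.slope
    if c < 0.0:
        import warnings

        warnings.warn(
            f"signal {signal_value} below blank: inverse prediction {c:.3g} mM "
            "is negative",
            stacklevel=2,
        )
    return c


def detect_peaks(
    sp: Spectrum,
    min_separation_nm: float = 30.0,
    min_prominence: float = 0.10,
) -> np.ndarray:
    """Emission peak wavelengths (nm), ascending.

    Local maxima whose prominence exceeds ``min_prominence`` of the
    spectrum's dynamic range (max - min; this keeps the detector invariant
    to constant baseline offsets) and that sit at least
    ``min_separation_nm`` apart.  To keep noisy, flat-topped fluorophore
    bands from jittering on the sampling grid, the spectrum is lightly
    smoothed (Savitzky-Golay, quadratic) before maxima are located, and
    each peak position is refined to the vertex of a local parabola.
    Deterministic; defaults suit two fluorophores ~100 nm apart.
    """
    n = sp.wavelengths_nm.size
    if n < 5:
        raise ValueError("need at least 5 samples to detect peaks")
    if float(np.ptp(sp.intensities)) == 0.0:
        return np.empty(0)
    w = sp.wavelengths_nm
    step = float(np.median(np.diff(w)))
    # smoothing window ~ 1/3 of the separation scale, odd, within [5, n]
    window = int(round(min_separation_nm / (3.0 * step)))
    window = min(max(window | 1, 5), n if n % 2 else n - 1)
    smoothed = signal.savgol_filter(sp.intensities, window, 2)
    span = float(np.ptp(smoothed))
    if span == 0.0:
        return np.empty(0)
    distance = max(int(np.ceil(min_separation_nm / step)), 1)
    idx, _ = signal.find_peaks(
        smoothed, prominence=min_prominence * span, distance=distance
    )
    half = max(int(round(min_separation_nm / (4.0 * step))), 2)
    peaks = []
    for i in idx:
        lo, hi = max(i - half, 0), min(i + half + 1, n)
        a, b, _ = np.polyfit(w[lo:hi], smoothed[lo:hi], 2)
        vertex = -b / (2.0 * a) if a < 0.0 else w[i]
        peaks.append(vertex if w[lo] <= vertex <= w[hi - 1] else w[i])
    return np.asarray(peaks)


def maleimide_retention(measured_ratio: float, nominal_ratio: float) -> float:
    """Percent of functionalized lipid retained: 100 * measured / nominal.

    Ratios are mole ratios of maleimide-lipid to bulk lipid before and
    after the insertion/wash protocol.
    """
    if nominal_ratio <= 0.0:
        raise ValueError(f"nominal_ratio must be > 0, got {nominal_ratio}")
    if measured_ratio < 0.0:
        raise ValueError(f"measured_ratio must be >= 0, got {measured_ratio}")
    return 100.0 * measured_ratio / nominal_ratio


def sink_ratio(solubility_mg_per_mL: float, assay_concentration_mg_per_mL: float) -> float:
    """Solubility-to-assay-concentration ratio for a release experiment."""
    if assay_concentration_mg_per_mL <= 0.0:
        raise ValueError("assay concentration must be > 0")
    if solubility_mg_per_mL <= 0.0:
        raise ValueError("solubility must be > 0")
    return solubility_mg_per_mL / assay_concentration_mg_per_mL


def meets_sink_condition(
    solubility_mg_per_mL: float,
    assay_concentration_mg_per_mL: float,
    min_ratio: float = 10.0,
) -> bool:
    """Whether the assay dilution keeps released drug far below solubility.

    The conventional requirement is an assay concentration 5-10x below
    solubility; ``min_ratio`` defaults to the conservative end.
    """
    return sink_ratio(solubility_mg_per_mL, assay_concentration_mg_per_mL) >= min_ratio
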