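"""Bulk assay quantitation: hemolysis, HbA1c drift, and flow-injection ATP.

Hemolysis
    Free hemoglobin is read at 540 nm after Drabkin conversion, calibrated
    against standards between 0 and 1 mg/mL, dilution-corrected (supernatant
    ×10, packed-cell pellet ×1000), and converted to a lysis percentage by

        Lysis% = 100 · [Hb_sup]·(1 − HCT) / ([Hb_sup] + [Hb_pellet]).

    The formula is applied exactly in this form.  Note that its denominator
    adds a supernatant-phase and a pellet-phase concentration, so it is not a
    strict mass balance; with HCT as a fraction in (0, 1) the result is
    bounded by 100·(1 − HCT), which keeps it inside [0, 100).

ATP
    Flow-injection chemiluminescence peaks are Savitzky–Golay smoothed
    (window = 0.5 % of the trace length), peak heights measured above a local
    pre-injection baseline, and the endogenous concentration obtained by the
    method of standard addition (x-intercept magnitude of height vs spiked
    concentration), which cancels matrix effects of the red-cell suspension.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter
from scipy.stats import linregress

from .synthetic.chemi import ChemiTrace
from .synthetic.hemolysis import AbsorbanceSet

__all__ = [
    "HbCalibration",
    "HemolysisSample",
    "StdAdditionSeries",
    "StdAdditionResult",
    "fit_hb_calibration",
    "percent_lysis",
    "hemolysis_from_absorbances",
    "delta_hba1c",
    "smooth_trace",
    "measure_peak_heights",
    "standard_addition_quantify",
]

#: seconds of signal before each injection used as the local baseline
BASELINE_WINDOW_S = 5.0


@dataclass(frozen=True)
class HbCalibration:
    """Linear 540 nm absorbance response to hemoglobin concentration."""

    slope: float  # absorbance per mg/mL
    intercept: float
    r2: float
    n_standards: int

    def concentration(self, absorbance: float, dilution: float = 1.0) -> float:
        """Invert the calibration; ``dilution`` undoes a pre-read dilution."""
        return (absorbance - self.intercept) / self.slope * dilution


@dataclass(frozen=True)
class HemolysisSample:
    """Dilution-corrected hemoglobin concentrations and hematocrit."""

    hb_supernatant: float  # mg/mL
    hb_pellet: float  # mg/mL
    hct: float  # fraction in (0, 1)

    def __post_init__(self) -> None:
        if self.hb_supernatant < 0 or self.hb_pellet < 0:
            raise ValueError("hemoglobin concentrations must be >= 0")
        if not (0.0 < self.hct < 1.0):
            raise ValueError("hct must be a fraction in (0, 1)")


def fit_hb_calibration(standards: Sequence[tuple[float, float]]) -> HbCalibration:
    """OLS fit of absorbance against standard concentration (mg/mL).

    Raises
    ------
    ValueError
        With fewer than two standards or all-identical concentrations.
    """
    conc = np.array([c for c, _ in standards], dtype=float)
    ab = np.array([a for _, a in standards], dtype=float)
    if conc.size < 2 or np.ptp(conc) == 0:
        raise ValueError("need >= 2 standards at distinct concentrations")
    fit = linregress(conc, ab)
    return HbCalibration(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        n_standards=int(conc.size),
    )


def percent_lysis(sample: HemolysisSample) -> float:
    """Lysis percentage from dilution-corrected hemoglobin concentrations."""
    denom = sample.hb_supernatant + sample.hb_pellet
    if denom <= 0:
        raise ValueError("supernatant and pellet hemoglobin are both zero")
    return 100.0 * sample.hb_supernatant * (1.0 - sample.hct) / denom


def hemolysis_from_absorbances(aset: AbsorbanceSet) -> float:
    """Full assay: calibration fit → dilution correction → lysis percentage."""
    cal = fit_hb_calibration(list(zip(aset.standards_mg_ml, aset.standards_abs)))
    hb_sup = cal.concentration(aset.abs_supernatant, aset.supernatant_dilution)
    hb_pel = cal.concentration(aset.abs_pellet, aset.pellet_dilution)
    return percent_lysis(
        HemolysisSample(hb_supernatant=max(hb_sup, 0.0),
                        hb_pellet=max(hb_pel, 0.0), hct=aset.hct)
    )


def delta_hba1c(series: Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
    """Change in glycated hemoglobin relative to the day-1 baseline.

    Raises
    ------
    ValueError
        If the series has no day-1 entry.
    """
    baseline = [v for d, v in series if d == 1]
    if not baseline:
        raise ValueError("series is missing the day-1 baseline")
    return [(d, v - baseline[0]) for d, v in series]


def smooth_trace(
    trace: ChemiTrace, window_fraction: float = 0.005, poly_order: int = 2
) -> ChemiTrace:
    """Savitzky–Golay smoothing with window = ``window_fraction`` of the trace.

    The window is forced odd and at least ``poly_order + 2`` samples, wide
    enough for the fit to be overdetermined.

    Raises
    ------
    ValueError
        If the trace is shorter than the minimum window.
    """
    n = trace.signal.size
    window = int(round(window_fraction * n))
    window = max(window, poly_order + 2)
    if window % 2 == 0:
        window += 1
    if n < window:
        raise ValueError(f"trace of {n} samples is shorter than window {window}")
    smoothed = savgol_filter(trace.signal, window_length=window, polyorder=poly_order)
    return ChemiTrace(
        time_s=trace.time_s, signal=smoothed,
        injection_times_s=trace.injection_times_s,
    )


def measure_peak_heights(
    trace: ChemiTrace,
    injection_times_s: Sequence[float] | None = None,
    search_window_s: float = 45.0,
) -> np.ndarray:
    """Baseline-subtracted peak height after each injection.

    Height = max(signal) within ``search_window_s`` after the injection minus
    the median signal over the 5 s before it.

    Raises
    ------
    ValueError
        If any injection's search window leaves the recorded trace.
    """
    if injection_times_s is None:
        injection_times_s = trace.injection_times_s
    t = trace.time_s
    heights = []
    for t0 in np.asarray(injection_times_s, dtype=float):
        if t0 < t[0] or t0 + search_window_s > t[-1]:
            raise ValueError(
                f"injection at {t0} s has its search window outside the trace"
            )
        pre = trace.signal[(t >= t0 - BASELINE_WINDOW_S) & (t < t0)]
        baseline = float(np.median(pre)) if pre.size else 0.0
        post = trace.signal[(t >= t0) & (t <= t0 + search_window_s)]
        heights.append(float(post.max()) - baseline)
    return np.array(heights)


@dataclass(frozen=True)
class StdAdditionSeries:
    """Spiked concentration vs replicate-averaged peak height."""

    added_nm: np.ndarray
    peak_heights: np.ndarray
    replicates: int = 3

    def __post_init__(self) -> None:
        added = np.asarray(self.added_nm, dtype=float)
        heights = np.asarray(self.peak_heights, dtype=float)
        if added.shape != heights.shape:
            raise ValueError("added_nm and peak_heights lengths differ")
        if not np.any(added == 0):
            raise ValueError("series must include an unspiked (0 nM) level")
        object.__setattr__(self, "added_nm", added)
        object.__setattr__(self, "peak_heights", heights)


@dataclass(frozen=True)
class StdAdditionResult:
    """Standard-addition outcome on both concentration bases."""

    endogenous_injected_nm: float  # in the injected (diluted) sample
    endogenous_reported_nm: float  # scaled by dilution_factor
    dilution_factor: float
    slope: float
    intercept: float
    r2: float


def standard_addition_quantify(
    series: StdAdditionSeries, dilution_factor: float = 1.0
) -> StdAdditionResult:
    """Endogenous concentration from the x-intercept of height vs spike.

    OLS of peak height against added concentration; the endogenous
    concentration in the injected sample is intercept/slope (the magnitude of
    the negative x-intercept).  ``dilution_factor`` scales the result back to
    a reference basis — e.g. the storage-suspension hematocrit when injections
    were made at a diluted 7 % hematocrit.

    Raises
    ------
    ValueError
        With fewer than 3 levels or a non-positive fitted slope.
    """
    if series.added_nm.size < 3:
        raise ValueError("standard addition needs >= 3 spike levels")
    fit = linregress(series.added_nm, series.peak_heights)
    if not (fit.slope > 0):
        raise ValueError("fitted response slope must be positive")
    endo = float(fit.intercept / fit.slope)
    return StdAdditionResult(
        endogenous_injected_nm=endo,
        endogenous_reported_nm=endo * dilution_factor,
        dilution_factor=dilution_factor,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
    )
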