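"""Concentration-response (Hill/IC50) fitting and AGE-fluorescence normalization.

Two small quantitative models used around the QSAR core:

* a four-parameter logistic (Hill) fit of percent-response versus
  concentration on a log10 axis, yielding IC50 (or CC50) with standard
  errors, and a three-parameter fallback (bottom fixed at 0) for
  under-determined data;
* the normalization used in the protein-glycation assay, where sample
  fluorescence ``A`` (glycated, glucose-containing) is referenced to the mean
  glucose-free blank ``B`` as ``Flu = 10**(log10 A - log10 B) - 1``
  (algebraically ``A/B - 1``), and activity percent is
  ``(1 - Flu_sample / Flu_control) * 100``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "DoseResponse", "HillFit", "fit_hill", "age_flu", "age_activity_percent",
    "AssayError",
]


class AssayError(ValueError):
    """Invalid assay data or a fit that cannot be performed."""


@dataclass
class HillFit:
    bottom: float
    top: float
    ic50: float
    hill_slope: float
    se: dict[str, float]
    n_params: int
    converged: bool = True
    ic50_in_range: bool = True

    def predict(self, conc: np.ndarray) -> np.ndarray:
        return _logistic4(np.log10(np.asarray(conc, dtype=float)),
                          self.bottom, self.top, math.log10(self.ic50), self.hill_slope)


@dataclass
class DoseResponse:
    """Concentrations (same unit throughout, > 0) and responses (percent)."""

    concentrations: np.ndarray
    responses: np.ndarray
    fit: Optional[HillFit] = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise AssayError("concentrations and responses must align")
        if np.any(self.concentrations <= 0):
            raise AssayError("concentrations must be positive")


def _logistic4(logc: np.ndarray, bottom: float, top: float,
               logic50: float, slope: float) -> np.ndarray:
    """Decreasing-in-concentration form: y -> top at low conc for slope > 0."""
    return bottom + (top - bottom) / (1.0 + 10.0 ** (slope * (logc - logic50)))


def fit_hill(
    dr: DoseResponse,
    top_max: Optional[float] = 100.0,
    bottom_fixed: Optional[float] = None,
) -> HillFit:
    """Least-squares logistic fit on the log10 concentration axis.

    Fits (bottom, top, log10 IC50, Hill slope); responses are percentages of
    control, so ``top`` is bounded above by ``top_max`` (pass None to lift
    the constraint).  With fewer than five points, or when ``bottom_fixed``
    is given, a three-parameter fit with fixed bottom is used.  The slope is
    free in sign, so both decreasing and rising curves are handled; IC50 is
    the midpoint either way.  The returned fit flags whether the IC50 lies
    inside the tested concentration range.
    """
    c = dr.concentrations
    y = dr.responses
    distinct = np.unique(c)
    if len(distinct) < 4:
        raise AssayError(f"need >= 4 distinct concentrations, got {len(distinct)}")
    if np.allclose(y, y[0]):
        raise AssayError("responses show no dose dependence")
    logc = np.log10(c)

    top0 = float(np.max(y))
    bot0 = float(np.min(y))
    mid0 = float(np.median(logc))
    top_hi = np.inf if top_max is None else top_max
    top0 = min(top0, top_hi)

    three_param = bottom_fixed is not None or len(distinct) < 5
    if three_param:
        b0 = 0.0 if bottom_fixed is None else float(bottom_fixed)

        def f3(lc, top, logic50, slope):
            return _logistic4(lc, b0, top, logic50, slope)

        p0 = [top0, mid0, 1.0]
        bounds = ([-np.inf, logc.min() - 3, -20], [top_hi, logc.max() + 3, 20])
        try:
            popt, pcov = curve_fit(f3, logc, y, p0=p0, bounds=bounds, maxfev=20000)
        except (RuntimeError, ValueError) as exc:
            raise AssayError(f"Hill fit did not converge: {exc}") from exc
        perr = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
        fit = HillFit(
            bottom=b0, top=float(popt[0]), ic50=float(10 ** popt[1]),
            hill_slope=float(popt[2]),
            se={"top": float(perr[0]), "log_ic50": float(perr[1]),
                "hill_slope": float(perr[2])},
            n_params=3,
        )
    else:
        p0 = [bot0, top0, mid0, 1.0]
        bounds = ([-np.inf, -np.inf, logc.min() - 3, -20],
                  [np.inf, top_hi, logc.max() + 3, 20])
        try:
            popt, pcov = curve_fit(_logistic4, logc, y, p0=p0, bounds=bounds, maxfev=20000)
        except (RuntimeError, ValueError) as exc:
            raise AssayError(f"Hill fit did not converge: {exc}") from exc
        perr = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
        fit = HillFit(
            bottom=float(popt[0]), top=float(popt[1]), ic50=float(10 ** popt[2]),
            hill_slope=float(popt[3]),
            se={"bottom": float(perr[0]), "top": float(perr[1]),
                "log_ic50": float(perr[2]), "hill_slope": float(perr[3])},
            n_params=4,
        )
    fit.ic50_in_range = bool(c.min() <= fit.ic50 <= c.max())
    dr.fit = fit
    return fit


def age_flu(A: float, B: float) -> float:
    """AGE fluorescence coefficient ``10**(log10 A - log10 B) - 1``.

    ``A`` is the absolute fluorescence of the glucose-containing sample, ``B``
    the mean fluorescence of the matched glucose-free blank.  Both must be
    positive (fluorescence counts).
    """
    if A <= 0 or B <= 0:
        raise AssayError("fluorescence values must be positive")
    return float(10.0 ** (math.log10(A) - math.log10(B)) - 1.0)


def age_activity_percent(flu_sample: float, flu_control: float) -> float:
    """Antiglycation activity percent ``(1 - Flu(sample)/Flu(control)) * 100``."""
    if flu_control == 0:
        raise AssayError("control Flu coefficient must be nonzero")
    return float((1.0 - flu_sample / flu_control) * 100.0)
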