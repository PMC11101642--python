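"""Electrophoretic mobility of DTD species from microfluidic migration times.

An analyte and the neutral marker rhodamine B co-migrate down a
microchannel under constant current; their fluorescence peaks pass an
observation point at times ``t_analyte`` and ``t_RB``. The analyte
mobility is

    mu = (A L) / (rho I) * (1 / t_analyte - 1 / t_RB)

with channel cross-section ``A`` (m^2), observation distance ``L`` (m),
buffer resistivity ``rho`` (Ohm m) and channel current ``I`` (A). The
neutral-marker term subtracts electroosmotic flow. Peak times come from
a least-squares Gaussian fit to the intensity trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "MigrationRun",
    "PeakFit",
    "PeakFitError",
    "fit_peak_time",
    "mobility_from_times",
]

#: HEPES/sucrose running buffer at pH 7.0
DEFAULT_RESISTIVITY_OHM_M = 35.1
#: standard observation point; 20 mm is used for the largest (150 kDa) DTD
DEFAULT_OBSERVATION_DISTANCE_M = 5e-3


class PeakFitError(RuntimeError):
    """Gaussian peak localization failed (no peak, boundary peak, no convergence)."""


@dataclass(frozen=True)
class MigrationRun:
    """Geometry and electrical metadata of one separation run."""

    channel_area: float  # m^2
    current: float  # A
    observation_distance: float = DEFAULT_OBSERVATION_DISTANCE_M  # m
    buffer_resistivity: float = DEFAULT_RESISTIVITY_OHM_M  # Ohm m

    def __post_init__(self) -> None:
        for name in ("channel_area", "current", "observation_distance", "buffer_resistivity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class PeakFit:
    """Result of a Gaussian peak fit: mean, width, amplitude, baseline, residual."""

    peak_time: float  # s
    width: float  # s
    amplitude: float
    baseline: float
    residual_norm: float


def _gaussian(t, amplitude, t0, width, baseline):
    return amplitude * np.exp(-((t - t0) ** 2) / (2.0 * width**2)) + baseline


def fit_peak_time(time, intensity) -> PeakFit:
    """Locate the migration-time peak of a fluorescence trace.

    Fits ``a exp(-(t-t0)^2 / 2w^2) + b`` by nonlinear least squares and
    returns the Gaussian mean. A flat trace, a non-converging fit or a
    peak pinned to the trace boundary raises :class:`PeakFitError`.
    """
    t = np.asarray(time, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if t.ndim != 1 or t.size < 5 or t.shape != y.shape:
        raise ValueError("trace must be 1-D with >= 5 samples and matching lengths")
    if np.any(np.diff(t) <= 0):
        raise ValueError("trace time axis must be strictly increasing")

    span = float(np.ptp(y))
    if span <= 0 or not np.isfinite(span):
        raise PeakFitError("flat or invalid trace: no peak to fit")

    i0 = int(np.argmax(y))
    baseline0 = float(np.min(y))
    amp0 = float(y[i0] - baseline0)
    width0 = max((t[-1] - t[0]) / 20.0, float(np.mean(np.diff(t))))
    try:
        popt, _ = curve_fit(
            _gaussian,
            t,
            y,
            p0=[amp0, t[i0], width0, baseline0],
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise PeakFitError(f"Gaussian fit did not converge: {exc}") from exc
    amplitude, t0, width, baseline = popt
    width = abs(float(width))
    if not (t[0] < t0 < t[-1]):
        raise PeakFitError(f"fitted peak time {t0:.4g} s lies outside the trace")
    if amplitude <= 0 or amplitude < 0.05 * span:
        raise PeakFitError("no dominant peak above baseline")
    resid = y - _gaussian(t, *popt)
    return PeakFit(
        peak_time=float(t0),
        width=width,
        amplitude=float(amplitude),
        baseline=float(baseline),
        residual_norm=float(np.linalg.norm(resid)),
    )


def mobility_from_times(t_analyte: float, t_rb: float, run: MigrationRun) -> float:
    """Electrophoretic mobility in m^2/(V s) from two migration times.

    ``(A L)/(rho I) (1/t_analyte - 1/t_RB)``; the sign gives the
    migration direction relative to the neutral rhodamine B marker, and
    co-migration gives exactly zero.
    """
    if t_analyte <= 0 or t_rb <= 0:
        raise ValueError(f"migration times must be > 0, got {t_analyte} and {t_rb}")
    prefactor = (run.channel_area * run.observation_distance) / (
        run.buffer_resistivity * run.current
    )
    return prefactor * (1.0 / t_analyte - 1.0 / t_rb)
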