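"""AFM force–indentation curves with a surface-tension-corrected cone model.

A conical tip of half angle ``phi`` indenting a cell obeys the Sneddon
relation ``P = (2/pi) E* d^2 tan(phi)`` at depths where the elastic
response dominates. A tensed surface adds a correction that is largest
at shallow indentation:

    P(d) = (2/pi) E* d^2 tan(phi) [ 1 + alpha_c ( (2 sigma / E*) / (d tan(phi)) )^beta_c ]

with apparent elastic modulus ``E*`` (Pa), surface tension ``sigma``
(pN/um = mN/m), and dimensionless shape constants ``alpha_c = 0.88``
and ``beta_c = 0.87`` for a symmetric cone of 45 degree half angle.
Fitting a measured curve over (E*, sigma) with the shape constants
fixed yields a per-curve tension estimate; repeated indentations of one
cell are summarized as mean +/- SE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "ForceCurve",
    "IndentationFit",
    "ForceFitError",
    "force_model",
    "fit_force_curve",
    "fit_curves",
    "aggregate_per_cell",
    "ALPHA_C",
    "BETA_C",
    "HALF_ANGLE",
]

ALPHA_C = 0.88
BETA_C = 0.87
HALF_ANGLE = np.pi / 4  # 45 degree conical tip

#: pN/um == mN/m == 1e-6 N/m
_TENSION_TO_N_PER_M = 1e-6
_NM_TO_M = 1e-9
_N_TO_PN = 1e12


class ForceFitError(RuntimeError):
    """All fit starts failed for a force curve."""


@dataclass(frozen=True)
class ForceCurve:
    """One indentation: depth (nm, strictly increasing) vs force (pN)."""

    depth_nm: np.ndarray
    force_pn: np.ndarray
    spring_constant: float | None = None  # N/m, metadata only
    cell_id: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.depth_nm, dtype=float)
        p = np.asarray(self.force_pn, dtype=float)
        if d.ndim != 1 or d.size < 10 or d.shape != p.shape:
            raise ValueError("force curve needs >= 10 matched (depth, force) samples")
        if np.any(d < 0) or np.any(np.diff(d) <= 0):
            raise ValueError("depth must be non-negative and strictly increasing")
        object.__setattr__(self, "depth_nm", d)
        object.__setattr__(self, "force_pn", p)


@dataclass(frozen=True)
class IndentationFit:
    apparent_modulus: float  # Pa
    surface_tension: float  # pN/um
    half_angle: float  # rad
    alpha_c: float
    beta_c: float
    residual_rms: float  # pN
    cell_id: str = ""


def force_model(
    depth_nm,
    apparent_modulus: float,
    surface_tension: float,
    half_angle: float = HALF_ANGLE,
    alpha_c: float = ALPHA_C,
    beta_c: float = BETA_C,
):
    """Force (pN) at indent depth (nm) for given modulus (Pa) and tension (pN/um).

    Reduces to the conical Sneddon form when ``surface_tension`` is 0;
    ``d = 0`` returns 0 by continuity. Homogeneous of degree 1 in
    (E*, sigma) jointly.
    """
    if apparent_modulus <= 0:
        raise ValueError(f"apparent modulus must be > 0 Pa, got {apparent_modulus}")
    if surface_tension < 0:
        raise ValueError(f"surface tension must be >= 0, got {surface_tension}")
    d = np.asarray(depth_nm, dtype=float) * _NM_TO_M
    tan_phi = np.tan(half_angle)
    sigma_si = surface_tension * _TENSION_TO_N_PER_M
    sneddon = (2.0 / np.pi) * apparent_modulus * d**2 * tan_phi
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d > 0, (2.0 * sigma_si / apparent_modulus) / (d * tan_phi), 0.0)
    correction = 1.0 + alpha_c * ratio**beta_c
    out = np.where(d > 0, sneddon * correction, 0.0) * _N_TO_PN
    return out if out.ndim else float(out)


def _initial_guesses(curve: ForceCurve, tan_phi: float) -> tuple[float, float]:
    """E*0 from the terminal P/d^2 slope, sigma0 from the small-depth excess."""
    d = curve.depth_nm * _NM_TO_M
    p = curve.force_pn / _N_TO_PN
    n_tail = max(3, len(d) // 4)
    ratio_tail = p[-n_tail:] / (d[-n_tail:] ** 2)
    e0 = float(np.median(ratio_tail)) * np.pi / (2.0 * tan_phi)
    e0 = max(e0, 1e-3)
    n_head = max(3, len(d) // 4)
    sneddon_head = (2.0 / np.pi) * e0 * d[:n_head] ** 2 * tan_phi
    with np.errstate(divide="ignore", invalid="ignore"):
        excess = np.median(np.maximum(p[:n_head] / np.maximum(sneddon_head, 1e-300) - 1.0, 0.0))
    # invert 1 + alpha (2 sigma/E* / (d tan))^beta ~ 1 + excess at median head depth
    d_head = float(np.median(d[:n_head]))
    if excess > 0:
        sigma0_si = 0.5 * e0 * d_head * tan_phi * (excess / ALPHA_C) ** (1.0 / BETA_C)
    else:
        sigma0_si = 1e-5 * e0 * d_head
    sigma0 = max(sigma0_si / _TENSION_TO_N_PER_M, 1e-3)
    return e0, sigma0


def fit_force_curve(
    curve: ForceCurve,
    half_angle: float = HALF_ANGLE,
    alpha_c: float = ALPHA_C,
    beta_c: float = BETA_C,
    n_starts: int = 5,
) -> IndentationFit:
    """Least-squares fit of (E*, sigma) to one force curve.

    Positivity is enforced by fitting in log space. ``n_starts``
    multi-start points spread around data-derived initial guesses; the
    best-residual solution is returned. Raises :class:`ForceFitError`
    if every start fails.
    """
    tan_phi = np.tan(half_angle)
    e0, sigma0 = _initial_guesses(curve, tan_phi)
    d, p = curve.depth_nm, curve.force_pn

    def residuals(theta):
        e_star, sigma = np.exp(np.clip(theta, -60.0, 60.0))
        return force_model(d, e_star, sigma, half_angle, alpha_c, beta_c) - p

    # spread starts over modulus x tension factors around the data-derived guess
    factors = [(1.0, 1.0), (1.0, 0.1), (1.0, 10.0), (0.3, 1.0), (3.0, 1.0), (1.0, 100.0), (0.1, 1.0)]
    best = None
    failures = []
    for fe, fs in factors[: max(n_starts, 1)]:
        theta0 = np.log([e0 * fe, sigma0 * fs])
        try:
            sol = least_squares(residuals, theta0, method="lm", max_nfev=5000)
        except Exception as exc:  # pragma: no cover - scipy internal failure
            failures.append((theta0, str(exc)))
            continue
        if not np.all(np.isfinite(sol.x)):
            failures.append((theta0, "non-finite solution"))
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise ForceFitError(f"all fit starts failed: {failures}")
    e_star, sigma = np.exp(best.x)
    rms = float(np.sqrt(np.mean((residuals(best.x)) ** 2)))
    return IndentationFit(
        apparent_modulus=float(e_star),
        surface_tension=float(sigma),
        half_angle=half_angle,
        alpha_c=alpha_c,
        beta_c=beta_c,
        residual_rms=rms,
        cell_id=curve.cell_id,
    )


def fit_curves(curves, **kwargs) -> pd.DataFrame:
    """Fit a batch of curves; one row per curve."""
    rows = []
    for i, curve in enumerate(curves):
        fit = fit_force_curve(curve, **kwargs)
        rows.append(
            {
                "curve": i,
                "cell_id": fit.cell_id,
                "apparent_modulus_pa": fit.apparent_modulus,
                "surface_tension_pn_um": fit.surface_tension,
                "residual_rms_pn": fit.residual_rms,
            }
        )
    return pd.DataFrame(rows)


def aggregate_per_cell(fits: pd.DataFrame) -> pd.DataFrame:
    """Per-cell mean +/- SE of repeated indentation fits."""
    grouped = fits.groupby("cell_id")["surface_tension_pn_um"]
    out = grouped.agg(["mean", "count"])
    out["se"] = grouped.sem(ddof=1)
    return out.rename(columns={"mean": "surface_tension_mean", "count": "n_curves"})
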