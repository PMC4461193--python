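"""Mass and resolution calibration.

Per calibration window, the core parameters (sigma, m0) are found by a
Nelder-Mead simplex over the window's mean squared deviation, where each
objective evaluation re-fits the species abundances by NNLS (a nested
linear/nonlinear split: the abundances are linear and solved exactly at
every simplex step, so the simplex searches only two parameters).  The
per-window optima are then joined into sigma(m) and m0(m) calibration
curves by monotone piecewise-cubic (PCHIP) interpolation with constant
extrapolation beyond the outermost windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.optimize
from scipy.interpolate import PchipInterpolator

from . import isotopes
from .isotopes import Formula, IsotopePattern, PruneConfig
from .spectra import CalibrationCurves, Spectrum, build_design_matrix

__all__ = ["CalibrationPoint", "CalibrationError", "calibrate_window", "build_curves"]


@dataclass(frozen=True)
class CalibrationPoint:
    """Optimal core parameters for one calibration window."""

    m_ref: float   # window centre, Th
    sigma: float
    m0: float
    mse: float     # mean squared deviation at the optimum

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.mse < 0:
            raise ValueError("mse must be >= 0")


class CalibrationError(RuntimeError):
    """Non-convergence; carries the best point found so far."""

    def __init__(self, message: str, best: CalibrationPoint):
        super().__init__(message)
        self.best = best


def _as_pattern(sp, cfg: PruneConfig) -> IsotopePattern:
    if isinstance(sp, IsotopePattern):
        return sp
    if isinstance(sp, str):
        sp = isotopes.parse_formula(sp)
    if isinstance(sp, Formula):
        return isotopes.species_pattern(sp, cfg)
    raise TypeError(f"cannot interpret {sp!r} as a species")


def calibrate_window(s: Spectrum, species_in_window: Sequence,
                     init: tuple[float, float],
                     cfg: PruneConfig = PruneConfig(),
                     template=None,
                     max_iter: int = 500,
                     xatol: float = 1e-6, fatol: float = 1e-8) -> CalibrationPoint:
    """Fit (sigma, m0) on one window by simplex with inner NNLS refits.

    ``species_in_window`` lists the species present (formula strings,
    Formula objects or precomputed patterns); ``init`` is (sigma0, m0_0),
    sigma0 typically from a nominal resolution.  Deterministic for fixed
    init and tolerances.
    """
    patterns = [_as_pattern(sp, cfg) for sp in species_in_window]
    if not patterns:
        raise ValueError("window contains no species")
    if s.mass.size < len(patterns) + 10:
        raise ValueError("window too small: need >= 10 grid points more than species")
    sigma0, m00 = init
    if sigma0 <= 0:
        raise ValueError("initial sigma must be > 0")

    def objective(theta: np.ndarray) -> float:
        sigma, m0 = theta
        if sigma <= 0:
            return np.inf
        curves = CalibrationCurves.constant(sigma, m0)
        S = build_design_matrix(patterns, curves, s.mass, template=template)
        A, rnorm = scipy.optimize.nnls(S.S, s.intensity)
        return rnorm**2 / s.mass.size

    res = scipy.optimize.minimize(
        objective, np.array([sigma0, m00]), method="Nelder-Mead",
        options={"xatol": xatol, "fatol": fatol, "maxiter": max_iter,
                 "maxfev": 4 * max_iter})
    m_ref = float(0.5 * (s.mass[0] + s.mass[-1]))
    point = CalibrationPoint(m_ref, float(res.x[0]), float(res.x[1]), float(res.fun))
    if not res.success:
        raise CalibrationError(f"simplex did not converge: {res.message}", best=point)
    return point


def _pchip_clamped(x: np.ndarray, y: np.ndarray):
    """PCHIP through (x, y) with constant extrapolation beyond the ends."""
    interp = PchipInterpolator(x, y, extrapolate=False)
    x0, x1 = x[0], x[-1]

    def f(m):
        return interp(np.clip(m, x0, x1))

    return f


def build_curves(points: Sequence[CalibrationPoint],
                 linear: bool = False) -> CalibrationCurves:
    """Join calibration points into sigma(m)/m0(m) curves.

    Default: monotone-safe PCHIP through the points (constant beyond the
    outermost ones); ``linear=True`` fits straight lines instead.  A single
    point gives constant curves.  Support is the m_ref span of the points.
    """
    if not points:
        raise ValueError("need at least one calibration point")
    pts = sorted(points, key=lambda p: p.m_ref)
    m = np.array([p.m_ref for p in pts])
    if np.any(np.diff(m) == 0):
        raise ValueError("duplicate calibration window centre m_ref")
    sig = np.array([p.sigma for p in pts])
    m0 = np.array([p.m0 for p in pts])
    if len(pts) == 1:
        # a single window gives constant curves valid everywhere
        return CalibrationCurves(lambda x: float(sig[0]), lambda x: float(m0[0]))
    if linear:
        cs = np.polyfit(m, sig, 1)
        c0 = np.polyfit(m, m0, 1)
        return CalibrationCurves(lambda x: np.polyval(cs, x),
                                 lambda x: np.polyval(c0, x),
                                 m_lo=float(m[0]), m_hi=float(m[-1]))
    return CalibrationCurves(_pchip_clamped(m, sig), _pchip_clamped(m, m0),
                             m_lo=float(m[0]), m_hi=float(m[-1]))
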