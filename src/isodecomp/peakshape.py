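"""Empirical peak-shape (convolution core) estimation by Fourier deconvolution.

Given a window of measured spectrum s(m) and the stick-sum model

    p_sum(m) = sum_i A_i p_i(m)

with abundances A_i estimated beforehand (e.g. from a Gaussian-core fit),
the measured signal is s = p_sum * kappa, so in the frequency domain the
core is K = S / P_sum.  The division is stabilised by a Tikhonov term,

    K = S conj(P) / (|P|^2 + delta * max|P|^2),

the back-transformed raw core is smoothed with a least-squares cubic
spline, and the result is normalised to unit area and unit FWHM so that it
can be reused as a width-scalable template.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline, LSQUnivariateSpline
from scipy.optimize import brentq

from .isotopes import IsotopePattern
from .spectra import Spectrum

__all__ = ["EmpiricalCore", "summed_pattern", "estimate_core", "normalize_core"]


@dataclass(frozen=True)
class EmpiricalCore:
    """A spline-sampled peak-shape template.

    ``offsets``/``values`` are the node samples of the smoothed core; after
    normalisation the interpolated template has area 1 and FWHM 1 and the
    template is zero outside the node support.  ``area_applied`` and
    ``width_applied`` record the normalisation scalings.
    """

    offsets: np.ndarray
    values: np.ndarray
    area_applied: float = 1.0
    width_applied: float = 1.0

    def __post_init__(self) -> None:
        x = np.asarray(self.offsets, dtype=float)
        y = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "offsets", x)
        object.__setattr__(self, "values", y)
        if x.ndim != 1 or y.shape != x.shape or x.size < 4:
            raise ValueError("need matching 1-D node arrays with >= 4 nodes")
        if not np.all(np.diff(x) > 0):
            raise ValueError("node offsets must be strictly increasing")
        object.__setattr__(self, "_spline",
                           CubicSpline(x, y, bc_type="natural", extrapolate=False))

    def __call__(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the template; zero outside the node support."""
        v = self._spline(np.asarray(x, dtype=float))
        return np.nan_to_num(v, nan=0.0)

    @property
    def support_halfwidth(self) -> float:
        return float(max(-self.offsets[0], self.offsets[-1]))

    def area(self, n: int = 4001) -> float:
        x = np.linspace(self.offsets[0], self.offsets[-1], n)
        return float(np.trapezoid(self(x), x))

    def fwhm(self, n: int = 4001) -> float:
        """FWHM of the interpolated template (linear crossing interpolation)."""
        x = np.linspace(self.offsets[0], self.offsets[-1], n)
        y = self(x)
        ipk = int(np.argmax(y))
        half = 0.5 * y[ipk]
        above = y >= half
        if not above.any():
            raise ValueError("template has no half maximum")
        lo = ipk
        while lo > 0 and above[lo - 1]:
            lo -= 1
        hi = ipk
        while hi < y.size - 1 and above[hi + 1]:
            hi += 1
        # refine the two half-height crossings on the spline itself
        def crossing(x_out, x_in):
            f = lambda t: float(self(np.array([t]))[0]) - half
            try:
                return brentq(f, x_out, x_in, xtol=1e-12)
            except ValueError:
                return x_out
        xl = x[lo] if lo == 0 else crossing(x[lo - 1], x[lo])
        xr = x[hi] if hi == y.size - 1 else crossing(x[hi + 1], x[hi])
        return float(xr - xl)

    # -- plain-text persistence ------------------------------------------
    def save(self, nodes_path, meta_path=None) -> None:
        arr = np.column_stack([self.offsets, self.values])
        np.savetxt(nodes_path, arr, header="offset,value", delimiter=",", comments="# ")
        if meta_path is not None:
            with open(meta_path, "w") as fh:
                json.dump({"area_applied": self.area_applied,
                           "width_applied": self.width_applied}, fh)

    @classmethod
    def load(cls, nodes_path, meta_path=None) -> "EmpiricalCore":
        arr = np.loadtxt(nodes_path, delimiter=",", comments="#")
        meta = {}
        if meta_path is not None:
            with open(meta_path) as fh:
                meta = json.load(fh)
        return cls(arr[:, 0], arr[:, 1],
                   area_applied=meta.get("area_applied", 1.0),
                   width_applied=meta.get("width_applied", 1.0))


def summed_pattern(species: Sequence[tuple[IsotopePattern, float]],
                   axis: np.ndarray) -> np.ndarray:
    """Deposit every stick (weight A_i * a_j) on its nearest grid point."""
    axis = np.asarray(axis, dtype=float)
    out = np.zeros_like(axis)
    step = axis[1] - axis[0]
    for p, A in species:
        idx = np.rint((p.masses - axis[0]) / step).astype(int)
        ok = (idx >= 0) & (idx < axis.size)
        np.add.at(out, idx[ok], A * p.abundances[ok])
    return out


def estimate_core(s: Spectrum, p_sum: np.ndarray, n_spline: int = 30,
                  reg: float = 1e-6) -> EmpiricalCore:
    """Recover the peak-shape core from data by regularised Fourier division.

    ``p_sum`` must be the stick-sum on the same grid as ``s``.  The raw core
    is spline-smoothed with ``n_spline`` control points over a +-4 FWHM
    support and normalised to unit area and unit FWHM.
    """
    y = np.asarray(s.intensity, dtype=float)
    p = np.asarray(p_sum, dtype=float)
    if p.shape != y.shape:
        raise ValueError("spectrum and stick-sum must share one grid")
    P = np.fft.rfft(p)
    pmax2 = float(np.max(np.abs(P)) ** 2)
    if pmax2 <= 0:
        raise ValueError("stick-sum is zero everywhere; nothing to deconvolve")
    K = np.fft.rfft(y) * np.conj(P) / (np.abs(P) ** 2 + reg * pmax2)
    raw = np.fft.irfft(K, n=y.size)
    # centre the core: its maximum defines zero offset
    raw = np.roll(raw, -int(np.argmax(raw)))
    raw = np.fft.fftshift(raw)
    k = y.size
    step = s.step
    offsets = (np.arange(k) - k // 2) * step
    # support from the raw core's own FWHM
    ipk = int(np.argmax(raw))
    half = 0.5 * raw[ipk]
    above = np.flatnonzero(raw >= half)
    fwhm_raw = max(step, (above[-1] - above[0]) * step)
    hw = 4.0 * fwhm_raw
    sel = (offsets >= -hw) & (offsets <= hw)
    x, v = offsets[sel], raw[sel]
    # least-squares cubic spline with n_spline evenly spaced control points
    n_knots = max(0, min(n_spline - 2, x.size - 10))
    knots = np.linspace(x[0], x[-1], n_knots + 2)[1:-1]
    if knots.size:
        spl = LSQUnivariateSpline(x, v, knots, k=3)
        nodes_x = np.linspace(x[0], x[-1], max(n_spline * 4, 64))
        nodes_y = spl(nodes_x)
    else:
        nodes_x, nodes_y = x, v
    return normalize_core(EmpiricalCore(nodes_x, nodes_y))


def normalize_core(core: EmpiricalCore) -> EmpiricalCore:
    """Scale a core to unit area and unit FWHM (idempotent)."""
    area = core.area()
    if area <= 0:
        raise ValueError("core area must be > 0")
    w = core.fwhm()
    if w <= 0:
        raise ValueError("core FWHM must be > 0")
    # offsets / w gives FWHM 1; values * w * ... keeps area 1 after both scalings
    return EmpiricalCore(core.offsets / w, core.values * (w / area),
                         area_applied=core.area_applied * area,
                         width_applied=core.width_applied * w)
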