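"""Forward modelling of profile mass spectra.

A measured spectrum is modelled as the superposition of stick patterns
convolved with an instrument peak-shape kernel (the "convolution core"):

    s(m) = sum_i A_i * (p_i * kappa)(m)

The core is either an analytic Gaussian of width sigma or an empirical
spline template; both carry a mass shift m0.  sigma and m0 generally vary
with mass and are supplied as calibration curves.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .isotopes import IsotopePattern

__all__ = [
    "FWHM_PER_SIGMA",
    "Spectrum",
    "ConvolutionCore",
    "CalibrationCurves",
    "DesignMatrix",
    "sigma_from_resolution",
    "render_species",
    "superpose",
    "build_design_matrix",
]

#: FWHM of a unit-sigma Gaussian, 2*sqrt(2*ln 2)
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Spectrum:
    """A profile spectrum on a uniform m/z grid (intensities in counts/bin)."""

    mass: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mass, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mass", m)
        object.__setattr__(self, "intensity", y)
        if m.ndim != 1 or y.shape != m.shape or m.size < 2:
            raise ValueError("spectrum needs matching 1-D arrays of length >= 2")
        steps = np.diff(m)
        if steps[0] <= 0 or np.any(np.abs(steps - steps[0]) > 1e-9 * abs(steps[0])):
            raise ValueError("mass axis must be uniform and increasing")

    @property
    def step(self) -> float:
        return float(self.mass[1] - self.mass[0])

    def with_intensity(self, y: np.ndarray) -> "Spectrum":
        return Spectrum(self.mass, y)

    def integral(self) -> float:
        """Trapezoidal integral of the intensity over the mass axis."""
        return float(np.trapezoid(self.intensity, self.mass))

    @classmethod
    def zeros(cls, axis: np.ndarray) -> "Spectrum":
        axis = np.asarray(axis, dtype=float)
        return cls(axis, np.zeros_like(axis))

    @staticmethod
    def axis(start: float, stop: float, step: float) -> np.ndarray:
        """A uniform grid from start to (at least) stop with the given step."""
        n = int(math.ceil((stop - start) / step)) + 1
        return start + step * np.arange(n)


@dataclass(frozen=True)
class ConvolutionCore:
    """Peak-shape kernel: unit-area template with width sigma and shift m0.

    ``sigma`` is always the Gaussian-equivalent width: for the analytic
    Gaussian it is the standard deviation (FWHM = sigma * 2*sqrt(2 ln 2));
    an empirical template, stored normalised to unit FWHM, is stretched to
    the same FWHM.  This makes calibration curves sigma(m) meaningful
    independently of the core kind.
    """

    kind: str  # "gaussian" | "empirical"
    sigma: float
    m0: float = 0.0
    template: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "empirical"):
            raise ValueError(f"unknown core kind {self.kind!r}")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.kind == "empirical" and self.template is None:
            raise ValueError("empirical core requires a template")

    @property
    def fwhm(self) -> float:
        return self.sigma * FWHM_PER_SIGMA

    def evaluate(self, m: np.ndarray, center: float) -> np.ndarray:
        """Kernel density at masses ``m`` for a stick at ``center``."""
        x = np.asarray(m, dtype=float) - center - self.m0
        if self.kind == "gaussian":
            s = self.sigma
            return np.exp(-0.5 * (x / s) ** 2) / (s * math.sqrt(2.0 * math.pi))
        w = self.fwhm  # template has unit FWHM
        return self.template(x / w) / w

    def support_halfwidth(self) -> float:
        """Half-width beyond which the kernel is treated as zero."""
        if self.kind == "gaussian":
            return 8.0 * self.sigma
        support = getattr(self.template, "support_halfwidth", 4.0)
        return float(support) * self.fwhm


@dataclass(frozen=True)
class CalibrationCurves:
    """sigma(m) and m0(m) as continuous interpolants with a support range."""

    sigma_of_m: Callable[[float], float]
    m0_of_m: Callable[[float], float]
    m_lo: float = -np.inf
    m_hi: float = np.inf

    def contains(self, m: float) -> bool:
        return self.m_lo <= m <= self.m_hi

    @classmethod
    def from_resolution(cls, R: float, m0: float = 0.0) -> "CalibrationCurves":
        """Constant-resolution curves: sigma(m) = (m/R)/(2 sqrt(2 ln 2))."""
        if R <= 0:
            raise ValueError("resolution must be > 0")
        return cls(lambda m: sigma_from_resolution(m, R), lambda m: m0)

    @classmethod
    def constant(cls, sigma: float, m0: float = 0.0) -> "CalibrationCurves":
        if sigma <= 0:
            raise ValueError("sigma must be > 0")
        return cls(lambda m: sigma, lambda m: m0)


@dataclass(frozen=True)
class DesignMatrix:
    """k x N matrix of unit-abundance model spectra, one column per species."""

    S: np.ndarray
    mass: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        object.__setattr__(self, "S", S)
        object.__setattr__(self, "mass", np.asarray(self.mass, dtype=float))
        if S.ndim != 2 or S.shape[0] != self.mass.size or S.shape[1] != len(self.labels):
            raise ValueError("inconsistent design matrix shapes")
        if S.shape[0] < S.shape[1]:
            raise ValueError("under-determined system: fewer grid points than species")

    @property
    def k(self) -> int:
        return self.S.shape[0]

    @property
    def N(self) -> int:
        return self.S.shape[1]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def sigma_from_resolution(m: float, R: float) -> float:
    """Gaussian sigma at mass m for resolving power R = m/FWHM."""
    if m <= 0 or R <= 0:
        raise ValueError("mass and resolution must be > 0")
    return (m / R) / FWHM_PER_SIGMA


def render_species(p: IsotopePattern, A: float, core: ConvolutionCore,
                   axis: np.ndarray) -> Spectrum:
    """Render one species: intensity(m) = A * sum_j a_j * kappa(m - m_j).

    The trapezoidal integral over the axis approximates A when the pattern
    (shifted by m0, padded by ~6 sigma) lies inside the axis; sticks whose
    kernels fall partly outside are rendered truncated with a warning.
    """
    axis = np.asarray(axis, dtype=float)
    out = np.zeros_like(axis)
    if A == 0.0:
        return Spectrum(axis, out)
    hw = core.support_halfwidth()
    lo, hi = axis[0], axis[-1]
    centers = p.masses + core.m0
    # area is conserved to <0.1% with ~6 sigma of padding; warn below that
    warn_hw = 0.75 * hw
    if np.any(centers - warn_hw < lo) or np.any(centers + warn_hw > hi):
        warnings.warn("pattern extends beyond the mass axis; render truncated",
                      stacklevel=2)
    for m_j, a_j in zip(p.masses, p.abundances):
        c = m_j + core.m0
        i0 = int(np.searchsorted(axis, c - hw, side="left"))
        i1 = int(np.searchsorted(axis, c + hw, side="right"))
        if i1 <= i0:
            continue
        out[i0:i1] += A * a_j * core.evaluate(axis[i0:i1], m_j)
    return Spectrum(axis, out)


def _core_for(pattern: IsotopePattern, curves: CalibrationCurves,
              template=None, label: str = "?") -> ConvolutionCore:
    mw = pattern.mean_mass
    if not curves.contains(mw):
        raise ValueError(
            f"species {label!r} at m/z {mw:.3f} is outside the calibration "
            f"support [{curves.m_lo:.3f}, {curves.m_hi:.3f}]")
    sigma = float(curves.sigma_of_m(mw))
    m0 = float(curves.m0_of_m(mw))
    if template is None:
        return ConvolutionCore("gaussian", sigma, m0)
    return ConvolutionCore("empirical", sigma, m0, template=template)


def superpose(species: Sequence[tuple[IsotopePattern, float]],
              curves: CalibrationCurves, axis: np.ndarray,
              template=None,
              labels: Sequence[str] | None = None) -> Spectrum:
    """Pointwise sum of rendered species; (sigma, m0) evaluated per species
    at its abundance-weighted mean stick mass."""
    axis = np.asarray(axis, dtype=float)
    total = np.zeros_like(axis)
    for i, (p, A) in enumerate(species):
        label = labels[i] if labels is not None else f"species {i}"
        core = _core_for(p, curves, template, label)
        total += render_species(p, A, core, axis).intensity
    return Spectrum(axis, total)


def build_design_matrix(patterns: Sequence[IsotopePattern],
                        curves: CalibrationCurves, axis: np.ndarray,
                        template=None,
                        labels: Sequence[str] | None = None) -> DesignMatrix:
    """Design matrix S whose column i is the unit-area render of pattern i."""
    axis = np.asarray(axis, dtype=float)
    if labels is None:
        labels = tuple(f"species {i}" for i in range(len(patterns)))
    if axis.size < len(patterns):
        raise ValueError("under-determined system: fewer grid points than species")
    S = np.empty((axis.size, len(patterns)))
    for i, p in enumerate(patterns):
        core = _core_for(p, curves, template, labels[i])
        S[:, i] = render_species(p, 1.0, core, axis).intensity
    return DesignMatrix(S, axis, tuple(labels))
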