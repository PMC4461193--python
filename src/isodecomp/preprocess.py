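"""Baseline and mass-drift correction.

Baseline: the axis is split into sub-ranges; in each, the mean of the
lowest ``noise_fraction`` percent of intensities defines a background node
at the sub-range centre, and a monotonicity-preserving cubic Hermite
(PCHIP) interpolant through the nodes gives the baseline, which is
subtracted without clipping (negative residuals are kept so the
least-squares residual stays unbiased).

Drift: a slow change of the mass scale over acquisition time blurs
long-averaged TOF spectra.  The rigid per-scan shift is the lag of the
cross-correlation maximum against a reference scan, refined to sub-grid
precision by parabolic interpolation; scans are unshifted and averaged to
restore the nominal resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .spectra import Spectrum

__all__ = [
    "BaselineModel",
    "DriftModel",
    "estimate_baseline",
    "subtract_baseline",
    "estimate_shift",
    "drift_from_scans",
    "correct_and_average",
]


@dataclass(frozen=True)
class BaselineModel:
    """Background level nodes with a monotone cubic interpolant."""

    node_mass: np.ndarray
    node_level: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.node_mass, dtype=float)
        y = np.asarray(self.node_level, dtype=float)
        object.__setattr__(self, "node_mass", x)
        object.__setattr__(self, "node_level", y)
        if x.ndim != 1 or y.shape != x.shape or x.size < 2:
            raise ValueError("need >= 2 baseline nodes")
        if not np.all(np.isfinite(y)):
            raise ValueError("baseline levels must be finite")
        object.__setattr__(self, "_interp", PchipInterpolator(x, y, extrapolate=False))

    def __call__(self, m: np.ndarray) -> np.ndarray:
        """Evaluate the baseline; constant beyond the outermost nodes."""
        m = np.clip(np.asarray(m, dtype=float), self.node_mass[0], self.node_mass[-1])
        return self._interp(m)


@dataclass(frozen=True)
class DriftModel:
    """Per-scan rigid mass shifts (Th) interpolated linearly over scan index."""

    scan_index: np.ndarray
    shifts: np.ndarray

    def __post_init__(self) -> None:
        i = np.asarray(self.scan_index, dtype=float)
        d = np.asarray(self.shifts, dtype=float)
        object.__setattr__(self, "scan_index", i)
        object.__setattr__(self, "shifts", d)
        if i.ndim != 1 or d.shape != i.shape or i.size == 0:
            raise ValueError("need matching 1-D scan index/shift arrays")
        if not np.all(np.isfinite(d)):
            raise ValueError("shifts must be finite")

    def __call__(self, idx) -> np.ndarray:
        return np.interp(idx, self.scan_index, self.shifts)


def estimate_baseline(s: Spectrum, n_subranges: int = 50,
                      noise_fraction: float = 25.0) -> BaselineModel:
    """Per-sub-range mean of the lowest ``noise_fraction``% of intensities."""
    if n_subranges < 2:
        raise ValueError("need at least 2 sub-ranges")
    if not (0.0 < noise_fraction <= 100.0):
        raise ValueError("noise_fraction must be in (0, 100]")
    chunks = np.array_split(np.arange(s.mass.size), n_subranges)
    nodes_m, nodes_b = [], []
    for idx in chunks:
        if idx.size < 3:
            raise ValueError("sub-range with fewer than 3 points; "
                             "reduce n_subranges")
        vals = np.sort(s.intensity[idx])
        n_low = max(1, int(round(idx.size * noise_fraction / 100.0)))
        nodes_m.append(0.5 * (s.mass[idx[0]] + s.mass[idx[-1]]))
        nodes_b.append(float(vals[:n_low].mean()))
    return BaselineModel(np.array(nodes_m), np.array(nodes_b))


def subtract_baseline(s: Spectrum, model: BaselineModel) -> Spectrum:
    """Subtract the evaluated baseline (negative results are not clipped)."""
    return s.with_intensity(s.intensity - model(s.mass))


def estimate_shift(a: Spectrum, b: Spectrum) -> float:
    """Mass shift of b relative to a from the cross-correlation maximum.

    Positive means b appears at higher mass than a.  The integer-lag peak is
    refined by parabolic interpolation, giving sub-grid precision.
    """
    if a.mass.size != b.mass.size or not np.allclose(a.mass, b.mass, rtol=0, atol=1e-9):
        raise ValueError("scans must share one mass axis")
    ya = a.intensity - a.intensity.mean()
    yb = b.intensity - b.intensity.mean()
    if np.all(ya == 0) or np.all(yb == 0):
        raise ValueError("flat scan: cross-correlation is degenerate")
    c = np.correlate(yb, ya, mode="full")
    n = a.mass.size
    i = int(np.argmax(c))
    lag = i - (n - 1)
    # parabolic refinement around the discrete maximum
    if 0 < i < c.size - 1:
        denom = c[i - 1] - 2.0 * c[i] + c[i + 1]
        if denom < 0:
            lag = lag + 0.5 * (c[i - 1] - c[i + 1]) / denom
    return float(lag * a.step)


def drift_from_scans(scans: Sequence[Spectrum], reference: int = 0) -> DriftModel:
    """Estimate every scan's shift against a reference scan (shift 0 there)."""
    shifts = [estimate_shift(scans[reference], sc) if i != reference else 0.0
              for i, sc in enumerate(scans)]
    return DriftModel(np.arange(len(scans), dtype=float), np.array(shifts))


def correct_and_average(scans: Sequence[Spectrum], model: DriftModel) -> Spectrum:
    """Undo each scan's drift by interpolation onto the common axis; average."""
    if not scans:
        raise ValueError("no scans")
    axis = scans[0].mass
    span = axis[-1] - axis[0]
    acc = np.zeros_like(axis)
    for i, sc in enumerate(scans):
        if sc.mass.size != axis.size or not np.allclose(sc.mass, axis, rtol=0, atol=1e-9):
            raise ValueError("scans must share one mass axis")
        shift = float(model(i))
        if abs(shift) > 0.1 * span:
            raise ValueError(f"scan {i}: shift {shift:.3g} exceeds 10% of the axis span")
        # a feature drifted to m+shift is brought back to m
        acc += np.interp(axis + shift, axis, sc.intensity,
                         left=sc.intensity[0], right=sc.intensity[-1])
    return Spectrum(axis, acc / len(scans))
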