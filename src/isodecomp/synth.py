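"""Synthetic spectrum generation with known ground truth.

Emulates the features the rest of the pipeline must cope with: stick
patterns of user-defined artificial elements (e.g. the two-isotope atom X
with masses 1 and 2 Da at abundances 0.2/0.8), Gaussian broadening at a
nominal resolving power R, additive Poisson or Gaussian noise, a slowly
varying Cauchy-shaped baseline, and rigid scan-to-scan mass drift.  Every
run is deterministic for a fixed seed and returns the ground truth (true
areas, baseline, per-scan shifts) alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import isotopes
from .isotopes import ElementRecord, IsotopePattern, PruneConfig
from .spectra import CalibrationCurves, Spectrum, sigma_from_resolution, superpose

__all__ = ["X_ISOTOPES", "SynthSpec", "register_artificial_elements",
           "generate_synthetic"]

#: The demonstration two-isotope artificial atom X: mass 1 at 20%, mass 2 at 80%.
X_ISOTOPES = ((1.0, 0.2), (2.0, 0.8))


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for a synthetic spectrum (or scan stack) with ground truth.

    species: (formula string, true area A) pairs.
    resolution/m0: Gaussian core parameters (R = m/FWHM).
    axis: (start, stop, step) in Th; None derives one covering the species.
    noise: None, ("poisson",) on counts, or ("gaussian", sigma).
    baseline: None or (location, scale, amplitude) of a Cauchy-shaped level
        amplitude / (1 + ((m - location)/scale)^2).
    drift: per-scan rigid shifts in Th (one scan per entry); None -> single scan.
    """

    elements: dict[str, Sequence[tuple[float, float]]] = field(default_factory=dict)
    species: Sequence[tuple[str, float]] = ()
    resolution: float = 100.0
    m0: float = 0.0
    axis: tuple[float, float, float] | None = None
    noise: tuple | None = None
    baseline: tuple[float, float, float] | None = None
    drift: Sequence[float] | None = None
    seed: int = 0
    prune: PruneConfig = PruneConfig()

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if not self.species:
            raise ValueError("need at least one species")
        for label, A in self.species:
            if A < 0:
                raise ValueError(f"abundance of {label!r} must be >= 0")


def register_artificial_elements(elements: dict[str, Sequence[tuple[float, float]]]) -> None:
    for sym, pairs in elements.items():
        isotopes.register_element(ElementRecord.from_pairs(sym, pairs))


def _default_axis(patterns: Sequence[IsotopePattern], R: float,
                  step: float | None = None) -> np.ndarray:
    lo = min(p.masses[0] for p in patterns)
    hi = max(p.masses[-1] for p in patterns)
    pad = 8.0 * sigma_from_resolution(max(hi, 1.0), R)
    sigma_min = sigma_from_resolution(max(lo, 1.0), R)
    if step is None:
        step = max(sigma_min / 10.0, 1e-6)
    return Spectrum.axis(lo - pad, hi + pad, step)


def generate_synthetic(spec: SynthSpec):
    """Build the spectrum (or scan stack) and its ground-truth record.

    Returns ``(data, truth)`` where data is a Spectrum or a list of per-scan
    Spectrum objects (if drift is given), and truth records the clean
    spectrum, per-species areas, baseline samples and per-scan shifts.
    """
    register_artificial_elements(
        {sym: pairs for sym, pairs in spec.elements.items()})
    formulas = [isotopes.parse_formula(label) for label, _ in spec.species]
    patterns = [isotopes.species_pattern(f, spec.prune) for f in formulas]
    if spec.axis is not None:
        start, stop, step = spec.axis
        axis = Spectrum.axis(start, stop, step)
    else:
        axis = _default_axis(patterns, spec.resolution)
    curves = CalibrationCurves.from_resolution(spec.resolution, spec.m0)
    pairs = list(zip(patterns, [A for _, A in spec.species]))
    clean = superpose(pairs, curves, axis,
                      labels=[label for label, _ in spec.species])

    base = np.zeros_like(axis)
    if spec.baseline is not None:
        loc, scale, amp = spec.baseline
        if scale <= 0:
            raise ValueError("baseline scale must be > 0")
        base = amp / (1.0 + ((axis - loc) / scale) ** 2)

    rng = np.random.default_rng(spec.seed)

    def realise(shift: float) -> Spectrum:
        if shift:
            # the drifted scan shows every feature at m + shift
            y = np.interp(axis - shift, axis, clean.intensity,
                          left=0.0, right=0.0)
        else:
            y = clean.intensity.copy()
        y = y + base
        if spec.noise is not None:
            kind = spec.noise[0]
            if kind == "poisson":
                y = rng.poisson(np.clip(y, 0.0, None)).astype(float)
            elif kind == "gaussian":
                y = y + rng.normal(0.0, spec.noise[1], size=y.size)
            else:
                raise ValueError(f"unknown noise model {kind!r}")
        return Spectrum(axis, y)

    truth = {
        "labels": [label for label, _ in spec.species],
        "areas": np.array([A for _, A in spec.species]),
        "clean": clean,
        "baseline": Spectrum(axis, base),
        "shifts": list(spec.drift) if spec.drift is not None else [0.0],
    }
    if spec.drift is None:
        return realise(0.0), truth
    return [realise(d) for d in spec.drift], truth
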