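"""File I/O and run-configuration handling.

Spectra are two-column delimited text (m/z, intensity; '#' comments);
scan stacks are either a directory of such files or one multi-column file
whose first column is the shared m/z axis.  Non-uniform input axes are
linearly resampled onto a uniform grid on load (the forward model, the
counts correction and the FFT-based peak-shape estimator all require one).
Cluster-series results go to CSV; a JSON provenance record makes every run
reproducible.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd
import yaml

from .spectra import Spectrum

__all__ = [
    "read_spectrum", "write_spectrum", "read_scan_stack",
    "write_cluster_series", "read_cluster_series",
    "load_config", "validate_config",
]


def _resample(m: np.ndarray, y: np.ndarray, step: float | None) -> Spectrum:
    order = np.argsort(m)
    m, y = m[order], y[order]
    dif = np.diff(m)
    uniform = np.all(np.abs(dif - dif[0]) <= 1e-9 * abs(dif[0]))
    if uniform and step is None:
        return Spectrum(m, y)
    step = step if step is not None else float(np.median(dif))
    axis = Spectrum.axis(float(m[0]), float(m[-1]), step)
    return Spectrum(axis, np.interp(axis, m, y))


def read_spectrum(path, resample_step: float | None = None) -> Spectrum:
    """Read a two-column (m/z, intensity) text spectrum; resample if needed."""
    arr = np.loadtxt(path, comments="#", ndmin=2)
    if arr.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (m/z, intensity)")
    return _resample(arr[:, 0], arr[:, 1], resample_step)


def write_spectrum(path, s: Spectrum) -> None:
    np.savetxt(path, np.column_stack([s.mass, s.intensity]),
               header="m/z intensity")


def read_scan_stack(path, resample_step: float | None = None) -> list[Spectrum]:
    """Read scans from a directory of two-column files (sorted by name) or a
    single multi-column file (first column = m/z, one column per scan)."""
    if os.path.isdir(path):
        names = sorted(f for f in os.listdir(path) if not f.startswith("."))
        if not names:
            raise ValueError(f"{path}: no scan files found")
        return [read_spectrum(os.path.join(path, n), resample_step) for n in names]
    arr = np.loadtxt(path, comments="#", ndmin=2)
    if arr.shape[1] < 2:
        raise ValueError(f"{path}: expected m/z plus at least one scan column")
    return [_resample(arr[:, 0], arr[:, j], resample_step)
            for j in range(1, arr.shape[1])]


def write_cluster_series(path, table: pd.DataFrame) -> None:
    """CSV, comma-separated, '.' decimal, UTF-8, with a header row."""
    table.to_csv(path, index=False, encoding="utf-8")


def read_cluster_series(path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_SCHEMA = {
    "species": list,        # formula strings, or {formula, core} mappings
    "prune": dict,          # {eps_a, eps_m}
    "resolution": (int, float),
    "m0": (int, float),
    "calibration": dict,    # {windows: [{m_lo, m_hi, species: [...]}]} or
                            # {resolution, m0} for fixed nominal curves
    "baseline": (dict, type(None)),   # {n_subranges, noise_fraction} or null
    "drift": (dict, type(None)),      # {enabled: bool} or null
    "resample_step": (int, float, type(None)),
    "seed": int,
    "output": str,
}

_REQUIRED = ("species",)


def validate_config(cfg: dict) -> dict:
    """Validate a run configuration against the documented schema.

    Required: ``species`` (non-empty list of formula strings).  Optional
    keys and their defaults: prune {eps_a: 1e-10, eps_m: 0}, resolution,
    m0 0, calibration (windows or fixed), baseline {n_subranges: 50,
    noise_fraction: 25}, drift, resample_step, seed 0, output 'series.csv'.
    """
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    for key in cfg:
        if key not in _SCHEMA:
            raise ValueError(f"unknown config key {key!r}")
    for key in _REQUIRED:
        if key not in cfg:
            raise ValueError(f"missing required config key {key!r}")
    for key, typ in _SCHEMA.items():
        if key in cfg and not isinstance(cfg[key], typ):
            raise ValueError(f"config key {key!r} has wrong type")
    if not cfg["species"]:
        raise ValueError("species list is empty")
    out = dict(cfg)
    out.setdefault("prune", {})
    out.setdefault("m0", 0.0)
    out.setdefault("baseline", {})
    out.setdefault("seed", 0)
    out.setdefault("output", "series.csv")
    if "calibration" not in out and "resolution" not in out:
        raise ValueError("config needs either 'resolution' or a 'calibration' block")
    return out


def load_config(path) -> dict:
    """Load and validate a YAML (or JSON, a YAML subset) run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return validate_config(cfg)


def write_provenance(path, record: dict) -> None:
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True, default=str)
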