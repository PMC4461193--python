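"""Non-negative least-squares abundance fitting with error estimation.

Solves A = argmin ||S A - s||^2 subject to A >= 0 (active-set NNLS), then
converts fitted areas to total counts (A* = A / dm on a uniform grid) and
attaches covariance-based 95% confidence intervals:

    cov(A) = (S^T S)^-1 * RSS / (k - N)
    dA_i   = t_{0.975, k-N} * sqrt(cov_ii)

The covariance is the unconstrained ordinary-least-squares form; active
non-negativity constraints are ignored, which is an approximation for
components fitted at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
from scipy.stats import t as student_t

from .spectra import DesignMatrix, Spectrum

__all__ = [
    "FitResult",
    "fit_abundances",
    "counts_correction",
    "covariance",
    "confidence_intervals",
    "fit",
]


@dataclass
class FitResult:
    """Fitted abundances and uncertainty for one NNLS solve.

    A: fitted areas; A_star: total counts (A / dm); dA: 95% CI half-widths;
    cov: N x N covariance of A; residual_ss: ||S A - s||^2; dof: k - N.
    """

    labels: tuple[str, ...]
    A: np.ndarray
    residual_ss: float
    dof: int
    A_star: np.ndarray | None = None
    dA: np.ndarray | None = None
    cov: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)


def fit_abundances(S: DesignMatrix, s: Spectrum) -> FitResult:
    """Active-set NNLS solve for the species areas."""
    if s.mass.size != S.k or not np.allclose(s.mass, S.mass, rtol=0, atol=1e-9):
        raise ValueError("spectrum mass axis does not match the design matrix")
    A, rnorm = scipy.optimize.nnls(S.S, s.intensity)
    return FitResult(S.labels, A, residual_ss=float(rnorm**2), dof=S.k - S.N)


def counts_correction(A: np.ndarray, dm) -> np.ndarray:
    """Convert fitted areas to total counts: A* = A / dm.

    ``dm`` is the grid step, or a mass axis from which the step is taken;
    a non-uniform axis is rejected (resample the input first).
    """
    dm = np.asarray(dm, dtype=float)
    if dm.ndim == 1:
        steps = np.diff(dm)
        if np.any(np.abs(steps - steps[0]) > 1e-9 * abs(steps[0])):
            raise ValueError("non-uniform mass axis: resample the spectrum "
                             "onto a uniform grid before counts correction")
        dm = steps[0]
    if dm <= 0:
        raise ValueError("grid step must be > 0")
    return np.asarray(A, dtype=float) / float(dm)


def covariance(S: DesignMatrix | np.ndarray, s_exp: np.ndarray,
               s_calc: np.ndarray, k: int | None = None,
               N: int | None = None) -> np.ndarray:
    """cov(A) = (S^T S)^-1 * RSS/(k-N); pseudo-inverse if S^T S is singular."""
    M = S.S if isinstance(S, DesignMatrix) else np.asarray(S, dtype=float)
    k = M.shape[0] if k is None else k
    N = M.shape[1] if N is None else N
    if k <= N:
        raise ValueError("need more data points than species (k > N)")
    rss = float(np.sum((np.asarray(s_exp) - np.asarray(s_calc)) ** 2))
    G = M.T @ M
    try:
        Ginv = np.linalg.inv(G)
        if not np.all(np.isfinite(Ginv)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn("singular normal matrix; using pseudo-inverse", stacklevel=2)
        Ginv = np.linalg.pinv(G)
    return Ginv * (rss / (k - N))


def confidence_intervals(cov: np.ndarray, dof: int) -> np.ndarray:
    """95% (two-sided) CI half-widths: t_{0.975, dof} * sqrt(diag cov)."""
    if dof < 1:
        raise ValueError("degrees of freedom must be >= 1")
    d = np.diag(np.asarray(cov, dtype=float)).copy()
    if np.any(d < -1e-12):
        raise ValueError("covariance has a negative diagonal element")
    d[d < 0] = 0.0
    return float(student_t.ppf(0.975, dof)) * np.sqrt(d)


def fit(S: DesignMatrix, s: Spectrum) -> FitResult:
    """Full fit: NNLS areas, counts correction, covariance and 95% CIs."""
    res = fit_abundances(S, s)
    res.A_star = counts_correction(res.A, s.step)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res.cov = covariance(S, s.intensity, S.S @ res.A, S.k, S.N)
    if any("pseudo-inverse" in str(w.message) for w in caught):
        res.flags.append("singular_normal_matrix")
    res.dA = confidence_intervals(res.cov, res.dof)
    return res
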