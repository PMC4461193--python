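# Methods

## The model

A profile mass spectrum of a cluster-ion mixture is modelled as a linear
superposition of isotopic stick patterns convolved with an instrument
peak-shape kernel ("convolution core") κ:

    s_calc(m) = Σ_i A_i · (p_i ∗ κ)(m)

where `p_i(m) = Σ_j a_ij δ(m − m_ij)` is the isotopic pattern of species
`i` (abundances `a_ij` sum to 1) and `A_i` is the species' spectral area.
Because the model is linear in `A`, the abundances of *all* species —
including ones whose envelopes overlap heavily — are obtained in one
non-negative least-squares solve against the measured spectrum, with
`k` grid points and `N ≤ k` species:

    Â = argmin_{A ≥ 0} ‖S·A − s‖²,

`S` being the k×N matrix of unit-area model spectra. Uncertainty comes
from the ordinary-least-squares covariance `cov(Â) = (SᵀS)⁻¹·RSS/(k−N)`
with 95% CI half-widths `t_{0.975,k−N}·√diag(cov)`; for large `k−N` the
multiplier is 1.96. This covariance deliberately ignores active
non-negativity constraints — for species fitted at the zero bound the
quoted interval is approximate.

Areas are converted to total counts per species by `A* = A/Δm` (uniform
grid step Δm); non-uniform grids are rejected rather than approximated,
and inputs on non-uniform axes are resampled linearly on load.

## Isotope patterns

A molecule's pattern is the convolution of its elements' isotope
patterns. Homonuclear powers use binary exponentiation
(square-and-multiply) so that an `ν`-mer needs `O(log ν)` convolutions
instead of the naive `ν`-fold chain, avoiding the `ν^{N_I}` isotopologue
blow-up. Two approximations run between every convolution step:

* **prune** (`eps_a`, default 1e-10): sticks with abundance < `eps_a`
  are dropped and the pattern is *not* renormalised — the removed mass is
  genuinely absent from the forward model and stays below `n_sticks·eps_a`.
* **merge** (`eps_m`, default 0): maximal runs of sticks with successive
  gaps < `eps_m` collapse to one stick at their abundance-weighted centre
  of mass, conserving Σa and Σa·m exactly. A practical `eps_m` is about
  FWHM/5 at the species' mass; the default 0 merges only exact
  collisions. The weighted-mean placement (rather than a plain sum of
  weighted masses) is what conserves the first moment for runs whose
  abundances do not sum to 1.

Multiply charged ions appear at 1/z of their mass; stick masses are
divided by z after convolution. An opt-in flag subtracts z electron
masses first (default off, since the effect is far below the resolutions
this model targets). The bundled element table carries standard isotopic
masses and abundances for 20 common elements; artificial elements (such
as the test atom X: mass 1 Da at 20%, mass 2 Da at 80%) are registrable
at runtime.

## Peak shape and width

The Gaussian core has σ related to resolving power R = m/FWHM by
σ = (m/R)/(2√(2 ln 2)). Everywhere in the package σ means the
*Gaussian-equivalent* width: an empirical template, stored normalised to
unit FWHM and unit area, is evaluated with scale FWHM = σ·2√(2 ln 2).
This convention makes σ(m) calibration curves transferable between core
kinds. σ and m0 are evaluated once per species, at its
abundance-weighted mean stick mass; this is accurate while the pattern
span is small compared with the scale on which σ(m) varies, which holds
for the cluster envelopes targeted here.

Empirical cores are recovered from data by Fourier deconvolution: with
estimated areas from a prior Gaussian-core fit, the stick-sum
`p_sum = Σ A_i p_i` is deposited on the grid and the core is the inverse
transform of `S(ω)·conj(P(ω))/(|P(ω)|² + δ·max|P|²)` — a Tikhonov-
stabilised pointwise division, δ = 1e-6 by default. The raw core is
smoothed by a least-squares cubic spline (30 control points over ±4 FWHM,
natural boundaries), then normalised to unit area and unit FWHM. The
normalisation is idempotent; its accuracy is limited by the numerical
FWHM measurement (spline-root refined), not by floating point.

## Calibration

σ and m0 vary over the mass range. Per user-chosen calibration window
the pair (σ, m0) is found by a Nelder–Mead simplex on the window's mean
squared deviation, where every objective evaluation re-fits the window's
abundances by NNLS — the linear parameters are always at their exact
optimum, so the simplex searches only two dimensions. Settings: fatol
1e-8, xatol 1e-6, 500 iterations max; non-convergence raises an error
carrying the best point. Initial σ comes from a user-supplied nominal
resolution; initial m0 is 0. Window selection is user-driven (windows
with clearly identified, high-signal species); automatic peak
identification is out of scope.

Per-window optima are joined into σ(m) and m0(m) by monotone piecewise
cubic Hermite (PCHIP) interpolation — chosen over an unconstrained
spline to rule out negative-σ overshoot between points — with constant
extrapolation beyond the outermost windows and an optional linear-fit
alternative. A single window yields constant curves. Species whose mean
mass lies outside the span of the calibration windows are rejected by
name during rendering.

## Baseline and drift

Baseline: the axis is split into `n_subranges` (default 50) equal
sub-ranges; in each, the mean of the lowest `noise_fraction`% (default
25%) of intensities defines a node at the sub-range centre, and PCHIP
interpolation through the nodes (constant beyond the outermost) gives
the background, which is subtracted without clipping. Note the estimator
is an order statistic: on noisy data it sits slightly *below* the mean
level (about one noise σ at 25%), which is intended — it resists
contamination by peaks occupying a minority of points.

Drift: a rigid per-scan mass shift is estimated as the lag of the
cross-correlation maximum against the first scan, refined by parabolic
interpolation of the three points around the peak (sub-grid precision;
positive shift = features at higher mass). Shifts are interpolated
piecewise-linearly over scan index, each scan is unshifted by linear
interpolation, and the stack is averaged. Only rigid shifts are
modelled; mass-dependent drift within a scan is out of scope. The
pipeline runs drift → average → baseline → calibrate → fit; the order of
baseline and drift is configurable, as no ordering is canonical.

## Synthetic data

The generator renders configured species at true areas with the Gaussian
core, optionally adds a Cauchy-shaped background
`amp/(1+((m−loc)/scale)²)`, per-scan rigid drift, and noise — Poisson on
counts by default (matching counting detectors), or Gaussian for
controlled-variance studies. All randomness derives from one seed, and
equal seeds give bit-identical output. What it does **not** emulate:
peak-shape asymmetry, detector saturation/dead-time, mass-dependent
drift within a scan, and chemical noise — so passing tests demonstrate
correctness of the algorithms under the stated noise model, not
robustness to every instrumental artifact of real spectra.

## Problem sizes and numerical choices

The validation fixtures use the two-isotope atom X on a 0.01 Th grid
over 8–24 Th (~1600 points, two species), where every stage's ground
truth is known in closed form or by construction. The reliability sweep
runs 1000 fits (20 count levels × 50 replicates, 10²–10⁵ counts per
compound); the CI-coverage check runs 1000 noisy replicates. Gaussian
kernels are truncated at ±8σ during rendering (truncation warnings fire
when pattern coverage falls below ~6σ, where area conservation to 0.1%
is no longer guaranteed). NNLS is the active-set algorithm; design
columns are assembled per species over the kernel's local support.
Exact-zero abundances arising from floating-point underflow in very
large convolutions are dropped, as they carry no signal.

## Known limitations

* The OLS covariance understates uncertainty for abundances pinned at 0.
* A single (σ, m0) per window assumes σ(m) is locally flat; windows much
  wider than that bias σ toward an average (a few percent across a
  two-fold mass span at R = 100).
* Fourier deconvolution assumes all peaks in the window share one core;
  per-species core assignment is supported in the species list, but no
  automatic detection of core differences (e.g. helium-containing vs
  pure-carbon peaks) is attempted.
* No negative ions, no isotope fine structure beyond the bundled table,
  and no regularised/Bayesian deconvolution.
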