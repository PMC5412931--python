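# Methods

## Signal model and conventions

The package models the diffusion-MRI signal of a voxel as a normalized
bi-exponential decay,

    S(b)/S(0) = f·exp(−b·D*) + (1 − f)·exp(−b·D),

carrying b-values in s/mm² and diffusion coefficients in mm²/s throughout;
no unit conversion happens anywhere. Signals are always handled normalized
(S(0) = 1); absolute signal intensity is never modeled, which matches the
simulation design where the maximum signal is 1 by construction.
Construction of a parameter triplet requires D > 0, D* > 0 and f ∈ [0, 1]
but deliberately does not require D* > D: noisy fits can legitimately land
outside the bi-exponential regime, and `IVIMParams.is_biexponential()`
reports whether the regime holds rather than forbidding its violation.

Two reference tissue models are built in: a gray-matter model
(D = 8.32×10⁻⁴ mm²/s, D* = 2.68×10⁻² mm²/s, f = 0.115) with strong
compartment separation (D*/D ≈ 32), and a low-perfused tumor model
(D = 1.63×10⁻³, D* = 7.23×10⁻³, f = 0.0953) where the separation is only
≈ 4.4× — the deliberately hard case. The default acquisition scheme is the
11-point schedule b = 0, 20, 40, 80, 110, 140, 170, 200, 300, 500,
1000 s/mm².

## Noise model

Noise is additive, zero-mean, white Gaussian on the normalized magnitude
signal, i.i.d. across b-values, with σ = μ/SNR and μ = 1 (the b = 0
normalized signal is the maximum of a decreasing curve). SNR ∈ {20…70}
covers the clinically observed range; 1000 iterations per (model, SNR)
cell is the default ensemble size. No Rician floor is modeled: at the
signal levels and SNRs simulated here (smallest mean signal ≈ 0.18 at
SNR 20) the Gaussian approximation is adequate, but see Limitations.
One noisy curve is drawn per iteration; acquisition of multiple gradient
directions and trace averaging is not simulated.

Seeding: a master seed spawns (via `numpy` `SeedSequence`) one independent
child stream per SNR level; the iteration index advances the stream. Runs
are bit-reproducible under a fixed seed, and streams at different SNR
levels are statistically independent rather than rescaled copies.

## Fitting cascades

All three cascades minimize squared residuals of the bi-exponential model
with `scipy.optimize.least_squares` using the trust-region-reflective
method — a damped (Levenberg-Marquardt-family) least-squares algorithm
that natively supports bound constraints — with an analytic Jacobian,
relative tolerances 10⁻⁸ on parameters and cost, and per-parameter scaling
by the initial values.

Defaults (chosen to bracket both tissue models without forcing D* > D):

| parameter | initial | bounds |
|---|---|---|
| D | 1.0×10⁻³ | [10⁻⁵, 5×10⁻³] |
| D* | 1.0×10⁻² | [10⁻⁴, 0.5] |
| f | 0.1 | [0, 1] |

The segmented sub-fit is ordinary least squares of log S on b over the
samples strictly above the perfusion threshold (default 200 s/mm², i.e.
{300, 500, 1000}; configurable to inclusive ≥). Non-positive noisy signal
values are dropped before the log transform and counted; fewer than two
usable points raises a fit-infeasibility error. The one-parameter cascade
converts the exponentiated intercept to f = (S(0) − S(int))/S(0) with
S(0) = 1, clamping to [0, 1] with a flag when noise pushes the intercept
outside (0, 1]. Estimates are never clipped after fitting; a bound-pinned
solution is flagged instead, because silent clipping would bias the
summary tables invisibly.

### Segmentation bias in low-perfused tissue

The segmented cascades assume perfusion is negligible above the
b-threshold. For the gray-matter model this is true to < 10⁻⁴ of the
signal; for the tumor model the slow pseudo-diffusion leaves 1.9% of the
signal perfusion-borne at b = 300, so even noiseless segmented fits carry
an intrinsic bias: D high by ≈ 1.5%, f low by ≈ 22% of its value, with a
compensating D* error. This is a structural property of segmented IVIM
fitting at low D*/D contrast, not a solver artifact; the simultaneous
cascade recovers the noiseless tumor model to machine precision. The test
suite freezes the closed-form value of this bias rather than pretending
segmented recovery is exact.

### Outlier definition

An iteration is excluded from all summary statistics when its fit is
*ill-conditioned*, operationalized as any of:

1. solver non-convergence;
2. a rank-deficient Jacobian at the solution — e.g. f fixed at 0 leaves
   the D* column identically zero;
3. Jacobian condition number above 10⁸;
4. any free estimate pinned at a bound (proximity within 10⁻³ of the box
   width, since trust-region solvers stop a small step inside an active
   bound);
5. a D* standard error exceeding the D* estimate itself — on
   near-mono-exponential data the cost surface is flat in D* and the
   "estimate" is arbitrary; this is the single-free-parameter face of
   ill-conditioning, which a condition number (identically 1 for a single
   column) cannot express;
6. a fitted perfusion fraction above 0.3 — non-physiological in brain
   tissue. In voxelwise mapping this marks CSF partial-volume
   contamination; in simulation it marks the degenerate amplitude-swap
   valley in which the pseudo-diffusion term captures the tissue
   compartment (f ≈ 0.7, D* ≈ tissue D), which is a good least-squares
   fit but not an estimate of perfusion.

`FitResult.outlier_reasons` records which criteria fired. Criteria 5 and 6
do most of the work at low SNR; without them the D* and f summary columns
are dominated by uninformative estimates (e.g. a pile-up at the D* upper
bound inflating its mean error by an order of magnitude). Exclusion is
not free of side effects: because the flags correlate with the noise
realization (a curve whose perfusion shoulder is flattened has both a
hopeless D* fit and a high segment intercept), the surviving subset is
slightly biased — surviving D estimates under-estimate truth by a few
percent at SNR 40-70, and the survivor CV of D* saturates near the width
of the acceptance region instead of shrinking indefinitely with SNR. Both
effects are visible in the emitted tables and are discussed in the tests.

## Summary metrics

Per (model, SNR, method, parameter) cell, over non-outlier iterations:
CV% = 100·SD/mean (sample SD, n−1, everywhere); mean error % =
100·|mean − truth|/truth; Bland-Altman on per-iteration relative
differences dᵢ = 100·(estimateᵢ − truth)/truth with bias = mean(d) and
95% limits of agreement bias ± 1.96·SD(d). The sign convention makes
overestimation positive. The outlier percentage is reported as its own
column. Cross-method comparison is a one-way ANOVA on the per-iteration
estimates at one (parameter, SNR), with Tukey HSD post-hoc pairwise
p-values at α = 0.05 (`scipy.stats.f_oneway` / `scipy.stats.tukey_hsd`).

## Confidence regions and minima census

Because covariance-based standard errors degrade when the bi-exponential
is weakly identified, parameter-pair uncertainty is mapped directly: the
two paired parameters are fixed on a grid (default 41×41, spanning the
best fit ± 5 standard errors per axis, falling back to ± 50% of the
estimate when a standard error is unavailable, clipped to bounds), any
remaining cascade-free parameters are re-optimized per node, and the cost
increase is converted to a confidence level with the fixed-parameter
F-test

    F = ((χ²_fix/χ²_best) − 1)·(N − P)/P_fix,   level = CDF_F(P_fix, N−P)(F),

where N is the number of b-values, P counts only solver-free parameters of
the cascade (P = 1 for the one-parameter cascade even though D and f were
fixed upstream), and P_fix = 2. On a linear model this construction
reduces exactly to the textbook t-interval (F(1, ν) = t²(ν)), which the
test suite uses as a closed-form oracle. A numerically zero best-fit
residual (noiseless data) makes the relative surface undefined and raises
a dedicated error instructing the caller to add noise.

The minima census runs a cascade from a log-spaced grid of starts (3 per
free parameter across the bounds box, interior points only — 27 starts for
the simultaneous cascade), keeps solutions that converged to a
well-conditioned interior point (the outlier criteria above; bound-pinned
or flat-surface terminations are not genuine minima of the model surface),
and merges solutions whose free parameters all agree within a relative
tolerance of 10⁻³. Curves where no start yields a usable solution are
counted as having no interior minimum, not as multi-minimum. With ground
truth supplied, the census records whether the lowest-cost solution is the
one nearest truth.

## Voxelwise mapping

Each in-mask voxel of a 4D (x, y, z, b) volume is normalized by its own
b = 0 sample (no spatial smoothing) and fitted independently; maps of D,
D* and f are emitted together with three masks: fitted, CSF-thresholded
(f > 0.3, applied after fitting as a mask, never as a fit bound), and
per-voxel outlier flags whose map values are withheld. Thresholded, fitted
and background voxels partition the masked volume. I/O is NIfTI via
nibabel, with b-values in a plain-text sidecar (one per line, in volume
order).

## Synthetic data: what it does and does not emulate

The generator reproduces the simulation conditions of the evaluation:
noiseless model curves on the printed schedule, Gaussian noise at exact
target SNR, and optional multi-compartment 4D phantoms (region-labeled
volumes where every voxel of a region shares one parameter triplet).
It does not emulate: Rician magnitude statistics, spatially correlated
or scanner-colored noise, partial-volume mixing at region boundaries,
eddy-current/motion artifacts, gradient-direction dependence, or
relaxation-time (TE/TR) modulation of the compartments. Passing tests
therefore demonstrate solver and pipeline correctness under the stated
noise model, not robustness to everything real acquisitions do.

## Numerical choices

- TRF rather than unbounded MINPACK Levenberg-Marquardt: bounds are part
  of the cascade definitions, and TRF handles them natively; both are
  damped least-squares methods with the same local behavior.
- `x_scale` set from the initial values so the three parameters
  (10⁻³, 10⁻², 10⁻¹ scales) are conditioned comparably inside the solver.
- Gauss-Newton covariance s²(JᵀJ)⁻¹ for standard errors, s² = RSS/(N−P);
  standard errors are reported NaN for cascade-fixed parameters and for
  rank-deficient solutions.
- Segment fits out of the D bounds (possible under heavy noise) flag the
  cascade as an outlier rather than being clipped into range.
- Ties/degeneracies: a constant curve has no decay information and is
  flagged; a zero-amplitude perfusion term is caught by rank deficiency.

## Known limitations

- The tumor model's segmented-fit bias (above) means "accuracy of the
  constrained cascades" in low-perfused tissue must be read as accuracy
  *given* the segmentation assumption; at D*/D ≲ 5 that assumption costs
  ~20% of f before noise enters.
- Survivor statistics are conditional on the outlier rule; a different
  operationalization of "ill-conditioned" shifts the D*/f columns
  materially (D and the outlier counts are robust to it).
- The Gaussian noise model understates low-SNR magnitude bias; extending
  to Rician noise would mainly affect the highest b-values at SNR ≈ 20.
- Voxelwise mapping fits voxels independently; no spatial regularization
  is attempted.
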