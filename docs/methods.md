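# Methods

## Problem and models

Short-T2* fibrocartilage (meniscus, tendon) loses most of its gradient-echo
signal within a few milliseconds, so quantitative T2* mapping there uses
(ultra)short echo times and explicit decay-curve fitting. Two nested models
describe the magnitude signal of a voxel as a function of echo time TE (ms):

- monoexponential, 3 parameters:
  `S(TE) = A1 exp(-TE/T2*) + eps`
- biexponential, 5 parameters:
  `S(TE) = B1 exp(-TE/T2*s) + B2 exp(-TE/T2*l) + eps`

`A1` (resp. `B1 + B2`) is the extrapolated signal at TE = 0; `eps` is a
constant baseline that absorbs the noise floor; the short and long
components are conventionally read as bound- and free-water pools, with the
short fraction `Fs = 100 B1/(B1+B2)`. The mono model is the `B2 = 0` special
case of the bi model, which is what makes the two selection criteria below
well-posed.

## Fitting

Each decay curve (a voxel, or an ROI-averaged curve) is fitted by bounded
trust-region nonlinear least squares (`scipy.optimize.least_squares`,
method `trf`) with analytic Jacobians. A trust-region method with box
bounds was chosen over classical Levenberg-Marquardt because plain LM
cannot honor the time-constant bounds; the objective is identical.

- Starting values: T2* = 10 ms (mono); T2*s/T2*l = 2/15 ms (bi). Amplitudes
  start from the first-echo signal (split 50/50 for the bi model), offset 0.
- Bounds: short time constant in [0, 20] ms, long (and mono T2*) in
  [0, 200] ms; amplitudes nonnegative; offset free.
- Multi-start: the mono fit adds a flat start (A1 = 0, offset = mean
  signal), which handles constant signals exactly. The bi fit runs three
  starts — data-driven, mono-seeded (B1 = B2 = A1/2, T2*s = 0.2 T2*m), and
  an exact embedding of the mono solution (B1 = 0, B2 = A1, T2*l = T2*m).
  Because the solver never worsens its starting point, the embedding start
  makes `sse_bi <= sse_mono` hold by construction for every curve.
- Tolerances: ftol = xtol = gtol = 1e-10, at most 200 function
  evaluations per start. A fit that exits at the evaluation limit is
  flagged non-converged and excluded from all downstream percentages
  (documented in the outputs; typically ~1% of voxels at SNR 35).
- Numerical guards: time constants have a 1e-6 ms positive floor inside
  the solver (the reported bounds keep 0), and amplitudes are capped at
  10x the largest observed signal. Without the cap the bi model has a
  degenerate ridge — a sub-TE time constant (T2*s well below the first
  echo) with an arbitrarily large amplitude fits one noisy point while the
  data constrain nothing — which stalls the solver and produces
  meaningless fraction maps. The cap is data-scaled and cannot bind for a
  physically meaningful solution, whose amplitude is of the order of the
  first-echo signal.
- The two bi components are exchangeable; fits are stored canonically with
  `T2*s <= T2*l`.
- Parameter standard errors are estimated from the Jacobian at the
  solution and stored; no filtering decision is taken from them.
- Weighting: none (unweighted least squares, matching the assumption of
  i.i.d. Gaussian residuals on magnitude data).

## Model selection

Per curve, with n echoes and k parameters (3 or 5) and SSE the residual sum
of squares:

- small-sample corrected Akaike criterion (natural log):
  `AICc = 2k + n ln(SSE/n) + 2k(k+1)/(n-k-1)`; lower wins, ties go to the
  mono model (parsimony). Since both models share n, the ranking is
  invariant to rescaling the signal and to the base of the logarithm.
- nested F-test: `F = ((SSE_mono - SSE_bi)/SSE_bi) * (v_bi / (v_mono -
  v_bi))` with `v = n - k`, referred to the F(2, n-5) distribution; the bi
  model is preferred when p < alpha (default 0.05). If a local-minimum
  artifact leaves `SSE_mono < SSE_bi`, F is clamped to 0.

Numerical choice: an SSE whose RMS residual is below 1e-12 of the signal
scale is treated as exactly 0 (perfect fit). On noise-free data both SSEs
are machine-rounding artifacts with arbitrary ratios; without the floor,
either criterion could "detect" biexponential decay in rounding noise. A
perfect fit gives AICc = -inf; two perfect fits tie and resolve to mono,
and give F = 0, p = 1.

Outputs: binary decay-type maps (0 = mono, 1 = bi) per criterion, short/long
fraction maps in percent (undefined where B1 + B2 = 0), F and p volumes,
and per-slice summary percentages. No multiple-testing correction is
applied across voxels.

## ROI-averaged analysis

Averaging the decay over an ROI of n voxels raises SNR by ~sqrt(n) (about
10x for a 100-voxel ROI), which is the mechanism by which ROI-level
analysis can detect biexponential decay where voxel-level analysis cannot.
Per ROI the pipeline fits both models to each slice's averaged curve,
applies both criteria, and reports mean +/- SD across slices (SD undefined
below 2 slices) plus the percentage of slices preferring the bi model.
Averaging across heterogeneous tissue creates genuine multi-exponential
mixtures; this is reported as-is because it is exactly what large clinical
ROIs measure. Whole-segment grand means are weighted by voxels per slice.

Group statistics: Bartlett's test decides homoscedasticity (p > 0.05);
classical factorial ANOVA (statsmodels OLS, type-II table) when
homoscedastic, otherwise Welch's ANOVA applied one factor at a time
(pingouin) — no common multi-way Welch procedure exists. The classical
model uses main effects only: with one ROI-averaged observation per
(angle, region, slice) cell, a full factorial would leave no residual
degrees of freedom. Factors are caller-configurable.

## Orientation model

Transverse relaxation in ordered collagen is driven by residual dipolar
coupling, modulated by `D(theta) = 3 cos^2(theta) - 1`, where theta is the
fiber-to-field angle; D vanishes at the magic angle (~54.74 deg). The
phantom adopts a rate model in which the dipolar contribution scales with
the squared residual coupling:

    R2*(theta) = R2*_iso + C * D(theta)^2,   R2* = 1/T2*,

with C >= 0 (1/ms) the anisotropy strength and R2*_iso the magic-angle
rate. This is a modelling choice — the empirical literature reports the
angle dependence without a functional form — and it reproduces the observed
ordering T2*(55) > T2*(90) > T2*(0) for any C > 0. For bi regions both
rates are modulated with the same C. `calibrate_anisotropy` solves the rate
model exactly from two (angle, T2*) anchors; the tendon-like calibration
used in the tests (12.19 ms at 55 deg, 3.3 ms at 0 deg) gives
C ~ 0.0553 /ms and a ~3.7x magic-angle-to-parallel ratio.

## Synthetic phantom

The generator emulates a meniscus-like cross-section: a triangular fibrous
body, a 0.2 mm outer laminar rim (the shell of the triangle), a tendon-like
band of anisotropic circumferential fibers, optionally a saline sphere;
geometries are specified in mm and rasterized at voxel centers, overlapping
regions resolved last-listed-wins. Defaults mirror the study conditions the
pipeline targets: 12 echoes at 0.82-23.55 ms (a 9-echo 0.4-12 ms schedule
is used where the shorter protocol is emulated), first-echo tissue SNR 35,
decay parameters of the order of the reported per-zone values, true offset
0 (the fitted offset absorbs the noise floor).

Noise is Gaussian on the magnitude signal by default, matching the fitting
assumption of normal residuals; Rician noise (the true distribution of
magnitude MR data, with its positive floor) is available as a sensitivity
option — at SNR 35 the Gaussian approximation is good in tissue but biased
in background. The noise SD is (mean tissue first-echo signal)/SNR, applied
independently per voxel and echo. The seed is mandatory; synthesis is
bit-reproducible.

What the phantom does not emulate: k-space acquisition and reconstruction,
B0/B1 inhomogeneity, partial-volume mixing at region boundaries, spatially
correlated noise, motion. Passing recovery tests therefore demonstrates the
correctness of the fitting/selection machinery under the stated noise
model, not robustness to every artifact of real acquisitions.

## Verification strategy and problem sizes

- Closed-form examples are asserted exactly (signal values, AICc penalty
  arithmetic, F(2, 7) tail `(1 + 2F/7)^(-7/2)`).
- Solver optimality is cross-checked against an independent brute-force
  oracle that profiles the linear parameters out exactly (bounded linear
  least squares) on a fine time-constant grid and polishes the 2D profile
  surface by Nelder-Mead; the solver must match its SSE within 1% on a
  20-voxel panel.
- Statistical behavior is checked by seeded Monte-Carlo at sizes chosen
  for desk-scale runtime: 5000 voxels for the F-test false-positive rate
  (bound: alpha plus three binomial SEs), 1000 replicates for mono
  recovery precision, 500 replicates for the close-component bi stress
  case (T2*s/T2*l = 1.34/4.50 ms), 80 replicates per cell for the 3x3
  power-monotonicity grid, 10 slices x 100 voxels for the ROI-vs-voxel
  SNR mechanism.
- The intrinsic median |T2*| error of the 3-parameter mono fit at SNR 35
  on the 12-echo schedule is ~7% (oracle-verified); the free offset is
  what it costs — a 2-parameter fit would be more precise but could not
  absorb the noise floor.

## Known limitations

- Voxel-wise fitting is plain Python over voxels (~35 ms per mono+bi pair);
  volumes beyond ~10^5 voxels call for coarser tolerances or
  parallelization.
- The Gaussian-noise default understates the Rician bias of low-SNR
  magnitude data; the Rician option exists precisely to quantify that
  sensitivity.
- The rate model for orientation dependence is a parsimonious
  single-coefficient choice; real tissue may modulate short and long
  components differently.
- "Confidence interval of 95%" as a fitting-time setting has no operative
  definition here; parameter standard errors are reported instead, and no
  voxel is filtered on them.
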