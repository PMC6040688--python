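# Methods

## The estimator

`fractal3d` estimates the correlation dimension D₂ of a binary 3D voxel set
by probabilistic box counting.  The volume is covered with a regular grid of
cubes of edge *r* voxels; cube *i* holding *Nᵢ(r)* of the object's *N_all*
voxels carries probability mass *pᵢ = Nᵢ(r)/N_all*, and the correlation sum

    C(r) = Σᵢ pᵢ²

is the probability that two points of the set fall in the same cube.  For a
set with scaling exponent D₂, C(r) ∝ r^D₂ over the scaling range, so D₂ is
the slope of ln C(r) against ln r.  The slope is taken with respect to ln r
(positive, since C grows with r); natural logarithms are used throughout,
though the slope is base-invariant.

Two practical refinements, both part of the estimator's contract:

* **Grid offsets.**  A single grid placement biases C(r) (it can align with
  or cut through structure).  For every box size the grid is re-counted at
  `n_offsets` integer offsets — the canonical (0,0,0) placement plus seeded
  uniform draws from [0, r−1]³ — and the median C(r) across offsets is kept.
  Offsets are drawn from a counter-based RNG keyed by `(offset_seed, r)`, so
  the profile is bitwise reproducible and independent of evaluation order.
  Boxes overhanging the grid edge are handled arithmetically
  (`floor((index+offset)/r)`), which is equivalent to zero-padding by r−1;
  physical padding is therefore cosmetic and off by default.

* **Breakpoint-optimized fit.**  Finite resolution bends the log-log curve
  at small r and saturation bends it at large r.  The final fit is ordinary
  least squares over the contiguous sub-range of box sizes (at least
  `min_fit_points` points) that maximizes R²; ties within 10⁻⁹ in R² prefer
  more points, then the smaller lower bound.  Windows with zero variance in
  ln C (e.g. the saturated single-box tail) carry no scaling information and
  are skipped.  The *breakpoint* is reported as the lower edge of the fitted
  range — the boundary between the discarded short-scale points and the
  linear portion — and equals `r_min_used` when nothing is excluded.  RMSE
  is the root-mean-square log-space residual over the included points only,
  paired with the R² of the same final fit.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `min_r` | 2 voxels | smallest box size; 1-voxel boxes only echo the voxel count |
| `max_r_fraction` | 0.70 | largest box size as a fraction of the shortest grid side |
| `r_step` | 1 voxel | box-size increment |
| `n_offsets` | 20 | grid placements per box size, median-aggregated |
| `offset_seed` | 0 | seed of the offset streams |
| `min_fit_points` | 10 | minimum points in the final fit; prevents degenerate 3-point "perfect" fits |
| `allow_anisotropic` | False | see below |

Box counting treats boxes as cubes in index space, so the estimator refuses
voxel spacings with max/min ratio above 1.05 unless `allow_anisotropic` is
set; volume computation (`mask_volume_mm3`) accepts any spacing.  Whether a
mask arrives in native or conformed space is the caller's business: the
analysis operates on the grid it is given and records spacing in its report.

### Numerical implementation

Counting uses a 3D summed-area (integral) table built once per volume in
int32; the box sums for any (r, offset) are one gather of the box-corner
lattice plus three differences.  This makes the cost per grid placement
proportional to the number of boxes, not voxels, so a full default profile
of a 486³ phantom (339 box sizes × 20 offsets) runs in seconds.  The window
scan is O(#rows²) with prefix sums, then the selected window is refit
directly in centered coordinates for numerical hygiene.

## Phantoms

**Menger sponge.**  The exact validation phantom.  A cell at recursion
level k is retained iff at every level the base-3 digits of its (x,y,z)
cell coordinates contain at most one digit equal to 1 — the digitwise form
of "divide into 27 subcubes, remove the 6 face centers and the body
center".  This is vectorizable, provably equivalent to recursive carving
(tested against an independent recursive construction), and gives exactly
20^k·s³ occupied voxels for hole size s.  Its similarity dimension is
ln 20 / ln 3 ≈ 2.726833.  On the 5-iteration, hole-size-2 sponge (486³)
the default estimator returns ≈ 2.68 — a known, small downward bias: the
sponge's lacunarity makes ln C(r) scallop with period ln 3 between the
grid-aligned scales, and random offsets suppress C progressively at larger
r.  At the grid-aligned divisor scales (r = 2, 6, 18, 54, …) the measured
C(r) reproduces the theoretical slope to machine precision, which is the
package's sharpest self-check of the counting core.  A memory guard
(default 1024³ voxels) refuses phantom grids that would not be desk-scale.

**Rough shells.**  The surrogate for thin convoluted cortical sheets such
as cerebellar gray matter.  A spherical shell of configurable thickness is
modulated radially by a seeded band-limited angular noise field: 64 random
plane-wave components with wavevector magnitudes log-uniform in
[3, `roughness_scale`] (default 96), flat spectrum, normalized to unit RMS.
The radial perturbation is `h·tanh(g·f(u)/h)` with gain
g = 0.2·radius·amplitude and h the radial headroom to the grid boundary;
the tanh soft clip guarantees the shell always fits the grid while
preserving monotonicity of surface irregularity in the amplitude.  On the
default 96³ grid (radius 32, thickness 2) amplitudes 0 → 1 drive the
estimated FD from ≈ 2.04 to ≈ 2.45-2.55, covering the range reported for
cerebellar cortex.  Only *monotonicity* of the amplitude → FD map is part
of the contract (verified empirically and frozen as a regression test); the
map is not assumed linear.  The generator is a pure function of its spec.

What the shells do **not** emulate: real cerebellar anatomy (lobules,
vermis, white-matter branching), partial-volume effects, segmentation
noise, or scanner/site effects.  Passing tests on shells show that the
estimator orders surface irregularity correctly and that the statistical
pipeline controls its error rates — not that any particular FD value for a
real brain structure is unbiased.

## Synthetic cohorts

`CohortSpec` describes a case/control cohort in the study's own terms:
20 cases and 18 controls by default, ages uniform over 6.5-10.5 years,
verbal IQ ~ N(109, 13²) in both groups (the matched covariate), case
performance IQ built as VIQ + spread with spread ~ N(13, 12²), control PIQ
~ N(104, 15²), and ~85% right-handedness.  Each subject carries a latent
roughness (control mean 0.7, sd 0.12) driving one rough shell per
hemisphere (with small independent hemisphere jitter, sd 0.03);
`fd_effect` lowers case roughness — hence expected FD — either globally or
per hemisphere.  The case group's PIQ−VIQ spread is coupled to roughness
by a Gaussian copula with Pearson parameter 2·sin(π·ρ/6), so the *rank*
correlation targets `piq_viq_rho` (default 0.5), matching the rank-based
analysis downstream.  Roughness values are clipped to [0, 1.5], the
generator's calibrated range.

## Statistics

Implemented from definitions, with scipy supplying only reference
distributions:

* **Mann-Whitney U** — midrank ties; U = min(U_a, U_b), two-tailed.  Exact
  p by full enumeration of group assignments (P(min U ≤ observed)) when the
  pooled n ≤ 12 and there are no ties; otherwise normal approximation with
  tie and continuity corrections (agreement with enumeration is within 0.02
  for 5 ≤ n₁,n₂ ≤ 8 in the property suite).
* **Bonferroni** — fixed m = 2 for the two hemispheres (threshold
  0.05/2 = 0.025); the fit-quality outcomes (R², RMSE) are reported
  unadjusted and labelled secondary.
* **Cohen's U3** — share of the lower group strictly below the higher
  group's median, with half credit for exact ties so identical
  distributions sit at the 0.5 null.  95% CI by seeded percentile bootstrap
  (default B = 10,000) resampling both groups; a bootstrap is the standard
  nonparametric choice where no interval method is prescribed.
* **Pooled t and Pearson χ²** — recomputable from printed summary tables;
  χ² without continuity correction (df = 1), matching the printed worked
  example to 3 significant figures.
* **Partial Spearman** — midrank-transform all variables, regress ranked x
  and y on the ranked covariates (with intercept), correlate the
  residuals; df = n − 2 − k, p from t = ρ√(df/(1−ρ²)).  Two-tailed by
  default; a one-tailed mode exists because directional hypotheses are
  common in this analysis, but it is never applied silently.
* **Kolmogorov-Smirnov** — two-sample: classical D with asymptotic p.
  One-sample normality: D against a normal with sample-estimated mean/sd;
  since estimated parameters make the classical null anti-conservative, p
  is calibrated by seeded Monte Carlo (Lilliefors-style, default 2000
  simulations), and the output records that variant.

## Pipeline

`run_group_analysis` validates the manifest against the covariates before
any computation, estimates FD for every (subject, hemisphere) mask under
the configured seeds, then reports per hemisphere: the FD comparison
(U, raw and Bonferroni-adjusted p, U3 with CI, medians and ranges), R² and
RMSE comparisons (both Mann-Whitney and pooled t, since either convention
is defensible for these secondary outcomes), and a volume-matching check
(Mann-Whitney on mm³).  The PIQ>VIQ analysis correlates the case group's
spread with FD controlling for age, both restricted to strictly positive
spreads (ties and reversals dropped, mirroring the 17-of-20 subset design)
and on all cases.  The report is a pydantic model serialized to JSON (the
schema is published in `docs/report_schema.json`) plus a per-subject CSV.

## Simulation sizes

The replicated simulations run at deliberately small scale so the whole
suite executes in minutes on one CPU: planted-effect and null-error
cohorts use 10+9 subjects with 40³-grid shells (radius 14) and 5 grid
offsets; the amplitude-monotonicity check uses five seeds per amplitude on
the default 96³ shells; the Menger validation runs the full 486³ phantom
with default parameters.  At 10+9 subjects the exact Mann-Whitney already
resolves adjusted p ≈ 2×10⁻⁵, so these sizes do not limit what the tests
can detect.

## Known limitations

* The estimator inherits box-counting's finite-size bias: values for small
  or strongly lacunar objects are biased low by a few hundredths even at
  the 486³ validation scale.  Comparisons *between* groups measured at the
  same scale are unaffected in rank terms.
* The exhaustive R²-max window selection favors locally smooth sub-ranges;
  on strongly scalloped log-log curves (exact self-similar phantoms) the
  selected window can sit at small r.  For natural, non-grid-aligned
  objects the curve is smooth and the selection is stable.
* One-sample KS p-values depend (mildly) on the Monte-Carlo budget; they
  are reproducible only under the same seed and budget.
* Anisotropic voxels are refused rather than resampled; resampling is out
  of scope.
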