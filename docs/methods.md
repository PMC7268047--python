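# Methods

This note documents the models, numerical choices and limitations of the
tractrr pipeline in the package's own terms. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself compute.

## Signal model and tensor fit

Per voxel the diffusion signal follows the monoexponential single-tensor
model, S(b, g) = S0·exp(−b·gᵀDg). Fitting is log-linear least squares on a
7-column design (ln S0 plus the six unique tensor components). The default is
weighted least squares (WLS) with weights equal to the squared model signals
from an OLS first pass — the standard correction for the heteroscedasticity
introduced by the log transform. Whether the original analyses behind the
reference table used OLS or WLS is unknowable; both are available
(`fit_method`), and they agree exactly on noise-free data (tested).

Numerical policy:

* signals are floored at 1e-6·S0 before the log (count logged); all-zero
  voxels are flagged invalid, never silently zeroed;
* negative eigenvalues are kept for MD/AD/RD (keeps MD unbiased) and clamped
  to zero only inside the FA formula (count logged);
* eigenvalues sort descending; eigenvector signs are fixed so the
  largest-magnitude component is positive, which makes tracking reproducible.

Scalar maps: AD = λ1, RD = (λ2+λ3)/2, MD = trace/3,
FA = √(3/2)·‖λ−λ̄‖/‖λ‖. Diffusivities are stored in mm²/s and displayed in
the 10⁻³ mm²/s convention in reports.

## Phantom and cohort generator

**Geometry.** A mostly vertical, gently bowed tract centerline per hemisphere
in a 40×40×60 grid of 1.8 mm isotropic voxels (defaults mirror a single-shell
clinical acquisition: b = 1000 s/mm², 56 Fibonacci-hemisphere directions, 7 b0
volumes). Voxels within `tract_radius_mm` (5.4 mm) of the centerline receive a
cylindrical tensor (default eigenvalues 1.4/0.45/0.45 ×10⁻³ mm²/s, FA ≈ 0.62)
oriented along the local tangent; a one-voxel partial-volume shell just
outside blends tract and background tensors, emulating voxels that mix white
matter with surrounding tissue. The background is isotropic (0.8×10⁻³ mm²/s).
Derived masks: six small "cortical" seed patches at the superior end, waypoint
slabs at internal-capsule and peduncle heights, a mid-sagittal exclusion
plane, an inferior exclusion plane, a lesion sphere on the ipsilesional tract
(FA scaled by 0.6 inside, MD preserved), and a ground-truth template mask
(core + shell).

**Variance model.** Subject offsets b_s ~ N(0, σ_between²) and session offsets
e_st ~ N(0, σ_session²) act on tract FA; the generator's true ICC is
σ_b²/(σ_b²+σ_s²). Defaults σ_between = 0.04, σ_session = 0.007 FA units give
true ICC = 0.970, matching the excellent-reliability regime the pipeline is
meant to probe; the ipsilesional tract is lower by a fixed FA gap (0.04).
Offsets are drawn independently per hemisphere — a deliberate choice (the
alternative, shared session offsets, makes FA-ratio reliability artificially
perfect). Target FAs are realised by scaling (λ2, λ3) jointly and resetting λ1
to preserve the trace, so FA moves while MD stays fixed. A configurable
session mean shift exists but defaults to 0: the few days between sessions are
assumed to cause no structural change.

**Noise.** DWI noise defaults to Gaussian at σ = 0.03·S0 (SNR ≈ 33 on b0,
realistic for 3 T single-shell data); Rician magnitude noise is available but
not the default, since Rician tensor-fit bias is not the question under study.
Reversed-phase-encoding duplicate runs and distortion correction are out of
scope, so one run per session is simulated.

## Probabilistic tracker

Streamlines propagate bidirectionally from each seed-voxel centre at 0.5 mm
steps along the trilinearly interpolated principal-eigenvector field. Instead
of Bayesian multi-fibre posterior sampling, orientation uncertainty is a
parametric angular dispersion (default SD 10°) applied per step — this keeps
the semantics under test (waypoint AND-filtering, exclusion discarding,
waytotal normalisation, 1% thresholding) at desk scale. A subsidiary-fibre
volume-fraction threshold is meaningless in a single-fibre model and is
deliberately not implemented.

Conventions, each configurable and tested at its boundary:

* curvature threshold = minimum cosine of the per-step turning angle (0.2);
* propagation stops at FA < 0.2 (nearest-voxel test), grid exit, curvature
  violation or `max_steps` (2000); touching an exclusion mask discards the
  whole streamline;
* a streamline "intersects" a mask if any step's nearest voxel is in it;
* `n_samples` streamlines per seed voxel; waytotal counts accepted
  streamlines; the 1% density threshold is **inclusive** (≥, a voxel at
  exactly 1% of waytotal is kept) while the FA threshold is **strict** (>, a
  voxel at exactly 0.2 is removed) — the reference phrasing supports the
  strict FA rule and is silent on the density rule, so the inclusive choice
  is documented here;
* voxel indices are 0-based, the third axis is axial, inferior = low index.

Because waypoints only filter accepted streamlines and exclusions only discard
them, trajectories never depend on either — adding a waypoint or exclusion
can only reduce the waytotal (tested as a property).

The default study reduces `n_samples` from the reference 5000 to 500 per seed
voxel purely for runtime (the full suite runs one 18-subject study in ~6 min
on one CPU); the acceptance checks are statements about semantics and
reliability structure, not about density-map resolution.

## The three extraction approaches

* **peduncle** — the ground-truth tract mask restricted to the 3 contiguous
  axial slices of largest cross-sectional area within the inferior third of
  the grid (ties → most inferior window); stands in for a hand-drawn ROI.
* **probabilistic** — six per-patch tracts, each waytotal-normalised and
  1%-thresholded, united per hemisphere.
* **template** — the ground-truth template mask resampled through a 4×4
  affine with nearest-neighbour interpolation. Registration error can be
  emulated by a small random translation (`template_jitter_mm`); the default
  is 0 mm so the approach is deterministic, which preserves the expected
  ordering (template most reliable). All approaches then apply FA > 0.2 and
  lesion-voxel removal before unweighted means are taken.

## Reliability statistics

ICC(A,1) is computed from the two-way ANOVA mean squares (the point estimate
is identical for two-way random and two-way mixed absolute-agreement
single-measure models). Confidence intervals follow the McGraw–Wong formulas
with Satterthwaite degrees of freedom for the combined MSC/MSE term; the
implementation is cross-checked against an independent library on random data
in the test suite. SEM uses the day-1 sample SD (n−1 denominator), not the
pooled SD. MDC95 uses the full-precision z = 1.959964 (rounding z to 1.96
changes MDC by < 0.1%); reports display 3 decimals. Negative ICC estimates
are reported as computed but clamped to 0 inside SEM with a warning. Rating
bands are closed on the left (0.5 → moderate, 0.75 → good, 0.9 → good,
excellent strictly above 0.9); no reference row falls on a boundary, so the
choice is untestable against the reference values and is simply documented.

The shipped reference reliability table is internally consistent under the
MDC formula: recomputing MDC95 from each row's own SD and ICC reproduces the
printed value within 0.0015 for all FA-family rows (rows limited by 3-decimal
input rounding are flagged, not failed). One narrative value in the source
publication (an ipsilesional peduncle-approach FA MDC of 0.045) is
inconsistent with its own tabulated SD = 0.052 and ICC = 0.844, which give
0.057; the package follows the tabulated values.

## What a green test does and does not establish

The synthetic cohort emulates: two sessions, a bilateral tract with an
ipsilesional FA deficit and lesion, controlled between-/within-subject FA
variance, partial-volume shells, imaging noise, and a behaviour covariate
(a synthetic impairment score generated as a noisy increasing function of
true ipsilesional FA, so positive FA–behaviour correlations are recoverable).
It does **not** emulate: susceptibility/eddy distortions, crossing fibres,
Rician floor effects at low SNR (by default), registration warps beyond
translation, inter-rater variability in mask drawing, or MD/AD/RD
between-subject variance — MD is deliberately held fixed by the FA
adjustment, so MD reliability in the synthetic study is near zero by
construction and its ICC rows exercise the negative-estimate code path
rather than mirroring empirical MD reliability. Likewise the ipsi-vs-contra
sign of the AD contrast follows from trace preservation (AD decreases with
FA) and is opposite to what lesioned tissue typically shows for
diffusivities; only the FA contrast is asserted.

Recovery of the generator's ICC by the full pipeline therefore establishes
that simulation, fitting, extraction and the ICC arithmetic compose
correctly — not that any particular empirical reliability value is correct.

## Known limitations

* Single-fibre phantom; the tracker's dispersion model cannot represent
  crossing-fibre posteriors.
* The exact CI procedure behind the reference table's printed intervals is
  unstated; the McGraw–Wong intervals here are treated as the definition, and
  printed CIs as approximate cross-checks only.
* Empty-tract subjects are excluded listwise per approach with a logged
  count; under the default configuration none occur.
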