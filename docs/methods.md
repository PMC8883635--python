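# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `orbigrow`, in the order the pipeline runs.

## The generative model for serial orbital volumes

The cohort simulator treats the log volume of one orbital side of patient
*i* at exact age *t* (years) as

```
ln V_side(t) = ln(V_base) + mu(t) + u_i + W_i(t) ± delta/2 + e
```

- `mu(t)`: age-indexed mean log-volume curve, anchored at 0 in the base
  age class (12 years). The default schedule is the published pooled
  age-class curve spanning roughly −0.10 (age 8) to +0.08 (age 18),
  i.e. ~1–2% volume growth per year.
- `u_i ~ N(0, sd_individual²)`: time-invariant individual size effect
  (default SD 0.05, i.e. ±5% patient-to-patient spread). It cancels in
  repeat-scan pairs, so its magnitude is inconsequential for the index —
  which is the methodological point of the repeat-scan design.
- `W_i(t)`: Gaussian random walk with `Var[W(t₂)−W(t₁)] =
  sd_walk_per_year²·(t₂−t₁)` (default 0.02/√yr): patient-specific drift
  away from the mean curve that grows with elapsed time.
- `e ~ N(0, sd_measurement²)` per scan per side (default SD 0.01):
  segmentation/measurement noise.
- `delta` (default 0.005): mean of ln(right/left), applied as +δ/2 on the
  right and −δ/2 on the left so the bilateral average is unbiased for
  `mu`.

The default noise magnitudes are plausible choices for manual CBCT
segmentation — roughly 1% measurement noise and 2%/√yr of individual
drift — not estimates from any dataset; real panels report no variance
components to calibrate against.

**Age placement.** Scan ages are drawn per patient subject to the minimum
inter-scan interval (default 365 days). Two modes exist:

- `"snap"` (default): exact ages land on integer age-class boundaries.
  With class-aligned ages the discrete schedule is *exactly* the estimand
  of the class-based index: zero-noise panels reproduce the schedule to
  machine precision, and the pair count of the study preset is a seed-free
  constant (81). This is the mode the recovery experiments use.
- `"continuous"`: exact ages are uniform over the feasible window and the
  mean curve is evaluated by linear interpolation between integer-age
  schedule values. This is more faithful to clinically driven scan timing,
  but it changes the estimand: the class-level coefficient then targets
  the within-class average of the interpolated curve, which differs from
  the schedule by a curvature (aggregation) term — up to ~0.014 at age 8
  for the default schedule. Consecutive scans can also round into the same
  age class (such pairs are dropped downstream). Recovery against the
  schedule is therefore only exact, and only seed-stable, in snap mode.

The preset's sex-by-scan-count assignment (4 scans: 3 F; 3 scans: 7 F +
3 M; 2 scans: 31 F + 21 M) is the mix that reproduces both the per-sex
scan totals (95 F / 51 M) and the per-sex pair counts (54 / 27) of the
study design it emulates.

**What the generator does not emulate:** segmentation error that depends
on anatomy or image quality, operator learning effects, informative scan
timing (scans triggered by growth), secular/cohort trends, or treatment
effects. Passing recovery tests therefore shows the estimator is correct
under its own assumptions, not that those assumptions hold in any real
panel.

## Panel reduction

- **Age class** = `round(age_days / 365.25)`, half-up at ties (the
  convention is arbitrary; it is fixed and tested). Scans rounding to 19
  are merged into class 18, where the data are thin.
- **Bilateral averaging**: the analysis volume is the arithmetic mean of
  left and right. This halves the per-scan measurement-noise variance
  (σ_e²/2), which matters when interpreting the stage-2 intercept (below).
- **Pairs**: adjacent scans only — a patient with m scans yields m−1
  pairs, never all C(m,2) combinations (which would double-count
  information and correlate rows mechanically). Pairs whose scans share an
  age class carry no cross-class growth information and are dropped with a
  warning rather than an error.

## The three-stage estimator

Stage 1 is OLS without intercept on the ±1 contrast design; a
connectivity check (age-class graph reachable from the base class through
pairs) pre-empts rank deficiency and names any unidentified classes.

Stage 2 regresses squared stage-1 residuals on the pair interval with an
intercept. Under the generative model the pair-residual variance is
`(per-scan noise variance)·2 + σ_w²·interval`; with bilateral means the
per-scan noise variance is σ_e²/2, so the intercept estimates σ_e² — on a
single-side series it estimates 2σ_e². With fewer than two distinct
interval values the slope is unidentified and the fit degrades to
intercept-only with a warning.

Stage 3 divides each row and response by the square root of the fitted
stage-2 variance (weight ∝ 1/variance), down-weighting long intervals.
The literal alternative — multiplying by that square root — is exposed as
`weight_mode="literal"` for sensitivity analysis only; it up-weights the
noisiest pairs and defeats the purpose of the weighting. Fitted variances
are floored at `max(1e-10, 1e-3 × median)` because the linear variance
model can go non-positive at short intervals. The reported R² is the
uncentered R² of the weighted no-intercept regression (the model has no
intercept, so centered R² is not well defined).

Clustered standard errors use the patient-level sandwich
`(X'X)⁻¹ (Σ_g X_g'u_g u_g'X_g) (X'X)⁻¹` on the weighted regression with
the small-sample factor `G/(G−1)·(N−1)/(N−K)` and a t reference with G−1
degrees of freedom — the convention of the major commercial package for
clustered panel inference, so results are comparable with published
practice; `small_sample="none"` gives the uncorrected sandwich. The
implementation is hand-assembled numpy and is cross-checked in the tests
against statsmodels' cluster covariance and against explicit
normal-equation/sandwich oracles on random small instances.

Level conversion anchors at the observed mean panel volume in the base
class: `level_l = base_mean · exp(γ_l)`. Age 12 is the default base
because it sits near the middle of the age and scan distributions;
any observed, connected class works.

## Asymmetry tests

The paired (dependent) t-test on per-subject right−left differences, the
one-sample t-test on right/left − 1, and OLS of the per-subject asymmetry
on sex (F = 0 reference, M = 1) with HC1 robust standard errors. Patients
with several scans are collapsed to their across-scan mean right and left
volumes by default — the tests concern a within-individual quantity, and
one observation per patient avoids pretending repeated scans are
independent subjects; `unit="scan"` is available. Degenerate zero-spread
inputs raise when the mean effect is also zero (t is 0/0) and return
t = ±∞, p = 0 otherwise.

## Reliability statistics

ICC from the two-way ANOVA mean-squares decomposition. The default
convention is two-way random effects, absolute agreement, single
measurement — the standard for operator-agreement designs, where
systematic operator offsets should count against agreement; consistency
(two-way) and one-way forms are selectable and the convention used is
labeled in the result. For two repeats the Pearson correlation is reported
alongside. Bland-Altman limits are `bias ± 1.96·SD(differences)` (sample
SD).

The ICC recovery experiment sets log-scale variance components with
`σ_b²/(σ_b² + σ_w²) = 0.945` and estimates the ICC on log-volumes: the
reliability generator is multiplicative lognormal, so the closed-form ICC
is exact on the log scale (on raw mm³ it holds only to first order).

## Phantom volumetry

Phantoms are ellipsoids (or open half-ellipsoids) with known analytic
volume, voxelized on an isotropic grid (default 0.3 mm) by the
voxel-center rule, with a one-voxel bone shell; the half-ellipsoid's
equatorial face is left open and rim fiducials (default 24, with a small
seeded angular jitter emulating manual placement) sit on the bone crest
one voxel outside the cavity rim.

The aperture cap triangulates the rim cloud (Delaunay of the points plus
copies offset two voxels along the outward rim-plane normal) and relabels
every voxel whose center falls inside the resulting convex surface as
barrier. Thickening *outward only* is deliberate: the cap seals the
aperture against a 6-connected flood fill without relabeling any cavity
voxel centers, so the measured volume of a capped half-sphere stays within
a fraction of a percent of 2/3·π·r³. Grid coordinates place voxel centers
at half-integer multiples of the spacing, so no center lies exactly on the
default aperture plane and inside/outside decisions are unambiguous.
Posterior clipping keeps a voxel iff its center lies strictly before the
plane (half-open rule, making split volumes exactly additive). Volume is
`count(label) × spacing³`.

Voxel-center counting has an oscillating signed error: refining the grid
does not monotonically shrink any single phantom's |relative error| (it
fluctuates at the ~10⁻⁴ level, two orders below the 1% accuracy
requirement). Convergence is therefore assessed on the *mean* relative
error over a fixed five-ellipsoid family, which decreases cleanly across
spacings 0.6 → 0.3 → 0.15 mm.

Grids are stored as NIfTI-2 (whose float64 affine preserves the spacing
bit-exactly; NIfTI-1's float32 srows cannot represent 0.3 mm). The five
manually painted openings of a real orbit (fissures, canals) are
represented as already sealed in phantoms; only the anterior cap and the
posterior clipping plane are automated.

## Problem sizes in the tests and acceptance script

Chosen to make Monte-Carlo error comfortably smaller than the assertion
bands: 200 replicates of the 65-patient preset for index recovery (mean
γ̂ SE ≈ 0.002 per class); ten 5000-pair single-side panels for the
variance model (the stage-2 intercept has ~22% relative SD in a *single*
5000-pair draw — Var(ε̂²) = 2σ⁴ makes it intrinsically noisy — so the
mean of ten draws, relative SE ≈ 7%, is the quantity compared to the ±20%
band); 1000 null replicates for test size and 200 for power; 500 seeds of
the 30-orbit × 2-repeat reliability design; and the five-ellipsoid family
at three spacings for volumetry.

## Known limitations

- The index estimates growth between *observed* age classes only; it does
  not interpolate or extrapolate (no spline/continuous-age variant).
- With few clusters the t(G−1) clustered inference is approximate, as in
  any sandwich-based panel analysis.
- The ICC convention behind any particular published coefficient is often
  unstated; results here label the convention explicitly, and different
  conventions give visibly different values when operator offsets exist.
- Phantom capping assumes a roughly planar rim; strongly non-planar rim
  clouds are handled (the cap is a convex surface), but the volume error
  bound of the flat-aperture analysis no longer applies.
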