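# Methods

## Generative model of the optic flow

A planar surface with slant `σ` (tilt fixed at 90°, i.e. slanted about the
horizontal axis) is viewed at distance `d`. A lateral head translation with
instantaneous velocity `v(t)` under fixation of the surface centre produces a
relative rotation rate `ω(t) = v(t)/d`; an independently rotating surface
would add its own term. Inside a small image patch the first-order velocity
field is `v(β) = ω (1 + β tan σ)` with elevation `β`; we treat the
linearization as valid for `|β| ≤ 0.07 rad` (an ~8° patch) and enforce that
bound at the API. The deformation component is the elevation gradient

    def(t) = ω(t) · tan σ,

signed, alternating with the direction of the back-and-forth motion. The
per-trial summary `max_def` is the mean over complete def cycles of the
per-cycle peak `|def|`; a cycle spans two consecutive velocity zero-crossings
of the same sign change (one full period), trailing partial cycles are
dropped, and an entirely unidirectional profile counts as a single cycle.

The exact perspective pinhole projection lives in `synthetic_observer`
(`project_dots`): dots are drawn uniformly in the image (no texture cues) and
back-projected onto the plane, then reprojected through any eye position.
Frame-differencing those projections and regressing per-dot horizontal
angular velocity on elevation recovers `def` within 5% inside the patch,
which is the independent oracle for the linearized model (and vice versa).

## The two estimators

Both estimators share the generative chain

    def_obs | Σ, Ω ~ Normal(Σ·Ω, σ_def)        (rigidity)
    Σ ~ half-Normal(0, σ_Σ)                     (flatness prior, Σ = tan σ)

and differ in the prior on the non-negative rotation magnitude `Ω`:

* **inverse-optics**: `Ω ~ Normal(ω_E, σ_Ω)` truncated at zero, centred on
  the egocentric rotation implied by the measured head motion (stationarity
  assumption);
* **retinal-only**: `Ω ~ half-Normal(0, σ_Ω)` with a broad spread — no
  extra-retinal information.

The readout is the posterior median of the marginal over `Σ` (the Bayes
estimator under absolute-error loss). For the retinal model in the
small-`σ_def` limit the posterior of `log Σ` is exactly symmetric about
`log(k√def)` with `k = √(σ_Σ/σ_Ω)` — substituting `Ω = def/Σ` turns the two
prior factors into `exp(−A cosh 2t)` in `t = log(Σ/k√def)` — so the median
is exactly `k√def`. This is why the rotation prior of the retinal model is a
zero-centred half-Gaussian rather than a bounded uniform density: the
square-root law is exact for it, and `k` has the stated meaning of a ratio
of prior standard deviations. A uniform prior on `[0, B]` yields a median
that drifts from `√(σ_Σ/B)·√def` by up to tens of percent across the
stimulus def range, which we verified numerically before fixing the
parameterization.

### Parameters and defaults

| parameter | meaning | default | why |
|---|---|---|---|
| `σ_Σ` | flatness-prior spread (tangent units) | 3.0 | covers tan 80° = 5.67 with appreciable mass while keeping >99% of prior mass inside the grid |
| `σ_Ω` | rotation-prior spread (rad/s) | 0.1 (stationarity); `σ_Σ/k²` (retinal) | stimulus rotation rates are 0.067–0.332 rad/s; retinal spread is derived from the behavioural slope `k` |
| `σ_def` | def measurement noise | CV mode, 0.05·def | the absolute noise level is a free parameter of the theory; a coefficient-of-variation parameterization (Weber-like precision) keeps the likelihood's relative width constant across regimes. Absolute mode is available. |
| grid | points per axis | 1024 over `Σ ∈ [0, 10]` | see numerical choices |

## Numerical choices

Posteriors are evaluated on a 2-D grid and integrated with trapezoidal
quadrature; the median is the interpolated 50th percentile of the
cumulative marginal.

* **Slant axis**: union of a uniform grid on `[0, 10]` and a geometric
  refinement from `10⁻⁴` to `1` (a 1/Σ-like spike develops near zero when
  the posterior spans decades, e.g. small `k` and small def; a uniform axis
  alone misses it and biases the median upward by several percent).
* **Rotation axis**: uniform over `ω_E ± 6σ_Ω` (clipped at 0) for the
  stationarity prior; geometric from `10⁻⁴σ_Ω` to `6σ_Ω` for the
  zero-centred prior, because the likelihood ridge `Σ·Ω = def` becomes
  narrower than any uniform spacing at small `Ω`. When a broad stationarity
  prior reaches zero the near-origin refinement is added there too.
* Construction fails loudly if the grid covers less than 99% of either
  prior's mass.
* With these axes at 1024 points the veridical-limit error is ≤ 0.3%
  (tolerance 2%), the square-root-law deviation ≤ 0.5% (tolerance 3%), and
  medians are stable within 1% under 2× grid refinement. A uniform 512²
  grid fails both tolerances at the extremes of the stimulus range, which
  is why the default is finer and non-uniform.

## Model contrasts verified

* **Veridical limit**: with `σ_Ω = σ_def = 10⁻³` the inverse-optics median
  recovers `tan σ` within 2% for slants 20–80° at both rotation rates.
* **Monotone bias**: at fixed def the inverse-optics estimate decreases as
  `σ_Ω` grows — for `σ_Ω ≳ 0.3 ω_E`. Below that a small (~2%)
  *over*-estimation appears first: spreading `Ω` symmetrically pushes mass
  along the convex hyperbola `Σ = def/Ω` toward larger slants (a Jensen
  effect) before the flatness prior dominates. The documented ladder
  (`σ_Ω/ω_E ∈ {0.3, 0.6, 1.2, 3, 9}`) sits in the monotone regime.
* **Passive equivalence**: an inverse-optics observer with `σ_Ω ≫ ω_E`
  converges to the retinal-only observer; the discrepancy scales like
  `ω_E/σ_Ω` (2.9% at 15×, 0.5% at 100×, where the 1% agreement is tested).
* **Velocity collapse**: per-velocity no-intercept slopes of estimate on
  `√def` differ by <2% for the retinal model and separate strictly (slower
  translation → larger slope) for the inverse-optics model with
  `σ_Ω = 0.5 ω_E`.

## Synthetic behavioural data

The generator emulates the study design: virtual-surface blocks (active and
passive) with slants {20, 35, 50, 65, 80}°, 5 repetitions, 860 mm distance;
a physical-surface block with {10, 20, 40, 50}°, 4 repetitions, 760 mm;
head-velocity regime assigned between subjects (17/17 of 34 by default);
the passive block replays the active block's def values. Head motion is an
idealized sinusoid of amplitude 25 mm (50 mm peak-to-peak shift) truncated
at 11 half-cycles, giving ~3.0 s stimuli at the 285.6 mm/s peak; `max_def`
is then exactly `(v_peak/d)·tan σ` and invariant to sample rate. Responses
are `max(0, k√def + ε)` with condition slopes `k = {PVV 1.04, AVV 1.88,
AVP 2.41}` and `ε ~ Normal(0, 0.218)` on the tangent scale; an optional
lognormal per-subject jitter on `k` supports mixed-effects-style recovery
tests.

What the generator does *not* emulate: human kinematic variability (real
head movements are not sinusoids, so the experiment's mean-velocity
feedback bands are advisory here and per-trial def varies across
repetitions in real data but not in ours), texture/foreshortening cues of
the physical surface, and any dependence of judgments on simulated slant
beyond def. Consequently passing recovery tests shows the analysis pipeline
is correct and well-calibrated at the design's sample sizes — not that the
square-root law is true of human observers. One visible consequence: the
mean synthetic response (~0.78 tangent units) is higher than a mean
computed over empirically variable def values would be, so the coefficient
of variation of the synthetic data (~0.28) is reported but not asserted.

## Analysis design

The original inference for data of this design would be mixed-effects
regression; here it is fixed-effects regression plus permutation tests,
which keeps the pipeline dependency-light while preserving the scientific
contrasts (the `√def` slope and the velocity effect).

* `no_intercept_slope`: `Σxy/Σx²` with an analytic standard error and an
  agreement statistic.
* `agreement_statistic`: a concordance-type measure,
  `1 − Σ(o−p)² / [Σ(o−m)² + Σ(p−m)²]` with `m` the grand mean of both
  vectors pooled. It is 1 iff observed == predicted, ≤0 when predictions do
  no better than the shared mean, and invariant under a common affine
  change. This algebraic variant is documented rather than asserted to
  match any particular published formula.
* `velocity_effect_test`: OLS of `response ~ 1 + √def + regime(0/1)`. The
  intercept is included deliberately: without it a planted additive regime
  offset is misspecified and the estimate biased (~35% low in our checks).
  The p-value uses Freedman–Lane residual permutation (reduced-model
  residuals permuted in subject-sized blocks): naive shuffling of regime
  labels is anticonservative (measured type-I ≈ 0.12 at nominal 0.05)
  because regime determines the def range and thus the design matrix.
  Freedman–Lane holds the covariate structure fixed; measured type-I error
  is 0.06–0.07.
* `observed_vs_predicted`: OLS of responses on `k_c·√def` with slope CI and
  agreement; slope ≈ 1, intercept ≈ 0 on self-consistent data.

## Problem sizes

Grid posteriors use 1024 points per axis (~0.1 s each). The Monte Carlo
contrast evaluates 5 slants × 2 velocities per model. Parameter recovery
uses the design's own sizes (17 subjects × 25 trials) over 100 seeds.
Type-I calibration uses 120 replicates of 8-subject data sets with 99
permutations each.

## Known limitations

* The estimators marginalize a 2-D grid; no conjugate shortcuts, no tilt
  estimation (tilt is fixed at 90° throughout).
* `def` is consumed as a magnitude; the sign convention of the relative
  rotation is absorbed by working in speeds.
* The printed stimulus durations of the slow regime (11.1 s) cannot be
  reconciled with a 57.7 mm/s-peak sinusoid over 5.5 periods (15.0 s);
  durations are derived from the trajectory model, not used as constraints.
* The square-root law is exact only in the small-measurement-noise limit;
  at CV 0.05 the grid median deviates from it by <0.5% over
  def ∈ [0.05, 3].
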