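# Methods

## The kinematic model behind the generator

The generator idealizes a rolling samara as a rigid span segment of
length S (seed tip to wingtip) carrying a perpendicular chord segment
of length c at a fixed station (default mid-span). Exactly the four
points an experimental pipeline digitizes are emitted: the two span
endpoints and the two chordal edges. The motion is *prescribed*, not
force-integrated — the generator is kinematic plumbing for testing the
estimators, and makes no aerodynamic claim:

- the centre of rotation (the span point at `cor_fraction` from the
  seed tip) descends at exactly V_d while tracing a horizontal circle
  of the precession radius at rate ωp;
- the span axis points radially outward from the helix axis (an
  adjustable azimuth offset exists) at a constant coning angle θ;
- the chord rotates at ωr in the plane perpendicular to the span,
  parameterized in the canonical co-precessing basis
  e₂ = ẑ×û/|ẑ×û|, e₃ = û×e₂;
- one sign, the roll direction, multiplies both angular phases, so the
  generator enforces the observed coupling in which the stochastic
  roll direction sets the precession direction;
- isotropic Gaussian tracking noise (default SD 0.05 cm, a plausible
  sub-millimetre digitization error; the real error structure of
  multi-camera tracking is unreported) is added last, per landmark per
  frame, under a mandatory seed.

Because the span is radial, the point of minimal horizontal
oscillation lies at `cor_fraction − r_p/(S·cosθ)`; with the default
precession radius r_p = 0.25·S and `cor_fraction` = 0.6 the estimated
COR sits at 0.35 of the span. The generator's `cor_fraction` and
radius jointly define the geometry; only at r_p = 0 do the generator
parameter and the estimate coincide, which is how the COR estimator is
validated.

**Units.** Field units at every boundary (cm, cm/s, mm, mg, cm²,
rad/s, degrees); SI only inside the lift model, with conversions
centralized in `samarakin.units`.

**Defaults that are choices, not measurements.** Precession radius
(0.25·S), coning angle (0°), chord station (0.5·S) and the noise SD
are unreported quantities; they are configurable and the package
treats them as free parameters of the emulation.

## Morphology ensembles

Per-species thickness, mass and area are drawn from normals truncated
at ±3 SD (guaranteeing positivity at the published coefficients of
variation). Span is absent from the published summary table, so it is
derived through the shape-factor convention A = f·S·c with f = 0.75
and a sampled aspect ratio AR = S/c ~ N(4.5, 0.7²): a tapered planform
fills about three quarters of its bounding rectangle, and this choice
reproduces the reported 3.6 cm tulip-poplar span from its 2.141 cm²
mean area. Chord follows as c = S/AR.

## Estimators

- **Angular rates** are unwrapped-phase least-squares slopes
  (precession: wingtip azimuth about the helix axis, located by a Kåsa
  circle fit of the horizontal wingtip track; roll: chord angle in the
  co-precessing basis above). Phase-slope fitting is unbiased for
  non-integer cycle counts, unlike spectral peaks at these short
  records. An independent frame-wise cumulative-rotation estimator is
  kept purely as a cross-check in the tests. The roll rate is defined
  relative to the co-precessing frame; at θ = 0 this equals the body
  roll rate about the span, and for small θ it differs by ωp·sinθ
  (<2% at θ = 10° for these species).
- **Descent velocity** is the negated least-squares slope of the
  COR-point vertical track over an integer number of precession cycles
  (full record, with a warning, below one cycle). The COR point is the
  smoothest track on a real samara.
- **COR location** minimizes the horizontal variance of
  seed + s·(wingtip − seed) on a 0.01 grid with parabolic refinement;
  a flat objective (no rotation) returns NaN rather than a number.
- **Angle of attack** treats the local flow at the 0.75-span station
  as the vector sum of the tangential speed 0.75·S·ωp (opposing the
  precession motion) and the upward V_d. α is the signed angle from
  the flow (projected into the span-normal plane) to the chord,
  measured about the span axis and folded to (−90°, 90°] by
  identifying C with −C — the wing has no distinguished face. The
  series is genuinely discontinuous, jumping 90° → −90° twice per roll
  cycle when the surface normal aligns with the flow.
- **Event times.** t_r is the first accumulation of 2π unwrapped roll
  phase (linear interpolation between frames). t_p is the start of the
  first sliding window, one precession period long, in which the
  COR-point vertical speed stays below ε_v·V_d with ε_v = 0.05. These
  thresholds replace the frame-by-frame human judgement of the
  original measurements (stated subjective error <40 ms); ε_v = 0.05
  keeps the detection comfortably inside that error at these frame
  rates. A free-fall-frame input is flagged "not reached", never an
  exception.

## Release transients

Only event times, not transient shapes, are reported for real
releases, so the startup law is a package choice: each rotation's rate
relaxes exponentially toward its steady value after an onset delay
(roll first, precession later — matching the observed ordering), and
the tunnel-frame vertical velocity decays from the full excess drop
−V_d in step with the precession spin-up, optionally toward a nonzero
residual. The five orientation presets (delays 35–230 ms, spin-up time
constants 4–100 ms, residual 0.2 for the span-vertical seed-down case)
were set so the emulated t_r/t_p land near the reported per-orientation
means at typical species rates; they are qualitative emulations, not
fitted dynamics. The closed-form phase integral of the spin-up law
(`time_to_first_roll`) provides the analytic counterpart used to
validate event detection.

## The wobble model

Eqs as implemented: C_L(t) = C₁sin(2πt/T) + C₂ (constants 0.9, 0.7
from the fluttering/tumbling-plate literature), F = ½C_LρV_d²A with
ρ = 1.23 kg/m³, τmax = (S/4)·Fmax with Fmax = ½(C₁+C₂)ρV_d²A (the peak
of the sinusoid), I = mb²/12 + m(S/4)², and
y_max = (3/32)Sπ²ω̇max/ωr² — identical to the kinematic statement
"lever arm 3S/4, acceleration ½ω̇maxt² over a quarter period T/4",
which the tests verify as an identity. Added-mass effects are
neglected throughout.

**The factor-4 audit.** The closed form
ω̇max = 3(C₁+C₂)ρV_d²AS/(2mb²+6mS²) is *not* τmax/I with the τmax and
I above: algebraically, composed/printed = 4(b²+3S²)/(4b²+3S²), which
is ≈3.9994 at b = 0.46 mm, S = 3.9 cm — essentially, but not exactly,
4. (The printed closed form is exactly what τmax/I would give for a
parallel-axis offset of S/2 instead of S/4.) The default mode
evaluates the closed form, which reproduces the documented
197 rad/s² and the 27 µm excursion; the composed mode and the ratio
are exposed via `angular_acceleration_audit` and the discrepancy is
deliberately surfaced rather than resolved.

A plausibility guard rejects parameter sets outside samara-scale SI
ranges, which catches the classic error of passing cm/s, cm², mg or mm
values unconverted; `LiftModelParams.from_field_units` does the
conversion correctly.

## Scaling analysis

Power laws are fitted by OLS of log₁₀y on log₁₀x (statsmodels);
exponent = slope, prefactor = 10^intercept, with 95% CIs from the
regression. R² is reported on the log scale — the scale of the fit —
because the convention used for the published R² values is unstated;
the straight-line R² on the original scale is reported alongside for
the power-vs-linear model comparison, and a nonlinear least-squares
variant on the original scale exists but is off the default path. No
multiple-testing correction is applied (per-fit R² and CIs are
reported instead, mirroring the original presentation).

Synthetic scaling datasets use x ~ Uniform(a,b) and
y = k·x^β·10^ε, ε ~ N(0, σ²). To match a target expected log-scale R²,
σ is set from the closed-form variance of log₁₀ of a uniform variate:
σ² = β²·Var(log₁₀X)·(1−R²)/R². For β = −1.44 on b ∈ [0.40, 0.52] mm
and R² = 0.81 this gives σ ≈ 0.023 dex.

The drag balance mg ~ ½C_DρV_d²A·cosθ gives the exponent identity
e_V = (e_m − e_A)/2, hence (−3/2, 1/2) → V_d ~ 1/b; θ defaults to 0
(cosθ = 1) when unmeasured. The drag-coefficient calibration solves
the balance across specimens by least squares (exact inversion for a
single specimen). The volume-conservation check fits
origin-constrained slopes of m against b·A per species — an effective
density in g/cm³ (≈0.42 for *F. americana* at the species means).

## What the synthetic data do and do not show

The generator reproduces the *kinematic structure* of dual-axis
descent (rates, coupling, signs, helical geometry, startup ordering,
tracking noise), so passing tests demonstrate that the estimators
recover what the tracks contain, at realistic noise, frame rate and
record length. It does not model aerodynamics — no leading-edge
vortex, no force-driven coupling between morphology and rates (rates
are drawn from per-species statistics, not computed from shape), no
unexplained slow coning oscillation, and traits are drawn
independently within species, so synthetic cross-species scaling
ensembles are weaker-trending than real pooled specimens (the
power-law machinery is therefore validated on dedicated synthetic
power-law datasets, where ground truth is exact). Conclusions about
real samaras rest on the analytical models and on the estimators'
demonstrated recovery properties, not on the generator's defaults.

## Problem sizes

Default validation sizes: 1 s records at 1000 fps for recovery tests
(≈13 precession cycles at the fastest species), 90-trial ensembles
(30 specimens × 3 flights, 0.5 s each) for the ensemble statistics,
200 replicates × n = 30 for exponent recovery, 100 seeds for the
drag-coefficient Monte Carlo. These match the scale of the original
study design (30 specimens, 3 replicate flights, 10 per species) while
keeping the full suite fast.

## Known limitations

- The COR estimator assumes the precession radius is small enough that
  the minimal-oscillation point lies on the span segment; configured
  radii above `cor_fraction·S` would clip at 0.
- Event detection assumes the tunnel frame and a reasonably steady
  final third of the record for the precession-period estimate.
- The roll-rate convention (co-precessing frame) matters at large
  coning angles; both generator and estimator share it, but tracks
  from other sources with θ ≳ 20° would need the ωp·sinθ correction.
- The transient presets emulate reported event times, not measured
  spin-up dynamics.
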