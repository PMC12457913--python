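# samarakin

Descent kinematics, scaling and quasi-steady lift analysis of **rolling
samaras** — the winged seeds of ash (*Fraxinus americana*,
*F. excelsior*) and tulip poplar (*Liriodendron tulipifera*) that fall
with a *dual-axis* rotation: the span axis precesses about the vertical
at rate ωp, tracing a helix, while the blade simultaneously rolls
end-over-end about its own span axis at the much faster rate ωr.

The package is for biomechanicists and fluid-dynamicists working with
3-D landmark tracks of falling seeds (or any passively rotating plate).
It provides:

- **`samarakin.synthetic`** — a rigid-body generator of the four
  landmark tracks such experiments digitize (seed tip, wingtip, two
  chordal edges), with configurable descent speed Vd, rates ωp and ωr,
  coning angle θ, centre-of-rotation location, release transients
  (exponential spin-up after orientation-dependent onset delays) and
  Gaussian tracking noise; plus morphology ensembles drawn from
  published per-species statistics and synthetic power-law datasets.
- **`samarakin.kinematics`** — estimators recovering every descent
  quantity from a track: Vd (COR-point vertical slope over whole
  precession cycles), ωp and ωr with their common direction sign
  (unwrapped-phase least-squares slopes), θ, the COR span fraction
  (minimal horizontal oscillation), the angle-of-attack series

  α(t) = signed angle between the chord C and the local flow
  R = (0.75·S·ωp, Vd), folded to (−90°, 90°],

  the coupling ratio |ωr|/|ωp| (≈5.2–5.6 across species), and the
  release events t_r (first full roll) and t_p (stable precession =
  levitation in the tunnel frame).
- **`samarakin.wobble`** — the sinusoidal roll-lift model
  C_L(t) = C₁·sin(2πt/T) + C₂ with C₁ = 0.9, C₂ = 0.7,
  F(t) = ½·C_L·ρ·V_d²·A, peak torque τmax = (S/4)·Fmax, thin-plate
  inertia I = mb²/12 + m(S/4)², the peak roll-induced angular
  acceleration ω̇max = 3(C₁+C₂)ρV_d²AS/(2mb²+6mS²) and the quarter-cycle
  wingtip excursion y_max = (3/32)·S·π²·ω̇max/ωr² — micrometres, hence
  no visible wobble.
- **`samarakin.scaling`** — log–log power-law regression (mass
  m ~ b^−1.44, area A ~ b^0.46, rates ωr ~ b^−0.84, ωp ~ b^−0.90
  against wing thickness b), the drag balance
  mg ~ ½·C_D·ρ·V_d²·A·cosθ whose convenient exponents (−3/2, 1/2)
  give **V_d ~ 1/b**, drag-coefficient calibration, the classical
  wing-loading predictor (mg/A)^½, and the volume-conservation check
  m vs b·A.

## Worked example

```sh
python examples/02_wobble_worked_example.py
```

```
lift coefficient      : -0.2 .. +1.6 over one roll period T = 12.3 ms
peak lift force       : 3.615e-04 N
peak torque (arm S/4) : 3.525e-06 N m
moment of inertia     : 4.469e-09 kg m^2
peak ang. accel.      : 197.2 rad/s^2 (closed form)
                        788.8 rad/s^2 (composed tau_max/I; ~4x, see docs/methods.md)
peak wingtip excursion: 27.3 um
```

The representative samara (V_d = 131 cm/s, A = 2.141 cm², S = 3.9 cm,
m = 47 mg, b = 0.46 mm, ωr = 510.2 rad/s) experiences a strong periodic
lift modulation, but the resulting peak angular acceleration acts for
only a quarter roll cycle (~3 ms), moving the wingtip ≈27 µm — far
below video resolution, which is why rolling samaras trace smooth
helices despite rolling five-to-six times per precession circuit.

`examples/01_simulate_and_recover.py` shows the generator → estimator
round trip (all parameters recovered to <0.1% on a noiseless track),
`03_thickness_scaling.py` the ensemble pipeline and power-law fits, and
`04_release_transient.py` the orientation-dependent release events.

A thin CLI mirrors the library: `samarakin simulate|transient|analyze|
wobble|scaling|report`, each writing a JSON run manifest beside its
output for bit-reproducibility.

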