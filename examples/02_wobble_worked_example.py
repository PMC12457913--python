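"""Why rolling does not visibly shake the wingtip.

Evaluates the sinusoidal roll-lift model at the representative samara
(Vd = 131 cm/s, A = 2.141 cm², S = 3.9 cm, m = 47 mg, b = 0.46 mm,
ωr = 510.2 rad/s).  The peak roll-induced torque, acting over a quarter
roll cycle, moves the wingtip by only tens of micrometres — far below
what high-speed video could resolve as wobble.
"""

from samarakin import evaluate_lift_model, representative_params

params = representative_params()
res = evaluate_lift_model(params)

print(f"lift coefficient      : {res.CL_series.min():+.1f} .. "
      f"{res.CL_series.max():+.1f} over one roll period T = {params.T*1e3:.1f} ms")
print(f"peak lift force       : {res.F_max:.3e} N")
print(f"peak torque (arm S/4) : {res.tau_max:.3e} N m")
print(f"moment of inertia     : {res.I:.3e} kg m^2")
print(f"peak ang. accel.      : {res.omega_dot_max_printed:.1f} rad/s^2 "
      "(closed form)")
print(f"                        {res.omega_dot_max_composed:.1f} rad/s^2 "
      "(composed tau_max/I; ~4x, see docs/methods.md)")
print(f"peak wingtip excursion: {res.y_max_um:.1f} um")
print("\nA ~27 um excursion on a ~4 cm blade is invisible at 1000 fps:")
print("the roll modulates lift strongly but far too briefly to wobble the tip.")
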