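"""Simulate calcium-tension curves at the five standard sarcomere lengths.

Uses the published per-curve parameter sets to integrate the tension ODE
over each sarcomere length's single-overlap region, then summarizes each
curve: EC50 (calcium at half the tension reached at 10 uM), peak tension,
and the apparent Hill coefficient of the best Hill fit.
"""

from mechchem import SarcomereGeometry, ca_tension_curve, peak_tension_change, presets
from mechchem.metrics import summarize_curve

curves = {}
print(f"{'SL (um)':>8} {'x_max (um)':>11} {'EC50 (uM)':>10} {'peak (S)':>9} {'nH':>5}")
for sl in presets.SARCOMERE_LENGTHS:
    geom = SarcomereGeometry(sl=sl)
    curve = ca_tension_curve(presets.PER_CURVE[sl], geom)
    curves[sl] = curve
    s = summarize_curve(curve)
    print(f"{sl:>8.2f} {geom.x_max:>11.3f} {s.ec50:>10.2f} {s.peak_tension:>9.3f} "
          f"{s.apparent_n_h:>5.2f}")

change = peak_tension_change(curves[1.85], curves[2.25])
print(f"\nPeak tension at 10 uM rises {change:.1f}% from SL 1.85 to 2.25 um.")
print("Longer sarcomeres expose more single overlap (larger x_max), so more")
print("cross-bridges can form: tension rises and EC50 falls (higher calcium")
print("sensitivity), while the apparent cooperativity sits around 6-7 --")
print("far above the intrinsic binding cooperativity of n = 3.")
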