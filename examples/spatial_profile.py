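"""Tension and troponin activation along the thin filament.

At fixed calcium, tension S(x) accumulates from the free end of the
single-overlap region (x = 0) toward the Z-disk, and the activated
troponin fraction P(x) rises with it: the mechanochemical feedback in
action.  Mid-protocol calcium levels (3, 4, 5 uM) at SL = 2.05 um.
"""

from mechchem import SarcomereGeometry, integrate_tension, presets

geom = SarcomereGeometry(sl=2.05)
params = presets.PER_CURVE[2.05]
print(f"SL = {geom.sl} um, single overlap x_max = {geom.x_max:.3f} um")
print(f"{'Ca (uM)':>8} {'S(x_max) (S)':>13} {'P(0)':>6} {'P(x_max)':>9}")
for ca in (3.0, 4.0, 5.0):
    prof = integrate_tension(params, ca=ca, x_max=geom.x_max)
    print(f"{ca:>8.1f} {prof.total_tension:>13.4f} {prof.p[0]:>6.3f} "
          f"{prof.p[-1]:>9.3f}")

print("\nP(0) is the activation with no tension support; near the Z-disk the")
print("accumulated tension locks calcium onto troponin and P approaches 1 at")
print("4-5 uM (a plateau: that stretch of filament is fully activated).  The")
print("model thus predicts cross-bridges cluster toward the Z-disk end.")
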