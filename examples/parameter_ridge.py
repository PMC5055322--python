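"""The k_tnca0-c_s identifiability ridge.

Scaling the zero-tension dissociation constant k_tnca0 up by a factor a
can be compensated almost exactly by raising the tension sensitivity c_s:
the calcium-tension curve barely changes.  The scan quantifies this
compensation law empirically for the SL = 2.05 um parameter set.
"""

from mechchem import SarcomereGeometry, presets, ridge_scan

params = presets.PER_CURVE[2.05]
table = ridge_scan(params, SarcomereGeometry(sl=2.05), [1.0, 1.1, 1.2, 1.5, 2.0])

print(f"reference: k_tnca0 = {params.k_tnca0} uM, c_s = {params.c_s} 1/S")
print(f"{'a':>5} {'k0*a (uM)':>10} {'best c_s (1/S)':>15} {'curve shift (% peak)':>21}")
for _, r in table.iterrows():
    print(f"{r['a']:>5.2f} {r['a'] * params.k_tnca0:>10.2f} {r['c_s_opt']:>15.3f} "
          f"{100 * r['curve_rmse_rel']:>21.3f}")

print("\nDoubling k_tnca0 moves the curve by only a few percent of peak once")
print("c_s re-adjusts: the data constrain a ridge in (k_tnca0, c_s) rather")
print("than a point, so fitted values of the pair should be read jointly.")
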