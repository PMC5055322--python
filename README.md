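# mechchem

A mechanochemical model of the steady-state calcium–tension relationship
in cardiac sarcomeres, for muscle physiologists and cardiac modelers who
need a mechanistic (rather than purely empirical) description of
force–pCa data.

## The model

Skinned cardiac muscle develops tension with striking steepness as bath
calcium rises: Hill fits to such data give apparent Hill coefficients
n<sub>H</sub> ≈ 7, while calcium binding to troponin measured with tension
blocked is only cooperatively ~3. This package implements the hypothesis
that the gap is *mechanical*: tension in the thin filament raises the
energy needed to detach calcium from troponin, so regions under load hold
their calcium.

Along the single-overlap region of one thin filament (x = 0 at the
mid-line end, x_max at the Z-disk end, x_max set by sarcomere length via
the standard overlap geometry), the accumulated tension S(x) obeys

    dS/dx = C_f · P(S),   S(0) = 0
    P(S)  = 1 / (1 + exp(n·(−C_s·S − ln([Ca²⁺]/K_TnCa0))))

where P is the activated-troponin fraction, C_f the force density at full
activation (S·µm⁻¹, with S the tension unit of the reference skinned-muscle
data), C_s (S⁻¹) the tension sensitivity of the binding equilibrium
K(x) = K_TnCa0·e^(−C_s·S(x)), and n = 3 the intrinsic cooperativity of
calcium binding to an in-register troponin pair. Total filament tension is
S(x_max). With C_s = 0 the model collapses to a Hill curve with
coefficient n; with C_s > 0 the tension feedback boosts the *apparent*
fitted Hill coefficient to ~7 without any extra chemical cooperativity.

The package provides the ODE simulation (spatial profiles and
calcium–tension curves), a discrete cross-bridge ladder as an independent
check, the classical Hill model as comparator, per-curve and
shared-parameter fitting, curve metrics (EC50, peak tension, apparent
n<sub>H</sub>), a synthetic skinned-muscle data generator, and a CLI.

## Worked example

```python
from mechchem import SarcomereGeometry, ca_tension_curve, presets
from mechchem.metrics import summarize_curve

for sl in (1.85, 2.05, 2.25):
    curve = ca_tension_curve(presets.PER_CURVE[sl], SarcomereGeometry(sl=sl))
    s = summarize_curve(curve)
    print(f"SL {sl} µm: EC50 {s.ec50:.2f} µM, peak {s.peak_tension:.3f} S, "
          f"apparent nH {s.apparent_n_h:.2f}")
```

prints

```
SL 1.85 µm: EC50 4.12 µM, peak 0.981 S, apparent nH 7.32
SL 2.05 µm: EC50 3.55 µM, peak 1.251 S, apparent nH 7.04
SL 2.25 µm: EC50 3.14 µM, peak 1.440 S, apparent nH 5.92
```

EC50 is the calcium giving half the tension reached at the 10 µM protocol
maximum; it falls with sarcomere length (length-dependent calcium
sensitization) while peak tension rises 46.8% — more single overlap means
more cross-bridges. The apparent n<sub>H</sub> is the Hill coefficient a
3-parameter Hill fit assigns to the simulated curve: around 6–7, more than
double the intrinsic n = 3, the mechanochemical boost in action.

The `examples/` scripts walk one capability each (curve simulation,
spatial profiles, synthetic-data fitting, Hill comparison, the
K_TnCa0–C_s identifiability ridge) and print annotated output. The same
operations are available from the shell:

```
mechchem simulate --sl 2.05 --ca 5 --cf 1.97 --cs 7.32 --k0 8.63 \
    --profile profile.csv --curve curve.csv
mechchem generate --model mechchem --preset table1-shared --seed 7 --out d.csv
mechchem fit d.csv --mode shared --out params.json
```

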