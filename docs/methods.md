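# Methods

## Model and assumptions

The model describes steady-state, isometric tension in a single
representative thin filament. Its assumptions, in order of consequence:

1. Chemical equilibrium. All binding reactions are equilibrated; there is
   no time dependence. This matches skinned-muscle protocols, where
   tension is read after steady state, and excludes twitch dynamics.
2. Activation implies force. Wherever the troponin/tropomyosin unit is
   activated, cross-bridges are assumed bound and generating equal force;
   the cross-bridge density is proportional to the activated fraction
   P(x). No explicit cross-bridge cycle is modeled.
3. Cross-bridges form only in the single-overlap region, whose length
   x_max follows from sarcomere length and the filament-length constants
   (see Geometry).
4. Mechanochemical coupling. The energy to detach calcium from troponin
   grows linearly with local filament tension, so the dissociation
   constant is K(x) = K_TnCa0·exp(−C_s·S(x)). This is the model's core
   hypothesis; C_s = 0 switches it off and the model reduces exactly to a
   Hill curve with coefficient n.
5. Intrinsic cooperativity n = 3 for calcium binding to an in-register
   troponin pair, per tension-blocked trabecula measurements. n is held
   fixed in all fits (it is strongly confounded with C_s if freed).
6. Passive tension (titin, extracellular matrix) is excluded; all
   tensions are active tensions in the data's arbitrary unit S.

The resulting initial-value problem, dS/dx = C_f·P(S) with S(0) = 0, is
the entire mechanical model; every other quantity in the package is
derived from its solutions.

## Parameters

| symbol  | meaning                               | unit   | default / range |
|---------|---------------------------------------|--------|-----------------|
| C_f     | force density at full activation      | S·µm⁻¹ | ~1.9 (fit bounds 0.5–5) |
| C_s     | tension sensitivity of Ca–Tn binding  | S⁻¹    | ~2.7–9.3 across SL (bounds 0–200) |
| K_TnCa0 | zero-tension dissociation constant    | µM     | ~5.7–10.1 across SL (bounds 0.5–1000) |
| n       | intrinsic cooperativity               | —      | 3, fixed |
| SL      | sarcomere length                      | µm     | protocol 1.85–2.25; accepted 1.5–2.4 |

The published per-curve, shared and Hill parameter blocks for the five
protocol sarcomere lengths ship in `mechchem.presets`. C_f is stored in
S·µm⁻¹ (numerically equal to the printed 10⁶·m⁻¹S). The wide k_tnca0
bound accommodates the n = 1 refit (K_TnCa0 ≈ 619 µM).

## Geometry

Single-overlap length uses the Rice et al. (2008) formulation:
x_max = min(thick/2, SL/2) − max(thin − SL/2, bare/2), with defaults
thick = 1.65 µm, thin = 1.2 µm, bare zone = 0.1 µm, all configurable.
Over SL 1.85–2.25 µm this gives x_max = 0.55–0.75 µm, non-decreasing in
SL. Double-overlap mechanical interference is not modeled beyond its
effect on x_max.

## Numerical choices

- ODE integration: `scipy.integrate.solve_ivp` (RK45) with rtol 1e-8,
  atol 1e-12. The right-hand side is smooth, bounded by C_f and
  non-stiff. Calcium–tension curves integrate all grid concentrations as
  one vector IVP (the components are independent; the error norm is
  controlled jointly, which the oracle tests show costs nothing at these
  tolerances). Profiles are sampled on a uniform 512-point x-grid.
- P is evaluated through `scipy.special.expit`, so extreme exponents
  saturate to 0/1 instead of overflowing.
- The discrete cross-bridge ladder (the model's stepwise original, and
  the independent oracle for the continuum ODE) uses the left-Riemann
  convention: site j's force is C_f·Δx·P(S at site j−1). It converges to
  the ODE at first order in Δx.
- Calcium grid: 200 log-spaced points over [0.001, 10] µM, the protocol
  range of the reference experiments.
- Peak tension is defined as tension at the top of the calcium grid
  (10 µM), matching how a bounded experimental protocol reports a
  maximum — not the C_f·x_max asymptote. Whether the original analysis
  used the 10 µM value or the asymptote is not stated; the grid-peak
  convention is used consistently here and shifts EC50 by well under the
  reporting precision for the steep curves in question.
- EC50: monotone piecewise-cubic (PCHIP) interpolation of tension against
  log-calcium, followed by bracketed root-finding of the half-peak
  crossing. A curve that never reaches half its peak is an error, not a
  number.
- Fitting: bounded trust-region least squares
  (`scipy.optimize.least_squares`) in linear tension space, mirroring the
  unweighted RMSE criterion. Five multi-starts with a fixed seed guard
  against the narrow valley created by n_H ≈ 7 (Hill) and by the
  K_TnCa0–C_s ridge (mechanochemical model). The shared fit seeds
  (C_f, C_s) from the mean of per-curve fits, then re-optimizes all
  2 + n_SL parameters jointly — a genuine joint optimum, reported per-SL.
- Identifiability: scaling K_TnCa0 by a and re-optimizing C_s reproduces
  the reference curve to under ~1% of peak for a up to 2 (`ridge_scan`).
  Parameter values of that pair should therefore be interpreted jointly;
  curve-space agreement is the meaningful recovery criterion. The
  printed compensation law relating a·K_TnCa0 to a³·C_s is dimensionally
  odd as stated, so the package characterizes the ridge empirically
  rather than asserting that algebra.

## Synthetic data generator

`generate_dataset` emulates skinned-muscle force–pCa measurements: for
each sarcomere length it evaluates a generating curve (mechanochemical or
Hill) on a calcium design of 18 log-spaced points over [1, 10] µM plus 3
sub-threshold points, adds homoscedastic Gaussian tension noise
(default σ = 0.02 S, comparable to the published residual RMSEs of
0.012–0.053 S), and clips at zero (skinned preparations cannot report
negative active tension). It does **not** emulate: heteroscedastic or
run-down drift in real preparations, sarcomere-length dispersion within a
preparation (which smears the sharp low-calcium bend of real curves), or
correlated errors from figure digitization. Passing recovery tests on
this generator therefore demonstrates correctness of the fitting
machinery under the stated noise model, not fidelity to every property of
the real measurements.

## Problem sizes

The validation suite simulates 200-point curves at five sarcomere
lengths, cross-checks the adaptive solver against fixed-step RK4
(Δx = 1e-4 µm) on 20 parameter/calcium combinations, runs ladder
convergence up to 4096 sites, and performs the shared fit on 105 noisy
synthetic points — sizes chosen to match the protocol of the reference
experiments while keeping the full suite under a minute.

## Known limitations and open points

- No cross-bridge cycle, no twitch/relaxation dynamics: steady state
  only.
- Per-curve apparent n_H at SL 2.25 µm comes out ≈ 5.9 (its fitted C_s
  is the smallest of the block); the shared-parameter block yields
  6.85–7.02 across all SLs. The "boost to ~7" claim is cleanest for the
  shared configuration, which is also the physiologically preferred one
  (a single mechanochemical mechanism, length entering only through
  K_TnCa0 and geometry).
- The source analysis's narrative mentions K_TnCa0 decreasing "from 16.6
  down to 11.8 µM", which matches neither published parameter block
  (10.09→5.73 per-curve, 9.26→7.48 shared). The discrepancy is noted and
  deliberately not reconciled; the presets carry the tabulated values.
- Simulated EC50s here (4.12 and 3.14 µM at SL 1.85/2.25) sit ~1.5%
  below the originally reported 4.18/3.17 µM; the original fits were made
  against figure-digitized data not available in numeric form, so exact
  agreement is not expected.
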