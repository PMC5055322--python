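"""Published parameter sets for the five skinned-muscle sarcomere lengths.

These are the fitted constants reported for the Dobesh et al. skinned
cardiac-muscle calcium–tension measurements at sarcomere lengths 1.85,
1.95, 2.05, 2.15 and 2.25 µm: a per-curve block (all three model constants
refitted at each SL), a shared block (c_f and c_s fixed across SL, only
the zero-tension dissociation constant varying), and the three-parameter
Hill fits to the same data.

c_f values are stored in S·µm⁻¹ (the published table prints 10⁶·m⁻¹S,
numerically identical).
"""

from __future__ import annotations

from .core import ModelParams
from .hill import HillParams

__all__ = [
    "SARCOMERE_LENGTHS",
    "PER_CURVE",
    "SHARED",
    "SHARED_C_F",
    "SHARED_C_S",
    "HILL",
    "N_SWEEP_SL205",
]

#: The five sarcomere lengths (µm) of the measurement protocol.
SARCOMERE_LENGTHS = (1.85, 1.95, 2.05, 2.15, 2.25)

#: Per-curve fits: each SL gets its own (c_f, c_s, k_tnca0), n = 3.
PER_CURVE: dict[float, ModelParams] = {
    1.85: ModelParams(c_f=1.85, c_s=9.27, k_tnca0=10.09),
    1.95: ModelParams(c_f=1.95, c_s=8.66, k_tnca0=9.46),
    2.05: ModelParams(c_f=1.97, c_s=7.32, k_tnca0=8.63),
    2.15: ModelParams(c_f=1.96, c_s=4.61, k_tnca0=7.14),
    2.25: ModelParams(c_f=1.95, c_s=2.73, k_tnca0=5.73),
}

SHARED_C_F = 1.93  # S·µm⁻¹, average across SLs
SHARED_C_S = 6.5  # S⁻¹, average across SLs

#: Shared fit: c_f and c_s pinned at their averages, k_tnca0 per SL.
SHARED: dict[float, ModelParams] = {
    1.85: ModelParams(c_f=SHARED_C_F, c_s=SHARED_C_S, k_tnca0=9.26),
    1.95: ModelParams(c_f=SHARED_C_F, c_s=SHARED_C_S, k_tnca0=8.56),
    2.05: ModelParams(c_f=SHARED_C_F, c_s=SHARED_C_S, k_tnca0=8.18),
    2.15: ModelParams(c_f=SHARED_C_F, c_s=SHARED_C_S, k_tnca0=7.91),
    2.25: ModelParams(c_f=SHARED_C_F, c_s=SHARED_C_S, k_tnca0=7.48),
}

#: Hill-type fits to the same data (Ca50 µM, n_H, S_max S).
HILL: dict[float, HillParams] = {
    1.85: HillParams(s_max=0.90, ec50=4.28, n_h=7.3),
    1.95: HillParams(s_max=1.04, ec50=3.9, n_h=7.5),
    2.05: HillParams(s_max=1.14, ec50=3.6, n_h=7.5),
    2.15: HillParams(s_max=1.22, ec50=3.4, n_h=7.2),
    2.25: HillParams(s_max=1.32, ec50=3.16, n_h=6.9),
}

#: Intrinsic-cooperativity sweep at SL = 2.05 µm: best fits with n pinned
#: at 1, 2 and 3 (c_f converted from nm⁻¹S to S·µm⁻¹, i.e. ×10³).
N_SWEEP_SL205: dict[int, ModelParams] = {
    1: ModelParams(c_f=2.93, c_s=134.90, k_tnca0=618.97, n=1),
    2: ModelParams(c_f=2.20, c_s=24.07, k_tnca0=22.14, n=2),
    3: ModelParams(c_f=1.97, c_s=7.32, k_tnca0=8.63, n=3),
}
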