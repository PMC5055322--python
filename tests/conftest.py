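"""Shared fixtures and independent numerical oracles.

The oracles here deliberately avoid the package's own integration path:
``rk4_total_tension`` is a fixed-step classical Runge–Kutta march written
directly against the model's right-hand side, used to cross-check the
adaptive solver.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from mechchem import ModelParams, SarcomereGeometry, presets


def rk4_total_tension(params: ModelParams, ca: float, x_max: float,
                      dx: float = 1e-4) -> float:
    """Fixed-step RK4 integration of dS/dx = c_f * P(S); independent oracle."""
    log_term = math.log(ca / params.k_tnca0)

    def f(s: float) -> float:
        z = params.n * (-params.c_s * s - log_term)
        if z > 700:
            return 0.0
        return params.c_f / (1.0 + math.exp(z))

    n_steps = max(int(round(x_max / dx)), 1)
    h = x_max / n_steps
    s = 0.0
    for _ in range(n_steps):
        k1 = f(s)
        k2 = f(s + 0.5 * h * k1)
        k3 = f(s + 0.5 * h * k2)
        k4 = f(s + h * k3)
        s += h * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
    return s


def hill_closed_form(c_f: float, k0: float, n: float, ca, x_max: float):
    """Analytic tension for the decoupled model (c_s = 0): linear in x."""
    ca = np.asarray(ca, dtype=float)
    return c_f * x_max / (1.0 + (k0 / ca) ** n)


@pytest.fixture(scope="session")
def per_curve_params() -> dict[float, ModelParams]:
    return presets.PER_CURVE


@pytest.fixture(scope="session")
def shared_params() -> dict[float, ModelParams]:
    return presets.SHARED


@pytest.fixture(scope="session")
def geometries() -> dict[float, SarcomereGeometry]:
    return {sl: SarcomereGeometry(sl=sl) for sl in presets.SARCOMERE_LENGTHS}


@pytest.fixture(scope="session")
def oracle_combos(per_curve_params) -> list[tuple[ModelParams, float, float]]:
    """(params, ca, x_max) combinations spanning the protocol: 5 SLs x 4
    calcium levels covering sub-threshold, steep region and saturation."""
    combos = []
    for sl, p in per_curve_params.items():
        x_max = SarcomereGeometry(sl=sl).x_max
        for ca in (1.0, 3.0, 5.0, 10.0):
            combos.append((p, ca, x_max))
    return combos
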