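"""Mechanochemical model of thin-filament tension generation.

The model couples the calcium–troponin binding equilibrium to the
mechanical tension carried by the thin filament.  Calcium binds an
in-register troponin pair with intrinsic cooperativity ``n``; each
activated troponin exposes cross-bridge binding sites, and every bound
cross-bridge adds its force to the tension ``S(x)`` carried by the thin
filament between position ``x`` and the Z-disk.  The mechanochemical
hypothesis is that this tension lowers the free energy of the
calcium-bound state, scaling the dissociation equilibrium constant as

    K(x) = K0 * exp(-c_s * S(x)),

so that regions under high tension hold on to their calcium.  With the
activated fraction

    P(x) = 1 / (1 + (K(x) / [Ca])**n)

and a force density ``c_f * P(x)`` of bound cross-bridges, the tension
obeys the initial-value problem

    dS/dx = c_f * P(S(x)),      S(0) = 0,

integrated over the single-overlap region ``0 <= x <= x_max``.  The total
tension the filament exerts on the Z-disk is ``S(x_max)``.

Units: µm for length, µM for calcium, and the arbitrary sarcomere-tension
unit S of the skinned-muscle data for tension; ``c_f`` is S·µm⁻¹ and
``c_s`` is S⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.integrate import solve_ivp
from scipy.special import expit

from .geometry import SarcomereGeometry

__all__ = [
    "ModelParams",
    "TensionProfile",
    "CaTensionCurve",
    "equilibrium_constant",
    "activation_fraction",
    "integrate_tension",
    "total_tension",
    "discrete_ladder",
    "ca_tension_curve",
    "default_ca_grid",
]

#: Calcium range (µM) of the standard simulation protocol.
CA_RANGE = (0.001, 10.0)

#: Points on the default log-spaced calcium grid.
CA_GRID_SIZE = 200

#: Points on the uniform x-grid used for spatial profiles.
PROFILE_GRID_SIZE = 512

_RTOL = 1e-8
_ATOL = 1e-12


@dataclass(frozen=True)
class ModelParams:
    """The constants defining one model instance.

    Parameters
    ----------
    c_f:
        Force density at full troponin activation, S·µm⁻¹.
    c_s:
        Tension sensitivity of the binding equilibrium, S⁻¹; ``c_s = 0``
        switches the mechanochemical coupling off.
    k_tnca0:
        Calcium–troponin dissociation constant at zero tension, µM.
    n:
        Intrinsic cooperativity coefficient of calcium binding to the
        in-register troponin pair; 3 in trabeculae with tension blocked.
    """

    c_f: float
    c_s: float
    k_tnca0: float
    n: float = 3.0

    def __post_init__(self) -> None:
        if not self.c_f > 0:
            raise ValueError(f"c_f must be > 0, got {self.c_f!r}")
        if not self.c_s >= 0:
            raise ValueError(f"c_s must be >= 0, got {self.c_s!r}")
        if not self.k_tnca0 > 0:
            raise ValueError(f"k_tnca0 must be > 0, got {self.k_tnca0!r}")
        if not self.n >= 1:
            raise ValueError(f"n must be >= 1, got {self.n!r}")


@dataclass(frozen=True)
class TensionProfile:
    """Tension and activation sampled along the single-overlap region.

    ``x`` ascends from 0 to ``x_max``; ``s`` is the accumulated tension at
    each position (``s[0] = 0``) and ``p`` the activated-troponin fraction,
    all at fixed calcium ``ca`` (µM) and sarcomere length ``sl`` (µm).
    """

    x: NDArray[np.float64]
    s: NDArray[np.float64]
    p: NDArray[np.float64]
    ca: float
    sl: float | None = None

    @property
    def total_tension(self) -> float:
        """Tension acting on the Z-disk, ``S(x_max)``."""
        return float(self.s[-1])


@dataclass(frozen=True)
class CaTensionCurve:
    """Steady-state total tension across a calcium grid at fixed SL."""

    ca: NDArray[np.float64]
    tension: NDArray[np.float64]
    sl: float
    params: ModelParams | None

    @property
    def peak_tension(self) -> float:
        """Tension at the top of the calcium grid (the protocol maximum)."""
        return float(self.tension[-1])


def default_ca_grid(
    num: int = CA_GRID_SIZE,
    lo: float = CA_RANGE[0],
    hi: float = CA_RANGE[1],
) -> NDArray[np.float64]:
    """Log-spaced calcium grid (µM) of the standard simulation protocol."""
    return np.geomspace(lo, hi, num)


def equilibrium_constant(params: ModelParams, s: ArrayLike) -> NDArray[np.float64] | float:
    """Tension-dependent dissociation constant ``K0 * exp(-c_s * s)`` in µM.

    Strictly decreasing in tension ``s`` when ``c_s > 0``: tension raises
    the energy needed to detach calcium, i.e. lowers the dissociation
    constant.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("tension s must be non-negative")
    out = params.k_tnca0 * np.exp(-params.c_s * s)
    return float(out) if out.ndim == 0 else out


def activation_fraction(
    params: ModelParams, ca: ArrayLike, s: ArrayLike = 0.0
) -> NDArray[np.float64] | float:
    """Fraction of activated troponin pairs, in (0, 1).

    Evaluates ``1 / (1 + exp(n * (-c_s*s - ln(ca / K0))))``, the logistic
    form of the binding equilibrium, via :func:`scipy.special.expit` so
    that large exponents saturate cleanly instead of overflowing.
    """
    ca = np.asarray(ca, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.any(ca <= 0):
        raise ValueError("calcium concentration must be > 0")
    if np.any(s < 0):
        raise ValueError("tension s must be non-negative")
    out = expit(params.n * (params.c_s * s + np.log(ca / params.k_tnca0)))
    return float(out) if out.ndim == 0 else out


def _solve_batch(
    params: ModelParams,
    ca: NDArray[np.float64],
    x_max: float,
    x_eval: NDArray[np.float64] | None = None,
) -> NDArray[np.float64]:
    """Integrate dS/dx for a whole vector of calcium values at once.

    Returns an array of shape (len(ca), len(x_eval)) or (len(ca),) when
    only the endpoint is requested.  The right-hand side is smooth and
    non-stiff, so an adaptive Runge–Kutta pair with tight tolerances is
    both fast and accurate.
    """
    log_ratio = params.n * np.log(ca / params.k_tnca0)
    ncs = params.n * params.c_s

    def rhs(x: float, s: NDArray[np.float64]) -> NDArray[np.float64]:
        return params.c_f * expit(ncs * s + log_ratio)

    sol = solve_ivp(
        rhs,
        (0.0, x_max),
        np.zeros_like(ca),
        method="RK45",
        rtol=_RTOL,
        atol=_ATOL,
        t_eval=x_eval,
        dense_output=False,
    )
    if not sol.success:  # pragma: no cover - smooth RHS; defensive
        raise RuntimeError(
            f"tension integration failed ({sol.message}) for params={params}, "
            f"x_max={x_max}, ca range [{ca.min()}, {ca.max()}] µM"
        )
    if x_eval is None:
        return sol.y[:, -1]
    return sol.y


def integrate_tension(
    params: ModelParams,
    ca: float,
    x_max: float,
    num: int = PROFILE_GRID_SIZE,
) -> TensionProfile:
    """Solve the tension ODE and return the spatial profile.

    Integrates ``dS/dx = c_f * P(S)`` from ``S(0) = 0`` across the
    single-overlap region and samples ``S`` and ``P`` on a uniform grid of
    ``num`` points.
    """
    if not x_max > 0:
        raise ValueError(f"x_max must be > 0, got {x_max!r}")
    if not ca > 0:
        raise ValueError(f"calcium concentration must be > 0, got {ca!r}")
    x = np.linspace(0.0, x_max, num)
    s = _solve_batch(params, np.asarray([ca], dtype=float), x_max, x_eval=x)[0]
    s = np.maximum.accumulate(np.maximum(s, 0.0))  # clamp solver jitter
    p = np.asarray(activation_fraction(params, ca, s))
    return TensionProfile(x=x, s=s, p=p, ca=float(ca))


def total_tension(
    params: ModelParams,
    ca: float,
    geom: SarcomereGeometry | float,
) -> float:
    """Total thin-filament tension ``S(x_max)`` acting on the Z-disk.

    ``geom`` may be a :class:`SarcomereGeometry` or a bare overlap length
    in µm.
    """
    x_max = geom.x_max if isinstance(geom, SarcomereGeometry) else float(geom)
    if not x_max > 0:
        raise ValueError(f"x_max must be > 0, got {x_max!r}")
    if not ca > 0:
        raise ValueError(f"calcium concentration must be > 0, got {ca!r}")
    return float(_solve_batch(params, np.asarray([ca], dtype=float), x_max)[0])


def discrete_ladder(
    params: ModelParams,
    ca: float,
    x_max: float,
    n_sites: int,
) -> TensionProfile:
    """Discrete cross-bridge ladder: the stepwise original of the ODE.

    Places ``n_sites`` equispaced cross-bridge sites on ``(0, x_max]``.
    Site ``j`` contributes a force ``c_f * dx * P(S_{j-1})`` evaluated at
    the tension accumulated strictly before it (left-Riemann convention),
    and ``S`` is the running sum — the staircase build-up of tension along
    the filament.  Converges to the continuum solution at first order in
    ``dx``; serves as an independent check on the ODE integration.
    """
    if n_sites < 1:
        raise ValueError(f"n_sites must be >= 1, got {n_sites!r}")
    if not ca > 0:
        raise ValueError(f"calcium concentration must be > 0, got {ca!r}")
    dx = x_max / n_sites
    x = np.linspace(0.0, x_max, n_sites + 1)
    s = np.zeros(n_sites + 1)
    for j in range(1, n_sites + 1):
        f_xb = params.c_f * dx * activation_fraction(params, ca, s[j - 1])
        s[j] = s[j - 1] + f_xb
    p = np.asarray(activation_fraction(params, ca, s))
    return TensionProfile(x=x, s=s, p=p, ca=float(ca))


def ca_tension_curve(
    params: ModelParams,
    geom: SarcomereGeometry | float,
    ca_grid: ArrayLike | None = None,
) -> CaTensionCurve:
    """Steady-state calcium–tension relation at fixed sarcomere length.

    Integrates the tension ODE for every concentration on ``ca_grid``
    (default: 200 log-spaced points over 0.001–10 µM) in a single batched
    solve and returns the resulting curve.
    """
    if isinstance(geom, SarcomereGeometry):
        x_max, sl = geom.x_max, geom.sl
    else:
        x_max, sl = float(geom), float("nan")
    if not x_max > 0:
        raise ValueError(f"x_max must be > 0, got {x_max!r}")
    ca = default_ca_grid() if ca_grid is None else np.asarray(ca_grid, dtype=float)
    if ca.ndim != 1 or len(ca) < 2:
        raise ValueError("ca_grid must be a 1-d array with at least 2 points")
    if np.any(ca <= 0):
        raise ValueError("ca_grid values must be > 0")
    if np.any(np.diff(ca) <= 0):
        raise ValueError("ca_grid must be strictly ascending")
    tension = _solve_batch(params, ca, x_max)
    return CaTensionCurve(ca=ca, tension=tension, sl=sl, params=params)
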