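"""Summary quantities derived from calcium–tension curves.

EC50, peak tension and its change with sarcomere length, the apparent
(fitted) Hill coefficient, and parameter-variation statistics across
sarcomere lengths.

Conventions: "peak" tension is the tension at the largest calcium on the
grid (10 µM in the standard protocol), matching how skinned-muscle
experiments report a maximum from a bounded protocol — not the
``c_f * x_max`` asymptote, which the protocol never reaches.  EC50 is the
calcium where the curve crosses half of that peak, interpolated
monotonically in log-calcium.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .core import CaTensionCurve, ModelParams
from .hill import fit_hill

__all__ = [
    "CurveSummary",
    "ec50",
    "peak_tension_change",
    "param_variation",
    "apparent_hill_coefficient",
    "summarize_curve",
]


@dataclass(frozen=True)
class CurveSummary:
    """Headline numbers for one simulated or fitted curve."""

    ec50: float  # µM
    peak_tension: float  # S, at the top of the calcium grid
    apparent_n_h: float
    sl: float  # µm


def ec50(curve: CaTensionCurve) -> float:
    """Calcium (µM) at half of the grid-peak tension.

    Interpolates the curve with a monotone piecewise-cubic (PCHIP) in
    (log ca, tension) — the curve is smooth and monotone, so shape-
    preserving interpolation cannot overshoot — and root-finds the
    half-peak crossing.

    Raises ``ValueError`` if the curve never reaches half of its peak
    within the grid.
    """
    ca = np.asarray(curve.ca, dtype=float)
    tension = np.asarray(curve.tension, dtype=float)
    half = curve.peak_tension / 2.0
    if not curve.peak_tension > 0:
        raise ValueError("curve peak tension is not positive; EC50 undefined")
    if tension[0] > half:
        raise ValueError(
            "curve already exceeds half-peak at the lowest grid calcium; "
            "extend the grid downward to locate EC50"
        )
    log_ca = np.log(ca)
    f = PchipInterpolator(log_ca, tension - half)
    # bracket using the grid itself: first index at/above half-peak
    idx = int(np.argmax(tension >= half))
    if tension[idx] < half:
        raise ValueError("curve never reaches half of its peak tension")
    lo = log_ca[max(idx - 1, 0)]
    hi = log_ca[idx]
    if f(hi) == 0.0:
        return float(np.exp(hi))
    return float(np.exp(brentq(f, lo, hi)))


def peak_tension_change(curve_a: CaTensionCurve, curve_b: CaTensionCurve) -> float:
    """Percent change in grid-peak tension from curve_a to curve_b.

    ``100 * (peak_b - peak_a) / peak_a``; the curves must share the
    calcium grid so the peaks refer to the same concentration.
    """
    if curve_a.ca.shape != curve_b.ca.shape or not np.allclose(curve_a.ca, curve_b.ca):
        raise ValueError("curves must share the same calcium grid")
    if not curve_a.peak_tension > 0:
        raise ValueError("reference curve has zero peak tension")
    return 100.0 * (curve_b.peak_tension - curve_a.peak_tension) / curve_a.peak_tension


def param_variation(params_by_sl: Sequence[ModelParams]) -> dict[str, float]:
    """Variation statistics across an SL-ordered list of parameter sets.

    Returns percentages: ``c_f_variation`` is the max relative spread
    ``(max - min) / min``; ``k_tnca0_decrease`` and ``c_s_decrease`` are
    the relative drops from the first (shortest-SL) entry to the last.
    """
    if len(params_by_sl) < 2:
        raise ValueError("need at least two parameter sets ordered by SL")
    c_f = np.array([p.c_f for p in params_by_sl])
    k0 = np.array([p.k_tnca0 for p in params_by_sl])
    c_s = np.array([p.c_s for p in params_by_sl])
    return {
        "c_f_variation": 100.0 * (c_f.max() - c_f.min()) / c_f.min(),
        "k_tnca0_decrease": 100.0 * (k0[0] - k0[-1]) / k0[0],
        "c_s_decrease": 100.0 * (c_s[0] - c_s[-1]) / c_s[0],
    }


def apparent_hill_coefficient(curve: CaTensionCurve) -> float:
    """Hill coefficient of the best Hill fit to the curve.

    With the mechanochemical coupling off (``c_s = 0``) this recovers the
    intrinsic ``n``; with coupling on it measures the boosted, apparent
    cooperativity (about 7 for the published parameter sets, versus the
    intrinsic 3).
    """
    return fit_hill(curve.ca, curve.tension).params.n_h


def summarize_curve(curve: CaTensionCurve) -> CurveSummary:
    """EC50, grid-peak tension and apparent Hill coefficient of a curve."""
    return CurveSummary(
        ec50=ec50(curve),
        peak_tension=curve.peak_tension,
        apparent_n_h=apparent_hill_coefficient(curve),
        sl=curve.sl,
    )
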