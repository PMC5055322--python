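"""Sarcomere filament-overlap geometry.

The sarcomere is bounded by two Z-disks; thin filaments protrude from each
Z-disk toward the mid-line, where thick filaments (with a central bare zone
free of myosin heads) interdigitate with them.  Cross-bridges can only form
in the *single overlap* region, the span where a thin filament overlaps the
cross-bridge-bearing part of exactly one thick-filament half.  Its length
``x_max`` grows with sarcomere length up to ~2.3 µm as the double-overlap
region (opposing thin filaments overlapping each other) shrinks.

The formulation follows Rice et al. (2008): measuring from the mid-line of
the sarcomere, the single-overlap region runs from the edge nearest the
center (limited by the opposing thin filament or the bare zone) out to the
thick-filament tip (or the Z-disk, whichever comes first).

Coordinate convention used throughout the package: ``x = 0`` at the
mid-line end of the single-overlap region, increasing toward the Z-disk,
so ``x`` runs over ``[0, x_max]``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = ["SarcomereGeometry", "single_overlap_length", "SL_RANGE"]

#: Sarcomere-length range (µm) accepted by the geometry; covers the
#: physiological working range of cardiac sarcomeres.  The model itself is
#: validated against skinned-muscle data on [1.85, 2.25] µm.
SL_RANGE = (1.5, 2.4)

# Rice et al. 2008 filament constants (µm); the defaults here.
THICK_LEN = 1.65
THIN_LEN = 1.2
BARE_ZONE_LEN = 0.1


@dataclass(frozen=True)
class SarcomereGeometry:
    """Filament lengths and sarcomere length, all in µm.

    Parameters
    ----------
    sl:
        Sarcomere length (Z-disk to Z-disk distance).
    thick_len:
        Thick (myosin) filament length.
    thin_len:
        Thin (actin) filament length, one Z-disk's filament.
    bare_zone_len:
        Length of the central thick-filament zone bare of myosin heads.
    """

    sl: float
    thick_len: float = THICK_LEN
    thin_len: float = THIN_LEN
    bare_zone_len: float = BARE_ZONE_LEN

    def __post_init__(self) -> None:
        for name in ("sl", "thick_len", "thin_len", "bare_zone_len"):
            v = getattr(self, name)
            if not (v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        if self.bare_zone_len >= self.thick_len:
            raise ValueError(
                f"bare_zone_len ({self.bare_zone_len}) must be smaller than "
                f"thick_len ({self.thick_len})"
            )
        if not (SL_RANGE[0] <= self.sl <= SL_RANGE[1]):
            raise ValueError(
                f"sarcomere length {self.sl} µm outside the supported range "
                f"[{SL_RANGE[0]}, {SL_RANGE[1]}] µm"
            )

    def with_sl(self, sl: float) -> "SarcomereGeometry":
        """Same filament constants at a different sarcomere length."""
        return replace(self, sl=sl)

    @property
    def x_max(self) -> float:
        """Single-overlap length (µm); see :func:`single_overlap_length`."""
        return single_overlap_length(self)


def single_overlap_length(geom: SarcomereGeometry) -> float:
    """Length of the single-overlap region for one thin filament, in µm.

    Measured from the sarcomere mid-line, the overlap region is bounded on
    the Z-disk side by the thick-filament tip ``thick_len / 2`` (or the
    Z-disk at ``sl / 2`` if the thick filament would poke past it) and on
    the center side by whichever reaches further out: the tip of the
    opposing thin filament ``thin_len - sl / 2`` (start of double overlap)
    or the bare-zone edge ``bare_zone_len / 2``.

    Returns 0 for geometries where the bounds cross (no overlap).
    """
    z_edge = min(geom.thick_len / 2.0, geom.sl / 2.0)
    center_edge = max(geom.thin_len - geom.sl / 2.0, geom.bare_zone_len / 2.0)
    return max(z_edge - center_edge, 0.0)
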