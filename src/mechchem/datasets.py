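"""Synthetic skinned-muscle-style datasets and CSV I/O.

The experimental reference data for this model exist only as points read
off a published figure, so tests and examples run on synthetic datasets
drawn from known generating curves (mechanochemical or Hill) plus
homoscedastic Gaussian tension noise, clipped at zero — a skinned
preparation cannot report negative active tension.  The generating model,
parameters, noise level and seed are carried as provenance so any dataset
can be regenerated exactly.

File format: CSV with header ``sarcomere_length_um, calcium_uM,
tension_S``; provenance is written to a JSON sidecar next to the CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike, NDArray

from .core import ModelParams, _solve_batch
from .geometry import SarcomereGeometry
from .hill import HillParams, hill_tension

__all__ = [
    "ExperimentDataset",
    "default_ca_design",
    "generate_dataset",
    "read_dataset",
    "write_dataset",
]

COLUMNS = ("sarcomere_length_um", "calcium_uM", "tension_S")

#: The five standard sarcomere lengths (µm) of the emulated protocol.
DEFAULT_SLS = (1.85, 1.95, 2.05, 2.15, 2.25)


def default_ca_design() -> NDArray[np.float64]:
    """Calcium design (µM) mimicking experimental practice.

    18 log-spaced points over [1, 10] µM covering the transition, plus 3
    sub-threshold points that pin the zero-tension baseline.
    """
    return np.concatenate([np.geomspace(0.2, 0.8, 3), np.geomspace(1.0, 10.0, 18)])


@dataclass(frozen=True)
class ExperimentDataset:
    """(SL, calcium, tension) triples with generator provenance.

    ``table`` holds one row per measurement with the columns of
    :data:`COLUMNS`; ``provenance`` records how the data were made (empty
    for data read from files without a sidecar).
    """

    table: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"dataset table is missing columns: {missing}")

    def groups(self) -> Iterator[tuple[float, pd.DataFrame]]:
        """Iterate (sarcomere length, sub-table) in ascending SL order."""
        for sl, g in self.table.groupby("sarcomere_length_um", sort=True):
            yield float(sl), g

    def arrays(self, sl: float) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
        """(ca, tension) arrays for one sarcomere length."""
        g = self.table[self.table["sarcomere_length_um"] == sl]
        if g.empty:
            raise KeyError(f"no records at sarcomere length {sl} µm")
        return g["calcium_uM"].to_numpy(), g["tension_S"].to_numpy()

    @property
    def sarcomere_lengths(self) -> list[float]:
        return sorted(self.table["sarcomere_length_um"].unique().tolist())


def generate_dataset(
    model: str,
    params_by_sl: Mapping[float, ModelParams | HillParams],
    ca_design: ArrayLike | None = None,
    noise_sigma: float = 0.02,
    seed: int | None = None,
    geometry: Mapping[float, SarcomereGeometry] | None = None,
) -> ExperimentDataset:
    """Draw a synthetic dataset from a known generating model.

    Parameters
    ----------
    model:
        ``"mechchem"`` (params are :class:`ModelParams`; curves come from
        the tension ODE over each SL's overlap region) or ``"hill"``
        (params are :class:`HillParams`).
    params_by_sl:
        Generating parameters keyed by sarcomere length (µm).
    ca_design:
        Calcium concentrations (µM) sampled at every SL; defaults to
        :func:`default_ca_design`.
    noise_sigma:
        Standard deviation of the additive Gaussian tension noise (S);
        0.02 S is comparable to the residual scatter of the published
        fits.  Tensions are clipped at zero after noising.
    seed:
        Seed for the noise stream; same seed, same dataset.
    geometry:
        Optional per-SL geometry overriding the default filament
        constants (mechchem model only).
    """
    if model not in ("mechchem", "hill"):
        raise ValueError(f"unknown model {model!r}; expected 'mechchem' or 'hill'")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    ca = default_ca_design() if ca_design is None else np.asarray(ca_design, float)
    if np.any(ca <= 0):
        raise ValueError("ca_design values must be > 0")
    rng = np.random.default_rng(seed)

    frames = []
    for sl in sorted(params_by_sl):
        p = params_by_sl[sl]
        if model == "mechchem":
            if not isinstance(p, ModelParams):
                raise TypeError(f"mechchem generator needs ModelParams, got {type(p)}")
            geom = geometry[sl] if geometry is not None else SarcomereGeometry(sl=sl)
            order = np.argsort(ca)
            clean = np.empty_like(ca)
            clean[order] = _solve_batch(p, ca[order], geom.x_max)
        else:
            if not isinstance(p, HillParams):
                raise TypeError(f"hill generator needs HillParams, got {type(p)}")
            clean = np.asarray(hill_tension(p, ca))
        noisy = clean + rng.normal(0.0, noise_sigma, size=clean.shape) if noise_sigma else clean
        frames.append(pd.DataFrame({
            "sarcomere_length_um": float(sl),
            "calcium_uM": ca,
            "tension_S": np.maximum(noisy, 0.0),
        }))

    provenance = {
        "model": model,
        "params_by_sl": {
            str(sl): vars(params_by_sl[sl]).copy() for sl in sorted(params_by_sl)
        },
        "noise_sigma": noise_sigma,
        "seed": seed,
        "ca_design": np.asarray(ca).tolist(),
    }
    return ExperimentDataset(pd.concat(frames, ignore_index=True), provenance)


def write_dataset(ds: ExperimentDataset, path: str | Path) -> None:
    """Write the dataset CSV (17 significant digits: lossless round-trip)
    and, when provenance exists, a ``<name>.provenance.json`` sidecar."""
    path = Path(path)
    ds.table.to_csv(path, index=False, columns=list(COLUMNS), float_format="%.17g")
    if ds.provenance:
        sidecar = path.with_suffix(path.suffix + ".provenance.json")
        sidecar.write_text(json.dumps(ds.provenance, indent=2) + "\n")


def read_dataset(path: str | Path) -> ExperimentDataset:
    """Read a dataset CSV, validating structure row by row.

    Raises ``ValueError`` naming the offending row (1-based, excluding
    the header) for non-numeric cells, non-positive calcium or negative
    tension; an empty file or missing columns are errors too.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: file is empty; expected header {COLUMNS}") from None
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if len(raw) == 0:
        raise ValueError(f"{path}: no data rows")

    table = pd.DataFrame()
    for col in COLUMNS:
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna() & raw[col].notna() | raw[col].isna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise ValueError(f"{path}: row {row}: non-numeric value in {col!r}")
        table[col] = vals.astype(float)
    if (table["calcium_uM"] <= 0).any():
        row = int((table["calcium_uM"] <= 0).idxmax()) + 1
        raise ValueError(f"{path}: row {row}: calcium_uM must be > 0")
    if (table["tension_S"] < 0).any():
        row = int((table["tension_S"] < 0).idxmax()) + 1
        raise ValueError(f"{path}: row {row}: tension_S must be >= 0")

    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    provenance = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return ExperimentDataset(table, provenance)
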