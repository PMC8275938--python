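"""Brain-tissue-deformation injury criteria: MPS, CSDM, DDM.

These operate on per-element field histories exported by an upstream finite
element solve of the brain: each element carries a constant (initial) volume,
a first-principal-strain history and a pressure history. CSDM and DDM use
once-exceeded semantics — an element counts if it ever crosses the threshold
at any timestep — so all three metrics are invariant to timestep reordering.

Pressure sign convention: positive = compression; the DDM tension threshold
is therefore negative (default -100 kPa).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .kinematic import CriterionResult


@dataclass(frozen=True)
class ElementFieldHistory:
    """Per-element brain field histories on a complete element x timestep grid.

    Attributes
    ----------
    element_id : int array, shape (n,)
        Unique element labels.
    volume : float array, shape (n,)
        Strictly positive element volumes (any consistent unit; only volume
        fractions are ever reported).
    t : float array, shape (m,)
        Timestep instants in seconds, strictly increasing.
    strain : float array, shape (n, m)
        First principal strain (dimensionless, Green-Lagrange as provided by
        the upstream solver).
    pressure : float array, shape (n, m)
        Pressure in kPa, positive = compression.
    """

    element_id: np.ndarray
    volume: np.ndarray
    t: np.ndarray
    strain: np.ndarray
    pressure: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "element_id", np.asarray(self.element_id, dtype=int))
        object.__setattr__(self, "volume", np.asarray(self.volume, dtype=float))
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "strain", np.asarray(self.strain, dtype=float))
        object.__setattr__(self, "pressure", np.asarray(self.pressure, dtype=float))
        n, m = len(self.element_id), len(self.t)
        if n < 1 or m < 1:
            raise ValidationError("field history needs at least 1 element and 1 timestep")
        if len(np.unique(self.element_id)) != n:
            raise ValidationError("element_id values must be unique")
        if self.volume.shape != (n,) or not np.all(self.volume > 0):
            raise ValidationError("volumes must be one per element and strictly positive")
        if m >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValidationError("time vector must be strictly increasing")
        for name in ("strain", "pressure"):
            arr = getattr(self, name)
            if arr.shape != (n, m):
                raise ValidationError(f"{name} must have shape ({n}, {m}), got {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name} contains NaN or infinite values")

    @property
    def n_elements(self) -> int:
        return len(self.element_id)

    @property
    def total_volume(self) -> float:
        return float(self.volume.sum())


def read_element_fields(path: str | Path) -> ElementFieldHistory:
    """Read a long-format delimited element-field file.

    Columns: element_id, volume, t, strain, pressure; one row per element per
    timestep, every element present at every timestep ('#' lines are comments).
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#", encoding="utf-8",
                     float_precision="round_trip")
    required = {"element_id", "volume", "t", "strain", "pressure"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    elems = df["element_id"].unique()
    times = np.sort(df["t"].unique())
    if len(df) != len(elems) * len(times):
        raise FormatError(
            f"{path}: ragged grid — {len(df)} rows for {len(elems)} elements "
            f"x {len(times)} timesteps")
    try:
        strain = df.pivot(index="element_id", columns="t", values="strain")
        pressure = df.pivot(index="element_id", columns="t", values="pressure")
    except ValueError as exc:  # duplicated (element, t) pairs
        raise FormatError(f"{path}: {exc}") from exc
    if strain.isna().any().any() or pressure.isna().any().any():
        raise FormatError(f"{path}: incomplete element x timestep grid")
    vols = df.groupby("element_id")["volume"].agg(["min", "max"])
    if not np.allclose(vols["min"], vols["max"]):
        raise FormatError(f"{path}: element volume varies across timesteps")
    order = strain.index.to_numpy()
    return ElementFieldHistory(
        element_id=order,
        volume=vols["min"].loc[order].to_numpy(),
        t=strain.columns.to_numpy(dtype=float),
        strain=strain.to_numpy(),
        pressure=pressure.to_numpy(),
    )


def write_element_fields(field: ElementFieldHistory, path: str | Path) -> None:
    """Write a field history in the long format ``read_element_fields`` consumes."""
    n, m = field.strain.shape
    df = pd.DataFrame({
        "element_id": np.repeat(field.element_id, m),
        "volume": np.repeat(field.volume, m),
        "t": np.tile(field.t, n),
        "strain": field.strain.ravel(),
        "pressure": field.pressure.ravel(),
    })
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# element field history: volume (consistent unit), strain "
                 "(first principal, dimensionless), pressure (kPa, +=compression)\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def mps(field: ElementFieldHistory) -> CriterionResult:
    """Maximum principal strain: the peak first principal strain over all
    elements and timesteps. May exceed 1 for severe impacts."""
    if field.n_elements < 1:
        raise ValidationError("empty field")
    return CriterionResult("MPS", float(field.strain.max()), units="")


def csdm(field: ElementFieldHistory, threshold: float = 0.25, strict: bool = True
         ) -> CriterionResult:
    """Cumulative strain damage measure at a strain threshold (0.15 or 0.25
    conventionally).

    The fraction of total brain volume in elements whose strain exceeds the
    threshold at any timestep. ``strict`` controls whether boundary-equal
    elements are excluded (default) or included.
    """
    if not threshold > 0:
        raise ValidationError(f"CSDM threshold must be positive, got {threshold}")
    peak = field.strain.max(axis=1)
    exceeds = peak > threshold if strict else peak >= threshold
    frac = float(field.volume[exceeds].sum() / field.total_volume)
    return CriterionResult(f"CSDM_{threshold:g}", frac, units="volume fraction",
                           params={"threshold": threshold, "strict": strict})


def ddm(field: ElementFieldHistory, threshold_kpa: float = -100.0, strict: bool = True
        ) -> CriterionResult:
    """Dilatation damage measure: fraction of brain volume whose pressure ever
    drops below the (negative, i.e. tensile) threshold, default -100 kPa."""
    if not threshold_kpa < 0:
        raise ValidationError(
            f"DDM threshold must be negative (tension), got {threshold_kpa}")
    trough = field.pressure.min(axis=1)
    exceeds = trough < threshold_kpa if strict else trough <= threshold_kpa
    frac = float(field.volume[exceeds].sum() / field.total_volume)
    return CriterionResult("DDM", frac, units="volume fraction",
                           params={"threshold_kpa": threshold_kpa, "strict": strict})
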