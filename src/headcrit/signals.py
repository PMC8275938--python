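"""Head-kinematics time histories: data model, readers, resultants, integration.

Every downstream criterion consumes a :class:`KinematicsRecord` — time-aligned
linear-acceleration, rotational-acceleration and (optionally) rotational-velocity
channels of the head centre of gravity. Channels are stored exactly as read;
unit conversion (g <-> m/s^2) is applied lazily by accessor methods so that a
record never silently changes representation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import cumulative_trapezoid
from scipy.signal import butter, filtfilt

from .errors import ConfigurationError, FormatError, ValidationError

logger = logging.getLogger(__name__)

#: m/s^2 per g. 9.81 is the package default; pass g_value=9.8 to match sources
#: that round the constant.
DEFAULT_G = 9.81

KINEMATICS_COLUMNS = ("t", "ax", "ay", "az", "alx", "aly", "alz")
ROT_VEL_COLUMNS = ("wx", "wy", "wz")

#: SAE-style channel frequency classes, keyed by class name, value = nominal
#: class frequency in Hz. The phaseless low-pass is a 2-pole Butterworth run
#: forward and backward (4 poles total, zero phase) with -3 dB point at
#: 1.65 x the class frequency, the conventional crash-channel design point.
CFC_CLASSES = {"CFC60": 60.0, "CFC180": 180.0, "CFC600": 600.0, "CFC1000": 1000.0}


@dataclass(frozen=True)
class UnitConfig:
    """How to interpret a kinematics file's linear-acceleration columns."""

    unit_lin: str = "m_per_s2"  # "g" or "m_per_s2"
    g_value: float = DEFAULT_G
    delimiter: Optional[str] = None  # None -> sniff comma, fall back to tab
    cfc_class: str = "none"

    def __post_init__(self) -> None:
        if self.unit_lin not in ("g", "m_per_s2"):
            raise ConfigurationError(f"unit_lin must be 'g' or 'm_per_s2', got {self.unit_lin!r}")
        if not self.g_value > 0:
            raise ConfigurationError(f"g_value must be positive, got {self.g_value}")
        if self.cfc_class != "none" and self.cfc_class not in CFC_CLASSES:
            raise ConfigurationError(f"unknown CFC class {self.cfc_class!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "UnitConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: raw[k] for k in ("unit_lin", "g_value", "delimiter", "cfc_class") if k in raw}
        return cls(**known)


@dataclass(frozen=True)
class ScalarSeries:
    """A single scalar time series with its unit carried as metadata."""

    t: np.ndarray
    v: np.ndarray
    unit: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "v", np.asarray(self.v, dtype=float))
        if self.t.ndim != 1 or self.v.ndim != 1:
            raise ValidationError("ScalarSeries t and v must be 1-D")
        if len(self.t) != len(self.v):
            raise ValidationError(f"length mismatch: t has {len(self.t)}, v has {len(self.v)}")
        if len(self.t) >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValidationError("time vector must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class KinematicsRecord:
    """Time-aligned head-COG kinematics channels.

    Parameters
    ----------
    t : array, shape (n,)
        Time in seconds, strictly increasing, n >= 2.
    lin_acc : array, shape (3, n)
        Linear acceleration channels (x, y, z) in the unit declared by
        ``unit_lin``.
    rot_acc : array, shape (3, n)
        Rotational acceleration channels in rad/s^2.
    rot_vel : array, shape (3, n), optional
        Rotational velocity channels in rad/s. May be absent; criteria that
        need it raise :class:`ValidationError`.
    unit_lin : {"g", "m_per_s2"}
        Unit of ``lin_acc`` as stored.
    g_value : float
        m/s^2 per g used for conversions.
    """

    case_id: str
    t: np.ndarray
    lin_acc: np.ndarray
    rot_acc: np.ndarray
    rot_vel: Optional[np.ndarray] = None
    unit_lin: str = "m_per_s2"
    g_value: float = DEFAULT_G

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "lin_acc", np.asarray(self.lin_acc, dtype=float))
        object.__setattr__(self, "rot_acc", np.asarray(self.rot_acc, dtype=float))
        if self.rot_vel is not None:
            object.__setattr__(self, "rot_vel", np.asarray(self.rot_vel, dtype=float))
        n = len(self.t)
        if n < 2:
            raise ValidationError("kinematics record needs at least 2 samples")
        if not np.all(np.diff(self.t) > 0):
            raise ValidationError("time vector must be strictly increasing")
        for name in ("lin_acc", "rot_acc", "rot_vel"):
            arr = getattr(self, name)
            if arr is None:
                continue
            if arr.shape != (3, n):
                raise ValidationError(f"{name} must have shape (3, {n}), got {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name} contains NaN or infinite values")
        if self.unit_lin not in ("g", "m_per_s2"):
            raise ValidationError(f"unit_lin must be 'g' or 'm_per_s2', got {self.unit_lin!r}")
        if not self.g_value > 0:
            raise ValidationError("g_value must be positive")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def lin_acc_in(self, unit: str) -> np.ndarray:
        """Linear-acceleration channels converted to ``unit`` ('g' or 'm_per_s2')."""
        if unit not in ("g", "m_per_s2"):
            raise ValidationError(f"unknown unit {unit!r}")
        if unit == self.unit_lin:
            return self.lin_acc
        if unit == "g":
            logger.debug("converting lin_acc m/s^2 -> g with g_value=%g", self.g_value)
            return self.lin_acc / self.g_value
        logger.debug("converting lin_acc g -> m/s^2 with g_value=%g", self.g_value)
        return self.lin_acc * self.g_value

    def resultant_lin(self, unit: str = "g") -> ScalarSeries:
        """Resultant (Euclidean-norm) linear acceleration of the head centroid."""
        a = self.lin_acc_in(unit)
        return resultant(
            ScalarSeries(self.t, a[0]), ScalarSeries(self.t, a[1]), ScalarSeries(self.t, a[2]),
            unit=unit,
        )

    def resultant_rot_acc(self) -> ScalarSeries:
        a = self.rot_acc
        return resultant(
            ScalarSeries(self.t, a[0]), ScalarSeries(self.t, a[1]), ScalarSeries(self.t, a[2]),
            unit="rad/s^2",
        )

    def resultant_rot_vel(self) -> ScalarSeries:
        if self.rot_vel is None:
            raise ValidationError("record has no rotational-velocity channels")
        w = self.rot_vel
        return resultant(
            ScalarSeries(self.t, w[0]), ScalarSeries(self.t, w[1]), ScalarSeries(self.t, w[2]),
            unit="rad/s",
        )

    def with_units(self, unit_lin: str) -> "KinematicsRecord":
        """A copy whose stored linear channels are re-expressed in ``unit_lin``."""
        return replace(self, lin_acc=self.lin_acc_in(unit_lin), unit_lin=unit_lin)


def resultant(x: ScalarSeries, y: ScalarSeries, z: ScalarSeries, unit: str = "") -> ScalarSeries:
    """Elementwise Euclidean norm sqrt(x^2 + y^2 + z^2) of three channels."""
    if not (len(x) == len(y) == len(z)):
        raise ValidationError(
            f"component length mismatch: {len(x)}, {len(y)}, {len(z)}"
        )
    v = np.sqrt(x.v ** 2 + y.v ** 2 + z.v ** 2)
    return ScalarSeries(x.t, v, unit=unit or x.unit)


def running_integral(s: ScalarSeries) -> ScalarSeries:
    """Cumulative trapezoidal integral of a series; first value 0.

    Trapezoids are exact for piecewise-linear signals and handle non-uniform
    time vectors, which is why they are the package-wide integration scheme.
    """
    if len(s) < 2:
        raise ValidationError("running_integral needs at least 2 samples")
    v = cumulative_trapezoid(s.v, s.t, initial=0.0)
    return ScalarSeries(s.t, v, unit=f"{s.unit}*s" if s.unit else "")


def cfc_filter(s: ScalarSeries, cfc_class: str = "none") -> ScalarSeries:
    """Phaseless low-pass filter of a crash channel by frequency class.

    ``none`` is a bit-identical passthrough. Other classes require uniform
    sampling and apply a 2-pole Butterworth forward-backward (4-pole
    phaseless), -3 dB at 1.65 x the class frequency.
    """
    if cfc_class == "none":
        return s
    if cfc_class not in CFC_CLASSES:
        raise ConfigurationError(f"unknown CFC class {cfc_class!r}")
    dt = np.diff(s.t)
    if len(dt) < 1:
        raise ValidationError("filtering needs at least 2 samples")
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=0.0):
        raise ValidationError("CFC filtering requires uniform sampling")
    fs = 1.0 / dt[0]
    fc = 1.65 * CFC_CLASSES[cfc_class]
    nyq = fs / 2.0
    if fc >= nyq:
        logger.warning("CFC cutoff %.0f Hz at/above Nyquist %.0f Hz; passthrough", fc, nyq)
        return s
    b, a = butter(2, fc / nyq)
    # filtfilt doubles the order and cancels phase
    v = filtfilt(b, a, s.v)
    return ScalarSeries(s.t, v, unit=s.unit)


def read_kinematics(path: str | Path, unit_config: UnitConfig | None = None) -> KinematicsRecord:
    """Read a delimited head-kinematics file into a validated record.

    The file needs a header row naming columns t, ax, ay, az, alx, aly, alz
    and optionally wx, wy, wz; comment lines starting with '#' are skipped.
    """
    cfg = unit_config or UnitConfig()
    path = Path(path)
    delimiters = [cfg.delimiter] if cfg.delimiter else [",", "\t"]
    df = None
    for delim in delimiters:
        candidate = pd.read_csv(path, sep=delim, comment="#", encoding="utf-8",
                                float_precision="round_trip")
        if set(KINEMATICS_COLUMNS) <= set(candidate.columns):
            df = candidate
            break
    if df is None:
        raise FormatError(
            f"{path}: missing mandatory columns; need {', '.join(KINEMATICS_COLUMNS)}"
        )
    for col in KINEMATICS_COLUMNS:
        if df[col].isna().any():
            raise ValidationError(f"{path}: NaN values in column {col!r}")
    t = df["t"].to_numpy(dtype=float)
    if len(t) >= 2 and not np.all(np.diff(t) > 0):
        raise ValidationError(f"{path}: time column not strictly increasing")
    lin = df[["ax", "ay", "az"]].to_numpy(dtype=float).T
    rot = df[["alx", "aly", "alz"]].to_numpy(dtype=float).T
    rot_vel = None
    if set(ROT_VEL_COLUMNS) <= set(df.columns):
        if df[list(ROT_VEL_COLUMNS)].isna().any().any():
            raise ValidationError(f"{path}: NaN values in rotational-velocity columns")
        rot_vel = df[list(ROT_VEL_COLUMNS)].to_numpy(dtype=float).T
    return KinematicsRecord(
        case_id=path.stem,
        t=t,
        lin_acc=lin,
        rot_acc=rot,
        rot_vel=rot_vel,
        unit_lin=cfg.unit_lin,
        g_value=cfg.g_value,
    )


def write_kinematics(rec: KinematicsRecord, path: str | Path, delimiter: str = ",") -> None:
    """Write a record in the same delimited layout ``read_kinematics`` consumes."""
    cols = {"t": rec.t}
    for name, row in zip(("ax", "ay", "az"), rec.lin_acc):
        cols[name] = row
    for name, row in zip(("alx", "aly", "alz"), rec.rot_acc):
        cols[name] = row
    if rec.rot_vel is not None:
        for name, row in zip(ROT_VEL_COLUMNS, rec.rot_vel):
            cols[name] = row
    pd.DataFrame(cols).to_csv(path, sep=delimiter, index=False, float_format="%.17g")
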