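"""Head-kinematics-based injury criteria: HIC15, RIC, GAMBIT, HIP, BrIC.

All five criteria reduce a :class:`~headcrit.signals.KinematicsRecord` to one
scalar. HIC and RIC maximize a windowed mean-acceleration power over start/end
times restricted to sample instants; GAMBIT and BrIC combine peak resultants
normalized by critical values; HIP is the peak instantaneous mechanical power
delivered to the head.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ValidationError
from .signals import KinematicsRecord, ScalarSeries, running_integral

logger = logging.getLogger(__name__)

CRITERIA_ORDER = ("HIC", "GAMBIT", "BrIC", "RIC", "HIP")


@dataclass(frozen=True)
class CriterionConstants:
    """Constants of the five kinematic criteria.

    Defaults: critical linear acceleration 350 g and critical rotational
    acceleration 12,000 rad/s^2 (GAMBIT and BrIC denominators), critical
    rotational velocity 140 rad/s (BrIC), head mass 4.5 kg and principal
    moments of inertia Ixx=0.016, Iyy=0.024, Izz=0.022 kg m^2 (HIP), HIC
    window cap 15 ms, RIC window cap 36 ms.
    """

    a_cr: float = 350.0            # g
    alpha_cr: float = 12_000.0     # rad/s^2
    omega_cr: float = 140.0        # rad/s
    gambit_n: float = 2.0
    gambit_m: float = 2.0
    gambit_s: float = 2.0
    head_mass: float = 4.5         # kg
    I_xx: float = 0.016            # kg m^2
    I_yy: float = 0.024
    I_zz: float = 0.022
    hic_window_max: float = 0.015  # s; override 0.036 for HIC36
    ric_window: float = 0.036      # s

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if not getattr(self, name) > 0:
                raise ValidationError(f"constant {name} must be positive")

    @property
    def inertia(self) -> np.ndarray:
        return np.array([self.I_xx, self.I_yy, self.I_zz])


@dataclass(frozen=True)
class CriterionResult:
    """A named scalar criterion value, with the maximizing window if one exists."""

    name: str
    value: float
    units: str = ""
    window: Optional[tuple[float, float]] = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValidationError(f"{self.name}: non-finite value {self.value}")
        if self.window is not None and not self.window[0] < self.window[1]:
            raise ValidationError(f"{self.name}: window must satisfy t1 < t2")


def _windowed_power_max(s: ScalarSeries, window_max: float, exponent: float = 2.5
                        ) -> tuple[float, Optional[tuple[float, float]]]:
    """max over sample-time pairs (t1, t2), 0 < t2-t1 <= window_max, of
    (t2-t1) * (mean of s over [t1, t2])**exponent.

    Uses the prefix trapezoidal integral, so the window mean is
    (I[j]-I[i])/(t[j]-t[i]); for each start index the admissible end indices
    are scanned vectorized.
    """
    t = s.t
    prefix = running_integral(s).v
    n = len(t)
    tol = window_max * 1e-9
    best = 0.0
    best_win: Optional[tuple[float, float]] = None
    for i in range(n - 1):
        j_hi = int(np.searchsorted(t, t[i] + window_max + tol, side="right"))
        if j_hi <= i + 1:  # no sample-time window within the cap
            continue
        j = np.arange(i + 1, j_hi)
        dt = t[j] - t[i]
        mean = (prefix[j] - prefix[i]) / dt
        # negative window means cannot occur for resultants but guard anyway
        vals = dt * np.sign(mean) * np.abs(mean) ** exponent
        k = int(np.argmax(vals))
        if vals[k] > best:
            best = float(vals[k])
            best_win = (float(t[i]), float(t[j[k]]))
    return best, best_win


def hic(rec: KinematicsRecord, constants: CriterionConstants = CriterionConstants()
        ) -> CriterionResult:
    """Head injury criterion on the resultant linear acceleration in g.

    HIC15 by default: maximum over windows of length <= 15 ms of
    (t2-t1) * (mean resultant g)^2.5, window endpoints at sample times.
    """
    a = rec.resultant_lin(unit="g")
    value, window = _windowed_power_max(a, constants.hic_window_max)
    return CriterionResult("HIC", value, units="", window=window,
                           params={"window_max_s": constants.hic_window_max,
                                   "g_value": rec.g_value})


def ric(rec: KinematicsRecord, constants: CriterionConstants = CriterionConstants()
        ) -> CriterionResult:
    """Rotational injury criterion: the HIC analogue on the resultant
    rotational acceleration (rad/s^2) with a 36 ms window cap."""
    alpha = rec.resultant_rot_acc()
    if rec.duration < constants.ric_window:
        logger.warning(
            "record %s duration %.4f s shorter than RIC window %.3f s; "
            "evaluating over the full duration", rec.case_id, rec.duration,
            constants.ric_window)
    value, window = _windowed_power_max(alpha, constants.ric_window)
    return CriterionResult("RIC", value, units="", window=window,
                           params={"window_max_s": constants.ric_window})


def gambit(rec: KinematicsRecord, constants: CriterionConstants = CriterionConstants()
           ) -> CriterionResult:
    """GAMBIT = [(a_max/a_cr)^n + (alpha_max/alpha_cr)^m]^(1/s).

    a_max is the peak resultant linear acceleration in g, alpha_max the peak
    resultant rotational acceleration in rad/s^2; n = m = s = 2 by default.
    """
    a_max = float(np.max(rec.resultant_lin(unit="g").v))
    alpha_max = float(np.max(rec.resultant_rot_acc().v))
    c = constants
    value = ((a_max / c.a_cr) ** c.gambit_n
             + (alpha_max / c.alpha_cr) ** c.gambit_m) ** (1.0 / c.gambit_s)
    return CriterionResult("GAMBIT", value, units="",
                           params={"a_max_g": a_max, "alpha_max": alpha_max,
                                   "a_cr": c.a_cr, "alpha_cr": c.alpha_cr,
                                   "n": c.gambit_n, "m": c.gambit_m, "s": c.gambit_s})


def hip(rec: KinematicsRecord, constants: CriterionConstants = CriterionConstants()
        ) -> CriterionResult:
    """Head impact power, reported in kW.

    HIP = max over t of  m * sum_i a_i(t) * int_0^t a_i dtau
                       + sum_i I_ii * alpha_i(t) * int_0^t alpha_i dtau,
    i in {x, y, z}; linear channels in m/s^2, rotational in rad/s^2. The
    signed maximum is taken (rebound power may be negative).
    """
    a = rec.lin_acc_in("m_per_s2")
    alpha = rec.rot_acc
    if alpha is None:
        raise ValidationError("HIP requires rotational-acceleration channels")
    power = np.zeros_like(rec.t)
    for i in range(3):
        v_i = running_integral(ScalarSeries(rec.t, a[i])).v
        power += constants.head_mass * a[i] * v_i
    for i, inertia in enumerate(constants.inertia):
        w_i = running_integral(ScalarSeries(rec.t, alpha[i])).v
        power += inertia * alpha[i] * w_i
    k = int(np.argmax(power))
    value_kw = float(power[k]) / 1000.0
    return CriterionResult("HIP", value_kw, units="kW",
                           params={"t_peak_s": float(rec.t[k]),
                                   "head_mass": constants.head_mass,
                                   "inertia": tuple(constants.inertia)})


def bric(rec: KinematicsRecord, constants: CriterionConstants = CriterionConstants()
         ) -> CriterionResult:
    """BrIC = omega_max/omega_cr + alpha_max/alpha_cr (peak resultant
    rotational velocity and acceleration over their critical values)."""
    if rec.rot_vel is None:
        raise ValidationError("BrIC requires rotational-velocity channels")
    omega_max = float(np.max(rec.resultant_rot_vel().v))
    alpha_max = float(np.max(rec.resultant_rot_acc().v))
    value = omega_max / constants.omega_cr + alpha_max / constants.alpha_cr
    return CriterionResult("BrIC", value, units="",
                           params={"omega_max": omega_max, "alpha_max": alpha_max,
                                   "omega_cr": constants.omega_cr,
                                   "alpha_cr": constants.alpha_cr})


def compute_all_kinematic(rec: KinematicsRecord,
                          constants: CriterionConstants = CriterionConstants()
                          ) -> list[CriterionResult]:
    """All five kinematic criteria in the fixed order HIC, GAMBIT, BrIC, RIC, HIP."""
    ops = {"HIC": hic, "GAMBIT": gambit, "BrIC": bric, "RIC": ric, "HIP": hip}
    results = []
    for name in CRITERIA_ORDER:
        try:
            results.append(ops[name](rec, constants))
        except Exception as exc:
            raise type(exc)(f"{name}: {exc}") from exc
    return results
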