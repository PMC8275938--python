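"""Synthetic kinematics pulses, brain element fields, and accident cohorts.

The study's raw reconstruction outputs (head time histories, per-element
brain fields) are not public, so these generators stand in for them with
known ground truth:

* :func:`synth_pulse` — idealized crash pulses (constant, haversine,
  triangular) whose criterion values are known in closed form or by
  high-resolution quadrature.
* :func:`synth_element_field` — element strain/pressure histories constructed
  so the volume-weighted exceedance fractions (CSDM, DDM) hit stated targets
  exactly.
* :func:`synth_cohort` — criterion/MAIS tables with a controlled Pearson
  association, emulating the statistical structure of a reconstructed
  accident cohort.

Every generator is a pure function of its spec; the seed is part of the spec
and there is no ambient randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .deformation import ElementFieldHistory
from .errors import SpecError
from .kinematic import CriterionConstants, compute_all_kinematic
from .signals import DEFAULT_G, KinematicsRecord

PULSE_SHAPES = ("constant", "haversine", "triangular")

#: Latent-severity cut points mapping a standard-normal severity to MAIS 0-6.
#: Fixed so that ground-truth associations are reproducible across runs.
MAIS_CUTPOINTS = (-1.1, -0.55, 0.0, 0.55, 1.1, 1.65)


# ---------------------------------------------------------------------------
# kinematics pulses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PulseSpec:
    """An idealized head-impact pulse.

    Amplitudes are peaks of the *resultant* channel group: peak_lin in g,
    peak_rot_acc in rad/s^2, peak_rot_vel in rad/s. Each group follows the
    same time profile along its (unit) direction vector.
    """

    shape: str = "haversine"
    peak_lin: float = 100.0          # g
    peak_rot_acc: float = 5_000.0    # rad/s^2
    peak_rot_vel: float = 40.0       # rad/s
    duration: float = 0.020          # s
    dt: float = 1e-4                 # s
    dir_lin: tuple[float, float, float] = (1.0, 0.0, 0.0)
    dir_rot: tuple[float, float, float] = (0.0, 0.0, 1.0)
    g_value: float = DEFAULT_G
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in PULSE_SHAPES:
            raise SpecError(f"unknown pulse shape {self.shape!r}")
        if not self.duration > self.dt > 0:
            raise SpecError("need duration > dt > 0")
        if min(self.peak_lin, self.peak_rot_acc, self.peak_rot_vel) < 0:
            raise SpecError("amplitudes must be non-negative")
        for d in (self.dir_lin, self.dir_rot):
            if not np.isclose(np.linalg.norm(d), 1.0):
                raise SpecError(f"direction {d} must be unit-norm")


def _profile(shape: str, t: np.ndarray, T: float) -> np.ndarray:
    if shape == "constant":
        return np.ones_like(t)
    if shape == "haversine":
        return np.sin(np.pi * t / T) ** 2
    # triangular: linear rise to 1 at T/2, fall back to 0
    return 1.0 - np.abs(2.0 * t / T - 1.0)


def _render(spec: PulseSpec, dt: float) -> KinematicsRecord:
    t = np.arange(0.0, spec.duration + dt / 2, dt)
    p = _profile(spec.shape, t, spec.duration)
    d_lin = np.asarray(spec.dir_lin)[:, None]
    d_rot = np.asarray(spec.dir_rot)[:, None]
    return KinematicsRecord(
        case_id=f"synth-{spec.shape}-{spec.seed}",
        t=t,
        lin_acc=spec.peak_lin * d_lin * p,
        rot_acc=spec.peak_rot_acc * d_rot * p,
        rot_vel=spec.peak_rot_vel * d_rot * p,
        unit_lin="g",
        g_value=spec.g_value,
    )


def synth_pulse(spec: PulseSpec,
                constants: CriterionConstants = CriterionConstants()
                ) -> tuple[KinematicsRecord, dict]:
    """Generate a pulse record plus its ground-truth criterion values.

    The ground-truth mapping carries ``values`` (per criterion) and ``exact``
    (the subset known in closed form; the rest are high-resolution numeric
    truth, computed on a 16x finer time grid).

    Closed forms for the constant shape (duration T, amplitude A):
    HIC = A^2.5 * min(T, cap); RIC likewise on the rotational amplitude;
    GAMBIT and BrIC from the peaks; HIP = (m*A_si^2 + sum_i I_ii*(alpha*d_i)^2) * T
    in kW, attained at t = T. For haversine and triangular shapes the peaks
    (GAMBIT, BrIC) remain exact.
    """
    rec = _render(spec, spec.dt)
    c = constants
    values: dict[str, float] = {}
    exact: set[str] = set()

    alpha = spec.peak_rot_acc
    values["GAMBIT"] = ((spec.peak_lin / c.a_cr) ** c.gambit_n
                        + (alpha / c.alpha_cr) ** c.gambit_m) ** (1.0 / c.gambit_s)
    values["BrIC"] = spec.peak_rot_vel / c.omega_cr + alpha / c.alpha_cr
    exact |= {"GAMBIT", "BrIC"}

    if spec.shape == "constant":
        T = spec.duration
        values["HIC"] = spec.peak_lin ** 2.5 * min(T, c.hic_window_max)
        values["RIC"] = alpha ** 2.5 * min(T, c.ric_window)
        a_si = spec.peak_lin * spec.g_value
        d = np.asarray(spec.dir_rot)
        hip_w = (c.head_mass * a_si ** 2 + float(c.inertia @ (alpha * d) ** 2)) * T
        values["HIP"] = hip_w / 1000.0
        exact |= {"HIC", "RIC", "HIP"}
    else:
        # numeric truth: the window optimum of a smooth pulse evaluated on a
        # much finer grid than the delivered record
        fine = _render(spec, spec.dt / 16.0)
        for res in compute_all_kinematic(fine, constants):
            if res.name not in exact:
                values[res.name] = res.value

    truth = {"values": values, "exact": exact, "spec": spec}
    return rec, truth


# ---------------------------------------------------------------------------
# element fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FieldSpec:
    """A synthetic brain element field with target exceedance fractions.

    target_csdm maps strain thresholds to desired volume fractions (targets
    must be non-increasing in the threshold); target_ddm is the desired
    fraction below ddm_threshold_kpa. Targets are met by construction —
    elements are assigned to exceedance sets by volume — not by sampling, so
    the generated field reproduces them exactly. With equal volumes only
    multiples of 1/n_elements are reachable.
    """

    n_elements: int = 100
    volume_law: str = "equal"            # "equal" or "lognormal"
    volumes: Optional[tuple[float, ...]] = None  # explicit override
    target_csdm: Mapping[float, float] = field(
        default_factory=lambda: {0.15: 0.5, 0.25: 0.25})
    target_ddm: float = 0.0
    ddm_threshold_kpa: float = -100.0
    strain_peak_max: float = 1.5
    pressure_min_kpa: float = -200.0
    timesteps: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_elements < 1:
            raise SpecError("n_elements must be >= 1")
        if self.volume_law not in ("equal", "lognormal"):
            raise SpecError(f"unknown volume law {self.volume_law!r}")
        for thr, frac in self.target_csdm.items():
            if not thr > 0 or not 0.0 <= frac <= 1.0:
                raise SpecError(f"invalid CSDM target {frac} at threshold {thr}")
        if not 0.0 <= self.target_ddm <= 1.0:
            raise SpecError("target_ddm must be in [0, 1]")
        if not self.ddm_threshold_kpa < 0:
            raise SpecError("DDM threshold must be negative")
        if self.target_csdm and self.strain_peak_max <= max(self.target_csdm):
            raise SpecError("strain_peak_max must exceed the highest CSDM threshold")
        if not self.pressure_min_kpa < self.ddm_threshold_kpa:
            raise SpecError("pressure_min_kpa must lie below the DDM threshold")
        if self.timesteps < 1:
            raise SpecError("timesteps must be >= 1")


def _greedy_subset(order: np.ndarray, volumes: np.ndarray, target: float,
                   label: str) -> np.ndarray:
    """Indices (in ``order``) whose volume fraction equals ``target``.

    Greedy prefix construction over the given element order; raises
    :class:`SpecError` naming the nearest reachable fractions when the target
    cannot be met exactly.
    """
    total = volumes.sum()
    goal = target * total
    chosen = []
    acc = 0.0
    eps = total * 1e-9
    nxt = None
    for idx in order:
        v = volumes[idx]
        if acc + v <= goal + eps:
            chosen.append(idx)
            acc += v
        elif nxt is None:
            nxt = (acc + v) / total
    if abs(acc - goal) > eps:
        reachable = f"{acc / total:.9g}"
        if nxt is not None:
            reachable += f" or {nxt:.9g}"
        raise SpecError(
            f"{label} target {target} unreachable with these volumes; "
            f"nearest reachable: {reachable}")
    return np.array(chosen, dtype=int)


def synth_element_field(spec: FieldSpec) -> tuple[ElementFieldHistory, dict]:
    """Generate an element field hitting its CSDM/DDM targets exactly.

    Exceedance sets are nested across strain thresholds (an element over the
    0.25 threshold is also over 0.15). Element peak strains are placed
    strictly inside their assigned band — strict '>' / '<' comparisons in the
    metrics then reproduce the targets exactly — and each element's history
    is its peak times a random unit-max profile, so the peak is attained at
    exactly one timestep.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_elements, spec.timesteps

    if spec.volumes is not None:
        volumes = np.asarray(spec.volumes, dtype=float)
        if volumes.shape != (n,):
            raise SpecError(f"volumes must have length n_elements={n}")
        if not np.all(volumes > 0):
            raise SpecError("volumes must be strictly positive")
    elif spec.volume_law == "equal":
        volumes = np.ones(n)
    else:
        volumes = rng.lognormal(mean=0.0, sigma=0.5, size=n)

    thresholds = sorted(spec.target_csdm, reverse=True)  # high to low
    fracs = [spec.target_csdm[thr] for thr in thresholds]
    if any(b < a for a, b in zip(fracs, fracs[1:])):
        raise SpecError("CSDM targets must be non-decreasing as the threshold drops")

    order = np.argsort(-volumes, kind="stable")  # big elements first
    bands = np.zeros(n, dtype=int)  # band k: strain in (thr_k, thr_{k-1})
    prev: set[int] = set()
    for k, (thr, frac) in enumerate(zip(thresholds, fracs), start=1):
        subset = _greedy_subset(order, volumes, frac, f"CSDM({thr})")
        if not prev <= set(subset):
            raise SpecError(
                f"CSDM targets not realizable as nested sets at threshold {thr}")
        bands[subset] = np.maximum(bands[subset], len(thresholds) - k + 1)
        prev = set(subset)

    # strain band edges, low band 0 = [0, lowest threshold)
    edges = [0.0] + sorted(thresholds) + [spec.strain_peak_max]
    margin = 1e-6
    peak_strain = np.empty(n)
    for band in range(len(edges) - 1):
        sel = bands == band
        lo, hi = edges[band], edges[band + 1]
        # strictly inside the band so strict comparisons classify exactly
        peak_strain[sel] = rng.uniform(lo + margin * (hi - lo),
                                       hi - margin * (hi - lo), sel.sum())

    ddm_set = _greedy_subset(order, volumes, spec.target_ddm, "DDM")
    in_ddm = np.zeros(n, dtype=bool)
    in_ddm[ddm_set] = True
    thr_p = spec.ddm_threshold_kpa
    trough = np.empty(n)
    span_lo = spec.pressure_min_kpa - thr_p
    trough[in_ddm] = rng.uniform(spec.pressure_min_kpa - margin * span_lo,
                                 thr_p + margin * span_lo, in_ddm.sum())
    trough[~in_ddm] = rng.uniform(thr_p * (1 - margin), 0.0, (~in_ddm).sum())

    t = np.arange(m, dtype=float) * 1e-3
    prof_s = rng.uniform(0.0, 1.0, size=(n, m))
    prof_s /= prof_s.max(axis=1, keepdims=True)
    prof_p = rng.uniform(0.0, 1.0, size=(n, m))
    prof_p /= prof_p.max(axis=1, keepdims=True)

    field_hist = ElementFieldHistory(
        element_id=np.arange(1, n + 1),
        volume=volumes,
        t=t,
        strain=peak_strain[:, None] * prof_s,
        pressure=trough[:, None] * prof_p,
    )
    total = volumes.sum()
    truth = {
        "csdm": {thr: float(volumes[peak_strain > thr].sum() / total)
                 for thr in thresholds},
        "ddm": float(volumes[trough < thr_p].sum() / total),
        "mps": float(peak_strain.max()),
        "spec": spec,
    }
    return field_hist, truth


# ---------------------------------------------------------------------------
# accident cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """A synthetic accident cohort with controlled criterion-MAIS association.

    A latent severity per case (standard normal) is discretized into MAIS 0-6
    at the fixed cut points :data:`MAIS_CUTPOINTS`. The criterion value is
    ``link(severity)`` plus Gaussian noise. When ``noise_sd`` is None the
    noise scale is calibrated from the realized link/MAIS moments so the
    cohort's Pearson association approaches ``target_r``; an explicit
    ``noise_sd`` overrides the calibration.

    ``link`` maps severity to the expected criterion value and must be
    monotone; None means "MAIS scale" (the discretized score itself).
    """

    n_cases: int = 1000
    link: Optional[Callable[[np.ndarray], np.ndarray]] = None
    target_r: float = 0.6
    noise_sd: Optional[float] = None
    criterion_name: str = "SYN"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 3:
            raise SpecError("n_cases must be >= 3")
        if not -1.0 < self.target_r < 1.0:
            raise SpecError("target_r must be in (-1, 1)")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise SpecError("noise_sd must be non-negative")


def mais_from_severity(severity: np.ndarray) -> np.ndarray:
    """Discretize latent severities into MAIS 0-6 at the fixed cut points."""
    return np.searchsorted(np.asarray(MAIS_CUTPOINTS), severity, side="right")


def synth_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate (criteria table, injury table, ground truth).

    The criteria table has columns case_id and ``spec.criterion_name``; the
    injury table mirrors the packaged record layout (dai_ais and
    contusion_ais all missing, mais complete). Ground truth carries the
    latent severities, the noiseless criterion, the noise scale used, and the
    realized empirical r.
    """
    rng = np.random.default_rng(spec.seed)
    severity = rng.standard_normal(spec.n_cases)
    mais = mais_from_severity(severity)

    link_vals = (mais.astype(float) if spec.link is None
                 else np.asarray(spec.link(severity), dtype=float))
    if link_vals.shape != severity.shape:
        raise SpecError("link must return one value per case")

    var_link = link_vals.var()
    if spec.noise_sd is None:
        cov = np.cov(link_vals, mais.astype(float))[0, 1]
        var_m = mais.astype(float).var(ddof=1)
        if cov == 0.0 or np.sign(cov) != np.sign(spec.target_r):
            raise SpecError(
                "target_r sign unreachable: link and MAIS are uncorrelated or "
                "correlated with the opposite sign")
        sigma2 = (cov / spec.target_r) ** 2 / var_m - link_vals.var(ddof=1)
        if sigma2 < 0:
            raise SpecError(
                f"target_r={spec.target_r} exceeds the attainable association "
                "for this link; lower it or change the link")
        noise_sd = float(np.sqrt(sigma2))
    else:
        noise_sd = spec.noise_sd
        if noise_sd == 0.0 and var_link == 0.0:
            raise SpecError("degenerate spec: constant link with zero noise")

    criterion = link_vals + noise_sd * rng.standard_normal(spec.n_cases)

    case_ids = np.arange(1, spec.n_cases + 1)
    criteria = pd.DataFrame({"case_id": case_ids, spec.criterion_name: criterion})
    injuries = pd.DataFrame({
        "case_id": case_ids,
        "dai_ais": pd.array([pd.NA] * spec.n_cases, dtype="Int64"),
        "contusion_ais": pd.array([pd.NA] * spec.n_cases, dtype="Int64"),
        "mais": mais,
    })
    dx = criterion - criterion.mean()
    dy = mais - mais.mean()
    empirical_r = float(dx @ dy / np.sqrt((dx @ dx) * (dy @ dy)))
    truth = {
        "severity": severity,
        "criterion_noiseless": link_vals,
        "noise_sd": noise_sd,
        "empirical_r": empirical_r,
        "spec": spec,
    }
    return criteria, injuries, truth
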