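"""Packaged study tables and one-command reproduction of the correlation result.

The package ships the published tables of the 31-case vulnerable-road-user
(VRU) accident study as delimited text resources:

* ``table1`` — case metadata (VRU type, anthropometry, vehicle, impact speeds)
* ``table2`` — head-injury ratings (DAI AIS, contusion AIS, MAIS; '-' = missing)
* ``table4`` — the five kinematic criterion values per case
* ``table6`` — DAI sub-study (8 cases): CSDM_0.15, CSDM_0.25, MPS
* ``table7`` — contusion sub-study (7 cases): MPS, DDM

Loaders verify a recorded checksum and never mutate the packaged data.
:func:`reproduce_table5` recomputes the published criterion-vs-MAIS Pearson
correlations from tables 4 and 2 and tabulates them beside the published
values.

Fixture notes: the tables are stored verbatim, quirks included — Case 8 has a
missing DAI AIS yet MAIS 4 with contusion AIS 3, and Case 10 records MAIS 4
with no sub-injury listed (injuries outside the DAI/contusion sub-studies).
No imputation is performed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Iterable, Sequence

import pandas as pd

from .errors import IntegrityError, ValidationError
from .evaluation import EvaluationReport, evaluate_criteria

_FIXTURES = {
    "table1": ("table1_cases.csv",
               "c640e6d984254ddbb130d6d78c101ed8b590ff01b00b8ff9c7aa15d89ba0ce95", 31),
    "table2": ("table2_injuries.csv",
               "6b3d9c4d6e5488490dff059c5d0cadc3e3a08b6cf0d2a349d533043282092bc3", 31),
    "table4": ("table4_criteria.csv",
               "506cd1c8dc6fdb4862bd1a9e456edd47198946078ae000cf22b9b94442757cbd", 31),
    "table6": ("table6_dai.csv",
               "adfb47486b7e66888fa939681988d4ea4ed59fcbd06bccc3cf738bf7bff439b2", 8),
    "table7": ("table7_contusion.csv",
               "37ecf4f4c7b2f6e7a948494aef6cd29bd3f061006a41672a98cdc8c0a755dfc6", 7),
}

#: Published correlation coefficients (criterion vs MAIS, all 31 cases).
PUBLISHED_TABLE5 = {"HIC": 0.606, "GAMBIT": 0.332, "BrIC": 0.340,
                    "RIC": 0.398, "HIP": 0.403}

_INT_COLS = {"table2": ["dai_ais", "contusion_ais", "mais"],
             "table6": ["dai_ais"], "table7": ["contusion_ais"]}


def load_fixture(table_id: str) -> pd.DataFrame:
    """Load a packaged study table by id ('table1', 'table2', 'table4',
    'table6' or 'table7'), checksum-verified."""
    if table_id not in _FIXTURES:
        raise ValidationError(f"unknown fixture {table_id!r}; "
                              f"choose from {sorted(_FIXTURES)}")
    fname, digest, n_rows = _FIXTURES[table_id]
    res = resources.files("headcrit.data").joinpath(fname)
    raw = res.read_bytes()
    actual = hashlib.sha256(raw).hexdigest()
    if actual != digest:
        raise IntegrityError(f"{fname}: checksum mismatch ({actual})")
    with res.open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh)
    for col in _INT_COLS.get(table_id, []):
        df[col] = df[col].astype("Int64")
    if len(df) != n_rows:
        raise IntegrityError(f"{fname}: expected {n_rows} rows, got {len(df)}")
    return df


@dataclass(frozen=True)
class AccidentCase:
    """One row of the case-metadata table."""

    case_id: int
    vru_type: str
    gender: str
    stature_cm: float
    weight_kg: float
    age: float
    vehicle_brand_model: str
    vehicle_weight_kg: float
    vehicle_length_mm: int
    vehicle_width_mm: int
    vehicle_height_mm: int
    impact_speed_vehicle_kmh: float
    impact_speed_vru_kmh: float

    def __post_init__(self) -> None:
        if self.vru_type not in ("pedestrian", "cyclist", "electric_two_wheeler"):
            raise ValidationError(f"unknown VRU type {self.vru_type!r}")
        if self.impact_speed_vehicle_kmh < 0 or self.impact_speed_vru_kmh < 0:
            raise ValidationError("impact speeds must be non-negative")


def load_cases() -> list[AccidentCase]:
    """The 31 accident cases as typed records."""
    df = load_fixture("table1")
    return [AccidentCase(**row) for row in df.to_dict(orient="records")]


#: Named selection predicates mirroring the study's inclusion criteria plus
#: VRU-type filters. The packaged cohort already satisfies the three
#: inclusion criteria (VRU hit by car, head hit the front windshield, head
#: injury occurred), so those predicates are identity filters on it.
SELECTION_PREDICATES: dict[str, Callable[[AccidentCase], bool]] = {
    "vru_impacts_vehicle": lambda c: True,
    "head_impacts_windshield": lambda c: True,
    "head_injury_occurred": lambda c: True,
    "pedestrian": lambda c: c.vru_type == "pedestrian",
    "cyclist": lambda c: c.vru_type == "cyclist",
    "electric_two_wheeler": lambda c: c.vru_type == "electric_two_wheeler",
    "two_wheeler": lambda c: c.vru_type in ("cyclist", "electric_two_wheeler"),
}


def select_cases(cases: Sequence[AccidentCase],
                 predicates: Iterable[str] = ()) -> list[AccidentCase]:
    """Filter cases by named predicates (conjunction), order preserved."""
    preds = []
    for name in predicates:
        if name not in SELECTION_PREDICATES:
            raise ValidationError(f"unknown predicate {name!r}; "
                                  f"choose from {sorted(SELECTION_PREDICATES)}")
        preds.append(SELECTION_PREDICATES[name])
    return [c for c in cases if all(p(c) for p in preds)]


def reproduce_table5() -> tuple[EvaluationReport, pd.DataFrame]:
    """Recompute the five criterion-vs-MAIS correlations from the packaged
    criterion and injury tables and compare them to the published values.

    Returns the evaluation report plus a comparison frame with columns
    criterion, r_computed, r_published, abs_diff. Deterministic and
    idempotent.
    """
    criteria = load_fixture("table4")
    injuries = load_fixture("table2")
    report = evaluate_criteria(criteria, injuries)
    rows = [{"criterion": name,
             "r_computed": report.r[name],
             "r_published": PUBLISHED_TABLE5[name],
             "abs_diff": abs(report.r[name] - PUBLISHED_TABLE5[name])}
            for name in PUBLISHED_TABLE5]
    return report, pd.DataFrame(rows)
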