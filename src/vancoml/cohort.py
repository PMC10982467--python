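"""Virtual adult patient cohorts for vancomycin clearance simulation.

A cohort is a :class:`pandas.DataFrame` with one row per patient and the
column schema in :data:`COHORT_COLUMNS`:

``id``            integer patient id (0-based)
``sex``           ``"male"`` / ``"female"``
``age_years``     age in years
``weight_kg``     body weight in kg
``scr_umol_L``    serum creatinine in µmol/L
``clcr_mL_min``   creatinine clearance in mL/min (Cockcroft–Gault, derived)
``cl_true_L_h``   realized individual vancomycin clearance in L/h
                  (NaN until populated by :func:`vancoml.ppk.simulate_individual_cl`)

Covariates are drawn independently and uniformly over their configured
ranges, with sex a Bernoulli draw; the default ranges are age 20–90 y,
weight 40–85 kg, serum creatinine 50–500 µmol/L and a 1:1 sex ratio, which
places each covariate's median at the midpoint of its range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError

COHORT_COLUMNS = [
    "id",
    "sex",
    "age_years",
    "weight_kg",
    "scr_umol_L",
    "clcr_mL_min",
    "cl_true_L_h",
]

#: µmol/L per mg/dL of creatinine
SCR_UMOL_PER_MGDL = 88.4


@dataclass(frozen=True)
class PatientRecord:
    """A single virtual patient.

    ``cl_true_L_h`` is ``None`` until an individual clearance has been
    realized from the PK model.
    """

    id: int
    sex: str
    age_years: float
    weight_kg: float
    scr_umol_L: float
    clcr_mL_min: float
    cl_true_L_h: float | None = None

    def __post_init__(self) -> None:
        if self.id < 0:
            raise ConfigurationError(f"patient id must be >= 0, got {self.id}")
        if self.sex not in ("male", "female"):
            raise ConfigurationError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.clcr_mL_min <= 0:
            raise DomainError(f"clcr must be > 0, got {self.clcr_mL_min}")
        if self.cl_true_L_h is not None and self.cl_true_L_h <= 0:
            raise DomainError(f"cl_true must be > 0, got {self.cl_true_L_h}")


@dataclass(frozen=True)
class CohortSpec:
    """Sampling design of a virtual cohort.

    Ranges are inclusive ``(min, max)`` bounds of independent uniform draws;
    ``sex_ratio`` is the expected male fraction.
    """

    n: int = 1000
    age_range: tuple[float, float] = (20.0, 90.0)
    weight_range: tuple[float, float] = (40.0, 85.0)
    scr_range: tuple[float, float] = (50.0, 500.0)
    sex_ratio: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ConfigurationError(f"cohort size must be >= 0, got n={self.n}")
        for name, (lo, hi) in (
            ("age_range", self.age_range),
            ("weight_range", self.weight_range),
            ("scr_range", self.scr_range),
        ):
            if lo > hi:
                raise ConfigurationError(f"{name}: min {lo} exceeds max {hi}")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ConfigurationError(f"sex_ratio must be in [0, 1], got {self.sex_ratio}")


def cockcroft_gault(age_years, weight_kg, scr_umol_L, sex):
    """Creatinine clearance (mL/min) by Cockcroft–Gault.

    CLcr = (140 − age) · weight / (72 · Scr[mg/dL]), times 0.85 for women,
    with serum creatinine converted from µmol/L (÷ 88.4). Accepts scalars or
    arrays; ``sex`` is ``"male"``/``"female"`` or an array thereof.
    """
    age = np.asarray(age_years, dtype=float)
    weight = np.asarray(weight_kg, dtype=float)
    scr = np.asarray(scr_umol_L, dtype=float)
    if np.any(scr <= 0):
        raise DomainError("serum creatinine must be > 0")
    if np.any(weight <= 0):
        raise DomainError("weight must be > 0")
    if np.any(age >= 140):
        raise DomainError("age must be < 140 years (Cockcroft-Gault numerator)")
    female = np.asarray(sex) == "female"
    scr_mgdl = scr / SCR_UMOL_PER_MGDL
    clcr = (140.0 - age) * weight / (72.0 * scr_mgdl)
    clcr = np.where(female, clcr * 0.85, clcr)
    if clcr.ndim == 0:
        return float(clcr)
    return clcr


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a seeded virtual cohort and derive creatinine clearance.

    Returns a DataFrame with :data:`COHORT_COLUMNS`; ``cl_true_L_h`` is NaN
    (no individual clearance realized yet). Two calls with the same spec
    produce identical frames.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    age = rng.uniform(*spec.age_range, size=n)
    weight = rng.uniform(*spec.weight_range, size=n)
    scr = rng.uniform(*spec.scr_range, size=n)
    male = rng.random(n) < spec.sex_ratio
    sex = np.where(male, "male", "female")
    if n > 0:
        clcr = cockcroft_gault(age, weight, scr, sex)
    else:
        clcr = np.empty(0)
    return pd.DataFrame(
        {
            "id": np.arange(n, dtype=int),
            "sex": sex,
            "age_years": age,
            "weight_kg": weight,
            "scr_umol_L": scr,
            "clcr_mL_min": np.atleast_1d(clcr) if n else clcr,
            "cl_true_L_h": np.full(n, np.nan),
        }
    )


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort to CSV (UTF-8, header row, 17-digit float round-trip)."""
    cohort.to_csv(path, index=False, float_format="%.17g", encoding="utf-8")


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort`."""
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"cohort CSV missing columns: {missing}")
    return df[COHORT_COLUMNS]
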