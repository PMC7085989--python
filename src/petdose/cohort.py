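"""Patient habitus parameters and stratified synthetic cohorts.

A subject is described by sex, body mass (kg) and body length (m); from
these the body mass index (BMI, kg/m²), the mass-per-length ratio (kg/m)
and the lean body mass (LBM, kg) are derived.  LBM uses the Janmahasatian
fat-free-mass equations::

    male:    LBM = 9270·W / (6680 + 216·BMI)
    female:  LBM = 9270·W / (8780 + 244·BMI)

with W the body mass in kg.

Synthetic cohorts mirror a weight-stratified prospective design: a fixed
number of subjects per 10-kg body-mass stratum, masses drawn uniformly
within each stratum, lengths from a truncated normal per sex and sex from
a Bernoulli draw.  All sampling is deterministic given the design seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PatientRecord",
    "CohortDesign",
    "derive_parameters",
    "lean_body_mass",
    "default_design",
    "sample_cohort",
    "cohort_to_frame",
    "write_cohort_csv",
    "read_cohort_csv",
]

# Janmahasatian fat-free-mass coefficients: numerator, offset, BMI slope.
_JANMAHASATIAN = {
    "male": (9270.0, 6680.0, 216.0),
    "female": (9270.0, 8780.0, 244.0),
}

_MASS_RANGE = (20.0, 300.0)  # kg, plausibility bounds
_LENGTH_RANGE = (1.0, 2.5)  # m


@dataclass(frozen=True)
class PatientRecord:
    """One subject's measured and derived habitus parameters."""

    id: str
    sex: str
    body_mass: float  # kg
    length: float  # m
    bmi: float  # kg/m²
    mass_per_length: float  # kg/m
    lbm: float  # kg


@dataclass(frozen=True)
class CohortDesign:
    """Stratified sampling plan for a synthetic cohort.

    ``strata`` is an ordered list of ``(lower_kg, upper_kg, count)``
    tuples; masses are drawn uniformly within each stratum.  Lengths are
    drawn from a per-sex normal distribution truncated to
    ``length_bounds``; sex is Bernoulli with ``sex_ratio`` the male
    fraction.
    """

    strata: tuple[tuple[float, float, int], ...]
    seed: int = 0
    length_distribution: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"male": (1.74, 0.10), "female": (1.74, 0.10)}
    )
    sex_ratio: float = 12 / 21
    length_bounds: tuple[float, float] = (1.5, 2.0)

    def __post_init__(self) -> None:
        prev_hi = -np.inf
        for lo, hi, count in self.strata:
            if hi <= lo:
                raise ValueError(f"stratum ({lo}, {hi}) has upper <= lower")
            if lo < prev_hi:
                raise ValueError("strata must be ordered and non-overlapping")
            if count < 0:
                raise ValueError("stratum count must be >= 0")
            prev_hi = hi
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must lie in [0, 1]")


def lean_body_mass(sex: str, body_mass: float, bmi: float) -> float:
    """Janmahasatian fat-free mass (kg) from sex, body mass and BMI."""
    try:
        num, offset, slope = _JANMAHASATIAN[sex]
    except KeyError:
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}") from None
    return num * body_mass / (offset + slope * bmi)


def derive_parameters(
    sex: str, body_mass: float, length: float, id: str = ""
) -> PatientRecord:
    """Fill the derived habitus parameters for one subject.

    Parameters
    ----------
    sex : {'male', 'female'}
    body_mass : float
        Body mass in kg; must lie in (20, 300).
    length : float
        Body length in m; must lie in (1.0, 2.5).
    id : str
        Optional subject identifier carried into the record.
    """
    if sex not in _JANMAHASATIAN:
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    if not _MASS_RANGE[0] < body_mass < _MASS_RANGE[1]:
        raise ValueError(
            f"body_mass={body_mass} kg outside plausible range {_MASS_RANGE}"
        )
    if not _LENGTH_RANGE[0] < length < _LENGTH_RANGE[1]:
        raise ValueError(f"length={length} m outside plausible range {_LENGTH_RANGE}")
    bmi = body_mass / length**2
    return PatientRecord(
        id=id,
        sex=sex,
        body_mass=float(body_mass),
        length=float(length),
        bmi=float(bmi),
        mass_per_length=float(body_mass / length),
        lbm=float(lean_body_mass(sex, body_mass, bmi)),
    )


#: Seven 10-kg strata of three subjects each, 50–120 kg.
DEFAULT_STRATA: tuple[tuple[float, float, int], ...] = (
    (50.0, 60.0, 3),
    (61.0, 70.0, 3),
    (71.0, 80.0, 3),
    (81.0, 90.0, 3),
    (91.0, 100.0, 3),
    (101.0, 110.0, 3),
    (111.0, 120.0, 3),
)

#: Printed cohort body-mass range (kg); used for regimen tables.
STUDY_MASS_RANGE: tuple[int, int] = (55, 124)


def default_design(seed: int = 0) -> CohortDesign:
    """The 21-subject stratified design (7 strata × 3 subjects)."""
    return CohortDesign(strata=DEFAULT_STRATA, seed=seed)


def sample_cohort(
    design: CohortDesign, rng: np.random.Generator | None = None
) -> list[PatientRecord]:
    """Draw a synthetic cohort following ``design``.

    Deterministic for a fixed ``design.seed`` (unless an explicit ``rng``
    is supplied).  Returns one record per planned subject, ordered by
    stratum.
    """
    if not design.strata:
        raise ValueError("design has no strata")
    if rng is None:
        rng = np.random.default_rng(design.seed)
    records: list[PatientRecord] = []
    idx = 0
    for lo, hi, count in design.strata:
        for _ in range(count):
            mass = float(rng.uniform(lo, hi))
            sex = "male" if rng.random() < design.sex_ratio else "female"
            mu, sd = design.length_distribution[sex]
            a, b = design.length_bounds
            length = float(
                stats.truncnorm.ppf(
                    rng.random(), (a - mu) / sd, (b - mu) / sd, loc=mu, scale=sd
                )
            )
            records.append(
                derive_parameters(sex, mass, length, id=f"P{idx:03d}")
            )
            idx += 1
    return records


def cohort_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    """Tabulate records with the canonical cohort CSV columns."""
    return pd.DataFrame(
        [
            {
                "id": r.id,
                "sex": r.sex,
                "body_mass_kg": r.body_mass,
                "length_m": r.length,
                "bmi": r.bmi,
                "mass_per_length": r.mass_per_length,
                "lbm_kg": r.lbm,
            }
            for r in records
        ]
    )


def write_cohort_csv(records: Iterable[PatientRecord], path: str | Path) -> None:
    cohort_to_frame(records).to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> list[PatientRecord]:
    """Read a cohort CSV, re-deriving the dependent parameters."""
    frame = pd.read_csv(path)
    return [
        derive_parameters(row.sex, row.body_mass_kg, row.length_m, id=str(row.id))
        for row in frame.itertuples()
    ]
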