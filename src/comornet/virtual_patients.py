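"""Virtual patient cohorts.

Generates demographically plausible virtual populations (age, sex, weight,
height) by independent truncated-normal sampling, one cohort per age
category (adult: 18+ years; pediatric-adolescent: 6 to <18 years) and
comorbidity. The minimum cohort size of 71 reflects the statistical-power
floor adopted for the study design; the default cohort size is 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

MIN_COHORT_SIZE = 71

__all__ = [
    "CohortSpec",
    "VirtualPatient",
    "CohortError",
    "generate_cohort",
    "adult_default_spec",
    "pediatric_default_spec",
    "write_cohort_csv",
    "load_cohort_csv",
]


class CohortError(ValueError):
    pass


@dataclass(frozen=True)
class CohortSpec:
    """Sampling specification for one virtual cohort.

    ``label`` must be "adult" (ages >= 18) or "pediatric-adolescent"
    (ages in [6, 18)). ``min_n`` is the enforced population-size floor;
    lowering it below the default 71 is only meant for toy runs.
    """

    label: str
    n: int = 100
    age_range: tuple[float, float] = (18.0, 65.0)
    age_mean: float = 35.0
    age_sd: float = 11.0
    fraction_male: float = 0.6
    weight_mean: float = 75.0
    weight_sd: float = 13.0
    weight_range: tuple[float, float] = (40.0, 140.0)
    height_mean: float = 172.0
    height_sd: float = 9.0
    height_range: tuple[float, float] = (145.0, 205.0)
    seed: int = 0
    comorbidity: str = ""
    min_n: int = MIN_COHORT_SIZE

    def __post_init__(self) -> None:
        if self.label not in ("adult", "pediatric-adolescent"):
            raise CohortError(f"unknown cohort label {self.label!r}")
        if self.n < self.min_n:
            raise CohortError(
                f"cohort size {self.n} below minimum population size {self.min_n}"
            )
        lo, hi = self.age_range
        if self.label == "adult" and lo < 18:
            raise CohortError("adult cohort must have age range >= 18")
        if self.label == "pediatric-adolescent" and not (6 <= lo and hi <= 18):
            raise CohortError("pediatric-adolescent cohort must have age range within [6, 18)")
        for name, (low, high), mean in (
            ("age", self.age_range, self.age_mean),
            ("weight", self.weight_range, self.weight_mean),
            ("height", self.height_range, self.height_mean),
        ):
            if not (low < high):
                raise CohortError(f"{name} range is empty")
            if not (low <= mean <= high):
                raise CohortError(f"{name} mean {mean} outside its range {(low, high)}")
        if not (0 <= self.fraction_male <= 1):
            raise CohortError("fraction_male must be in [0, 1]")


@dataclass(frozen=True)
class VirtualPatient:
    id: str
    age: float
    sex: str
    weight: float
    height: float
    cohort: str
    comorbidity: str = ""

    def __post_init__(self) -> None:
        if self.age <= 0 or self.weight <= 0 or self.height <= 0:
            raise CohortError(f"{self.id}: non-positive anthropometrics")
        if self.sex not in ("M", "F"):
            raise CohortError(f"{self.id}: sex must be M or F")


def adult_default_spec(**overrides) -> CohortSpec:
    """Default adult cohort: 100 patients, ages 18-65, trial-typical anthropometrics."""
    return CohortSpec(label="adult", **overrides)


def pediatric_default_spec(**overrides) -> CohortSpec:
    """Default pediatric-adolescent cohort: 100 patients, ages 6 to <18."""
    defaults = dict(
        age_range=(6.0, 17.99),
        age_mean=11.5,
        age_sd=3.0,
        fraction_male=0.67,
        weight_mean=42.0,
        weight_sd=14.0,
        weight_range=(18.0, 100.0),
        height_mean=148.0,
        height_sd=16.0,
        height_range=(110.0, 190.0),
    )
    defaults.update(overrides)
    return CohortSpec(label="pediatric-adolescent", **defaults)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, low: float, high: float, n: int) -> np.ndarray:
    a, b = (low - mean) / sd, (high - mean) / sd
    dist = truncnorm(a, b, loc=mean, scale=sd)
    return dist.ppf(rng.uniform(size=n))


def generate_cohort(spec: CohortSpec) -> list[VirtualPatient]:
    """Sample ``spec.n`` virtual patients; seeded and reproducible."""
    rng = np.random.default_rng(spec.seed)
    ages = _truncated_normal(rng, spec.age_mean, spec.age_sd, *spec.age_range, spec.n)
    weights = _truncated_normal(rng, spec.weight_mean, spec.weight_sd, *spec.weight_range, spec.n)
    heights = _truncated_normal(rng, spec.height_mean, spec.height_sd, *spec.height_range, spec.n)
    sexes = np.where(rng.uniform(size=spec.n) < spec.fraction_male, "M", "F")
    prefix = spec.comorbidity or spec.label
    return [
        VirtualPatient(
            id=f"{prefix}-{spec.label}-{i:04d}",
            age=float(ages[i]),
            sex=str(sexes[i]),
            weight=float(weights[i]),
            height=float(heights[i]),
            cohort=spec.label,
            comorbidity=spec.comorbidity,
        )
        for i in range(spec.n)
    ]


def write_cohort_csv(patients: Sequence[VirtualPatient], path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": [p.id for p in patients],
            "age": [p.age for p in patients],
            "sex": [p.sex for p in patients],
            "weight": [p.weight for p in patients],
            "height": [p.height for p in patients],
            "cohort": [p.cohort for p in patients],
            "comorbidity": [p.comorbidity for p in patients],
        }
    ).to_csv(path, index=False)


def load_cohort_csv(path: str | Path) -> list[VirtualPatient]:
    frame = pd.read_csv(path)
    return [
        VirtualPatient(
            id=str(r.id),
            age=float(r.age),
            sex=str(r.sex),
            weight=float(r.weight),
            height=float(r.height),
            cohort=str(r.cohort),
            comorbidity="" if pd.isna(r.comorbidity) else str(r.comorbidity),
        )
        for r in frame.itertuples()
    ]
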