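"""Weighted obstetric comorbidity scoring.

The obstetric comorbidity index (OBCMI) condenses the comorbidities and
pregnancy risk factors a woman presents with on admission for delivery into
one additive integer score.  Each item carries an integer weight between 1
and 5.  Three groups of items are mutually exclusive rather than additive:

* maternal age is scored for exactly one band (35-39 -> 1, 40-44 -> 2,
  >= 45 -> 3; under 35 contributes nothing);
* body-mass index is scored for the highest applicable band only
  (> 40 kg/m^2 -> 2, > 50 kg/m^2 -> 3);
* the hypertensive-disorder category is scored once: preeclampsia with
  severe features or eclampsia carries 5 points and supersedes the 2-point
  non-severe category (mild/unspecified preeclampsia, gestational
  hypertension, chronic hypertension), any combination of which scores a
  single 2.

Two built-in weight tables are shipped as package data: the prospectively
validated system, and a locally modified system that adds 2 points each for
spontaneous rupture of membranes beyond 48 hours and for an unbooked
pregnancy (no adequate antenatal care before presenting for delivery).
Custom tables with the same band/hierarchy structure can be supplied as
JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Iterable, Sequence

from pydantic import BaseModel, ConfigDict, Field, field_validator

__all__ = [
    "FLAG_FIELDS",
    "HYPERTENSION_SEVERE",
    "HYPERTENSION_NONSEVERE",
    "RiskFactorProfile",
    "ScoringSystem",
    "OBCMIScore",
    "available_systems",
    "get_system",
    "load_system_file",
    "compute_obcmi",
    "max_score",
    "score_cohort",
]

#: every boolean scoring input, in canonical (CSV column) order
FLAG_FIELDS: tuple[str, ...] = (
    "severe_preeclampsia_or_eclampsia",
    "congestive_heart_failure",
    "pulmonary_hypertension",
    "congenital_or_valvular_heart_disease",
    "placenta_previa_accreta_abruption",
    "ischemic_heart_disease_or_arrhythmia",
    "sickle_cell_bleeding_coagulopathy_anticoagulation",
    "mild_preeclampsia",
    "gestational_hypertension",
    "chronic_hypertension",
    "multiple_gestation",
    "iufd",
    "autoimmune_or_lupus",
    "hiv_aids",
    "epilepsy_cva_neuromuscular",
    "substance_abuse",
    "previous_cesarean_or_myomectomy",
    "chronic_renal_disease",
    "asthma",
    "diabetes_on_insulin",
    "alcohol_abuse",
    "srom_over_48h",
    "unbooked",
)

HYPERTENSION_SEVERE = "severe_preeclampsia_or_eclampsia"
HYPERTENSION_NONSEVERE: tuple[str, ...] = (
    "mild_preeclampsia",
    "gestational_hypertension",
    "chronic_hypertension",
)
_HYPERTENSION_ALL = (HYPERTENSION_SEVERE, *HYPERTENSION_NONSEVERE)


class RiskFactorProfile(BaseModel):
    """Scoring inputs for one woman at admission for delivery.

    Flags default to ``False`` so profiles can be built by naming only the
    risk factors that are present; after validation every flag is a
    concrete boolean.  Age and BMI are bounded by loose plausibility
    limits; out-of-range values are rejected rather than clamped.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    age_years: int = Field(ge=12, le=60)
    bmi: float = Field(gt=10, lt=100)

    severe_preeclampsia_or_eclampsia: bool = False
    congestive_heart_failure: bool = False
    pulmonary_hypertension: bool = False
    congenital_or_valvular_heart_disease: bool = False
    placenta_previa_accreta_abruption: bool = False
    ischemic_heart_disease_or_arrhythmia: bool = False
    sickle_cell_bleeding_coagulopathy_anticoagulation: bool = False
    mild_preeclampsia: bool = False
    gestational_hypertension: bool = False
    chronic_hypertension: bool = False
    multiple_gestation: bool = False
    iufd: bool = False
    autoimmune_or_lupus: bool = False
    hiv_aids: bool = False
    epilepsy_cva_neuromuscular: bool = False
    substance_abuse: bool = False
    previous_cesarean_or_myomectomy: bool = False
    chronic_renal_disease: bool = False
    asthma: bool = False
    diabetes_on_insulin: bool = False
    alcohol_abuse: bool = False
    srom_over_48h: bool = False
    unbooked: bool = False


class ScoringSystem(BaseModel):
    """A named weight table plus the age/BMI band definitions.

    ``weights`` maps risk-factor flag names to integer points (1..5).  Items
    absent from the table contribute nothing even when flagged, so partial
    tables are legal.  ``age_bands`` is an ascending list of
    ``(lower_bound_years, points)`` pairs scored inclusively
    (``age >= lower_bound``); ``bmi_bands`` is an ascending list of
    ``(threshold_kg_m2, points)`` pairs scored strictly
    (``bmi > threshold``).  In both cases only the highest applicable band
    counts.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    weights: dict[str, int]
    age_bands: tuple[tuple[int, int], ...] = ((35, 1), (40, 2), (45, 3))
    bmi_bands: tuple[tuple[float, int], ...] = ((40, 2), (50, 3))

    @field_validator("weights")
    @classmethod
    def _check_weights(cls, weights: dict[str, int]) -> dict[str, int]:
        unknown = sorted(set(weights) - set(FLAG_FIELDS))
        if unknown:
            raise ValueError(f"unknown scoring items: {unknown}")
        bad = {k: v for k, v in weights.items() if not 1 <= int(v) <= 5}
        if bad:
            raise ValueError(f"weights must be integers in 1..5, got {bad}")
        return weights

    @field_validator("age_bands", "bmi_bands")
    @classmethod
    def _check_bands(cls, bands):
        bounds = [b for b, _ in bands]
        if bounds != sorted(bounds):
            raise ValueError("bands must be listed in ascending bound order")
        return bands


@dataclass(frozen=True)
class OBCMIScore:
    """A computed index value, tagged with the system that produced it."""

    value: int
    system: str

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("score cannot be negative")

    def __int__(self) -> int:  # arithmetic convenience
        return self.value


@lru_cache(maxsize=1)
def _builtin_systems() -> dict[str, ScoringSystem]:
    text = resources.files("obcmi").joinpath("data/weights.json").read_text("utf-8")
    raw = json.loads(text)
    return {name: ScoringSystem(name=name, **spec) for name, spec in raw.items()}


def available_systems() -> tuple[str, ...]:
    """Names of the built-in scoring systems."""
    return tuple(_builtin_systems())


def get_system(name: str) -> ScoringSystem:
    """Return a built-in scoring system (``validated`` or ``modified``)."""
    systems = _builtin_systems()
    try:
        return systems[name]
    except KeyError:
        raise KeyError(
            f"unknown scoring system {name!r}; built-ins: {sorted(systems)}"
        ) from None


def load_system_file(path, name: str | None = None) -> ScoringSystem:
    """Load a user-supplied weight table from a JSON file.

    The file holds ``weights`` plus optional ``age_bands``/``bmi_bands``
    in the same shape as the shipped table.
    """
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    raw.setdefault("name", name or "custom")
    if name is not None:
        raw["name"] = name
    return ScoringSystem(**raw)


def _band_points(value: float, bands: Iterable[tuple[float, int]], strict: bool) -> int:
    points = 0
    for bound, pts in bands:
        if (value > bound) if strict else (value >= bound):
            points = pts
    return points


def compute_obcmi(profile: RiskFactorProfile, system: ScoringSystem) -> OBCMIScore:
    """Score one profile under one scoring system.

    Applies the single-band rules for age and BMI and scores the
    hypertensive category once (severe preeclampsia/eclampsia supersedes
    the non-severe 2-point category); every other flagged item adds its
    weight independently.
    """
    w = system.weights
    total = 0

    if profile.severe_preeclampsia_or_eclampsia and HYPERTENSION_SEVERE in w:
        total += w[HYPERTENSION_SEVERE]
    else:
        category = [
            w[f] for f in HYPERTENSION_NONSEVERE if f in w and getattr(profile, f)
        ]
        if category:
            total += max(category)

    for item, weight in w.items():
        if item in _HYPERTENSION_ALL:
            continue
        if getattr(profile, item):
            total += weight

    total += _band_points(profile.age_years, system.age_bands, strict=False)
    total += _band_points(profile.bmi, system.bmi_bands, strict=True)
    return OBCMIScore(value=total, system=system.name)


def max_score(system: ScoringSystem) -> int:
    """Highest score attainable under the exclusion rules.

    Computed from the weight table itself: all independent items, plus the
    best hypertensive-category item, plus the top age and BMI bands.
    """
    total = sum(v for k, v in system.weights.items() if k not in _HYPERTENSION_ALL)
    htn_options = [
        system.weights[f] for f in _HYPERTENSION_ALL if f in system.weights
    ]
    total += max(htn_options, default=0)
    total += max((p for _, p in system.age_bands), default=0)
    total += max((p for _, p in system.bmi_bands), default=0)
    return total


def score_cohort(
    records: Sequence[RiskFactorProfile], system: ScoringSystem
) -> list[OBCMIScore]:
    """Element-wise :func:`compute_obcmi`, preserving order and length.

    Validation failures are re-raised with the offending row index.
    """
    scores: list[OBCMIScore] = []
    for i, record in enumerate(records):
        try:
            scores.append(compute_obcmi(record, system))
        except Exception as exc:  # pragma: no cover - defensive re-raise
            raise type(exc)(f"record {i}: {exc}") from exc
    return scores
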