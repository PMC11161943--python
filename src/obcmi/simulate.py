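"""Synthetic delivery-cohort generator.

Emulates a tertiary-centre cohort of ~1000 deliveries in which risk-factor
prevalences match the study population's published marginals and the two
composite outcomes follow a single-index logistic model in the comorbidity
score::

    P(outcome | score s) = expit(beta0 + beta1 * s)

``beta1`` is the log of the per-unit odds ratio (defaults: OR 1.44 for
severe maternal morbidity, OR 1.28 for cumulative fetal morbidity under the
modified scoring system) and ``beta0`` is calibrated by root finding so the
cohort-average event probability hits the target incidence (13.1% and 11.3%
respectively).  Individual indicators are then allocated among
composite-positive deliveries in proportion to their observed conditional
frequencies.

Risk factors are sampled independently (only marginal prevalences are
published); the hypertensive-disorder category is drawn as a three-way
categorical (none / non-severe / severe) so the mutual exclusion between
severe preeclampsia and the non-severe category holds by construction.

Randomness uses one root seed split into per-stage child streams
(profiles, maternal outcomes, fetal outcomes, indicator allocation), so
adding a stage never perturbs earlier draws and identical configurations
reproduce identical cohorts byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator
from scipy.optimize import brentq
from scipy.special import expit

from .core import (
    HYPERTENSION_NONSEVERE,
    RiskFactorProfile,
    ScoringSystem,
    get_system,
    score_cohort,
)
from .outcomes import CFM_INDICATORS, SMM_INDICATORS, OutcomeRecord

__all__ = [
    "OutcomeModel",
    "SimulationConfig",
    "SyntheticCohort",
    "generate_profiles",
    "calibrate_intercept",
    "simulate_outcomes",
    "generate_cohort",
]

#: flags that make up the pooled "prior medical comorbidity" block whose
#: combined prevalence (3.5%) is published without a per-item breakdown;
#: split uniformly across the constituents.
MEDICAL_BLOCK_FLAGS: tuple[str, ...] = (
    "autoimmune_or_lupus",
    "sickle_cell_bleeding_coagulopathy_anticoagulation",
    "epilepsy_cva_neuromuscular",
    "congenital_or_valvular_heart_disease",
    "ischemic_heart_disease_or_arrhythmia",
    "asthma",
    "chronic_renal_disease",
)

# conditional indicator frequencies given the composite, from the study's
# indicator counts (130 maternal and 113 fetal composite events)
_SMM_INDICATOR_RATES = {
    "postpartum_hemorrhage": 42 / 130,
    "hdu_admission": 55 / 130,
    "surgical_complication": 42 / 130,
    "sepsis": 14 / 130,
    "cardiac_complication": 6 / 130,
    "chest_complication": 8 / 130,
    "renal_complication": 21 / 130,
    "neurological_complication": 11 / 130,
    "anesthesia_complication": 5 / 130,
    "maternal_death": 0.0,
}
_CFM_INDICATOR_RATES = {
    "fetal_distress_cesarean": 56 / 113,
    "low_apgar_5min": 9 / 113,
    "low_ua_ph": 49 / 113,
    "hie": 9 / 113,
    "nicu_admission_asphyxia": 12 / 113,
}

# integer age ranges for the five demographic bands (18-29 is the
# reference band; 45+ capped at 50 for plausibility)
_AGE_BAND_RANGES = ((18, 29), (30, 34), (35, 39), (40, 44), (45, 50))


class OutcomeModel(BaseModel):
    """Logistic outcome model for one composite."""

    model_config = ConfigDict(frozen=True)

    or_per_unit: float = Field(gt=0)
    target_incidence: float = Field(gt=0, lt=1)
    indicator_rates: dict[str, float]

    @property
    def beta1(self) -> float:
        return float(np.log(self.or_per_unit))

    @field_validator("indicator_rates")
    @classmethod
    def _check_rates(cls, rates):
        bad = {k: v for k, v in rates.items() if not 0 <= v <= 1}
        if bad:
            raise ValueError(f"indicator rates must lie in [0,1]: {bad}")
        return rates


def _default_smm_model() -> OutcomeModel:
    return OutcomeModel(
        or_per_unit=1.44, target_incidence=0.131, indicator_rates=_SMM_INDICATOR_RATES
    )


def _default_cfm_model() -> OutcomeModel:
    return OutcomeModel(
        or_per_unit=1.28, target_incidence=0.113, indicator_rates=_CFM_INDICATOR_RATES
    )


class SimulationConfig(BaseModel):
    """All knobs of the generator, defaulting to the study conditions."""

    model_config = ConfigDict(frozen=True)

    n: int = Field(default=999, ge=0)
    seed: int = 0
    system: str = "modified"

    # P(age band) for <30, 30-34, 35-39, 40-44, >=45; any shortfall from 1
    # is folded into the reference (<30) band
    age_band_probs: tuple[float, float, float, float, float] = (
        0.397,
        0.356,
        0.185,
        0.058,
        0.003,
    )
    bmi_over_40: float = Field(default=0.047, ge=0, le=1)  # includes >50
    bmi_over_50: float = Field(default=0.002, ge=0, le=1)

    nonsevere_hypertension: float = Field(default=0.034, ge=0, le=1)
    severe_preeclampsia: float = Field(default=0.014, ge=0, le=1)
    medical_block_prevalence: float = Field(default=0.035, ge=0, le=1)
    flag_prevalences: dict[str, float] = Field(
        default_factory=lambda: {
            "previous_cesarean_or_myomectomy": 0.272,
            "diabetes_on_insulin": 0.049,
            "unbooked": 0.034,
            "multiple_gestation": 0.028,
            "srom_over_48h": 0.019,
            "placenta_previa_accreta_abruption": 0.022,
            "iufd": 0.004,
        }
    )

    smm_model: OutcomeModel = Field(default_factory=_default_smm_model)
    cfm_model: OutcomeModel = Field(default_factory=_default_cfm_model)

    @model_validator(mode="after")
    def _check_probs(self) -> "SimulationConfig":
        if not all(0 <= p <= 1 for p in self.age_band_probs):
            raise ValueError("age-band probabilities must lie in [0,1]")
        if sum(self.age_band_probs) > 1 + 1e-9:
            raise ValueError("age-band probabilities must sum to at most 1")
        if self.bmi_over_50 > self.bmi_over_40:
            raise ValueError("P(BMI>50) cannot exceed P(BMI>40)")
        if self.nonsevere_hypertension + self.severe_preeclampsia > 1:
            raise ValueError("hypertension category probabilities exceed 1")
        bad = {k: v for k, v in self.flag_prevalences.items() if not 0 <= v <= 1}
        if bad:
            raise ValueError(f"prevalences must lie in [0,1]: {bad}")
        return self


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort plus the configuration that produced it."""

    profiles: tuple[RiskFactorProfile, ...]
    outcomes: tuple[OutcomeRecord, ...]
    config: SimulationConfig

    def __post_init__(self) -> None:
        if len(self.profiles) != len(self.outcomes):
            raise ValueError("profiles and outcomes must align")

    def __len__(self) -> int:
        return len(self.profiles)

    @property
    def records(self) -> tuple[tuple[RiskFactorProfile, OutcomeRecord], ...]:
        return tuple(zip(self.profiles, self.outcomes))


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("profiles", "smm", "cfm", "indicators")
    return {k: np.random.default_rng(s) for k, s in zip(names, children)}


def generate_profiles(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[RiskFactorProfile]:
    """Draw ``config.n`` independent risk-factor profiles."""
    if rng is None:
        rng = _streams(config.seed)["profiles"]
    n = config.n
    if n == 0:
        return []

    probs = np.asarray(config.age_band_probs, dtype=float)
    probs = probs.copy()
    probs[0] += max(0.0, 1.0 - probs.sum())  # shortfall to reference band
    probs = probs / probs.sum()
    band = rng.choice(len(_AGE_BAND_RANGES), size=n, p=probs)
    lows = np.array([lo for lo, _ in _AGE_BAND_RANGES])
    highs = np.array([hi for _, hi in _AGE_BAND_RANGES])
    ages = rng.integers(lows[band], highs[band] + 1)

    p_mid = config.bmi_over_40 - config.bmi_over_50
    bmi_cat = rng.choice(
        3, size=n, p=[1 - config.bmi_over_40, p_mid, config.bmi_over_50]
    )
    bmi = np.round(rng.uniform(19.0, 40.0, size=n), 1)
    bmi = np.where(bmi_cat == 1, np.round(rng.uniform(40.5, 50.0, size=n), 1), bmi)
    bmi = np.where(bmi_cat == 2, np.round(rng.uniform(50.5, 58.0, size=n), 1), bmi)

    htn_cat = rng.choice(
        3,
        size=n,
        p=[
            1 - config.nonsevere_hypertension - config.severe_preeclampsia,
            config.nonsevere_hypertension,
            config.severe_preeclampsia,
        ],
    )
    nonsevere_choice = rng.integers(0, len(HYPERTENSION_NONSEVERE), size=n)

    flags: dict[str, np.ndarray] = {}
    flags["severe_preeclampsia_or_eclampsia"] = htn_cat == 2
    for j, name in enumerate(HYPERTENSION_NONSEVERE):
        flags[name] = (htn_cat == 1) & (nonsevere_choice == j)

    p_block = config.medical_block_prevalence / len(MEDICAL_BLOCK_FLAGS)
    for name in MEDICAL_BLOCK_FLAGS:
        flags[name] = rng.random(n) < p_block
    for name, p in config.flag_prevalences.items():
        flags[name] = rng.random(n) < p

    profiles = []
    for i in range(n):
        kwargs = {name: bool(values[i]) for name, values in flags.items()}
        profiles.append(
            RiskFactorProfile(age_years=int(ages[i]), bmi=float(bmi[i]), **kwargs)
        )
    return profiles


def calibrate_intercept(
    beta1: float, target_incidence: float, scores: Sequence[int]
) -> float:
    """Solve for the intercept that yields the target mean event probability.

    Finds ``beta0`` with ``mean(expit(beta0 + beta1 * s)) == target`` by
    bracketed root finding; the residual is verified to be below 1e-10.
    """
    if not 0 < target_incidence < 1:
        raise ValueError("target incidence must lie strictly in (0, 1)")
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("scores must be nonempty")

    def residual(beta0: float) -> float:
        return float(expit(beta0 + beta1 * s).mean() - target_incidence)

    span = 60.0 + abs(beta1) * float(np.abs(s).max())
    beta0 = brentq(residual, -span, span, xtol=1e-13, rtol=1e-15)
    assert abs(residual(beta0)) < 1e-10
    return float(beta0)


def _allocate_indicators(
    positive: np.ndarray, rates: dict[str, float], rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Draw indicator flags so every composite-positive row has >= 1.

    Indicators are drawn independently and all-zero rows are redrawn.
    Redrawing inflates every marginal by 1/P(any), so the draw
    probabilities are the target conditional rates scaled by the factor
    ``t`` solving ``t = 1 - prod(1 - t * r_i)``; the post-rejection
    conditional frequencies then match the targets in expectation.  When
    the rates sum to <= 1 (at most one indicator expected per case) a
    single label is drawn categorically instead.
    """
    names = list(rates)
    r = np.array([rates[k] for k in names])
    n_pos_total = int(positive.sum())
    out_zero = {k: np.zeros(positive.size, dtype=bool) for k in names}
    if n_pos_total == 0:
        return out_zero
    if r.sum() <= 0:
        out_zero[names[0]][np.flatnonzero(positive)] = True
        return out_zero
    if r.sum() <= 1:
        labels = rng.choice(len(names), size=n_pos_total, p=r / r.sum())
        rows = np.flatnonzero(positive)
        for j, name in enumerate(names):
            out_zero[name][rows[labels == j]] = True
        return out_zero

    def fixed_point(t: float) -> float:
        return 1 - np.prod(1 - t * r) - t

    t = brentq(fixed_point, 1e-9, 1 - 1e-12, xtol=1e-12)
    p = t * r
    out = out_zero
    draws = np.zeros((n_pos_total, len(names)), dtype=bool)
    pending = np.ones(n_pos_total, dtype=bool)
    while pending.any():
        k = int(pending.sum())
        draws[pending] = rng.random((k, len(names))) < p
        pending = ~draws.any(axis=1)
    rows = np.flatnonzero(positive)
    for j, name in enumerate(names):
        out[name][rows] = draws[:, j]
    return out


def simulate_outcomes(
    profiles: Sequence[RiskFactorProfile],
    system: ScoringSystem | str,
    config: SimulationConfig,
    rngs: dict[str, np.random.Generator] | None = None,
) -> list[OutcomeRecord]:
    """Draw maternal and fetal outcomes for scored profiles.

    The composite events are Bernoulli with logistic probability in the
    score; intercepts are calibrated on the realised score distribution.
    """
    if isinstance(system, str):
        system = get_system(system)
    if rngs is None:
        rngs = _streams(config.seed)
    scores = np.array([s.value for s in score_cohort(profiles, system)], dtype=float)
    if scores.size == 0:
        return []

    out_flags: dict[str, np.ndarray] = {}
    for model, rng_key, indicator_names in (
        (config.smm_model, "smm", SMM_INDICATORS),
        (config.cfm_model, "cfm", CFM_INDICATORS),
    ):
        beta0 = calibrate_intercept(model.beta1, model.target_incidence, scores)
        p_event = expit(beta0 + model.beta1 * scores)
        positive = rngs[rng_key].random(scores.size) < p_event
        rates = {k: model.indicator_rates.get(k, 0.0) for k in indicator_names}
        out_flags.update(_allocate_indicators(positive, rates, rngs["indicators"]))

    records = []
    for i in range(scores.size):
        records.append(
            OutcomeRecord(**{k: bool(v[i]) for k, v in out_flags.items()})
        )
    return records


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate profiles and outcomes in one reproducible pass."""
    streams = _streams(config.seed)
    profiles = generate_profiles(config, rng=streams["profiles"])
    outcomes = simulate_outcomes(profiles, config.system, config, rngs=streams)
    return SyntheticCohort(
        profiles=tuple(profiles), outcomes=tuple(outcomes), config=config
    )
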