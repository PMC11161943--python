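"""Composite adverse-outcome definitions.

Severe maternal morbidity (SMM) is an any-of composite over ten indicators
of maternal end-organ damage recorded from admission for delivery to 72 h
postpartum, following the ACOG consensus-style definition.  Cumulative
fetal morbidity (CFM) is the analogous any-of composite over five
fetal/neonatal indicators: fetal distress in labour requiring cesarean,
5-minute APGAR below 6, umbilical-artery pH below 7.2, hypoxic-ischemic
encephalopathy, and NICU admission for respiratory concerns or asphyxia.

The composites are always recomputed from the indicator flags, never
trusted from an input file.
"""

from __future__ import annotations

from typing import Mapping

from pydantic import BaseModel, ConfigDict

__all__ = [
    "SMM_INDICATORS",
    "CFM_INDICATORS",
    "OutcomeRecord",
    "smm_composite",
    "cfm_composite",
]

SMM_INDICATORS: tuple[str, ...] = (
    "postpartum_hemorrhage",
    "hdu_admission",
    "surgical_complication",
    "sepsis",
    "cardiac_complication",
    "chest_complication",
    "renal_complication",
    "neurological_complication",
    "anesthesia_complication",
    "maternal_death",
)

CFM_INDICATORS: tuple[str, ...] = (
    "fetal_distress_cesarean",
    "low_apgar_5min",
    "low_ua_ph",
    "hie",
    "nicu_admission_asphyxia",
)


class OutcomeRecord(BaseModel):
    """Indicator flags for one delivery; composites are derived properties."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    postpartum_hemorrhage: bool = False
    hdu_admission: bool = False
    surgical_complication: bool = False
    sepsis: bool = False
    cardiac_complication: bool = False
    chest_complication: bool = False
    renal_complication: bool = False
    neurological_complication: bool = False
    anesthesia_complication: bool = False
    maternal_death: bool = False

    fetal_distress_cesarean: bool = False
    low_apgar_5min: bool = False
    low_ua_ph: bool = False
    hie: bool = False
    nicu_admission_asphyxia: bool = False

    @property
    def smm(self) -> bool:
        """Severe maternal morbidity: any maternal indicator present."""
        return any(getattr(self, f) for f in SMM_INDICATORS)

    @property
    def cfm(self) -> bool:
        """Cumulative fetal morbidity: any fetal indicator present."""
        return any(getattr(self, f) for f in CFM_INDICATORS)


def _composite(indicators: Mapping[str, bool], required: tuple[str, ...]) -> bool:
    missing = sorted(set(required) - set(indicators))
    if missing:
        raise ValueError(f"missing outcome indicators: {missing}")
    extra = sorted(set(indicators) - set(required))
    if extra:
        raise ValueError(f"unknown outcome indicators: {extra}")
    return any(bool(indicators[f]) for f in required)


def smm_composite(indicators: Mapping[str, bool]) -> bool:
    """True iff at least one of the ten maternal indicators is present."""
    return _composite(indicators, SMM_INDICATORS)


def cfm_composite(indicators: Mapping[str, bool]) -> bool:
    """True iff at least one of the five fetal indicators is present."""
    return _composite(indicators, CFM_INDICATORS)
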