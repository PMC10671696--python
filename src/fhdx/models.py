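"""Core domain types for the FH diagnostic pipeline.

Units are mmol/L throughout (total cholesterol, LDL-C, HDL-C,
triglycerides).  A :class:`Subject` bundles everything the clinical
criteria need: demographics, family and personal history, physical
signs, lipid panels (pretreatment and/or on-treatment), the peak LDL-C
ever recorded, the lipid-lowering regimen and the genetic result.
"""

from __future__ import annotations

from enum import Enum
from typing import Optional, Tuple

from pydantic import BaseModel, Field, model_validator

#: Triglyceride level (mmol/L) above which Friedewald-derived LDL-C is
#: not reported.
FRIEDEWALD_TG_LIMIT = 4.5

#: Statin names recognised by the regimen model.  Ezetimibe is the only
#: non-statin component supported.
STATINS = frozenset(
    {
        "simvastatin",
        "atorvastatin",
        "rosuvastatin",
        "pravastatin",
        "fluvastatin",
        "pitavastatin",
        "lovastatin",
    }
)


class Sex(str, Enum):
    male = "M"
    female = "F"


class Role(str, Enum):
    proband = "proband"
    cascade_relative = "cascade_relative"


class LipidPanel(BaseModel):
    """One lipid measurement set, mmol/L."""

    total_cholesterol: Optional[float] = None
    ldl_c: Optional[float] = None
    hdl_c: Optional[float] = None
    triglycerides: Optional[float] = None
    is_pretreatment: bool = False
    is_peak: bool = False
    ldl_is_friedewald: bool = False

    @model_validator(mode="after")
    def _check(self) -> "LipidPanel":
        for name in ("total_cholesterol", "ldl_c", "hdl_c", "triglycerides"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if (
            self.ldl_is_friedewald
            and self.ldl_c is not None
            and self.triglycerides is not None
            and self.triglycerides > FRIEDEWALD_TG_LIMIT
        ):
            raise ValueError(
                "Friedewald-derived LDL-C must be suppressed when "
                f"triglycerides exceed {FRIEDEWALD_TG_LIMIT} mmol/L"
            )
        return self


class FamilyHistory(BaseModel):
    first_degree_pcvd: bool = False
    first_degree_hyperlipidemia: bool = False
    relative_with_fh_diagnosis: bool = False
    relative_tendon_xanthoma: bool = False
    child_under18_high_ldl: bool = False


class PersonalHistory(BaseModel):
    premature_cad: bool = False
    premature_cerebral_or_peripheral: bool = False


class Signs(BaseModel):
    tendon_xanthoma: bool = False
    arcus_under_45: bool = False
    xanthelasma: bool = False


class DrugDose(BaseModel):
    """One regimen component: a statin or ezetimibe at a daily dose in mg."""

    drug: str
    daily_dose_mg: float = Field(gt=0)

    @model_validator(mode="after")
    def _normalise(self) -> "DrugDose":
        self.drug = self.drug.strip().lower()
        if self.drug not in STATINS and self.drug != "ezetimibe":
            raise ValueError(f"unknown lipid-lowering drug: {self.drug!r}")
        return self


class TreatmentRegimen(BaseModel):
    """A lipid-lowering regimen; an empty component list means untreated."""

    components: Tuple[DrugDose, ...] = ()

    @model_validator(mode="after")
    def _check(self) -> "TreatmentRegimen":
        statins = [c for c in self.components if c.drug in STATINS]
        ez = [c for c in self.components if c.drug == "ezetimibe"]
        if len(statins) > 1:
            raise ValueError("at most one statin component allowed")
        if len(ez) > 1:
            raise ValueError("ezetimibe may appear at most once")
        return self

    @property
    def is_untreated(self) -> bool:
        return len(self.components) == 0

    @property
    def statin(self) -> Optional[DrugDose]:
        for c in self.components:
            if c.drug in STATINS:
                return c
        return None

    @property
    def ezetimibe(self) -> Optional[DrugDose]:
        for c in self.components:
            if c.drug == "ezetimibe":
                return c
        return None


class GeneticResult(BaseModel):
    tested: bool = True
    variant_detected: bool = False
    variants: Tuple[str, ...] = ()


class Subject(BaseModel):
    """One individual in a cohort (proband or cascade-screened relative)."""

    id: str
    age_years: float = Field(ge=0, le=120)
    sex: Optional[Sex] = None
    role: Role = Role.proband
    family_history: FamilyHistory = Field(default_factory=FamilyHistory)
    personal_history: PersonalHistory = Field(default_factory=PersonalHistory)
    signs: Signs = Field(default_factory=Signs)
    pretreatment_lipids: Optional[LipidPanel] = None
    on_treatment_lipids: Optional[LipidPanel] = None
    peak_ldl_c: Optional[float] = Field(default=None, ge=0)
    #: ``None`` means the regimen is unknown; an empty regimen means
    #: documented untreated.
    regimen: Optional[TreatmentRegimen] = None
    genetic: Optional[GeneticResult] = None
    excluded_alternative_diagnosis: bool = False

    @property
    def is_pediatric(self) -> bool:
        return self.age_years < 18

    @property
    def genetic_positive(self) -> Optional[bool]:
        if self.genetic is None or not self.genetic.tested:
            return None
        return self.genetic.variant_detected

    def pretreatment_ldl(self) -> Optional[float]:
        if self.pretreatment_lipids is not None:
            return self.pretreatment_lipids.ldl_c
        return None

    def pretreatment_tc(self) -> Optional[float]:
        if self.pretreatment_lipids is not None:
            return self.pretreatment_lipids.total_cholesterol
        return None


class CriterionName(str, Enum):
    dlcnc = "DLCNC"
    modified_dlcnc = "modified_DLCNC"
    simon_broome = "SimonBroome"
    medped = "MEDPED"
    jfhmc = "JFHMC"
    hk_panel = "HK_panel"


class Category(str, Enum):
    definite = "definite"
    probable = "probable"
    possible = "possible"
    negative = "negative"
    positive = "positive"


class LdlProvenance(str, Enum):
    measured = "measured"
    corrected = "corrected"
    peak = "peak"


class CriterionResult(BaseModel):
    """Outcome of scoring one subject against one diagnostic criterion."""

    criterion: CriterionName
    score: Optional[float] = None
    category: Category
    binary_call: Optional[bool] = None
    ldl_used: Optional[float] = None
    ldl_provenance: Optional[LdlProvenance] = None
    notes: Tuple[str, ...] = ()

    @model_validator(mode="after")
    def _check(self) -> "CriterionResult":
        if self.score is not None and self.score < 0:
            raise ValueError("score must be >= 0")
        return self


class ScoringError(ValueError):
    """Raised when a subject cannot be scored against a criterion."""
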