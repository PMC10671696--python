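"""Treatment-intensity multipliers and untreated-LDL-C estimation.

A lipid-lowering regimen is translated into a dimensionless *treatment
intensity* I >= 1: the factor by which on-treatment LDL-C is multiplied
to estimate the untreated level.  Equivalently, the regimen's implied
fractional LDL-C reduction is 1 - 1/I, so intensity 1.8 corresponds to
an expected reduction of about 44%.

The statin factor table ships in the default configuration, anchored so
that simvastatin 40-80 mg/day spans intensity 1.7-1.9 and atorvastatin
20 mg/day and rosuvastatin 5 mg/day both sit at 1.8; ezetimibe
contributes a multiplicative 1.2.

This module also implements the two regimen-based diagnostic rules:
*intensity criterion* (intensity >= 1.8 achieving an "around 50%" LDL-C
drop) and its conjunction with a pretreatment LDL-C >= 5.5 mmol/L
cutoff, plus the Friedewald LDL-C estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

from .config import IntensityConfig, default_config
from .models import FRIEDEWALD_TG_LIMIT, Subject, TreatmentRegimen


class UnknownRegimenError(KeyError):
    """A regimen component is missing from the correction-factor table."""


@dataclass(frozen=True)
class IntensityResult:
    """Treatment intensity and the LDL-C reduction it implies."""

    intensity: float

    @property
    def implied_fractional_reduction(self) -> float:
        if self.intensity <= 0:
            return 0.0
        return 1.0 - 1.0 / self.intensity


def _intensity_config(config: Optional[IntensityConfig]) -> IntensityConfig:
    if config is None:
        return default_config().intensity
    return config


def _lookup_factor(drug: str, dose_mg: float, config: IntensityConfig) -> float:
    table = config.factors.get(drug)
    if table is None:
        raise UnknownRegimenError(f"no correction factors for drug {drug!r}")
    for dose, factor in table.items():
        if float(dose) == float(dose_mg):
            return factor
    raise UnknownRegimenError(
        f"no correction factor for {drug} at {dose_mg:g} mg/day "
        f"(table has doses {sorted(float(d) for d in table)})"
    )


def treatment_intensity(
    regimen: TreatmentRegimen, config: Optional[IntensityConfig] = None
) -> IntensityResult:
    """Translate a regimen into its treatment-intensity multiplier.

    The untreated regimen maps to exactly ``untreated_intensity``
    (1.0 by default).  Statin and ezetimibe factors combine
    multiplicatively under the default combination rule.
    """
    cfg = _intensity_config(config)
    if regimen.is_untreated:
        return IntensityResult(intensity=cfg.untreated_intensity)
    intensity = 1.0
    reduction = 0.0
    for comp in regimen.components:
        factor = _lookup_factor(comp.drug, comp.daily_dose_mg, cfg)
        if cfg.combination == "multiplicative":
            intensity *= factor
        else:  # additive on the reduction scale: r = r1 + r2 - r1*r2 anyway
            r = 1.0 - 1.0 / factor
            reduction = reduction + r - reduction * r
    if cfg.combination != "multiplicative":
        intensity = 1.0 / (1.0 - reduction)
    return IntensityResult(intensity=intensity)


def estimate_untreated_ldl(
    on_treatment_ldl: float,
    regimen: TreatmentRegimen,
    config: Optional[IntensityConfig] = None,
) -> float:
    """Estimate untreated LDL-C from an on-treatment value via intensity."""
    if on_treatment_ldl <= 0:
        raise ValueError("on-treatment LDL-C must be > 0")
    result = treatment_intensity(regimen, config)
    intensity = result.intensity if result.intensity > 0 else 1.0
    return on_treatment_ldl * intensity


def observed_reduction(pretreatment_ldl: float, on_treatment_ldl: float) -> float:
    """Fractional LDL-C reduction achieved on treatment, (pre - on) / pre."""
    if pretreatment_ldl <= 0:
        raise ValueError("pretreatment LDL-C must be > 0")
    frac = (pretreatment_ldl - on_treatment_ldl) / pretreatment_ldl
    if frac < 0:
        warnings.warn(
            "on-treatment LDL-C exceeds pretreatment LDL-C; "
            "reporting reduction as 0",
            stacklevel=2,
        )
        return 0.0
    return frac


def _pre_and_on_ldl(
    subject: Subject, config: IntensityConfig
) -> Tuple[Optional[float], Optional[float]]:
    on = (
        subject.on_treatment_lipids.ldl_c
        if subject.on_treatment_lipids is not None
        else None
    )
    pre = subject.pretreatment_ldl()
    if pre is None and on is not None and subject.regimen is not None:
        pre = estimate_untreated_ldl(on, subject.regimen, config)
    return pre, on


def intensity_criterion(
    subject: Subject, config: Optional[IntensityConfig] = None
) -> Optional[bool]:
    """Intensity >= threshold achieving an "around 50%" LDL-C drop.

    Returns ``True``/``False`` for a call, or ``None`` when the subject
    lacks the inputs (unknown regimen, or treated without both LDL-C
    values) and must be excluded rather than called negative.  A subject
    documented as untreated is a negative call (intensity is the
    untreated identity).
    """
    cfg = _intensity_config(config)
    if subject.regimen is None:
        return None
    if subject.regimen.is_untreated:
        return False
    pre, on = _pre_and_on_ldl(subject, cfg)
    if pre is None or on is None:
        return None
    intensity = treatment_intensity(subject.regimen, cfg).intensity
    reduction = observed_reduction(pre, on)
    lo, hi = cfg.reduction_band
    return intensity >= cfg.threshold and lo <= reduction <= hi


def combined_criterion(
    subject: Subject, config: Optional[IntensityConfig] = None
) -> Optional[bool]:
    """Intensity criterion AND pretreatment LDL-C >= the configured cutoff."""
    cfg = _intensity_config(config)
    base = intensity_criterion(subject, cfg)
    if base is None:
        return None
    if not base:
        return False
    pre, _ = _pre_and_on_ldl(subject, cfg)
    if pre is None:
        return None
    return pre >= cfg.combined_ldl_cutoff


#: Marker returned when Friedewald LDL-C may not be reported.
SUPPRESSED = None


def friedewald_ldl(tc: float, hdl: float, tg: float) -> Optional[float]:
    """Friedewald LDL-C estimate, TC - HDL - TG/2.2 (mmol/L).

    Returns ``None`` (suppressed) when triglycerides exceed 4.5 mmol/L
    or the estimate is negative.
    """
    if min(tc, hdl, tg) < 0:
        raise ValueError("lipid concentrations must be >= 0")
    if tg > FRIEDEWALD_TG_LIMIT:
        return SUPPRESSED
    ldl = tc - hdl - tg / 2.2
    if ldl < 0:
        warnings.warn("Friedewald estimate is negative; suppressed", stacklevel=2)
        return SUPPRESSED
    return ldl
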