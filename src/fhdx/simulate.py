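"""Synthetic FH screening cohorts with the study's statistical structure.

The generator emulates a hospital FH genetic-testing program: adult and
pediatric probands plus cascade-screened first-degree relatives of
genotype-positive probands.  Genotype is drawn at a configured
prevalence per stratum; pretreatment LDL-C comes from a zero-truncated
normal per (role x genotype x age-group) stratum; total cholesterol is
LDL-C plus a noisy offset; family-history flags are conditionally
independent given genotype; regimens are sampled from a configured
distribution and on-treatment LDL-C is derived from the regimen's
treatment intensity with multiplicative noise.

Randomness is fully reproducible: a single global seed plus a
counter-based substream per subject, so extending the cohort never
perturbs subjects already generated.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import stats

from .config import IntensityConfig, default_config
from .lipids import treatment_intensity
from .models import (
    FamilyHistory,
    GeneticResult,
    LipidPanel,
    PersonalHistory,
    Role,
    Sex,
    Signs,
    Subject,
    TreatmentRegimen,
)
from .io import parse_regimen
from .variants import Variant


class Stratum(BaseModel):
    ldl_mean: float = Field(gt=0)
    ldl_sd: float = Field(gt=0)


class CohortConfig(BaseModel):
    """Generative parameters for a synthetic cohort.

    Defaults mirror the study conditions: 19 adult and 12 pediatric
    probands, cascade screening of first-degree relatives of positive
    probands, ~84% genotype prevalence in adult probands and 50% in
    children, stratum LDL-C means of 8.77 / 6.53 mmol/L for genotype
    positive / negative adult probands and 6.60 mmol/L for positive
    cascade relatives, and a 69.2% vs 0% family history of premature
    cardiovascular disease by genotype.  No LDL-C dispersion is
    published for these strata; 1.5 mmol/L is the package's assumption.
    """

    n_adult_probands: int = 19
    n_pediatric_probands: int = 12
    cascade_rate_per_positive_proband: float = Field(default=0.75, ge=0)
    genotype_prevalence_adult: float = 0.842
    genotype_prevalence_pediatric: float = 0.50
    cascade_positive_rate: float = 0.833
    strata: Dict[str, Stratum] = Field(
        default_factory=lambda: {
            "adult_proband_pos": Stratum(ldl_mean=8.77, ldl_sd=1.5),
            "adult_proband_neg": Stratum(ldl_mean=6.53, ldl_sd=1.5),
            "adult_cascade_pos": Stratum(ldl_mean=6.60, ldl_sd=1.5),
            "adult_cascade_neg": Stratum(ldl_mean=4.50, ldl_sd=1.0),
            "pediatric_pos": Stratum(ldl_mean=7.50, ldl_sd=1.5),
            "pediatric_neg": Stratum(ldl_mean=5.50, ldl_sd=1.5),
        }
    )
    tc_offset_mean: float = 1.6
    tc_offset_sd: float = 0.4
    family_pcvd_rate_pos: float = 0.692
    family_pcvd_rate_neg: float = 0.0
    family_hyperlipidemia_rate_pos: float = 0.95
    family_hyperlipidemia_rate_neg: float = 0.60
    tendon_xanthoma_rate: float = 0.15
    arcus_rate: float = 0.05
    xanthelasma_rate: float = 0.05
    #: (regimen string, probability); the empty string is untreated
    regimen_distribution: Tuple[Tuple[str, float], ...] = (
        ("rosuvastatin:20", 0.25),
        ("rosuvastatin:20;ezetimibe:10", 0.20),
        ("atorvastatin:40", 0.20),
        ("atorvastatin:80;ezetimibe:10", 0.15),
        ("simvastatin:40", 0.10),
        ("atorvastatin:20", 0.10),
    )
    treated_fraction_probands: float = 1.0
    treated_fraction_cascade: float = 0.7
    on_treatment_noise_sd: float = 0.10
    peak_exceeds_fraction: float = 0.6
    peak_ratio_mean: float = 1.05
    peak_ratio_sd: float = 0.03
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        probs = [
            self.genotype_prevalence_adult,
            self.genotype_prevalence_pediatric,
            self.cascade_positive_rate,
            self.family_pcvd_rate_pos,
            self.family_pcvd_rate_neg,
            self.family_hyperlipidemia_rate_pos,
            self.family_hyperlipidemia_rate_neg,
            self.tendon_xanthoma_rate,
            self.arcus_rate,
            self.xanthelasma_rate,
            self.treated_fraction_probands,
            self.treated_fraction_cascade,
            self.peak_exceeds_fraction,
        ]
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        total = sum(p for _, p in self.regimen_distribution)
        if total <= 0:
            raise ValueError("regimen distribution must have positive mass")
        return self


def _rng(seed: int, counter: int) -> np.random.Generator:
    return np.random.default_rng([seed, counter])


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    # rejection sampling from the zero-truncated normal; for lipid-scale
    # parameters the acceptance probability is essentially 1
    while True:
        draw = float(rng.normal(mean, sd))
        if draw > 0:
            return draw


def truncated_normal_mean(mean: float, sd: float) -> float:
    """Analytic mean of the zero-truncated normal used for lipid draws."""
    a = (0.0 - mean) / sd
    return float(stats.truncnorm.mean(a, np.inf, loc=mean, scale=sd))


def positive_fraction_above(threshold: float, mean: float, sd: float) -> float:
    """P(LDL > threshold) under a zero-truncated normal stratum."""
    a = (0.0 - mean) / sd
    return float(stats.truncnorm.sf(threshold, a, np.inf, loc=mean, scale=sd))


def _sample_regimen(
    rng: np.random.Generator, config: CohortConfig
) -> TreatmentRegimen:
    names = [r for r, _ in config.regimen_distribution]
    probs = np.array([p for _, p in config.regimen_distribution], dtype=float)
    probs /= probs.sum()
    choice = names[int(rng.choice(len(names), p=probs))]
    return parse_regimen(choice)


def _make_subject(
    idx: int,
    role: Role,
    pediatric: bool,
    positive: bool,
    config: CohortConfig,
    intensity_cfg: IntensityConfig,
) -> Subject:
    rng = _rng(config.seed, idx)
    if pediatric:
        stratum = config.strata["pediatric_pos" if positive else "pediatric_neg"]
        age = float(rng.integers(4, 18))
    else:
        key = "adult_%s_%s" % (
            "proband" if role == Role.proband else "cascade",
            "pos" if positive else "neg",
        )
        stratum = config.strata[key]
        age = float(rng.integers(20, 70))

    ldl = _truncated_normal(rng, stratum.ldl_mean, stratum.ldl_sd)
    tc = ldl + max(0.2, rng.normal(config.tc_offset_mean, config.tc_offset_sd))

    pcvd_rate = config.family_pcvd_rate_pos if positive else config.family_pcvd_rate_neg
    hyper_rate = (
        config.family_hyperlipidemia_rate_pos
        if positive
        else config.family_hyperlipidemia_rate_neg
    )
    family = FamilyHistory(
        first_degree_pcvd=bool(rng.random() < pcvd_rate),
        first_degree_hyperlipidemia=bool(rng.random() < hyper_rate),
        relative_with_fh_diagnosis=role == Role.cascade_relative,
    )
    signs = Signs(
        tendon_xanthoma=bool(rng.random() < config.tendon_xanthoma_rate),
        arcus_under_45=bool(age < 45 and rng.random() < config.arcus_rate),
        xanthelasma=bool(rng.random() < config.xanthelasma_rate),
    )

    treated_frac = (
        config.treated_fraction_probands
        if role == Role.proband
        else config.treated_fraction_cascade
    )
    regimen = (
        _sample_regimen(rng, config)
        if rng.random() < treated_frac
        else TreatmentRegimen()
    )
    on_panel = None
    if not regimen.is_untreated:
        intensity = treatment_intensity(regimen, intensity_cfg).intensity
        noise = float(rng.normal(1.0, config.on_treatment_noise_sd))
        on_ldl = max(0.3, ldl / intensity * max(0.5, noise))
        on_panel = LipidPanel(ldl_c=round(on_ldl, 2))

    peak = None
    if positive and rng.random() < config.peak_exceeds_fraction:
        ratio = max(1.0, rng.normal(config.peak_ratio_mean, config.peak_ratio_sd))
        peak = round(ldl * ratio, 2)

    return Subject(
        id=f"S{idx:05d}",
        age_years=age,
        sex=Sex.male if rng.random() < 0.5 else Sex.female,
        role=role,
        family_history=family,
        personal_history=PersonalHistory(),
        signs=signs,
        pretreatment_lipids=LipidPanel(
            total_cholesterol=round(tc, 2), ldl_c=round(ldl, 2), is_pretreatment=True
        ),
        on_treatment_lipids=on_panel,
        peak_ldl_c=peak,
        regimen=regimen,
        genetic=GeneticResult(tested=True, variant_detected=positive),
    )


def generate_cohort(
    config: Optional[CohortConfig] = None, seed: Optional[int] = None
) -> List[Subject]:
    """Generate a cohort; a pure function of (config, seed)."""
    cfg = config if config is not None else CohortConfig()
    if seed is not None:
        cfg = cfg.model_copy(update={"seed": seed})
    intensity_cfg = default_config().intensity

    subjects: List[Subject] = []
    counter = 0
    master = _rng(cfg.seed, 2**20)  # structural draws (genotype, cascade sizes)
    for _ in range(cfg.n_adult_probands):
        positive = bool(master.random() < cfg.genotype_prevalence_adult)
        subjects.append(
            _make_subject(counter, Role.proband, False, positive, cfg, intensity_cfg)
        )
        counter += 1
        if positive:
            for _ in range(int(master.poisson(cfg.cascade_rate_per_positive_proband))):
                rel_pos = bool(master.random() < cfg.cascade_positive_rate)
                subjects.append(
                    _make_subject(
                        counter, Role.cascade_relative, False, rel_pos, cfg, intensity_cfg
                    )
                )
                counter += 1
    for _ in range(cfg.n_pediatric_probands):
        positive = bool(master.random() < cfg.genotype_prevalence_pediatric)
        subjects.append(
            _make_subject(counter, Role.proband, True, positive, cfg, intensity_cfg)
        )
        counter += 1
    return subjects


def generate_variant_assignments(
    cohort: Sequence[Subject],
    variants: Sequence[Variant],
    seed: int = 0,
    compound_het_fraction: float = 4 / 22,
) -> Dict[str, Tuple[str, ...]]:
    """Assign one or two variants to each genotype-positive subject.

    Draw probabilities are proportional to the table's proband counts;
    a configurable fraction of cases carries two distinct variants
    (compound heterozygous pattern).
    """
    if not 0 <= compound_het_fraction <= 1:
        raise ValueError("compound_het_fraction must lie in [0, 1]")
    weights = np.array([max(v.n_probands, 1) for v in variants], dtype=float)
    weights /= weights.sum()
    names = [v.cdna for v in variants]
    out: Dict[str, Tuple[str, ...]] = {}
    for i, subject in enumerate(cohort):
        if not subject.genetic_positive:
            continue
        rng = _rng(seed, i)
        k = 2 if rng.random() < compound_het_fraction else 1
        picks = rng.choice(len(names), size=k, replace=False, p=weights)
        out[subject.id] = tuple(names[int(j)] for j in picks)
    return out


def attach_variants(
    cohort: Sequence[Subject], assignments: Dict[str, Tuple[str, ...]]
) -> List[Subject]:
    """Return a cohort copy with variant names filled into genetic results."""
    updated = []
    for s in cohort:
        if s.id in assignments and s.genetic is not None:
            updated.append(
                s.model_copy(
                    update={
                        "genetic": s.genetic.model_copy(
                            update={"variants": assignments[s.id]}
                        )
                    }
                )
            )
        else:
            updated.append(s)
    return updated
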