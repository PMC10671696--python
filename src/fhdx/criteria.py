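"""Clinical FH diagnostic criteria: DLCNC, modified DLCNC, Simon Broome,
MEDPED, JFHMC and the Hong Kong expert-panel recommendation.

Each ``score_*`` / ``classify_*`` function is a pure function of a
:class:`~fhdx.models.Subject` and the run configuration and returns a
:class:`~fhdx.models.CriterionResult` with a categorical and a binary
call.  LDL-C thresholds are strict (">") throughout; point-based scores
(DLCNC family) take the maximum within each item group, as in the
published instrument.

The LDL-C value used for scoring is chosen by :func:`select_ldl_for_scoring`:
a measured pretreatment value when present, otherwise an on-treatment
value corrected by the regimen's treatment intensity; the recorded peak
LDL-C is used only under the explicit ``peak_first`` policy.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

from .config import RunConfig, default_config
from .lipids import estimate_untreated_ldl
from .models import (
    Category,
    CriterionName,
    CriterionResult,
    LdlProvenance,
    ScoringError,
    Subject,
)


def _cfg(config: Optional[RunConfig]) -> RunConfig:
    return config if config is not None else default_config()


def select_ldl_for_scoring(
    subject: Subject, config: Optional[RunConfig] = None
) -> Tuple[float, LdlProvenance]:
    """Pick the LDL-C value a criterion should score, with provenance."""
    cfg = _cfg(config)
    if cfg.ldl_policy.source == "peak_first" and subject.peak_ldl_c is not None:
        return subject.peak_ldl_c, LdlProvenance.peak
    pre = subject.pretreatment_ldl()
    if pre is not None:
        return pre, LdlProvenance.measured
    on = (
        subject.on_treatment_lipids.ldl_c
        if subject.on_treatment_lipids is not None
        else None
    )
    if on is not None and subject.regimen is not None:
        corrected = estimate_untreated_ldl(on, subject.regimen, cfg.intensity)
        return corrected, LdlProvenance.corrected
    raise ScoringError(
        f"subject {subject.id!r} has no usable LDL-C source "
        "(no pretreatment value and no correctable on-treatment value)"
    )


def _ldl_band_points(ldl: float, bands: List[Tuple[float, int]]) -> int:
    for lower, points in sorted(bands, reverse=True):
        if ldl >= lower:
            return points
    return 0


def _genetic_positive(subject: Subject, include_genetic: bool) -> bool:
    return bool(include_genetic and subject.genetic_positive)


def _dlcnc_like(
    subject: Subject,
    criterion: CriterionName,
    bands: List[Tuple[float, int]],
    config: RunConfig,
) -> CriterionResult:
    d = config.criteria.dlcnc
    ldl, provenance = select_ldl_for_scoring(subject, config)

    fam = subject.family_history
    if d.score_family_pcvd_separately:
        fam_one = int(fam.first_degree_pcvd) + int(fam.first_degree_hyperlipidemia)
        fam_one *= d.family_pcvd_or_hyperlipidemia_points
    else:
        fam_one = (
            d.family_pcvd_or_hyperlipidemia_points
            if (fam.first_degree_pcvd or fam.first_degree_hyperlipidemia)
            else 0
        )
    fam_two = (
        d.family_xanthoma_or_child_high_ldl_points
        if (fam.relative_tendon_xanthoma or fam.child_under18_high_ldl)
        else 0
    )
    family = max(fam_one, fam_two)

    pers = subject.personal_history
    personal = max(
        d.personal_premature_cad_points if pers.premature_cad else 0,
        d.personal_cerebral_or_peripheral_points
        if pers.premature_cerebral_or_peripheral
        else 0,
    )

    physical = max(
        d.tendon_xanthoma_points if subject.signs.tendon_xanthoma else 0,
        d.arcus_under_45_points
        if (subject.signs.arcus_under_45 and subject.age_years < 45)
        else 0,
    )

    dna = d.dna_variant_points if _genetic_positive(subject, d.include_genetic) else 0

    score = family + personal + physical + _ldl_band_points(ldl, bands) + dna

    if score > d.definite_above:
        category = Category.definite
    elif score >= d.probable_min:
        category = Category.probable
    elif score >= d.possible_min:
        category = Category.possible
    else:
        category = Category.negative

    notes: Tuple[str, ...] = ()
    binary: Optional[bool] = score >= d.binary_cutoff
    if subject.is_pediatric:
        notes = ("not validated in pediatric subjects",)
        if d.pediatric_policy == "suppress":
            binary = None

    return CriterionResult(
        criterion=criterion,
        score=float(score),
        category=category,
        binary_call=binary,
        ldl_used=ldl,
        ldl_provenance=provenance,
        notes=notes,
    )


def score_dlcnc(subject: Subject, config: Optional[RunConfig] = None) -> CriterionResult:
    """Dutch Lipid Clinic Network score (definite >8, probable 6-8,
    possible 3-5; binary call at the configured cutoff, default >=3)."""
    cfg = _cfg(config)
    return _dlcnc_like(subject, CriterionName.dlcnc, cfg.criteria.dlcnc.ldl_bands, cfg)


def score_modified_dlcnc(
    subject: Subject, config: Optional[RunConfig] = None
) -> CriterionResult:
    """DLCNC with LDL-C bands lowered for Chinese populations."""
    cfg = _cfg(config)
    return _dlcnc_like(
        subject, CriterionName.modified_dlcnc, cfg.criteria.modified_dlcnc.ldl_bands, cfg
    )


def classify_simon_broome(
    subject: Subject, config: Optional[RunConfig] = None
) -> CriterionResult:
    """Simon Broome Register criteria (definite / possible / negative)."""
    cfg = _cfg(config)
    sb = cfg.criteria.simon_broome
    ldl, provenance = select_ldl_for_scoring(subject, cfg)
    cutoff = sb.child_ldl_cutoff if subject.is_pediatric else sb.adult_ldl_cutoff

    high_ldl = ldl > cutoff
    xanthoma = subject.signs.tendon_xanthoma or (
        sb.include_relative_tendon_xanthoma
        and subject.family_history.relative_tendon_xanthoma
    )
    definite = high_ldl and (
        xanthoma or _genetic_positive(subject, sb.include_genetic)
    )
    possible = high_ldl and (
        subject.family_history.first_degree_pcvd
        or subject.family_history.first_degree_hyperlipidemia
    )

    if definite:
        category = Category.definite
    elif possible:
        category = Category.possible
    else:
        category = Category.negative
    return CriterionResult(
        criterion=CriterionName.simon_broome,
        category=category,
        binary_call=definite or possible,
        ldl_used=ldl,
        ldl_provenance=provenance,
    )


def _medped_band(age: float) -> str:
    if age < 20:
        return "<20"
    if age < 30:
        return "20-29"
    if age < 40:
        return "30-39"
    return ">=40"


def classify_medped(
    subject: Subject, config: Optional[RunConfig] = None
) -> CriterionResult:
    """MEDPED total-cholesterol criteria by age band and FH-relative degree.

    Only first-degree relatives are modelled in the cohort schema, so the
    applicable column is "first" when a relative carries an FH diagnosis
    and "general" otherwise.
    """
    cfg = _cfg(config)
    if subject.age_years is None:
        raise ScoringError(f"subject {subject.id!r} has no age for MEDPED")
    tc = subject.pretreatment_tc()
    if tc is None:
        raise ScoringError(
            f"subject {subject.id!r} has no pretreatment total cholesterol"
        )
    band = cfg.criteria.medped.thresholds[_medped_band(subject.age_years)]
    degree = (
        "first" if subject.family_history.relative_with_fh_diagnosis else "general"
    )
    positive = tc > band[degree]
    return CriterionResult(
        criterion=CriterionName.medped,
        category=Category.positive if positive else Category.negative,
        binary_call=positive,
        ldl_used=None,
        ldl_provenance=None,
        notes=(f"TC {tc:g} vs {band[degree]:g} ({_medped_band(subject.age_years)}, {degree})",),
    )


def classify_jfhmc(
    subject: Subject, config: Optional[RunConfig] = None
) -> CriterionResult:
    """Japanese FH management criteria; flags a homozygous pattern when
    total cholesterol exceeds 15.5 mmol/L."""
    cfg = _cfg(config)
    j = cfg.criteria.jfhmc
    ldl, provenance = select_ldl_for_scoring(subject, cfg)
    cutoff = j.child_ldl_cutoff if subject.is_pediatric else j.adult_ldl_cutoff

    supporting = (
        subject.signs.tendon_xanthoma
        or subject.family_history.relative_tendon_xanthoma
        or subject.family_history.first_degree_pcvd
        or subject.family_history.first_degree_hyperlipidemia
        or subject.family_history.relative_with_fh_diagnosis
    )
    hefh = ldl > cutoff and supporting
    tc = subject.pretreatment_tc()
    hofh = tc is not None and tc > j.hofh_tc_cutoff
    notes = ("homozygous pattern: TC > 15.5 mmol/L",) if hofh else ()
    positive = hefh or hofh
    return CriterionResult(
        criterion=CriterionName.jfhmc,
        category=Category.positive if positive else Category.negative,
        binary_call=positive,
        ldl_used=ldl,
        ldl_provenance=provenance,
        notes=notes,
    )


def classify_hk_panel(
    subject: Subject, config: Optional[RunConfig] = None
) -> CriterionResult:
    """Hong Kong expert-panel recommendation for FH genetic testing."""
    cfg = _cfg(config)
    hk = cfg.criteria.hk_panel
    ldl, provenance = select_ldl_for_scoring(subject, cfg)
    fam = subject.family_history
    history = (
        fam.relative_with_fh_diagnosis
        or fam.first_degree_pcvd
        or fam.first_degree_hyperlipidemia
    )
    signs = (
        subject.signs.tendon_xanthoma
        or subject.signs.xanthelasma
        or subject.signs.arcus_under_45
    )
    if subject.is_pediatric:
        positive = (
            (history and ldl > hk.child_ldl_cutoff_with_history)
            or ldl > hk.child_ldl_cutoff
            or signs
        )
    else:
        positive = ldl > hk.adult_ldl_cutoff or (
            history and ldl > hk.adult_ldl_cutoff_with_history
        )
    return CriterionResult(
        criterion=CriterionName.hk_panel,
        category=Category.positive if positive else Category.negative,
        binary_call=positive,
        ldl_used=ldl,
        ldl_provenance=provenance,
    )


#: Deterministic evaluation order for :func:`evaluate_all_criteria`.
ALL_CRITERIA = (
    (CriterionName.dlcnc, score_dlcnc),
    (CriterionName.modified_dlcnc, score_modified_dlcnc),
    (CriterionName.simon_broome, classify_simon_broome),
    (CriterionName.medped, classify_medped),
    (CriterionName.jfhmc, classify_jfhmc),
    (CriterionName.hk_panel, classify_hk_panel),
)


def evaluate_all_criteria(
    subject: Subject, config: Optional[RunConfig] = None
) -> List[CriterionResult]:
    """Score a subject against every criterion, in a fixed order."""
    cfg = _cfg(config)
    return [scorer(subject, cfg) for _, scorer in ALL_CRITERIA]
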