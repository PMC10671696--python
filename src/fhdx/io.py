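"""Cohort CSV and variant TSV reading/writing.

Cohort files are one row per subject with lipids in mmol/L; regimens are
encoded as ``"drug:mg;drug:mg"`` (empty cell = regimen unknown, the
literal ``none`` = documented untreated); missing values are empty
cells.  Headers are validated before any computation; unknown columns
warn but never crash.  A crude unit guard rejects LDL-C or TC values
that only make sense in mg/dL.
"""

from __future__ import annotations

import importlib.resources
import warnings
from pathlib import Path
from typing import List, Optional, Sequence, Union

import pandas as pd

from .config import IoConfig, default_config
from .models import (
    DrugDose,
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
from .variants import Variant

MGDL_TO_MMOL = 0.02586

REQUIRED_COLUMNS = ["id", "age_years", "role"]

ALL_COLUMNS = [
    "id",
    "role",
    "age_years",
    "sex",
    "fam_pcvd",
    "fam_hyperlipidemia",
    "fam_fh_diagnosis",
    "fam_relative_tendon_xanthoma",
    "fam_child_high_ldl",
    "pers_premature_cad",
    "pers_premature_cerebral_peripheral",
    "sign_tendon_xanthoma",
    "sign_arcus_under_45",
    "sign_xanthelasma",
    "pre_tc",
    "pre_ldl",
    "pre_hdl",
    "pre_tg",
    "on_ldl",
    "peak_ldl",
    "regimen",
    "variant_detected",
    "variants",
    "excluded_alternative_diagnosis",
]


class CohortFormatError(ValueError):
    pass


def parse_regimen(text: Optional[str]) -> Optional[TreatmentRegimen]:
    """Parse ``"drug:mg;drug:mg"``; empty/NaN -> unknown (None); "none"
    -> documented untreated."""
    if text is None or (isinstance(text, float) and pd.isna(text)):
        return None
    text = str(text).strip()
    if text == "":
        return None
    if text.lower() == "none":
        return TreatmentRegimen()
    components = []
    for part in text.split(";"):
        part = part.strip()
        if not part:
            continue
        try:
            drug, dose = part.split(":")
            components.append(DrugDose(drug=drug, daily_dose_mg=float(dose)))
        except ValueError as exc:
            raise CohortFormatError(f"cannot parse regimen component {part!r}") from exc
    return TreatmentRegimen(components=tuple(components))


def format_regimen(regimen: Optional[TreatmentRegimen]) -> str:
    if regimen is None:
        return ""
    if regimen.is_untreated:
        return "none"
    return ";".join(f"{c.drug}:{c.daily_dose_mg:g}" for c in regimen.components)


def _flag(value) -> bool:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return False
    return str(value).strip().lower() in ("1", "true", "t", "yes", "y")


def _num(value, column: str, io_cfg: IoConfig, is_ldl_like: bool = False):
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    try:
        v = float(value)
    except (TypeError, ValueError):
        raise CohortFormatError(f"non-numeric value {value!r} in column {column!r}")
    if io_cfg.mgdl_input and is_ldl_like:
        v *= MGDL_TO_MMOL
    if is_ldl_like and v > io_cfg.ldl_plausible_max:
        raise CohortFormatError(
            f"{column}={v:g} mmol/L is implausible; if the file is in mg/dL "
            f"multiply by {MGDL_TO_MMOL} or set io.mgdl_input: true"
        )
    return v


def _subject_from_row(row: pd.Series, io_cfg: IoConfig) -> Subject:
    pre_ldl = _num(row.get("pre_ldl"), "pre_ldl", io_cfg, True)
    pre_tc = _num(row.get("pre_tc"), "pre_tc", io_cfg, True)
    pre_hdl = _num(row.get("pre_hdl"), "pre_hdl", io_cfg)
    pre_tg = _num(row.get("pre_tg"), "pre_tg", io_cfg)
    pre = None
    if any(v is not None for v in (pre_ldl, pre_tc, pre_hdl, pre_tg)):
        pre = LipidPanel(
            total_cholesterol=pre_tc,
            ldl_c=pre_ldl,
            hdl_c=pre_hdl,
            triglycerides=pre_tg,
            is_pretreatment=True,
        )
    on_ldl = _num(row.get("on_ldl"), "on_ldl", io_cfg, True)
    on = LipidPanel(ldl_c=on_ldl) if on_ldl is not None else None

    genetic = None
    raw_detected = row.get("variant_detected")
    if raw_detected is not None and not (
        isinstance(raw_detected, float) and pd.isna(raw_detected)
    ) and str(raw_detected).strip() != "":
        names = row.get("variants")
        variant_names = ()
        if names is not None and not (isinstance(names, float) and pd.isna(names)):
            variant_names = tuple(v.strip() for v in str(names).split("|") if v.strip())
        genetic = GeneticResult(
            tested=True, variant_detected=_flag(raw_detected), variants=variant_names
        )

    sex_raw = row.get("sex")
    sex = None
    if sex_raw is not None and not (isinstance(sex_raw, float) and pd.isna(sex_raw)):
        s = str(sex_raw).strip().upper()
        if s:
            sex = Sex(s)

    return Subject(
        id=str(row["id"]),
        age_years=float(row["age_years"]),
        sex=sex,
        role=Role(str(row["role"])),
        family_history=FamilyHistory(
            first_degree_pcvd=_flag(row.get("fam_pcvd")),
            first_degree_hyperlipidemia=_flag(row.get("fam_hyperlipidemia")),
            relative_with_fh_diagnosis=_flag(row.get("fam_fh_diagnosis")),
            relative_tendon_xanthoma=_flag(row.get("fam_relative_tendon_xanthoma")),
            child_under18_high_ldl=_flag(row.get("fam_child_high_ldl")),
        ),
        personal_history=PersonalHistory(
            premature_cad=_flag(row.get("pers_premature_cad")),
            premature_cerebral_or_peripheral=_flag(
                row.get("pers_premature_cerebral_peripheral")
            ),
        ),
        signs=Signs(
            tendon_xanthoma=_flag(row.get("sign_tendon_xanthoma")),
            arcus_under_45=_flag(row.get("sign_arcus_under_45")),
            xanthelasma=_flag(row.get("sign_xanthelasma")),
        ),
        pretreatment_lipids=pre,
        on_treatment_lipids=on,
        peak_ldl_c=_num(row.get("peak_ldl"), "peak_ldl", io_cfg, True),
        regimen=parse_regimen(row.get("regimen")),
        genetic=genetic,
        excluded_alternative_diagnosis=_flag(row.get("excluded_alternative_diagnosis")),
    )


def read_cohort(
    path: Union[str, Path], io_cfg: Optional[IoConfig] = None
) -> List[Subject]:
    """Read a cohort CSV into Subject records (header validated first)."""
    cfg = io_cfg if io_cfg is not None else default_config().io
    df = pd.read_csv(path, dtype=str)
    if df.empty:
        raise CohortFormatError(f"cohort file {path} contains no subjects")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"cohort file missing required columns: {missing}")
    extra = [c for c in df.columns if c not in ALL_COLUMNS]
    if extra:
        warnings.warn(f"ignoring unknown cohort columns: {extra}", stacklevel=2)
    return [_subject_from_row(row, cfg) for _, row in df.iterrows()]


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return f"{value:g}"
    return str(value)


def write_cohort(subjects: Sequence[Subject], path: Union[str, Path]) -> None:
    """Write subjects to the standard cohort CSV schema."""
    rows = []
    for s in subjects:
        pre = s.pretreatment_lipids
        rows.append(
            {
                "id": s.id,
                "role": s.role.value,
                "age_years": _fmt(float(s.age_years)),
                "sex": s.sex.value if s.sex else "",
                "fam_pcvd": _fmt(s.family_history.first_degree_pcvd),
                "fam_hyperlipidemia": _fmt(s.family_history.first_degree_hyperlipidemia),
                "fam_fh_diagnosis": _fmt(s.family_history.relative_with_fh_diagnosis),
                "fam_relative_tendon_xanthoma": _fmt(
                    s.family_history.relative_tendon_xanthoma
                ),
                "fam_child_high_ldl": _fmt(s.family_history.child_under18_high_ldl),
                "pers_premature_cad": _fmt(s.personal_history.premature_cad),
                "pers_premature_cerebral_peripheral": _fmt(
                    s.personal_history.premature_cerebral_or_peripheral
                ),
                "sign_tendon_xanthoma": _fmt(s.signs.tendon_xanthoma),
                "sign_arcus_under_45": _fmt(s.signs.arcus_under_45),
                "sign_xanthelasma": _fmt(s.signs.xanthelasma),
                "pre_tc": _fmt(pre.total_cholesterol if pre else None),
                "pre_ldl": _fmt(pre.ldl_c if pre else None),
                "pre_hdl": _fmt(pre.hdl_c if pre else None),
                "pre_tg": _fmt(pre.triglycerides if pre else None),
                "on_ldl": _fmt(
                    s.on_treatment_lipids.ldl_c if s.on_treatment_lipids else None
                ),
                "peak_ldl": _fmt(s.peak_ldl_c),
                "regimen": format_regimen(s.regimen),
                "variant_detected": _fmt(s.genetic.variant_detected)
                if s.genetic
                else "",
                "variants": "|".join(s.genetic.variants) if s.genetic else "",
                "excluded_alternative_diagnosis": _fmt(
                    s.excluded_alternative_diagnosis
                ),
            }
        )
    pd.DataFrame(rows, columns=ALL_COLUMNS).to_csv(path, index=False)


def read_variant_table(path: Union[str, Path]) -> List[Variant]:
    """Read a variant TSV (Table-3-shaped) into Variant records."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise CohortFormatError(f"variant table {path} is empty")
    required = {"cdna", "n_probands"}
    missing = required - set(df.columns)
    if missing:
        raise CohortFormatError(f"variant table missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        def get(col):
            v = row.get(col)
            if v is None or (isinstance(v, float) and pd.isna(v)):
                return None
            v = str(v).strip()
            return v or None

        out.append(
            Variant(
                cdna=str(row["cdna"]).strip(),
                protein_change=get("protein_change"),
                localization=get("localization"),
                clinical_significance=get("clinical_significance"),
                novel=_flag(row.get("novel")),
                n_probands=int(row["n_probands"]),
                n_cascade=int(get("n_cascade") or 0),
                note=get("note"),
            )
        )
    return out


def packaged_variant_table() -> List[Variant]:
    """The shipped LDLR variant table for the Hong Kong FH cohort."""
    with importlib.resources.as_file(
        importlib.resources.files("fhdx.data").joinpath("ldlr_variants_hk.tsv")
    ) as p:
        return read_variant_table(p)


def packaged_reconstruction_cohort() -> List[Subject]:
    """The shipped synthetic 31-adult reconstruction cohort."""
    with importlib.resources.as_file(
        importlib.resources.files("fhdx.data").joinpath(
            "adult_cohort_reconstruction_synthetic.csv"
        )
    ) as p:
        return read_cohort(p)


def write_report(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write an evaluation/summary table as TSV."""
    df.to_csv(path, sep="\t", index=False)
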