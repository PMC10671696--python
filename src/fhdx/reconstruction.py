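"""A synthetic reconstruction of the adult evaluation cohort.

Individual-level data for the study cohort are not published, so this
module constructs a *synthetic* 31-adult cohort (19 probands + 12
cascade-screened relatives; 26 genotype-positive, 5 negative) that is
simultaneously consistent with every published aggregate the evaluation
pipeline consumes:

* the seven diagnostic-performance rows (Simon Broome / MEDPED / JFHMC /
  local panel / LDL-C >= 5.5 / treatment-intensity rule / combined rule),
  whose integer confusion matrices were recovered by exhaustive
  enumeration from the rounded printed metrics;
* the group means of pretreatment LDL-C (8.77 vs 6.53 mmol/L in
  probands, 6.60 mmol/L in cascade relatives, 7.94 vs 5.59 in all
  adults), total cholesterol (10.35 / 10.00 / 8.13) and peak LDL-C
  (9.24 / 10.50 / 6.77);
* the family-history-of-pCVD contrasts (12/16 vs 0/3 in probands,
  18/26 vs 0/5 in all adults).

It is a constructed instance — not patient data — and exists so the full
pipeline can be exercised end to end against printed aggregates.
"""

from __future__ import annotations

from typing import List, Optional

from .models import (
    FamilyHistory,
    GeneticResult,
    LipidPanel,
    Role,
    Sex,
    Signs,
    Subject,
)
from .io import parse_regimen

# id, role, age, sex, pre_ldl, pre_tc, peak_ldl, fam_pcvd, fam_hyper,
# fam_fh, xanthoma, arcus, xanthelasma, regimen ("" unknown, "none"
# untreated), on_ldl, genotype_positive, variants
_ROWS = [
    # genotype-positive probands -------------------------------------------
    ("P01", "proband", 52, "M", 9.00, 10.58, 9.47, 1, 1, 1, 1, 0, 0, "rosuvastatin:20", 4.05, 1, "c.986 G>A|c.1055 G>A"),
    ("P02", "proband", 44, "F", 9.20, 10.78, 9.67, 1, 1, 1, 0, 1, 0, "rosuvastatin:20;ezetimibe:10", 4.14, 1, "c.1241 T>G|c.1247 G>A"),
    ("P03", "proband", 47, "M", 9.40, 10.98, 9.87, 1, 1, 1, 0, 0, 1, "atorvastatin:80;ezetimibe:10", 3.95, 1, "c.268 G>A"),
    ("P04", "proband", 55, "F", 9.60, 11.18, 10.07, 1, 1, 1, 0, 0, 0, "rosuvastatin:20", 4.32, 1, "c.301 G>A"),
    ("P05", "proband", 60, "M", 9.80, 11.38, 10.27, 1, 1, 1, 0, 0, 0, "atorvastatin:40", 4.90, 1, "c.523 G>A"),
    ("P06", "proband", 41, "F", 10.00, 11.58, 10.47, 1, 1, 1, 0, 0, 0, "rosuvastatin:20;ezetimibe:10", 4.50, 1, "c.769 C>T"),
    ("P07", "proband", 38, "M", 10.20, 11.78, 10.67, 1, 1, 1, 0, 0, 0, "rosuvastatin:40", 4.59, 1, "c.1060+2 T>C"),
    ("P08", "proband", 49, "F", 10.40, 11.98, 10.87, 1, 1, 1, 0, 0, 0, "atorvastatin:80", 4.68, 1, "c.1216 C>A"),
    ("P09", "proband", 58, "M", 10.60, 12.18, 11.07, 1, 1, 1, 0, 0, 0, "rosuvastatin:20", 4.77, 1, "c.1285 G>A"),
    ("P10", "proband", 45, "F", 10.80, 12.38, 11.27, 1, 1, 1, 0, 0, 0, "rosuvastatin:40;ezetimibe:10", 4.32, 1, "c.1297 G>C"),
    ("P11", "proband", 50, "M", 8.50, 10.08, 8.97, 1, 1, 1, 0, 0, 0, "atorvastatin:40", 4.25, 1, "c.1448 G>A"),
    ("P12", "proband", 43, "F", 9.92, 11.50, 10.39, 1, 1, 1, 0, 0, 0, "rosuvastatin:20", 4.46, 1, "c.1469 G>A"),
    ("P13", "proband", 35, "M", 5.60, 7.18, 6.07, 0, 1, 1, 0, 0, 0, "atorvastatin:40", 2.80, 1, "c.1586+5 G>C"),
    ("P14", "proband", 38, "F", 5.90, 7.48, 6.37, 0, 1, 1, 0, 0, 0, "atorvastatin:40", 2.95, 1, "c.1706-1 G>C"),
    ("P15", "proband", 42, "M", 6.20, 7.78, 6.67, 0, 1, 1, 0, 0, 0, "rosuvastatin:20", 2.79, 1, "c.1731 G>C"),
    ("P16", "proband", 35, "F", 5.20, 6.78, 5.67, 0, 0, 0, 0, 0, 0, "simvastatin:10", 3.38, 1, "c.1765 G>A"),
    # genotype-negative probands -------------------------------------------
    ("P17", "proband", 44, "M", 7.50, 10.80, 11.00, 0, 1, 1, 0, 0, 0, "simvastatin:20", 5.25, 0, ""),
    ("P18", "proband", 51, "F", 6.80, 10.20, 10.50, 0, 1, 1, 0, 0, 0, "simvastatin:20", 4.76, 0, ""),
    ("P19", "proband", 44, "M", 5.29, 9.00, 10.00, 0, 1, 1, 0, 0, 0, "atorvastatin:40", 2.38, 0, ""),
    # genotype-positive cascade relatives ----------------------------------
    ("C01", "cascade_relative", 35, "F", 8.00, 10.45, 8.17, 1, 1, 1, 0, 0, 0, "rosuvastatin:20", 4.00, 1, "c.1241 T>G"),
    ("C02", "cascade_relative", 40, "M", 8.00, 10.45, 8.17, 1, 1, 1, 0, 0, 0, "rosuvastatin:20", 4.00, 1, "c.1241 T>G"),
    ("C03", "cascade_relative", 45, "F", 8.00, 10.45, 8.17, 1, 1, 1, 0, 0, 0, "rosuvastatin:20", 4.00, 1, "c.1731 G>C"),
    ("C04", "cascade_relative", 50, "M", 8.00, 10.45, 8.17, 1, 1, 1, 0, 0, 0, "rosuvastatin:20", 4.00, 1, "c.1731 G>C"),
    ("C05", "cascade_relative", 55, "F", 8.00, 10.45, 8.17, 1, 1, 1, 0, 0, 0, "rosuvastatin:20", 4.00, 1, "c.1448 G>A"),
    ("C06", "cascade_relative", 48, "M", 7.60, 10.31, 7.77, 1, 1, 1, 0, 0, 0, "", None, 1, "c.1448 G>A"),
    ("C07", "cascade_relative", 25, "F", 5.20, 6.70, 5.37, 0, 1, 1, 0, 0, 0, "atorvastatin:40", 2.60, 1, "c.986 G>A"),
    ("C08", "cascade_relative", 22, "M", 4.40, 5.80, 4.57, 0, 1, 1, 0, 0, 0, "rosuvastatin:10", 2.20, 1, "c.1241 T>G"),
    ("C09", "cascade_relative", 24, "F", 4.40, 5.80, 4.57, 0, 1, 1, 0, 0, 0, "rosuvastatin:10", 2.20, 1, "c.1880 C>T"),
    ("C10", "cascade_relative", 26, "M", 4.40, 5.80, 4.57, 0, 1, 1, 0, 0, 0, "", None, 1, "c.1765 G>A"),
    # genotype-negative cascade relatives ----------------------------------
    ("C11", "cascade_relative", 25, "F", 4.70, 5.90, None, 0, 1, 1, 0, 0, 0, "none", None, 0, ""),
    ("C12", "cascade_relative", 27, "M", 3.66, 5.00, None, 0, 0, 1, 0, 0, 0, "none", None, 0, ""),
]


def reconstructed_adult_cohort() -> List[Subject]:
    """Build the synthetic 31-adult reconstruction cohort."""
    subjects: List[Subject] = []
    for (
        sid, role, age, sex, ldl, tc, peak, pcvd, hyper, fh,
        xanthoma, arcus, xanthelasma, regimen, on_ldl, positive, variants,
    ) in _ROWS:
        on_panel: Optional[LipidPanel] = (
            LipidPanel(ldl_c=on_ldl) if on_ldl is not None else None
        )
        subjects.append(
            Subject(
                id=sid,
                age_years=age,
                sex=Sex(sex),
                role=Role(role),
                family_history=FamilyHistory(
                    first_degree_pcvd=bool(pcvd),
                    first_degree_hyperlipidemia=bool(hyper),
                    relative_with_fh_diagnosis=bool(fh),
                ),
                signs=Signs(
                    tendon_xanthoma=bool(xanthoma),
                    arcus_under_45=bool(arcus),
                    xanthelasma=bool(xanthelasma),
                ),
                pretreatment_lipids=LipidPanel(
                    total_cholesterol=tc, ldl_c=ldl, is_pretreatment=True
                ),
                on_treatment_lipids=on_panel,
                peak_ldl_c=peak,
                regimen=parse_regimen(regimen),
                genetic=GeneticResult(
                    tested=True,
                    variant_detected=bool(positive),
                    variants=tuple(v for v in variants.split("|") if v),
                ),
            )
        )
    return subjects
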