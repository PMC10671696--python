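# Default configuration for the fhdx pipeline.
#
# All lipid thresholds are in mmol/L.  LDL bands are [lower_bound, points]
# pairs, applied as lower-bound-inclusive intervals from the top down;
# all single-value thresholds are strict (">").

criteria:
  dlcnc:
    # Points for the LDL-C bands of the Dutch Lipid Clinic Network score.
    ldl_bands: [[8.5, 8], [6.5, 5], [5.0, 3], [4.0, 1]]
    family_pcvd_or_hyperlipidemia_points: 1
    family_xanthoma_or_child_high_ldl_points: 2
    personal_premature_cad_points: 2
    personal_cerebral_or_peripheral_points: 1
    tendon_xanthoma_points: 6
    arcus_under_45_points: 4
    dna_variant_points: 8
    definite_above: 8      # score > 8 -> definite
    probable_min: 6        # 6..definite_above -> probable
    possible_min: 3        # possible_min..probable_min-1 -> possible
    binary_cutoff: 3       # binary_call = score >= cutoff
    score_family_pcvd_separately: false
    include_genetic: true
    pediatric_policy: flag   # flag | suppress
  modified_dlcnc:
    # LDL bands lowered for Chinese populations; all other items shared
    # with the DLCNC block above.
    ldl_bands: [[6.0, 8], [5.0, 5], [3.5, 3], [2.5, 1]]
  simon_broome:
    adult_ldl_cutoff: 4.9
    child_ldl_cutoff: 4.0
    include_relative_tendon_xanthoma: true
    include_genetic: true
  medped:
    # Total-cholesterol thresholds (mmol/L) by age band and the closest
    # degree of relative with FH; "general" applies with no FH relative.
    thresholds:
      "<20":  {first: 5.7, second: 5.9, third: 6.2, general: 7.0}
      "20-29": {first: 6.2, second: 6.5, third: 6.7, general: 7.5}
      "30-39": {first: 7.0, second: 7.2, third: 7.5, general: 8.8}
      ">=40": {first: 7.5, second: 7.8, third: 8.0, general: 9.3}
  jfhmc:
    adult_ldl_cutoff: 4.7
    child_ldl_cutoff: 3.6
    hofh_tc_cutoff: 15.5
  hk_panel:
    adult_ldl_cutoff: 5.0
    adult_ldl_cutoff_with_history: 4.5
    child_ldl_cutoff: 4.9
    child_ldl_cutoff_with_history: 3.6

ldl_policy:
  # pretreatment_first: measured pretreatment LDL-C, else corrected
  # on-treatment value.  peak_first: peak LDL-C when recorded, else the
  # pretreatment_first chain.
  source: pretreatment_first

intensity:
  # Treatment-intensity multipliers (untreated LDL-C ~= on-treatment
  # LDL-C x factor).  Anchored so that simvastatin 40-80 mg spans
  # 1.7-1.9 and atorvastatin 20 mg / rosuvastatin 5 mg sit at 1.8.
  factors:
    simvastatin:  {10: 1.4, 20: 1.55, 40: 1.7, 80: 1.9}
    atorvastatin: {10: 1.7, 20: 1.8, 40: 2.0, 80: 2.2}
    rosuvastatin: {5: 1.8, 10: 1.9, 20: 2.1, 40: 2.3}
    pravastatin:  {10: 1.3, 20: 1.4, 40: 1.5}
    fluvastatin:  {20: 1.3, 40: 1.4, 80: 1.6}
    pitavastatin: {1: 1.6, 2: 1.7, 4: 1.8}
    lovastatin:   {20: 1.4, 40: 1.55, 80: 1.7}
    ezetimibe:    {10: 1.2}
  combination: multiplicative
  untreated_intensity: 1.0     # set to 0.0 to code untreated as zero
  threshold: 1.8
  reduction_band: [0.40, 0.70]  # "around 50%" LDL-C drop
  combined_ldl_cutoff: 5.5

variants:
  splice_offset_window: 5
  receptor_class_map:
    missense: defective
    nonsense: negative
    frameshift: negative
    splice: negative
    synonymous_splice: negative

io:
  mgdl_input: false
  ldl_plausible_max: 30.0   # mmol/L; above this an mg/dL mix-up is assumed
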