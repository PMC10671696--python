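# Methods

This note documents the models, parameter choices and numerical
conventions behind `fhdx`, in the order the pipeline applies them.

## Subjects and LDL-C selection

A `Subject` carries demographics, family history (first-degree pCVD,
first-degree hyperlipidemia, a relative with an FH diagnosis, a relative
with tendon xanthoma, a child under 18 with high LDL-C), personal
history of premature coronary or cerebral/peripheral vascular disease,
physical signs (tendon xanthoma, corneal arcus before 45, xanthelasma),
lipid panels, the peak LDL-C ever recorded, a lipid-lowering regimen and
a genetic result. Pediatric means age < 18 years. All lipid values are
mmol/L.

Criteria score one LDL-C value per subject, chosen by policy:

1. a measured pretreatment LDL-C when present;
2. otherwise an on-treatment LDL-C multiplied by the regimen's
   treatment intensity ("corrected");
3. the recorded peak LDL-C only under the explicit `peak_first` policy.

Subjects with no usable source raise a scoring error naming the subject;
cohort-level evaluation converts such errors into per-criterion
exclusion (never imputation), and every report row carries its own
effective n and prevalence.

## Treatment intensity

A regimen maps to a dimensionless multiplier *I*; the untreated regimen
maps to exactly 1.0 and the implied fractional LDL-C reduction is
1 − 1/*I* (so *I* = 1.8 implies a 44% reduction, the moderate-intensity
band). Statin and ezetimibe factors combine multiplicatively (ezetimibe
1.2); the source study states no combination operator, and the
multiplicative rule is the natural composition of residual fractions.
The per-dose factor table ships in the default config, anchored at three
calibration points — simvastatin 40–80 mg/day spans 1.7–1.9, and
atorvastatin 20 mg/day and rosuvastatin 5 mg/day both sit at 1.8 — with
the remaining doses filled in from literature-standard dose–response
multipliers and constrained to be non-decreasing in dose within a drug.
Unknown drug/dose pairs raise an error naming the missing table entry
rather than interpolating.

One published group mean (0.86 in a genotype-negative group) is
impossible for a ≥1 multiplier; the likely explanation is that untreated
subjects were coded as 0 in that analysis. The default here keeps the
identity coding (untreated = 1.0), and `intensity.untreated_intensity:
0.0` reproduces the alternative. No group-mean intensity is asserted
anywhere.

The **intensity criterion** calls a subject positive when *I* ≥ 1.8 and
the observed reduction (pre − on)/pre lies in a configurable "around
50%" band, default [0.40, 0.70], which brackets the study's group means
of 55.0%/55.5%. Subjects documented untreated are negative (identity
intensity); subjects with an unknown regimen or a missing LDL-C value
are excluded, not called negative — the exclusion-versus-negative
choice is not specified by the source and exclusion is the conservative
default. The **combined criterion** additionally requires pretreatment
LDL-C ≥ 5.5 mmol/L.

Friedewald LDL-C is TC − HDL − TG/2.2, suppressed (not zeroed) when
TG > 4.5 mmol/L — strictly greater — or when the estimate is negative.

## Clinical criteria

Only the LDL-C bands of the DLCNC and modified DLCNC differ between the
two instruments; all other point items (family history 1–2, clinical
history 1–2, tendon xanthoma 6, arcus before 45 4, DNA variant 8) come
from the published DLCNC scheme and live in the config, with the maximum
taken within each item group. The modified bands (≥6 → 8, 5–5.9 → 5,
3.5–4.9 → 3, 2.5–3.4 → 1) dominate the classic bands pointwise, so the
modified score is never below the classic score — a tested invariant.
DLCNC on pediatric subjects is computed but annotated "not validated";
`pediatric_policy: suppress` withholds the binary call instead. An
optional switch scores family pCVD separately from family
hyperlipidemia (adding rather than taking the maximum), reflecting the
observation that family pCVD history can be perfectly specific for a
molecular diagnosis; it is off by default.

Simon Broome: definite = LDL-C above the age cutoff (4.9 adult / 4.0
child, strict) plus tendon xanthoma (in the subject or, configurably, a
relative) or a DNA variant; possible = LDL-C above cutoff plus family
pCVD or hyperlipidemia.

MEDPED: positive iff total cholesterol strictly exceeds the age-band ×
relative-degree threshold. The study prints no thresholds; the shipped
defaults are the published MEDPED table (mmol/L) over age bands <20 /
20–29 / 30–39 / ≥40 and first/second/third-degree/general columns. The
cohort schema models first-degree relatives only, so the applicable
column is "first" when a relative carries an FH diagnosis, else
"general".

JFHMC: LDL-C > 4.7 (adult) / 3.6 (child) plus xanthoma or family
history; total cholesterol > 15.5 mmol/L flags a homozygous pattern.

Hong Kong panel: adults are positive at LDL-C > 5, or > 4.5 with family
history of FH or pCVD; children at > 3.6 with family history, > 4.9, or
physical signs. Family history marked "optional" in the source is
treated identically whether undocumented or documented-absent.

## Evaluation statistics

Metric ratios are computed as exact rational numbers and rendered
half-up to one decimal on the percent scale — matching the printed style
of the source tables — with zero-denominator metrics marked undefined
rather than zero. PPV from counts equals PPV from (sensitivity,
specificity, prevalence) by exact fraction arithmetic (tested). Fisher's
exact test is two-sided by the sum-of-smaller-probabilities convention
(delegated to `scipy.stats.fisher_exact`; an independent hypergeometric
enumeration oracle in the test suite confirms equality).

ROC curves place thresholds at midpoints between distinct observed
scores plus sentinels, call positive at score ≥ threshold, and integrate
by trapezoid along descending thresholds; this equals the rank
(Mann–Whitney) AUC, ties counted half, and is invariant under strictly
monotone score transforms (both tested, including against
scikit-learn). The Youden optimum is the arg-max of se + sp − 1 over
thresholds, ties broken toward the lower threshold (higher
sensitivity).

`reconstruct_confusion` exhaustively enumerates integer matrices with
n ≤ n_max whose metrics round (same half-up rule) to a supplied set of
published percentages, ordered by n. It serves as the bridge between
rounded printed tables and exact integer counts: given four printed
metrics of a row, the smallest consistent matrix determines the fifth.
Enumeration to n = 60 visits under a million candidate matrices with
early pruning and runs in well under a second.

Cohort-level evaluation scores the clinical criteria with the genetic
result masked, since the genotype is the truth being predicted; the
DLCNC/Simon Broome genetic items therefore contribute only in
standalone scoring, not in diagnostic-performance tables.

## Variant spectrum

The cDNA parser covers the grammar the cohort table needs
(substitutions, duplications, deletions, insertions, intronic offsets)
and round-trips on every fixture entry; it is not a general HGVS
implementation. Consequence typing: protein "fs" → frameshift;
synonymous change plus a new-splice-site note → synonymous splice;
intronic offsets within a configurable ±5 window → splice (the window
covers a near-splice +5 change carried as likely pathogenic);
out-of-frame indels → frameshift even when annotated only with the
resulting stop; protein Ter/* → nonsense; otherwise missense. Expected
receptor class maps missense → defective and all truncating/splice
classes → negative (configurable). Coordinates stay in cDNA space
(transcript NM_000527.5 as annotation); no genome liftover.

The shipped 22-row table's proband observations sum to 25. The source
study declares 25 unique variants against the table's 22 rows, and 18
single- plus 4 double-variant cases imply 26 observations against the
table's 25; neither discrepancy is resolvable from published data, so
`spectrum_summary` reports both numbers and attaches an explicit note
instead of silently reconciling. Spectrum expansion is n_new /
(prior_total − n_new) when the prior total includes the new variants
(14 new against 73 total → 23.7%).

## Synthetic cohort generator

The generator emulates the study conditions: 19 adult and 12 pediatric
probands by default, cascade screening of first-degree relatives of
genotype-positive probands (Poisson, mean 0.75 per positive proband),
genotype prevalence 84.2% (adult probands), 50% (children) and 83.3%
(cascade relatives). Pretreatment LDL-C is zero-truncated normal per
stratum with means 8.77 / 6.53 (adult probands by genotype), 6.60
(positive cascade relatives) and 7.50 / 5.50 mmol/L (children); the
study publishes no dispersions, so the 1.5 mmol/L SD (1.0 for negative
relatives, mean 4.5) is this package's assumption. Total cholesterol is
LDL-C plus N(1.6, 0.4) offset floored at 0.2. Family pCVD history rates
are 69.2% vs 0% by genotype; family-history flags are conditionally
independent given genotype — a simplification: real pedigrees correlate
histories across relatives. Regimens are drawn from a configurable
distribution over moderate/high-intensity statins ± ezetimibe, and
on-treatment LDL-C is pretreatment / intensity × multiplicative noise
(SD 0.10). A configurable fraction (0.6) of genotype-positive subjects
carries a peak LDL-C above pretreatment (ratio ≈ 1.05).

Randomness: one global seed; each subject draws from
`default_rng([seed, counter])`, so extending a cohort leaves earlier
subjects bit-identical (tested). Structural draws (genotype, cascade
sizes) use a dedicated substream.

What passing tests on synthetic cohorts show — and do not show: stratum
means, rule operating points and AUC ordering are recovered against
closed-form values of the generating distributions, which validates the
pipeline's arithmetic, not the clinical realism of any instrument;
cascade relatives are sampled marginally, not through transmitted
alleles, and no pedigree or adherence structure is modelled.

## The reconstruction cohort

`fhdx.reconstruction` constructs a synthetic 31-adult cohort (16/3
genotype-positive/negative probands, 10/2 cascade relatives) that
simultaneously satisfies: all seven published diagnostic-performance
rows (via the enumerated integer matrices, including the two subjects
excluded from the treatment-intensity rows), the published group means
of pretreatment LDL-C, total cholesterol and peak LDL-C in probands and
cascade relatives, the family-pCVD contrasts (12/16 vs 0/3; 18/26 vs
0/5) with their Fisher p-values (0.036, 0.008), and full sensitivity /
zero specificity of DLCNC and modified DLCNC at cutoff 3 among probands.
Two published cascade aggregates are ambiguous about their denominator
(positive relatives vs all relatives); the cohort matches LDL-C and peak
means over positive relatives and the total-cholesterol mean over all
relatives. It is a constructed instance for end-to-end testing and
demonstration — not patient data, and not unique: other cohorts could
satisfy the same aggregates.

## Known limitations

- The criteria engine models first-degree family history only; MEDPED's
  second/third-degree columns are configurable but unused by the schema.
- The correction-factor table is calibrated at three published anchor
  points; other doses carry literature-standard values and should be
  reviewed before clinical use.
- ROC confidence intervals and AUC-difference tests (e.g. DeLong) are
  out of scope.
- The parser rejects HGVS constructs outside the fixture grammar
  (delins, inversions, large rearrangements); large *LDLR*
  rearrangements are not modelled at all.
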