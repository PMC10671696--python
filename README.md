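# fhdx

Familial hypercholesterolemia (FH) is a monogenic disorder of
lipoprotein metabolism — lifelong elevated LDL-cholesterol and premature
atherosclerotic cardiovascular disease (pCVD) — most often caused by
variants in the *LDLR* gene. Because there is no universal clinical gold
standard, FH is diagnosed against competing instruments: the Dutch Lipid
Clinic Network score (DLCNC), its Chinese-modified variant, the Simon
Broome Register criteria, MEDPED total-cholesterol thresholds, the
Japanese FH Management Criteria (JFHMC), and a Hong Kong expert-panel
recommendation for genetic testing.

`fhdx` is a tested, reusable pipeline for benchmarking those instruments
against genetic results in lipid-clinic cohorts. It is aimed at clinical
biochemists and lipidologists who want to score cohorts reproducibly and
quantify how well each rule predicts a molecular diagnosis. It provides:

- **Criteria engine** (`fhdx.criteria`) — all six instruments as pure
  functions of a `Subject`, with every threshold and point value in one
  editable YAML config. LDL-C comparisons are strict (`>`); DLCNC
  categories are definite (>8), probable (6–8), possible (3–5), with a
  configurable binary cutoff (default ≥3).
- **Treatment-intensity correction** (`fhdx.lipids`) — a regimen maps to
  a dimensionless multiplier *I* ≥ 1 with implied LDL-C reduction
  1 − 1/*I*; untreated LDL-C is estimated as on-treatment LDL-C × *I*.
  Includes the intensity-based rule (*I* ≥ 1.8 achieving an ≈50% LDL-C
  drop), its conjunction with an LDL-C ≥ 5.5 mmol/L cutoff, and the
  Friedewald estimate (suppressed when triglycerides > 4.5 mmol/L).
- **Evaluation** (`fhdx.evaluation`) — confusion matrices, sensitivity /
  specificity / PPV / NPV / accuracy with exact half-up percent
  rounding, two-sided Fisher exact tests, empirical ROC curves with
  trapezoidal AUC and Youden-optimal cutoffs (J = se + sp − 1), and an
  exhaustive integer reconstruction of confusion matrices from rounded
  published percentages.
- **Variant spectrum** (`fhdx.variants`) — HGVS-style cDNA parsing,
  consequence typing (missense / nonsense / frameshift / splice),
  expected receptor class (negative vs defective), and spectrum
  summaries; a 22-row *LDLR* variant table from a Hong Kong cohort ships
  as a fixture.
- **Synthetic cohorts** (`fhdx.simulate`) — seeded generator emulating a
  proband + cascade-screening cohort with configurable genotype
  prevalence, stratum LDL-C distributions, family-history rates and
  regimens, so the whole pipeline is testable without patient data.

Units are mmol/L throughout.

## Worked example

The package ships a clearly-labelled *synthetic* 31-adult cohort
(19 probands + 12 cascade-screened relatives, 26 genotype-positive)
reconstructed to be consistent with a published Hong Kong FH study's
aggregate statistics. Evaluate every criterion against the genetic
results:

```bash
fhdx evaluate src/fhdx/data/adult_cohort_reconstruction_synthetic.csv --out report.tsv
```

```
     criterion  n  excluded  tp  fp  fn  tn  sensitivity  specificity   ppv  npv  accuracy  prevalence  fisher_p
   SimonBroome 31         0  22   3   4   2         84.6         40.0  88.0 33.3      77.4        83.9     0.241
        MEDPED 31         0  22   3   4   2         84.6         40.0  88.0 33.3      77.4        83.9     0.241
         JFHMC 31         0  22   3   4   2         84.6         40.0  88.0 33.3      77.4        83.9     0.241
      HK_panel 31         0  23   4   3   1         88.5         20.0  85.2 25.0      77.4        83.9     0.525
       ldl_5.5 31         0  21   2   5   3         80.8         60.0  91.3 37.5      77.4        83.9     0.093
     intensity 29         2  23   1   1   4         95.8         80.0  95.8 80.0      93.1        82.8     0.001
      combined 29         2  20   0   4   5         83.3        100.0 100.0 55.6      86.2        82.8     0.001
         DLCNC 31         0  23   3   3   2         88.5         40.0  88.5 40.0      80.6        83.9     0.173
modified_DLCNC 31         0  26   5   0   0        100.0          0.0  83.9  NaN      83.9        83.9     1.000
```

Reading the table: the clinical instruments are sensitive (84.6–100%)
but poorly specific in this highly pre-selected cohort, while the
treatment-intensity rule (`intensity`: *I* ≥ 1.8 achieving an ≈50%
LDL-C drop) reaches 95.8% sensitivity and 80.0% specificity (accuracy
93.1%), and its conjunction with LDL-C ≥ 5.5 mmol/L (`combined`) trades
sensitivity (83.3%) for perfect specificity. `n` is the per-row
effective sample: two subjects lack treatment data and are excluded from
the intensity rows rather than called negative. `fisher_p` is the
two-sided Fisher exact p for the call × genotype table.

Other commands: `fhdx score` (per-subject criterion results),
`fhdx spectrum` (variant-table summaries), `fhdx simulate --seed N`
(write a synthetic cohort CSV). All honor `--config` for YAML overrides
of any threshold, point table or correction factor, and echo the full
configuration next to their output.

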