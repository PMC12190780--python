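# fgf21val

Analytical validation and clinical diagnostics for a plasma FGF21 ELISA run
on an automated immunoassay platform.

Circulating fibroblast growth factor 21 (FGF21) is a liver-derived hormone
under evaluation as a blood biomarker of hepatic steatosis. Before such a
biomarker can be used clinically, the assay that measures it must be
validated — precision, quantification limit, linearity, recovery,
interference, specimen handling and stability — and its diagnostic value
against an imaging reference must be quantified. `fgf21val` implements that
whole workflow as a tested, reusable pipeline for laboratory scientists and
biostatisticians, together with a synthetic-data generator that emulates
every study design with known ground truth.

## What it computes

**Calibration.** Optical signals are mapped to concentrations through the
four-parameter logistic standard curve

    y = D + (A − D) / (1 + (x/C)^B)

fitted by least squares with multi-start initialisation, inverted in closed
form (`x = C·((A−D)/(y−D) − 1)^{1/B}`), with dilution-factor correction and
working-range flags (31.3–2000 pg/mL for the kit modelled here).

**Analytical validation.** Precision as CV = 100·SD/mean (sample SD;
acceptance CV < 15%), intra-assay (20 replicates per level) and inter-assay
(5 runs × 5 replicates, pooled total CV); LLOQ interpolated from blank mean
+ 10·SD; dilution linearity (%recovery per fold-dilution and the maximal
linear prefix); spike recovery (total mode `100·measured/(neat + spike)` by
default, marginal mode available); interference relative bias; stability
percent change; and paired tube-type comparison (Spearman, Wilcoxon
signed-rank, OLS line). Biases and changes are judged against the total
change limit

    TCL = √((2.77·CV_a)² + (0.5·CV_b)²)

combining analytical imprecision CV_a with within-run variability CV_b.

**Clinical diagnostics.** Eligibility filtering (age 20–69, BMI < 30 kg/m²,
FIB-4 = AST·age/(platelets·√ALT) < 2.67, alcohol < 140/210 g per week for
women/men); steatosis grading by ultrasound attenuation coefficient
(< 0.58 normal, 0.58–0.70 suspected, > 0.70 dB/cm/MHz confirmed; binary
diagnosis at ≥ 0.66); Spearman correlation tables; pairwise Mann-Whitney
tests across grades; ROC/AUC; and dual diagnostic cut-offs — a
high-sensitivity rule-out threshold with LR⁻ = (1−sens)/spec and a
high-specificity rule-in threshold with LR⁺ = sens/(1−spec).

**Synthetic data.** 4PL plate signals with multiplicative noise at a
configurable CV, every replicate design above, stability as first-order
decay, planted tube-matrix offsets, and a patient cohort in which the
attenuation coefficient and log-normal FGF21 share a configurable Spearman
correlation (default 0.44) through a Gaussian copula.

## Worked example

```bash
fgf21val all --out run1 --seed 7
```

generates the synthetic inputs, validates the assay and analyses the
cohort. From `run1/validation/validation_report.json` (generated at 5%
well CV):

```
intra-assay CV (%):  low 4.8   medium 4.4   high 3.4     — all pass (< 15)
inter-assay CV (%):  low 6.4   medium 6.5   high 5.0     — all pass
LLOQ: 8.9 pg/mL;  dilution linear through ×128 (TCL-judged)
tubes: heparin vs EDTA   rank r = 0.992, signed-rank p = 0.93 (no difference)
       heparin vs serum  signed-rank p < 0.001, slope 0.835 (planted −12% loss)
```

and from `run1/clinical/clinical_report.json` (97 simulated patients,
planted rank correlation 0.44):

```
AUC = 0.719
rule-out threshold 202.7 pg/mL  (sensitivity 0.86, LR⁻ = 0.36)
rule-in  threshold 345.1 pg/mL  (specificity 0.85, LR⁺ = 2.96)
```

Read: FGF21 below ~203 pg/mL argues against steatosis (a negative test
leaves about one-third the pre-test odds); FGF21 at or above ~345 pg/mL
supports it (tripling the odds). The estimated attenuation–FGF21 Spearman
correlation for this seed is 0.47, matching the planted 0.44 within
sampling error.

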