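# Methods

## Calibration model

The standard curve is the four-parameter logistic (4PL)
`y = D + (A − D)/(1 + (x/C)^B)`, the de facto model for ligand-binding
assays: `A` is the signal at zero analyte, `D` the saturation signal, `C`
the inflection concentration (pg/mL) and `B > 0` the Hill slope. The kit's
documentation implies a sigmoidal calibration without naming the model; 4PL
is this package's choice, and a descending orientation (A > D, competitive
formats) is supported by inferring the direction from the standards.

Fitting is plain least squares on replicate-averaged standards
(`scipy.optimize.least_squares`, Levenberg-Marquardt, tight tolerances).
Initialisation: asymptotes from the extreme-concentration signals, `C` from
the concentration whose signal is nearest mid-range, `B = 1`; three
deterministically perturbed restarts (×/÷2 on `C` and `B`) precede a
declared fit failure. `C` and `B` are optimised on the log scale, which
enforces positivity without bounds. On noise-free 4PL data the generating
parameters are recovered to better than 1e-5 relative error (property-tested
over the admissible parameter box).

Inversion uses the closed form `x = C·((A−D)/(y−D) − 1)^{1/B}`. Signals at
or beyond an asymptote are returned as flagged censored values
(0 on the blank side, NaN on the saturation side), never infinities;
invertible results additionally carry below/above working-range flags
relative to the kit's 31.3–2000 pg/mL interval.

## Validation statistics

* **CV** uses the sample SD (n−1) throughout — the bioanalytical
  convention, and the one that reproduces printed assay-report tables from
  their means and SDs. CV at non-positive mean is an explicit
  undefined-statistic error, not NaN.
* **Inter-assay CV** pools all 25 values of a level across the five runs
  into one total CV. The run structure is preserved in the data model, so a
  between/within ANOVA decomposition can be added without changing inputs,
  but a single CV per level is what assay reports state.
* **LLOQ** = concentration at blank mean + k·SD (default k = 10), computed
  on blank *signals* and pushed through the fitted curve. The result is
  routinely below the nominal working range; only a threshold beyond the
  saturation asymptote is an error.
* **Dilution linearity**: recovery = 100·observed/expected per fold-step;
  the linear range is the maximal *prefix* of increasing factors meeting
  both the deviation limit (default: the TCL) and the CV limit — a
  mid-series failure ends the range even if later steps recover.
* **Spike recovery** defaults to the total convention
  100·measured/(neat + spike), which is the arithmetic that published
  spike-recovery tables actually satisfy; the marginal convention
  100·(measured − neat)/spike is an explicit mode and both are reported
  side by side. Spike amounts are pg/mL increments.
* **TCL** = √((2.77·CV_a)² + (0.5·CV_b)²). The pipeline wires CV_a to the
  intra-assay CV at the matched concentration level and CV_b to the tested
  sample's replicate CV; with a ~5% intra CV this lands near the 14%
  figure conventionally quoted for this assay class.
* **Tube comparison** reports Spearman correlation (midrank ties), the
  two-sided Wilcoxon signed-rank test (zeros dropped, exact null for small
  tie-free samples, normal approximation with continuity correction
  otherwise — `scipy.stats.wilcoxon`), and the OLS line of y on x.
  Ordinary rather than Deming regression is a deliberate simplification:
  with rank correlations ≈ 0.99 the attenuation of the slope is negligible.

## Clinical stage

Eligibility uses strict inequalities exactly as stated (FIB-4 = 2.67 is
ineligible). FIB-4 takes platelets in 10⁹/L; counts printed as ×10⁴/μL must
be multiplied by 10 by the caller. Attenuation band boundaries 0.58 and
0.70 dB/cm/MHz are assigned to the middle (suspected) grade, since the
bands are published as "0.58–0.70" without a boundary rule; the binary
diagnosis is attenuation ≥ 0.66.

ROC analysis treats higher FGF21 as more steatotic. AUC is the trapezoid
over the tie-grouped empirical ROC (`sklearn.metrics.roc_curve`), which
equals the rescaled Mann-Whitney statistic U/(n₁n₀); that identity is kept
as a cross-implementation test rather than the implementation. Threshold
candidates are the observed scores with the rule "score ≥ t ⇒ positive".
The rule-out cut-off maximises specificity (then sensitivity) among
thresholds with sensitivity ≥ the floor — for monotone empirical curves,
simply the largest such threshold; the rule-in cut-off mirrors this for
specificity. When a classifier beats both floors on an overlapping region
(e.g. perfect separation), both roles collapse to the single
Youden-optimal threshold satisfying both floors, keeping
rule_out ≤ rule_in. Floors default to 0.84/0.81, the operating points
characteristic of this biomarker's published performance; both are
configurable. Pairwise grade comparisons are reported unadjusted (a
Bonferroni option exists, off by default) and all tests are two-sided at
α = 0.05.

## Synthetic-data generator

The generator's defaults *are* the study conditions: 20 intra-assay
replicates per level at 159/579/1177 pg/mL, 5×5 inter-assay design, 16
blanks, nine two-fold dilutions from 3000 pg/mL, a 3×3 spike design with
neats 164/220/392 pg/mL and spikes 0/100/200 pg, six-point interference
panels, freeze-thaw cycles 1/2/3/5/7 plus 1 h–7 d time courses and one
month at −20 °C, 18 paired three-tube subjects, and a 97-patient cohort.

Noise is multiplicative Gaussian (constant CV, default 5% per well, 5%
between-run effect), matching how immunoassay imprecision is reported.
Plate *signals* carry that noise directly; note that inverting a noisy
signal through the 4PL scales the concentration CV by the local slope
factor y/(x·dy/dx), which the package exposes (`concentration_cv_factor`)
and the tests verify by the delta method. Replicate files carry the noise
at the concentration scale, i.e. they emulate reported concentrations whose
imprecision is the assay CV.

Stability is first-order exponential decay per condition (room temperature
0.051/day ⇒ ≈30% loss by day 7; 4 °C 0.0215/day ⇒ ≈14%; −20 °C
0.0008/day), with freeze-thaw as a 1.5% per-cycle step loss — the
qualitative shapes of plasma-protein stability series. The serum tube
carries a planted −12% proteolysis offset; heparin vs EDTA is null. The
dilution series collapses (50% recovery, inflated CV) once the expected
concentration falls below 15 pg/mL — near the LLOQ rather than at the
nominal working-range floor, because the assay quantifies below its nominal
range.

The cohort uses a Gaussian copula: a latent bivariate normal with Pearson
correlation 2·sin(π·ρ_s/6) drives the attenuation coefficient (uniform over
0.32–0.97 dB/cm/MHz via the normal CDF) and log-normal FGF21 (log-median
log 290, log-SD 0.55). Because both marginal maps are monotone, the Spearman
correlation equals the target ρ_s (default 0.44) by construction, and the
implied AUC against the 0.66-attenuation diagnosis emerges at ≈0.72.
Chemistry and demographic marginals are truncated normals/log-normals
inside realistic outpatient ranges chosen so that ≥90% of records pass
eligibility. Targets with |ρ_s| ≥ 1 are rejected as infeasible.

What the generator does **not** emulate: plate spatial effects (edge,
drift), calibration drift between runs, non-Gaussian heavy-tailed outliers,
FGF21's known covariate dependencies (age, alcohol, fibrosis) beyond the
single planted attenuation association, and any pharmacokinetics.
Passing tests therefore demonstrate that the *statistics* are computed
correctly and recover planted truth under idealised noise — not that the
assay or biomarker behaves this way in real specimens.

## Numerical choices and degenerate inputs

* Report tables round percentages half-up to one decimal at render time
  only; all internal computation is unrounded.
* Wilcoxon zeros are dropped (the original convention); tied absolute
  differences take midranks.
* Constant vectors make rank correlations an explicit undefined-statistic
  error; within the cohort report a constant covariate yields a NaN row
  rather than aborting the analysis.
* Exact permutation p-values are available for Spearman at n ≤ 8; the
  Mann-Whitney exact null is used automatically for small tie-free samples.
* All simulation randomness flows from one integer seed through a fixed
  consumption order; identical configs produce byte-identical files.

## Problem sizes

Default designs run in milliseconds; the repeated-simulation checks use
500 seeded suites (intra-CV recovery) and a 5000-patient cohort
(rank-correlation concentration), sizes at which Monte-Carlo error is an
order of magnitude below the asserted tolerances.

## Known limitations

Single-analyte, single-plate model; no 5PL or weighting options in the
fit; inter-assay CV has no variance-component decomposition; the dual
thresholds are floor-based (target-sensitivity/-specificity), with no
Youden or cost-ratio alternatives except in the overlap-collapse case; the
eligibility alcohol criterion implements the weekly phrasing only.
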