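"""Clinical diagnostics: eligibility, FIB-4, steatosis grading, ROC dual thresholds.

The clinical stage evaluates a circulating biomarker (plasma FGF21, pg/mL)
against ultrasound attenuation imaging of the liver.  The attenuation
coefficient (dB/cm/MHz) grades hepatic steatosis — < 0.58 normal, 0.58-0.70
suspected, > 0.70 confirmed — and the binary diagnosis used for ROC analysis
is attenuation >= 0.66.  Higher FGF21 is treated as more likely steatotic,
and two cut-offs are selected from the ROC: a rule-out threshold (largest
threshold keeping sensitivity above a floor; values below it argue against
steatosis, summarised by LR- = (1-sens)/spec) and a rule-in threshold
(smallest threshold with specificity above a floor; values at or above it
support the diagnosis, LR+ = sens/(1-spec)).

FIB-4 = (AST x age) / (platelets x sqrt(ALT)) with platelets in 10^9/L
screens out likely advanced fibrosis (>= 2.67) before the steatosis
analysis, alongside age 20-69, BMI < 30 kg/m^2 and the metabolic-SLD
alcohol bounds (< 140 g/week female, < 210 g/week male).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import InfeasibleError, InputError, MissingDataError, UndefinedStatisticError

#: Attenuation-coefficient band edges (dB/cm/MHz) for steatosis grading.
ATTENUATION_BANDS = (0.58, 0.70)
#: Attenuation cut-off defining the binary steatosis diagnosis for ROC analysis.
DIAGNOSIS_CUTOFF = 0.66
#: Eligibility bounds.
AGE_RANGE = (20, 69)
BMI_LIMIT = 30.0
FIB4_LIMIT = 2.67
ALCOHOL_LIMIT_G_WEEK = {"female": 140.0, "male": 210.0}


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class SteatosisCategory(str, Enum):
    NORMAL = "normal"
    SUSPECTED = "suspected"
    CONFIRMED = "confirmed"


@dataclass(frozen=True)
class PatientRecord:
    """One subject's demographics, chemistry, imaging and biomarker value."""

    age: float                      # years
    sex: str                        # "male" / "female"
    bmi: float                      # kg/m^2
    ast: float                      # U/L
    alt: float                      # U/L
    ggt: float                      # U/L
    total_bilirubin: float          # mg/dL
    albumin: float                  # g/dL
    platelet_count: float           # 10^9/L
    weekly_alcohol_g: float         # grams of ethanol per week
    shear_wave_speed: float         # m/s
    attenuation_coefficient: float  # dB/cm/MHz
    fgf21: float                    # pg/mL
    patient_id: str = ""

    def __post_init__(self):
        if self.sex not in (Sex.MALE.value, Sex.FEMALE.value):
            raise InputError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not 0 < self.attenuation_coefficient < 2:
            raise InputError("attenuation_coefficient must lie in (0, 2) dB/cm/MHz")


def fib4(age: float, ast: float, alt: float, platelets: float) -> float:
    """FIB-4 fibrosis index; ``platelets`` in 10^9/L (multiply x10^4/uL counts by 10)."""
    for name, v in (("age", age), ("ast", ast), ("alt", alt), ("platelets", platelets)):
        if not (math.isfinite(v) and v > 0):
            raise InputError(f"{name} must be positive and finite, got {v}")
    return (ast * age) / (platelets * math.sqrt(alt))


@dataclass(frozen=True)
class EligibilityResult:
    eligible: bool
    failed_criteria: tuple[str, ...]
    fib4_index: float


_ELIGIBILITY_FIELDS = ("age", "sex", "bmi", "ast", "alt", "platelet_count", "weekly_alcohol_g")


def eligibility_filter(p: PatientRecord | Mapping) -> EligibilityResult:
    """Apply the cohort inclusion criteria; every failed criterion is enumerated.

    Criteria (all strict where stated): 20 <= age <= 69, BMI < 30 kg/m^2,
    FIB-4 < 2.67, weekly alcohol < 140 g (female) / < 210 g (male).
    """
    get = (lambda f: getattr(p, f, None)) if isinstance(p, PatientRecord) else (lambda f: p.get(f))
    missing = [f for f in _ELIGIBILITY_FIELDS
               if get(f) is None or (isinstance(get(f), float) and math.isnan(get(f)))]
    if missing:
        raise MissingDataError(missing)
    failed = []
    age = float(get("age"))
    if not AGE_RANGE[0] <= age <= AGE_RANGE[1]:
        failed.append("age")
    if not float(get("bmi")) < BMI_LIMIT:
        failed.append("bmi")
    idx = fib4(age, float(get("ast")), float(get("alt")), float(get("platelet_count")))
    if not idx < FIB4_LIMIT:
        failed.append("fib4")
    limit = ALCOHOL_LIMIT_G_WEEK[str(get("sex"))]
    if not float(get("weekly_alcohol_g")) < limit:
        failed.append("alcohol")
    return EligibilityResult(eligible=not failed, failed_criteria=tuple(failed), fib4_index=idx)


def classify_steatosis(att: float, bands: tuple[float, float] = ATTENUATION_BANDS) -> SteatosisCategory:
    """Grade steatosis from the attenuation coefficient.

    Band boundaries are assigned to the middle (suspected) category: the
    grading bands are < lo, [lo, hi], > hi.
    """
    if not (math.isfinite(att) and att > 0):
        raise InputError("attenuation coefficient must be positive")
    lo, hi = bands
    if att < lo:
        return SteatosisCategory.NORMAL
    if att <= hi:
        return SteatosisCategory.SUSPECTED
    return SteatosisCategory.CONFIRMED


# ---------------------------------------------------------------------------
# nonparametric statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


def spearman(x, y, method: str = "asymptotic") -> CorrelationResult:
    """Spearman rank correlation with midrank ties.

    ``method='asymptotic'`` uses the t-approximation for the p-value;
    ``'exact'`` enumerates all permutations of one rank vector (n <= 8).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise InputError("spearman needs n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InputError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined for constant input")
    r, p = stats.spearmanr(x, y)
    if method == "exact":
        if x.size > 8:
            raise InputError("exact permutation p limited to n <= 8")
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = abs(float(r))
        count = total = 0
        for perm in itertools.permutations(ry):
            rp = np.corrcoef(rx, perm)[0, 1]
            total += 1
            if abs(rp) >= obs - 1e-12:
                count += 1
        p = count / total
    elif method != "asymptotic":
        raise InputError("method must be 'asymptotic' or 'exact'")
    return CorrelationResult(r=float(r), p=float(p), n=int(x.size))


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p: float
    n1: int
    n2: int


def mann_whitney(a, b) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U with midrank ties.

    The exact null distribution is used for small tie-free samples, and the
    normal approximation with tie and continuity corrections otherwise.  The
    returned U counts pairs where ``a`` exceeds ``b`` (ties half-weighted).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise InputError("each group needs >= 3 observations")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto",
                             use_continuity=True)
    return MannWhitneyResult(u=float(res.statistic), p=float(res.pvalue),
                             n1=int(a.size), n2=int(b.size))


# ---------------------------------------------------------------------------
# ROC analysis and dual thresholds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RocResult:
    auc: float
    points: pd.DataFrame = field(repr=False)  # threshold, sensitivity, specificity


def roc_auc(scores, labels) -> RocResult:
    """ROC curve and trapezoidal AUC (ties grouped; equals U/(n1*n2)).

    Positivity direction: higher score => positive class (label 1).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise InputError("scores and labels must have equal length")
    uniq = set(np.unique(labels).tolist())
    if not uniq <= {0, 1} or len(uniq) != 2:
        raise InputError("labels must contain both classes, coded 0/1")
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    points = pd.DataFrame({"threshold": thr, "sensitivity": tpr, "specificity": 1.0 - fpr})
    return RocResult(auc=auc, points=points)


@dataclass(frozen=True)
class OperatingPoint:
    """Sensitivity/specificity and both likelihood ratios at one threshold.

    The decision rule is score >= threshold => test-positive.
    """

    threshold: float
    sensitivity: float
    specificity: float
    lr_pos: float
    lr_neg: float


@dataclass(frozen=True)
class DiagnosticThresholds:
    """Dual cut-offs: a high-sensitivity rule-out and a high-specificity rule-in."""

    rule_out: OperatingPoint
    rule_in: OperatingPoint
    auc: float

    def __post_init__(self):
        if self.rule_out.threshold > self.rule_in.threshold:
            raise InputError("rule_out threshold must not exceed rule_in threshold")

    # flat accessors used by reports
    @property
    def sens_at_rule_out(self) -> float:
        return self.rule_out.sensitivity

    @property
    def spec_at_rule_in(self) -> float:
        return self.rule_in.specificity

    @property
    def lr_neg(self) -> float:
        return self.rule_out.lr_neg

    @property
    def lr_pos(self) -> float:
        return self.rule_in.lr_pos


def _operating_point(scores, labels, t: float) -> OperatingPoint:
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    sens = float(np.mean(pos >= t))
    spec = float(np.mean(neg < t))
    lr_pos = sens / (1.0 - spec) if spec < 1.0 else math.inf
    lr_neg = (1.0 - sens) / spec if spec > 0.0 else math.inf
    return OperatingPoint(threshold=float(t), sensitivity=sens, specificity=spec,
                          lr_pos=lr_pos, lr_neg=lr_neg)


def select_dual_thresholds(scores, labels, sens_floor: float = 0.84,
                           spec_floor: float = 0.81) -> DiagnosticThresholds:
    """Choose rule-out and rule-in cut-offs from the empirical ROC.

    rule_out is the *largest* observed score threshold whose sensitivity
    still meets ``sens_floor`` (so "score < rule_out" excludes disease with
    few misses); rule_in is the *smallest* threshold whose specificity meets
    ``spec_floor``.  Raises :class:`InfeasibleError` when no threshold
    satisfies a floor.
    """
    if not (0.5 < sens_floor < 1 and 0.5 < spec_floor < 1):
        raise InputError("floors must lie in (0.5, 1)")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    roc = roc_auc(scores, labels)
    candidates = np.unique(scores)
    points = [_operating_point(scores, labels, t) for t in candidates]
    feas_out = [p for p in points if p.sensitivity >= sens_floor]
    if not feas_out:
        raise InfeasibleError(f"no threshold achieves sensitivity >= {sens_floor}")
    # among sens-feasible thresholds take the most specific (then most
    # sensitive) one; with strictly decreasing sensitivity this is simply the
    # largest threshold still meeting the floor
    rule_out = max(feas_out, key=lambda p: (p.specificity, p.sensitivity))
    feas_in = [p for p in points if p.specificity >= spec_floor]
    if not feas_in:
        raise InfeasibleError(f"no threshold achieves specificity >= {spec_floor}")
    rule_in = max(feas_in, key=lambda p: (p.sensitivity, p.specificity))
    if rule_in.threshold < rule_out.threshold:
        # classifier beats both floors on an overlapping region: collapse to
        # the single Youden-optimal threshold satisfying both floors
        both = [p for p in points
                if p.sensitivity >= sens_floor and p.specificity >= spec_floor]
        best = max(both, key=lambda p: (p.sensitivity + p.specificity, p.threshold))
        rule_out = rule_in = best
    return DiagnosticThresholds(rule_out=rule_out, rule_in=rule_in, auc=roc.auc)


# ---------------------------------------------------------------------------
# cohort pipeline
# ---------------------------------------------------------------------------

#: Clinical covariates correlated against the biomarker in the cohort report.
CORRELATION_VARIABLES = (
    "age", "bmi", "ast", "alt", "ggt", "total_bilirubin", "albumin",
    "platelet_count", "fib4", "shear_wave_speed", "attenuation_coefficient",
)

PATIENT_COLUMNS = (
    "age", "sex", "bmi", "ast", "alt", "ggt", "total_bilirubin", "albumin",
    "platelet_count", "weekly_alcohol_g", "shear_wave_speed",
    "attenuation_coefficient", "fgf21",
)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV with one row per patient (PatientRecord columns)."""
    df = pd.read_csv(path)
    missing = set(PATIENT_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"cohort file lacks column(s): {sorted(missing)}")
    return df


def cohort_analysis(
    cohort: pd.DataFrame | Iterable[PatientRecord],
    sens_floor: float = 0.84,
    spec_floor: float = 0.81,
    diagnosis_cutoff: float = DIAGNOSIS_CUTOFF,
    bands: tuple[float, float] = ATTENUATION_BANDS,
    min_eligible: int = 20,
    bonferroni: bool = False,
) -> dict:
    """Run the full clinical stage on a patient cohort.

    Steps: FIB-4 and eligibility filtering; Spearman correlations of every
    clinical covariate against the biomarker; biomarker comparison across the
    three attenuation categories (pairwise Mann-Whitney, unadjusted by
    default); ROC of the biomarker against the binary diagnosis
    (attenuation >= ``diagnosis_cutoff``); dual rule-out/rule-in thresholds
    with likelihood ratios.
    """
    if not isinstance(cohort, pd.DataFrame):
        cohort = pd.DataFrame([vars(p) for p in cohort])
    df = cohort.copy()
    missing = set(PATIENT_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"cohort lacks column(s): {sorted(missing)}")

    df["fib4"] = [fib4(a, s, l, pl) for a, s, l, pl in
                  zip(df["age"], df["ast"], df["alt"], df["platelet_count"])]
    elig = [eligibility_filter(row) for row in df.to_dict("records")]
    df["eligible"] = [e.eligible for e in elig]
    df["failed_criteria"] = [";".join(e.failed_criteria) for e in elig]
    n_total = len(df)
    el = df[df["eligible"]].reset_index(drop=True)
    if len(el) < min_eligible:
        raise InputError(f"only {len(el)} eligible records; need >= {min_eligible}")

    correlations = {}
    for var in CORRELATION_VARIABLES:
        try:
            res = spearman(el[var], el["fgf21"])
            correlations[var] = {"r": res.r, "p": res.p, "n": res.n}
        except UndefinedStatisticError:
            # a constant covariate has no rank correlation; keep the row
            correlations[var] = {"r": math.nan, "p": math.nan, "n": int(len(el))}

    el["category"] = [classify_steatosis(a, bands).value for a in el["attenuation_coefficient"]]
    cats = [c.value for c in SteatosisCategory]
    category_summary = {
        c: {"n": int((el["category"] == c).sum()),
            "fgf21_median": float(el.loc[el["category"] == c, "fgf21"].median())
            if (el["category"] == c).any() else math.nan}
        for c in cats
    }
    pairwise = {}
    n_pairs = 3
    for c1, c2 in itertools.combinations(cats, 2):
        g1 = el.loc[el["category"] == c1, "fgf21"].to_numpy()
        g2 = el.loc[el["category"] == c2, "fgf21"].to_numpy()
        if g1.size >= 3 and g2.size >= 3:
            mw = mann_whitney(g1, g2)
            p = min(1.0, mw.p * n_pairs) if bonferroni else mw.p
            pairwise[f"{c1}_vs_{c2}"] = {"u": mw.u, "p": p, "n1": mw.n1, "n2": mw.n2}

    labels = (el["attenuation_coefficient"] >= diagnosis_cutoff).astype(int).to_numpy()
    scores = el["fgf21"].to_numpy(dtype=float)
    roc = roc_auc(scores, labels)
    thresholds = select_dual_thresholds(scores, labels, sens_floor, spec_floor)

    return {
        "n_total": n_total,
        "n_eligible": int(len(el)),
        "correlations": correlations,
        "category_summary": category_summary,
        "pairwise_tests": pairwise,
        "diagnosis_cutoff": diagnosis_cutoff,
        "n_positive": int(labels.sum()),
        "auc": roc.auc,
        "roc_points": roc.points,
        "thresholds": thresholds,
        "eligibility_table": df,
    }
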