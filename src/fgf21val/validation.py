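"""Analytical-validation statistics for a plate immunoassay.

Implements the full accuracy/precision battery used to validate a
ligand-binding assay on an automated platform:

* intra- and inter-assay precision (CV = 100*SD/mean, sample SD, pass if
  CV < 15% by default),
* lower limit of quantification from blank signals (mean + 10*SD,
  interpolated through the calibration curve),
* dilution linearity (% recovery per fold-dilution against the expected
  concentration, with a maximal linear prefix),
* spike recovery (total-recovery convention by default, marginal available),
* interference relative bias against the total change limit,
* stability time courses (percent change from a reference aliquot judged
  against the TCL),
* blood-collection-tube comparison (Spearman correlation, Wilcoxon
  signed-rank, ordinary least-squares line).

The total change limit combines analytical imprecision CV_a with within-run
variability CV_b as TCL = sqrt((2.77*CV_a)^2 + (0.5*CV_b)^2); an absolute
bias or percent change inside the TCL is analytically insignificant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import CalibrationCurve, signal_to_concentration
from .errors import InputError, UndefinedStatisticError

#: Default precision acceptance bound (%CV) for ligand-binding assays.
DEFAULT_CV_LIMIT = 15.0

LEVELS = ("low", "medium", "high", "blank", "lloq", "other")

STABILITY_CONDITIONS = ("freeze_thaw", "fridge_4C", "room_temp", "minus20C")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up, matching how assay report tables are printed."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# replicate sets and precision
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReplicateSet:
    """A coded sample's replicate measurements — the unit of CV analysis.

    ``values`` are concentrations in pg/mL, except for blank sets where they
    are raw signals (blanks sit below the quantifiable range by definition).
    """

    sample_id: str
    level: str
    run_id: str
    values: tuple[float, ...]

    def __post_init__(self):
        if self.level not in LEVELS:
            raise InputError(f"level must be one of {LEVELS}, got {self.level!r}")
        vals = tuple(float(v) for v in self.values)
        if len(vals) == 0:
            raise InputError("values must be non-empty")
        if not all(math.isfinite(v) and v >= 0 for v in vals):
            raise InputError("values must be finite and non-negative")
        object.__setattr__(self, "values", vals)


@dataclass(frozen=True)
class PrecisionResult:
    n: int
    mean: float
    sd: float
    cv_percent: float
    passes: bool
    threshold: float = DEFAULT_CV_LIMIT


def _values_of(data) -> np.ndarray:
    if isinstance(data, ReplicateSet):
        return np.asarray(data.values, dtype=float)
    return np.asarray(list(data), dtype=float)


def precision_summary(replicates, threshold: float = DEFAULT_CV_LIMIT) -> PrecisionResult:
    """Within-run precision: mean, sample SD (n-1), %CV and pass flag.

    Accepts a :class:`ReplicateSet` or any sequence of values.
    """
    v = _values_of(replicates)
    if v.size < 2:
        raise InputError("precision needs at least 2 replicates")
    if not np.all(np.isfinite(v)):
        raise InputError("replicate values must be finite")
    mean = float(np.mean(v))
    if mean <= 0:
        raise UndefinedStatisticError("CV undefined for non-positive mean")
    sd = float(np.std(v, ddof=1))
    cv = 100.0 * sd / mean
    return PrecisionResult(n=int(v.size), mean=mean, sd=sd, cv_percent=cv,
                           passes=cv < threshold, threshold=threshold)


def inter_assay_summary(sets: Iterable[ReplicateSet],
                        threshold: float = DEFAULT_CV_LIMIT) -> PrecisionResult:
    """Between-run precision: pool all values across runs into one total CV.

    The run structure is retained in the inputs (one :class:`ReplicateSet`
    per run) but the summary follows the single-CV-per-level reporting
    convention rather than an ANOVA variance decomposition.
    """
    sets = list(sets)
    runs = {s.run_id for s in sets}
    if len(runs) < 2:
        raise InputError("inter-assay precision needs >= 2 distinct runs")
    pooled = np.concatenate([_values_of(s) for s in sets])
    return precision_summary(pooled, threshold=threshold)


def lloq_from_blanks(blanks, curve: CalibrationCurve, k: float = 10.0) -> float:
    """Lower limit of quantification: invert (blank mean + k*SD) through the curve.

    ``blanks`` holds raw blank *signals*; ``k`` defaults to 10 per the
    mean-plus-ten-SD convention.  The interpolated concentration may fall
    below the kit working range — that is the point of the exercise — but a
    threshold signal at or beyond the saturation asymptote is an error.
    """
    v = _values_of(blanks)
    if v.size < 2:
        raise InputError("LLOQ estimation needs >= 2 blank signals")
    if k < 0:
        raise InputError("multiplier k must be >= 0")
    threshold = float(np.mean(v)) + k * float(np.std(v, ddof=1))
    est = signal_to_concentration(curve, threshold)
    if est.censored and math.isnan(est.concentration):
        raise InputError("blank mean + k*SD exceeds the curve's saturation asymptote")
    return est.concentration


# ---------------------------------------------------------------------------
# recovery statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoveryResult:
    """One dilution step or spike level: measured vs theoretical concentration."""

    label: str
    theoretical: float
    measured: float
    recovery_percent: float
    cv_percent: float = math.nan


@dataclass(frozen=True)
class DilutionLinearityResult:
    results: tuple[RecoveryResult, ...]
    linear_factors: tuple[int, ...]
    deviation_limit: float
    cv_limit: float

    @property
    def max_linear_factor(self) -> int | None:
        return self.linear_factors[-1] if self.linear_factors else None


def dilution_linearity(
    series: Iterable[Mapping] | pd.DataFrame,
    deviation_limit: float | None = None,
    criterion: "StabilityCriterion | None" = None,
    cv_limit: float = DEFAULT_CV_LIMIT,
) -> DilutionLinearityResult:
    """Per-factor % recovery for a serial-dilution series and its linear range.

    Each row needs ``factor`` (fold dilution), ``expected`` (top
    concentration / factor, pg/mL), ``observed`` (back-calculated, already
    dilution-adjusted, pg/mL) and optionally ``cv`` (replicate %CV).
    Recovery is 100*observed/expected.  The linear range is the maximal
    prefix of increasing factors whose |recovery - 100| stays within the
    deviation limit (the TCL, by default) and whose CV stays below
    ``cv_limit``.
    """
    if deviation_limit is None:
        if criterion is None:
            raise InputError("provide deviation_limit or a StabilityCriterion")
        deviation_limit = criterion.tcl
    rows = series.to_dict("records") if isinstance(series, pd.DataFrame) else [dict(r) for r in series]
    if not rows:
        raise InputError("empty dilution series")
    factors = [float(r["factor"]) for r in rows]
    if any(b <= a for a, b in zip(factors, factors[1:])):
        raise InputError("dilution factors must be strictly increasing")
    results: list[RecoveryResult] = []
    linear: list[int] = []
    still_linear = True
    for r in rows:
        expected = float(r["expected"])
        observed = float(r["observed"])
        if expected <= 0:
            raise InputError("expected concentration must be positive")
        rec = 100.0 * observed / expected
        cv = float(r.get("cv", math.nan))
        results.append(RecoveryResult(label=f"x{int(r['factor'])}", theoretical=expected,
                                      measured=observed, recovery_percent=rec, cv_percent=cv))
        ok = abs(rec - 100.0) <= deviation_limit and not (math.isfinite(cv) and cv >= cv_limit)
        if still_linear and ok:
            linear.append(int(r["factor"]))
        else:
            still_linear = False
    return DilutionLinearityResult(tuple(results), tuple(linear), deviation_limit, cv_limit)


def spike_recovery(neat: float, spiked_measured: float, spike_added: float,
                   mode: str = "total", cv_percent: float = math.nan,
                   label: str = "") -> RecoveryResult:
    """% recovery of a known spike.

    ``total`` mode (the default) compares the spiked measurement with the
    full theoretical concentration neat + spike; ``marginal`` mode compares
    the measured increment with the spike alone.  The two coincide when
    neat = 0 and both read 100% for a perfect measurement.
    """
    if spike_added <= 0:
        raise InputError("spike_added must be positive")
    if neat < 0 or spiked_measured < 0:
        raise InputError("concentrations must be non-negative")
    if mode == "total":
        theoretical = neat + spike_added
        measured = spiked_measured
    elif mode == "marginal":
        theoretical = spike_added
        measured = spiked_measured - neat
    else:
        raise InputError(f"mode must be 'total' or 'marginal', got {mode!r}")
    if theoretical <= 0:
        raise InputError("theoretical concentration must be positive")
    return RecoveryResult(label=label or f"+{spike_added:g}", theoretical=theoretical,
                          measured=measured, recovery_percent=100.0 * measured / theoretical,
                          cv_percent=cv_percent)


def spike_recovery_table(spikes: pd.DataFrame) -> pd.DataFrame:
    """Both recovery modes for a spike design table.

    ``spikes`` columns: sample_id, spike_pg, measured, optional cv.  The
    spike_pg == 0 row of each sample is its neat measurement.
    """
    out = []
    for sid, g in spikes.groupby("sample_id", sort=False):
        g = g.sort_values("spike_pg")
        neat_rows = g[g["spike_pg"] == 0]
        if neat_rows.empty:
            raise InputError(f"sample {sid!r} has no neat (spike 0) row")
        neat = float(neat_rows["measured"].iloc[0])
        for _, r in g[g["spike_pg"] > 0].iterrows():
            tot = spike_recovery(neat, float(r["measured"]), float(r["spike_pg"]), "total")
            marg = spike_recovery(neat, float(r["measured"]), float(r["spike_pg"]), "marginal")
            out.append({
                "sample_id": sid,
                "spike_pg": float(r["spike_pg"]),
                "neat": neat,
                "measured": float(r["measured"]),
                "cv_percent": float(r.get("cv", math.nan)),
                "theoretical_total": tot.theoretical,
                "recovery_total_percent": tot.recovery_percent,
                "recovery_marginal_percent": marg.recovery_percent,
            })
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# total change limit, interference, stability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StabilityCriterion:
    """CV_a/CV_b pair and the derived total change limit (all in %)."""

    cv_a: float
    cv_b: float
    tcl: float

    def __post_init__(self):
        expected = math.hypot(2.77 * self.cv_a, 0.5 * self.cv_b)
        if not math.isclose(self.tcl, expected, rel_tol=1e-9, abs_tol=1e-12):
            raise InputError("tcl inconsistent with cv_a/cv_b")


def total_change_limit(cv_a: float, cv_b: float) -> StabilityCriterion:
    """TCL = sqrt((2.77*CV_a)^2 + (0.5*CV_b)^2), in percent."""
    if cv_a < 0 or cv_b < 0:
        raise InputError("CV inputs must be non-negative")
    return StabilityCriterion(cv_a=cv_a, cv_b=cv_b,
                              tcl=math.hypot(2.77 * cv_a, 0.5 * cv_b))


@dataclass(frozen=True)
class InterferencePoint:
    interferent: str
    level: int
    observed: float
    relative_bias_percent: float
    exceeds_tcl: bool


def interference_bias(baseline: float, panel: Iterable[Mapping],
                      criterion: StabilityCriterion) -> list[InterferencePoint]:
    """Relative bias of each interference-panel point vs the interferent-free baseline.

    bias = 100*(observed - baseline)/baseline; a point is acceptable when
    |bias| <= TCL.
    """
    if baseline <= 0:
        raise InputError("baseline must be positive")
    rows = [dict(r) for r in panel]
    if not rows:
        raise InputError("interference panel is empty")
    out = []
    for r in rows:
        obs = float(r["observed"])
        bias = 100.0 * (obs - baseline) / baseline
        out.append(InterferencePoint(
            interferent=str(r["interferent"]), level=int(r["level"]), observed=obs,
            relative_bias_percent=bias, exceeds_tcl=abs(bias) > criterion.tcl))
    return out


@dataclass(frozen=True)
class StabilityPoint:
    """One stability observation: condition x exposure x level vs its reference."""

    condition: str
    exposure: float
    level: str
    reference_value: float
    measured_value: float
    percent_change: float
    exceeds_tcl: bool


def stability_series(points: Iterable[Mapping],
                     criterion: StabilityCriterion) -> list[StabilityPoint]:
    """Percent change from the reference aliquot for every stability point.

    Input rows need condition, exposure (cycles or days), level, reference,
    measured.  Output is ordered by condition, level, exposure.
    """
    rows = [dict(r) for r in points]
    if not rows:
        raise InputError("no stability points supplied")
    out = []
    for r in rows:
        if "reference" not in r or r["reference"] is None or not math.isfinite(float(r["reference"])):
            raise InputError(f"stability point missing reference value: {r}")
        ref = float(r["reference"])
        if ref <= 0:
            raise InputError("reference value must be positive")
        meas = float(r["measured"])
        change = 100.0 * (meas - ref) / ref
        out.append(StabilityPoint(
            condition=str(r["condition"]), exposure=float(r["exposure"]),
            level=str(r["level"]), reference_value=ref, measured_value=meas,
            percent_change=change, exceeds_tcl=abs(change) > criterion.tcl))
    out.sort(key=lambda p: (p.condition, p.level, p.exposure))
    return out


def stability_summary(points: Sequence[StabilityPoint]) -> pd.DataFrame:
    """Long-format summary table ordered by condition/level/exposure."""
    return pd.DataFrame([{
        "condition": p.condition, "level": p.level, "exposure": p.exposure,
        "reference": p.reference_value, "measured": p.measured_value,
        "percent_change": p.percent_change, "exceeds_tcl": p.exceeds_tcl,
    } for p in points])


# ---------------------------------------------------------------------------
# tube-type comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TubeComparisonResult:
    pair: tuple[str, str]
    n: int
    rank_correlation: float
    rank_correlation_p: float
    signed_rank_p: float
    slope: float
    intercept: float


def tube_comparison(x, y, pair: tuple[str, str] = ("heparin", "edta")) -> TubeComparisonResult:
    """Agreement between two collection-tube types on paired samples.

    Computes Spearman rank correlation (midrank ties), the two-sided
    Wilcoxon signed-rank test (zeros dropped; exact null for small n,
    normal approximation with continuity correction otherwise) and the
    ordinary least-squares line of y on x.  Incomplete pairs are dropped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputError("paired vectors must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 5:
        raise InputError("tube comparison needs >= 5 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("rank correlation undefined for a constant vector")
    rho, rho_p = stats.spearmanr(x, y)
    d = x - y
    if np.all(d == 0):
        sr_p = 1.0
    else:
        sr = stats.wilcoxon(x, y, zero_method="wilcox", correction=True,
                            alternative="two-sided", method="auto")
        sr_p = float(sr.pvalue)
    reg = stats.linregress(x, y)
    return TubeComparisonResult(pair=tuple(pair), n=int(x.size),
                                rank_correlation=float(rho), rank_correlation_p=float(rho_p),
                                signed_rank_p=sr_p, slope=float(reg.slope),
                                intercept=float(reg.intercept))


# ---------------------------------------------------------------------------
# CSV ingestion helpers (schemas shared with the simulator and CLI)
# ---------------------------------------------------------------------------

def read_replicates(path) -> list[ReplicateSet]:
    """Read replicates.csv (sample_id, level, run_id, value) into ReplicateSets."""
    df = pd.read_csv(path)
    required = {"sample_id", "level", "run_id", "value"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"replicates file lacks column(s): {sorted(missing)}")
    sets = []
    for (sid, level, run), g in df.groupby(["sample_id", "level", "run_id"], sort=False):
        sets.append(ReplicateSet(sample_id=str(sid), level=str(level), run_id=str(run),
                                 values=tuple(float(v) for v in g["value"])))
    return sets
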