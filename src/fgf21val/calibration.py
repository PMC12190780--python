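"""Four-parameter logistic (4PL) calibration for plate immunoassays.

An ELISA standard curve relates analyte concentration *x* (pg/mL) to optical
signal *y* through the four-parameter logistic

    y = D + (A - D) / (1 + (x / C)^B)

where ``A`` is the signal at zero concentration, ``D`` the signal at
saturating concentration, ``C`` the inflection concentration (the point of
half-maximal signal) and ``B > 0`` the Hill slope.  Sandwich assays are
*ascending* (A < D); competitive formats are descending (A > D) and are
supported by inferring the orientation from the standards.

The module fits the curve by least squares with multi-start initialisation,
inverts it in closed form for back-calculation of unknowns, applies
dilution-factor correction, and flags results outside the kit's working
range (31.3-2000 pg/mL for the assay this package models).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import FitError, InputError

#: Kit working range in pg/mL (manufacturer's quantifiable interval).
DEFAULT_WORKING_RANGE: tuple[float, float] = (31.3, 2000.0)

#: Concentrations (pg/mL) of the kit's standard series, top standard 2000
#: with seven two-fold dilutions plus a zero (blank) standard.
KIT_STANDARDS: tuple[float, ...] = (0.0, 31.3, 62.5, 125.0, 250.0, 500.0, 1000.0, 2000.0)


class RangeFlag(str, Enum):
    """Working-range status of a back-calculated concentration."""

    IN_RANGE = "in_range"
    BELOW_RANGE = "below_range"
    ABOVE_RANGE = "above_range"


@dataclass(frozen=True)
class StandardPoint:
    """One well of the standard series: known concentration, observed signal."""

    concentration: float
    signal: float
    replicate_id: int = 1

    def __post_init__(self):
        if not (math.isfinite(self.concentration) and self.concentration >= 0):
            raise InputError(f"standard concentration must be finite and >= 0, got {self.concentration}")
        if not (math.isfinite(self.signal) and self.signal >= 0):
            raise InputError(f"standard signal must be finite and >= 0, got {self.signal}")


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Back-calculated concentration with its working-range flag.

    ``censored`` marks signals at or beyond an asymptote, where the inverse
    is undefined; the concentration is then 0 (zero-concentration side) or
    NaN (saturation side), never infinity.
    """

    concentration: float
    flag: RangeFlag
    censored: bool = False


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted 4PL parameters defining the signal<->concentration map.

    ``lower_asymptote``/``upper_asymptote`` are in signal units and bracket
    every attainable noise-free signal; ``ascending`` records whether signal
    grows with concentration (sandwich format) or falls (competitive).
    """

    lower_asymptote: float
    upper_asymptote: float
    inflection: float
    slope: float
    ascending: bool = True
    working_range: tuple[float, float] = DEFAULT_WORKING_RANGE
    fit_residual: float = 0.0

    def __post_init__(self):
        if not self.upper_asymptote > self.lower_asymptote:
            raise InputError("upper_asymptote must exceed lower_asymptote")
        if not (math.isfinite(self.inflection) and self.inflection > 0):
            raise InputError("inflection must be a positive concentration")
        if not (math.isfinite(self.slope) and self.slope > 0):
            raise InputError("slope must be positive (orientation is carried by `ascending`)")
        lo, hi = self.working_range
        if not (0 < lo < hi):
            raise InputError("working_range must satisfy 0 < lower < upper")
        if self.fit_residual < 0:
            raise InputError("fit_residual must be non-negative")

    @property
    def zero_asymptote(self) -> float:
        """Signal approached as concentration -> 0 (the 4PL ``A``)."""
        return self.lower_asymptote if self.ascending else self.upper_asymptote

    @property
    def plateau_asymptote(self) -> float:
        """Signal approached at saturating concentration (the 4PL ``D``)."""
        return self.upper_asymptote if self.ascending else self.lower_asymptote

    def signal(self, concentration):
        """Forward model: noise-free signal at ``concentration`` (vectorised)."""
        x = np.asarray(concentration, dtype=float)
        if np.any(x < 0):
            raise InputError("concentration must be >= 0")
        a, d = self.zero_asymptote, self.plateau_asymptote
        with np.errstate(divide="ignore"):
            u = np.power(x / self.inflection, self.slope)
        y = d + (a - d) / (1.0 + u)
        return float(y) if np.isscalar(concentration) else y

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "model": "4PL",
            "lower_asymptote": self.lower_asymptote,
            "upper_asymptote": self.upper_asymptote,
            "inflection": self.inflection,
            "slope": self.slope,
            "ascending": self.ascending,
            "working_range": list(self.working_range),
            "fit_residual": self.fit_residual,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CalibrationCurve":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            lower_asymptote=d["lower_asymptote"],
            upper_asymptote=d["upper_asymptote"],
            inflection=d["inflection"],
            slope=d["slope"],
            ascending=d.get("ascending", True),
            working_range=tuple(d.get("working_range", DEFAULT_WORKING_RANGE)),
            fit_residual=d.get("fit_residual", 0.0),
        )


def read_standards(path: str | Path) -> list[StandardPoint]:
    """Read a standard-curve CSV with columns concentration_pg_ml, signal, replicate."""
    df = pd.read_csv(path)
    required = {"concentration_pg_ml", "signal"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"standards file lacks column(s): {sorted(missing)}")
    reps = df["replicate"] if "replicate" in df.columns else pd.Series(1, index=df.index)
    return [
        StandardPoint(float(c), float(s), int(r))
        for c, s, r in zip(df["concentration_pg_ml"], df["signal"], reps)
    ]


def _averaged_levels(standards: Iterable[StandardPoint]) -> tuple[np.ndarray, np.ndarray]:
    """Mean signal per distinct concentration (replicates averaged, uniform weights)."""
    pts = list(standards)
    if not pts:
        raise InputError("no standard points supplied")
    df = pd.DataFrame({"x": [p.concentration for p in pts], "y": [p.signal for p in pts]})
    g = df.groupby("x", sort=True)["y"].mean()
    return g.index.to_numpy(dtype=float), g.to_numpy(dtype=float)


def _forward(x: np.ndarray, a: float, d: float, c: float, b: float) -> np.ndarray:
    with np.errstate(divide="ignore"):
        u = np.power(x / c, b)
    return d + (a - d) / (1.0 + u)


def fit_4pl(
    standards: Iterable[StandardPoint] | pd.DataFrame,
    working_range: tuple[float, float] = DEFAULT_WORKING_RANGE,
    max_restarts: int = 3,
) -> CalibrationCurve:
    """Fit the 4PL standard curve by least squares.

    Replicate standards at the same concentration are averaged before
    fitting.  Initialisation takes the asymptotes from the signals at the
    extreme concentrations, the inflection from the concentration whose
    signal is nearest mid-range, and Hill slope 1; up to ``max_restarts``
    perturbed restarts are attempted before declaring failure.

    Raises
    ------
    InputError
        Fewer than five distinct non-blank concentration levels.
    FitError
        No start converged to a valid curve.
    """
    if isinstance(standards, pd.DataFrame):
        standards = [
            StandardPoint(float(r["concentration_pg_ml"]), float(r["signal"]),
                          int(r.get("replicate", 1)))
            for _, r in standards.iterrows()
        ]
    x, y = _averaged_levels(standards)
    n_levels = int(np.sum(x > 0))
    if n_levels < 5:
        raise InputError(f"4PL fit needs >= 5 distinct non-blank levels, got {n_levels}")

    pos = x > 0
    ascending = y[pos][np.argmax(x[pos])] >= y[pos][np.argmin(x[pos])]
    a0 = y[x == 0].mean() if np.any(x == 0) else (y[pos][np.argmin(x[pos])])
    d0 = y[pos][np.argmax(x[pos])]
    if math.isclose(a0, d0):
        raise FitError("standards span no signal range; curve is degenerate")
    mid = 0.5 * (a0 + d0)
    c0 = float(x[pos][np.argmin(np.abs(y[pos] - mid))])
    if c0 <= 0:
        c0 = float(np.median(x[pos]))

    span = abs(d0 - a0)

    def residuals(theta):
        a, d, logc, logb = theta
        return _forward(x, a, d, math.exp(logc), math.exp(logb)) - y

    # deterministic perturbation schedule for the restarts
    perturbations = [(1.0, 1.0), (0.5, 2.0), (2.0, 0.5), (1.5, 1.5)][: max_restarts + 1]
    best = None
    for fc, fb in perturbations:
        theta0 = np.array([a0, d0, math.log(c0 * fc), math.log(1.0 * fb)])
        try:
            sol = least_squares(residuals, theta0, method="lm", xtol=1e-14, ftol=1e-14,
                                gtol=1e-14, max_nfev=20000)
        except Exception:
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        if best is None or sol.cost < best.cost - 1e-15 * max(1.0, best.cost):
            best = sol
    if best is None:
        raise FitError("4PL fit did not converge from any start")

    a, d, c, b = best.x[0], best.x[1], math.exp(best.x[2]), math.exp(best.x[3])
    if not (np.isfinite([a, d, c, b]).all() and c > 0 and b > 0) or math.isclose(a, d, rel_tol=1e-12, abs_tol=1e-12 * span):
        raise FitError("4PL fit converged to a degenerate curve")
    rms = float(np.sqrt(np.mean(residuals(best.x) ** 2)))
    a, d = float(a), float(d)
    lower, upper = (a, d) if a < d else (d, a)
    return CalibrationCurve(
        lower_asymptote=lower,
        upper_asymptote=upper,
        inflection=c,
        slope=b,
        ascending=bool(a < d),
        working_range=tuple(working_range),
        fit_residual=rms,
    )


def signal_to_concentration(curve: CalibrationCurve, signal: float) -> ConcentrationEstimate:
    """Invert the 4PL: back-calculate the concentration producing ``signal``.

    The closed-form inverse is x = C * ((A - D)/(y - D) - 1)^(1/B), valid for
    signals strictly between the asymptotes.  A signal at or beyond the
    zero-concentration asymptote maps to concentration 0 (censored below);
    at or beyond the saturation asymptote to NaN (censored above).  In-range
    results additionally carry a below/above working-range flag.
    """
    y = float(signal)
    if not math.isfinite(y):
        raise InputError("signal must be finite")
    a, d = curve.zero_asymptote, curve.plateau_asymptote
    low_side = (y <= a) if curve.ascending else (y >= a)
    high_side = (y >= d) if curve.ascending else (y <= d)
    if low_side:
        return ConcentrationEstimate(0.0, RangeFlag.BELOW_RANGE, censored=True)
    if high_side:
        return ConcentrationEstimate(math.nan, RangeFlag.ABOVE_RANGE, censored=True)
    ratio = (a - d) / (y - d) - 1.0
    x = curve.inflection * ratio ** (1.0 / curve.slope)
    lo, hi = curve.working_range
    if x < lo:
        flag = RangeFlag.BELOW_RANGE
    elif x > hi:
        flag = RangeFlag.ABOVE_RANGE
    else:
        flag = RangeFlag.IN_RANGE
    return ConcentrationEstimate(float(x), flag)


def apply_dilution(concentration: float, factor: float) -> float:
    """Scale a back-calculated concentration by its dilution factor (>= 1)."""
    if not (math.isfinite(concentration) and concentration >= 0):
        raise InputError("concentration must be finite and >= 0")
    if not (math.isfinite(factor) and factor >= 1):
        raise InputError(f"dilution factor must be >= 1, got {factor}")
    return concentration * factor
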