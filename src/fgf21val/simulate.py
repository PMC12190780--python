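"""Synthetic plate reads, validation designs and patient cohorts.

Everything the pipeline consumes can be generated here with known ground
truth: 4PL plate signals with multiplicative per-well noise at a
configurable CV, the standard validation designs (20 intra-assay
replicates per level, a 5x5 inter-assay layout with multiplicative run
effects, 16 blanks, a nine-step two-fold dilution series, a 3x3 spike
design, six-point interference panels, stability time courses modelled as
first-order decay with freeze-thaw as a per-cycle step loss, and an
18-subject three-tube comparison with a planted serum proteolysis offset),
plus a patient cohort in which the attenuation coefficient and log-FGF21
share a configurable Spearman correlation through a Gaussian copula while
the clinical marginals stay inside realistic outpatient ranges.

All randomness flows from ``SimulationConfig.seed`` through a fixed
consumption order, so identical configs give byte-identical output files.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import stats

from .calibration import (DEFAULT_WORKING_RANGE, KIT_STANDARDS, CalibrationCurve,
                          signal_to_concentration)
from .errors import InputError


class CurveParams(BaseModel):
    """Generating 4PL parameters (ascending sandwich format by default)."""

    zero_signal: float = 0.05     # asymptote at zero concentration (signal units)
    plateau_signal: float = 2.0   # saturation asymptote
    inflection: float = 400.0     # pg/mL
    hill_slope: float = 1.2

    @model_validator(mode="after")
    def _check(self):
        if self.zero_signal == self.plateau_signal:
            raise ValueError("asymptotes must differ")
        if self.inflection <= 0 or self.hill_slope <= 0:
            raise ValueError("inflection and hill_slope must be positive")
        return self

    def signal(self, concentration):
        x = np.asarray(concentration, dtype=float)
        u = np.power(x / self.inflection, self.hill_slope)
        return self.plateau_signal + (self.zero_signal - self.plateau_signal) / (1.0 + u)

    def to_curve(self, working_range=DEFAULT_WORKING_RANGE) -> CalibrationCurve:
        lo, hi = sorted((self.zero_signal, self.plateau_signal))
        return CalibrationCurve(lower_asymptote=lo, upper_asymptote=hi,
                                inflection=self.inflection, slope=self.hill_slope,
                                ascending=self.zero_signal < self.plateau_signal,
                                working_range=tuple(working_range))


class StabilityDesign(BaseModel):
    """First-order decay rates per storage condition.

    ``freeze_thaw_step`` is the fractional loss per freeze-thaw cycle; the
    other rates are per day.  Defaults give ~10% loss after 7 cycles, ~14%
    after 7 days at 4 C, ~30% after 7 days at room temperature and ~2-3%
    after a month at -20 C — the qualitative shapes of plasma-protein
    stability series.
    """

    freeze_thaw_step: float = 0.015
    fridge_rate_per_day: float = 0.0215
    room_rate_per_day: float = 0.051
    minus20_rate_per_day: float = 0.0008
    freeze_thaw_cycles: tuple[int, ...] = (1, 2, 3, 5, 7)
    time_points_days: tuple[float, ...] = (1 / 24, 2 / 24, 4 / 24, 1.0, 3.0, 7.0)
    minus20_days: tuple[float, ...] = (30.0,)


class CohortConfig(BaseModel):
    """Generating parameters for the synthetic patient cohort."""

    n: int = Field(97, ge=10)
    rank_correlation: float = 0.44   # target Spearman between attenuation and FGF21
    fgf21_log_median: float = math.log(290.0)
    fgf21_log_sd: float = 0.55
    attenuation_range: tuple[float, float] = (0.32, 0.97)
    male_fraction: float = 0.48

    @model_validator(mode="after")
    def _check(self):
        if not -1 < self.rank_correlation < 1:
            raise ValueError("rank correlation target must lie strictly inside (-1, 1)")
        lo, hi = self.attenuation_range
        if not 0 < lo < hi < 2:
            raise ValueError("attenuation range must satisfy 0 < lo < hi < 2")
        if self.fgf21_log_sd < 0:
            raise ValueError("fgf21_log_sd must be >= 0")
        return self


class SimulationConfig(BaseModel):
    """Full study design: plate noise, replicate layouts and cohort targets."""

    seed: int = 0
    curve: CurveParams = CurveParams()
    working_range: tuple[float, float] = DEFAULT_WORKING_RANGE
    noise_cv: float = Field(5.0, ge=0)          # per-well multiplicative CV (%)
    run_effect_cv: float = Field(5.0, ge=0)     # between-run multiplicative CV (%)
    n_intra: int = Field(20, ge=2)
    n_runs: int = Field(5, ge=2)
    n_per_run: int = Field(5, ge=1)
    n_blanks: int = Field(16, ge=2)
    level_concentrations: dict[str, float] = {"low": 159.0, "medium": 579.0, "high": 1177.0}
    lloq_level: float = 2.9                     # pg/mL, low-concentration precision set
    n_lloq: int = Field(20, ge=2)
    dilution_factors: tuple[int, ...] = (2, 4, 8, 16, 32, 64, 128, 256, 512)
    dilution_top: float = 3000.0                # neat concentration before dilution
    dilution_collapse_below: float = 15.0       # pg/mL; linearity fails near the LLOQ region
    below_range_recovery: float = 0.5           # fractional recovery past the collapse point
    spike_neat: tuple[float, ...] = (164.0, 220.0, 392.0)
    spike_levels: tuple[float, ...] = (0.0, 100.0, 200.0)
    interferents: tuple[str, ...] = ("bilirubin_conjugated", "bilirubin_free",
                                     "hemoglobin", "intralipid", "rheumatoid_factor")
    interference_baseline: float = 300.0
    interference_points: int = 6
    interference_planted: Optional[tuple[str, float]] = None  # (interferent, fractional bias)
    stability: StabilityDesign = StabilityDesign()
    tube_n: int = Field(18, ge=5)
    tube_edta_bias: float = 0.0
    tube_serum_bias: float = -0.12              # fractional loss from clotting proteolysis
    cohort: CohortConfig = CohortConfig()


def _noise(rng: np.random.Generator, cv_percent: float, size) -> np.ndarray:
    """Multiplicative noise factors 1 + eps, eps ~ N(0, cv/100)."""
    return 1.0 + rng.normal(0.0, cv_percent / 100.0, size=size)


def simulate_plate(config: SimulationConfig, true_concentrations: Sequence[float],
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Noisy plate signals for known concentrations.

    signal = 4PL(conc) * (1 + eps) with eps mean-zero and SD = noise_cv/100.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    x = np.asarray(true_concentrations, dtype=float)
    if np.any(x < 0):
        raise InputError("concentrations must be >= 0")
    signal = config.curve.signal(x) * _noise(rng, config.noise_cv, x.shape)
    return pd.DataFrame({"concentration": x, "signal": signal})


def concentration_cv_factor(config: SimulationConfig, concentration: float) -> float:
    """Delta-method factor relating signal CV to back-calculated concentration CV.

    CV_conc ~= factor * CV_signal, with factor = y / (x * dy/dx) evaluated on
    the noise-free curve.
    """
    c = config.curve
    x = float(concentration)
    y = float(c.signal(x))
    h = x * 1e-6
    dydx = (float(c.signal(x + h)) - float(c.signal(x - h))) / (2 * h)
    return abs(y / (x * dydx))


def simulate_standards(config: SimulationConfig, rng: np.random.Generator,
                       replicates: int = 2) -> pd.DataFrame:
    rows = []
    for rep in range(1, replicates + 1):
        df = simulate_plate(config, KIT_STANDARDS, rng)
        df = df.rename(columns={"concentration": "concentration_pg_ml"})
        df["replicate"] = rep
        rows.append(df)
    return pd.concat(rows, ignore_index=True)[["concentration_pg_ml", "signal", "replicate"]]


def true_lloq(config: SimulationConfig, k: float = 10.0) -> float:
    """LLOQ implied by the generating model: invert blank mean + k*SD noise-free.

    Blank signals are A*(1+eps), so mean = A and SD = A*noise_cv/100.
    """
    a = config.curve.zero_signal
    threshold = a + k * a * config.noise_cv / 100.0
    curve = config.curve.to_curve(config.working_range)
    return signal_to_concentration(curve, threshold).concentration


def simulate_validation_suite(config: SimulationConfig,
                              out_dir: str | Path | None = None) -> dict:
    """Generate every analytical-validation input file with ground truth.

    Returns a dict of DataFrames keyed by file stem (standards, replicates,
    dilution, spike, interference, stability, tubes) plus ``truth`` — the
    generating parameters each downstream estimate should recover.  With
    ``out_dir`` set, writes the CSVs and ``truth.json``.
    """
    rng = np.random.default_rng(config.seed)
    levels = config.level_concentrations

    standards = simulate_standards(config, rng)

    # replicates.csv: blanks (signal units), intra sets, 5x5 inter sets, LLOQ set
    rep_rows = []
    blank_signals = config.curve.zero_signal * _noise(rng, config.noise_cv, config.n_blanks)
    for v in blank_signals:
        rep_rows.append(("blank", "blank", "run1", float(v)))
    for level, conc in levels.items():
        vals = conc * _noise(rng, config.noise_cv, config.n_intra)
        for v in vals:
            rep_rows.append((f"intra_{level}", level, "run1", float(v)))
    for level, conc in levels.items():
        run_effects = _noise(rng, config.run_effect_cv, config.n_runs)
        for i, eff in enumerate(run_effects, start=1):
            vals = conc * eff * _noise(rng, config.noise_cv, config.n_per_run)
            for v in vals:
                rep_rows.append((f"inter_{level}", level, f"run{i}", float(v)))
    lloq_vals = config.lloq_level * _noise(rng, config.noise_cv, config.n_lloq)
    for v in lloq_vals:
        rep_rows.append(("lloq", "lloq", "run1", float(v)))
    replicates = pd.DataFrame(rep_rows, columns=["sample_id", "level", "run_id", "value"])

    # dilution.csv: duplicates per factor; linearity collapses below the working range
    dil_rows = []
    lo = config.dilution_collapse_below
    true_recovery = {}
    for f in config.dilution_factors:
        expected = config.dilution_top / f
        r_true = 1.0 if expected >= lo else config.below_range_recovery
        cv = config.noise_cv * (4.0 if expected < lo else 1.0)
        dups = expected * r_true * _noise(rng, cv, 2)
        dups = np.clip(dups, 0.0, None)
        mean = float(np.mean(dups))
        sd = float(np.std(dups, ddof=1))
        dil_rows.append({"factor": f, "expected": expected, "observed": mean,
                         "cv": 100.0 * sd / mean if mean > 0 else math.nan})
        true_recovery[f] = r_true
    dilution = pd.DataFrame(dil_rows)

    # spike.csv: 3 samples x 3 spike levels, duplicates per aliquot
    spike_rows = []
    for i, neat in enumerate(config.spike_neat, start=1):
        for spike in config.spike_levels:
            dups = (neat + spike) * _noise(rng, config.noise_cv, 2)
            mean = float(np.mean(dups))
            sd = float(np.std(dups, ddof=1))
            spike_rows.append({"sample_id": f"sample{i}", "spike_pg": spike,
                               "measured": mean,
                               "cv": 100.0 * sd / mean if mean > 0 else math.nan})
    spike = pd.DataFrame(spike_rows)

    # interference.csv: six-point panels per interferent
    int_rows = []
    planted = dict([config.interference_planted]) if config.interference_planted else {}
    for interferent in config.interferents:
        bias = planted.get(interferent, 0.0)
        for level in range(1, config.interference_points + 1):
            # planted bias scales with the interferent level (level 6 = highest)
            frac = bias * level / config.interference_points
            obs = config.interference_baseline * (1 + frac) * float(_noise(rng, config.noise_cv / 2, ()))
            int_rows.append({"interferent": interferent, "level": level,
                             "baseline": config.interference_baseline, "observed": obs})
    interference = pd.DataFrame(int_rows)

    # stability.csv: decay per condition x level
    st = config.stability
    stab_rows = []
    for level, conc in levels.items():
        for cyc in st.freeze_thaw_cycles:
            retain = (1 - st.freeze_thaw_step) ** cyc
            meas = conc * retain * float(_noise(rng, config.noise_cv, ()))
            stab_rows.append({"condition": "freeze_thaw", "exposure": cyc, "level": level,
                              "reference": conc, "measured": meas})
        for cond, rate in (("fridge_4C", st.fridge_rate_per_day),
                           ("room_temp", st.room_rate_per_day)):
            for t in st.time_points_days:
                meas = conc * math.exp(-rate * t) * float(_noise(rng, config.noise_cv, ()))
                stab_rows.append({"condition": cond, "exposure": t, "level": level,
                                  "reference": conc, "measured": meas})
        for t in st.minus20_days:
            meas = conc * math.exp(-st.minus20_rate_per_day * t) * float(_noise(rng, config.noise_cv, ()))
            stab_rows.append({"condition": "minus20C", "exposure": t, "level": level,
                              "reference": conc, "measured": meas})
    stability = pd.DataFrame(stab_rows)

    # tubes.csv: paired heparin/EDTA/serum with planted matrix offsets
    fgf_true = np.exp(rng.normal(math.log(300.0), 0.6, config.tube_n))
    heparin = fgf_true * _noise(rng, config.noise_cv / 2, config.tube_n)
    edta = fgf_true * (1 + config.tube_edta_bias) * _noise(rng, config.noise_cv / 2, config.tube_n)
    serum = fgf_true * (1 + config.tube_serum_bias) * _noise(rng, config.noise_cv / 2, config.tube_n)
    tubes = pd.DataFrame({"subject_id": [f"s{i + 1}" for i in range(config.tube_n)],
                          "heparin": heparin, "edta": edta, "serum": serum})

    truth = {
        "seed": config.seed,
        "noise_cv": config.noise_cv,
        "run_effect_cv": config.run_effect_cv,
        "expected_inter_cv": math.hypot(config.noise_cv, config.run_effect_cv),
        "level_concentrations": dict(levels),
        "lloq_level": config.lloq_level,
        "true_lloq": true_lloq(config),
        "dilution_true_recovery": {str(k): v for k, v in true_recovery.items()},
        "spike_true_recovery_percent": 100.0,
        "interference_planted": list(config.interference_planted) if config.interference_planted else None,
        "stability_rates": st.model_dump(),
        "tube_edta_bias": config.tube_edta_bias,
        "tube_serum_bias": config.tube_serum_bias,
        "curve": config.curve.model_dump(),
    }
    out = {"standards": standards, "replicates": replicates, "dilution": dilution,
           "spike": spike, "interference": interference, "stability": stability,
           "tubes": tubes, "truth": truth}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name in ("standards", "replicates", "dilution", "spike",
                     "interference", "stability", "tubes"):
            out[name].to_csv(out_dir / f"{name}.csv", index=False)
        (out_dir / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    return out


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _truncated_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _truncated_lognormal(rng, log_median, log_sd, lo, hi, size):
    a = (math.log(lo) - log_median) / log_sd
    b = (math.log(hi) - log_median) / log_sd
    z = stats.truncnorm.rvs(a, b, size=size, random_state=rng)
    return np.exp(log_median + log_sd * z)


def simulate_cohort(config: SimulationConfig | CohortConfig,
                    seed: int | None = None,
                    out_path: str | Path | None = None) -> tuple[pd.DataFrame, dict]:
    """Synthetic outpatient cohort with a planted attenuation-FGF21 association.

    A latent bivariate normal with Pearson correlation 2*sin(pi*rho_s/6)
    (the Gaussian-copula inverse of the Spearman target) drives the
    attenuation coefficient (uniform over its clinical range via the normal
    CDF) and log-normal FGF21; because both marginal maps are monotone, the
    Spearman correlation of the pair equals the target by construction.
    Chemistry, imaging and demographic fields are drawn inside realistic
    outpatient ranges so that the vast majority of records pass eligibility.
    """
    if isinstance(config, SimulationConfig):
        cc = config.cohort
        seed = config.seed if seed is None else seed
    else:
        cc = config
        seed = 0 if seed is None else seed
    rng = np.random.default_rng(seed)
    n = cc.n

    rho_s = cc.rank_correlation
    r_z = 2.0 * math.sin(math.pi * rho_s / 6.0)
    cov = np.array([[1.0, r_z], [r_z, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n, method="cholesky")
    lo, hi = cc.attenuation_range
    att = lo + (hi - lo) * stats.norm.cdf(z[:, 0])
    fgf21 = np.exp(cc.fgf21_log_median + cc.fgf21_log_sd * z[:, 1])

    df = pd.DataFrame({
        "patient_id": [f"p{i + 1:03d}" for i in range(n)],
        "age": rng.integers(27, 70, size=n),
        "sex": np.where(rng.random(n) < cc.male_fraction, "male", "female"),
        "bmi": _truncated_normal(rng, 22.5, 3.0, 15.4, 29.3, n),
        "ast": _truncated_lognormal(rng, math.log(20.0), 0.25, 13.0, 67.0, n),
        "alt": _truncated_lognormal(rng, math.log(21.0), 0.40, 7.0, 134.0, n),
        "ggt": _truncated_lognormal(rng, math.log(21.0), 0.60, 6.0, 414.0, n),
        "total_bilirubin": _truncated_normal(rng, 0.8, 0.3, 0.3, 2.8, n),
        "albumin": _truncated_normal(rng, 4.3, 0.3, 3.6, 5.1, n),
        "platelet_count": _truncated_normal(rng, 233.0, 50.0, 139.0, 466.0, n),
        "weekly_alcohol_g": rng.exponential(40.0, size=n),
        "shear_wave_speed": _truncated_normal(rng, 1.24, 0.12, 0.94, 1.58, n),
        "attenuation_coefficient": att,
        "fgf21": fgf21,
    })
    truth = {
        "seed": seed,
        "n": n,
        "target_rank_correlation": rho_s,
        "latent_pearson": r_z,
        "fgf21_log_median": cc.fgf21_log_median,
        "fgf21_log_sd": cc.fgf21_log_sd,
        "steatotic_066": (att >= 0.66).astype(int).tolist(),
        "n_steatotic_066": int((att >= 0.66).sum()),
    }
    if out_path is not None:
        out_path = Path(out_path)
        out_path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_path, index=False)
        out_path.with_suffix(".truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    return df, truth
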