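"""Precision, LLOQ, recovery, TCL, interference, stability and tube statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fgf21val.calibration import CalibrationCurve, signal_to_concentration
from fgf21val.errors import InputError, UndefinedStatisticError
from fgf21val.validation import (
    DilutionLinearityResult,
    ReplicateSet,
    dilution_linearity,
    inter_assay_summary,
    interference_bias,
    lloq_from_blanks,
    precision_summary,
    round_half_up,
    spike_recovery,
    spike_recovery_table,
    stability_series,
    total_change_limit,
    tube_comparison,
)


def two_values_with(mean, sd):
    """The unique symmetric pair with given sample mean and SD (n-1)."""
    h = sd / math.sqrt(2)
    return [mean - h, mean + h]


class TestPrecision:
    # printed assay-report summaries: (mean, SD, reported CV)
    REPORT_CELLS = [
        (579.0, 18.6, 3.2),    # intra medium
        (1177.0, 61.7, 5.2),   # intra high
        (207.0, 17.8, 8.6),    # inter low
        (607.0, 31.1, 5.1),    # inter medium
        (1020.0, 81.9, 8.0),   # inter high
    ]

    @pytest.mark.parametrize("mean,sd,cv", REPORT_CELLS)
    def test_reconstructs_reported_cvs(self, mean, sd, cv):
        res = precision_summary(two_values_with(mean, sd))
        assert round_half_up(res.cv_percent) == cv
        assert res.passes

    def test_intra_low_cell_is_a_rounding_artifact(self):
        # mean 159, SD 8.5 gives 5.346 -> 5.3, one tenth off the reported 5.4:
        # the summary was rounded before the CV was printed
        res = precision_summary(two_values_with(159.0, 8.5))
        assert round_half_up(res.cv_percent) == 5.3

    def test_two_point_hand_computation(self):
        res = precision_summary([10.0, 20.0])
        assert res.mean == pytest.approx(15.0)
        assert res.sd == pytest.approx(math.sqrt(50.0))
        assert res.cv_percent == pytest.approx(47.1405, abs=1e-3)
        assert not res.passes

    def test_constant_replicates(self):
        res = precision_summary([100.0, 100.0, 100.0])
        assert res.cv_percent == 0.0 and res.passes

    def test_errors(self):
        with pytest.raises(InputError):
            precision_summary([5.0])
        with pytest.raises(UndefinedStatisticError):
            precision_summary([0.0, 0.0])

    @settings(max_examples=50)
    @given(values=st.lists(st.floats(1.0, 1e4), min_size=2, max_size=20),
           scale=st.floats(0.01, 100.0))
    def test_cv_is_scale_invariant(self, values, scale):
        base = precision_summary(values)
        scaled = precision_summary([scale * v for v in values])
        assert scaled.cv_percent == pytest.approx(base.cv_percent, rel=1e-9, abs=1e-9)

    def test_accepts_replicate_set(self):
        rs = ReplicateSet("intra_low", "low", "run1", (150.0, 160.0, 168.0))
        assert precision_summary(rs).n == 3


class TestInterAssay:
    def test_pooled_two_by_two(self):
        sets = [ReplicateSet("s", "low", "run1", (1.0, 3.0)),
                ReplicateSet("s", "low", "run2", (2.0, 4.0))]
        res = inter_assay_summary(sets)
        assert res.mean == pytest.approx(2.5)
        assert res.sd == pytest.approx(1.290994, abs=1e-5)
        assert res.cv_percent == pytest.approx(51.6398, abs=1e-3)

    def test_identical_values_zero_cv(self):
        sets = [ReplicateSet("s", "low", f"run{i}", (7.0, 7.0)) for i in range(1, 6)]
        assert inter_assay_summary(sets).cv_percent == 0.0

    def test_single_run_rejected(self):
        with pytest.raises(InputError):
            inter_assay_summary([ReplicateSet("s", "low", "run1", (1.0, 2.0))])


class TestLLOQ:
    curve = CalibrationCurve(lower_asymptote=0.05, upper_asymptote=2.0,
                             inflection=400.0, slope=1.2)

    def test_zero_sd_collapse(self):
        s0 = 0.2
        lloq = lloq_from_blanks([s0, s0, s0], self.curve, k=10)
        assert lloq == pytest.approx(signal_to_concentration(self.curve, s0).concentration)

    def test_matches_independent_two_line_oracle(self):
        rng = np.random.default_rng(5)
        blanks = 0.06 + rng.normal(0, 0.004, 16)
        lloq = lloq_from_blanks(blanks, self.curve, k=10)
        # oracle: mean + 10*SD then the closed-form inverse, written inline
        thr = blanks.mean() + 10 * blanks.std(ddof=1)
        a, d, c, b = 0.05, 2.0, 400.0, 1.2
        expected = c * ((a - d) / (thr - d) - 1) ** (1 / b)
        assert lloq == pytest.approx(expected, rel=1e-12)

    def test_zero_multiplier_degenerates_to_blank_inversion(self):
        lloq = lloq_from_blanks([0.3, 0.3], self.curve, k=0)
        assert lloq == pytest.approx(
            signal_to_concentration(self.curve, 0.3).concentration)

    def test_threshold_beyond_saturation_errors(self):
        with pytest.raises(InputError):
            lloq_from_blanks([1.9, 2.1], self.curve, k=10)


# printed dilution-series report: factor, expected, observed, recovery, CV
DILUTION_TABLE = [
    (2, 1500.0, 1508.6, 100.6, 0.9),
    (4, 750.0, 793.75, 105.8, 0.3),
    (8, 375.0, 388.05, 103.5, 2.2),
    (16, 187.5, 182.4, 97.3, 1.5),
    (32, 93.8, 94.7, 101.0, 1.2),
    (64, 46.9, 51.95, 110.8, 0.1),
    (128, 23.4, 23.65, 101.1, 5.7),
    (256, 11.7, 5.9, 50.4, 28.8),
    (512, 5.9, 2.7, 45.8, 55.6),
]


class TestDilutionLinearity:
    def test_reproduces_printed_recoveries_and_linear_range(self):
        series = [{"factor": f, "expected": e, "observed": o, "cv": cv}
                  for f, e, o, _, cv in DILUTION_TABLE]
        res = dilution_linearity(series, deviation_limit=14.0)
        got = [round_half_up(r.recovery_percent) for r in res.results]
        assert got == [row[3] for row in DILUTION_TABLE]
        assert res.max_linear_factor == 128

    def test_perfect_series_fully_linear(self):
        series = [{"factor": f, "expected": e, "observed": e} for f, e, *_ in DILUTION_TABLE]
        res = dilution_linearity(series, deviation_limit=14.0)
        assert all(r.recovery_percent == 100.0 for r in res.results)
        assert res.linear_factors == tuple(r[0] for r in DILUTION_TABLE)

    def test_linear_range_is_a_prefix(self):
        # a mid-series failure truncates the range even if later factors recover
        series = [{"factor": 2, "expected": 100, "observed": 100},
                  {"factor": 4, "expected": 50, "observed": 25},
                  {"factor": 8, "expected": 25, "observed": 25}]
        res = dilution_linearity(series, deviation_limit=14.0)
        assert res.linear_factors == (2,)

    def test_errors(self):
        with pytest.raises(InputError):
            dilution_linearity([{"factor": 4, "expected": 10, "observed": 9},
                                {"factor": 2, "expected": 20, "observed": 19}],
                               deviation_limit=14.0)
        with pytest.raises(InputError):
            dilution_linearity([{"factor": 2, "expected": 0.0, "observed": 1.0}],
                               deviation_limit=14.0)
        with pytest.raises(InputError):
            dilution_linearity([{"factor": 2, "expected": 10, "observed": 10}])


# printed spike-recovery report: neat, spike, measured, reported total recovery
SPIKE_TABLE = [
    (164.0, 100.0, 261.0, 98.9),
    (164.0, 200.0, 360.0, 98.9),
    (220.0, 100.0, 319.0, 99.7),
    (220.0, 200.0, 413.0, 98.3),
    (392.0, 100.0, 483.0, 98.2),
    (392.0, 200.0, 568.0, 95.9),
]


class TestSpikeRecovery:
    @pytest.mark.parametrize("neat,spike,measured,reported", SPIKE_TABLE)
    def test_total_mode_reproduces_report(self, neat, spike, measured, reported):
        res = spike_recovery(neat, measured, spike, mode="total")
        assert res.theoretical == pytest.approx(neat + spike)
        assert round_half_up(res.recovery_percent) == reported

    def test_perfect_recovery_fixed_point(self):
        for mode in ("total", "marginal"):
            res = spike_recovery(150.0, 250.0, 100.0, mode=mode)
            assert res.recovery_percent == pytest.approx(100.0)

    def test_modes_coincide_at_zero_neat(self):
        t = spike_recovery(0.0, 91.0, 100.0, mode="total")
        m = spike_recovery(0.0, 91.0, 100.0, mode="marginal")
        assert t.recovery_percent == pytest.approx(m.recovery_percent)

    def test_marginal_mode_formula(self):
        res = spike_recovery(164.0, 261.0, 100.0, mode="marginal")
        assert res.recovery_percent == pytest.approx(97.0)

    def test_errors(self):
        with pytest.raises(InputError):
            spike_recovery(100.0, 150.0, 0.0)
        with pytest.raises(InputError):
            spike_recovery(-1.0, 150.0, 100.0)
        with pytest.raises(InputError):
            spike_recovery(100.0, 150.0, 50.0, mode="other")

    def test_table_reports_both_modes(self):
        df = pd.DataFrame([
            {"sample_id": "s1", "spike_pg": 0.0, "measured": 164.0},
            {"sample_id": "s1", "spike_pg": 100.0, "measured": 261.0},
        ])
        tab = spike_recovery_table(df)
        assert round_half_up(tab["recovery_total_percent"].iloc[0]) == 98.9
        assert round_half_up(tab["recovery_marginal_percent"].iloc[0]) == 97.0


class TestTotalChangeLimit:
    def test_examples(self):
        assert total_change_limit(0.0, 0.0).tcl == 0.0
        assert total_change_limit(3.0, 0.0).tcl == pytest.approx(2.77 * 3.0)
        assert total_change_limit(5.0, 4.0).tcl == pytest.approx(
            math.sqrt(13.85 ** 2 + 2.0 ** 2))
        assert total_change_limit(5.0, 4.0).tcl == pytest.approx(13.9936, abs=1e-3)

    @given(a=st.floats(0, 50), b=st.floats(0, 50),
           da=st.floats(0, 10), db=st.floats(0, 10))
    def test_monotone_and_bounded_below(self, a, b, da, db):
        t = total_change_limit(a, b).tcl
        assert total_change_limit(a + da, b).tcl >= t
        assert total_change_limit(a, b + db).tcl >= t
        assert t >= max(2.77 * a, 0.5 * b) - 1e-12

    def test_negative_input_rejected(self):
        with pytest.raises(InputError):
            total_change_limit(-1.0, 0.0)


class TestInterference:
    criterion = total_change_limit(14.0 / 2.77, 0.0)  # TCL exactly 14%

    def test_no_bias_no_exceedance(self):
        panel = [{"interferent": "hemoglobin", "level": i, "observed": 200.0}
                 for i in range(1, 7)]
        pts = interference_bias(200.0, panel, self.criterion)
        assert all(p.relative_bias_percent == 0.0 and not p.exceeds_tcl for p in pts)

    @pytest.mark.parametrize("observed,bias,exceeds", [
        (230.0, 15.0, True),
        (214.0, 7.0, False),
    ])
    def test_bias_arithmetic(self, observed, bias, exceeds):
        pts = interference_bias(200.0, [{"interferent": "rf", "level": 6,
                                         "observed": observed}], self.criterion)
        assert pts[0].relative_bias_percent == pytest.approx(bias)
        assert pts[0].exceeds_tcl is exceeds

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(InputError):
            interference_bias(0.0, [{"interferent": "rf", "level": 1, "observed": 1.0}],
                              self.criterion)


class TestStability:
    criterion = total_change_limit(5.0, 2.0)

    def test_unchanged_sample(self):
        pts = stability_series([{"condition": "minus20C", "exposure": 30, "level": "low",
                                 "reference": 500.0, "measured": 500.0}], self.criterion)
        assert pts[0].percent_change == 0.0 and not pts[0].exceeds_tcl

    def test_ten_percent_loss(self):
        pts = stability_series([{"condition": "room_temp", "exposure": 7, "level": "high",
                                 "reference": 500.0, "measured": 450.0}], self.criterion)
        assert pts[0].percent_change == pytest.approx(-10.0)

    def test_first_order_decay_is_monotone(self):
        times = [1 / 24, 2 / 24, 4 / 24, 1, 3, 7]
        rows = [{"condition": "room_temp", "exposure": t, "level": "medium",
                 "reference": 400.0, "measured": 400.0 * math.exp(-0.05 * t)}
                for t in times]
        pts = stability_series(rows, self.criterion)
        changes = [p.percent_change for p in pts]
        assert all(b <= a + 1e-12 for a, b in zip(changes, changes[1:]))

    def test_missing_reference_rejected(self):
        with pytest.raises(InputError):
            stability_series([{"condition": "room_temp", "exposure": 1, "level": "low",
                               "reference": float("nan"), "measured": 10.0}],
                             self.criterion)


class TestTubeComparison:
    def test_identity_pair(self):
        x = np.array([100.0, 200.0, 300.0, 400.0, 500.0])
        res = tube_comparison(x, x)
        assert res.rank_correlation == pytest.approx(1.0)
        assert res.slope == pytest.approx(1.0) and res.intercept == pytest.approx(0.0)
        assert res.signed_rank_p == 1.0

    def test_constant_shift(self):
        x = np.arange(1.0, 9.0)
        res = tube_comparison(x, x + 25.0)
        assert res.slope == pytest.approx(1.0)
        assert res.intercept == pytest.approx(25.0)
        # all 8 differences share one sign: the smallest achievable exact
        # two-sided p at n = 8 is 2/2^8
        assert res.signed_rank_p == pytest.approx(2 / 256)

    def test_signed_rank_matches_sign_flip_enumeration(self):
        x = np.array([310.0, 150.0, 880.0, 95.0, 410.0, 230.0, 560.0])
        y = np.array([295.0, 161.0, 850.0, 99.0, 380.0, 245.0, 530.0])
        res = tube_comparison(x, y)
        d = x - y
        ranks = pd.Series(np.abs(d)).rank().to_numpy()
        w_obs = ranks[d > 0].sum()
        dist = [sum(r for r, s in zip(ranks, signs) if s)
                for signs in itertools.product([False, True], repeat=len(d))]
        dist = np.array(dist)
        p_exact = min(1.0, 2 * min((dist <= w_obs).mean(), (dist >= w_obs).mean()))
        assert res.signed_rank_p == pytest.approx(p_exact)

    def test_too_few_or_constant_pairs(self):
        with pytest.raises(InputError):
            tube_comparison([1, 2, 3], [1, 2, 3])
        with pytest.raises(UndefinedStatisticError):
            tube_comparison([5.0] * 6, [1, 2, 3, 4, 5, 6])
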