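"""Unit and property tests for the isotope flux-index estimator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hetfix.isotope_flux import (
    DEFAULT_ALPHA,
    FLAG_BELOW_BASAL,
    FLAG_OK,
    FLAG_SATURATED,
    IsotopologueMeasurement,
    compare_mfi_groups,
    estimate_basal_ratio,
    forward_pool_ratio,
    mfi_point,
    mfi_series,
)
from hetfix.synthetic_data import LabelingSimConfig, simulate_labeling


def meas(x, y, sample_id="s1", strain="A", t=0.0):
    return IsotopologueMeasurement(sample_id, strain, t, x, y)


class TestBasalRatio:
    @pytest.mark.parametrize(
        "ratios, alpha, sd",
        [
            ([0.0345, 0.0345, 0.0345], 0.0345, 0.0),
            ([0.0], 0.0, 0.0),
            ([0.03, 0.04], 0.035, float(np.std([0.03, 0.04], ddof=1))),
        ],
    )
    def test_mean_and_dispersion(self, ratios, alpha, sd):
        controls = [meas(100.0, 100.0 * r, sample_id=f"c{i}") for i, r in enumerate(ratios)]
        basal = estimate_basal_ratio(controls)
        assert basal.alpha == pytest.approx(alpha, abs=1e-12)
        assert basal.dispersion == pytest.approx(sd, abs=1e-12)
        assert basal.n_samples == len(ratios)

    def test_empty_controls_rejected(self):
        with pytest.raises(ValueError, match="no control samples"):
            estimate_basal_ratio([])

    def test_nonpositive_unlabeled_pool_names_sample(self):
        with pytest.raises(ValueError, match="bad_sample"):
            meas(0.0, 1.0, sample_id="bad_sample")


class TestForwardPoolRatio:
    def test_no_bypass_no_natural_abundance(self):
        assert forward_pool_ratio(1.0, 0.0, 0.0) == 0.0

    def test_reference_fluxes(self):
        # (0.13 + 0.0345*1.13) / (0.9655*1.13)
        assert forward_pool_ratio(1.0, 0.13, 0.0345) == pytest.approx(0.15490, abs=5e-5)

    def test_saturation_limit_as_central_flux_vanishes(self):
        alpha = 0.0345
        limit = (1 + alpha) / (1 - alpha)
        assert forward_pool_ratio(1e-9, 1.0, alpha) == pytest.approx(limit, rel=1e-6)

    def test_requires_positive_central_flux(self):
        with pytest.raises(ValueError):
            forward_pool_ratio(0.0, 1.0, 0.0)


class TestMfiPoint:
    def test_labeled_pool_at_basal_level_gives_zero(self):
        alpha = 0.0345
        y = alpha / (1 - alpha)
        res = mfi_point(1.0, y, alpha)
        assert res.mfi == pytest.approx(0.0, abs=1e-12)
        assert res.flag == FLAG_OK

    def test_inverts_forward_model_output(self):
        # x, y are the forward-model pools (5-decimal rounded) for b/a = 0.13
        res = mfi_point(1.09102, 0.16899, 0.0345)
        assert res.mfi == pytest.approx(0.130, abs=5e-4)
        assert res.valid and res.flag == FLAG_OK

    def test_no_label_no_basal_coupling(self):
        assert mfi_point(1.0, 0.0, 0.0).mfi == 0.0

    def test_rounded_coefficient_mode_biases_upward(self):
        # the fixed printed coefficients (0.97/0.03/1.03) overstate the index
        res = mfi_point(1.09102, 0.16899, mode="paper_rounded")
        assert res.mfi == pytest.approx(0.137, abs=5e-4)
        assert res.mfi > mfi_point(1.09102, 0.16899, 0.0345).mfi

    def test_below_basal_label_is_negative_not_clamped(self):
        res = mfi_point(1.0, 0.0, 0.0345)
        assert res.mfi < 0
        assert res.flag == FLAG_BELOW_BASAL
        assert res.valid

    def test_saturated_sample_flagged_invalid(self):
        alpha = 0.0345
        y = (1 + alpha) / (1 - alpha) + 0.01
        res = mfi_point(1.0, y, alpha)
        assert not res.valid
        assert res.flag == FLAG_SATURATED
        assert math.isinf(res.mfi)

    def test_rejects_nonpositive_x(self):
        with pytest.raises(ValueError):
            mfi_point(0.0, 0.1)

    @pytest.mark.parametrize("a", [0.5, 1.0, 2.0])
    @pytest.mark.parametrize("b_over_a", [0.0, 0.05, 0.13, 0.3, 0.5])
    @pytest.mark.parametrize("alpha", [0.0, 0.0345, 0.08])
    def test_round_trip_identity(self, a, b_over_a, alpha):
        """Estimator inverts the forward labeling model exactly."""
        ratio = forward_pool_ratio(a, a * b_over_a, alpha)
        res = mfi_point(1.0, ratio, alpha)
        assert res.mfi == pytest.approx(b_over_a, abs=1e-9)

    @given(
        x=st.floats(0.01, 1e3),
        r=st.floats(0.0, 0.95),
        k=st.floats(1e-3, 1e3),
        alpha=st.floats(0.0, 0.45),
    )
    @settings(max_examples=200, derandomize=True)
    def test_scale_invariance(self, x, r, k, alpha):
        # y/x spans [0, 95 %] of the saturation ratio; at the boundary the
        # denominator vanishes and floating-point comparison is meaningless
        y = r * (1 + alpha) / (1 - alpha) * x
        base = mfi_point(x, y, alpha)
        scaled = mfi_point(k * x, k * y, alpha)
        # the ok/below_basal boundary itself is not float-stable under
        # rescaling, but validity and the value are
        assert scaled.valid == base.valid
        assert scaled.mfi == pytest.approx(base.mfi, rel=1e-6, abs=1e-9)

    @given(alpha=st.floats(0.0, 0.45), r=st.floats(0.0, 0.9))
    @settings(max_examples=200, derandomize=True)
    def test_zero_crossing_and_monotonicity(self, alpha, r):
        """MFI crosses zero exactly at y/x = alpha/(1-alpha) and increases in y."""
        basal_ratio = alpha / (1 - alpha)
        assert mfi_point(1.0, basal_ratio, alpha).mfi == pytest.approx(0.0, abs=1e-12)
        sat = (1 + alpha) / (1 - alpha)
        y1 = r * sat * 0.999
        y2 = min(y1 + 1e-4, sat * 0.9995)
        m1, m2 = mfi_point(1.0, y1, alpha), mfi_point(1.0, y2, alpha)
        if y2 > y1:
            assert m2.mfi > m1.mfi

    def test_saturation_boundary(self):
        alpha = 0.0345
        sat = (1 + alpha) / (1 - alpha)
        assert not mfi_point(1.0, sat, alpha).valid
        assert mfi_point(1.0, sat * (1 - 1e-9), alpha).valid


class TestMfiSeries:
    def test_identical_samples_have_zero_spread(self):
        alpha = 0.0345
        y = forward_pool_ratio(1.0, 0.13, alpha)
        ms = [meas(1.0, y, sample_id=f"s{i}", t=6.0) for i in range(3)]
        table = mfi_series(ms, alpha)
        assert len(table) == 1
        row = table.iloc[0]
        assert row.mfi_mean == pytest.approx(0.13, abs=1e-9)
        assert row.mfi_sd == 0.0
        assert row.n == 3

    def test_time_course_shape(self):
        """One sample per timepoint reproduces the rise-then-plateau course."""
        alpha = 0.0345
        ms = [
            meas(1.0, forward_pool_ratio(1.0, b, alpha), sample_id=f"t{t}", t=t)
            for t, b in [(3.0, 0.07), (6.0, 0.13), (13.0, 0.12)]
        ]
        table = mfi_series(ms, alpha).sort_values("time_h")
        assert table.mfi_mean.tolist() == pytest.approx([0.07, 0.13, 0.12], abs=1e-9)

    def test_saturated_samples_excluded_with_warning(self, caplog):
        alpha = 0.0345
        ok_y = forward_pool_ratio(1.0, 0.13, alpha)
        sat_y = (1 + alpha) / (1 - alpha) + 0.1
        ms = [meas(1.0, ok_y, "ok1", t=6.0), meas(1.0, sat_y, "sat1", t=6.0)]
        with caplog.at_level("WARNING", logger="hetfix.isotope_flux"):
            table = mfi_series(ms, alpha)
        assert table.iloc[0].n == 1
        assert table.iloc[0].n_saturated == 1
        assert table.iloc[0].mfi_mean == pytest.approx(0.13, abs=1e-9)
        assert any("sat1" in r.message for r in caplog.records)

    def test_error_carries_sample_context(self):
        with pytest.raises(ValueError, match="no measurements"):
            mfi_series([], 0.0345)

    def test_monte_carlo_mean_recovers_truth(self):
        """At 5 % measurement noise the per-sample mean stays near b/a = 0.13."""
        cfg = LabelingSimConfig(
            b_over_a=0.13, noise_cv=0.05, n_replicates=1000,
            timepoints_h=(6.0,), seed=20150618,
        )
        table = mfi_series(simulate_labeling(cfg), cfg.alpha)
        assert table.iloc[0].mfi_mean == pytest.approx(0.13, abs=0.005)


class TestCompareGroups:
    def test_identical_groups(self):
        t, p = compare_mfi_groups([0.1, 0.1, 0.1], [0.1, 0.1, 0.1])
        assert t == 0.0 and p == 1.0
        t, p = compare_mfi_groups([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_pooled_variance_closed_form(self):
        # hand-computed: pooled sd 0.01, t = -0.04/(0.01*sqrt(2/3)) = -4.898979..., df = 4
        t, p = compare_mfi_groups([0.12, 0.13, 0.14], [0.16, 0.17, 0.18])
        assert t == pytest.approx(-0.04 / (0.01 * math.sqrt(2 / 3)), rel=1e-9)
        assert p == pytest.approx(0.0080499, abs=1e-6)

    def test_p_value_symmetric_in_group_order(self):
        g1, g2 = [0.12, 0.13, 0.14], [0.16, 0.17, 0.18]
        _, p12 = compare_mfi_groups(g1, g2)
        _, p21 = compare_mfi_groups(g2, g1)
        assert p12 == pytest.approx(p21, rel=1e-12)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_mfi_groups([0.1], [0.2, 0.3])
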