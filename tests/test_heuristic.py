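import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import curve_from_pattern, make_response
from vepacuity.conversion import sf_limit_from_logmar
from vepacuity.heuristic import (
    AcuityEstimate,
    build_curve,
    estimate_acuity,
    fit_sf_limit,
    flag_spurious,
    to_acuity,
)
from vepacuity.spectral import analyze_recording
from vepacuity.synthetic import ParticipantModel, StimulusSet, simulate_recording


def noise_free_curve(true_logmar, stimulus=None, seed=3):
    stimulus = stimulus or StimulusSet(n_segments=2, sampling_rate=250.0)
    p = ParticipantModel(
        true_logmar_normal=true_logmar, noise_sd=0.0, blink_rate=0.0, seed=seed
    )
    responses = [
        analyze_recording(simulate_recording(p, stimulus, c, true_logmar))
        for c in stimulus.check_sizes
    ]
    return build_curve(responses)


class TestBuildCurve:
    def test_sorts_by_log_sf(self):
        pts = [make_response(x, 1.0) for x in (1.2, 0.3, 0.9)]
        curve = build_curve(pts)
        assert [p.log_sf for p in curve.points] == [0.3, 0.9, 1.2]

    def test_duplicate_spatial_frequency_names_check_size(self):
        pts = [make_response(0.5, 1.0, check_size=9.49), make_response(0.5, 2.0, check_size=9.49)]
        with pytest.raises(ValueError, match="9.49"):
            build_curve(pts)

    def test_fewer_than_two_points_rejected(self):
        with pytest.raises(ValueError):
            build_curve([make_response(0.5, 1.0), None])


class TestFlagSpurious:
    def test_isolated_high_sf_significance_overridden(self):
        curve = curve_from_pattern([5, 4, 1, 1, 3], [1, 1, 0, 0, 1])
        flagged = flag_spurious(curve, "auto")
        assert flagged.significance_pattern == [True, True, False, False, False]

    def test_contiguous_block_unchanged(self):
        curve = curve_from_pattern([5, 4, 3, 1, 1], [1, 1, 1, 0, 0])
        flagged = flag_spurious(curve, "auto")
        assert flagged.significance_pattern == [True, True, True, False, False]

    def test_single_gap_is_tolerated(self):
        curve = curve_from_pattern([5, 4, 1, 3, 2], [1, 1, 0, 1, 1])
        flagged = flag_spurious(curve, "auto")
        assert flagged.significance_pattern == [True, True, False, True, True]

    def test_everything_beyond_a_double_gap_is_spurious(self):
        curve = curve_from_pattern([5, 1, 1, 3, 1, 2], [1, 0, 0, 1, 0, 1])
        flagged = flag_spurious(curve, "auto")
        assert flagged.significance_pattern == [True, False, False, False, False, False]

    def test_manual_override_applies_downstream(self):
        curve = curve_from_pattern([5, 4, 3, 2, 1], [1, 1, 1, 1, 1])
        flagged = flag_spurious(curve, [4])
        assert flagged.significance_pattern == [True, True, True, True, False]
        est = fit_sf_limit(flagged)
        assert 4 not in est.fit_points

    def test_out_of_range_index_rejected(self):
        curve = curve_from_pattern([5, 4], [1, 1])
        with pytest.raises(IndexError):
            flag_spurious(curve, [2])


class TestFitSfLimit:
    def test_two_point_line_intercept(self):
        curve = curve_from_pattern([4.0, 2.0], [1, 1], log_sfs=[0.5, 1.0])
        est = fit_sf_limit(curve)
        assert est.status == "ok"
        assert est.sf_limit == pytest.approx(10**1.5, rel=1e-6)

    def test_no_significant_points_yields_no_estimate(self):
        curve = curve_from_pattern([1, 1, 1], [0, 0, 0])
        est = fit_sf_limit(curve)
        assert est.status == "no_estimate"
        assert est.sf_limit is None and est.logmar is None

    def test_single_fit_point_yields_no_estimate(self):
        curve = curve_from_pattern([1, 5, 0.1, 0.1], [0, 1, 0, 0])
        assert fit_sf_limit(curve).status == "no_estimate"

    def test_non_negative_slope_yields_no_estimate(self):
        curve = curve_from_pattern([3.0, 3.0, 3.0], [1, 1, 1])
        est = fit_sf_limit(curve)
        assert est.status == "no_estimate"
        assert "slope" in est.reason

    def test_peak_tie_breaks_toward_lower_sf(self):
        curve = curve_from_pattern([5.0, 5.0, 2.0], [1, 1, 1])
        est = fit_sf_limit(curve)
        assert est.fit_points[0] == 0

    def test_trailing_nonsignificant_point_optional(self):
        curve = curve_from_pattern([4.0, 2.0, 0.5], [1, 1, 0], log_sfs=[0.5, 1.0, 1.5])
        default = fit_sf_limit(curve)
        assert default.fit_points == (0, 1)
        with_trailing = fit_sf_limit(curve, include_trailing_nonsig=True)
        assert with_trailing.fit_points == (0, 1, 2)

    @pytest.mark.parametrize("true_logmar", np.linspace(-0.15, 0.5, 20))
    def test_noise_free_recovery_is_exact(self, true_logmar):
        curve = noise_free_curve(float(true_logmar))
        est = fit_sf_limit(curve)
        assert est.status == "ok"
        true_limit = sf_limit_from_logmar(true_logmar)
        assert abs(math.log10(est.sf_limit) - math.log10(true_limit)) < 0.02


class TestToAcuity:
    def test_clipping_at_decimal_1_6(self):
        decimal, logmar, clipped = to_acuity(sf_limit=2.0 * 17.6)
        assert clipped
        assert decimal == 1.6
        assert logmar == pytest.approx(-math.log10(1.6))

    def test_unit_decimal_acuity_is_logmar_zero(self):
        decimal, logmar, clipped = to_acuity(sf_limit=17.6)
        assert decimal == pytest.approx(1.0)
        assert logmar == pytest.approx(0.0, abs=1e-12)
        assert not clipped

    def test_degraded_level_conversion(self):
        decimal, logmar, _ = to_acuity(sf_limit=0.09 * 17.6)
        assert decimal == pytest.approx(0.09)
        assert logmar == pytest.approx(1.046, abs=1e-3)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_non_positive_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            to_acuity(bad)
        with pytest.raises(ValueError):
            to_acuity(1.0, conversion_factor=bad)


class TestEstimateProperties:
    @given(st.floats(min_value=0.2, max_value=40.0))
    @settings(derandomize=True, max_examples=40)
    def test_logmar_decimal_round_trip(self, sf_limit):
        decimal, logmar, _ = to_acuity(sf_limit)
        assert decimal == pytest.approx(10.0 ** (-logmar), rel=1e-14)

    @given(st.floats(min_value=0.05, max_value=20.0))
    @settings(derandomize=True, max_examples=40)
    def test_shift_equivariance_in_spatial_frequency(self, c):
        amps, pattern = [6.0, 4.0, 2.0, 0.5], [1, 1, 1, 1]
        base_logsf = np.log10([0.5, 1.0, 2.0, 4.0])
        est0 = fit_sf_limit(curve_from_pattern(amps, pattern, log_sfs=base_logsf))
        est1 = fit_sf_limit(
            curve_from_pattern(amps, pattern, log_sfs=base_logsf + np.log10(c))
        )
        assert est1.sf_limit == pytest.approx(c * est0.sf_limit, rel=1e-9)

    @given(st.floats(min_value=1e-6, max_value=1e6))
    @settings(derandomize=True, max_examples=100)
    def test_global_amplitude_scale_leaves_sf_limit_bit_identical(self, k):
        amps = np.array([6.0, 4.7, 2.2, 0.9, 0.3])
        pattern = [1, 1, 1, 1, 0]
        est0 = fit_sf_limit(curve_from_pattern(amps, pattern))
        est1 = fit_sf_limit(curve_from_pattern(k * amps, pattern))
        assert est1.sf_limit == est0.sf_limit

    def test_forcing_last_significant_point_never_raises_limit(self):
        for lm in np.linspace(-0.1, 0.4, 8):
            curve = noise_free_curve(float(lm))
            base = fit_sf_limit(curve)
            last_sig = max(i for i, s in enumerate(curve.significance_pattern) if s)
            reduced = fit_sf_limit(flag_spurious(curve, [last_sig]))
            if base.status == "ok" and reduced.status == "ok":
                # equality up to the fit's single-precision resolution
                assert reduced.sf_limit <= base.sf_limit * (1 + 1e-6)


def test_estimate_acuity_composes_fit_and_conversion():
    curve = noise_free_curve(0.1)
    est = estimate_acuity(curve)
    assert est.status == "ok"
    assert est.logmar == pytest.approx(0.1, abs=5e-3)
    assert est.decimal_acuity == pytest.approx(10 ** -est.logmar)
    assert not est.clipped


def test_estimate_invariant_validation():
    with pytest.raises(ValueError):
        AcuityEstimate(status="ok", sf_limit=5.0, decimal_acuity=1.0, logmar=0.5)
    with pytest.raises(ValueError):
        AcuityEstimate(status="no_estimate", sf_limit=5.0)
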