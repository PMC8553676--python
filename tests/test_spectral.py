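import numpy as np
import pytest
from scipy import stats as sps

from vepacuity.recording import Recording
from vepacuity.spectral import (
    analyze_recording,
    estimate_noise,
    first_harmonic,
    noise_correct,
    segment_and_reject,
    significance,
)


def make_recording(samples, fs=250.0, reversal=8.0, seglen=1.0):
    return Recording(
        samples=samples, sampling_rate=fs, reversal_rate=reversal, check_size=30.0,
        segment_length=seglen,
    )


class TestSegmentRejection:
    def test_threshold_is_exceed_not_reach(self):
        n = 250
        seg_ok = np.zeros(n)
        seg_ok[10] = 119.0
        seg_bad = np.zeros(n)
        seg_bad[10] = -121.0
        seg_at = np.zeros(n)
        seg_at[10] = 120.0
        rec = make_recording(np.concatenate([seg_ok, seg_bad, seg_at]))
        kept, n_rejected = segment_and_reject(rec, threshold=120.0)
        assert n_rejected == 1
        assert kept.shape[0] == 2

    def test_peak_to_peak_criterion_alternative(self):
        n = 250
        seg = np.zeros(2 * n)
        seg[10], seg[20] = 70.0, -70.0  # p-p 140 > 120, peak 70 < 120
        rec = make_recording(seg)
        _, by_peak = segment_and_reject(rec, criterion="peak")
        _, by_pp = segment_and_reject(rec, criterion="peak_to_peak")
        assert by_peak == 0 and by_pp == 1
        with pytest.raises(ValueError):
            segment_and_reject(rec, criterion="rms")

    def test_constant_zero_recording_keeps_everything(self):
        rec = make_recording(np.zeros(4 * 250))
        kept, n_rejected = segment_and_reject(rec)
        assert n_rejected == 0 and kept.shape[0] == 4

    def test_all_rejected_yields_missing_response_not_exception(self):
        rec = make_recording(np.full(2 * 250, 200.0))
        assert analyze_recording(rec) is None

    def test_kept_set_pipeline_is_idempotent(self):
        rng = np.random.default_rng(0)
        samples = rng.normal(0, 35.0, 16 * 250)
        rec = make_recording(samples)
        kept, n1 = segment_and_reject(rec)
        assert 0 < n1 < 16
        amp1, *_ = first_harmonic(kept, 8.0, 250.0)
        # re-running rejection and readout on the kept set changes nothing
        rec2 = make_recording(kept.ravel())
        kept2, n2 = segment_and_reject(rec2)
        amp2, *_ = first_harmonic(kept2, 8.0, 250.0)
        assert n2 == 0 and amp1 == amp2


class TestFirstHarmonic:
    @pytest.mark.parametrize("n_segments", [1, 3, 8])
    def test_pure_sinusoid_amplitude_is_exact(self, n_segments):
        t = np.arange(n_segments * 250) / 250.0
        a = 3.7
        amp, phase, _, k = first_harmonic(
            (a * np.sin(2 * np.pi * 8.0 * t)).reshape(n_segments, 250), 8.0, 250.0
        )
        assert amp == pytest.approx(a, abs=1e-9)
        assert k == 8

    def test_doubling_signal_doubles_amplitude_exactly(self):
        t = np.arange(4 * 250) / 250.0
        x = np.sin(2 * np.pi * 8.0 * t + 0.3).reshape(4, 250)
        a1, *_ = first_harmonic(x, 8.0, 250.0)
        a2, *_ = first_harmonic(2.0 * x, 8.0, 250.0)
        assert a2 == 2.0 * a1

    def test_antiphase_segments_cancel(self):
        t = np.arange(250) / 250.0
        seg = np.sin(2 * np.pi * 8.0 * t)
        amp, *_ = first_harmonic(np.stack([seg, -seg]), 8.0, 250.0)
        assert amp == pytest.approx(0.0, abs=1e-12)

    def test_incoherent_readout_is_phase_insensitive(self):
        # antiphase segments cancel coherently but not spectrum-wise
        t = np.arange(250) / 250.0
        seg = 2.0 * np.sin(2 * np.pi * 8.0 * t)
        pair = np.stack([seg, -seg])
        coherent, *_ = first_harmonic(pair, 8.0, 250.0)
        incoherent, *_ = first_harmonic(pair, 8.0, 250.0, mode="incoherent")
        assert coherent == pytest.approx(0.0, abs=1e-12)
        assert incoherent == pytest.approx(2.0, abs=1e-9)

    def test_off_bin_harmonic_rejected(self):
        with pytest.raises(ValueError, match="whole number of cycles"):
            first_harmonic(np.zeros((2, 250)), 7.5, 250.0)

    def test_noisy_amplitude_estimate_is_unbiased(self):
        """Monte-Carlo oracle: the mean readout over 200 noisy replicates
        sits within 3 standard errors of the embedded 2-uV amplitude."""
        rng = np.random.default_rng(123)
        t = np.arange(80 * 250) / 250.0
        signal = 2.0 * np.sin(2 * np.pi * 8.0 * t)
        estimates = []
        for _ in range(200):
            x = (signal + rng.normal(0, 5.0, t.size)).reshape(80, 250)
            amp, *_ = first_harmonic(x, 8.0, 250.0)
            estimates.append(amp)
        estimates = np.array(estimates)
        se = estimates.std(ddof=1) / np.sqrt(len(estimates))
        assert abs(estimates.mean() - 2.0) < 3 * se + 1e-3


class TestNoiseEstimate:
    def test_flat_spectrum_returns_the_common_amplitude(self):
        spectrum = np.full(40, 1.7)
        assert estimate_noise(spectrum, harmonic_bin=8) == pytest.approx(1.7)

    def test_isolated_harmonic_has_zero_noise(self):
        spectrum = np.zeros(40)
        spectrum[8] = 5.0
        assert estimate_noise(spectrum, 8) == 0.0

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError, match="neighbour"):
            estimate_noise(np.ones(5), harmonic_bin=3, k_neighbors=2)

    def test_neighbor_bins_estimate_the_harmonic_bins_own_noise_floor(self):
        """On pure noise, neighbour-bin power and harmonic-bin power
        estimate the same floor: their means over 500 runs agree to 5%."""
        rng = np.random.default_rng(7)
        raw2, noise2 = [], []
        for _ in range(500):
            x = rng.normal(0, 20.0, 4 * 250).reshape(4, 250)
            amp, _, spectrum, k = first_harmonic(x, 8.0, 250.0)
            raw2.append(amp**2)
            noise2.append(estimate_noise(spectrum, k) ** 2)
        assert np.mean(noise2) == pytest.approx(np.mean(raw2), rel=0.05)


class TestNoiseCorrection:
    @pytest.mark.parametrize(
        "raw,noise,expected", [(5.0, 3.0, 4.0), (3.0, 3.0, 0.0), (2.0, 3.0, 0.0), (4.0, 0.0, 4.0)]
    )
    def test_power_domain_subtraction_with_floor(self, raw, noise, expected):
        assert noise_correct(raw, noise) == pytest.approx(expected)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            noise_correct(-1.0, 0.0)

    def test_correction_removes_noise_power_bias(self):
        """Over noise-only runs the signed power subtraction is unbiased
        (the Rayleigh noise bias cancels in expectation), and flooring at
        zero leaves well under half of the raw power."""
        rng = np.random.default_rng(21)
        raw2, signed, corr2 = [], [], []
        for _ in range(500):
            x = rng.normal(0, 20.0, 4 * 250).reshape(4, 250)
            amp, _, spectrum, k = first_harmonic(x, 8.0, 250.0)
            noise = estimate_noise(spectrum, k)
            raw2.append(amp**2)
            signed.append(amp**2 - noise**2)
            corr2.append(noise_correct(amp, noise) ** 2)
        # unbiasedness of the subtraction itself, before the zero floor
        assert abs(np.mean(signed)) <= 0.10 * np.mean(raw2)
        # the floored estimate retains only the positive residual
        # (e^-1 of the raw power for exponentially distributed bin power)
        assert np.mean(corr2) <= 0.5 * np.mean(raw2)


class TestSignificance:
    def test_ratio_one_is_unremarkable_under_the_null(self):
        p = significance(1.0, np.ones(4))
        assert p == pytest.approx(sps.f.sf(1.0, 2, 8))
        assert p > 0.05

    def test_zero_noise_conventions(self):
        assert significance(0.0, np.zeros(4)) == 1.0
        assert significance(1.0, np.zeros(4)) == 0.0

    def test_p_monotone_decreasing_in_signal_power(self):
        floor = np.full(4, 0.5)
        ps = [significance(a, floor) for a in (0.5, 1.0, 2.0, 4.0, 8.0)]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        assert ps[-1] == pytest.approx(sps.f.sf(64.0 / 0.5, 2, 8))

    def test_null_calibration_coarse(self):
        """Type-I rate on white noise near the nominal 5% level (coarse
        check; the full 10^4-run calibration lives in the acceptance
        suite)."""
        rng = np.random.default_rng(3)
        hits = 0
        n = 1500
        for _ in range(n):
            x = rng.normal(0, 20.0, 4 * 250)
            rec = make_recording(x)
            resp = analyze_recording(rec)
            hits += resp.significant
        assert 0.03 < hits / n < 0.07


def test_analyze_recording_composes_all_stages():
    rng = np.random.default_rng(5)
    t = np.arange(20 * 250) / 250.0
    x = 6.0 * np.sin(2 * np.pi * 8.0 * t) + rng.normal(0, 10.0, t.size)
    x[100] = 300.0  # one artifact segment
    resp = analyze_recording(make_recording(x))
    assert resp.n_segments_rejected == 1
    assert resp.n_segments_kept == 19
    assert resp.significant and resp.p_value < 1e-4
    assert 0 < resp.amplitude_corrected <= resp.amplitude_raw
    assert resp.spatial_frequency == pytest.approx(1.0)
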