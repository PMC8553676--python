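import numpy as np
import pytest

from vepacuity.spectral import SpectralResponse
from vepacuity.synthetic import StimulusSet


def make_response(
    log_sf: float,
    amplitude: float,
    significant: bool = True,
    check_size: float | None = None,
    noise: float = 0.0,
) -> SpectralResponse:
    """Hand-built spectral response for tuning-curve unit tests."""
    sf = 10.0**log_sf
    return SpectralResponse(
        check_size=check_size if check_size is not None else 30.0 / sf,
        spatial_frequency=sf,
        log_sf=log_sf,
        amplitude_raw=amplitude + noise,
        phase=0.0,
        noise_amplitude=noise,
        amplitude_corrected=amplitude,
        p_value=0.01 if significant else 0.5,
        significant=significant,
        n_segments_kept=80,
        n_segments_rejected=0,
    )


def curve_from_pattern(amplitudes, pattern, log_sfs=None):
    """Build a TuningCurve from amplitudes and a significance pattern."""
    from vepacuity.heuristic import TuningCurve

    if log_sfs is None:
        log_sfs = np.log10([0.5, 1.0, 2.0, 4.0, 8.0, 16.0])[: len(amplitudes)]
    points = [
        make_response(float(x), float(a), bool(s))
        for x, a, s in zip(log_sfs, amplitudes, pattern)
    ]
    return TuningCurve(points=points)


@pytest.fixture(scope="session")
def fast_stimulus() -> StimulusSet:
    """Reduced acquisition (8 segments, 250 Hz) for cheap simulations."""
    return StimulusSet(n_segments=8, sampling_rate=250.0)


@pytest.fixture(scope="session")
def default_stimulus() -> StimulusSet:
    return StimulusSet()
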