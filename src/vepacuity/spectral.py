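"""First-harmonic spectral analysis of steady-state VEP recordings.

Stages: segment-wise artifact rejection against a 120-uV amplitude
criterion, coherent (time-domain) averaging of the accepted segments,
DFT readout of the bin at the stimulation's first harmonic, a noise
estimate from the neighbouring bins, power-domain noise correction, and
an F-ratio significance test of the harmonic against the neighbour bins.

The whole-cycles constraint (reversal_rate x segment_length integer)
guarantees the first harmonic falls exactly on a DFT bin of the averaged
segment, so no windowing or interpolation is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .conversion import sf_from_check_size
from .recording import Recording

#: Segment rejection threshold, microvolts.
DEFAULT_REJECTION_THRESHOLD_UV: float = 120.0

#: Neighbour bins per side used for the noise estimate and the F test.
DEFAULT_K_NEIGHBORS: int = 2

#: Single-test significance level.
DEFAULT_ALPHA: float = 0.05


@dataclass(frozen=True)
class SpectralResponse:
    """First-harmonic response of one recording (one check size).

    ``amplitude_raw`` is the single-sided sinusoid amplitude (uV) at the
    first harmonic of the coherently averaged segment; ``noise_amplitude``
    is the RMS amplitude of the neighbouring bins; ``amplitude_corrected``
    subtracts the noise in the power domain (floored at zero). ``p_value``
    comes from the F-ratio test of harmonic power against mean neighbour
    power; ``significant`` is the single-test flag at ``alpha``.
    """

    check_size: float
    spatial_frequency: float
    log_sf: float
    amplitude_raw: float
    phase: float
    noise_amplitude: float
    amplitude_corrected: float
    p_value: float
    significant: bool
    n_segments_kept: int
    n_segments_rejected: int
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        if self.amplitude_raw < 0 or self.noise_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value out of range: {self.p_value}")
        if self.amplitude_corrected < 0 or self.amplitude_corrected > self.amplitude_raw + 1e-12:
            raise ValueError("amplitude_corrected must lie in [0, amplitude_raw]")
        if self.significant != (self.p_value < self.alpha):
            raise ValueError("significant flag inconsistent with p_value and alpha")


def segment_and_reject(
    recording: Recording,
    threshold: float = DEFAULT_REJECTION_THRESHOLD_UV,
    criterion: str = "peak",
) -> tuple[np.ndarray, int]:
    """Split a recording into segments and drop artifact-contaminated ones.

    A segment is rejected iff its amplitude excursion exceeds ``threshold``
    (uV). With ``criterion="peak"`` (default) the excursion is
    peak-to-baseline — the maximum absolute sample value within the
    segment; ``criterion="peak_to_peak"`` uses max minus min instead.
    Returns the kept segments (in temporal order, shape
    ``(n_kept, samples_per_segment)``) and the rejection count. When every
    segment is rejected the kept array has zero rows; callers treat that
    as a "no usable data" outcome rather than an error.
    """
    segments = recording.segments()
    if segments.shape[0] < 1:
        raise ValueError("recording contains no full segment")
    if criterion == "peak":
        excursion = np.abs(segments).max(axis=1)
    elif criterion == "peak_to_peak":
        excursion = segments.max(axis=1) - segments.min(axis=1)
    else:
        raise ValueError(f"criterion must be 'peak' or 'peak_to_peak', got {criterion!r}")
    keep = excursion <= threshold
    return segments[keep], int((~keep).sum())


def first_harmonic(
    segments: np.ndarray,
    reversal_rate: float,
    sampling_rate: float,
    mode: str = "coherent",
) -> tuple[float, float, np.ndarray, int]:
    """Amplitude and phase at the stimulation's first harmonic.

    With ``mode="coherent"`` (default) segments are averaged in the time
    domain and the DFT bin at ``reversal_rate`` Hz is read out of the
    averaged segment. ``mode="incoherent"`` instead averages per-segment
    amplitude spectra — phase-insensitive, hence biased upward by noise,
    provided only as an alternative readout. Returns ``(amplitude, phase,
    spectrum_amplitudes, harmonic_bin)`` where ``spectrum_amplitudes`` is
    the full single-sided amplitude spectrum (uV).

    Raises if the harmonic does not fall exactly on a DFT bin (the
    whole-cycles-per-segment requirement).
    """
    segments = np.atleast_2d(np.asarray(segments, dtype=float))
    if segments.shape[0] < 1 or segments.size == 0:
        raise ValueError("need at least one accepted segment")
    n = segments.shape[1]
    cycles = reversal_rate * n / sampling_rate
    if abs(cycles - round(cycles)) > 1e-6:
        raise ValueError(
            f"first harmonic at {reversal_rate} Hz is off-bin for "
            f"{n / sampling_rate}-s segments: reversal_rate x segment_length "
            "must be a whole number of cycles"
        )
    harmonic_bin = int(round(cycles))
    if harmonic_bin < 1 or harmonic_bin > n // 2:
        raise ValueError("harmonic bin outside the spectrum")
    if mode == "coherent":
        spectrum = np.fft.rfft(segments.mean(axis=0))
        moduli = np.abs(spectrum)
        phase = float(np.angle(spectrum[harmonic_bin]))
    elif mode == "incoherent":
        per_segment = np.fft.rfft(segments, axis=1)
        moduli = np.abs(per_segment).mean(axis=0)
        phase = float(np.angle(per_segment[:, harmonic_bin].mean()))
    else:
        raise ValueError(f"mode must be 'coherent' or 'incoherent', got {mode!r}")
    # single-sided sinusoid amplitude: A*sin(...) -> |X_k| = A*N/2
    amplitudes = moduli * (2.0 / n)
    amplitudes[0] = moduli[0] / n
    if n % 2 == 0:
        amplitudes[-1] = moduli[-1] / n
    return float(amplitudes[harmonic_bin]), phase, amplitudes, harmonic_bin


def estimate_noise(
    spectrum_amplitudes: np.ndarray,
    harmonic_bin: int,
    k_neighbors: int = DEFAULT_K_NEIGHBORS,
) -> float:
    """RMS amplitude of the bins flanking the harmonic.

    Uses the ``k_neighbors`` nearest bins on each side of (and excluding)
    the harmonic bin — ``2 * k_neighbors`` bins in total — and returns the
    square root of their mean power.
    """
    powers = _neighbor_powers(spectrum_amplitudes, harmonic_bin, k_neighbors)
    return float(np.sqrt(powers.mean()))


def _neighbor_powers(
    spectrum_amplitudes: np.ndarray, harmonic_bin: int, k_neighbors: int
) -> np.ndarray:
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    n_bins = len(spectrum_amplitudes)
    lo = harmonic_bin - k_neighbors
    hi = harmonic_bin + k_neighbors
    if lo < 1 or hi >= n_bins:
        raise ValueError(
            f"spectrum too short for {k_neighbors} neighbour bins on each "
            f"side of bin {harmonic_bin} (have bins 1..{n_bins - 1})"
        )
    idx = np.r_[lo:harmonic_bin, harmonic_bin + 1 : hi + 1]
    amps = np.asarray(spectrum_amplitudes, dtype=float)[idx]
    return amps**2


def noise_correct(amplitude_raw: float, noise_amplitude: float) -> float:
    """Noise-corrected amplitude: power-domain subtraction, floored at 0.

    ``sqrt(max(raw^2 - noise^2, 0))`` — removes the expected contribution
    of background noise power to the measured harmonic power while
    preserving non-negativity.
    """
    if amplitude_raw < 0 or noise_amplitude < 0:
        raise ValueError("amplitudes must be non-negative")
    return float(np.sqrt(max(amplitude_raw**2 - noise_amplitude**2, 0.0)))


def significance(amplitude_raw: float, neighbor_powers: np.ndarray) -> float:
    """p-value that the harmonic response exceeds the local noise floor.

    The harmonic's power is compared with the mean neighbour-bin power via
    an F ratio with 2 numerator and ``2 * len(neighbor_powers)``
    denominator degrees of freedom. Under a circularly-symmetric Gaussian
    null each complex DFT bin contributes two independent Gaussian
    quadratures, so the ratio is exactly F-distributed and the test is
    exactly calibrated for white noise.

    Conventions for a degenerate (zero) noise floor: zero signal -> p = 1,
    positive signal -> p = 0.
    """
    neighbor_powers = np.asarray(neighbor_powers, dtype=float)
    if neighbor_powers.size < 2:
        raise ValueError("need at least 2 neighbour bins")
    if amplitude_raw < 0:
        raise ValueError("amplitude_raw must be non-negative")
    mean_noise_power = neighbor_powers.mean()
    signal_power = amplitude_raw**2
    if mean_noise_power == 0.0:
        return 1.0 if signal_power == 0.0 else 0.0
    ratio = signal_power / mean_noise_power
    return float(sps.f.sf(ratio, 2, 2 * neighbor_powers.size))


def analyze_recording(
    recording: Recording,
    *,
    threshold: float = DEFAULT_REJECTION_THRESHOLD_UV,
    k_neighbors: int = DEFAULT_K_NEIGHBORS,
    alpha: float = DEFAULT_ALPHA,
) -> SpectralResponse | None:
    """Full per-recording pipeline: reject, average, read out, test.

    Returns ``None`` when every segment is rejected (the "no usable data"
    outcome); downstream stages treat the corresponding check size as a
    missing tuning-curve point.
    """
    kept, n_rejected = segment_and_reject(recording, threshold)
    if kept.shape[0] == 0:
        return None
    amplitude, phase, spectrum, harmonic_bin = first_harmonic(
        kept, recording.reversal_rate, recording.sampling_rate
    )
    noise = estimate_noise(spectrum, harmonic_bin, k_neighbors)
    corrected = noise_correct(amplitude, noise)
    powers = _neighbor_powers(spectrum, harmonic_bin, k_neighbors)
    p = significance(amplitude, powers)
    sf = sf_from_check_size(recording.check_size)
    return SpectralResponse(
        check_size=recording.check_size,
        spatial_frequency=sf,
        log_sf=float(np.log10(sf)),
        amplitude_raw=amplitude,
        phase=phase,
        noise_amplitude=noise,
        amplitude_corrected=corrected,
        p_value=p,
        significant=bool(p < alpha),
        n_segments_kept=int(kept.shape[0]),
        n_segments_rejected=n_rejected,
        alpha=alpha,
    )


def responses_to_frame(responses: list[SpectralResponse | None]) -> "pd.DataFrame":
    """Tidy table of spectral responses (one row per check size)."""
    import pandas as pd

    rows = []
    for r in responses:
        if r is None:
            continue
        rows.append(
            {
                "check_size": r.check_size,
                "spatial_frequency": r.spatial_frequency,
                "log_sf": r.log_sf,
                "amplitude_raw": r.amplitude_raw,
                "phase": r.phase,
                "noise_amplitude": r.noise_amplitude,
                "amplitude_corrected": r.amplitude_corrected,
                "p_value": r.p_value,
                "significant": r.significant,
                "n_segments_kept": r.n_segments_kept,
                "n_segments_rejected": r.n_segments_rejected,
                "alpha": r.alpha,
            }
        )
    return pd.DataFrame(rows)


def frame_to_responses(df: "pd.DataFrame") -> list[SpectralResponse]:
    """Rebuild :class:`SpectralResponse` objects from a tidy table.

    Inverse of :func:`responses_to_frame`; a missing ``phase`` or
    ``alpha`` column falls back to 0.0 / the default alpha.
    """
    out = []
    for _, row in df.iterrows():
        out.append(
            SpectralResponse(
                check_size=float(row["check_size"]),
                spatial_frequency=float(row["spatial_frequency"]),
                log_sf=float(row["log_sf"]),
                amplitude_raw=float(row["amplitude_raw"]),
                phase=float(row.get("phase", 0.0)),
                noise_amplitude=float(row["noise_amplitude"]),
                amplitude_corrected=float(row["amplitude_corrected"]),
                p_value=float(row["p_value"]),
                significant=bool(row["significant"]),
                n_segments_kept=int(row["n_segments_kept"]),
                n_segments_rejected=int(row["n_segments_rejected"]),
                alpha=float(row.get("alpha", DEFAULT_ALPHA)),
            )
        )
    return out
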