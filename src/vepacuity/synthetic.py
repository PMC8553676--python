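"""Synthetic steady-state VEP generator with known ground truth.

Emulates a monocular pattern-reversal acuity study: per eye/occlusion
condition, one recording per check size (six sizes), 1-s segments, white
background EEG, blink artifacts that trip the 120-uV rejection criterion,
and a first-harmonic response whose amplitude follows a tuning curve that
falls to zero at a participant- and condition-specific spatial-frequency
limit. Cohorts follow a 2x2 design (normal/degraded vision x
translucent/opaque contralateral occlusion) with counterbalanced condition
order, so every downstream stage — spectral analysis, acuity extrapolation,
paired statistics — can be exercised against planted truth.

The tuning function declines *linearly in log10 spatial frequency* from a
peak amplitude down to zero at the SF limit and is flat below the peak.
Under this shape the acuity heuristic's straight-line extrapolation is
exact by construction, which gives a clean recovery oracle for tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .conversion import (
    DEFAULT_CONVERSION_FACTOR,
    sf_from_check_size,
    sf_limit_from_logmar,
)
from .recording import Recording, write_recording

#: The four study conditions: vision of the tested eye x occlusion of the
#: fellow eye. Order here is the canonical labelling order, not the
#: presentation order (which is counterbalanced).
CONDITIONS: tuple[str, ...] = (
    "normal_translucent",
    "normal_opaque",
    "degraded_translucent",
    "degraded_opaque",
)

#: Williams (balanced Latin square) presentation orders for 4 conditions.
_ORDERS = (
    (0, 1, 3, 2),
    (1, 2, 0, 3),
    (2, 3, 1, 0),
    (3, 0, 2, 1),
)

_BLINK_DURATION_S = 0.2
_BLINK_AMPLITUDE_RANGE_UV = (150.0, 300.0)


@dataclass(frozen=True)
class StimulusSet:
    """Stimulus and acquisition parameters shared by all recordings.

    Defaults: six check sizes in a geometric series (factor 2, spanning
    1.5 log units, i.e. dominant spatial frequencies 0.5-16 cpd), 8
    pattern reversals/s, 1-s segments, 80 segments per recording at
    1000 Hz. These are configurable study parameters, not claims about
    any particular clinical protocol.
    """

    check_sizes: tuple[float, ...] = (60.0, 30.0, 15.0, 7.5, 3.75, 1.875)
    reversal_rate: float = 8.0
    segment_length: float = 1.0
    n_segments: int = 80
    sampling_rate: float = 1000.0

    def __post_init__(self) -> None:
        sizes = tuple(float(c) for c in self.check_sizes)
        if len(sizes) != 6:
            raise ValueError(f"expected exactly 6 check sizes, got {len(sizes)}")
        if any(b >= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("check sizes must be strictly decreasing (arcmin)")
        n_samp = self.segment_length * self.sampling_rate
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise ValueError("segment_length x sampling_rate must be an integer")
        n_cyc = self.reversal_rate * self.segment_length
        if abs(n_cyc - round(n_cyc)) > 1e-9:
            raise ValueError(
                "reversal_rate x segment_length must be a whole number of "
                "cycles so the first harmonic falls on a DFT bin"
            )
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        object.__setattr__(self, "check_sizes", sizes)

    @property
    def spatial_frequencies(self) -> np.ndarray:
        """Dominant spatial frequency (cpd) per check size, increasing."""
        return np.array([sf_from_check_size(c) for c in self.check_sizes])


@dataclass(frozen=True)
class ParticipantModel:
    """Ground-truth generative model for one participant.

    ``true_logmar_normal + degradation_delta`` is the degraded-vision
    ground truth; ``occlusion_delta`` is added in translucent-occlusion
    conditions (the simulated effect under test; negative = translucent
    better).
    """

    true_logmar_normal: float
    degradation_delta: float = 1.06
    occlusion_delta: float = 0.0
    peak_amplitude: float = 10.0
    noise_sd: float = 20.0
    blink_rate: float = 3.0
    pink_noise_sd: float = 0.0
    seed: int = 0
    participant_id: str = "P00"

    def __post_init__(self) -> None:
        if self.peak_amplitude <= 0:
            raise ValueError("peak_amplitude must be > 0")
        if self.noise_sd < 0 or self.blink_rate < 0 or self.pink_noise_sd < 0:
            raise ValueError("noise_sd, blink_rate and pink_noise_sd must be >= 0")

    def condition_logmar(self, condition: str) -> float:
        """Ground-truth logMAR for one of the four study conditions."""
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}; valid: {CONDITIONS}")
        vision, occlusion = condition.split("_")
        logmar = self.true_logmar_normal
        if vision == "degraded":
            logmar += self.degradation_delta
        if occlusion == "translucent":
            logmar += self.occlusion_delta
        return logmar


def tuning_amplitude(
    sf: float,
    sf_limit: float,
    peak_amplitude: float,
    peak_sf: float = 0.5,
) -> float:
    """First-harmonic amplitude (uV) of the tuning function at ``sf`` cpd.

    Flat at ``peak_amplitude`` below ``peak_sf``, declining linearly in
    log10(sf) to zero at ``sf_limit``, zero above. Degenerate case
    ``sf_limit <= peak_sf``: a step, ``peak_amplitude`` below the limit
    and zero at or above it.
    """
    if sf <= 0 or peak_amplitude <= 0 or peak_sf <= 0:
        raise ValueError("sf, peak_amplitude and peak_sf must be positive")
    if sf_limit <= 0 or sf >= sf_limit:
        return 0.0
    if sf <= peak_sf or sf_limit <= peak_sf:
        return peak_amplitude
    frac = (np.log10(sf_limit) - np.log10(sf)) / (np.log10(sf_limit) - np.log10(peak_sf))
    return float(peak_amplitude * frac)


def _blink_waveform(sampling_rate: float, amplitude: float) -> np.ndarray:
    """Raised-cosine transient of 200 ms peaking at ``amplitude`` uV."""
    n = int(round(_BLINK_DURATION_S * sampling_rate))
    t = np.arange(n) / n
    return amplitude * 0.5 * (1.0 - np.cos(2.0 * np.pi * t))


def _pink_noise(rng: np.random.Generator, n: int, sd: float, sampling_rate: float) -> np.ndarray:
    """1/f-shaped Gaussian noise with standard deviation ``sd``."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    shaping = np.ones_like(freqs)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])
    shaping[0] = 0.0
    shaped = np.fft.irfft(spec * shaping, n)
    s = shaped.std()
    return shaped * (sd / s) if s > 0 else shaped


def _recording_seed(participant: ParticipantModel, check_index: int, condition_key: int):
    return np.random.SeedSequence([int(participant.seed) % (2**31), condition_key, check_index])


def simulate_recording(
    participant: ParticipantModel,
    stimulus: StimulusSet,
    check_size: float,
    condition_logmar: float,
    *,
    conversion_factor: float = DEFAULT_CONVERSION_FACTOR,
    peak_sf: float = 0.5,
    condition_key: int | None = None,
    meta: dict | None = None,
) -> Recording:
    """Simulate one recording (one check size, one condition).

    The embedded first-harmonic sinusoid has the tuning function's
    amplitude at the check size's spatial frequency, with the SF limit
    derived from ``condition_logmar`` through the inverse acuity
    conversion. Additive white Gaussian noise (sd ``noise_sd``), optional
    1/f noise, and blink transients (>120 uV peak, each confined to a
    single segment) are added. Fully reproducible from the participant
    seed, the check size and the condition.
    """
    if not np.isfinite(condition_logmar):
        raise ValueError("condition_logmar must be finite")
    if check_size not in stimulus.check_sizes:
        raise ValueError(
            f"check size {check_size} arcmin is not in the stimulus set "
            f"{stimulus.check_sizes}"
        )
    check_index = stimulus.check_sizes.index(check_size)
    if condition_key is None:
        condition_key = int(round(abs(condition_logmar) * 1e6)) % (2**31)
    rng = np.random.default_rng(_recording_seed(participant, check_index, condition_key))

    sf = sf_from_check_size(check_size)
    sf_limit = sf_limit_from_logmar(condition_logmar, conversion_factor)
    amplitude = tuning_amplitude(sf, sf_limit, participant.peak_amplitude, peak_sf)

    n_per_seg = int(round(stimulus.segment_length * stimulus.sampling_rate))
    n_total = n_per_seg * stimulus.n_segments
    t = np.arange(n_total) / stimulus.sampling_rate
    phase = rng.uniform(0.0, 2.0 * np.pi)
    samples = amplitude * np.sin(2.0 * np.pi * stimulus.reversal_rate * t + phase)

    if participant.noise_sd > 0:
        samples = samples + rng.normal(0.0, participant.noise_sd, n_total)
    if participant.pink_noise_sd > 0:
        samples = samples + _pink_noise(
            rng, n_total, participant.pink_noise_sd, stimulus.sampling_rate
        )

    # Blinks: Poisson count over the recording, each placed wholly inside a
    # distinct segment so one blink trips exactly one segment rejection.
    duration_min = stimulus.n_segments * stimulus.segment_length / 60.0
    n_blinks = min(int(rng.poisson(participant.blink_rate * duration_min)), stimulus.n_segments)
    blink_segments: list[int] = []
    if n_blinks > 0:
        blink_segments = sorted(
            int(i) for i in rng.choice(stimulus.n_segments, size=n_blinks, replace=False)
        )
        blink_len = int(round(_BLINK_DURATION_S * stimulus.sampling_rate))
        for seg in blink_segments:
            amp = rng.uniform(*_BLINK_AMPLITUDE_RANGE_UV)
            offset = seg * n_per_seg + int(rng.integers(0, n_per_seg - blink_len + 1))
            samples[offset : offset + blink_len] += _blink_waveform(
                stimulus.sampling_rate, amp
            )

    info = {
        "participant_id": participant.participant_id,
        "condition_logmar": condition_logmar,
        "true_amplitude": amplitude,
        "true_sf_limit": sf_limit,
        "blink_segments": blink_segments,
    }
    if meta:
        info.update(meta)
    return Recording(
        samples=samples,
        sampling_rate=stimulus.sampling_rate,
        reversal_rate=stimulus.reversal_rate,
        check_size=check_size,
        segment_length=stimulus.segment_length,
        meta=info,
    )


@dataclass
class CohortDataset:
    """A simulated cohort: participants, stimulus, and lazy recordings.

    Recordings are deterministic functions of the participant model and
    stimulus, so they are generated on demand rather than held in memory;
    regenerating with the same seed yields byte-identical data.
    """

    participants: list[ParticipantModel]
    stimulus: StimulusSet
    conversion_factor: float = DEFAULT_CONVERSION_FACTOR
    peak_sf: float = 0.5
    condition_orders: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def ground_truth(self) -> pd.DataFrame:
        """Tidy table: participant, condition, vision, occlusion, true logMAR."""
        rows = []
        for p in self.participants:
            order = self.condition_orders.get(p.participant_id, CONDITIONS)
            for cond in CONDITIONS:
                vision, occlusion = cond.split("_")
                rows.append(
                    {
                        "participant": p.participant_id,
                        "condition": cond,
                        "vision": vision,
                        "occlusion": occlusion,
                        "true_logmar": p.condition_logmar(cond),
                        "presentation_position": order.index(cond) + 1,
                    }
                )
        return pd.DataFrame(rows)

    def recording(self, participant: ParticipantModel, condition: str, check_size: float) -> Recording:
        cond_idx = CONDITIONS.index(condition)
        return simulate_recording(
            participant,
            self.stimulus,
            check_size,
            participant.condition_logmar(condition),
            conversion_factor=self.conversion_factor,
            peak_sf=self.peak_sf,
            condition_key=cond_idx,
            meta={"condition": condition},
        )

    def condition_recordings(self, participant: ParticipantModel, condition: str) -> list[Recording]:
        """All six recordings of one participant x condition cell."""
        return [self.recording(participant, condition, c) for c in self.stimulus.check_sizes]

    def iter_recordings(self) -> Iterator[tuple[ParticipantModel, str, Recording]]:
        for p in self.participants:
            for cond in CONDITIONS:
                for c in self.stimulus.check_sizes:
                    yield p, cond, self.recording(p, cond, c)


def generate_cohort(
    n_participants: int = 16,
    effect: float = -0.06,
    seed: int = 0,
    stimulus: StimulusSet | None = None,
    *,
    degradation_delta: float = 1.06,
    noise_sd: float | None = None,
    blink_rate: float | None = None,
    peak_amplitude: float | None = None,
    conversion_factor: float = DEFAULT_CONVERSION_FACTOR,
    peak_sf: float = 0.5,
) -> CohortDataset:
    """Generate a 2x2-design cohort with a planted occlusion effect.

    Parameters
    ----------
    n_participants
        Cohort size (>= 2). The study design this emulates used 16.
    effect
        ``occlusion_delta`` in logMAR applied in translucent conditions;
        negative means translucent occlusion yields better acuity. The
        default -0.06 matches the effect scale the method is meant to
        detect.
    seed
        Master seed; participant parameters and recordings all derive
        from it.
    noise_sd, blink_rate, peak_amplitude
        Override the per-participant draws with a fixed value (e.g.
        ``noise_sd=0, blink_rate=0`` for noise-free oracle cohorts).

    Per-participant defaults are drawn to emulate a normally sighted adult
    cohort: true normal-vision logMAR ~ N(0.02, 0.08) clipped to
    [-0.2, 0.3], first-harmonic peak amplitude ~ U(6, 14) uV, background
    EEG sd ~ U(15, 25) uV, blink rate ~ U(1, 5) per minute. Condition
    order is counterbalanced over a balanced Latin square.
    """
    if n_participants < 2:
        raise ValueError("n_participants must be >= 2")
    stimulus = stimulus or StimulusSet()
    master = np.random.SeedSequence(int(seed) % (2**31))
    participants: list[ParticipantModel] = []
    orders: dict[str, tuple[str, ...]] = {}
    for i, child in enumerate(master.spawn(n_participants)):
        rng = np.random.default_rng(child)
        pid = f"P{i:02d}"
        participants.append(
            ParticipantModel(
                true_logmar_normal=float(np.clip(rng.normal(0.02, 0.08), -0.2, 0.3)),
                degradation_delta=degradation_delta,
                occlusion_delta=effect,
                peak_amplitude=(
                    peak_amplitude if peak_amplitude is not None else float(rng.uniform(6.0, 14.0))
                ),
                noise_sd=noise_sd if noise_sd is not None else float(rng.uniform(15.0, 25.0)),
                blink_rate=blink_rate if blink_rate is not None else float(rng.uniform(1.0, 5.0)),
                seed=int(rng.integers(0, 2**31)),
                participant_id=pid,
            )
        )
        orders[pid] = tuple(CONDITIONS[j] for j in _ORDERS[i % len(_ORDERS)])
    return CohortDataset(
        participants=participants,
        stimulus=stimulus,
        conversion_factor=conversion_factor,
        peak_sf=peak_sf,
        condition_orders=orders,
    )


def write_cohort(dataset: CohortDataset, out_dir: str | Path) -> Path:
    """Persist a cohort as a directory tree of per-recording CSV files.

    Layout: ``<out>/<participant>/<condition>/check_<size>.csv`` (+ JSON
    sidecars), plus ``ground_truth.csv`` and ``cohort.json`` at the root.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for participant, condition, rec in dataset.iter_recordings():
        name = f"check_{rec.check_size:g}arcmin.csv"
        write_recording(rec, out_dir / participant.participant_id / condition / name)
    dataset.ground_truth.to_csv(out_dir / "ground_truth.csv", index=False, float_format="%.9g")
    manifest = {
        "n_participants": len(dataset.participants),
        "conditions": list(CONDITIONS),
        "check_sizes_arcmin": list(dataset.stimulus.check_sizes),
        "reversal_rate": dataset.stimulus.reversal_rate,
        "segment_length": dataset.stimulus.segment_length,
        "n_segments": dataset.stimulus.n_segments,
        "sampling_rate": dataset.stimulus.sampling_rate,
        "conversion_factor": dataset.conversion_factor,
        "peak_sf": dataset.peak_sf,
    }
    (out_dir / "cohort.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out_dir


def replace_participant(p: ParticipantModel, **changes) -> ParticipantModel:
    """Dataclass ``replace`` convenience for tests and what-if cohorts."""
    return replace(p, **changes)
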