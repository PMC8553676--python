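"""The :class:`Recording` container and its text/EDF readers and writers.

A recording is a single-channel EEG-like time series acquired while one
checkerboard check size was presented, plus the stimulus metadata needed
to analyse it. On disk a recording is a two-column CSV (``time_s``,
``amplitude_uV``) with a JSON sidecar carrying the metadata; EDF input is
supported when :mod:`mne` is installed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class Recording:
    """Single-condition SSVEP recording.

    Attributes
    ----------
    samples
        Time series in microvolts.
    sampling_rate
        Hz.
    reversal_rate
        Pattern reversals per second; the steady-state response's first
        harmonic sits at this frequency.
    check_size
        Check edge length in arc minutes.
    segment_length
        Segment duration in seconds used for averaging and artifact
        rejection.
    meta
        Free-form provenance (participant, condition, ground truth,
        inserted-artifact bookkeeping for synthetic data).
    """

    samples: np.ndarray
    sampling_rate: float
    reversal_rate: float
    check_size: float
    segment_length: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        n_per_seg = self.samples_per_segment
        if self.samples.size == 0 or self.samples.size % n_per_seg != 0:
            raise ValueError(
                f"recording length {self.samples.size} is not a whole number of "
                f"{n_per_seg}-sample segments"
            )

    @property
    def samples_per_segment(self) -> int:
        n = self.segment_length * self.sampling_rate
        if abs(n - round(n)) > 1e-9 or n <= 0:
            raise ValueError(
                "segment_length x sampling_rate must be a positive integer "
                f"number of samples, got {n}"
            )
        return int(round(n))

    @property
    def n_segments(self) -> int:
        return self.samples.size // self.samples_per_segment

    def segments(self) -> np.ndarray:
        """Segment matrix of shape (n_segments, samples_per_segment)."""
        return self.samples.reshape(self.n_segments, self.samples_per_segment)


def write_recording(recording: Recording, path: str | Path) -> Path:
    """Write a recording as CSV plus a ``.meta.json`` sidecar.

    Returns the CSV path. The sidecar holds stimulus metadata so the CSV
    alone round-trips through :func:`read_recording`.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    t = np.arange(recording.samples.size) / recording.sampling_rate
    df = pd.DataFrame({"time_s": t, "amplitude_uV": recording.samples})
    df.to_csv(path, index=False, float_format="%.9g")
    sidecar = {
        "sampling_rate": recording.sampling_rate,
        "reversal_rate": recording.reversal_rate,
        "check_size": recording.check_size,
        "segment_length": recording.segment_length,
        "meta": _jsonable(recording.meta),
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(sidecar, indent=1, sort_keys=True)
    )
    return path


def read_recording(path: str | Path) -> Recording:
    """Read a recording written by :func:`write_recording`."""
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".meta.json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"metadata sidecar not found: {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    df = pd.read_csv(path)
    return Recording(
        samples=df["amplitude_uV"].to_numpy(),
        sampling_rate=sidecar["sampling_rate"],
        reversal_rate=sidecar["reversal_rate"],
        check_size=sidecar["check_size"],
        segment_length=sidecar["segment_length"],
        meta=sidecar.get("meta", {}),
    )


def read_recording_edf(
    path: str | Path,
    *,
    reversal_rate: float,
    check_size: float,
    segment_length: float = 1.0,
    channel: int | str = 0,
) -> Recording:
    """Read the first (or named) channel of an EDF file as a Recording.

    Stimulus metadata is not part of EDF and must be supplied. Requires
    :mod:`mne`. Trailing samples that do not fill a whole segment are
    dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"EDF file not found: {path}")
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - mne is an optional extra
        raise ImportError("EDF input requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    picks = [channel] if isinstance(channel, str) else [raw.ch_names[channel]]
    data = raw.get_data(picks=picks)[0] * 1e6  # volts -> microvolts
    sfreq = float(raw.info["sfreq"])
    n_per_seg = int(round(segment_length * sfreq))
    n_whole = (data.size // n_per_seg) * n_per_seg
    if n_whole == 0:
        raise ValueError("EDF channel shorter than one segment")
    return Recording(
        samples=data[:n_whole],
        sampling_rate=sfreq,
        reversal_rate=reversal_rate,
        check_size=check_size,
        segment_length=segment_length,
        meta={"source": str(path)},
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
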