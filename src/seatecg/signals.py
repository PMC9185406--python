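"""Shared containers for sampled signals and detected beat series."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

#: Recognised channel roles: chest reference ECG, experimental thigh ECG,
#: and the two optical synchronisation channels.
CHANNEL_ROLES = ("REF", "EXP", "LED", "LUX")


@dataclass
class SignalRecord:
    """One channel of a uniformly sampled recording.

    Parameters
    ----------
    samples : ndarray
        Signal values in arbitrary units.
    fs : float
        Sampling rate in Hz, > 0.
    channel_role : str
        One of ``REF``, ``EXP``, ``LED``, ``LUX``.
    subject_id : str
        Token identifying the subject/session.
    t0 : float
        Session-clock time of the first sample, seconds.
    meta : dict
        Free-form metadata (e.g. ground-truth R-peak indices from the
        synthetic generator, under key ``"r_peaks_true"``).
    """

    samples: np.ndarray
    fs: float
    channel_role: str = "REF"
    subject_id: str = ""
    t0: float = 0.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.samples.size == 0:
            raise ValueError("samples must be non-empty")
        if self.channel_role not in CHANNEL_ROLES:
            raise ValueError(f"channel_role must be one of {CHANNEL_ROLES}")

    @property
    def duration(self) -> float:
        """Session length in seconds."""
        return self.samples.size / self.fs

    @property
    def time(self) -> np.ndarray:
        """Time axis in seconds (session clock)."""
        return self.t0 + np.arange(self.samples.size) / self.fs


@dataclass
class BeatSeries:
    """Detected R-peak indices and the derived NN-interval series.

    ``r_peaks`` are sample indices into the originating record, strictly
    increasing and at least 0.2 s apart (physiological refractory period).
    ``nn_intervals`` holds the seconds between successive peaks; it is
    empty when fewer than two peaks were found — rate statistics need at
    least two consecutive R peaks.
    """

    r_peaks: np.ndarray
    fs: float
    nn_intervals: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.r_peaks = np.asarray(self.r_peaks, dtype=np.int64)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.r_peaks.size > 1:
            d = np.diff(self.r_peaks)
            if np.any(d <= 0):
                raise ValueError("r_peaks must be strictly increasing")
            if np.any(d < 0.2 * self.fs):
                raise ValueError("consecutive r_peaks closer than 0.2 s")
            self.nn_intervals = d / self.fs
        else:
            self.nn_intervals = np.empty(0, dtype=float)

    def __len__(self) -> int:
        return int(self.r_peaks.size)

    @property
    def times(self) -> np.ndarray:
        """R-peak times in seconds."""
        return self.r_peaks / self.fs

    def instantaneous_hr(self) -> np.ndarray:
        """Instantaneous heart rate, 60/NN, in BPM (one value per interval)."""
        return 60.0 / self.nn_intervals
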